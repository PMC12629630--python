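"""Seeded synthetic inputs for both pipeline stages.

Real inputs to this package are AlphaFold-predicted complexes and DESeq2
contrast tables, neither of which can be regenerated at desk scale.  The
generators here produce structurally minimal stand-ins:

* **complex fixtures** — geometric scaffolds with just enough PDB
  semantics (two chains, residue names, atom names CA/O/SG) for every
  screening operation to run, with controllable inter-chain separation,
  clash load and catalytic-atom placement.  They are not physically
  realistic proteins; the screen is a geometry pipeline and correctness
  testing needs geometry, not rotamers.
* **DE contrast tables** — per-gene log2FC / adjusted-p tables with
  dependence-class structure planted directly (induced genes get a large
  positive log2FC and a tiny adjusted p; nulls sit near zero with adjusted
  p near 1).  Adjusted p values are planted rather than derived from
  simulated counts because the count-level pipeline (DESeq2 + BH) is
  consumed upstream, not modelled.

Every fixture ships with ground truth computed by independent oracles —
O(n²) clash enumeration, an exhaustive min-distance scan and a separately
written Shrake–Rupley evaluation at 4× quadrature density — never by the
production code path it is used to test.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deg_classifier as dc
from .structure_io import Atom, RadiiTable, StructureModel, load_radii_table
from .substrate_screen import FilterThresholds, VERDICT_PASS, VERDICT_REJECT

__all__ = [
    "FixtureParams",
    "FixtureTruth",
    "DEGSimParams",
    "generate_complex_fixture",
    "make_verdict_suite",
    "generate_de_tables",
    "write_de_tables",
    "brute_force_clash_count",
    "oracle_min_distance",
    "oracle_sasa",
    "oracle_bsa",
]

ORACLE_N_POINTS = 3840  # 4x the production default


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_clash_count(
    model: StructureModel, radii: RadiiTable, overlap_threshold: float = 0.4
) -> int:
    """O(n²) inter-chain clash enumeration, no spatial acceleration."""
    enz = [a for a in model.enzyme_atoms if not a.is_hydrogen]
    sub = [a for a in model.substrate_atoms if not a.is_hydrogen]
    count = 0
    for a in enz:
        ra = radii.radius(a.element)
        for b in sub:
            d = float(np.linalg.norm(np.asarray(a.coord) - np.asarray(b.coord)))
            if ra + radii.radius(b.element) - d >= overlap_threshold - 1e-9:
                count += 1
    return count


def oracle_min_distance(model: StructureModel, sg_coord: np.ndarray) -> float:
    """Exhaustive scan for the closest substrate heavy atom to SG."""
    best = np.inf
    for a in model.substrate_atoms:
        if a.is_hydrogen:
            continue
        best = min(best, float(np.linalg.norm(np.asarray(a.coord) - sg_coord)))
    return best


def oracle_sasa(
    atoms: list[Atom],
    radii: RadiiTable,
    probe: float = 1.4,
    n_points: int = ORACLE_N_POINTS,
) -> float:
    """Plain-loop Shrake–Rupley at high quadrature density.

    Written independently of the production implementation (no KD-tree,
    no neighbour pruning) to serve as a reference value.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    coords = np.array([a.coord for a in heavy], dtype=float)
    expanded = np.array([radii.radius(a.element) for a in heavy]) + probe
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    unit = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    total = 0.0
    for k in range(len(heavy)):
        test = coords[k] + expanded[k] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(heavy)):
            if j == k:
                continue
            # Exact skip: spheres that cannot intersect cannot occlude.
            if np.linalg.norm(coords[k] - coords[j]) >= expanded[k] + expanded[j]:
                continue
            exposed &= np.linalg.norm(test - coords[j], axis=1) >= expanded[j]
        total += 4.0 * np.pi * expanded[k] ** 2 * exposed.mean()
    return total


def oracle_bsa(model: StructureModel, radii: RadiiTable, probe: float = 1.4) -> float:
    """Reference buried interface area at oracle quadrature density."""
    enz = [a for a in model.enzyme_atoms if not a.is_hydrogen]
    sub = [a for a in model.substrate_atoms if not a.is_hydrogen]
    bsa = (
        oracle_sasa(enz, radii, probe)
        + oracle_sasa(sub, radii, probe)
        - oracle_sasa(enz + sub, radii, probe)
    ) / 2.0
    return max(bsa, 0.0)


# ---------------------------------------------------------------------------
# Complex fixtures
# ---------------------------------------------------------------------------

CATALYTIC_RES_SEQ = 139  # echoes Cys139 of AtMC4 so specs read naturally


@dataclass(frozen=True)
class FixtureParams:
    """Controls for one generated enzyme–substrate complex."""

    n_enzyme_atoms: int = 40
    n_substrate_atoms: int = 12
    separation: float = 10.0  # signed x offset between chain centroids, Å
    jitter: float = 0.0
    place_arg_lys: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enzyme_atoms < 1 or self.n_substrate_atoms < 1:
            raise ValueError("atom counts must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class FixtureTruth:
    """Oracle-computed ground truth for one fixture."""

    clash_count: int
    bsa: float
    min_distance: float
    designed_verdict: str
    designed_failed_filter: str


def _fixture_truth(
    model: StructureModel,
    radii: RadiiTable,
    thresholds: FilterThresholds,
) -> FixtureTruth:
    from .structure_io import CatalyticSiteSpec, locate_atom

    sg = locate_atom(model, CatalyticSiteSpec(model.enzyme_chain, CATALYTIC_RES_SEQ, "SG"))
    clashes = brute_force_clash_count(model, radii)
    bsa = oracle_bsa(model, radii)
    mind = oracle_min_distance(model, np.asarray(sg.coord))
    if clashes > thresholds.max_clashes:
        verdict, failed = VERDICT_REJECT, "clash"
    elif bsa < thresholds.min_interface:
        verdict, failed = VERDICT_REJECT, "interface"
    elif mind >= thresholds.max_catalytic_distance:
        verdict, failed = VERDICT_REJECT, "distance"
    else:
        verdict, failed = VERDICT_PASS, "none"
    return FixtureTruth(clashes, bsa, mind, verdict, failed)


def generate_complex_fixture(
    params: FixtureParams,
    radii: RadiiTable | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[StructureModel, FixtureTruth]:
    """One random two-chain fixture with oracle truth.

    The enzyme (chain A) is a compact carbon cluster carrying a CYS
    residue whose SG atom faces the substrate; the substrate (chain B) is
    a short peptide-like strand with main-chain O atoms, centred at
    ``separation`` along x.  Deterministic for a fixed seed.
    """
    radii = radii or load_radii_table()
    thresholds = thresholds or FilterThresholds()
    rng = np.random.default_rng(params.seed)
    atoms: list[Atom] = []
    serial = itertools.count(1)

    # Enzyme: carbons in a ball of radius ~4 A around the origin.
    cluster = rng.normal(0.0, 2.0, size=(params.n_enzyme_atoms, 3))
    for k, pos in enumerate(cluster, start=1):
        atoms.append(
            Atom(next(serial), "CA", "C", "ALA", k, "A", tuple(pos))
        )
    sg_pos = np.array([cluster[:, 0].max() + 1.0, 0.0, 0.0])
    atoms.append(
        Atom(next(serial), "SG", "S", "CYS", CATALYTIC_RES_SEQ, "A", tuple(sg_pos))
    )

    # Substrate: strand along y, backbone CA + carbonyl O per residue.
    res_names = (
        itertools.cycle(["LYS", "GLY", "ARG", "GLY"])
        if params.place_arg_lys
        else itertools.cycle(["GLY", "ALA"])
    )
    n_res = max(1, params.n_substrate_atoms // 2)
    for k in range(n_res):
        name = next(res_names)
        y = (k - (n_res - 1) / 2.0) * 3.8
        ca = np.array([params.separation, y, 0.0]) + rng.normal(0, params.jitter, 3)
        o = np.array([params.separation, y, 1.8]) + rng.normal(0, params.jitter, 3)
        atoms.append(Atom(next(serial), "CA", "C", name, k + 1, "B", tuple(ca)))
        atoms.append(Atom(next(serial), "O", "O", name, k + 1, "B", tuple(o)))

    model = StructureModel(atoms, "A", "B", label=f"fixture-seed{params.seed}")
    return model, _fixture_truth(model, radii, thresholds)


def _slab_model(
    n_side: int,
    gap: float,
    sg_front: bool,
    rng: np.random.Generator,
    spacing: float = 3.0,
    jitter: float = 0.01,
) -> StructureModel:
    """Two facing n×n carbon slabs; SG either at the interface or behind.

    The slab geometry gives a large, tunable interface: with the planes
    ``gap`` Å apart, each facing pair has vdW overlap 3.4 − gap, so
    gap 3.5 Å is contact without clash and gap 1.0 Å is a heavy clash
    load.  ``sg_front`` puts the catalytic SG 3.3 Å from the substrate's
    central atom; otherwise it sits 5 Å behind the enzyme slab.
    """
    atoms: list[Atom] = []
    serial = itertools.count(1)
    offsets = (np.arange(n_side) - (n_side - 1) / 2.0) * spacing
    res = itertools.count(1)
    for y in offsets:
        for z in offsets:
            pos = np.array([0.0, y, z]) + rng.normal(0, jitter, 3)
            atoms.append(Atom(next(serial), "CA", "C", "ALA", next(res), "A", tuple(pos)))
    sg = np.array([gap - 3.3 if sg_front else -5.0, 0.0, 0.0])
    atoms.append(Atom(next(serial), "SG", "S", "CYS", CATALYTIC_RES_SEQ, "A", tuple(sg)))
    res_b = itertools.count(1)
    names = itertools.cycle(["LYS", "GLY", "ARG"])
    for y in offsets:
        for z in offsets:
            pos = np.array([gap, y, z]) + rng.normal(0, jitter, 3)
            k = next(res_b)
            name = next(names)
            atoms.append(Atom(next(serial), "CA", "C", name, k, "B", tuple(pos)))
            if name in ("LYS", "ARG"):
                atoms.append(
                    Atom(next(serial), "O", "O", name, k, "B", tuple(pos + [0.0, 0.0, 1.23]))
                )
    return StructureModel(atoms, "A", "B")


def make_verdict_suite(
    seed: int = 0,
    radii: RadiiTable | None = None,
    thresholds: FilterThresholds | None = None,
    max_attempts: int = 4,
) -> dict[str, tuple[StructureModel, FixtureTruth]]:
    """Four oracle-validated fixtures, one per screening outcome.

    Labels: ``pass``, ``fail-clash``, ``fail-interface``, ``fail-distance``.
    Each fixture is checked against the independent oracles before being
    returned; if the designed verdict is not met (e.g. the slab is too
    small to bury 500 Å²) the slab size is grown over a bounded number of
    attempts.
    """
    radii = radii or load_radii_table()
    thresholds = thresholds or FilterThresholds()
    designs = {
        "pass": dict(gap=3.5, sg_front=True, expect="none"),
        "fail-clash": dict(gap=1.0, sg_front=True, expect="clash"),
        "fail-interface": dict(gap=100.0, sg_front=False, expect="interface"),
        "fail-distance": dict(gap=3.5, sg_front=False, expect="distance"),
    }
    suite: dict[str, tuple[StructureModel, FixtureTruth]] = {}
    for label, d in designs.items():
        last_truth = None
        for attempt in range(max_attempts):
            n_side = 9 + 2 * attempt
            rng = np.random.default_rng([seed, attempt, hash(label) % (2**31)])
            model = _slab_model(n_side, d["gap"], d["sg_front"], rng)
            model.label = label
            truth = _fixture_truth(model, radii, thresholds)
            last_truth = truth
            if truth.designed_failed_filter == d["expect"]:
                suite[label] = (model, truth)
                break
        else:
            raise RuntimeError(
                f"could not tune fixture {label!r} after {max_attempts} attempts; "
                f"last truth: {last_truth}"
            )
    return suite


def write_fixture(
    model: StructureModel, truth: FixtureTruth, out_dir: str | Path, stem: str
) -> None:
    """Write one fixture as PDB plus a truth JSON sidecar."""
    from .structure_io import write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_structure(model, out / f"{stem}.pdb")
    payload = {
        "clash_count": truth.clash_count,
        "bsa": truth.bsa,
        "min_distance": truth.min_distance,
        "designed_verdict": truth.designed_verdict,
        "designed_failed_filter": truth.designed_failed_filter,
    }
    (out / f"{stem}.truth.json").write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

# (class, pep1_status) keys the generator understands.  Pep status applies
# only to WT-significant classes; others take "not_applicable".
_PLANT_KEYS = [
    ("MC4_SPECIFIC", dc.PEP_PLUS),
    ("MC4_SPECIFIC", dc.PEP_MINUS),
    ("MC9_SPECIFIC", dc.PEP_PLUS),
    ("MC9_SPECIFIC", dc.PEP_MINUS),
    ("CO_DEPENDENT", dc.PEP_PLUS),
    ("CO_DEPENDENT", dc.PEP_MINUS),
    ("MC_INDEPENDENT", dc.PEP_PLUS),
    ("MC_INDEPENDENT", dc.PEP_MINUS),
    ("MC9_REPRESSED", dc.PEP_NA),
    ("MC4_ONLY_MUTANT", dc.PEP_NA),
    ("BOTH_MUTANTS_ONLY", dc.PEP_NA),
]

# Wound-contrast membership (WT, m4, m9) per class.
_CLASS_MEMBERSHIP = {
    "MC4_SPECIFIC": (True, False, True),
    "MC9_SPECIFIC": (True, True, False),
    "CO_DEPENDENT": (True, False, False),
    "MC_INDEPENDENT": (True, True, True),
    "MC9_REPRESSED": (False, False, True),
    "MC4_ONLY_MUTANT": (False, True, False),
    "BOTH_MUTANTS_ONLY": (False, True, True),
}


@dataclass(frozen=True)
class DEGSimParams:
    """Planted-effect design for synthetic contrast tables.

    Defaults mirror a clean DESeq2 outcome: induced genes at log2FC ≈ 4
    with adjusted p 1e-6, nulls near 0 with adjusted p 0.99 — far from
    the 2/0.05 calling thresholds on both sides.
    """

    n_per_class: dict[tuple[str, str], int] = field(
        default_factory=lambda: {k: 10 for k in _PLANT_KEYS}
    )
    n_null: int = 1000
    induced_lfc_mean: float = 4.0
    induced_lfc_sd: float = 0.25
    null_lfc_sd: float = 0.2
    induced_padj: float = 1e-6
    null_padj: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        for key, n in self.n_per_class.items():
            if key not in _PLANT_KEYS:
                raise ValueError(f"unknown plant key {key!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")
        if self.n_null < 0:
            raise ValueError("n_null must be >= 0")


def generate_de_tables(
    params: DEGSimParams,
) -> tuple[dict[tuple[str, str], dc.ContrastTable], pd.DataFrame]:
    """Synthetic contrast tables with planted dependence classes.

    Returns contrast tables keyed by (genotype, treatment) for the wound
    and Pep1 treatments of all three genotypes, and a truth table
    (gene_id, dependence_class, pep1_status, marker_group) derived from
    the planted design, not from the classifier.  Pep1-responsive genes
    are induced in the Pep1 contrast of every genotype; the classifier
    only consults the WT one.
    """
    rng = np.random.default_rng(params.seed)
    genes: list[tuple[str, str, str]] = []  # gene_id, class, pep_status
    counter = itertools.count(1)
    for (cls, pep), n in sorted(params.n_per_class.items()):
        for _ in range(n):
            genes.append((f"G{next(counter):06d}", cls, pep))
    for _ in range(params.n_null):
        genes.append((f"G{next(counter):06d}", "NOT_DEG", dc.PEP_NA))

    contrast_keys = [
        (g, t) for g in dc.GENOTYPES for t in ("wound", "Pep1")
    ]
    columns: dict[tuple[str, str], list[tuple[str, float, float]]] = {
        k: [] for k in contrast_keys
    }
    truth_rows = []
    for gene_id, cls, pep in genes:
        if cls == "NOT_DEG":
            member = (False, False, False)
        else:
            member = _CLASS_MEMBERSHIP[cls]
        wt_sig = member[0]
        pep_status = pep if wt_sig else dc.PEP_NA
        group = dc.assign_marker_group(dc.DependenceClass(cls), pep_status).value
        truth_rows.append((gene_id, cls, pep_status, group))
        for (genotype, treatment) in contrast_keys:
            gi = dc.GENOTYPES.index(genotype)
            if treatment == "wound":
                induced = member[gi]
            else:
                induced = pep == dc.PEP_PLUS
            if induced:
                lfc = rng.normal(params.induced_lfc_mean, params.induced_lfc_sd)
                padj = params.induced_padj
            else:
                lfc = rng.normal(0.0, params.null_lfc_sd)
                padj = params.null_padj
            columns[(genotype, treatment)].append((gene_id, lfc, padj))

    tables = {
        key: dc.ContrastTable(
            key[0],
            key[1],
            pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"]),
        )
        for key, rows in columns.items()
    }
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "dependence_class", "pep1_status", "marker_group"]
    )
    return tables, truth


def write_de_tables(
    tables: dict[tuple[str, str], dc.ContrastTable],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write contrast TSVs, truth labels and a manifest the CLI can read."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for (genotype, treatment), table in sorted(tables.items()):
        safe = f"{genotype}_{treatment}".replace("+", "-")
        fname = f"{safe}.tsv"
        df = table.data.copy()
        df.columns = ["gene_id", "log2FoldChange", "padj"]
        df.to_csv(out / fname, sep="\t", index=False, float_format="%.6g")
        manifest[fname] = {"genotype": genotype, "treatment": treatment}
    truth.sort_values("gene_id").to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
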