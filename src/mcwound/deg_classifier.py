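"""Dependence-class partition of wound/elicitor-induced DEGs.

Wounding induces a transcriptome response in Arabidopsis that is largely
routed through the type II metacaspases AtMC4 and AtMC9.  Comparing the
significant gene sets of the same contrast in WT, *atmc4-1* and *atmc9-1*
plants places every differentially expressed gene in one of the 2³ Venn
cells over (WT, m4, m9) significance:

======================  =========================  =============================
class                   membership (WT, m4, m9)    reading
======================  =========================  =============================
MC4_SPECIFIC            (1, 0, 1)                  requires AtMC4 alone
MC9_SPECIFIC            (1, 1, 0)                  requires AtMC9 alone
CO_DEPENDENT            (1, 0, 0)                  requires both MCs
MC_INDEPENDENT          (1, 1, 1)                  induced regardless of MCs
MC9_REPRESSED           (0, 0, 1)                  de-repressed without AtMC9
MC4_ONLY_MUTANT         (0, 1, 0)                  de-repressed without AtMC4
BOTH_MUTANTS_ONLY       (0, 1, 1)                  repressed by either MC in WT
NOT_DEG                 (0, 0, 0)                  not significant anywhere
======================  =========================  =============================

"Dependent on an MC" is operationalised purely set-theoretically:
significant in WT and not significant in the corresponding mutant under
the same rule.  WT-significant genes are further annotated as Pep1+
(also significant in the WT Pep1-infiltration contrast, optionally
union'd with Propep1+wound) or Pep1−, and AtMC4-dependent genes map onto
marker Groups 1–4 (Group 1 = MC4-specific ∧ Pep1+, Group 2 = co-dependent
∧ Pep1+, Groups 3/4 their Pep1− counterparts).

Significance uses strict thresholds as printed: log2FC > cutoff (or
< −cutoff for the repressed direction) and adjusted p < 0.05; genes with
missing adjusted p, or absent from a contrast table, count as not
significant there.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DependenceClass",
    "MarkerGroup",
    "SignificanceRule",
    "ContrastTable",
    "PartitionResult",
    "read_contrast_table",
    "significant_set",
    "venn_partition",
    "pep1_split",
    "derepressed_set",
    "assign_marker_group",
    "classify_contrasts",
    "summarize_partition",
    "round_percent",
]

GENOTYPES = ("WT", "atmc4-1", "atmc9-1")
TREATMENTS = ("wound", "water", "Pep1", "Propep1+wound", "flg22")

# DESeq2 export headers accepted as aliases for the canonical columns.
_COLUMN_ALIASES = {
    "gene_id": ("gene_id", "gene", "id", "row", ""),
    "log2fc": ("log2fc", "log2foldchange", "log2_fold_change", "lfc"),
    "padj": ("padj", "p_adj", "fdr", "qvalue", "adj_p"),
}


class DependenceClass(enum.Enum):
    MC4_SPECIFIC = "MC4_SPECIFIC"
    MC9_SPECIFIC = "MC9_SPECIFIC"
    CO_DEPENDENT = "CO_DEPENDENT"
    MC_INDEPENDENT = "MC_INDEPENDENT"
    MC9_REPRESSED = "MC9_REPRESSED"
    MC4_ONLY_MUTANT = "MC4_ONLY_MUTANT"
    BOTH_MUTANTS_ONLY = "BOTH_MUTANTS_ONLY"
    NOT_DEG = "NOT_DEG"


# Venn-cell membership (in WT, in m4, in m9) -> class.
_VENN_MAP = {
    (True, False, True): DependenceClass.MC4_SPECIFIC,
    (True, True, False): DependenceClass.MC9_SPECIFIC,
    (True, False, False): DependenceClass.CO_DEPENDENT,
    (True, True, True): DependenceClass.MC_INDEPENDENT,
    (False, False, True): DependenceClass.MC9_REPRESSED,
    (False, True, False): DependenceClass.MC4_ONLY_MUTANT,
    (False, True, True): DependenceClass.BOTH_MUTANTS_ONLY,
    (False, False, False): DependenceClass.NOT_DEG,
}

# Classes in which the gene required AtMC4 (significant in WT, lost in atmc4-1).
MC4_DEPENDENT_CLASSES = (DependenceClass.MC4_SPECIFIC, DependenceClass.CO_DEPENDENT)


class MarkerGroup(enum.Enum):
    GROUP1 = "GROUP1"  # MC4-specific, Pep1-responsive
    GROUP2 = "GROUP2"  # co-dependent, Pep1-responsive
    GROUP3 = "GROUP3"  # MC4-specific, Pep1-independent
    GROUP4 = "GROUP4"  # co-dependent, Pep1-independent
    NONE = "NONE"


PEP_PLUS = "pep_plus"
PEP_MINUS = "pep_minus"
PEP_NA = "not_applicable"


@dataclass(frozen=True)
class SignificanceRule:
    """Thresholds for calling a gene differentially expressed.

    ``lfc_cutoff`` is 2 for the standard analysis and 3 for the
    high-stringency one; ``direction`` selects induced (log2FC > cutoff)
    or repressed (log2FC < −cutoff) genes.
    """

    lfc_cutoff: float = 2.0
    padj_cutoff: float = 0.05
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.lfc_cutoff <= 0:
            raise ValueError("lfc_cutoff must be positive")
        if not (0.0 < self.padj_cutoff < 1.0):
            raise ValueError("padj_cutoff must be in (0, 1)")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass
class ContrastTable:
    """Per-gene log2FC and adjusted p for one genotype × treatment contrast."""

    genotype: str
    treatment: str
    data: pd.DataFrame  # columns: gene_id, log2fc, padj (padj may be NaN)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.data["gene_id"].duplicated().any():
            dupes = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in contrast: {dupes[:5]}")


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename: dict[str, str] = {}
    lowered = {c: c.strip().lower().replace(" ", "_") for c in df.columns}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for col, low in lowered.items():
            if low in aliases:
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    missing = [c for c in ("gene_id", "log2fc", "padj") if c not in df.columns]
    if missing:
        raise ValueError(f"contrast table missing columns: {missing}")
    out = df[["gene_id", "log2fc", "padj"]].copy()
    out["gene_id"] = out["gene_id"].astype(str)
    out["log2fc"] = pd.to_numeric(out["log2fc"], errors="raise")
    out["padj"] = pd.to_numeric(out["padj"], errors="coerce")
    return out


def read_contrast_table(path: str | Path, genotype: str, treatment: str) -> ContrastTable:
    """Read a DESeq2-style TSV (gene_id, log2FoldChange, padj) contrast."""
    df = pd.read_csv(path, sep="\t")
    return ContrastTable(genotype, treatment, _canonical_columns(df))


def significant_set(table: ContrastTable, rule: SignificanceRule) -> set[str]:
    """Gene ids passing the fold-change and adjusted-p thresholds.

    Strict inequalities; missing adjusted p excludes the gene.
    """
    df = table.data
    sig_p = df["padj"].notna() & (df["padj"] < rule.padj_cutoff)
    if rule.direction == "up":
        sig_fc = df["log2fc"] > rule.lfc_cutoff
    else:
        sig_fc = df["log2fc"] < -rule.lfc_cutoff
    return set(df.loc[sig_p & sig_fc, "gene_id"])


def venn_partition(
    wt_set: set[str], m4_set: set[str], m9_set: set[str]
) -> dict[str, DependenceClass]:
    """Assign every gene in the union to its Venn cell."""
    out: dict[str, DependenceClass] = {}
    for gene in wt_set | m4_set | m9_set:
        out[gene] = _VENN_MAP[(gene in wt_set, gene in m4_set, gene in m9_set)]
    return out


def pep1_split(mc4_dependent: set[str], pep1_wt: set[str]) -> tuple[set[str], set[str]]:
    """Partition AtMC4-dependent genes into Pep1-responsive and not."""
    pep_plus = mc4_dependent & pep1_wt
    return pep_plus, mc4_dependent - pep_plus


def derepressed_set(wt_set: set[str], mutant_set: set[str]) -> set[str]:
    """Genes significant in a mutant but not WT — normally MC-repressed."""
    return mutant_set - wt_set


def assign_marker_group(cls: DependenceClass, pep1_status: str) -> MarkerGroup:
    """Map dependence class × Pep1 status onto marker Groups 1–4."""
    table = {
        (DependenceClass.MC4_SPECIFIC, PEP_PLUS): MarkerGroup.GROUP1,
        (DependenceClass.CO_DEPENDENT, PEP_PLUS): MarkerGroup.GROUP2,
        (DependenceClass.MC4_SPECIFIC, PEP_MINUS): MarkerGroup.GROUP3,
        (DependenceClass.CO_DEPENDENT, PEP_MINUS): MarkerGroup.GROUP4,
    }
    return table.get((cls, pep1_status), MarkerGroup.NONE)


@dataclass
class PartitionResult:
    """Per-gene assignments plus per-class/per-group counts."""

    assignments: pd.DataFrame  # gene_id, dependence_class, pep1_status, marker_group
    class_counts: dict[str, int]
    group_counts: dict[str, int]
    pep_plus_percent: float | None  # % of MC4-dependent genes that are Pep1+

    def to_tsv(self) -> str:
        df = self.assignments.sort_values("gene_id")
        return df.to_csv(sep="\t", index=False)

    def summary_json(self) -> str:
        mc4_dep = sum(
            self.class_counts.get(c.value, 0) for c in MC4_DEPENDENT_CLASSES
        )
        payload = {
            "class_counts": self.class_counts,
            "group_counts": self.group_counts,
            "n_mc4_dependent": mc4_dep,
            "pep_plus_percent": self.pep_plus_percent,
            "pep_plus_percent_rounded": (
                round_percent(self.pep_plus_percent)
                if self.pep_plus_percent is not None
                else None
            ),
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def round_percent(value: float) -> int:
    """Round a percentage half-up to an integer (128/377 → 34)."""
    return int(math.floor(value + 0.5))


def classify_contrasts(
    tables: Mapping[tuple[str, str], ContrastTable],
    rule: SignificanceRule | None = None,
    pep_plus_mode: str = "pep1_only",
) -> PartitionResult:
    """Run the full partition over a set of contrast tables.

    ``tables`` is keyed by (genotype, treatment).  The three wound (or
    water) contrasts are required; Pep1 (and optionally Propep1+wound)
    WT contrasts drive the Pep1± annotation — without them every gene is
    annotated ``not_applicable`` and marker groups are NONE.
    """
    rule = rule or SignificanceRule()
    if pep_plus_mode not in ("pep1_only", "pep1_or_propep1"):
        raise ValueError(f"unknown pep_plus_mode {pep_plus_mode!r}")

    def sig(genotype: str, treatment: str) -> set[str] | None:
        table = tables.get((genotype, treatment))
        return None if table is None else significant_set(table, rule)

    wt = sig("WT", "wound")
    m4 = sig("atmc4-1", "wound")
    m9 = sig("atmc9-1", "wound")
    if wt is None or m4 is None or m9 is None:
        raise ValueError("wound contrasts for WT, atmc4-1 and atmc9-1 are required")

    classes = venn_partition(wt, m4, m9)

    pep1_wt = sig("WT", "Pep1")
    if pep_plus_mode == "pep1_or_propep1":
        propep = sig("WT", "Propep1+wound")
        if pep1_wt is not None and propep is not None:
            pep1_wt = pep1_wt | propep
    have_pep = pep1_wt is not None

    rows = []
    for gene in sorted(classes):
        cls = classes[gene]
        if have_pep and gene in wt:
            status = PEP_PLUS if gene in pep1_wt else PEP_MINUS
        else:
            status = PEP_NA
        group = assign_marker_group(cls, status)
        rows.append((gene, cls.value, status, group.value))
    assignments = pd.DataFrame(
        rows, columns=["gene_id", "dependence_class", "pep1_status", "marker_group"]
    )
    return summarize_partition(assignments)


def summarize_partition(assignments: pd.DataFrame) -> PartitionResult:
    """Count classes and marker groups; derive the Pep1+ share.

    ``pep_plus_percent`` is the share of AtMC4-dependent genes
    (MC4-specific + co-dependent) annotated Pep1+, in percent at full
    precision; the JSON summary also carries the half-up integer
    rounding used for reporting.  Empty partitions report null.
    """
    class_counts = {c.value: 0 for c in DependenceClass if c is not DependenceClass.NOT_DEG}
    for value, n in assignments["dependence_class"].value_counts().items():
        class_counts[value] = class_counts.get(value, 0) + int(n)
    group_counts = {g.value: 0 for g in MarkerGroup if g is not MarkerGroup.NONE}
    for value, n in assignments["marker_group"].value_counts().items():
        if value != MarkerGroup.NONE.value:
            group_counts[value] = int(n)
    dep_values = [c.value for c in MC4_DEPENDENT_CLASSES]
    dep_mask = assignments["dependence_class"].isin(dep_values)
    n_dep = int(dep_mask.sum())
    if n_dep == 0:
        pep_pct: float | None = None
    else:
        n_plus = int((assignments.loc[dep_mask, "pep1_status"] == PEP_PLUS).sum())
        pep_pct = 100.0 * n_plus / n_dep
    return PartitionResult(assignments, class_counts, group_counts, pep_pct)
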