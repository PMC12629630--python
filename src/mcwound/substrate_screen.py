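"""The three-filter substrate screen and the enzyme × substrate matrix.

A candidate complex is accepted as a predicted cleavage pair only if, in
order: (1) it has at most 50 inter-chain clashes, (2) its buried interface
area is at least 500 Å², and (3) the catalytic SG sits closer than 4.5 Å
to the substrate.  Boundaries are strict as printed: reject if clashes
> 50, if BSA < 500, or if distance >= 4.5.  All three metrics are computed
for every pair regardless of the verdict — only the verdict itself
short-circuits — so rejected pairs still carry full metrics and candidate
P1 sites.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .interface_metrics import (
    DEFAULT_N_POINTS,
    DEFAULT_OVERLAP_THRESHOLD,
    DEFAULT_PROBE,
    buried_interface_area,
    catalytic_geometry,
    count_clashes,
)
from .structure_io import CatalyticSiteSpec, RadiiTable, StructureModel, read_structure

__all__ = [
    "FilterThresholds",
    "ScreenMetrics",
    "ScreenDecision",
    "PredictionMatrix",
    "apply_filters",
    "screen_pair",
    "screen_batch",
    "parse_pair_label",
]

VERDICT_PASS = "predicted-substrate"
VERDICT_REJECT = "rejected"

_LABEL_RE = re.compile(r"^(?P<enzyme>[^_]+(?:_[^_]+)*?)__(?P<substrate>.+)$")


@dataclass(frozen=True)
class FilterThresholds:
    """The screen's three cutoffs (defaults as published)."""

    max_clashes: int = 50
    min_interface: float = 500.0
    max_catalytic_distance: float = 4.5

    def __post_init__(self) -> None:
        if self.max_clashes <= 0 or self.min_interface <= 0 or self.max_catalytic_distance <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ScreenMetrics:
    clash_count: int
    bsa: float
    min_distance: float
    best_site: tuple[int, str, float] | None = None
    candidates: tuple[tuple[int, str, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "clash_count": self.clash_count,
            "bsa": self.bsa,
            "min_distance": self.min_distance,
            "best_site": list(self.best_site) if self.best_site else None,
            "candidates": [list(c) for c in self.candidates],
        }


@dataclass(frozen=True)
class ScreenDecision:
    verdict: str
    failed_filter: str  # "none" | "clash" | "interface" | "distance"

    def __post_init__(self) -> None:
        ok = (self.verdict == VERDICT_PASS) == (self.failed_filter == "none")
        if not ok:
            raise ValueError("verdict/failed_filter inconsistent")


def apply_filters(metrics: ScreenMetrics, thresholds: FilterThresholds) -> ScreenDecision:
    """Apply the three filters in order and report the first failure."""
    if metrics.clash_count > thresholds.max_clashes:
        return ScreenDecision(VERDICT_REJECT, "clash")
    if metrics.bsa < thresholds.min_interface:
        return ScreenDecision(VERDICT_REJECT, "interface")
    if metrics.min_distance >= thresholds.max_catalytic_distance:
        return ScreenDecision(VERDICT_REJECT, "distance")
    return ScreenDecision(VERDICT_PASS, "none")


def screen_pair(
    model: StructureModel,
    site: CatalyticSiteSpec,
    thresholds: FilterThresholds | None = None,
    radii: RadiiTable | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    halve_bsa: bool = True,
) -> tuple[ScreenMetrics, ScreenDecision]:
    """Compute all metrics for one complex and decide its verdict."""
    from .structure_io import load_radii_table

    thresholds = thresholds or FilterThresholds()
    radii = radii or load_radii_table()
    clashes = count_clashes(model, radii, overlap_threshold)
    bsa = buried_interface_area(model, radii, probe, n_points, halve_bsa=halve_bsa)
    geom = catalytic_geometry(model, site)
    metrics = ScreenMetrics(
        clash_count=clashes.clash_count,
        bsa=bsa,
        min_distance=geom.min_distance,
        best_site=geom.site_candidates[0] if geom.site_candidates else None,
        candidates=tuple(geom.site_candidates),
    )
    return metrics, apply_filters(metrics, thresholds)


def parse_pair_label(stem: str) -> tuple[str, str]:
    """Split ``<enzyme>__<substrate>`` file stems into the pair labels."""
    if "__" not in stem:
        raise ValueError(f"cannot parse pair label from {stem!r} (expected ENZ__SUB)")
    enzyme, _, substrate = stem.partition("__")
    if not enzyme or not substrate:
        raise ValueError(f"cannot parse pair label from {stem!r} (expected ENZ__SUB)")
    return enzyme, substrate


@dataclass
class PredictionMatrix:
    """Enzymes × substrates verdict grid with per-cell metrics."""

    enzymes: list[str]
    substrates: list[str]
    cells: dict[tuple[str, str], tuple[ScreenMetrics, ScreenDecision]]

    def verdict(self, enzyme: str, substrate: str) -> str | None:
        cell = self.cells.get((enzyme, substrate))
        return cell[1].verdict if cell else None

    def to_tsv(self) -> str:
        lines = ["\t".join(["enzyme"] + self.substrates)]
        for enz in self.enzymes:
            row = [enz]
            for sub in self.substrates:
                cell = self.cells.get((enz, sub))
                row.append(cell[1].verdict if cell else "missing")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "enzymes": self.enzymes,
            "substrates": self.substrates,
            "pairs": {
                f"{enz}__{sub}": {
                    **metrics.to_dict(),
                    "verdict": decision.verdict,
                    "failed_filter": decision.failed_filter,
                }
                for (enz, sub), (metrics, decision) in sorted(self.cells.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def screen_batch(
    inputs: list[tuple[str, str, StructureModel, CatalyticSiteSpec]],
    thresholds: FilterThresholds | None = None,
    radii: RadiiTable | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> PredictionMatrix:
    """Screen labelled (enzyme, substrate, model, site) tuples into a matrix.

    Verdicts are a pure per-pair function; duplicate pairs are an error.
    """
    enzymes: list[str] = []
    substrates: list[str] = []
    cells: dict[tuple[str, str], tuple[ScreenMetrics, ScreenDecision]] = {}
    for enz, sub, model, site in inputs:
        key = (enz, sub)
        if key in cells:
            raise ValueError(f"duplicate pair {enz}__{sub}")
        if enz not in enzymes:
            enzymes.append(enz)
        if sub not in substrates:
            substrates.append(sub)
        cells[key] = screen_pair(model, site, thresholds, radii, probe, n_points)
    return PredictionMatrix(enzymes, substrates, cells)
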