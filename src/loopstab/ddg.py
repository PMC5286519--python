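"""Predicted-ΔΔG organisation and prediction-vs-experiment zone analysis.

Predicted stability changes (ΔΔG, negative = stabilising) for point
mutations are consumed from tables produced by an external predictor; this
module enumerates saturation libraries, ranks predictions, cross-tabulates
predicted sign against the experimental stability outcome (relative to wild
type = 1) into four zones, and reports the qualitative prediction accuracy.

Zone conventions (wild type at the cross centre):
  I   ΔΔG > 0, outcome < 1 — correctly predicted destabilising
  II  ΔΔG > 0, outcome > 1 — incorrect
  III ΔΔG < 0, outcome < 1 — incorrect
  IV  ΔΔG < 0, outcome > 1 — correctly predicted stabilising
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .turns import _AA1

__all__ = [
    "DdgRecord",
    "VariantOutcome",
    "ZoneClassification",
    "SaturationGrid",
    "parse_variant",
    "enumerate_saturation",
    "classify_zone",
    "classify_zones",
    "accuracy",
    "rank_ddg",
    "export_heatmap_table",
    "read_heatmap_table",
    "read_ddg_csv",
    "read_outcome_csv",
]

AMINO_ACIDS = tuple(sorted(_AA1))  # 20 one-letter codes, alphabetical

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_variant(variant: str) -> tuple[str, int, str]:
    """Split ``"X123Y"`` into (wild-type, position, mutant)."""
    m = _VARIANT_RE.match(variant.strip().upper())
    if not m:
        raise ValueError(f"cannot parse variant name {variant!r}")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if wt not in _AA1 or mut not in _AA1:
        raise ValueError(f"non-standard residue in variant {variant!r}")
    return wt, pos, mut


@dataclass(frozen=True)
class DdgRecord:
    """One predicted stability change; negative ΔΔG = predicted stabilising."""

    variant: str
    ddg: float

    def __post_init__(self):
        wt, _, mut = parse_variant(self.variant)
        if wt == mut:
            raise ValueError(f"variant {self.variant!r} proposes the wild type")

    @property
    def position(self) -> int:
        return parse_variant(self.variant)[1]

    @property
    def wt_residue(self) -> str:
        return parse_variant(self.variant)[0]

    @property
    def mutant_residue(self) -> str:
        return parse_variant(self.variant)[2]


@dataclass(frozen=True)
class VariantOutcome:
    """Experimental stability outcome relative to wild type (= 1)."""

    variant: str
    relative_stability: float
    measure_kind: str = "residual_activity"  # or "tm"

    def __post_init__(self):
        if self.measure_kind not in ("residual_activity", "tm"):
            raise ValueError(f"unknown measure kind {self.measure_kind!r}")
        if self.measure_kind == "residual_activity" and self.relative_stability <= 0:
            raise ValueError("residual-activity ratios must be positive")


@dataclass(frozen=True)
class ZoneClassification:
    variant: str
    zone: str  # "I" | "II" | "III" | "IV" | "indeterminate"
    concordant: bool

    def __post_init__(self):
        if self.zone not in ("I", "II", "III", "IV", "indeterminate"):
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.zone != "indeterminate" and self.concordant != (self.zone in ("I", "IV")):
            raise ValueError("concordance must match zone membership")


@dataclass
class SaturationGrid:
    """Every single substitution at a set of positions (19 per position)."""

    positions: list[tuple[int, str]]  # (residue_number, wt 1-letter)
    ddg: dict[str, float]

    @property
    def variants(self) -> list[str]:
        out = []
        for pos, wt in self.positions:
            out.extend(f"{wt}{pos}{aa}" for aa in AMINO_ACIDS if aa != wt)
        return out

    @property
    def n_variants(self) -> int:
        return 19 * len(self.positions)

    def fill(self, records: Sequence[DdgRecord]) -> None:
        known = set(self.variants)
        for rec in records:
            if rec.variant not in known:
                raise ValueError(f"variant {rec.variant!r} outside the grid")
            self.ddg[rec.variant] = rec.ddg

    def records(self) -> list[DdgRecord]:
        return [DdgRecord(v, g) for v, g in self.ddg.items()]


def enumerate_saturation(positions: Sequence[tuple[int, str]]) -> SaturationGrid:
    """Grid of all single substitutions: 19 non-wild-type residues per
    position (49 positions -> 931 variants)."""
    seen = set()
    cleaned = []
    for pos, wt in positions:
        wt = wt.upper()
        if wt not in _AA1:
            raise ValueError(f"non-standard wild-type residue {wt!r} at {pos}")
        if pos in seen:
            raise ValueError(f"duplicate position {pos}")
        seen.add(pos)
        cleaned.append((int(pos), wt))
    return SaturationGrid(cleaned, {})


def classify_zone(
    ddg: DdgRecord,
    outcome: VariantOutcome,
    stability_tolerance: float = 0.0,
) -> ZoneClassification:
    """Place one variant in the 2x2 prediction-vs-experiment zone chart.

    With the default tolerance of 0 the inequalities are strict and ties
    (ΔΔG exactly 0, or outcome exactly 1) are flagged indeterminate; a
    positive tolerance widens the indeterminate band around outcome = 1.
    """
    if ddg.variant != outcome.variant:
        raise ValueError(
            f"record mismatch: {ddg.variant!r} vs {outcome.variant!r}")
    tol = stability_tolerance
    stab = outcome.relative_stability
    if ddg.ddg == 0 or abs(stab - 1.0) <= tol or (tol == 0 and stab == 1.0):
        return ZoneClassification(ddg.variant, "indeterminate", False)
    improved = stab > 1.0
    if ddg.ddg > 0:
        zone = "II" if improved else "I"
    else:
        zone = "IV" if improved else "III"
    return ZoneClassification(ddg.variant, zone, zone in ("I", "IV"))


def classify_zones(
    records: Sequence[DdgRecord],
    outcomes: Sequence[VariantOutcome],
    stability_tolerance: float = 0.0,
) -> list[ZoneClassification]:
    """Classify every variant present in both tables (matched by name)."""
    by_variant = {o.variant: o for o in outcomes}
    out = []
    for rec in records:
        if rec.variant in by_variant:
            out.append(classify_zone(rec, by_variant[rec.variant], stability_tolerance))
    return out


def accuracy(classifications: Sequence[ZoneClassification]) -> dict:
    """Qualitative prediction accuracy: percent of determinate variants in
    the concordant zones (I and IV).

    Returns the raw fraction, the percentage rounded to one decimal, the
    per-zone counts, and how many indeterminates were excluded.
    """
    determinate = [c for c in classifications if c.zone != "indeterminate"]
    if not determinate:
        raise ValueError("no determinate classifications to score")
    counts = {z: sum(1 for c in determinate if c.zone == z) for z in ("I", "II", "III", "IV")}
    n_conc = counts["I"] + counts["IV"]
    frac = n_conc / len(determinate)
    return {
        "n": len(determinate),
        "n_concordant": n_conc,
        "fraction": frac,
        "percent": round(100.0 * frac, 1),
        "zone_counts": counts,
        "n_indeterminate": len(classifications) - len(determinate),
    }


def rank_ddg(records: Sequence[DdgRecord]) -> list[DdgRecord]:
    """Ascending ΔΔG (most stabilising first); ties break lexicographically
    by variant name."""
    return sorted(records, key=lambda r: (r.ddg, r.variant))


def export_heatmap_table(grid: SaturationGrid, path: str | Path) -> pd.DataFrame:
    """Positions x 20-residue ΔΔG matrix for external plotting.

    Wild-type cells are marked "WT"; unfilled cells are empty.  The written
    TSV round-trips through :func:`read_heatmap_table`.
    """
    rows = []
    for pos, wt in grid.positions:
        row: dict[str, object] = {"position": pos, "wt": wt}
        for aa in AMINO_ACIDS:
            if aa == wt:
                row[aa] = "WT"
            else:
                row[aa] = grid.ddg.get(f"{wt}{pos}{aa}", "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=["position", "wt", *AMINO_ACIDS])
    df.to_csv(path, sep="\t", index=False)
    return df


def read_heatmap_table(path: str | Path) -> SaturationGrid:
    df = pd.read_csv(path, sep="\t", dtype={"wt": str})
    positions = [(int(r.position), str(r.wt)) for r in df.itertuples(index=False)]
    grid = enumerate_saturation(positions)
    for r in df.itertuples(index=False):
        for aa in AMINO_ACIDS:
            val = getattr(r, aa)
            if isinstance(val, str) and (val == "WT" or not val.strip()):
                continue
            if pd.isna(val):
                continue
            grid.ddg[f"{r.wt}{int(r.position)}{aa}"] = float(val)
    return grid


def read_ddg_csv(path: str | Path) -> list[DdgRecord]:
    """Read a ``variant,ddg`` CSV."""
    df = pd.read_csv(path)
    return [DdgRecord(str(r.variant), float(r.ddg)) for r in df.itertuples(index=False)]


def read_outcome_csv(path: str | Path) -> list[VariantOutcome]:
    """Read a ``variant,relative_stability,measure_kind`` CSV."""
    df = pd.read_csv(path)
    return [
        VariantOutcome(str(r.variant), float(r.relative_stability),
                       str(getattr(r, "measure_kind", "residual_activity")))
        for r in df.itertuples(index=False)
    ]


def summary_json(classifications: Sequence[ZoneClassification], path: str | Path) -> dict:
    """Write the accuracy summary as JSON and return it."""
    summary = accuracy(classifications)
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary
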