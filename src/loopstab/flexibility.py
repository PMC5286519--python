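"""Per-residue and per-loop flexibility measures.

Two flexibility proxies are supported: crystallographic B-factors (averaged
over the non-hydrogen atoms of each residue, optionally averaged across the
two chains of a homodimer) and root-mean-square fluctuations (RMSF) computed
from a coordinate ensemble standing in for an MD trajectory.  Because the
absolute RMSF baseline varies between independent runs, RMSF profiles are
normalized by the whole-protein mean before runs or temperatures are
compared; the temperature differential (ΔRMSF, high minus low) ranks loops
by thermal sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import AtomRecord, LoopDefinition, StructureModel

__all__ = [
    "FlexibilityProfile",
    "CoordinateEnsemble",
    "LoopFlexibilitySummary",
    "residue_bfactor",
    "loop_bfactor",
    "rmsf",
    "normalize_rmsf",
    "average_profiles",
    "delta_rmsf",
    "loop_rmsd_series",
    "pearson",
    "superpose",
]

ResidueKey = tuple[str, int]


@dataclass
class FlexibilityProfile:
    """Ordered per-residue scalar series with metric and temperature tags."""

    residue_keys: list[ResidueKey]
    values: np.ndarray
    metric: str  # "bfactor" | "rmsf_raw" | "rmsf_normalized"
    temperature_label: str = "crystal"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_keys) != len(self.values):
            raise ValueError("residue_keys and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def value_for(self, key: ResidueKey) -> float:
        return float(self.values[self.residue_keys.index(key)])

    def loop_values(self, loop: LoopDefinition, any_chain: bool = False) -> np.ndarray:
        mask = [
            loop.covers(num) and (any_chain or chain == loop.chain_id)
            for chain, num in self.residue_keys
        ]
        return self.values[np.asarray(mask, dtype=bool)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [c for c, _ in self.residue_keys],
                "residue": [r for _, r in self.residue_keys],
                "value": self.values,
                "metric": self.metric,
                "temperature": self.temperature_label,
            }
        )


@dataclass
class CoordinateEnsemble:
    """Fixed atom set observed over frames (an MD-trajectory stand-in).

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``frame_interval`` is
    the sampling interval in ps.
    """

    frames: np.ndarray
    atom_metadata: list[AtomRecord]
    frame_interval: float = 2.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atom_metadata):
            raise ValueError("frame atom count does not match metadata")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def window_slice(self, window: tuple[int, int] | None) -> slice:
        """Validated [start, stop) frame range; None means all frames."""
        if window is None:
            return slice(0, self.n_frames)
        start, stop = window
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(
                f"window {window} outside ensemble of {self.n_frames} frames"
            )
        return slice(start, stop)

    def last_fraction(self, fraction: float) -> tuple[int, int]:
        """Window covering the trailing fraction of the run (e.g. last 10 ns
        of 30 ns -> fraction=1/3)."""
        start = int(round(self.n_frames * (1.0 - fraction)))
        return (start, self.n_frames)

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        for i, a in enumerate(self.atom_metadata):
            if (a.chain_id == chain_id and a.residue_number == residue_number
                    and a.name == atom_name):
                return i
        raise KeyError(f"atom {chain_id}/{residue_number}/{atom_name} not in ensemble")


@dataclass
class LoopFlexibilitySummary:
    loop_id: int
    mean_bfactor: float | None = None
    mean_norm_rmsf: dict[str, float] = field(default_factory=dict)
    delta_rmsf: float | None = None
    depth: float | None = None


# ---------------------------------------------------------------------------
# B-factor profiles

def residue_bfactor(model: StructureModel, average_chains: bool = False) -> FlexibilityProfile:
    """Per-residue mean B-factor over non-hydrogen atoms.

    With ``average_chains`` the per-residue values of all chains carrying a
    given residue number are averaged (the homodimer convention); residues
    present in only one chain use that chain alone and are flagged with a
    warning.
    """
    per_res: dict[ResidueKey, list[float]] = {}
    order: list[ResidueKey] = []
    for a in model.atoms:
        if a.is_hydrogen or a.is_hetero:
            continue
        key = a.residue_key
        if key not in per_res:
            per_res[key] = []
            order.append(key)
        per_res[key].append(a.b_factor)
    hydrogen_only = [
        a.residue_key
        for a in model.atoms
        if not a.is_hetero and a.residue_key not in per_res
    ]
    if hydrogen_only:
        warnings.warn(
            f"{len(set(hydrogen_only))} residue(s) with only hydrogens excluded",
            stacklevel=2,
        )
    if not average_chains:
        values = np.array([np.mean(per_res[k]) for k in order])
        return FlexibilityProfile(order, values, "bfactor")

    by_number: dict[int, list[float]] = {}
    num_order: list[int] = []
    for chain, num in order:
        if num not in by_number:
            by_number[num] = []
            num_order.append(num)
        by_number[num].append(float(np.mean(per_res[(chain, num)])))
    n_chains = len({c for c, _ in order})
    singles = [n for n in num_order if len(by_number[n]) < n_chains]
    if singles and n_chains > 1:
        warnings.warn(
            f"{len(singles)} residue number(s) present in only one chain", stacklevel=2
        )
    keys = [("*", n) for n in num_order]
    values = np.array([np.mean(by_number[n]) for n in num_order])
    return FlexibilityProfile(keys, values, "bfactor")


def loop_bfactor(profile: FlexibilityProfile, loop: LoopDefinition) -> float:
    """Arithmetic mean of the profile over the loop's residues."""
    vals = profile.loop_values(loop, any_chain=all(c == "*" for c, _ in profile.residue_keys))
    if vals.size == 0:
        raise ValueError(f"no profile residues inside loop {loop.loop_id}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Superposition (Kabsch) and RMSF

_BACKBONE = ("N", "CA", "C")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_indices: np.ndarray | None = None) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The rotation/translation is fit on ``fit_indices`` (default: all atoms)
    and applied to every atom.
    """
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    m = mobile[fit_indices]
    r = reference[fit_indices]
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (mobile - mc) @ rot.T + rc


def _backbone_indices(ensemble: CoordinateEnsemble) -> np.ndarray:
    idx = [
        i for i, a in enumerate(ensemble.atom_metadata)
        if a.name in _BACKBONE and not a.is_hydrogen
    ]
    if len(idx) < 3:  # fall back on heavy atoms for toy systems
        idx = [i for i, a in enumerate(ensemble.atom_metadata) if not a.is_hydrogen]
    return np.asarray(idx)


def _superposed_window(ensemble: CoordinateEnsemble, window, superpose_frames: bool):
    sl = ensemble.window_slice(window)
    frames = ensemble.frames[sl].copy()
    if frames.shape[0] < 2:
        raise ValueError("RMSF window needs at least 2 frames")
    if superpose_frames:
        fit_idx = _backbone_indices(ensemble)
        # two-pass: align to first frame, then to the window average
        ref = frames[0]
        frames = np.stack([superpose(f, ref, fit_idx) for f in frames])
        mean = frames.mean(axis=0)
        frames = np.stack([superpose(f, mean, fit_idx) for f in frames])
    return frames


def rmsf(
    ensemble: CoordinateEnsemble,
    window: tuple[int, int] | None = None,
    superpose_frames: bool = True,
    per_residue: str = "atom_mean",
    temperature_label: str = "300K",
) -> FlexibilityProfile:
    """Per-residue RMSF over a frame window.

    Atomic RMSF is the root-mean-square displacement from the window-average
    position.  ``per_residue`` chooses how non-hydrogen atomic values are
    reduced to one value per residue: ``"atom_mean"`` (mean of atomic RMSF,
    default) or ``"pooled"`` (RMS over the pooled squared deviations of the
    residue's atoms).
    """
    frames = _superposed_window(ensemble, window, superpose_frames)
    mean = frames.mean(axis=0)
    sq_dev = ((frames - mean) ** 2).sum(axis=2)  # (n_frames, n_atoms)
    atom_msf = sq_dev.mean(axis=0)

    per_res: dict[ResidueKey, list[int]] = {}
    order: list[ResidueKey] = []
    for i, a in enumerate(ensemble.atom_metadata):
        if a.is_hydrogen:
            continue
        key = a.residue_key
        if key not in per_res:
            per_res[key] = []
            order.append(key)
        per_res[key].append(i)
    if per_residue == "atom_mean":
        values = np.array([np.mean(np.sqrt(atom_msf[per_res[k]])) for k in order])
    elif per_residue == "pooled":
        values = np.array([np.sqrt(np.mean(atom_msf[per_res[k]])) for k in order])
    else:
        raise ValueError(f"unknown per_residue mode {per_residue!r}")
    return FlexibilityProfile(order, values, "rmsf_raw", temperature_label)


def normalize_rmsf(profile: FlexibilityProfile) -> FlexibilityProfile:
    """Divide by the whole-protein mean so the output profile has mean 1."""
    mean = float(np.mean(profile.values))
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return FlexibilityProfile(
        list(profile.residue_keys),
        profile.values / mean,
        "rmsf_normalized",
        profile.temperature_label,
    )


def average_profiles(profiles: Sequence[FlexibilityProfile]) -> FlexibilityProfile:
    """Average replicate profiles (normalize each first for RMSF replicates —
    the between-run baseline varies)."""
    if not profiles:
        raise ValueError("no profiles to average")
    keys = profiles[0].residue_keys
    for p in profiles[1:]:
        if p.residue_keys != keys:
            raise ValueError("replicate profiles must share residue keys")
    values = np.mean([p.values for p in profiles], axis=0)
    return FlexibilityProfile(list(keys), values, profiles[0].metric,
                              profiles[0].temperature_label)


def delta_rmsf(
    profile_high: FlexibilityProfile,
    profile_low: FlexibilityProfile,
    loops: Sequence[LoopDefinition],
) -> pd.DataFrame:
    """Per-loop mean normalized-RMSF difference, high minus low temperature.

    Positive values mark thermally sensitive loops; negative values mark
    loops rigidified at high temperature.
    """
    for p in (profile_high, profile_low):
        if p.metric != "rmsf_normalized":
            raise ValueError("delta_rmsf expects normalized profiles")
    if profile_high.residue_keys != profile_low.residue_keys:
        raise ValueError("profiles have mismatched residue keys")
    rows = []
    for loop in loops:
        hi = profile_high.loop_values(loop)
        lo = profile_low.loop_values(loop)
        if hi.size == 0:
            raise ValueError(f"loop {loop.loop_id} has no residues in the profiles")
        rows.append(
            {
                "loop_id": loop.loop_id,
                "mean_norm_rmsf_high": float(np.mean(hi)),
                "mean_norm_rmsf_low": float(np.mean(lo)),
                "delta_rmsf": float(np.mean(hi) - np.mean(lo)),
            }
        )
    return pd.DataFrame(rows)


def loop_rmsd_series(
    ensemble: CoordinateEnsemble,
    loop: LoopDefinition,
    window: tuple[int, int] | None = None,
    superpose_frames: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the loop's non-hydrogen atoms against the
    loop's window-average conformation, after whole-structure superposition.

    Measures local loop mobility over the stationary phase of a trajectory.
    """
    frames = _superposed_window(ensemble, window, superpose_frames)
    loop_idx = np.asarray(
        [
            i
            for i, a in enumerate(ensemble.atom_metadata)
            if not a.is_hydrogen and a.chain_id == loop.chain_id
            and loop.covers(a.residue_number)
        ]
    )
    if loop_idx.size == 0:
        raise ValueError(f"loop {loop.loop_id} has no atoms in the ensemble")
    loop_frames = frames[:, loop_idx]
    mean = loop_frames.mean(axis=0)
    return np.sqrt(((loop_frames - mean) ** 2).sum(axis=2).mean(axis=1))


def pearson(profile_a: FlexibilityProfile, profile_b: FlexibilityProfile) -> float:
    """Pearson correlation between two matched profiles."""
    if profile_a.residue_keys != profile_b.residue_keys:
        raise ValueError("profiles have mismatched residue keys")
    if len(profile_a.values) < 3:
        raise ValueError("need at least 3 residues for a correlation")
    if np.std(profile_a.values) == 0 or np.std(profile_b.values) == 0:
        raise ValueError("zero variance in a profile")
    r, _ = stats.pearsonr(profile_a.values, profile_b.values)
    return float(r)


# ---------------------------------------------------------------------------
# Ensemble I/O: plain frames table (frame, atom_index, x, y, z)

def read_frames_table(path: str | Path, atom_metadata: list[AtomRecord],
                      frame_interval: float = 2.0) -> CoordinateEnsemble:
    df = pd.read_csv(path, sep="\t")
    n_atoms = len(atom_metadata)
    frames = []
    for _, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("atom_index")
        if len(grp) != n_atoms:
            raise ValueError("frame atom count does not match metadata")
        frames.append(grp[["x", "y", "z"]].to_numpy())
    return CoordinateEnsemble(np.stack(frames), atom_metadata, frame_interval)


def write_frames_table(ensemble: CoordinateEnsemble, path: str | Path) -> None:
    rows = []
    for f in range(ensemble.n_frames):
        for i in range(ensemble.n_atoms):
            x, y, z = ensemble.frames[f, i]
            rows.append((f, i, x, y, z))
    pd.DataFrame(rows, columns=["frame", "atom_index", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )
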