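"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and returns its output
together with a machine-readable ground-truth record, so parameter-recovery
tests need no external data.  Defaults mirror the assay conditions the
pipeline targets: 2 ps trajectory sampling, 30–90 °C melting scans in 1 °C
steps, glycolaldehyde levels of 4–80 mM, decay sampled over one hour.

The toy structures use an idealised backbone trace — every downstream
computation here is geometric or statistical, so no physical realism is
needed (or claimed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ddg import AMINO_ACIDS, DdgRecord, VariantOutcome
from .fits import DecaySeries, SpectralSeries, _fraction_unfolded
from .flexibility import CoordinateEnsemble
from .structure import AtomRecord, StructureModel, SecondaryStructureAnnotation

__all__ = [
    "make_toy_structure",
    "make_ensemble",
    "make_decay",
    "make_melting_spectra",
    "make_mm_data",
    "make_variant_table",
    "write_ground_truth",
]

# one residue = N, CA, C, O placed around a gently curving backbone trace
_ATOM_OFFSETS = {
    "N": np.array([-1.0, 0.4, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.1, 0.5, 0.2]),
    "O": np.array([1.3, 1.6, 0.5]),
}
_CA_SPACING = 3.8  # Å between consecutive CA atoms


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Sidecar ground-truth JSON for a generated file."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=2, default=_default) + "\n")


def _backbone_trace(n_residues: int) -> np.ndarray:
    """CA positions along a wide helix so the chain is non-degenerate in 3D."""
    i = np.arange(n_residues)
    angle = i * 0.35
    radius = 12.0
    return np.stack(
        [radius * np.cos(angle), radius * np.sin(angle), 1.9 * i], axis=1
    )


def make_toy_structure(
    n_residues: int = 30,
    ss_layout: Sequence[tuple[str, int, int]] = (),
    b_profile: Sequence[float] | float = 20.0,
    homodimer: bool = False,
    b_noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[StructureModel, dict]:
    """Idealised annotated structure with prescribed per-residue B-factors.

    ``ss_layout`` lists (kind, start, end) annotations in 1-based residue
    numbers; everything else is loop.  ``b_profile`` gives the per-residue
    B-factor mean (scalar = constant); the four atoms of a residue carry
    that value exactly, so the residue mean equals the profile.  With
    ``homodimer`` a chain B copy is added, offset in space, with independent
    Gaussian B noise of sd ``b_noise_sd`` (clipped at zero).

    Returns (model, ground_truth) where the truth records the loop ranges
    implied by the layout and the per-chain per-residue B means.
    """
    if np.isscalar(b_profile):
        b_values = np.full(n_residues, float(b_profile))
    else:
        b_values = np.asarray(b_profile, dtype=float)
        if len(b_values) != n_residues:
            raise ValueError("b_profile length must equal n_residues")
    annotations = []
    covered = set()
    for kind, start, end in ss_layout:
        if not (1 <= start <= end <= n_residues):
            raise ValueError(f"layout range {start}-{end} outside 1..{n_residues}")
        covered.update(range(start, end + 1))
    rng = np.random.default_rng(rng_seed)
    trace = _backbone_trace(n_residues)

    chains = ["A", "B"] if homodimer else ["A"]
    atoms: list[AtomRecord] = []
    truth_b: dict[str, list[float]] = {}
    serial = 1
    for ci, chain in enumerate(chains):
        offset = np.array([0.0, 0.0, 80.0]) * ci  # well-separated copy
        if ci == 0 or b_noise_sd == 0:
            chain_b = b_values.copy()
        else:
            chain_b = np.clip(b_values + rng.normal(0, b_noise_sd, n_residues), 0.0, None)
        truth_b[chain] = chain_b.tolist()
        for r in range(n_residues):
            for name, local in _ATOM_OFFSETS.items():
                atoms.append(AtomRecord(
                    serial=serial,
                    name=name,
                    element=name[0],
                    alt_loc="",
                    chain_id=chain,
                    residue_number=r + 1,
                    residue_name="GLY" if name != "O" else "GLY",
                    coordinates=tuple(trace[r] + local + offset),
                    b_factor=float(chain_b[r]),
                ))
                serial += 1
    for kind, start, end in ss_layout:
        for chain in chains:
            annotations.append(SecondaryStructureAnnotation(kind, chain, start, end))
    model = StructureModel(atoms, annotations)

    loops = []
    run = None
    for r in range(1, n_residues + 1):
        if r not in covered:
            run = run or [r, r]
            run[1] = r
        elif run:
            loops.append(tuple(run))
            run = None
    if run:
        loops.append(tuple(run))
    truth = {
        "n_residues": n_residues,
        "chains": chains,
        "loop_ranges": loops,
        "b_means": truth_b,
    }
    return model, truth


def make_ensemble(
    base: StructureModel,
    sigma_profile: Sequence[float] | float,
    n_frames: int = 2000,
    frame_interval: float = 2.0,
    rng_seed: int = 0,
) -> tuple[CoordinateEnsemble, dict]:
    """Gaussian-fluctuation ensemble around a base structure.

    Every atom of residue *i* is displaced, independently per frame and per
    axis, by N(0, σ_i²); the expected atomic RMSF is therefore σ_i·√3.
    ``sigma_profile`` maps 1:1 onto the ordered residues of the base model
    (scalar = uniform).  Stands in for an equilibrated MD trajectory sampled
    every ``frame_interval`` ps.
    """
    atoms = list(base.atoms)
    res_keys: list[tuple[str, int]] = []
    for a in atoms:
        if a.residue_key not in res_keys:
            res_keys.append(a.residue_key)
    if np.isscalar(sigma_profile):
        sigma = {k: float(sigma_profile) for k in res_keys}
    else:
        values = np.asarray(sigma_profile, dtype=float)
        if len(values) != len(res_keys):
            raise ValueError("sigma_profile length must equal residue count")
        sigma = dict(zip(res_keys, values))
    if any(s < 0 for s in sigma.values()):
        raise ValueError("sigma values must be non-negative")
    atom_sigma = np.array([sigma[a.residue_key] for a in atoms])
    base_xyz = np.array([a.coordinates for a in atoms])
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(size=(n_frames, len(atoms), 3)) * atom_sigma[None, :, None]
    ensemble = CoordinateEnsemble(base_xyz[None] + noise, atoms, frame_interval)
    truth = {
        "sigma": {f"{c}:{r}": s for (c, r), s in sigma.items()},
        "expected_rmsf": {f"{c}:{r}": s * np.sqrt(3.0) for (c, r), s in sigma.items()},
        "n_frames": n_frames,
        "frame_interval": frame_interval,
    }
    return ensemble, truth


def make_decay(
    k_d: float,
    times: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[DecaySeries, dict]:
    """First-order decay series: activity = exp(−k_d·t) x lognormal noise.

    Default sampling matches a one-hour inactivation assay read every
    5 minutes.
    """
    if times is None:
        times = np.arange(0.0, 61.0, 5.0)
    times = np.asarray(times, dtype=float)
    activity = np.exp(-k_d * times)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        activity = activity * np.exp(rng.normal(0.0, noise_sd, size=times.shape))
    series = DecaySeries(times, activity)
    truth = {"k_d": k_d, "half_life": float(np.log(2) / k_d) if k_d > 0 else np.inf}
    return series, truth


def make_melting_spectra(
    t_m: float,
    dH: float = 400.0,
    native_peak_nm: float = 335.0,
    unfolded_peak_nm: float = 355.0,
    temperature_grid: Sequence[float] | None = None,
    wavelength_grid: Sequence[float] | None = None,
    peak_width_nm: float = 10.0,
    native_slope_nm_per_C: float = 0.0,
    unfolded_slope_nm_per_C: float = 0.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[SpectralSeries, dict]:
    """Two-state melting spectra: a native and an unfolded Gaussian emission
    peak mixed by the van't Hoff unfolded fraction.

    Defaults follow an intrinsic-fluorescence melt: 30–90 °C in 1 °C steps,
    emission sampled 300–400 nm, ΔH = 400 kJ/mol.  Optional linear drifts of
    the peak centres give sloping native/unfolded baselines; Gaussian noise
    (sd as a fraction of peak amplitude) can be added on top.
    """
    if temperature_grid is None:
        temperature_grid = np.arange(30.0, 91.0, 1.0)
    if wavelength_grid is None:
        wavelength_grid = np.arange(300.0, 401.0, 1.0)
    temps = np.asarray(temperature_grid, dtype=float)
    lams = np.asarray(wavelength_grid, dtype=float)
    frac = _fraction_unfolded(temps, t_m, dH)
    centre_n = native_peak_nm + native_slope_nm_per_C * temps
    centre_u = unfolded_peak_nm + unfolded_slope_nm_per_C * temps
    native = np.exp(-0.5 * ((lams[None, :] - centre_n[:, None]) / peak_width_nm) ** 2)
    unfolded = np.exp(-0.5 * ((lams[None, :] - centre_u[:, None]) / peak_width_nm) ** 2)
    intensities = (1.0 - frac)[:, None] * native + frac[:, None] * unfolded
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        intensities = np.clip(
            intensities + rng.normal(0.0, noise_sd, intensities.shape), 0.0, None)
    series = SpectralSeries(temps, lams, intensities)
    truth = {"t_m": t_m, "dH": dH, "native_peak": native_peak_nm,
             "unfolded_peak": unfolded_peak_nm}
    return series, truth


def make_mm_data(
    k_m: float,
    k_cat: float,
    enzyme_molar_M: float = 1.0e-6,
    substrate_levels: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Michaelis–Menten initial rates with multiplicative lognormal noise.

    Rates are in mM/s: V_max = k_cat·[E]·1000.  Default substrate levels
    span 4–80 mM.  Returns (substrate, rates, ground_truth).
    """
    if substrate_levels is None:
        substrate_levels = np.array([4.0, 8.0, 16.0, 32.0, 48.0, 64.0, 80.0])
    s = np.asarray(substrate_levels, dtype=float)
    v_max = k_cat * enzyme_molar_M * 1000.0  # mM/s
    rates = v_max * s / (k_m + s)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        rates = rates * np.exp(rng.normal(0.0, noise_sd, size=s.shape))
    truth = {"k_m": k_m, "k_cat": k_cat, "v_max": v_max,
             "enzyme_molar_M": enzyme_molar_M}
    return s, rates, truth


def make_variant_table(
    n_variants: int = 49,
    concordance_rate: float = 0.653,
    rng_seed: int = 0,
) -> tuple[list[DdgRecord], list[VariantOutcome], dict]:
    """Paired ΔΔG/outcome tables with an exactly constructed concordant count.

    round(n_variants x concordance_rate) variants are concordant (ΔΔG sign
    agrees with the outcome side of 1); the rest are discordant.  Positions,
    residues, magnitudes and the shuffle are seeded.
    """
    if not 0.0 <= concordance_rate <= 1.0:
        raise ValueError("concordance_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_concordant = int(round(n_variants * concordance_rate))
    flags = np.zeros(n_variants, dtype=bool)
    flags[:n_concordant] = True
    rng.shuffle(flags)

    positions = rng.choice(np.arange(100, 100 + 5 * n_variants, 5),
                           size=n_variants, replace=False)
    records, outcomes, concordant_names = [], [], []
    for pos, concordant in zip(positions, flags):
        wt, mut = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        name = f"{wt}{int(pos)}{mut}"
        ddg = float(rng.uniform(0.2, 5.0) * rng.choice([-1.0, 1.0]))
        improved = (ddg < 0) if concordant else (ddg > 0)
        stability = float(rng.uniform(1.1, 3.0) if improved else rng.uniform(0.2, 0.9))
        records.append(DdgRecord(name, ddg))
        outcomes.append(VariantOutcome(name, stability))
        if concordant:
            concordant_names.append(name)
    truth = {
        "n_variants": n_variants,
        "n_concordant": n_concordant,
        "expected_accuracy_percent": round(100.0 * n_concordant / n_variants, 1),
        "concordant_variants": sorted(concordant_names),
    }
    return records, outcomes, truth
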