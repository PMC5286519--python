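# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structure model and loop extraction

Structures are read from fixed-width PDB text into a flat list of atom
records (author residue numbering, inclusive ranges throughout). Secondary
structure is taken from the file's HELIX/SHEET records rather than
recomputed from geometry: loop inventories should match what the
depositors annotated, and a per-residue override hook (`external_ss`)
covers files without records. Loops are the maximal runs of amino-acid
residues not covered by any helix/strand annotation, numbered 1..K along
the chain; terminal unannotated runs count as loops, and heteroatoms
(cofactors, waters) are retained but never counted as loop residues.

Alternate locations keep the highest-occupancy conformer (ties: first
encountered) so that all geometry is single-conformer and deterministic.
For homodimers, loops are defined on one chain and mapped to the other by
residue number.

## Flexibility profiles

* **B-factors** — per residue, the mean B over non-hydrogen atoms;
  hydrogen-only residues are excluded with a warning. With
  `average_chains=True` the per-residue values of the chains are averaged
  (residues present in one chain only use that chain, flagged).
* **RMSF** — atomic RMSF is the RMS displacement from the window-average
  position over a frame window; the residue value is the mean of its
  non-hydrogen atomic RMSFs (`atom_mean`, default) or the RMS over pooled
  squared deviations (`pooled`). Frames are optionally superposed
  (Kabsch, fit on backbone N/CA/C) onto the window average via a two-pass
  scheme: align to frame 0, average, re-align to the average. Which atoms
  the original workflow superposed on is not knowable from the record;
  backbone fitting is standard trajectory practice and is configurable.
* **Normalization** — RMSF baselines differ between independent runs, so
  profiles are divided by the whole-protein mean (output mean exactly 1);
  replicate profiles are averaged *after* per-run normalization.
* **ΔRMSF** — per loop, mean normalized RMSF at the high-temperature label
  minus the low one (default labels 370 K − 300 K; temperatures are labels
  of the input ensembles, nothing is re-simulated). Positive values mark
  thermally sensitive loops. Note a structural property of normalized
  profiles: strongly heated regions push the whole-protein mean up, so
  unchanged regions drift slightly below their old normalized values —
  small negative ΔRMSF is the expected signature of relative rigidity,
  not an artefact.
* **Loop RMSD series** — per frame, RMSD of a loop's non-hydrogen atoms
  against the loop's window-average conformation after whole-structure
  superposition; used to compare local mobility of point variants over the
  stationary phase of a trajectory.

## Residue depth

Depth is the distance from an atom to the nearest bulk water. The
reference implementation of this idea solvates with pre-equilibrated water
boxes; to avoid that external dependency we place candidate water sites on
a cubic lattice (spacing 2.75 Å ≈ bulk-water packing), randomly rotated
and offset each cycle, delete sites within a clash distance (default
2.6 Å ≈ sum of vdW radii, configurable) of any protein heavy atom, then
iteratively delete non-bulk sites having fewer than `min_neighbour_waters`
(default 2) water neighbours within `neighbourhood_radius` (default
4.2 Å) until stable — this drains narrow clefts so cleft water does not
masquerade as bulk. Depth is averaged over `n_cycles` (default 25) seeded
cycles, with the between-cycle standard deviation reported. With
`min_neighbour_waters=0` the procedure reduces to distance-to-nearest
non-clashing lattice site, which the tests use as a brute-force oracle.

Because the solvation is simplified, absolute depths differ from
water-box implementations; only orderings and burial contrasts are
asserted (rotation invariance within cycle noise, monotone increase under
added burial shells, surface < core).

## Interaction geometry

Hydrogen bonds use distance criteria only: donor–acceptor ≤ 3.9 Å, plus
hydrogen–acceptor ≤ 2.5 Å when the model carries hydrogens (without
hydrogens the H–A criterion is unevaluable and only D–A applies; donors
with no modelled hydrogen cannot qualify when other hydrogens exist).
Angular filters common in dedicated H-bond software are off by default —
only the distance thresholds are part of the criteria implemented here —
with an optional D–H…A ≥ 90° switch. Salt bridges pair acidic oxygens
(Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT) with basic nitrogens (Lys NZ,
Arg NE/NH1/NH2) at ≤ 3.2 Å, reported per residue pair at the minimum
atom-pair distance; His imidazole nitrogens are excluded by default
(protonation unknown) and switchable.

Per-loop counts use an *at-least-one-end-in-loop* membership rule — a
documented choice; counts over ensembles are computed per frame and
averaged. Occupancy of a tagged atom pair is the per-frame satisfaction
of a distance threshold; total intact time = satisfied frames × frame
interval.

## β-turn consensus design

Only type I and II turns are designed against (types IV/VIII are parsed
but never mutated): they are the most common types with the most
significant positional statistics. The shipped preference table covers
type II positions 1–4 ({C,P}, {A,E,K,P}, {G,N}, {C,D,K,Q,S,T}) and type I
positions 3–4 ({D,N,S,T}, {C,G,N}); type I positions 1–2 are not covered
and are skipped with a warning unless a user table supplies them. The
(I,3) set is the minimal reconstruction consistent with the shipped
designs: {D,S,T} is forced by the union set of the triple-shared lysine
below, and N is included so that Asn at (I,3) conforms, matching the
turn-position statistics this table descends from.

Rules: for a residue in exactly one turn, if the wild type is outside the
preferred set for its (type, position), one candidate per preferred
residue is emitted. For overlapping turns (sharing ≥ 1 residue), only the
residues common to *every* turn of the overlap cluster are considered —
the reading under which a lysine shared by three turns collects the union
{C,G,N} ∪ {D,N,S,T} ∪ {C,P} minus K = {C,D,G,N,P,S,T}, while the
non-shared residues of the cluster yield nothing. The weaker
shared-by-two reading would design extra, unwanted positions. Candidates
are deduplicated and canonically sorted (residue number, then proposed
residue), so output is independent of turn input order, and can be
restricted to a given loop set.

## ΔΔG zones and accuracy

Running a ΔΔG predictor is out of scope; predictions arrive as
`variant,ddg` tables (negative = stabilising). Saturation grids enumerate
19 substitutions per position. Zone labels are anchored by two facts: the
concordant zones are I and IV, and a predicted-stabilising,
experimentally-stabilised variant lies in zone IV; hence I = (+, worse),
II = (+, better), III = (−, worse), IV = (−, better), with experiment
expressed relative to wild type = 1. Default stability tolerance is 0:
inequalities are strict and exact ties (ΔΔG = 0 or outcome = 1) are
flagged indeterminate and excluded from the accuracy, which is reported
as a raw fraction plus a percentage rounded to one decimal. Ranking is
ascending in ΔΔG with lexicographic tie-break on the variant name.

## Stability and kinetics fits

* **Deactivation** — `linregress` of ln(activity) vs time; k_d = −slope;
  t½ = ln 2 / k_d holds exactly by construction. Non-positive rates warn
  and report infinite half-life. The window policy defaults to all points.
* **Two-state melt** — λ_bcm(T) = (1−f)(a_N + b_N·T) + f(a_U + b_U·T)
  with f = 1/(1 + exp[(ΔH/R)(1/T − 1/T_m)]), T in Kelvin internally, °C at
  all interfaces. Initial guesses: T_m at the steepest signal change,
  baselines from the first/last sixth of the curve; T_m is bounded to the
  measured range and f(T_m) = 0.5 by construction. Curves with a second,
  higher transition are outside the single-transition model; the residual
  norm is reported as a lack-of-fit diagnostic rather than fitting
  multiple transitions.
* **Michaelis–Menten** — bounded nonlinear least squares of
  v = V_max·S/(K_m+S); K_m initial guess is the substrate level nearest
  half the maximum observed rate. k_cat = V_max/[E] with [E] given in
  molar or as mg/mL plus molar mass. Catalytic efficiency k_cat/(K_m/1000)
  is reported in s⁻¹·M⁻¹ (rounded to integer for tables, full precision
  retained); fold changes to one decimal.

## Synthetic data: what it does and does not establish

Generators are deterministic under a fixed seed and attach ground truth.
Toy structures use an idealised backbone trace (N/CA/C/O per residue on a
wide helix curve) — every downstream computation is geometric or
statistical, so physical realism is neither needed nor claimed. Ensembles
displace atoms by independent isotropic Gaussian noise with a per-residue
amplitude σ (expected atomic RMSF = σ√3): they emulate amplitude
*profiles*, not correlated dynamics, so green RMSF tests establish
estimator correctness, not anything about real conformational sampling.
Decay uses lognormal noise (positivity), spectra Gaussian noise; melting
spectra mix two Gaussian emission peaks (defaults 335/355 nm, width
10 nm, 30–90 °C in 1 °C steps, ΔH = 400 kJ/mol) by the two-state
fraction. Michaelis–Menten data default to substrate levels spanning
4–80 mM with multiplicative noise. Variant tables plant an exact number
of concordant variants, so accuracy checks are constructions, not
statistics.

Consequently, quantities that depend on a real crystal structure and real
multi-nanosecond trajectories — loop counts of a specific structure,
B-factor/RMSF correlation magnitudes, per-loop hydrogen-bond averages,
salt-bridge occupancy times — are *not* reproduced at desk scale; the
test suite covers the corresponding machinery with oracle-backed property
tests instead.

## Known limitations

- No geometric secondary-structure assignment, mmCIF support, or
  anisotropic B-factors.
- Depth is not bit-compatible with water-box solvation servers.
- H-bond chemistry is distance-driven; no energy scoring, π interactions
  or water-mediated bridges.
- Single-transition melting fits only; multi-state unfolding reports
  lack of fit.
- The consensus designer never invents statistics: slots without shipped
  or user-supplied preference sets are skipped, loudly.
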