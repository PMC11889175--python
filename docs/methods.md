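# Methods

`rnfpump` models the redox-coupled sodium pump of the Rnf complex — the
membrane-bound ferredoxin:NAD⁺ oxidoreductase of anaerobic prokaryotes such
as *Acetobacterium woodii* — as a set of small, composable computations:
unit-safe redox thermodynamics, empirical rate laws, a ten-state
master-equation pumping cycle, cofactor-network extraction from coordinate
files, and trajectory analytics for the alternating-access mechanism.  This
note records the models, their assumptions, the defaults that matter, and
the choices made where the design was genuinely open.

## Thermodynamic frame

Reaction free energies come from midpoint potentials via ΔG₀′ = −nFΔE with
the Faraday constant fixed at 23.061 kcal mol⁻¹ V⁻¹ (96.49 kJ mol⁻¹ V⁻¹).
Unit conversion goes through a single base unit (kcal/mol) so arbitrary
conversion chains are self-consistent; 1 kcal/mol ≡ 43.36 meV.  Sign
conventions throughout: ΔG < 0 exergonic, sodium-motive force (SMF) ≥ 0
opposes outward pumping, and a positive donor→acceptor potential difference
is downhill for the electron.

Defaults encode the physiological couples: ferredoxin at −450 mV
(configurable over the −430 to −500 mV range — the choice moves the
break-even SMF from 130 to 180 mV, so it is an explicit parameter of every
model build), NAD⁺/NADH at −320 mV, ubiquinone at +90 mV for the Nqr
comparison.  Temperature defaults to 310 K.

The coupling between the AE1 [2Fe2S] cluster's redox state and Na⁺ binding
is a thermodynamic square: with binding free energies ΔG_bind^ox and
ΔG_bind^red, the midpoint potential shifts by
ΔE_m = (ΔG_bind^ox − ΔG_bind^red)/F upon Na⁺ binding.  The default −1/−3
kcal/mol pair gives +87 mV.  A stronger literature figure of ~130 mV for
the release-coupled downshift corresponds to a 3 kcal/mol affinity
difference; since the two numbers cannot be reconciled from the printed
binding energies alone, both parameterizations are exposed
(`NaBindingThermo(-1, -3)` vs `NaBindingThermo(0, -3)`) rather than
averaged or hidden.

## Rate laws

Electron tunneling uses the empirical protein distance ruler

    log₁₀ k = 15 − 0.6·R − 3.1·(ΔG + λ)²/λ

with R the edge-to-edge distance in Å and energies in eV.  The
coefficients are exposed as configuration; λ defaults to 0.7 eV, a typical
protein reorganization energy (no per-site value is available, so it is a
declared reconstruction).  Activated steps (conformational switching, ion
binding/release, hydride transfer) use transition-state theory,
k = κ(k_BT/h)exp(−ΔG‡/RT), with κ = 1.  Reverse rates always follow from
detailed balance, k_f/k_r = exp(−ΔG/RT).

The default six-step chain from the terminal B8 [4Fe4S] cluster to the
NAD-reducing FMN (B8→AE1 17 Å, AE1→FMN^G 16 Å, FMN^G→FMN^D 9 Å,
FMN^D→RBF 9 Å, RBF→C1 18 Å, C1→FMN^C 14 Å) reproduces the millisecond
overall transfer time.  Only the first two distances are stated in text
sources; the remainder are figure-level reconstructions and plain
configuration.  The per-chain driving force (−0.13 eV per electron) is
split evenly across the steps — a flat-landscape assumption in the absence
of per-cofactor midpoint potentials.

## The ten-state pumping cycle

The cycle follows the alternating-access mechanism: per stroke, an
electron from ferredoxin reaches B8, hops to the membrane-embedded AE1
cluster in the inward-facing conformation (17 Å, versus 24 Å outward — the
conformational gate), electrostatically recruits a cytosolic Na⁺
(−3 kcal/mol with AE1 reduced versus −1 oxidized), the RnfA/E dimer
switches inward→outward (barrier +4 kcal/mol with AE1 reduced, +10
oxidized), and oxidation of AE1 by FMN^G releases the Na⁺ to the periplasm
while the electron continues to FMN^C.  Two strokes move two Na⁺; a final
hydride transfer yields NADH.  Ten states, ten transitions, one ring.

Design choices the sources leave open:

* **State lumping.** The first stroke is resolved into five steps and the
  second into four (ET + uptake merged), plus the hydride step — matching
  the ten-step scheme while keeping one ring.
* **Intermediate potentials.** B8 is taken isopotential with ferredoxin
  and AE1 60 mV above it; the last ET step of each stroke absorbs the
  closure residual so the cycle sums *exactly* to the two-electron
  reaction free energy (≈ −6 kcal/mol).  `cycle_closure_check` verifies
  this to 1e−6 kcal/mol and is invariant under SMF by construction.
* **SMF partitioning.** Each transition carries a signed electrogenic
  fraction (the share of the membrane dielectric crossed by net charge):
  0.3 for Na⁺ uptake, 0.4 for the inward/outward translocation, 0.3 for
  release, summing to 1 per Na⁺ and 2 per cycle.  An SMF of Δψ shifts a
  step's ΔG by f·F·Δψ, split symmetrically (½ in the exponent) between
  forward and backward rates — a standard symmetric-barrier choice — so
  detailed balance holds at every SMF and the pump stalls exactly at the
  thermodynamic break-even (130 mV for Fd −450 mV; 180 mV for −500 mV).
* **Substrate events** (Fd and NAD⁺ binding) are lumped pseudo-first-order
  at saturating concentrations, so turnover is substrate-independent
  unless reconfigured.
* **Rate conditioning.** Activated steps at +3/+4 kcal/mol barriers run at
  10¹⁰–10¹¹ s⁻¹, five orders of magnitude above the rate-limiting ET
  steps.  Forward rates are capped at 10⁵ s⁻¹ (configurable) with the
  Boltzmann forward/backward ratio preserved.  This leaves every
  equilibrium property exact, moves the steady-state flux by ~2 %, and
  makes the exact stochastic sampler tractable.

The master equation uses the column convention dp/dt = Qp.  Steady states
come from the null space of Q (tolerance 1e−10; the net flux is measured
on every edge and the values agree at stationarity).  Deterministic time
courses are propagated by matrix exponential — exact for a linear system —
with the mean cumulative Na⁺ integrated exactly through an augmented
counting row.  The stochastic path is an exact event-driven (Gillespie)
sampler; seeds are mandatory and recorded.

## Structure analysis

PDB/mmCIF parsing is delegated to gemmi; author residue numbering and
insertion codes pass through untouched, coordinates are Å.  Cofactors are
detected from HETATM residue codes (SF4, FES, FMN, RBF, NAD/NAI); iron is
counted per record, making the inventory identity 4·#SF4 + 2·#FES
structural rather than assumed.  Unknown Fe-containing codes are kept with
a warning rather than dropped.

Edge-to-edge distances default to the minimum over all heavy atoms (the
common tunneling-distance convention); a conjugated-only subset (Fe/S core
for clusters, isoalloxazine ring for flavins) is selectable because the
convention used for the published distance labels is not stated.  Ligating
residues are found by donor atoms (S/O/N) within 2.6 Å of any cluster Fe —
a cysteinate Fe–S bond (~2.3 Å) plus slack; more than four hits warns of
over-ligation.  The ET chain is the minimal-total-distance simple path
with edges under a 25 Å ceiling (tunneling beyond that is irrelevant);
ties break on fewer hops then lexicographic ids, and on small networks the
search is exhaustive so it provably agrees with enumeration.

## Trajectory analysis

Trajectories enter through a minimal reader contract: a frames × atoms × 3
array, an atom roster, and named selections.  Binary MD formats are
deliberately out of scope; the plain-text columnar fixture keeps the whole
suite dependency-free.  The membrane normal is taken as the z axis of the
input frames (no membrane-plane fitting).

* **Gating classification.**  Two gate pairs (intracellular
  L108^RnfA^–L22^RnfE^, extracellular L103^RnfE^–L22^RnfA^) with
  closed ≤ 6 Å / open ≥ 9 Å sidechain-minimum thresholds; no numeric
  thresholds are published, so these are declared reconstructions.  A
  frame is inward (intra open, extra closed), outward (converse), occluded
  (both closed) or a flagged leak (both open — forbidden by the
  alternating-access principle).  Classification is *stateless*: in-band
  distances resolve by the midpoint and are counted as ambiguous.  A
  hysteresis scheme was considered and rejected because it would make
  labels depend on frame order, breaking permutation invariance.
* **Ion pair.**  Closed means minimum N–O distance ≤ 4 Å (common
  salt-bridge practice), reported as per-class fractions.
* **Densities.**  Na⁺ axial densities are histograms of z-offsets from a
  reference centroid (AE1 for RnfA/E), normalized to unit integral; empty
  selections yield an explicit zero profile with a warning.
* **2D PMFs.**  Boltzmann inversion, −k_BT·ln of the normalized 2D
  histogram, minimum at zero, empty bins undefined (NaN) rather than zero.
  On Gaussian samples the recovered curvature matches k_BT/σ² to a few
  percent at 1.5×10⁵ samples.
* **Pathway continuity.**  Free space is voxelized (0.8 Å grid; a voxel is
  free beyond probe 1.4 Å + per-element vdW radius from every atom) and
  flood-filled; continuity means one connected component touches both
  membrane faces.  The result is monotone in probe radius by construction.

## Synthetic data

The generators encode the statistical structure the analyses assume — not
force-field physics.  The toy complex carries the full cofactor complement
(8 + 2 [4Fe4S], one [2Fe2S], 3 FMN, 1 RBF → 42 Fe), the four-cysteine
AE1 ligation motif at 2.3 Å, gate and ion-pair residues, and a
2.0 Å-spaced membrane slab with an optional 4.5 Å bore; it stays under
3,000 atoms so structure analyses run in well under a second.  The
trajectory generator runs a two-state Markov chain (dwell probabilities
0.97/0.955, stationary inward fraction 0.6) over 4,000 frames, draws the
B8–AE1 distance from Gaussians at 17/24 Å (σ 0.8 Å), toggles the ion pair
open with probability 0.2 inward / 0.8 outward, assigns a per-frame AE1
redox flag (p = 0.5), and occupies the buried Na⁺ site with probability
0.8/0.2 (reduced/oxidized) inward and 0.7/0.2 outward.  Everything is a
pure function of the seed (byte-identical outputs), and every parameter is
written to a ground-truth manifest so the analyses are tested by parameter
recovery within binomial/normal sampling tolerances (Markov-chain
estimates use autocorrelation-corrected effective sample sizes).

What passing these tests shows — and does not.  The fixtures demonstrate
that the analysis operations measure what they claim on data with known
structure at realistic sample sizes.  They do not emulate force-field
correlations, solvent structure, per-frame atom-count changes, or
classification edge cases of genuinely continuous conformational
ensembles; conclusions about real trajectories still require the real
data.

## Problem sizes

Default problem sizes were chosen so the full suite runs in well under a
minute on one CPU: 4,000-frame trajectories, ≤3,000-atom structures,
400-run stochastic ensembles over 0.02 s of cycle time, and 1.5×10⁵-sample
PMFs.  All are configuration, not constants.

## Known limitations

* The ten-step state inventory, the per-step ΔG split, and the
  electrogenic partition are reconstructions; the published kinetic
  simulations rest on supplementary rate tables that are not reproduced
  here.  Cycle-level *properties* (closure, stall point, stoichiometry,
  monotonicity) are exact; absolute fluxes are not calibrated.
* No continuum electrostatics: midpoint shifts are inputs, not computed.
* No density-map handling, structure refinement, or MD execution; the
  trajectory layer analyzes coordinates it is given (or generates).
* The pathway grid uses a fixed per-element vdW table and a rigid frame;
  transient hydration-driven openings are invisible to a single-frame
  analysis.
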