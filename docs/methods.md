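# Methods

This note documents the models, estimators and numerical choices behind
`lipidpmf`, and what the synthetic generator does and does not emulate.

## Units and conventions

Lengths in nm, energies in kJ/mol, temperatures in K, concentrations in
mol/L (1 nm³ = 10⁻²⁴ L). R = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹,
N_A = 6.02214076×10²³ mol⁻¹. The default temperature is 323 K
throughout. Collective variables: ξ₁ = protein–lipid minimum distance,
ξ₂ = protein–membrane COM distance, ξ₃ = cos θ of the protein's helix
tilt (ξ₃ ∈ [−1, 1]).

## The synthetic ground truth

The generator replaces a coarse-grained MD engine with a model surface

U(ξ₁, ξ₂, ξ₃) = U₁(ξ₁) − RT₀ ln ρ(ξ₂, ξ₃ | ξ₁)

on ξ₁ ∈ [0.3, 2.0] nm. U₁ is a sum of Gaussian wells (default: bound
well at 0.48 nm, −17 kJ/mol; encounter well at 0.73 nm, −13 kJ/mol; both
of width 0.04 nm) on a zero plateau; ρ is a *normalised* conditional
density over the orientation variables — a mixture of four fixed
components (bound orientations B_A at ξ₂ = 3.94 nm / ξ₃ = 0.41 and B_B
at 3.48 nm / 0.94, an encounter component at ξ₂ = 4.3 nm, and a broad
unbound background) whose mixture weights are smooth Gaussian gates in
ξ₁. Because ρ integrates to one at every ξ₁, the Boltzmann marginal
along ξ₁ at the reference temperature T₀ equals U₁ *exactly*, which
makes closed-form and quadrature oracles available for every downstream
estimator. This is why the orientation structure is built as a gated
mixture of fixed components rather than an affine ξ₂(ξ₁) map: an
affine mean shift would distort the marginal and leave only approximate
oracles. The geometry is preserved — B_B sits closer to the bilayer
centre, the encounter basin at COM ≈ 4.3 nm.

Increasing the lipid count n deepens the bound well by a configurable
increment (default 4 kJ/mol per lipid) saturating at n = 5; this single
parameter anchors a 4 kJ/mol encounter→bound stabilisation at n = 1 and
20 kJ/mol at n = 5.

**Sampling.** Each window runs Metropolis Monte Carlo along ξ₁ with the
harmonic window bias (Gaussian proposals of width 0.025 nm, reflection
at the domain walls), and (ξ₂, ξ₃) are drawn *exactly* from ρ(·|ξ₁)
afterwards — a collapsed-Gibbs scheme whose joint target is exactly the
biased Boltzmann distribution. Replica exchange attempts neighbour swaps
every `exchange_interval` steps on alternating even/odd pairs, accepted
with min(1, e^{−βΔ}) where Δ is the bias-energy swap difference. The
exchange log records every attempt, so replica paths can be
demultiplexed exactly.

**What the generator does not emulate:** molecular detail (force field,
solvent, membrane undulations), realistic time correlations of MD, CV
cross-talk beyond the gated mixture, and finite-size electrostatics.
Passing tests therefore demonstrate estimator correctness on data with
the *assumed statistical structure* (harmonic biases on an equilibrium
ensemble), not robustness to the pathologies of real trajectories.

## Protocol defaults

16 windows linearly spaced on [0.4, 1.5] nm, force constant
1000 kJ mol⁻¹ nm⁻², exchange attempts every 1000 steps, 323 K; each
window emulates 15 µs of physical sampling (240 µs aggregate). The
analysis discards the first 2/15 of each series (burn-in), mirroring a
2 µs discard from 15 µs windows. Tests and examples run 2×10⁴–4×10⁵ MC
steps per window — chosen so each check's statistical error is well
inside its tolerance; the convergence-sensitive checks (deep-well
recovery at n = 5, the 20 kJ/mol basin gap) use the longer chains with
exchanges every 100–200 steps.

## WHAM

Histogram WHAM on ξ₁ with 0.02 nm bins over [0.35, 1.6] nm (resolving
the 0.48/0.73 nm minima pair). The self-consistent equations are
iterated directly in log space (logsumexp accumulation); convergence is
max|Δfᵢ| < 10⁻⁷ kJ/mol or 10⁵ iterations, after which the profile is
flagged unconverged and reweighting refuses it unless overridden. Empty
bins are undefined (NaN), never ±inf, and are excluded from alignment
and minima detection — this avoids fabricating barriers from unsampled
gaps. The gauge is fᵢ₌₀ = 0 internally; profiles are reported min-zero
and re-gauged to plateau-zero (mean zero over [1.4, 1.5] nm, the unbound
plateau) before any thermodynamic use. No Jacobian/volume correction is
applied to the minimum-distance CV; the K_d formula consumes F(r) as
estimated.

Minima detection runs on the longest contiguous finite run, after an
optional 3-bin moving average (recorded in the output), using a
prominence filter (default 0.5 kJ/mol) to suppress statistical wiggles;
boundary minima of monotone profiles are reported separately as edge
minima. Note the smoothing biases reported *depths* of narrow wells
upward; `PMFProfile.well_depth()` (the unsmoothed minimum) is the
depth used in binding tables.

Block convergence: the post-burn-in time range is split into contiguous
blocks, WHAM runs per block, and pairwise RMS discrepancies (mean
difference removed) quantify drift.

## Reweighting

Binless per-frame weights from the converged offsets,
wₙ ∝ 1/Σⱼ Nⱼ e^{β(fⱼ − uⱼ(ξ₁ₙ))}, computed in log space and normalised;
the Kish effective sample size is always reported. 2D surfaces are
weighted histograms on 60×60 grids spanning the observed data ± 2%,
converted to −RT ln and gauged min-zero; zero-count cells are undefined
and excluded from statistics, and a sampling-adequacy warning fires when
more than half the grid is empty (single-CV biasing does not guarantee
the orthogonal variables are well sampled). Basin occupancies sum frame
weights inside closed CV boxes; free energies are −RT ln p relative to
the most occupied state, and empty states give probability 0 with
undefined free energy rather than an error.

## Binding thermodynamics

K_d = (1 − b/L_z) / (N_A · A · I) with I = ∫₀ᵇ e^{−βF(r)} dr, the
infinite-box limit dropping the prefactor; b defaults to 1 nm, A (the
membrane x–y area) has *no default* because it is a property of the
simulated box. I is computed by a composite midpoint rule over the
bins' full extents clipped to [0, b]: each finite bin contributes its
Boltzmann factor times its overlap with the integration range, the
partial bin straddling b is clipped exactly, distances below the first
finite bin's lower edge contribute zero (steric wall — the windows never
sample there and e^{−βF} is undefined where unsampled), and any gap
between the last finite bin and b contributes at the plateau value. The
midpoint form (rather than a trapezoid through bin centres) is chosen
because it covers the binned range exactly, reproducing the flat-profile
closed form K_d = 1/(N_A·A·I) without half-bin truncation error; for
smooth profiles it agrees with adaptive quadrature to better than 10⁻³
relative at the default bin width.

ΔG = RT ln(K_d/1 M) at the simulation temperature (323 K) by default;
conversions of experimental ranges at room temperature are a documented
comparison (e.g. 5 nM ↔ −47.4 kJ/mol at 298 K), and the temperature is
always an explicit parameter because literature conversions are
temperature-ambiguous.

The well-depth aggregation table reports, per lipid count: unsmoothed
depth, K_d, ΔG, a monotonicity flag, and the saturation point (first n
beyond which the depth deepens by less than 1 kJ/mol). With the default
generator, K_d decreases strictly with n up to the saturation at five
lipids and is flat beyond — a family run asserts strict decrease only up
to saturation.

## States, contacts, density maps

Bound-state boxes (closed intervals on all three CVs): B_A = ξ₁ [0.46,
0.52], ξ₂ [3.91, 3.97], ξ₃ [0.36, 0.46]; B_B = ξ₁ [0.45, 0.51], ξ₂
[3.45, 3.51], ξ₃ [0.89, 0.99]. The two boxes overlap in ξ₁ but are
disjoint in ξ₂ and ξ₃; a loader check warns about any pair of
definitions overlapping on *all* axes (order-dependent classification).
The encounter state has no published box; the repository default is the
ξ₁ slab [0.70, 0.76] nm with ξ₂, ξ₃ unconstrained — a package default,
not a literature value. Classification is first-match over the supplied
definitions, `None` otherwise.

Contacts use a 0.7 nm protein–lipid cutoff with *strict* inequality
(the boundary convention is not specified by the usual definition; the
strict choice is documented and tested at 0.70 exactly), under the
minimum-image convention in the periodic membrane plane; head groups sit
in the z = 0 plane and protein beads carry their height unperiodically.

Density maps re-centre each frame on the protein's in-plane centroid
(minimum-image displacements, so maps are periodic-safe) and accumulate
weighted 2D histograms on 0.2 nm cells over a ±4 nm extent, then divide
by the maximum cell — empty cells are 0, not NaN, because the map is a
density, not a free energy. Maps are invariant under global weight
rescaling. The synthetic membrane generator plants Gaussian hotspots
(defaults: three sites at protein-relative positions with weights
0.35/0.30/0.25 over a uniform background) and a two-ring protein bead
footprint dense enough that lipids under the footprint register as
contacts; with three lipids per leaflet the contact PDF concentrates on
{2, 3} and with five on {4, 5}.

## Workflow

`run_pipeline` chains simulate → WHAM → 2D surfaces → K_d → states →
density maps, writing headered whitespace tables and a JSON manifest
(config snapshot, seed, package version, SHA-256 digest of every output,
warnings, completed stages). All randomness derives from the single run
seed; reruns are byte-identical (fixed float formatting, sorted JSON
keys). A stage failure raises with the stage name and the manifest of
completed stages. The PMF table's error column is the leading-order
counting estimate RT/√n per bin — a convenience diagnostic, not a full
covariance treatment.

## Known limitations

- Statistical errors on the PMF are reported as per-bin counting
  estimates; no bootstrap over correlated frames is implemented.
- The binless weights use the histogram-WHAM offsets rather than a full
  self-consistent binless (MBAR) solution; on well-overlapped ladders
  the difference is far below the statistical error, and the 2D-marginal
  consistency check (≤ 0.5 kJ/mol against the 1D PMF) bounds it in
  practice.
- The synthetic sampler's orientation draws are conditionally exact, so
  orientation mixing limitations of real MD (slow tilt flips between
  B_A and B_B) are not emulated.
- Density-map alignment uses the in-plane centroid only; rotational
  alignment to the protein's principal axis is unnecessary for the
  synthetic footprint (rotationally fixed by construction) and is not
  implemented.
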