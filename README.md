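# lipidpmf

Free-energy analysis of peripheral protein–membrane binding from
replica-exchange umbrella sampling (REUS), built around the case of a
pleckstrin homology (PH) domain recognising PIP₃-containing lipid
bilayers.

Peripheral membrane proteins such as PH domains bind anionic signalling
lipids (phosphoinositides) through several sites at once, so their
membrane affinity depends on the *local* lipid concentration. Simulation
campaigns probe this by biasing a collective variable — here
ξ₁, the minimum distance between the protein and the lipid phosphate
groups — in a ladder of harmonic umbrella windows with replica exchange,
and then reconstructing unbiased thermodynamics from the biased data.
`lipidpmf` implements that reconstruction chain for anyone analysing
this kind of campaign:

- **WHAM** — the weighted histogram analysis method combines the biased
  window histograms into one unbiased potential of mean force (PMF)
  F(ξ₁), solving the self-consistent equations
  p_l ∝ (Σᵢ n_il) / (Σᵢ Nᵢ e^{β(fᵢ − wᵢ(x_l))}),
  e^{−βfᵢ} = Σ_l p_l e^{−βwᵢ(x_l)} in log space, with convergence
  diagnostics and block-wise convergence analysis.
- **Binless reweighting** — per-frame unbiased weights
  wₙ ∝ 1 / Σⱼ Nⱼ e^{β(fⱼ − uⱼ(xₙ))} turn the ξ₁-biased ensemble into 2D
  free-energy landscapes over orientation variables (protein–membrane
  COM distance ξ₂, helix tilt cos θ = ξ₃) and basin occupancies.
- **Binding thermodynamics** — the PMF converts to a dissociation
  constant via 1/K_d = N_A · A · ∫₀ᵇ e^{−βF(r)} dr (with the finite-box
  factor (1 − b/L_z) when the box height is finite) and to a
  standard-state free energy ΔG = RT ln(K_d / 1 M).
- **States, contacts, density maps** — classification of frames into
  encounter (E) and two bound orientations (B_A, B_B) by CV-interval
  boxes, lipid–protein contact counting under the 0.7 nm cutoff with
  periodic minimum image, and max-normalised in-plane lipid density maps.
- **Synthetic REUS generator** — a Metropolis/collapsed-Gibbs sampler on
  an analytically known three-variable free-energy surface (bound well at
  0.48 nm, encounter well at 0.73 nm, flat unbound plateau, two
  orientation basins) stands in for the MD engine, so every estimator in
  the package is testable against exact quadrature oracles.

## Worked example

```python
import lipidpmf as lp

config = lp.AnalysisConfig(
    protocol=lp.UmbrellaProtocol(n_steps=60_000, seed=11,
                                 exchange_interval=200),
    area_A=40.0)
potential = lp.default_potential(n_pip3=1)

reus = lp.run_reus(potential, config.protocol)
post = [lp.apply_burn_in(t, config) for t in reus.trajectories]
pmf = lp.align_pmf(lp.wham_1d(post, config.protocol, config),
                   config.plateau_region)
print(pmf.well_depth())                      # -16.7
print(lp.find_minima(pmf).minima)            # [(0.48, -15.5), (0.72, -11.7)]
res = lp.kd_from_pmf(pmf, lp.BindingParams(area_A=40.0))
print(f"{res.kd:.2e}", round(res.delta_g, 1))  # 8.86e-04 -18.9
```

The recovered PMF shows the bound minimum at 0.48 nm (depth −16.7 kJ/mol
against a −17 ground truth; the minima listing is 3-bin smoothed) and the
encounter minimum at 0.72 nm. With a 40 nm² membrane patch the −17 kJ/mol
well corresponds to sub-millimolar K_d. Converting the five simulated
systems' dissociation constants at 323 K:

```
 1 PIP3: Kd = 2.1e-04 M  ->  dG =  -22.7 kJ/mol
 2 PIP3: Kd = 3.0e-06 M  ->  dG =  -34.2 kJ/mol
 3 PIP3: Kd = 1.6e-07 M  ->  dG =  -42.0 kJ/mol
 5 PIP3: Kd = 6.3e-09 M  ->  dG =  -50.7 kJ/mol
10 PIP3: Kd = 3.9e-10 M  ->  dG =  -58.2 kJ/mol
```

i.e. binding strengthens steeply with the number of lipids available to
the protein and crosses the experimental affinity range (≈ −48 to −34
kJ/mol) once three or more lipids engage.

The `examples/` directory holds one short script per capability
(synthetic campaign, WHAM, 2D landscapes, binding thermodynamics,
states/density maps); each prints the numbers it computes with a line on
what they mean.

## Command line

The same pipeline is available as a thin CLI:

```bash
lipidpmf simulate --seed 7 --outdir run/        # synthetic COLVAR files
lipidpmf wham --outdir run/                     # pmf.dat
lipidpmf fes2d --outdir run/ --pair xi2,xi3
lipidpmf kd --outdir run/ --area 40.0
lipidpmf run-all --seed 7 --outdir run/         # everything + manifest.json
```

Exit code 2 flags validation errors (bad config), 3 numerical failures.
`run-all` writes a manifest with SHA-256 digests of every output; reruns
with the same seed are byte-identical.

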