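# Methods

This note documents the models implemented in `spo0relay`, the default
parameter set, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Phosphorelay model

Species (μM): free and phosphorylated KinA, KinC, Spo0F, Spo0B, Spo0A;
Sda; Spo0E; and the enzyme–substrate complexes KinA·Sda,
Spo0B·Spo0A~P, Spo0E·Spo0A~P (plus KinC·Spo0F~P in the phosphatase
variant). Reactions, all elementary mass action:

| reaction | constants | units |
|---|---|---|
| KinA ⇌ KinA~P (autophosphorylation) | k_a1, k_a2 | h⁻¹ |
| KinC ⇌ KinC~P | k_c1, k_c2 | h⁻¹ |
| KinA~P + Spo0F ⇌ KinA + Spo0F~P | k_a3, k_a4 | μM⁻¹h⁻¹ |
| KinC~P + Spo0F ⇌ KinC + Spo0F~P | k_c3, k_c4 | μM⁻¹h⁻¹ |
| Spo0F~P + Spo0B ⇌ Spo0F + Spo0B~P | k1, k2 | μM⁻¹h⁻¹ |
| Spo0B~P + Spo0A ⇌ Spo0B·Spo0A~P | k3 (μM⁻¹h⁻¹), k4 (h⁻¹) | |
| Spo0B·Spo0A~P ⇌ Spo0B + Spo0A~P | k5 (h⁻¹), k6 (μM⁻¹h⁻¹) | |
| KinA + Sda ⇌ KinA·Sda | k_i (μM⁻¹h⁻¹), k_b (h⁻¹) | |
| Spo0E + Spo0A~P ⇌ Spo0E·Spo0A~P → Spo0E + Spo0A | v_f (μM⁻¹h⁻¹), v_b, v_e (h⁻¹) | |

Each synthesised protein has a production term (below) and every
species decays at degradation + dilution. Two modelling points that the
published description leaves implicit but that the system's behaviour
requires:

* **Bound Sda is still degraded.** The KinA·Sda complex loses Sda by
  proteolysis (at the excess of Sda's degradation rate over the
  complex's bulk turnover), releasing KinA intact. Without this the
  complex would shelter Sda from its fast turnover, total Sda would
  always exceed total KinA, and the titration switch could never cross.
* **Phosphatase variant.** KinC's reverse phosphotransfer is replaced
  by committed binding KinC + Spo0F~P → KinC·Spo0F~P (rate k_c4,
  set equal to k_a4 so the association is unit-consistent) followed by
  hydrolysis at k_pc = 20 h⁻¹; forward-transfer constants are tied to
  KinA's (k_c3 = k_a3). This preserves the source/sink switch, which is
  the point of the variant.

### Default kinetic constants

The defaults were chosen once, as a coherent set, to reproduce the
system's published anchor behaviours (source/sink flip between 0.03 and
3 μM KinA, KinC alone sustaining intermediate Spo0A~P above the 0.2 μM
matrix-gene threshold, active KinA rising steeply once growth slows,
and the direction of the single-cell distribution shifts):

* KinA: k_a1 = 10, k_a2 = 1 h⁻¹; k_a3 = 3000, k_a4 = 300 μM⁻¹h⁻¹ — an
  efficient forward kinase.
* KinC: k_c1 = 20, k_c2 = 100 h⁻¹; k_c3 = 300, k_c4 = 1500 μM⁻¹h⁻¹ —
  a weaker forward phosphotransferase with strong reverse transfer and
  fast reverse autophosphorylation, which is what lets it drain
  phosphate. The ratio (k_c1·k_c3)/(k_c2·k_c4) = 0.04 is the
  Spo0F~P/Spo0F level at which KinC switches between source and sink;
  the relay operates below it when KinA is scarce and far above it when
  KinA floods the relay.
* Relay core: k1 = k2 = 3000 μM⁻¹h⁻¹; k3 = 1000 μM⁻¹h⁻¹, k4 = k5 =
  100 h⁻¹, k6 = 100 μM⁻¹h⁻¹.
* Sda: k_i = 1000 μM⁻¹h⁻¹, k_b = 1 h⁻¹ (K_d = 1 nM, effectively
  stoichiometric).
* Spo0E: v_f = 1000 μM⁻¹h⁻¹, v_b = 100 h⁻¹, v_e = 20 h⁻¹
  (K_M = 0.12 μM).

Steady-state Spo0A~P fractions are insensitive to the absolute scale of
the fast bimolecular constants; the conclusions are carried by the
ratios above, which is what the Monte-Carlo robustness study perturbs.

## Growth coupling

Production of protein i at growth rate μ is v_i = n_i·v_p,i·F(μ) with
F(μ) = 2^{0.95(1.11−μ)} (volume shrinks as growth slows, raising
concentrations) and gene dosage n_i = 2^{1−τ_c p_i/τ_cyc}, τ_c = 0.78 +
0.15/μ h, τ_cyc = ln2/μ. Multifork replication is excluded;
replication starts at division. Decay is k_deg + μ with k_deg =
0.2 h⁻¹ for all proteins except Sda (9 h⁻¹). Defaults: v_p (μM/h) =
KinA 0.3, KinC 0.15, Spo0F 0.2, Spo0B 0.2, Spo0A 1.0, Sda 3.2,
Spo0E 0.05; positions p = kinA 0.66, kinC 0.72, spo0F 0.17, spo0B
0.35, spo0A 0.20, sda 0.20, spo0E 0.66 (representative origin
distances; only the origin-proximal vs -distal split matters). With
these values total KinA crosses total Sda near μ ≈ 0.5 h⁻¹, i.e. at
about 5 h of the default growth curve — the titration switch that turns
on sporulation signalling.

Growth rates below 10⁻³ h⁻¹ are clamped (τ_c diverges at μ → 0).

## Batch growth (Moser model)

dC/dt = C(k_g·H₁(N) − k_d·H₂(N)), dN/dt = −γC(k_g·H₁(N) − ψ·k_d·H₂(N)),
with H₁ a Hill function of nutrient N for growth and H₂ an inverse Hill
term for death/sporulation onset; N₀ = 1 (normalised), C₀ = 0.1 (OD).
Defaults: k_g = 0.85 h⁻¹, k_d = 0.15 h⁻¹, K₁ = 0.35, K₂ = 0.05,
h₁ = 1, h₂ = 4, γ = 0.25, ψ = 0.5 — a culture that grows near-maximally
for ~4 h and decelerates between 5 and 8 h (μ(5) ≈ 0.51, μ(6) ≈ 0.35,
μ(7) ≈ 0.11 h⁻¹). ψ = 1 is admitted as the closed-system limit, where
N + γC is exactly conserved (a standing test).

The μ(t) that drives the relay is the **gross** growth term (protein
dilution tracks biomass synthesis); the net term is also exported.

Fitting: bound-constrained multistart least squares on **log OD** —
measurement noise is multiplicative, so log-space residuals are the
maximum-likelihood choice and keep the exponential phase from being
swamped by the plateau. One start is data-driven (early log-slope →
k_g; plateau height → γ). Identifiability caveat: with 2% OD noise the
deceleration kink is weakly constrained, and for some noise
realisations the global optimum sits 10–15% away from the true μ(t) in
sup-norm even though the OD fit is at the noise floor. The tests assert
the derived bounds (< 15% always, < 10% for most realisations); users
fitting real curves should treat late-time μ estimates with the same
caution.

## Promoter read-outs

PtapA and PspoIIG activities are Hill functions of Spo0A~P with an
explicit fitted scale (the proportionality left open by the activity
definition). Defaults: n_t = 4, K_t = 0.2 μM (matrix genes switch on at
low Spo0A~P); n_g = 6, K_g = 2.5 μM (sporulation genes require high
Spo0A~P; the steep coefficient reflects the strongly cooperative
high-threshold response and keeps the ΔkinA course flat, as observed).
The repression variant multiplies activation by a decreasing Hill term
(defaults n_t2 = 2, K_t2 = 4 μM) and is deliberately nonmonotone.

Fitting minimises one unweighted squared error across all strains and
time points, by a seeded particle swarm (24 particles, 60 iterations)
over (n, log K, log scale) followed by Nelder–Mead polish;
deterministic per seed.

## Single-cell layer

Generation times at a snapshot are Normal(τ̄, 0.25·τ̄) with τ̄ =
ln2/μ(t), rejecting draws below 0.2 h and redrawing (so the requested
population size is preserved). Each cell's μ = ln2/τ deterministically
fixes its Spo0A~P — growth-rate noise is the only noise source, so two
cells with equal μ are identical and cell order is irrelevant (steady
states are cached on μ rounded to 4 decimals). Model cells count as
"expressing" above 1% of the promoter scale.

Snapshot times: the T6 snapshot carries the headline single-cell
number (fraction of ΔkinC cells below 0.2 μM ≈ 42%). The full
mean/variance paradox — ΔkinC showing higher mean *and* variance of
Spo0A~P yet lower mean PtapA activity, with higher mean PspoIIG — holds
at late snapshots (≈ 6.5 h with the default growth curve, where most
cells have crossed into the KinA-dominated regime); the snapshot time
is an exposed parameter.

## Robustness study

Each of the 19 relay constants is redrawn independently and uniformly
from [p/3, 3p]; for every draw the Spo0A~P fraction is computed at four
corners of the kinase plane (KinA, KinC ∈ {0.03, 3} μM, μ = 0.5 h⁻¹,
Spo0A production 1 μM/h, Sda off so the axes read as active kinase).
Corner labels follow the directional encoding: f1/f2 compare low/high
KinC at low KinA (f1/f2 < 1 ⇔ KinC is a source), f3/f4 compare high/low
KinC at high KinA (f3/f4 < 1 ⇔ KinC is a sink). Solver failures are
retried once at tighter tolerance, then counted and excluded from
denominators. With the default base set, the sink conclusion holds in
~100% of draws and the source conclusion in ~95%.

## Numerics

Steady states: stiff integration (LSODA, rtol 1e-8, atol 1e-12) from
the unphosphorylated production/decay balance over successively longer
horizons, with a Newton polish (hybrid root solve) once the trajectory
is near the fixed point; accepted only if the residual max-norm is
below tolerance (default 1e-9 μM/h) and concentrations are above
−1e-9 (then clamped to 0). The system is monostable over the parameter
ranges exercised here (verified from random initial states to 1e-6
relative agreement). Scan grid points report per-index errors rather
than aborting the scan.

## Synthetic data: what it does and does not emulate

Generators draw from named substreams of one root seed (od, promoter,
cells, betagal), so outputs are byte-reproducible and mutually
independent. They emulate: OD600 curves (Moser trajectory ×
2% lognormal noise), promoter-activity courses (QSS-chain prediction +
additive normal noise at 10% of the promoter scale, triplicate means
with SDs), per-cell fluorescence tables (non-expressing cells are pure
pixel-averaged background noise, Normal(0, σ_p/√n); expressing cells
add a truncated-normal shift; ground-truth labels retained), and raw
β-galactosidase readings that decode to prescribed activities.

They do **not** emulate: lineage- or time-correlated growth noise
(snapshots only), intrinsic chemical noise in the relay, the
SinI–SinR–SlrR bistable network downstream of Spo0A~P, segmentation
artefacts, or raw images. Consequently, passing tests validate the
noise-propagation and calling machinery, not those biological noise
sources; on real data the measured expressing fractions are expected to
fall below the model's (the downstream network adds heterogeneity the
model deliberately omits).

## Known limitations

* Kinetic constants and expression rates are a coherent reconstruction
  calibrated to the published anchor behaviours, not measured values;
  absolute concentrations and times should be read qualitatively.
* The deterministic relay is monostable by construction; no
  Spo0A autoregulation or feedback on KinA/Spo0F expression.
* KinB is lumped with KinA; KinD and KinE are not modelled.
* The Moser fit's late-time μ is weakly identified from OD alone (see
  above).
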