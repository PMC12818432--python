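# Methods

## Physical model

Chemical exchange between conformational states is modeled with the
Bloch–McConnell equations. For n exchanging states the magnetization
vector (Mx, My, Mz per state) evolves under a 3n × 3n generator

    dM/dt = (Ω + R + B1 + K ⊗ I₃) M

with per-state offset precession Ω, relaxation R (R1 on z, R2 on x/y),
the saturation field B1 coupling y ↔ z, and the first-order exchange
matrix K (columns sum to zero; rates obey detailed balance,
k_AB = k_ex·p_B/(p_A+p_B)). Three-state topology is linear B ↔ A ↔ C —
the minor states exchange with the major state, not with each other.

**CEST.** For each carrier offset the z-magnetization starts at the
equilibrium populations and is propagated for the saturation time
T_relax under B1; the reported ratio I/I₀ divides by a reference
propagation with B1 off. The default grid places one offset every 20 Hz
over ±6 ppm around the major resonance (B1 = 10 Hz, T_relax = 0.5 s,
60.83 MHz ¹⁵N, i.e. a 600 MHz spectrometer).

**CPMG.** The transverse magnetization evolves under
dM/dt = (iΩ − R2 − K)M. One constant-time echo unit
τ–180°–2τ–180°–τ collapses to the linear map E = Q·conj(R)·Q with
Q = exp(Aτ), R = exp(A·2τ), τ = T/(4·n_cyc); after n_cyc applications,
R2,eff = −ln(|M_A(T)|/p_A)/T. The default schedule is T = 40 ms with
n_cyc ∈ {1,2,3,4,6,8,10,14,18,24,30,40,50,60} (ν_CPMG = 25–1500 Hz).
Matrix exponentials are computed batched by eigendecomposition, with a
scipy `expm` fallback whenever the eigenvector condition number exceeds
1e10.

**Carver–Richards oracle.** The closed-form two-state R2,eff
(Davis generalization, allowing unequal R2) is implemented as an
independent cross-check of the numerical propagator. Carver–Richards is
exact for the *asymptotic* decay rate of the echo train but neglects the
finite-time amplitude (prefactor) contribution of the minor state, so
the two agree to a stated tolerance only in a validity envelope. We
verified the implementation by matching it to the dominant-eigenvalue
rate of the cycle propagator (agreement to ~0.2%), and mapped the
envelope empirically: for p_B ≤ 0.08, Δω between 1 and 4 ppm and
k_ex ≥ 3·Δω (rad/s), the worst deviation from the full numerical result
over 500 random parameter sets is 1.9%. The acceptance oracle test
samples that envelope. Outside it (slow exchange, large p_B) deviations
of several percent are expected and are a property of the approximation,
not an implementation error.

## Fitting

All fits are weighted least squares (Levenberg–Marquardt via lmfit).
Exchange objectives are multimodal in k_ex, so each fit screens a grid of
log-spaced k_ex starts crossed with a few minor-population starts by
χ² of the initial model (cheap forward evaluations), then polishes the
best candidates fully.

* **CEST global fit**: shared k_ex and p_B; per-residue signed Δω
  (initialized from the position of the secondary dip), R1 and R2. The
  dip detector uses mirror asymmetry, ratio(−offset) − ratio(+offset),
  which separates the (symmetric) direct-saturation dip from the minor
  resonance even on the main-dip shoulder; when no residue shows a dip
  above 4σ the fit proceeds with p_B force-flagged.
* **CPMG two-state global fit**: shared k_ex and p_B; per-residue |Δω|
  and R2 baseline. Residues whose dispersion amplitude is below
  1 s⁻¹ are excluded; if all are flat the result reports "no exchange
  detected" with NaN, flagged shared parameters instead of raising. The
  per-residue fast-exchange invariant φ = p_A·p_B·Δω² is attached.
* **Three-state CPMG fit**: the slow A↔B process (k_ex, per-residue Δω,
  optionally p_B) is fixed to CEST-derived values; free parameters are
  the shared fast rate k_ex,AC, per-residue |Δω_AC| and R2 baselines.
  The populations are reported force-flagged: CPMG data in this regime
  constrain φ-like products, not the populations individually.
* **Model selection**: AIC = N ln(χ²/N) + 2k on fits of identical data,
  plus the mean signed weighted residual over the three lowest ν_CPMG
  for each model — a systematic sign there is the fingerprint of an
  unmodeled slow process.
* **Rate grouping**: residues are sorted by fitted k_ex and merged
  greedily into groups within 0.3 log₁₀ units of the running group
  center; singletons mark residues that join no group.

**Uncertainty and flagging.** Reported errors are 1σ from the
least-squares covariance. A parameter is flagged underdetermined when no
covariance is available, when its 2σ interval spans more than half of
its allowed range, or when the optimizer parks it at a bound (within
1e-8 of the bound range). A calibration test checks that the 1σ
intervals cover the generator truth at the nominal ~68% rate.

## Populations, affinities, relaxation

* Open population: v_open/(v_open+v_closed) per reporter; mean ± sample
  SD (n−1) in percent across reporters; a single reporter yields no SD
  and is flagged.
* ΔΔG = −RT ln r with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ (a twofold
  population change at 298 K gives −0.41 kcal/mol).
* CSP = sqrt(ΔδH² + (0.154·ΔδN)²); K_D fits use the exact single-site
  depletion isotherm (quadratic formula) with K_D shared across residues
  and per-residue Δδ_max. Titrations without curvature are flagged as
  lower bounds; flat titrations return NaN, flagged.
* Exchange regime: slow if k_ex < |Δω|/5, fast if k_ex > 5|Δω|,
  intermediate otherwise.
* R2/R1 screening: residues above mean + 1 sample SD (strict >, single
  pass, no outlier exclusion) are flagged as exchange-broadened.

## Structure

Multi-model PDBs are parsed with gemmi; alternate locations resolve to
the highest-occupancy copy (with a warning). The zip distance (backbone
amide N to carbonyl O across the strand pair) classifies a model as
zipped when ≤ 3.4 Å (boundary inclusive — 3.4 Å is the conventional
upper limit for N–H···O hydrogen bonding) and unzipped otherwise. The
hydroxyl-to-carboxylate contact takes the nearer of the two carboxylate
oxygens per model and classifies ≤ 2.7 Å as a short hydrogen bond,
≤ 3.5 Å as an ordinary one.

## Synthetic data

Generators draw from a seeded numpy Generator: identical specs give
bit-identical outputs and zero-noise specs lie exactly on the forward
model. Noise structure matches what the fits assume — additive Gaussian
fractional intensity noise on CEST/CPMG (0.5%) and decays (2%), Gaussian
ppm noise on shifts (0.01 ppm), multiplicative lognormal noise on peak
volumes (σ_log = 0.2). Per-residue Δω draws are uniform in 1–4 ppm with
random sign unless specified. The ensemble generator builds a minimal
four-residue scaffold carrying exactly the atoms the distance queries
need, with the two key distances drawn per model from stated normal
distributions and placed exactly (filler atoms are jittered); it is a
stand-in for an ensemble-refinement structure, not realistic geometry.

Desk scales are deliberate: 10 residues for the main CEST group (a real
domain-scale analysis would use a few dozen), 2 for the slow group, 5–6
per CPMG fit,
6 reporters per volume estimate, 6 residues × 10 points per titration.
These sizes keep every acceptance scenario under ~15 s while leaving the
recovered uncertainties at realistic experimental magnitudes.

## Recovery scenarios

`betazip recover --scenario <name> --seed <int>` runs a full
generate → fit → compare cycle. Scenarios: `cest-group1` (k_ex = 104 s⁻¹,
p_B = 11%), `cest-group2` (45 s⁻¹, 16%), `cpmg-2state` (1740 s⁻¹, with
Δω drawn in 0.5–1.2 ppm so the data sit in the fast-intermediate regime,
where p_B is individually undetermined and reported flagged),
`cpmg-3state` (A↔B fixed at the CEST group-1 values, k_ex,AC =
2600 s⁻¹), `titration-ptyr` (400 µM), `titration-t42a` (250 µM),
`titration-weak` (2.3 mM), `volumes-wt` (15%), `volumes-e139d` (31%),
and `zipping`. Default tolerances: 3σ for fitted parameters, 1 SD for
population means, 0.05 Å absolute for ensemble geometry; `--noise 0`
with `--tolerance-mode rel --tolerance 0.001` checks the zero-noise
round trip. Reports serialize to JSON without wall-clock time, so
fixed-seed runs are byte-identical.

## Limitations

* No full spectral simulation: peak lists, volumes and intensity tables
  are the ingestion boundary.
* Carver–Richards is used only as an oracle inside its validity
  envelope; all fitting uses the numerical propagator.
* The three-state fit assumes the linear B ↔ A ↔ C topology and requires
  externally fixed slow-process parameters; it does not attempt to
  determine the topology from CPMG data alone.
* Hydrogen-bond classification is distance-only (no angular criterion),
  appropriate for coarse ensemble surveys.
* The exchange-regime boundaries (factor 5) and the rate-grouping
  threshold (0.3 log units) are conventional heuristics, configurable at
  the call sites.
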