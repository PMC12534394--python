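# Methods

## Neutrosophic uncertainty model

Each image element x carries a triple (T, I, F) of independent
memberships in [0, 1] constrained by T + I + F ≤ 3. The three maps are
computed element-wise:

* **Truth** — `clip(α_T·sigmoid(z) + β_T·C(x) + γ_T·G(x), 0, 1)` with
  z = (intensity − μ_healthy)/σ_pathological, clinical evidence C and
  genetic evidence G. Weights default to α_T = 0.45, β_T = 0.35,
  γ_T = 0.20.
* **Indeterminacy** — `clip(γ_I·exp(−(intensity − μ_transition)² /
  (2σ_dev²)) + δ_I·U(x) + ε_I·D(x), 0, 1)` with examiner uncertainty U
  and developmental uncertainty D; γ_I = 0.40, δ_I = 0.35, ε_I = 0.25.
* **Falsehood** — `clip(ζ_F·(1 − T) + η_F·H(x) + θ_F·max(0, 1 − I − T),
  0, 1)` with healthy-tissue evidence H; ζ_F = 0.50, η_F = 0.30,
  θ_F = 0.20.

The weighted sums can exceed 1 when parameters are perturbed (the
default truth weights already sum to exactly 1), so all memberships
are clipped to [0, 1]; the T + I + F ≤ 3 bound then holds by
construction and is asserted over seeded random images.

**Shape parameters.** μ_healthy = 0.75, σ_pathological = 0.15,
μ_transition = 0.50, σ_developmental = 0.12 (all config-overridable).
These place sound enamel in the bright range of a normalized
radiograph, lesions in the dark range, and peak ambiguity at
mid-intensity, which is where mixed-dentition transition zones fall.

**Lesion polarity.** On radiographs carious lesions are darker than
sound enamel, while the truth sigmoid as written makes bright pixels
pathological. `MembershipParams.dark_lesions` (default true) negates
the sigmoid argument so dark pixels raise truth; the printed signed
form remains available for bright-lesion modalities, and monotonicity
tests cover both conventions.

**Absent evidence.** When auxiliary maps are not supplied they default
to neutral constants: C = G = U = D = 0, H = 1. These are "no
information" priors; real clinical score maps would replace them.

**Age strata.** Ages 3–6 / 7–12 / 13–17 map to early childhood, school
age and adolescence (closed upper boundaries: 6 and 12 belong to the
lower stratum). Each stratum adjusts exactly one truth weight
(α_T ×1.15, β_T ×1.10, γ_T ×0.88 respectively), without
renormalization; the adjustment is not idempotent, so callers apply it
once per record.

## Diffusion dynamics

Truth evolves by an anatomically constrained heat equation
∂T/∂t = D_T∇²T + S_T·A − λ_T·T and indeterminacy by an
advection–diffusion law ∂I/∂t = D_I∇²I + v·∇I − μ_I·I
(D_T = D_I = 0.15, λ_T = μ_I = 0.025). Discretization is the simplest
scheme with provable properties: explicit Euler on a unit-spaced grid,
5-point Laplacian with zero-flux (mirrored-edge) boundaries, and
first-order upwind advection. The mirrored boundary makes the stencil
exactly mass-conserving (output sums to zero), which the tests assert
to 1e−9 per step. The advection term enters with the plus sign, so
transport is anti-parallel to v.

Stability: dt·max(D_T, D_I) ≤ 0.25 on the unit grid, enforced at
construction with the admissible maximum named in the error; the
default dt is 0.9× that limit, with 10 steps per evolution. A
first-order convergence trend (halving dt shrinks the change) is
tested rather than a formal order estimate.

The falsehood grid is not evolved — only T and I have evolution laws —
and is recomputed from the diffused T and I so the triple stays
internally consistent.

A separate scalar temporal-decay operator x·e^{−λt} models evidence
aging between acquisition and fusion; λ is constrained to (0, 1].

## Enzyme-kinetic operators

* **Amylase**: v = V_max·S / (K_m + S·(1 + Inh/K_i)) with V_max = 1.2,
  K_m = 0.3, K_i = 2.1. The inhibition factor multiplies the substrate
  term, which is the adapted image-domain form; the textbook
  competitive placement K_m·(1 + Inh/K_i) is available behind
  `classical_competitive`. Substrate is 1 − intensity under the
  dark-lesion convention (demineralized pixels are high-substrate) and
  the inhibitor is the healthy-tissue evidence grid, so sound enamel
  suppresses the response.
* **Binding affinity**: K_0·exp(−E_act(age)/(R·T))·M with
  K_0 = 1.5e6, E_act falling linearly from 45 kJ/mol at age 3 to
  35 kJ/mol at age 17 (enamel maturation), R = 8.314 J/(mol·K),
  T = 310 K, and a per-tooth maturation factor M in [0.8, 1.2].
* **Lysozyme**: Σ_k w_k·φ_k·exp(−d_k/σ_cleavage) over 12 reference
  infection patterns with σ_cleavage = 0.15 and weights in [0.1, 0.9].
  The feature space is a 12-D per-pixel texture descriptor (local
  mean, variance, gradient magnitude and nine oriented
  Gaussian-derivative responses, each min-max normalized); the
  reference patterns are library fixtures generated from a fixed seed,
  since no canonical template set exists. φ_k is a scalar response
  gain (default 1).
* **Immune scaling**: a linear ramp I_base·(1 + β·(age − 3)/14)·G_gen
  with β = 0.5 — immune capacity grows through the pediatric range;
  the trailing genetic factor defaults to 1.
* **Lactoferrin**: L_tot·Fe / (K_Fe + Fe + Ca/K_Ca). The literal molar
  constants (K_Fe = 1e−20 M) underflow any [0, 1] image use and mix
  molar with dimensionless terms, so the default profile rescales to
  the image domain (K_Fe = 0.1, K_Ca = 0.5); the molar profile remains
  available via `LactoferrinParams.literal_molar()`. The iron proxy is
  the auxiliary clinical (inflammation) channel and the calcium proxy
  is pixel brightness (mineralized tissue is bright).

## Regeneration model

The pediatric regeneration rate is Gaussian-modulated:
λ(age) = λ₀·exp(−(age − age_opt)²/(2σ_age²))·H(age) with
λ₀ = 0.25 day⁻¹, age_opt = 8 y, σ_age = 4 y. The hormonal factor has
a stated amplitude (0.4) and sinusoidal character but no stated
period or phase; this package uses one full period across ages 3–17,
H(age) = 1 + A·sin(2π(age − 3)/14), neutral at both ends and the
midpoint, with |A| < 1 enforced for positivity.

Growth factor follows ∂G/∂t = D_G∇²G + R_prod − K_deg·G − K_cons·G·C
with D_G = 1e−7 cm²/s rescaled to grid units by a configurable factor
(default 1e6, putting per-step diffusion and degradation on comparable
magnitudes, since no grid geometry is physically specified);
K_deg = 0.2 day⁻¹ is held inside its plausible band [0.1, 0.3] unless
explicitly overridden. Production and cell-density fields have no
prescribed functional form and are caller-supplied grids.

The healing trajectory summarizes recovery as
healing(t) = 1 − severity·e^{−λ(age)·t}, monotone from 1 − severity
toward 1. Its hormonal multiplier defaults to neutral (1) so that the
characteristic-time arithmetic is exact; callers opt into the
sinusoidal modulation explicitly.

## Fusion and diagnosis

Per-modality triples fuse by a convex weighted mean (weights
non-negative, summing to 1; default 0.35 clinical, 0.40 imaging,
0.15 genetic, 0.10 behavioral — imaging and clinical carry most of the
evidence, mirroring their incremental diagnostic value). The pipeline
composition is: neutrosophify each modality → temporal decay → fuse →
score. Scalar modality scores s are mapped onto the image convention
(intensity 1 − s, healthy evidence 1 − s, with s feeding the
modality's own evidence channel); the radiographic modality
neutrosophifies its image, runs the diffusion stage, and is summarized
to a triple by the spatial mean (a top-decile summarizer is available
for focal-lesion sensitivity). Missing modalities renormalize the
weights over those present.

The diagnosis score is (T + (1 − F))/2 — evidence for disease plus
absence of evidence against — and the reported uncertainty is the
fused indeterminacy, kept separate rather than folded into the score.
Labels follow thresholds 0.25/0.50/0.75 into healthy / incipient /
moderate / severe. The score is a ranking statistic, not a calibrated
probability: on synthetic cohorts it separates classes sharply (AUC
≳ 0.95) while its expected calibration error remains large, which the
worked example shows honestly.

## Immune-genetic optimizer

A generational loop with both genetic and immune operators, all driven
by one seeded generator: fast non-dominated sorting and crowding
distance (NSGA-style); tournament selection with fractional pressure
2.1 realized probabilistically (ceil-size tournament, best returned
with probability pressure/ceil); blend crossover at rate 0.8; Gaussian
mutation at rate 0.05 (σ = 10% of gene range) with 0.99^generation
decay and a 30% raise in an early-childhood context; elite
preservation of the top 10%; affinity-proportional clonal expansion
(factor 20, largest-remainder rounding, every elite cloned);
inverse-affinity hypermutation at rate 0.4; negative selection
removing candidates whose bounds-scaled similarity to a "self" set
exceeds 0.85; a 35-member memory pool re-injecting 10% of each
generation; and a crowding-truncated Pareto archive of 100.

Affinity is the negated sum of min-max-normalized objectives over the
current evaluation pool. Because that normalization is per-generation,
affinities are not comparable across generations; the elitism
guarantee is therefore stated (and tested) on raw objectives: with
elites copied unchanged, the best raw objective in a single-objective
reduction never worsens. Each generation assembles elites + best
hypermutated clones + memory injections + GA offspring back to the
fixed population size; a filter that empties a pool is refilled with
random individuals.

The default "self" set is empty — negative selection is exercised when
the caller supplies disallowed reference genomes (e.g. parameter
vectors violating normalization constraints).

## Synthetic data

Phantoms emulate exactly the cues the operators target and nothing
more: a Gaussian-noise enamel background (μ = 0.75, σ = 0.03), dark
circular lesions (maximal darkening 0.5·severity, full depth inside
70% of the radius with a Gaussian edge of σ = 0.2·radius — smooth
edges without shrinking the core), and inflammation disks that raise a
separate clinical channel, keeping the image single-channel. Masks are
exact disk indicators. They do not model projective geometry,
anatomy, beam hardening or realistic noise spectra, so passing tests
demonstrate internal consistency and correct signal direction, not
clinical performance.

Cohorts draw a diseased indicator at the target prevalence (default
0.5), a latent severity uniform within the healthy (< 0.2) or diseased
(≥ 0.2) stratum, ages uniform on [3, 17], and four modality scores as
the severity plus Gaussian noise (default σ = 0.1 per modality),
clipped to [0, 1]. The radiographic record carries a 32×32 phantom
whose lesion severity equals the latent severity. Labels are the four
severity strata (healthy below 0.2, then thirds of the remainder).
Because scores are noisy monotone functions of severity, pipeline
discrimination (AUC) and rank correlation are meaningful acceptance
properties; absolute accuracies depend on the noise levels chosen
here.

## Metrics

Confusion-derived metrics use the standard definitions with undefined
ratios reported as missing rather than zero. AUC is the Mann–Whitney
rank statistic (ties half-counted), cross-checked in tests against an
all-pairs oracle and scikit-learn. ECE uses equal-width count-weighted
bins (default 10). Net benefit is TP/N − (FP/N)·p_t/(1 − p_t) at
threshold p_t ∈ (0, 1). Multi-class use is one-vs-rest on the healthy
boundary in the CLI pipeline.

## Problem sizes

Default test and demo sizes — 64×64 constraint images, 32×32 cohort
phantoms, 200-record cohorts, optimizer runs up to population 200 ×
100 generations — were chosen so the full suite and demos complete in
about a minute on a single core while still exercising every code
path at the scale the properties require.

## Known limitations

* The framework is not trained; all parameters are fixed optima, and
  no claim is made about real radiographs.
* Diffusion is 2-D only; no volumetric (CBCT) support.
* The lysozyme reference patterns are seeded fixtures, not learned
  infection templates.
* The diagnosis score is uncalibrated; a calibration layer (e.g.
  isotonic) would be needed before probabilistic use.
* The development-related term sometimes associated with the
  indeterminacy evolution has no defined functional form and is
  omitted from the PDE.
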