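# neutrodent

Bio-inspired diagnostic image analysis for pediatric dental data.

Pediatric caries diagnosis is dominated by uncertainty that binary or
fuzzy classifiers cannot represent: mixed dentition, erupting teeth and
inter-examiner disagreement make "not sure" a first-class diagnostic
state. `neutrodent` implements a neutrosophic framework in which every
image element carries three independent memberships — truth *T*
(evidence for pathology), indeterminacy *I* (diagnostic ambiguity) and
falsehood *F* (evidence for healthy tissue), each in [0, 1] with
*T* + *I* + *F* ≤ 3 — and combines them with enzyme-kinetic feature
operators, reaction–diffusion evidence propagation, axolotl-inspired
regeneration dynamics, multi-modal fusion and an immune-genetic
multi-objective optimizer. Synthetic dental phantoms and patient
cohorts with known ground truth serve as the test substrate, so every
pipeline stage is verifiable end to end.

## The model

Truth blends a sigmoid intensity response with clinical and genetic
evidence (weights α_T = 0.45, β_T = 0.35, γ_T = 0.20):

    T(x) = clip(α_T·σ((I(x) − μ_healthy)/σ_path) + β_T·C(x) + γ_T·G(x), 0, 1)

Indeterminacy peaks at a transitional intensity via a Gaussian kernel
plus examiner/developmental uncertainty (γ_I = 0.40, δ_I = 0.35,
ε_I = 0.25); falsehood rewards low truth, healthy-tissue evidence and
the residual max(0, 1 − I − T) (ζ_F = 0.50, η_F = 0.30, θ_F = 0.20).
Age strata adjust the truth weights (α_T +15% at ages 3–6, β_T +10% at
7–12, γ_T −12% at 13–17).

Truth then evolves by an anatomically constrained heat equation
∂T/∂t = D_T∇²T + S_T·A − λ_T·T (D_T = 0.15, λ_T = 0.025) and
indeterminacy by an advection–diffusion law; falsehood is recomputed
from the diffused fields. Enzyme operators map salivary-defense rate
laws into image space — α-amylase Michaelis–Menten kinetics with
competitive inhibition (V_max = 1.2, K_m = 0.3, K_i = 2.1), lysozyme
multi-pattern matching (12 reference patterns, σ_cleavage = 0.15),
Arrhenius-type binding affinity and lactoferrin Fe/Ca competition.
Healing follows a Gaussian-modulated regeneration rate
λ(age) = λ₀·exp(−(age − 8)²/32)·H(age) with λ₀ = 0.25 day⁻¹. Fused
modality triples yield a diagnosis score (T + (1 − F))/2 with the
fused indeterminacy reported as the uncertainty. The immune-genetic
optimizer (population 200, clonal factor 20, hypermutation 0.4,
negative-selection threshold 0.85, Pareto archive 100) tunes parameter
vectors against multiple objectives.

## Worked example

Run the end-to-end pipeline on a seeded 100-patient synthetic cohort:

```sh
neutrodent --seed 7 --out demo pipeline --n 100
```

prints `{"auc": 0.9974533106960951, "accuracy": 0.97}` and writes
`demo/diagnoses.csv`, `demo/eval.json` and `demo/dca.csv`. The
evaluation JSON for this seed reads (rounded):

| metric | value | meaning |
|---|---|---|
| accuracy | 0.970 | healthy-vs-diseased agreement with ground truth |
| sensitivity | 0.947 | diseased patients flagged |
| specificity | 0.984 | healthy patients cleared |
| auc | 0.997 | score separates the latent disease state |
| brier | 0.146 | squared-error calibration of the raw score |
| ece | 0.285 | the raw score is a rank statistic, not a calibrated probability |

and the decision-curve column shows net benefit 0.323 at threshold
0.10 and 0.357 at 0.25 — above both treat-all and treat-none in the
clinically relevant range. The same library calls are available in
Python:

```python
import neutrodent as nd

records = nd.make_cohort(nd.CohortSpec(n=100, seed=7))
d = nd.run_pipeline(records[0])
print(d.score, d.uncertainty, d.label)
```

Other subcommands: `phantom` and `cohort` (synthetic data with ground
truth), `transform` (image → T/I/F maps), `features` (enzyme maps),
`diffuse`, `fuse`, `optimize` (immune-genetic optimizer on a benchmark
objective), `evaluate`.

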