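# concord

Design and analysis of multi-reader concordance trials for AI-based
diagnostic imaging devices.

## The problem

Reporting systems such as the BI-RADS ultrasound lexicon have no gold
standard: there is no ground truth against which an AI reader's "oval" or
"irregular" can be scored. A device trial therefore evaluates the AI by
*agreement*: each of *n* subjects' images is read by the device and by a
panel of radiologists, and two readers concur on an image when they assign
the identical category label. `concord` implements the statistics for two
such trial objectives:

1. **Device vs panel (non-inferiority).** Is the concordance rate *pₛ*
   between the device and radiologists as high as the rate *pᵣ* among the
   radiologists themselves, up to a similarity margin δ₁ > 0? The test
   rejects H₁: *pₛ* ≤ *pᵣ* − δ₁ when

   Z₁ = √n (p̂ₛ − p̂ᵣ + δ₁)/σ̂₁ > z₁₋α,  σ̂₁² = n⁻¹ Σᵢ (sᵢ − rᵢ + δ₁)²,

   where rᵢ and sᵢ are subject *i*'s mean pairwise-radiologist and
   device–radiologist concordance scores. p̂ᵣ and p̂ₛ are the GEE
   (working-independence) estimators, and a robust sandwich variance
   σ̃₁² = n⁻¹ Σᵢ (sᵢ − rᵢ − (p̂ₛ − p̂ᵣ))² is available as an alternative.

2. **Senior vs junior (two-sided).** Is the device more concordant with
   experienced radiologists (rate *pₓ*) than with junior ones (rate *p_y*)?
   H₂: *pₓ* = *p_y* is rejected when |Z₂| = |√n (p̂ₓ − p̂_y)/σ̂₂| > z₁₋α/2
   with σ̂₂² = n⁻¹ Σᵢ (xᵢ − yᵢ)².

Because every reader reads every image, the binary concordance indicators
are correlated within subject. Sample-size planning needs the compound
correlation ρ₁ = corr(rᵢ, sᵢ) (or ρ₂ = corr(xᵢ, yᵢ)), which the package
computes from the small set of structural component correlations
(ρ_r1, ρ_r2, ρ_s1, ρ_s2, ρ_ss | ρ_xx, ρ_yy, ρ_xy), solves inversely under
offset constraints, or estimates from pilot data. The required sample size
for power 1 − β is

n = (z₁₋α √(σ² + δ²) + z₁₋β σ)² / δ²,  rounded up,

with σ² the closed-form variance of the per-subject score difference (see
`docs/methods.md`). A latent-Gaussian simulator (dichotomised multivariate
normal with exactly matched pairwise binary correlations) backs Monte-Carlo
checks of the empirical type-I error and power.

## Worked example

Plan a device-vs-panel trial with m = 10 radiologists, expected
radiologist concordance pᵣ = 0.5, margin δ₁ = 0.05, compound correlation
ρ₁ = 0.3, one-sided α = 0.05, power 0.8:

```bash
$ concord samplesize --objective 1 --rate 0.5 --delta 0.05 --rho 0.3 --power 0.8
{"n": 245, "sigma_sq": 0.09704..., "rho": 0.3, "components": {"m": 10,
 "rho_r1": 0.2603, "rho_r2": 0.1603, "rho_s1": 0.1603, "rho_s2": 0.0603,
 "rho_ss": 0.2603}}
```

245 subjects are required; the component correlations shown are the ones
solved from ρ₁ = 0.3 under the offsets ρ_s1 = ρ_s2 + 0.1,
ρ_r1 = ρ_r2 + 0.1, ρ_ss = ρ_r1 = ρ_s1 + 0.1.

Analysing data (here simulated at the alternative pₛ = pᵣ = 0.5):

```python
from concord import DeviceRadiologistConcordance, solve_components_obj1

comps = solve_components_obj1(0.3, 10)
model = DeviceRadiologistConcordance.simulate(206, 10, 0.5, 0.5, comps, seed=7)
print(model.fit(delta1=0.05).summary())
```

```
Device vs radiologist-panel concordance (one-sided margin test)
===============================================================
ps_hat                    0.506796
pr_hat                    0.479072
delta1                    0.050000
n subjects               206
Z statistic               3.532208
p-value                   0.000206053
critical value            1.644854  (one_sided_upper, alpha=0.05)
variance estimate         0.0997432  (null_anchored)
reject null              True
```

The device's concordance with the panel (p̂ₛ = 0.507) is well above the
margin boundary p̂ᵣ − δ₁ = 0.429, so non-inferiority is declared. Real
trials enter the same way through `DeviceRadiologistConcordance.from_readings`
(long CSV of categorical readings) or `from_indicators_csv`;
`SeniorJuniorConcordance` is the objective-2 counterpart.

Monte-Carlo operating characteristics for any design cell:

```bash
concord table --id 1 --reps 2000 --seed 1 --out table1.csv \
    --cells "0.3,0.05,0.1,0.8;0.5,0.1,0.7,0.9"
```

## File formats

- **Readings CSV** (long): columns `subject_id, reader_id, reader_role,
  classification, value`; roles are `device`/`radiologist` (objective 1)
  or `device`/`senior`/`junior` (objective 2); one reading per (subject,
  reader, classification), complete blocks required.
- **Indicators CSV** (wide): one row per subject; columns `r_<j>_<k>` and
  `s_<j>` (objective 1) or `x_<j>` and `y_<j>` (objective 2).
- **Component YAML/JSON**: keys `rho_r1, rho_r2, rho_s1, rho_s2, rho_ss`
  or `rho_xx, rho_yy, rho_xy`, optional `m`.
- Test results are emitted as JSON lines; tables as CSV.
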