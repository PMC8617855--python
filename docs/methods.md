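# Methods

## Setting and model

Each of *n* subjects contributes one image read under a categorical
lexicon classification by an AI device and a panel of radiologists
(objective 1: one panel of *m* radiologists; objective 2: *m* senior and
*m* junior radiologists). Concordance between two readers on an image is
the binary indicator of identical category labels — exact string equality
after whitespace stripping and case folding, with no partial credit for
adjacent categories, because the lexicon is nominal. Reading tables must
be complete single-replicate blocks; a missing or duplicated reading is an
error, never imputed.

Per subject *i* the indicators are reduced to mean scores:

- objective 1: rᵢ = mean of the m(m−1)/2 radiologist-pair indicators
  r_ijj′, sᵢ = mean of the m device–radiologist indicators s_ij;
- objective 2: xᵢ, yᵢ = means of the device–senior and device–junior
  indicators.

Across subjects these score vectors are i.i.d., so p̂ᵣ = mean(rᵢ) etc. are
unbiased and asymptotically normal regardless of the within-subject
dependence; this is the GEE estimator with working-independence
correlation, and all inference is large-sample (z-based). No finite-sample
(t) correction is applied, matching the asymptotic design formulas being
checked.

## Tests

- Objective 1, one-sided upper at level α (one-sided because the
  hypothesis is one-sided and a two-sided test would inflate the sample
  size at small margins): reject H₁: pₛ ≤ pᵣ − δ₁ iff
  Z₁ = √n(p̂ₛ − p̂ᵣ + δ₁)/σ̂₁ > z₁₋α with the null-anchored variance
  σ̂₁² = n⁻¹Σ(sᵢ − rᵢ + δ₁)². The GEE sandwich alternative
  σ̃₁² = n⁻¹Σ(sᵢ − rᵢ − (p̂ₛ − p̂ᵣ))² (the empirical variance of the
  differences) is asymptotically identical under H₁ and available via
  `variance_flavor="gee_robust"`; the null-anchored flavor is the default
  because it is the statistic whose operating characteristics the
  Monte-Carlo study certifies.
- Objective 2, two-sided: reject H₂: pₓ = p_y iff
  |Z₂| = |√n(p̂ₓ − p̂_y)/σ̂₂| > z₁₋α/2, σ̂₂² = n⁻¹Σ(xᵢ − yᵢ)².

Variance divisors are 1/n, not 1/(n−1): the power and sample-size
formulas invert exactly these estimators. A degenerate variance (all
per-subject differences identical, σ̂ = 0 up to a 1e−24 floating-point
floor) raises an error instead of returning an infinite statistic — it is
a finite-sample artifact the asymptotic theory does not cover, and the
caller must decide. p-values are reported alongside the reject flag as a
convenience.

## Compound correlation algebra

Planning requires ρ₁ = corr(rᵢ, sᵢ) and ρ₂ = corr(xᵢ, yᵢ). Writing
f_s(ρ) = 1/m + (m−1)ρ/m and
f_r(ρa, ρb) = 2/(m(m−1)) + 4(m−2)ρa/(m(m−1)) + (m−2)(m−3)ρb/(m(m−1)),
the marginal-rate factors cancel and

ρ₁ = [(2/m)ρ_s1 + ((m−2)/m)ρ_s2] / √(f_r(ρ_r1, ρ_r2) · f_s(ρ_ss)),
ρ₂ = ρ_xy / √(f_s(ρ_xx) · f_s(ρ_yy)).

The ρ₂ expression follows from the same covariance algebra as ρ₁ (each of
the m² cross covariances contributes ρ_xy·√(pₓqₓp_y q_y)); it is verified
in the test suite against a Monte-Carlo oracle (empirical corr(xᵢ, yᵢ)
over 10⁵ simulated subjects within 0.01) and against the four published
offset-constrained tuples.

Because one scalar target cannot identify five (or three) components, the
inverse solvers adopt the offset constraints used in the numerical
studies — ρ_s1 = ρ_s2 + 0.1, ρ_r1 = ρ_r2 + 0.1, ρ_ss = ρ_r1 = ρ_s1 + 0.1
(objective 1, Brent root-find on ρ_s2 to 1e−10 over the feasibility
interval derived from the linear constraints), and ρ_xx = ρ_yy = ρ_xy +
0.1 (objective 2, closed form). General multi-parameter identification is
out of scope; pilot data can instead be fed to
`estimate_components_from_pilot`, which pools empirical Pearson
correlations over all indicator pairs within each structural class
(shared-reader r-pairs, disjoint r-pairs, r-vs-s sharing a reader, …) and
refuses constant indicator columns.

## Power and sample size

At the design alternative (pₛ = pᵣ for objective 1; p_y = pₓ − δ₂ for
objective 2) the variance of the score difference is

σ₁² = var(sᵢ) + var(rᵢ) − 2ρ₁√(var(sᵢ)var(rᵢ)),
  var(sᵢ) = pᵣ(1−pᵣ)f_s(ρ_ss), var(rᵢ) = pᵣ(1−pᵣ)f_r(ρ_r1, ρ_r2),

and analogously σ₂² with var(xᵢ) = pₓ(1−pₓ)f_s(ρ_xx), var(yᵢ) =
(pₓ−δ₂)(1−pₓ+δ₂)f_s(ρ_yy). Power at n subjects is
Φ̄([z₁₋α√(σ² + δ²) − √n δ]/σ) (z₁₋α/2 for objective 2; the far-tail
rejection probability of the two-sided test is ignored, as is standard),
and the required n is the inversion, rounded up to an integer. Ceiling
rounding is adopted because it is the conventional "at least this power"
reading and reproduces every published table cell (e.g. 209.47 → 210);
quantiles come from `scipy.stats.norm` at machine precision — a printed
z-table is not accurate enough for exact table reproduction. The
objective-1 n depends on pᵣ only through pᵣ(1−pᵣ), giving the exact
pᵣ ↔ 1−pᵣ symmetry asserted in the tests.

## Correlated binary simulation

Indicator vectors (dimension m(m−1)/2 + m for objective 1, 2m for
objective 2) are generated by dichotomising a multivariate standard
normal: indicator k = 1 iff Z_k > τ_k with τ_k the upper-tail quantile of
its marginal. For each pair the latent correlation is solved exactly
(Emrich–Piedmonte inversion of the bivariate-normal orthant probability,
Brent to 1e−12, with Fréchet-bound limits substituted at ρ → ±1), because
the asymptotic variances under test are functions of the *binary*
correlations — copying binary targets onto the latent scale would bias
the operating characteristics. Feasibility of every target correlation is
checked against the Fréchet bounds for its marginal pair before solving.

Pairwise-solved latent matrices can be marginally non-PSD; they are
repaired by clipping eigenvalues at 1e−10 and renormalising to unit
diagonal. The maximum entry perturbation is recorded on the `LatentModel`
and a warning is emitted above 0.01 (at the standard design settings the
perturbation is zero). Two deliberate non-features: joint distributions
beyond pairwise moments follow the Gaussian copula and are not asserted,
and logical transitivity of exact-match concordance (r₁₂ = r₁₃ = 1 ⇒
r₂₃ = 1) is *not* enforced — indicators are simulated directly, which is
what the score-level asymptotics consume. Passing Monte-Carlo checks
therefore certify the tests under the assumed moment structure, not under
every joint distribution a real reader panel could produce.

A separate i.i.d. categorical `simulate_readings` generator exists purely
as an I/O fixture; it carries no correlation structure.

## Monte-Carlo study

For each design cell the study solves components, computes n, simulates
trials under the null boundary (pₛ = pᵣ − δ₁, or pₓ = p_y at rate pₓ) and
under the alternative, both with the same component correlations (the
design tables use a single tuple per ρ, so correlations are held fixed
across hypotheses), and reports rejection fractions with binomial
Monte-Carlo standard errors. Replicates with degenerate variance are
counted; more than 0.1 % of them aborts the cell. Simulation is
vectorised over replicates in blocks capped at 8 M latent draws.

Seeding is hierarchical — `SeedSequence(seed, spawn_key=(objective,
cell_index, hypothesis))` — so every cell/hypothesis stream is
reproducible independently of which other cells run. Default replicates:
10,000 per hypothesis (the scale of the published tables; ~10 s per cell
single-threaded); the bundled tests and the acceptance checks use 2,000
for the per-cell sweeps, where the binomial standard error (≈ 0.005 for
size, ≈ 0.009 for power) is comfortably inside the asserted envelopes
(size 0.05 ± 0.015, power ± 0.04).

## Scope notes and limitations

- Each lexicon classification is tested separately; no multiplicity
  adjustment is applied across classifications (none is standard for this
  design — trials typically power only the primary classification).
  Adjustment, if wanted, is left to the user.
- Two-stage/adaptive re-estimation is supported only to the extent of
  pilot-based component estimation; stopping rules are out of scope, as
  are kappa-type agreement measures, ordinal/weighted concordance,
  unequal group sizes for objective 2, and multiple lesions per subject.
- All inference is asymptotic in n; at the small end of the design tables
  (n ≈ 50) the Monte-Carlo study itself is the evidence that the normal
  approximation holds.
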