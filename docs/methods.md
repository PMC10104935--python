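# Methods

## Error-statistical severity

The severity function is implemented for the one-sided-greater test of a
normal mean with known standard deviation. With standard error
se = σ/√n, the test rejects H₀: μ ≤ μ₀ when x̄ ≥ μ₀ + z₁₋α·se, and the
severity of the claim C: μ ≥ μ₁ given x̄ is Φ((x̄ − μ₁)/se) — the
probability of a result no larger than the observed one at the claim
boundary. The boundary point μ = μ₁ is used as the representative of
"C is false" because it is the point in C closest to the null; any other
representative would give a larger severity, so the reported value is a
lower bound on P(less extreme data; not-C).

Two deliberate exposures of the construction's behavior: the rejection
cutoff is returned exactly (151.96 for the reference example, alongside
its conventional rounding), and the severity value is computed without
reference to μ₀, so that two tests differing only in their null value
return identical severities. That invariance is asserted as a property —
it is the substantive point that severity assessments in this style are
blind to the scientific context, which motivates the Bayesian half of
the package.

Only the one-sided-greater direction is implemented; the spec type
carries a `direction` field so a lesser/two-sided extension is additive
rather than a signature change. The test statistic is the standard
z-statistic (x̄ − μ₀)/se, under which all reference values reproduce.
Probability comparisons in tests use 1e-9 absolute tolerance; the
CDF/SF complement identity holds to 1e-12.

## Encompassing-prior Bayes factors for interval hypotheses

The encompassing model H_e places independent Beta(1,1) priors on the two
success rates; an interval hypothesis H = [lo_A, hi_A] × [lo_B, hi_B]
inherits the truncated uniform as its prior. For a hypothesis nested in
H_e this makes the Bayes factor equal to the ratio of posterior to prior
mass of H's region, and both masses factor over arms:

- prior mass = Π (hi − lo) — the hypothesis's *specificity*;
- posterior mass = Π [F(hi) − F(lo)] with F the Beta(S+1, N−S+1) CDF.

Everything is computed from regularized incomplete beta functions; no
quadrature or sampling is used on the main path. Quadrature and Monte
Carlo appear only as independent oracles in the test suite, where the
mass-ratio route is also checked against the marginal-likelihood route
p(y|H)/p(y|H_e) at 1e-6 relative tolerance (the two are equal
analytically; the check guards the implementation, and runs inside
`bf_vs_encompassing` as well). An outcome with numerically zero posterior
mass yields bf = 0 with log_bf = −∞ and an `underflowed` flag rather than
an exception, since full-lattice displays legitimately contain such
entries. Natural logarithms throughout.

Point (zero-width) hypotheses are rejected: they have measure zero under
the encompassing prior and need a different construction entirely.
Hypotheses are two-arm boxes; the product form would extend to K arms
but only K = 2 is exposed.

### Prior predictive distributions and HDRs

The per-arm prior predictive of S successes in N trials under a truncated
uniform on [lo, hi] is

p(S) = [F₍S+1,N−S+1₎(hi) − F₍S+1,N−S+1₎(lo)] / ((N+1)(hi − lo)),

using C(N,S)·B(S+1, N−S+1) = 1/(N+1); the joint lattice pmf is the outer
product of the arms. A discrete highest-density region of coverage X is
built greedily: support points enter in decreasing pmf order until the
accumulated mass reaches X, and any point whose pmf ties the last
admitted one (relative tolerance 1e-12) enters with it, so symmetric
predictives never get an arbitrarily broken tie. HDRs are computed on
per-arm marginals, which is what the reference displays report. One
borderline case is worth recording: for the specific hypothesis at
N = 20, arm A, the masses of S = 0 (0.004126) and S = 11 (0.004070) are
close enough that displays produced by other means may swap them; the
exact greedy region is {1..10}, making the 99% complement {0} ∪ {11..20}.

## Expected evidential value

The pre-experimental severity measure is E_y[|ln BF(y)|] with the
outcome distribution p(y) = w_c·p(y|H) + w_e·p(y|H_e), a convex mixture
of the two models' prior predictives. The outcome space is the finite
lattice, so the expectation is an exact sum — no integration error. The
model weights default to (0.5, 0.5), the symmetric choice when the
design genuinely entertains both models; they are a parameter, and the
reference values (6.32, 3.14, 1.61, 1.25 nats for the four worked
designs) reproduce only under equal weights and natural log, which fixes
the reading of both conventions. Outcomes with p(y) = 0 contribute
nothing regardless of their Bayes factor; a zero Bayes factor at an
outcome with positive mixture mass would make the expectation infinite,
and is reported as such rather than clipped (it cannot occur for
box-interval hypotheses, whose posterior region masses are strictly
positive on the open unit square).

Posterior-odds updating is the plain product rule, and the
empirical-content calculator counts tolerated binary sequences in exact
integer arithmetic (closed forms for "exactly k of n" and fully
specified patterns; brute-force enumeration otherwise, refused above 25
slots where 2^n exceeds 3·10⁷).

## Bayes factor design analysis

One replicate draws n observations per group from N(0,1) and N(d,1),
forms the pooled-variance two-sample t (group 2 minus group 1), and
converts it to the JZS Bayes factor: H₀ fixes the standardized effect δ
at 0; H₁ gives δ a Cauchy(0, r) prior. Given δ, the t statistic is
noncentral t with ν = n₁+n₂−2 and noncentrality δ√(n₁n₂/(n₁+n₂)), so
the H₁ marginal is a one-dimensional integral over the prior. It is
evaluated with 96-node Gauss–Legendre quadrature after the substitution
δ = r·tan(φ), which absorbs the Cauchy tails into a finite interval;
against an adaptive-quadrature oracle the result is accurate to ~1e-13
relative, far inside the 4-significant-digit requirement.

Defaults: r = √2/2 (the conventional medium prior scale) and a
*directional* alternative — a half-Cauchy on δ > 0 — because a design
analysis that stipulates a positive true effect is normally paired with
the directional test of that effect. The symmetric two-sided prior is
available (`alternative="two-sided"`); it roughly doubles the
misleading-evidence rate at the reference design (19.5% vs 9.6% at
n = 36, d = 0.4) because negative-t samples that the half-Cauchy
numerator penalizes heavily are merely mildly discounted by the
symmetric one. Sensitivity to the prior scale at the reference design
(directional, exact threshold inversion rather than simulation):
r = 0.5 → 5.0% misleading / 57.3% inconclusive; r = √2/2 → 9.6% / 55.2%;
r = 1.0 → 15.7% / 52.4%.

Classification uses open thresholds: evidence for H₁ iff BF > U,
evidence for H₀ iff BF < L, inconclusive otherwise; with a positive true
effect the BF < L rate is the misleading-evidence rate. The three rates
sum to one by construction and carry binomial standard errors. Runs are
bit-reproducible from the seed; `rate_curve` spawns independent child
seeds per sample size from one root seed. Only the fixed-n design is
implemented; sequential designs are out of scope.

### Numerical note: the noncentral t density at large ν

The scipy noncentral-t pdf overflows for ν beyond a few hundred in parts
of the (t, ncp) plane, which a 190-per-group design already reaches. The
package therefore evaluates log f(t; ν, μ) through the chi–normal
integral representation, reducing it to gammaln terms plus
∫₀^∞ s^ν exp(−(s−a)²/2) ds, computed by trapezoidal log-space quadrature
(160 points over ±10 local scales around the integrand's mode) and
logsumexp. Validated against scipy at ν ≤ 300 to better than 1e-10
relative; no overflow at any ν.

## Synthetic data and what the tests show

All inputs are synthetic by nature: the package's subject is the test
procedures themselves, and the simulation half (BFDA) generates exactly
the data its model assumes — independent normal groups with unit
variance and a mean shift. Passing tests therefore certify the
arithmetic and the simulation logic, not robustness to variance
heterogeneity, non-normality, or optional stopping, none of which are
modeled. Problem sizes in tests and in the acceptance script are the
worked-example sizes themselves (lattices up to 21×21, 10⁴ BFDA
replicates), which the package treats as its reference conditions.

## Interface decisions

The library is the primary surface; the `sevbayes` CLI is a thin
dispatcher over it with one subcommand per analysis plus `run` for
scenario files. Scenario YAMLs validate against a per-kind key schema
and reject unknown keys by name. JSON is the canonical output (stdout
and `--output` directory); CSVs are written only for tabular
by-products (severity curves, per-outcome tables, BF lattices and
samples). Exit codes: 0 success, 2 configuration error, 3 numerical
error. Logging goes to stderr at INFO, including seeds and wall time.
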