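# Methods

## The problem

Multiple imputation (MI) replaces each missing value m times, yielding m
completed datasets.  For a scalar point estimator Q with per-imputation
estimates Q_i and variance estimates U_i, Rubin's rules give

    Q̄ = mean(Q_i)
    Ū = mean(U_i)
    B = Σ(Q_i − Q̄)² / (m − 1)        (between-imputation variance)
    T = Ū + (1 + 1/m) B               (total variance)

The classical argument for small m rests on the relative efficiency
RE = (1 + γ₀/m)^(−1/2) (γ₀ the fraction of missing information), which is
already near 1 at m = 3.  But RE says nothing about the stability of B
itself, and B is the quantity MI exists to deliver: without a reliable B,
single imputation would do.  This package determines η, the minimally
sufficient m, from how fast the sampling error of B shrinks with m.

## The replication design

A pool of M completed copies of the target variable (default M = 500) is
treated as the population of imputations.  For each m on a grid (default
2, 3, 5, 10, 15, 20, 25, 30, 35, 40, 60, 80, 100), n independent MI samples
(default n = 10) of m *distinct* pool columns are drawn — without
replacement within a sample, independently (overlap allowed) across
samples.  Each sample yields one B; the spread over the n replicates is

    V_B = Σ(B − B̄)² / (n − 1),   SD_B = √V_B,   ω = SD_B / √n.

ω(m), the standard error of B, is the decision curve.  If the Q_i are
i.i.d. normal, B is distributed as σ_B²·χ²_{m−1}/(m−1), so
Var(B) = 2σ_B⁴/(m−1) and ω falls like (m−1)^(−1/2); the acceptance suite
verifies the fitted log ω vs log(m−1) slope is −0.5 ± 0.1 on synthetic
normal pools.  E[B] does not depend on m, only its spread does.

Randomness: each (m, replicate) pair consumes a `SeedSequence` substream
keyed by the m *value* (not its grid position), so the B values at a given
m are unchanged by adding or removing other grid points, and the whole
curve is bit-reproducible from one master seed.  ω is computed from
unrounded B values; rounding happens only in display.

## Hot-deck imputation

Donor groups are the cells of the complete categorical stratifiers
(region × specialty × employment code by default).  Each missing cell is
filled with the value of a donor drawn uniformly with replacement from the
recipient's cell, independently across cells and across the M pool copies
(cell-wise hot deck; variables are imputed separately, one pool each).
Uniform unweighted selection matches an unweighted analysis.  Observed
cells are identical in every pool copy — only originally-missing cells
vary, which is exactly what B measures.

By default an empty donor cell is an error naming the cell.  The pipeline
enables a documented fallback (`collapse=True`): a recipient in an empty
cell is matched on progressively fewer key columns, dropped from the right
(employment code first, then specialty).  This exists because simulated
stratifiers are independent, so a 448-cell grid over 2567 records reliably
strands a few recipients — real survey stratifiers are correlated and
their joint cells better populated.

## Deciding η

**Moving regression.**  Slide a window of h = 3 consecutive grid points
and fit OLS of ω on m.  Report S₅ = 5·slope (ω change per 5 extra
imputations) and RS₅ = 100·S₅/ω̄ (the same as a percent of the window's
mean ω).  Scanning from low m, η is the middle point of the first window
with |RS₅| < cutoff (default 10; equality does not qualify).

With only three points per fit, one aberrant ω can fake a flat window.  A
window is flagged as an outlier artefact iff its |RS₅| is below the cutoff
*and* one of the next three windows (toward higher m) is above it.  Flagged
windows are attributed to an outlier grid point o_m and resolved by
averaging the RS₅ of the window whose largest m is o_m with that of the
window whose smallest m is o_m: |average| < cutoff makes o_m itself η;
otherwise every window containing o_m is treated as above the cutoff and
the scan continues.

Two situations the flag/average prose leaves open are settled as follows:

* *Attributing o_m.*  When the flagged windows jointly contain more than
  one shared grid point, the outlier is taken to be the shared point whose
  ω deviates most from the linear interpolation of its two grid
  neighbours.  This picks the visually obvious bump on the reference
  worksheet (m = 25) and correctly attributes a dip to the dip rather than
  to the rebound after it.
* *Edges.*  If o_m is too close to a grid edge for both flanking windows
  to exist, `resolve_outlier` raises (no principled average exists).  The
  full decision scan instead treats the unresolvable cluster
  conservatively as exceeding the cutoff, records the event in the audit
  trail, and keeps scanning — a crash would otherwise occur stochastically
  on simulated curves.

h must be odd (the "middle point" of an even window is undefined); h = 3
is the default and the only width with published worked values.

**Confidence interval.**  B̄ at each m is a mean of n replicate B values;
B is approximately a scaled χ²_{m−1}, so B̄ is near-normal even at small m
and a Student t interval applies with n − 1 degrees of freedom (t = 2.2622
at the default n = 10).  The statistic is

    P = 100 · t₀.₀₅ · ω / B̄,

the half-width of the 95% CI as a percent of B̄.  η is the smallest grid m
with P strictly below the cutoff (default 15).  P is invariant to
rescaling the variable, and no monotonicity is enforced: a later rebound
of P above the cutoff (sampling noise) does not revoke the first crossing.
Normality of B̄ is not re-verified per run; a diagnostic check would gate
nothing that the t approximation does not already absorb at these n.

The two rules answer different questions (curve flatness vs relative
precision) and legitimately disagree: on the bundled reference worksheet
they give η = 60 and η = 40 from the same curve.

## The synthetic survey

The default generator emulates a 2567-record physician workflow mail
survey: complete stratifiers REGION (4 levels), SPECR (14 levels), PRIMEMP
(8 levels); a 1–100 practice-size master variable with 3.62% missing plus
its deterministic 2-group (solo vs group), 5-group (breaks 1, 3, 8, 20)
and top-coded-at-20 recodes sharing the master's missing cells; and a 0–99
clinical-staff count with 8.88% missing.  Missingness is MCAR: exactly
round(fraction × n) cells (half away from zero — 93 of 2567 at 3.62%)
blanked uniformly at random, independent of every stratifier.

Stand-ins and their limits: the stratifier level probabilities, the
right-skewed truncated-geometric count distributions (p = 0.12 and 0.10)
and the 5-group recode boundaries are plausible choices, not calibrated to
any microdata (the source survey's marginals are not public).  The
generator also makes stratifiers mutually independent and missingness
purely MCAR, neither of which holds in real surveys.  A green test on
synthetic data therefore establishes that the machinery (donor-group hot
deck, replication design, decision rules, seeding) behaves correctly and
that the ω curve has the theoretically expected shape — not that any
particular η value generalises to real data.  Published-worksheet
reproduction tests cover the numerical fidelity of the decision rules on
real-survey-derived numbers.

Note on scale: with the default Q (the unweighted mean of a 2567-record
variable), B is of order n_missing·σ²/n² ≈ 10⁻⁵ — far below the ~1.0
reported for comparable survey variables, whose estimator was not
disclosed.  η depends only on the shape of ω(m), never on the scale of B
(RS₅ and P are both scale-free), so no attempt is made to match B
magnitudes; the point estimator is injectable for users whose Q differs.

## Numerical choices

* OLS slopes via the centred cross-product formula; verified against
  brute-force normal equations to 1e-10 relative.
* B via the two-pass sample variance, divisor m − 1; V_B divisor n − 1.
* Strict inequalities at every cutoff comparison.
* Worksheet CSVs round to display precision (4 decimals for ω-related
  columns); decision JSONs keep full precision.
* Degenerate inputs: constant ω gives slope = RS₅ = 0 (qualifies under any
  positive cutoff); ω = 0 gives P = 0; B̄ ≤ 0 or missing n is an error in
  the CI method; m < 2, empty vectors, even h, and grids shorter than h
  are errors.

## Known limitations

* Cell-wise hot deck only; no model-based or joint multivariate
  imputation, no survey weights.
* The replication design assumes the pool (M = 500) is large relative to
  the biggest m tested; at m = 100 the without-replacement finite-pool
  correction slightly steepens the ω curve (visible only as a small bias
  in the −0.5 scaling slope).
* Published-worksheet reproduction is tolerance-based where the printed
  tables mixed rounded and unrounded intermediates (their RS₅ −1.03 row
  reproduces exactly only from the rounded S₅ −0.0011; this package
  standardises on unrounded arithmetic).
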