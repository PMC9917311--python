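# Methods

## Model

The state of a cell is its karyotype, an integer copy-number vector over M
chromosome types (M = 1 for the aggregate ploidy model, 22 for whole
autosomes). The population is a nonnegative abundance vector **n** over the
finite box of viable karyotypes, one copy-number interval [k_c, K_c] per
chromosome. Dynamics are linear and deterministic:

    dn_i/dt = Σ_j λ_j q_(j→i) n_j − λ_i (1 − q_ii) n_i − μ_i n_i,

i.e. d**n**/dt = J **n** with J_ii = λ_i (2 q_ii − 1) − μ_i and
J_ij = λ_j q_(j→i). The column convention d**n**/dt = J **n** is used
throughout; the row form **n** J has the identical spectrum, so every
spectral statement is convention-free.

### Division tensor

Copy-number coordinates count whole chromosomes before S-phase: a parent with
i_k copies replicates to 2 i_k chromatids and a daughter receives
j_k ∈ [0, 2 i_k], with exact conservation 2 i_k = j_k(1) + j_k(2). Each copy
missegregates independently with probability β (per copy per division); a
missegregated copy's chromatid pair lands wholly in one daughter with
probability 1/2. The resulting per-chromosome shift law P(t | i_k) is
symmetric, sums to 1, and satisfies P(t | i_k) ≤ 1/2 for all t ≠ 0. The
first-daughter distribution is the product over chromosomes; the
division-event distribution doubles the off-diagonal entries (the daughter
pair (j, 2i − j) realizes the event through either member), so its rows sum
to 2 − q_ii. Off-diagonal entries are computed as 2 × the first-daughter
probability, using the proven symmetry of the shift law, rather than as two
separate products — numerically identical and half the work, and it makes
the mirror identity q1(i→j) = q1(i→2i−j) explicit in the data structure.

Entries below 1e−12 are dropped *without renormalization*: renormalizing
would silently alter net growth, which the extinction analysis hinges on.
Parents with a zero-copy chromosome never divide (nullisomy is lethal); this
also sidesteps 0^0 ambiguities in the shift law.

**Truncation.** For extinction analysis the tensor is restricted to the
viable box and flux to nonviable daughters is dropped — those daughters die
on arrival and leave the system. The untruncated form cannot live on the
viable box (a parent at the ceiling K reaches daughters up to 2K), so
`division_tensor(..., truncate=False)` enumerates the full reachable box
[0, 2 K_c] with only viable states as parents; nonviable daughters are dead,
non-dividing states. On that enumeration the normalization identities (rows
of q1 sum to 1; parent columns of J sum to λ − μ) hold exactly and are
tested.

### Extinction analysis

J is Metzler (nonnegative off-diagonal), so its spectral abscissa is a real
eigenvalue — the Perron root of the nonnegative shift J + cI minus c. The
population grows iff s(J) > 0. Implementation: dense eigendecomposition up
to 1200 states, ARPACK on the shifted matrix above that, dense fallback on
non-convergence; failure raises rather than returning NaN.

*Critical turnover.* With homogeneous birth and death, death enters only as
−μI, so J(μ) = A − μI and the critical turnover is μ_crit/λ = s(A)/λ — one
eigensolve per missegregation rate instead of 2-D root finding. For
heterogeneous death kernels the dominant eigenvalue is driven to zero by
bisection (Brent) on a global multiplier of the death kernel; the multiplier
is reported as the critical turnover scale, and points with no bracket are
reported as NaN, never fabricated.

*Gershgorin screens.* MIE is ruled out if every Gershgorin disc lies in the
open right half-plane: min_i (J_ii − Σ_{j≠i} J_ij) > 0, or the column
analogue. Because a matrix and its transpose share a spectrum, either margin
positive suffices; both margins are reported and the screen is their OR.
Three closed-form scenarios are provided: (1) at most one missegregation per
division with homogeneous rates — safe iff β < (1 − μ/λ)/4, where β is the
per-division probability in the nearest-neighbor (tridiagonal) tensor;
(2) fully heterogeneous rates on the 1-D aggregate model — safe iff
λ_i(1 − 3β_i) − μ_i − λ_{i+1}β_{i+1} > 0 for all i; (3) homogeneous β —
safe iff β < (1 − μ_i/λ_i)/(3 + λ_{i+1}/λ_i) for all i. States above the
viable ceiling contribute no inflow term (the boundary convention is not
otherwise determined). These are sufficient, not necessary: a population can
grow while both margins are negative.

*Kronecker factorization.* With homogeneous rates the truncated
single-daughter matrix of a product box factorizes over chromosomes,
Q = ⊗_c Q_c, and J = 2λ Qᵀ − (λ+μ)I, so the joint critical turnover is
2 Π_c ρ(Q_c) − 1 from per-chromosome spectral radii. The identity is
validated entrywise and spectrally against explicitly built 2-chromosome
generators; it is what makes the 22-autosome analysis a handful of 8×8
eigensolves.

*Steady-state proportions.* The dominant right eigenvector of J, sign-fixed
nonnegative and normalized to sum 1; a complex or non-simple dominant
eigenvalue (gap tolerance 1e−9) is an explicit error.

*Continuum limit.* Treating DNA content p as continuous gives the
reaction-diffusion model ∂n/∂t = (λ−μ) n + βλ ∂²n/∂p² with absorbing
boundaries at p_min and p_max (the viable-content interval; the model only
states that populations outside it cannot survive, and absorption is the
conservative reading). Separation of variables gives the dominant growth
eigenvalue (λ−μ) − βλπ²/L², L = p_max − p_min, hence
μ_crit/λ = 1 − βπ²/L². The timescale heuristic (extinction plausible when
the diffusion timescale L_p²/(βλ) is much shorter than the growth timescale
1/(λ−μ)) is reported as a boolean with a configurable "much less than"
factor, default 0.1; L_p defaults to the interval width.

### Quasi-steady state (QSS)

Simulations start from a uniform diploid population (all mass on the all-2s
karyotype, clamped into the box; configurable) and integrate in windows of
`dt_check` days (default 10) using the sparse matrix-exponential propagator,
which is exact for this linear system up to roundoff and preserves
nonnegativity. The abundance vector is renormalized each window and the log
of the total accumulated separately, so exponential growth or decay over
10^4 days never overflows a double. QSS is declared when the L1 change in
karyotype composition per day drops below `qss_tol` (default 0.001/day, i.e.
0.1%/day; L1 is the strictest simple aggregate of per-state changes). At QSS
the sign of the log-total growth rate classifies growth versus extinction;
non-convergence by `t_max` (default 10^4 days) is flagged, never silently
classified. The population-average missegregation rate β_pop is the
cell-proportion-weighted fraction of divisions with at least one
missegregation, Σ_i p_i (1 − (1−β_i)^{‖i‖₁}); weighting by divisions
(λ_i p_i) would coincide for homogeneous birth rates, and cell weighting is
the simpler convention. μ_pop is the proportion-weighted mean death rate.

## Rate kernels

Birth, death and missegregation rates are functions of karyotype. Units:
λ, μ in events per cell per day; β is a probability per chromosome copy per
division, converted to a per-division probability by 1 − (1−β)^copies.

* **constant** — homogeneous populations; turnover μ/λ > 1 is allowed (a
  shrinking population is a regime, not an input error).
* **linear** — β(i) = clip(b0 + θ1·(i[c] − c_ref), floor, ceil), slope θ1
  per extra copy of one chromosome, reference copy number c_ref = 2
  (diploid), floor 1e−4, ceil 1.
* **sinusoidal** — β(i) = clip(b0 + θ2·cos(2π(ploidy − p_peak)/period)),
  anchored by its maximum at p_peak. Defaults p_peak = 66 (the near-triploid
  autosome total, where observed per-chromosome missegregation rates peak)
  and period 44 (one diploid-equivalent of ploidy, putting the minimum at
  the diploid and tetraploid totals). The functional constants behind the
  empirical ploidy–missegregation relationship are not published at point
  level, so θ2, b0, p_peak and period are all user parameters.
* **tabulated** — exact per-state lookup, validated for completeness against
  a space up front; missing states are named errors.

Death kernels reuse the same families so missegregation- and death-rate
kernels can be combined pairwise. With heterogeneous β and homogeneous
death, the steady state concentrates on the minimum-β ("refuge") karyotype
and the population-average β stays above the minimum. Note one tempting
bound that is *false* in general: the kernel model's critical turnover is
not bounded below by the homogeneous curve at min_i β_i — the refuge leaks
into higher-β neighbors (e.g. a sinusoidal kernel with b0 = 0.05,
θ2 = 0.01, period 4 on the ploidy box [2, 10] gives μ_crit = 0.9761 versus
0.9803 for homogeneous β = 0.04). The bound that holds, and is tested, is
against the homogeneous curve at max_i β_i.

## Inference from expression summaries

The inference layer consumes precomputed tables (chromosome-level mean
expression for tumor and normal cell groups, differential-expression
p-values, pathway/interferon scores); upstream normalization, pathway
scoring and differential testing are out of scope.

**Ploidy.** Chromosome-level expression is assumed proportional to copy
number up to one global tumor/normal scale factor (clonal SCNAs, at least
one diploid chromosome). Chromosomes are sorted by differential-expression
p-value, least significant first, so the leading x chromosomes are the
diploid candidates; for each x the scale s_x is their mean tumor/normal
ratio, the rest get raw estimates j_k = 2·ratio_k/s_x, and the x minimizing
an integer-deviation error wins (ties to the smallest x). The reported bias
is 1 − s_x (deviation of the mean diploid ratio from 1); the scale-factor
formulation avoids the division by zero the raw bias definition suffers on
unbiased data. Rounding is half-away-from-zero to keep exact .5 estimates
deterministic. Two deliberate choices where the procedure was underdefined:

* *Sort order.* "Most significant first" would put SCNA chromosomes in the
  assumed-diploid set; the default puts the least significant first, which
  is the only ordering under which the scale is a diploid baseline. The
  literal ordering remains available (`sort_mode="significance_first"`).
* *Error criterion.* Scoring only the non-candidate set's deviation from
  integers is non-identifiable: a balanced contamination of the candidate
  set (one gained plus one lost chromosome cancelling in the mean ratio)
  leaves every remaining estimate near an integer while the candidate set is
  wrong, and the argmin lands there in a third of random aneuploid
  karyotypes. The default (`error_mode="full"`) therefore also scores the
  candidate set's deviation from exactly 2, which restores identifiability
  (exact recovery in 100% of 200 seeded fixtures at noise σ = 0 and 0.02);
  the literal criterion is kept as `error_mode="scna_only"`.

**Turnover.** Ordinary least squares of literature turnover rates on a
cell-death pathway score; per-cell turnover τ = a·score + b, with birth rate
set to 1 and death rate μ := τ downstream. Cells with τ > 1 (beyond
homeostasis) are flagged, not clipped.

**Missegregation.** OLS of log2(% cells with lagging chromosomes) on
interferon gamma signaling activity. Prediction inverts the log
(2^L / 100 = per-division missegregation probability) and divides by ploidy
to obtain the per-copy rate β — the only reading of the calibration that
lands in (0, 1). Values clipped into [0, 1] are reported as clipped.

## Synthetic data

The generators emulate the inference inputs with known ground truth, all
deterministic under a fixed seed:

* expression summaries: normal means lognormal around a common baseline
  (scale 10, σ = 0.3); tumor mean = bias · (copies/2) · normal ·
  exp(N(0, σ²)) with multiplicative lognormal noise (positivity guaranteed,
  matches ratio behavior); p-values are a deterministic monotone surrogate
  of |copies − 2| with seeded jitter — diploid chromosomes draw from
  [0.5, 1], aneuploid ones are shrunk by 10^(−3·|copies−2|), since only the
  rank order enters the estimator. Defaults for randomized recovery studies:
  karyotypes uniform in [1, 4] per autosome, bias uniform in [0.5, 1.5],
  noise σ up to 0.02.
* calibration tables: y = a·x + b + N(0, sd²) on a fixed grid.
* division sampling: per-copy missegregation and daughter assignment drawn
  directly (the mechanism, not the formula), returning both daughters per
  division with exact copy conservation — the independent Monte-Carlo oracle
  for the analytic shift and daughter distributions.

What the generators do **not** emulate: scRNA-seq counts (dropout, library
size, cell-to-cell variability within a group), subclonal SCNAs (a
half-integer fixture is used only to check that the error profile flags
them), chromosome-arm resolution, and real differential-expression testing.
Passing recovery tests therefore demonstrate correctness of the estimation
procedure under its own assumptions, not robustness to real scRNA-seq noise.

## Numerical choices and problem sizes

* Tensor sparsity threshold 1e−12, dropped without renormalization.
* Eigensolves: dense ≤ 1200 states, else ARPACK with dense fallback.
* QSS: dt_check 10 days, tol 0.001/day, t_max 10^4 days.
* Critical-curve bisection: Brent, xtol 1e−10, turnover multiplier bracket
  doubled up to 64.
* Test and acceptance workloads use desk-scale spaces (single chromosomes on
  [1,5]–[1,8], 2-chromosome boxes up to [1,8]², the 22-autosome case via
  factorization) and Monte-Carlo sizes of 10^6 draws with 4σ binomial
  tolerances; these sizes resolve every tested effect while keeping the full
  suite in seconds.

## Limitations

Deterministic ODE dynamics: conclusions hold for large populations where
every karyotype is populated; stochastic extinction of small populations is
out of scope. No density dependence (no carrying capacity or Allee effect),
no whole-genome doubling, no missegregation-induced G1 apoptosis or
micronuclei, no structural CIN, no biased segregation mechanisms. The
Gershgorin conditions are one-sided screens. Calibration fits are univariate
OLS on small tissue-level tables and inherit their uncertainty.
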