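# Methods

`latedose` simulates phase I dose-escalation trials in which the
dose-limiting-toxicity (DLT) risk extends over several treatment cycles,
and compares eight escalation designs under a common data-generating
mechanism, common enforcement/stopping rules, and a shared patient
stream. This note records the models, the numerical choices, and the
places where the design space was genuinely open.

## Trial setting

Six doses (1.5, 2.5, 3.5, 4.5, 6.0, 7.0 MBq, the grid of a
radiopharmaceutical first-in-human trial) are investigated with cohorts
of 3 up to 30 patients. Follow-up spans S = 3 cycles of 6 weeks. A new
cohort enters at the start of every cycle (rolling enrollment), so each
interim decision sees complete data only for cohorts enrolled at least
three cycles earlier and partial follow-up for the rest. The target is
tau = 0.391, the probability of a DLT anywhere in the three cycles; under
the generator's hazard decay this is equivalent to a cycle-1 target of
0.3. The MTD is the maximum dose with whole-follow-up DLT probability on
target or below.

## Synthetic data

Each patient carries one latent uniform variable z that fixes their
outcome on every dose and cycle. With v = 1 - z and p_s the cumulative
DLT probability of a dose through cycle s (conditional cycle hazard
p1 * (1/3)^(s-1)), the patient's DLT cycle is the unique s with
p_{s-1} < v <= p_s (half-open bands; no DLT if v > p_S). Because a
higher dose has larger p_s, the same patient is weakly more toxic on
higher doses; this coupling is what makes the empirical benchmark and
cross-design comparisons meaningful, and the same (seed, replicate)
stream feeds every design.

The maximum grade per cycle is also a deterministic function of z. In
cycle 1 the grade bands follow the piecewise masses tied to p1 (grades 3
and 4 split the DLT mass equally; grades 2/1/0 fill the survivor region,
with larger v mapping to lower grades). For later cycles the printed
scaling of the grade masses by the survivor fraction conflicts with the
cycle's marginal DLT probability from the cumulative formula (the former
gives grade>=3 mass (1-p_{s-1}) p1, the latter (1-p_{s-1}) p1/3); the
source does not reconcile them. Resolution adopted: DLT occurrence is
governed solely by the cumulative bands, a DLT cycle's grade is 3 or 4
with equal probability, and the sub-DLT grades 0-2 are drawn from the
survivor-scaled masses renormalized over the non-DLT region. This
preserves the binary DLT process exactly and reduces to the printed
formulas in cycle 1.

Given the maximum grade, the triple of per-type grades (renal,
hematological, neurological; 125 combinations in total) is uniform over
the combinations attaining that maximum, selected by one auxiliary
uniform per patient-cycle drawn from a separate per-patient stream so
that design choices never perturb outcome draws.

The nTTP (normalized total toxicity profile) of a cycle is the Euclidean
norm of per-type severity weights divided by the norm of the worst-case
weights, so scores lie in [0, 1]. The weight matrix is a package default
(shipped as `data/nttp_weights.csv`, replaceable via
`NttpWeights.from_csv`); the comparison study takes its weights from a
cited reference without printing them, so any fixed monotone matrix
plays the same structural role. The nTTP design's target is derived from
the same mechanism: tau_nTTP = E[nTTP in cycle 1 | p1 = 0.3] (0.332 under
the default weights).

What the generator does **not** emulate: continuous event times within a
cycle, dropout unrelated to DLT, inter-patient heterogeneity beyond the
single latent, and correlation structure between toxicity types beyond
the shared maximum. Passing tests therefore certify the designs'
behavior under this stylized mechanism, not under real trial data.

## Designs

**TITE-CRM (1-parameter).** Weighted power model G = w * d^exp(beta) on
the skeleton d = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30), beta ~ N(0, 1),
weights w = u/S (w = 1 after a DLT). The posterior mean of beta is
computed by dense quadrature on beta in [-10, 10] (2001 nodes; matches a
100k-node oracle to 1e-6). Dose selection minimizes
|skeleton^exp(beta_hat) - tau|. An initial phase escalates one level per
decision until the first DLT is observed anywhere, with only one cycle
of follow-up required between steps (consistent with rolling
enrollment).

**TITE-CRM2.** Two-parameter logistic F = expit(a0 + a1 d) on the
physical doses, a0 ~ N(-1, 1/0.3), log a1 ~ N(log 0.2, 1/0.3) (the
calibrated values are printed as precisions). The posterior is evaluated
on a dense 2-D grid over (a0, log a1) spanning +-6 prior SDs (121x121
nodes) — for two parameters this is deterministic, cheap, and free of
convergence diagnostics; posterior means are grid expectations and
posterior draws are resampled grid points.

**ICSDP.** Discrete-hazard model cloglog(pi_{j,s}) = gamma_s +
theta log d_j fitted by BFGS on the interval-censored likelihood
augmented with fractional pseudo-patients at the two extreme doses
(cycle-1 anchors pi_1* and pi_J*, n0 pseudo-patients each; later-cycle
anchor rates scale the cycle hazard by (1/3)^(s-1), which the model
represents exactly, so the pseudo-data-only fit reproduces the anchors).
Dose selection maximizes the gain 1/(tau - rho_j)^2 with rho_j =
1 - prod_s (1 - pi_{j,s}). A failed optimization retains the previous
estimates and the current dose.

**POMM.** Three-level ordinal outcome (grade <=1 / grade 2 / grade >=3).
First 15 subjects: weighted ML logistic fit of the cycle-1 DLT indicator
vs dose, targeting the cycle-1 tau of 0.3. From subject 16: proportional
odds mixed model logit P(Y<=k) = alpha_k - beta1 d - beta2 s - u_i with
u_i ~ N(0, sigma0^2) integrated out by 21-node Gauss-Hermite quadrature;
the fit is penalized ML (the prior is pseudo-data: total weight n0 = 2
spread evenly over all dose-cycle cells, category probabilities from the
per-dose anchors and grade-2 ratios, decayed across cycles), with a
Laplace approximation supplying posterior draws. Selection minimizes
|1 - prod_s P(Y<=2 | d, s, u=0) - tau|. A DLT cycle contributes its
category-3 term and later cycles nothing — the censored-likelihood
convention, which the data container enforces by construction.

**nTTP.** Bayesian linear mixed model y_{i,s} = beta0 + beta1 x_i +
beta2 s + gamma_i + eps_{i,s} with normal priors on the coefficients and
IG(0.001, 0.001) on both variances. All full conditionals are conjugate,
so the posterior is sampled by a Gibbs sampler (1000 draws after 500
burn-in, seeded from the trial seed and interim index). Selection
minimizes |E(beta0 + beta1 d + beta2) - tau_nTTP| (cycle-1 criterion).

**TITE-BOIN.** Escalation boundaries lambda_e = 0.3512, lambda_d =
0.4492 from the closed forms at the calibrated interval (0.3128,
0.5083). Observed DLTs alone de-escalate when m/n >= lambda_d. With
pending patients, the DLT rate is imputed: p is the Beta posterior mean
under follow-up weighting (effective exposure m + c + STFT) and each
pending patient contributes residual risk p(1-w)/(1-p w); the imputed
rate is compared with the boundaries. No accrual-suspension rule is
applied — with per-cycle rolling cohorts a 50%-pending suspension would
suspend at every newly visited dose and is incompatible with the
reported trial sizes/durations of this design.

**TITE-mTPI2 (keyboard).** Keys of width tau2 - tau1 = 0.1955 tile [0,1]
outward from the target key [0.3519, 0.5474), end keys absorbing the
remainders. The Beta(1,1) posterior on effective binomial data (pending
DLT-free patients count u/S; DLTs count 1) picks the strongest key.
Accrual is suspended while more than half the patients at the current
dose are pending — this reproduces the near-doubled trial durations
reported for the mTPI2 family.

**R-mTPI2.** Rule cascade: plain keyboard on complete data when nothing
is pending; de-escalate when even the best case does; take the move when
best-case (pending all clean) and worst-case (pending all DLT)
imputations agree; otherwise continue at the current dose up to 6
consecutively assigned patients, then suspend. The consecutive limit is
a configurable rule constant standing in for the cited design's full
tables.

**Final selection (model-assisted).** Isotonic regression (weighted
PAVA) of per-dose posterior means with a neutral Beta(1,1) selection
prior, recommending the treated admissible dose closest to tau. Exact
ties are structural (pooled estimates coincide; clean doses tie at the
same posterior mean), so ties are broken directionally: highest tied
dose when the tied estimates are below target, lowest otherwise. A
strictly-lower tie mode is available but degrades correct-selection
rates wherever several low doses are DLT-free. Model-based designs use
their own dose criterion on the complete data, with ties to the lower
dose.

## Enforcement and stopping rules

Setting 1: k-fold enforcement (no more than a 2-fold rise over the
highest dose tried), sufficient-information stop, maximum 30 patients.
Setting 2 adds: hard safety (exclude a dose and all above when
P(p1 > 0.3 | Beta(1+r, 1+n-r)) > 0.95 on cycle-1 data — the 3/3, 4/6,
5/9 triples; stop with no recommendation if dose 1 is excluded), the
lowest-dose-unsafe and highest-dose-safe posterior stops (threshold
0.80, active once the dose has a full cohort; Beta-binomial for the
model-assisted designs and the nTTP design, a cycle-1-restricted refit
for the CRM variants, the design's own cycle-1 estimate for ICSDP/POMM),
and the precision stop CV(MTD) < 0.30 with CV = 1.4826 MAD / median over
posterior MTD draws on the physical dose scale, active once 9 patients
have at least one cycle; it applies to model-based designs only.

The sufficient-information rule fires when the design proposes a next
dose that already carries 9 patients; several rules can trigger at the
same interim and all are recorded. Continuous MTD draws are carried to
the MBq scale with linear extrapolation beyond the grid rather than
truncation (truncation piles draws on the end doses and fires the
precision rule spuriously). When any rule stops enrollment, already
enrolled patients complete follow-up, the trial duration is the
completion week of the last patient (or their DLT), and the final
recommendation is computed from the complete data — none after a safety
stop. A flag (`truncate_duration_at_stop`) instead freezes the clock at
the stopping decision; the reported durations are compatible with the
untruncated reading for most designs and it is the default.

## Calibration and benchmark

Hyper-parameters are calibrated by grid search maximizing the geometric
mean of correct-selection proportions over the six calibration scenarios
(four in setting 1), 1000 replicates per candidate by default; a zero in
any scenario zeroes the score. The shipped defaults are the calibrated
values of the comparison study; `analysis/06_calibration_demo.py` runs a
reduced-replicate search to demonstrate the harness.

The empirical optimal benchmark evaluates every patient's
full-follow-up response on every dose from the shared latent and picks
the dose with mean response nearest the target (nTTP mean for the score
design, DLT fraction otherwise), always with the full 30 patients. Tied
means — which occur exactly whenever adjacent doses share the same true
toxicity — resolve to the highest tied dose below target, mirroring the
MTD definition.

## Numerical choices and problem sizes

Quadrature grids: 2001 nodes on [-10, 10] (1-parameter CRM), 121^2 nodes
over +-6 prior SDs (CRM2). BFGS tolerance 1e-6 with a gradient-based
acceptance of "precision-loss" terminations. Gauss-Hermite: 21 nodes.
Gibbs: 1000 draws / 500 burn-in. Precision rule: 1000 draws (400
grid-argmin draws for POMM). Reported analyses use 500 replicates for
the quadrature/table designs, 100 for the optimization-based fits and 25
for the mixed models; the acceptance script uses 1000 replicates for its
two simulated targets. Boundary ties in the latent bands are
measure-zero and resolved by the half-open convention.

## Known limitations

The later-cycle grade mechanism and the ICSDP/POMM pseudo-data layouts
beyond cycle 1 are consistent constructions, not uniquely determined by
the source study; both are configurable. The R-mTPI2 consecutive-
assignment rule and the TITE-BOIN suspension handling stand in for rule
tables published with the cited designs. Scenario D and the calibration
scenarios are exact; scenarios A, B, C, E, F are synthetic stand-ins for
shapes the study reports only graphically, so their absolute operating
characteristics are indicative rather than reproductions.
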