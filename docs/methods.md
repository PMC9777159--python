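# Methods

## Scope

`neopkpd` implements a developmental population pharmacokinetic–
pharmacodynamic analysis of intravenous meropenem in neonates and young
infants treated for late-onset sepsis: a covariate-parameterized
one-compartment infusion model, FOCE-I mixed-effects estimation with
stepwise covariate selection, an internal/external validation suite
(CWRES, bootstrap, NPDE, VPC, MPE/MAPE), and Monte Carlo
probability-of-target-attainment (PTA) simulation over a dosing-regimen
grid. Because no patient-level data are distributable, a calibrated
synthetic-cohort generator stands in for the study population; it is
first-class, tested code, not a fixture.

## Structural and statistical model

One compartment, zero-order (infusion) input, first-order elimination.
For subject *i* with current weight CW (g), postnatal age PNA (d) and
gestational age GA (wk):

    V_i  = θ1 · (CW/2680) · exp(η_V)
    CL_i = θ2 · (CW/2680)^0.75 · (PNA/12)^θ3 · (GA/36.5)^θ4 · exp(η_CL)

2680 g, 12 d and 36.5 wk are the population median covariates. The
allometric exponents (1 on V, 0.75 on CL) are fixed a priori; the
maturation exponents θ3, θ4 are estimated. Between-subject variability is
exponential (log-normal), η = (η_CL, η_V) ~ N(0, Ω) with Ω diagonal;
residual error is proportional, y = f·(1 + σε), ε ~ N(0,1).

Final estimates used throughout simulation: θ1 = 1.63 L, θ2 = 0.503 L/h,
θ3 = 0.209, θ4 = 2.14, ω_CL = 0.508, ω_V = 0.175 (reported as %CV =
100·ω), σ = 0.288. Two conventions worth noting:

- The IIV percentages are interpreted as 100·sqrt(ω²), the usual
  reporting convention for exponential eta models.
- PNA enters the maturation function in **days** with reference 12 d.
  The source table's footnote nominally labels PNA in weeks while also
  stating that 12 *days* is the population median; days is the only
  self-consistent reading and is used everywhere.

Concentrations are evaluated in closed form — during an infusion
(R₀/CL)(1 − e^(−ke·s)), mono-exponential decay afterwards — with
superposition across doses, and a geometric accumulation factor
1/(1 − e^(−ke·τ)) for steady state. An adaptive Runge–Kutta ODE
integration of dC/dt = R(t)/V − ke·C serves as an independent test
oracle only; the analytic solution is exact and fast enough for
10⁵-scale Monte Carlo.

## Synthetic cohort generator

The generator emulates the study population's printed summaries (n = 78;
GA mean 35.0 SD 4.65 wk, median 36.5, range 26.3–42.1; PNA median 12 d,
range 1–113; BW mean 2349 SD 973 g; CW mean 2661 SD 927 g, median 2680;
CREA median 23.8 µmol/L; BUN median 3.79 mmol/L; ALB median 25.6 g/L;
44.9% of infants with GA > 37 wk). Distribution families were chosen to
reproduce those summaries jointly:

- **GA** — a two-component truncated-normal mixture (46% term,
  N(39.2, 1.3²); 54% preterm, N(31.6, 3.0²); truncated to [26.3, 42.1]).
  A single normal cannot simultaneously match mean 35.0, median 36.5 and
  a 44.9% > 37 wk fraction; the left-skewed preterm/term mixture is also
  the physiologically natural shape for a NICU cohort.
- **PNA** — truncated log-normal (median 12 d, log-SD 0.875 chosen so the
  mean ≈ 17.6 d), truncated to [1, 113].
- **BW** — log-linear fetal-growth regression on GA,
  ln BW = 4.49 + 0.0916·GA + N(0, 0.10²), clipped to [480, 4100] g. This
  induces the realistic GA–weight correlation that drives the joint
  CL distribution.
- **CW** — BW × (1 + 0.011·max(PNA − 7, 0)) × exp(N(0, 0.03²)), i.e.
  postnatal weight gain of ~1.1%/day after a one-week lag, clipped to
  [980, 5310] g.
- **CREA, BUN** — truncated log-normals matched to median and mean (both
  markers are right-skewed; a normal would misplace the median by tens of
  percent).
- **ALB** — truncated normal with location 26.3 g/L (slightly below the
  printed mean to respect the mild right skew of the printed
  median/mean pair).
- **PMA** — the identity GA + PNA/7, enforced at construction.

At n = 5000 every covariate's sample median falls within 5% of its
population target and the GA > 37 wk fraction within 3 points of 44.9%
(tested). What the generator does **not** emulate: covariate
autocorrelation over time (covariates are per-study constants),
informative sampling (sampling times are independent of covariates and
concentrations), renal-function–age coupling beyond what GA/PNA induce,
and any site or batch structure. Passing tests therefore demonstrate
correctness of the estimation and simulation machinery under the stated
generative model, not robustness to real-data pathologies.

Study simulation uses 20 mg/kg q8h 1-h infusions over 5 treatment days
(the study's median dose was 19.7 mg/kg), with 1 + Poisson(0.4) samples
per subject drawn uniformly over a random treatment day — a sparse
opportunistic design averaging 1.4 samples/subject, reproducing the
study's ~110 observations over 78 subjects. Observations below the
0.2 mg/L quantification limit are flagged and retained in files; fitting
excludes them (M1-style) and reports the excluded count. A rich design
(8 fixed offsets after a day-3 dose) is provided for recovery
experiments.

## Estimation

The marginal −2 log-likelihood is approximated by first-order conditional
estimation with interaction. Per subject, the conditional mode η̂ of

    Σ_j [ (y_j − f_j(η))²/(σ²f_j(η)²) + ln(σ²f_j(η)²) ] + ηᵀΩ⁻¹η

is found by a damped Newton scheme with analytic first derivatives of the
infusion model with respect to ln CL and ln V, vectorized across all
subjects simultaneously (curvature uses first-derivative products with a
Gauss–Newton fallback where indefinite, a step-length trust region of
2.0, and a backtracking line search; convergence at gradient ∞-norm
1e-8, maximum 80 iterations). The subject contribution is then the
linearized marginal form

    n_i ln 2π + ln det V_i + r_iᵀ V_i⁻¹ r_i,
    V_i = G_i Ω G_iᵀ + diag(σ² f_i(η̂)²),  r_i = y_i − f_i(η̂) + G_i η̂,

with G_i = ∂f/∂η at η̂ and residual variance at individual predictions
(the interaction). All 2π constants are kept so the objective is
comparable to an exact marginal −2LL; on tiny single-eta fixtures it
agrees with a 64-node adaptive Gauss–Hermite quadrature within 0.5
units (tested).

The outer problem minimizes the objective over log-transformed (θ, ω, σ)
plus unconstrained covariate exponents with Nelder–Mead (adaptive
simplex, fatol 1e-4 ≈ 1e-6 relative at typical OFV magnitudes), warm
starting each inner solve from the previous conditional modes. The
search is restarted with a fresh simplex at its own optimum (default 2
passes, stopping early when a pass gains < 0.01 OFV); restarting is the
standard remedy for premature simplex collapse and is what rescues the
stiff noise-free limit. Standard errors come from a central
finite-difference Hessian of the objective on the natural scale
(covariance = 2H⁻¹); RSE% = 100·SE/estimate.

Empirical Bayes (MAP) estimation at a frozen model reuses the inner
solver; because very informative subjects can make the individual
objective multimodal, EBE runs a small fixed grid of starting points
(0, ±1.5ω, ±3ω along η_CL; ±1.5ω along η_V) and keeps the per-subject
best. Subjects without quantifiable observations sit at the prior mode
η = 0. Weight-normalized individual parameters divide by current weight
in kg.

Covariate selection is the classical forward/backward likelihood-ratio
procedure over power models on dataset-median-normalized covariates:
univariate ΔOFV > 3.84 (χ²₁, p = 0.05) admits a candidate to the full
model; backward deletion retains only effects whose removal raises the
OFV by > 6.635 (p = 0.01). Candidates default to
{BW, CW, PNA, GA, PMA, ALB, BUN, CREA} on both CL and V (the search
covers V even though only CL effects survive in the final model — the
source reports CL effects only, so both are offered). Nested fits warm
start from the enclosing model's estimates. Numerical failures skip the
candidate with a logged warning.

## Validation tooling

- **CWRES** — the FOCE-linearized residual r_i whitened by the Cholesky
  factor of V_i; approximately iid N(0,1) under a correct model.
- **Bootstrap** — subjects resampled with replacement (study size
  preserved), each replicate refitted from the original point estimates
  (single Nelder–Mead pass); medians and 5th–95th percentiles reported,
  non-converged replicates counted and excluded, > 20% failures flag the
  result unreliable.
- **NPDE** — n_sim replicate datasets simulated under the full model;
  per subject, observed and simulated vectors decorrelated by the inverse
  Cholesky factor of the empirical simulated covariance (scalar
  standardization for single-observation subjects); the prediction
  discrepancy is the mid-rank of the observation among its simulations
  (ties counted at half weight, +0.5/(K+1) offset so 0 and 1 are
  unreachable), mapped through Φ⁻¹. Ranking uses a 1e-6 tolerance on the
  whitened scale so floating-point round-off between analytically equal
  quantities counts as a tie. Normality is tested by Kolmogorov–Smirnov.
- **VPC** — equal-count bins (default 4) on time since last dose;
  observed 5th/50th/95th percentiles against simulation-based 95%
  confidence bands; empty bins dropped with a warning; no prediction
  correction (the emulated analysis plots a plain VPC).
- **External validation** — per observation r = (IPRED − OBS)/OBS with
  IPRED from EBE at the frozen model; MPE = 100·mean(r) (signed),
  MAPE = 100·mean(|r|). The within-±20%/±30% summaries count subjects by
  their per-subject MPE (the quantity described as "percentage of
  newborns"); a per-observation variant is available behind a flag. The
  two error formulas are typeset identically in the source; they are
  implemented as the universal signed-mean / mean-absolute pair.

## PTA simulation

The PK-PD target is 70% fT>MIC: free concentration (free fraction 0.98)
above the MIC for ≥ 70% of the steady-state dosing interval; MIC 8 mg/L
is the late-onset-sepsis breakpoint used throughout. The steady-state
profile over one interval is unimodal, so the fraction above threshold
has exactly one upward crossing (solved by Brent's method during the
infusion) and one downward crossing (closed form on the post-infusion
exponential); agreement with a Δt = 1e-4 h dense-grid oracle is within
1e-3 (tested). Attainment uses ≥ at the 0.70 boundary.

"1000 Monte Carlo runs" is read as ≥1000 virtual subjects per
regimen × GA group: covariates resampled from the generator restricted
to the group (GA cutoff 37 wk), fresh η ~ N(0, Ω) per subject, dose
computed from simulated CW on a mg/kg basis with no rounding or cap.
Residual (assay) error is excluded — attainment concerns true
concentrations. The regimen grid (20–60 mg/kg × BID/TID × 1–5 h
infusions) uses common random numbers: one cohort and one η matrix per
GA group shared across all regimens, making PTA monotone in dose and
infusion duration by construction rather than up to Monte Carlo noise.

The source's discussion prints the two underdosed 20 mg/kg TID PTA
values with the same group label twice (an evident duplication typo);
they are assigned by clearance ordering — term neonates clear faster, so
the lower value (34.07%) belongs to GA > 37 wk and the higher (57.76%)
to GA ≤ 37 wk.

## Problem sizes and numerical choices

Test and reproduction runs are sized for a single CPU: PTA uses
8000–16000 virtual subjects per scenario (Monte Carlo SE ≤ 0.55 points,
so comparisons reflect the generator, not seed noise); parameter
recovery uses 20 replicates of 100 subjects × 8 samples; selection
calibration uses 20 replicates of 40 subjects × 4 samples; NPDE
calibration uses 100 replicate studies at 400 simulations each;
the bootstrap check uses 200 resamples of a 78-subject study. Degenerate
inputs are defined explicitly: zero-variance cohort specs produce point
masses at the medians; ω = 0 uses a zero Cholesky factor (no jitter
noise); predictions are floored at 1e-12 inside residual variances;
ln ω and ln σ are clipped at −10 (≈ 4.5e-5) to keep the objective finite.

## Known limitations

- FOCE-I is an approximation; its error grows with residual CV and
  sparsity (within 0.5 OFV units of exact quadrature on 3–5-subject
  fixtures at 12% residual CV, the regime the oracle tests cover). No
  SAEM or importance-sampling alternative is provided.
- Ω is diagonal; CL–V covariance is not estimated.
- One compartment only; no CSF compartment, no nonlinear elimination.
- The bootstrap reuses the original initial values, which can understate
  replicate-to-replicate optimizer variability on pathological resamples.
- The cohort generator matches marginal summaries and one induced
  correlation (GA–weight); other joint features of the real population
  are not represented, so external-validation magnitudes on synthetic
  cohorts mirror, but do not reproduce, the study's real-data values.
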