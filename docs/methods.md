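# Methods

## The model

`pdqsp` implements a three-compartment quantitative-systems-pharmacology
model of anti-PD-1 / anti-PD-L1 antibody treatment of CT26 syngeneic
tumors in Balb/c mice. Two linear PK compartments (central, peripheral)
carry each antibody; the tumor compartment carries viable tumor cells
`T`, damaged tumor cells `T_D`, and a PD-1+CD8+ T-cell life cycle with
21 states: inactive `E_I`, eight proliferation stages (`E_A`,
`E_P1..E_P7`), CTLs with a ten-kill capacity ladder (`E_D10..E_D1`) and
exhausted CTLs (`E_D0`).

**Binding.** PD-1 (on CD8+ and a constant pool of other PD-1+ T cells),
PD-L1 (on tumor cells, damaged included) and the two antibodies react at
quasi-equilibrium in the tumor interstitium (volume = void fraction x
tumor volume). Antibody concentrations are clamped at the central-plasma
value — elimination is linear, so the receptor pool does not measurably
deplete the plasma pool. With the antibodies clamped, the three-reaction
equilibrium collapses to one quadratic in free PD-1, solved in closed
form; mass-balance residuals are at rounding level (checked to 1e-9).
The readout is `x`, PD-1:PD-L1 complexes per PD-1+ cell (all PD-1+ cells
carry the same receptor count, so complexes distribute evenly).

**Control functions.** Inactive-cell influx and activation are both
inhibited by `x`:

    f_influx(x) = max(0, Emax_inf/(1+EC50/x_ref) - Emax_inf/(1+EC50/x)) + ks_IVt
    f_act(x)    = Emax_act - Emax_act/(1+EC50/x)

At the untreated anchor `x_ref = 6.6` complexes/cell the influx bracket
cancels exactly, so control tumors see a constant baseline influx
`ks_IVt` and the T-cell subsystem sits at a steady state. Receptor
blockade lowers `x`, raising both influx and activation.

**Cell kinetics.** Each proliferation-stage transit (rate
`ln2/Thalf_CD8pfr`) doubles the cohort, for 2^8 = 256-fold expansion
from activation to CTL when losses are negligible. Each CTL kill
(`k_kill * T` per CTL per day) moves one tumor cell to the damaged pool
and the CTL one rung down its capacity ladder; exhausted CTLs no longer
kill. Tumor volume `V = (T + T_D) * v_cell / (1 - void_fraction)` grows
logistically (`kpfr_T`, capacity `klimit_T` in mm^3); anti-PD-L1 adds an
ADCC damage flux `Emax_ADCC * occ_PDL1 * T`; damaged cells apoptose at
`kapop`.

**Calibrations.** Two routines pin literature-free anchors:
`calibrate_binding_anchor` solves 1-D for `R_PDL1` so the untreated
equilibrium at the profiling burden (8e6 cells, the day-7 size of a
2e6-cell implant) sits at `x = 6.6`; `calibrate_tcell_kinetics` solves
the chain steady state for {`Emax_activate`, `kd_CD8`, `kd_CTL`,
`Thalf_CD8pfr`} so the five-stage composition matches flow-style target
fractions (a zero exhausted fraction is structurally infeasible while
killing occurs, and is rejected).

## Parameter provenance

Fixed effects, covariate coefficients, the proliferation-rate
variability and the residual-error terms default to the published
population estimates (`kpfr_T = 0.199/d`, `klimit_T = 8370 mm^3`,
`beta_kpfr_site2 = 0.444`, `beta_klimit_site2 = -1.47`,
`Thalf_CD8pfr = 0.418 d`, `Emax_ADCC = 0.146/d`, `kapop = 0.191/d`,
`Emax_influx = 8.43e7 cells/d`, `omega_kpfr = 0.21`, `err_a = 53 mm^3`,
`err_b = 0.142`).

Random-effect scales: a log-normal model requires log-scale SDs. The
printed carrying-capacity variability (3.67e3 mm^3) is a natural-scale
SD and is converted to a log-scale CV of 3670/8370 = 0.438. The printed
proliferation-half-life variability is not usable on either scale
(its shrinkage of 88% says individual half-lives were essentially
uninformed by tumor volumes); the generator uses a moderate log-scale SD
of 0.35 as this package's own choice.

Constants whose sources are not printed (binding KDs, receptor counts,
T-cell rates, killing rate, PK block, geometry) are `assumed` defaults,
chosen once so that the model reproduces the qualitative treatment
phenotypes: control growth insensitive to immune parameters (<0.1% AUC
change under +/-30% perturbations), >25% day-10 volume reduction under
both antibodies with >10-fold CTL expansion, anti-PD-L1 at least as
effective as anti-PD-1, near-zero anti-PD-1 effect when the influx is
clamped constant, monotone dose response, and higher trough PD-L1 than
PD-1 occupancy. The assumed two-compartment PK (CL 1.2 mL/d, V1 = V2 =
1.5 mL, Q 0.5 mL/d, ka 1/d, F_IP 0.8) clears faster than a typical mouse
IgG; this is deliberate — partial inter-dose receptor occupancy is what
produces the partial, dose-ordered treatment responses above.

## Numerics

The binding solve is analytic (numerically stable quadratic root). The
ODE system is integrated two ways: LSODA at rtol 1e-8 / atol 1e-10 (the
`simulate_individual` default, with integration restarts at every dose
event), and a fixed-step RK4 kernel (numba) used by the fitting and
sensitivity paths, dt = 5e-3 d for cohort generation and 2e-2 d inside
the fit (step-halving changes treated endpoints by <0.05%). States are
clamped at zero after each RK4 step; the continuous system is
forward-invariant on the non-negative orthant, so the clamp only removes
boundary under/overshoot. IV doses are boluses into the central
compartment; IP doses enter a depot with bioavailability applied at
dosing time. Trajectories store the pre-dose state at a dose time.

## Virtual cohorts

The generator mirrors the five tumor-growth-inhibition studies (group
sizes 10/10/10/12/21, two sites, inocula 2e6 or 2e5 cells, treatment
starts days 7-11, Q5Dx2 / Q4Dx4 / Q3Dx3 schedules, IV at site 1 and IP
at site 2) with a twice-weekly caliper schedule (alternating 3/4-day
gaps from day 4; the real schedule is not printed) and a default 40-day
horizon. Individual parameters follow the exponential covariate model
`theta_i = theta_pop * exp(beta * 1[site 2]) * exp(eta)`; observed
volumes add combined-2 noise `y = f + sqrt(a^2 + b^2 f^2) eps`,
truncated at a 1 mm^3 measurement floor.

By default the eta draws of a cohort are moment-matched within each site
stratum (exact sample mean 0 and SD omega), the virtual-population
practice of making a small cohort representative of its generating
distribution; `eta_balance="iid"` gives plain sampling. What the
generator does **not** emulate: dropout/sacrifice rules, the 148- and
242-day study tails, inter-individual PK variability, or any real
biological misspecification — recovery results therefore demonstrate
estimator correctness under the assumed model, not robustness to model
error.

## Population estimation

`fit_population` is a deterministic "NLME-lite" scheme (the published
analysis used stochastic-approximation EM; that algorithm is
deliberately replaced):

1. conditional modes of the per-mouse etas (penalized least squares,
   Nelder-Mead) with an eta-recentering step that transfers within-site
   eta means into the free population values (removing the ridge the
   blocked update otherwise walks along);
2. EM update of the free omegas using Laplace posterior variances
   (finite-difference Hessians), so shrinkage does not deflate them;
3. ML update of the combined-2 error terms given the conditional-mode
   predictions, followed by an effective-degrees-of-freedom (REML-style)
   inflation — the fitted etas absorb residual noise and the naive ML
   error terms would otherwise be biased low by ~10%;
4. bounded quasi-Newton (L-BFGS-B) update of the free fixed effects
   with etas held at their modes — the sharp, strongly correlated
   growth-parameter valley defeats direction-set methods;
5. after the alternating loop, a FOCE-style polish cycle: Powell on the
   Laplace marginal objective with the etas re-solved from fixed
   cycle-base modes at every trial (log-determinant terms frozen within
   the cycle).

Observations at the 1 mm^3 floor enter the likelihood as left-censored
(Gaussian lower-tail mass); ignoring the censoring visibly biases the
additive error term and the ADCC rate. Starting values are data-driven:
weighted per-mouse logistic fits (combined-error weights on the log
scale, capacity bounded by 4x the largest observed volume) aggregated by
site medians, and an indirect-inference start for `Emax_ADCC` that
matches the simulated treated-arm log-volume slope to the observed one.
Likelihood, AIC and BIC use the per-mouse Laplace approximation;
relative standard errors (optional) come from the finite-difference
curvature of the marginal objective; shrinkage is
`100 * (1 - SD(eta_hat)/omega)`.

Identifiability at desk scale: the site-1 carrying capacity rides a soft
(r, K) logistic ridge when tumors are only followed to ~60% of capacity
(40-day horizon), and the ADCC rate shares a soft direction with the
per-mouse proliferation-half-life effects in treated arms. Their
recovery spread across cohort seeds is accordingly wider (roughly
+/-20-30%) than for the remaining parameters (typically within
+/-10%); the longer real studies and larger real cohort are what gave
the published analysis its tight standard errors for these two.

## Sensitivity, response metrics, sweep

Local sensitivity perturbs each parameter +/-30% one at a time
(half-life parameters are perturbed on the half-life scale) and reports
the percent change of the 0-30-day tumor-volume AUC under control,
anti-PD-1 and anti-PD-L1 10 mg/kg Q3Dx3 (first dose day 7), each
relative to its own scenario's nominal; parameters are ranked by the
maximum absolute change with alphabetical tie-breaks.

The responder metric is the least-squares slope of volume against day
over days 7-13 after treatment start (nearest observation within +/-2
days pulled in when none falls on a window edge; the two-point case
reduces to the difference quotient); rates strictly below 25 mm^3/day
mark responders. Group comparisons use Kruskal-Wallis across studies and
within-study Wilcoxon rank-sum tests, reported unadjusted with
Bonferroni thresholds attached as metadata. The expression sweep
overrides PD-1 or PD-L1 per cell for each fitted mouse, re-equilibrates
the untreated T-cell baseline at the new level before dosing, and
reports the percent volume change twelve days after treatment start,
with mice ordered by their individual proliferation rates.

## Known limitations

- Supplementary equation forms (plasma binding, killing saturation,
  turnover of the other PD-1+ pool) are not public; the reconstructed
  forms are the simplest consistent with the main-text description.
- Quasi-equilibrium binding ignores binding kinetics; clamped antibody
  ignores target-mediated disposition.
- The estimation scheme is deterministic and Laplace-based; it matches
  stochastic EM at desk scale but inherits Laplace bias for very sparse
  designs.
- Percent-change figures quoted for the real studies (CTL expansions,
  occupancy percentages) are reproduced directionally, not numerically —
  they depend on unpublished constants.
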