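# Methods

## Model and assumptions

The core model is a mean-field compartmental ODE system for the spread of
online public opinion after a major emergency. The netizen population is
split into susceptible (*S*, unaware), latent (*E*, aware and interacting
but not spreading), spreader (*I*), and removed (*R*) fractions; a
constant inflow *A* of new netizens enters the susceptible class.
Homogeneous mixing is assumed: the exposure rate is proportional to the
product *S·I* with contact rate γ. A distinctive feature is the
*direct-immunizer* rate ε — the fraction of susceptibles per unit time
that becomes immune to engagement without ever passing through the latent
or spreader classes, interpreted as education-driven resistance. A second
distinctive feature is direct seeding: susceptibles become spreaders at
rate αS without a latent stage, so spreaders never fully vanish when
α, A > 0.

Government intervention enters as additive offsets to the natural rates,
signed so positive offsets suppress spreading: α = α\* − ᾱ (awareness →
spreading), β = β\* + β̄ (spreader removal), ξ = ξ\* − ξ̄ (latent
activation), γ = γ\* − γ̄ (contact), and η̄ added to the latent-removal
rate η\*. Validity bounds (each natural rate in [0, 1], each offset in
[−1, 1], every effective rate in range, α ≥ ε) are enforced strictly by
default, with a permissive mode that downgrades violations to warnings.

### The three variants

The published four-equation system is not mass-conserving: the latent
outflow is (ξ + η̄)E while the removed class gains (η\* + η̄)E, and the
εS drain leaves the system entirely, so d(total)/dt = A − εS + η\*E. The
mismatch cancels exactly on the manifold εS = η\*E, the side identity the
source analysis imposes. Because the downstream theory (equilibria,
thresholds, stability) uses the (ξ + η̄)E outflow, the package ships

* `faithful` — the published system verbatim (default);
* `balanced` — a mass-balanced repair: latent outflow (ξ + η̄ + η\*)E
  and εS routed into R, so d(total)/dt = A exactly;
* `reduced` — the equivalent three-equation (S, E, I) system used by all
  equilibrium/stability machinery (R decouples and can be reconstructed
  by quadrature, which is tested).

`faithful` and `balanced` differ in dE/dt by η\*E and in dR/dt by εS.
The shared S, E, I dynamics are identical across all three variants.

Every model is represented as labelled flows (source, target, symbolic
rate); the right-hand side is the signed sum of flows, lambdified once
for integration. Conservation identities are therefore checkable
symbolically, and printed-form discrepancies in the lineage models
(classic SIR's missing infection gain, the rumour model's sign
corruption) are archived in model metadata next to the canonical
mechanism actually integrated.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| A | inflow of new netizens | fraction/day | 0.02 |
| α\*, ᾱ | susceptible→spreader natural rate, offset | /day | 0.02, 0 |
| β\*, β̄ | spreader→removed natural rate, offset | /day | 0.03, 0 |
| ξ\*, ξ̄ | latent→spreader natural rate, offset | /day | 0.05, 0 |
| η\*, η̄ | latent→removed natural rate, offset | /day | 0.03, 0 |
| ε | direct-immunizer rate | /day | 0.02 |
| γ\*, γ̄ | contact rate, offset | /day | 0.5, 0 |

The defaults are the baseline scenario of the motivating case study. The
contact rate γ\* has no tabulated reference value anywhere, so it is a
required configuration field with documented default 0.5/day; every
scenario output echoes the γ actually used. Configs omitting it get the
default plus a logged warning.

## Equilibria: constrained vs exact

Two notions of steady state are kept deliberately distinct. The
*constrained* equilibria follow the source analysis, which replaces the
latent balance equation with the side identity εS = η\*E: the
spreader-free point P₀ = (A/(α+ε), εA/(η\*(α+ε)), 0) and the
persistent-spreading point solving the linear system
{A − (ξ+η̄)E − (α+ε)S = 0, αS + ξE − βI = 0, εS = η\*E}. These do not in
general zero the full right-hand side — at P₀ both the latent line
(−(ξ+η̄)E) and the spreader line (αS + ξE) are nonzero — and the
per-equation residuals are always computed and reported rather than
hidden. The *exact* equilibrium is a numeric root of all three equations
(hybrid Newton from the constrained point; residuals verified below
1e−10, the residual being authoritative over the optimizer's own
convergence flag). At the baseline the two differ substantially
(S: 0.273 vs 0.057), which the equilibrium report quantifies as a
distance.

The persistent-spreading susceptible fraction has closed form
S\* = Aη\*/(ε(ξ+η̄+η\*) + αη\*). A circulated variant of this denominator
drops the factor of ε on two terms; the linear solve is authoritative
(at the baseline it gives 0.0006/0.0022 = 3/11, the variant would give
0.019), and the variant value is archived in the result notes.

## Reproduction numbers and stability

With infected set {E, I}, new-transmission vector ((1−ε)γSI, 0), and
transfer vector ((ξ+η̄)E, βI − ξE − αS), the next-generation matrices at
a point with susceptible fraction S are F = [[0, (1−ε)γS], [0, 0]] and
V = [[ξ+η̄, 0], [−ξ, β]], giving R₀ = ρ(FV⁻¹) = ξ(1−ε)γS/(β(ξ+η̄)). The
direct-seed flow αS differentiates to zero with respect to (E, I), so
reassigning it between the transmission and transfer vectors (exposed as
a flag) provably changes nothing. Two closed forms are shipped: the
spreader-free form (1−ε)γA/(β(α+ε)), quoted without the ξ/(ξ+η̄)
spectral factor, and the endemic form ξ(1−ε)γS\*/(β(ξ+η̄)), which agrees
with the numeric spectral radius to 1e−12 (tested over 200 random valid
draws). The numeric computation is the arbiter where the two closed
forms disagree.

Stability is classified from the eigenvalues of the analytic Jacobian
(verified against central finite differences), with the characteristic
cubic assembled as (−tr J, Σ principal 2×2 minors, −det J) and the
Routh–Hurwitz conditions (a₁>0, a₂>0, a₃>0, a₁a₂−a₃>0) computed as an
independent route; disagreement outside the marginal band raises an
error rather than returning a verdict. The endemic R₀ is strictly
decreasing in ε on (0, α] (tested on a 20-point grid), the quantitative
expression of "more public education, less sustained spread".

The classical threshold reading "R₀ ≤ 1 ⇒ spreading dies out" cannot
hold literally here: the direct-seeding flow αS sustains a spreader pool
regardless of the contact process. Sub-threshold behaviour is therefore
checked as a reported diagnostic (long-run I compared against its
seeding-sustained level), never as a hard assertion.

## Scenario study

The built-in scenario set is the baseline plus five one-parameter
sweeps: ᾱ, β̄, ξ̄, η̄ each over the symmetric grid {−0.01, −0.005, 0,
0.005, 0.01}, and ε over {0.005, 0.01, 0.015, 0.02} (respecting ε ≤ α).
The grids are package choices — no authoritative values exist — and are
config-overridable. The ᾱ sweep runs in permissive mode: its positive
offsets push the effective α below ε, violating the α ≥ ε bound, yet
that is exactly the experiment the scenario family prescribes, so the
bound is demoted to a warning there. All sweep values integrate from one
shared initial condition; summaries are the spreader peak and its time,
cumulative spreader mass, and the final removed share. Diagnostics
include monotonicity flags and an asymmetry statistic (|Δ cumulative I|
at the largest positive offset minus at the largest negative one,
relative to zero offset); the asymmetry is reported, not asserted, as no
quantitative criterion exists for it.

Default initial condition: spreader seed I₀ = 1e−3, R₀ = 0, and E₀
chosen so the side identity εS = η\*E holds at t = 0 (closed form
E₀ = ε(1−I₀)/(η\*+ε)). Default horizon 30 days on a 601-point grid: the
motivating engagement burst spans about a week, and 30 days shows the
settling behaviour.

## Engagement data, synthesis, and calibration

Engagement counts (daily retweets + comments + likes) proxy the spreader
fraction as prevalence: counts ≈ scale·I(day). This is a modelling
convention — visible engagement volume tracks the current spreader pool,
not the flux into it. The packaged fixture stores the handful of counts
published for the December 14–20, 2020 episode with per-day provenance
notes; the source narrative is internally inconsistent about the day-1
figures, the series is flagged accordingly, and it is used for
demonstration only.

The synthetic generator draws daily counts from a negative binomial with
mean scale·I(day) and variance μ + φμ² (Poisson-gamma mixture); φ = 0 is
the noiseless limit (rounded means). Defaults for the recovery
experiments: scale 5000 (thousands of engagements per day, as in the
motivating episode) and φ = 0.01, i.e. ≈10% extra-Poisson coefficient of
variation — modest overdispersion typical of daily tallies at that
scale. The generator emulates magnitude and noise of daily engagement;
it does not emulate platform mechanics the model lacks (reposting
cascades, diurnal cycles, censoring of deleted posts), so passing
recovery tests show the calibration machinery works under the model's
own assumptions, not that the model is identified by real platform data.

Calibration is bounded least squares of scale·I(day; θ) against counts
(trust-region reflective; optional Poisson-deviance residuals), with any
subset of {γ\*, ᾱ, β̄, ξ̄, η̄, ε, scale} free. The γ\*-recovery
experiment observes daily counts over the full 30-day window: an
identifiability analysis showed γ\* is nearly unidentifiable from the
first week alone (early spreader growth is dominated by the direct
seeding αS — I at day 6 moves only a few percent as γ\* runs 0.1 to
0.9), while the settling phase depends on γ\* materially. With 31 daily
counts, truth 0.5, bounds [0.1, 0.9], and 20 seeds, the median absolute
recovery error is below 0.1 (tested). All stochastic operations default
to seed 20201214 (the event date).

## Numerical choices

* Integrator: `solve_ivp` with LSODA (automatic stiff/non-stiff
  switching), rtol 1e−8, atol 1e−10, dense uniform output grid. States
  dipping below −10·atol trigger a negativity warning and flag.
* Mass-balance defect: d(total)/dt is evaluated by the exact assembled
  RHS at the stored states (default) or by central differences of the
  summed states; compared against the constant inflow or against the
  model's own algebraic identity. For the faithful variant the
  inflow-referenced defect equals |η\*E − εS| pointwise (tested to
  1e−12).
* Equilibrium residual tolerance 1e−10 absolute (states are O(1)
  fractions); constrained-system linear-solve residuals at machine
  precision.
* Stability: 'marginal' when |max Re λ| < 1e−8; Routh–Hurwitz margins
  within 1e−12 of zero are likewise marginal; cross-route disagreement
  outside those bands is an error.
* Final-size roots by bracketed Brent iteration (xtol 1e−10 or better)
  on brackets that exclude the trivial root at 1.
* Test problem sizes: 200 random draws for the R₀ and stability
  cross-validations, 10 perturbation-return runs with horizon
  30/|max Re λ| (capped), 20 calibration seeds. These keep the full
  suite under a minute while leaving the checks statistically
  meaningful.

## Known limitations

* Mean-field, homogeneous mixing: no degree structure, communities, or
  agent-level stochasticity (deliberately out of scope).
* The faithful variant's mass leak means its total population is only
  meaningful relative to the εS = η\*E manifold; long faithful runs
  drift away from total 1 + A·t by design, and the defect is reported.
* The constrained equilibria are the analysis convention of the source
  model family, not exact steady states; conclusions drawn from them
  (e.g. the endemic R₀) inherit that convention. The exact root is
  always available for comparison.
* Calibration identifiability is weak for parameters whose effect is
  masked by direct seeding; only γ\* recovery is validated, and only
  under the synthetic generator's assumptions.
* No bifurcation continuation, Lyapunov/global stability analysis, or
  event detection.
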