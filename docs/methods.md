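# Methods

## The system being modelled

A supramolecular polymer of benzene-1,3,5-tricarboxamide (BTA) monomers
carries single-stranded 10-nucleotide DNA handles on a tunable fraction of
its monomers (BTA-DNA; the rest is inert BTA-3OH). Recruiter
oligonucleotides complementary to both a handle and a protein's 21-nt
conjugate strand tether DNA-conjugated proteins to the fiber. The package
models the consequences for an enzyme–inhibitor pair (β-lactamase E104D /
BLIP, solution inhibition constant K_i = 1.5 µM): recruitment concentrates
both proteins into the fiber volume, driving complex formation at bulk
concentrations three orders of magnitude below K_i.

## Cylinder effective-concentration model

The fiber is idealised as a cylinder of radius r in which each stacked
monomer adds an axial rise h, so a tethered protein samples a volume
π·r²·h per monomer and the in-fiber (effective) concentration of a species
at bulk concentration C_bulk is

    C_eff = C_bulk / (C_BTA,total · N_A · π r² h · 1e-24 L/nm³).

Both numerator and denominator scale with solution volume, so C_eff depends
only on the protein-to-monomer ratio: doubling the total BTA at fixed bulk
protein halves C_eff (the receptor-density dilution experiments exploit
exactly this).

Parameters:

| parameter | default | units | provenance |
|---|---|---|---|
| radius r | 15 | nm | the cylinder radius the recruitment experiments are analysed with |
| axial rise h | 0.452 | nm/monomer | calibrated (below); config-overridable |

h is not independently measured here; it is obtained in closed form by
`calibrate_axial_rise` from a single anchor — C_eff = 26 µM at 10 nM bulk
protein on 2 µM total BTA — giving h = 0.4518 nm, stored as the default
0.452. The point of the calibration is that one parameter then reproduces
the other printed outputs of the same model out-of-sample: 0.78 µM
(rounding to 0.8) at 0.75% receptor density, the 2600-fold enhancement, and
a mean inter-protein spacing of 82 nm for 11 nM total protein
(fiber length per liter C_total·N_A·h divided by proteins per liter),
consistent with the ~85 nm scale at which protein redistribution becomes
necessary for complex formation.

The effective concentration deliberately uses the *bulk* protein amount; a
hybridization-occupancy correction is applied, optionally, one level up in
the activity model (see below), never inside the geometry.

Non-goals: excluded volume, persistence-length corrections, non-uniform
protein distributions, and the tubular morphologies seen with recruiter
strands alone are all outside this model.

## Handle–recruiter hybridization equilibria

Each recruiter forms a 10-bp duplex with a scaffold handle. For one
recruiter the exact bimolecular equilibrium is solved with the numerically
stable quadratic root; for several recruiters sharing the handle pool, the
free-handle concentration x solves the monotone conservation equation

    handle_total = x + Σ_i R_i · x / (K_i + x),

bisected on [0, handle_total]. Bisection is chosen for guaranteed
convergence on a monotone function; it runs to float convergence (adjacent
floats, ≤ 200 iterations) so that bound/free concentrations conserve mass
to better than 1e-9 relative — the level at which tests compare the solver
to an independent root-finder.

The default handle-duplex K_d (0.162 µM) is itself a one-point calibration:
it is the value at which 0.5 µM handles bind 75% of 20 nM recruiter,
i.e. leave 25% of the enzyme free in solution. That incompleteness is the
model's explanation for the residual activity plateau at saturating
inhibitor: free enzyme cannot be inhibited at nanomolar bulk inhibitor.

Two simplifications are intentional:

* the 21-nt protein–recruiter duplex is treated as fully formed (its K_d is
  far below the working concentrations), so a protein's scaffold-bound
  fraction equals its recruiter's — valid only while protein ≤ recruiter,
  which is enforced;
* toehold displacement is stoichiometric, not an explicit three-strand
  equilibrium: the fully complementary recruiter–displacer duplex
  out-competes the nicked 10-bp attachment essentially completely, so each
  displacer sequesters one recruiter
  (`effective R = max(0, R_total − D_total)`). This idealisation makes full
  displacement restore the pre-recruitment activity exactly and repeats
  cycles identically; the experimentally observed attenuation of cycling at
  high strand concentrations is *not* modelled.

## Templated activity model

Bulk enzyme activity averages two populations:

    V = (1 − f_E) + f_E · (1 − θ),      θ = C_eff,I / (K_i + C_eff,I),

with f_E the scaffold-bound enzyme fraction from the competition solver and
θ the single-site competitive-inhibition occupancy of scaffold-bound enzyme
at the inhibitor's effective concentration. Consequences the tests
exercise: V ∈ [1 − f_E, 1]; V → 1 − f_E at saturating inhibitor (~75%
maximal inhibition at the reference condition); V = 1 whenever a recruiter,
the receptors, or the inhibitor is absent; and V rises back toward 1 as
inert monomer dilutes C_eff,I below K_i.

Because f_I (the inhibitor's scaffold fraction) does not depend on the
inhibitor's own protein concentration, the forward titration collapses
*exactly* to the hyperbolic form

    V = V_b + (1 − V_b) · K_i,app / ([I] + K_i,app),
    V_b = 1 − f_E,  K_i,app = K_i / (f_I · fold_enhancement),

which is why the inhibition fit recovers the forward model's parameters to
numerical precision on noiseless data — a genuine closed-loop consistency
check between independently written code paths.

Two effective-concentration conventions are exposed:
`apply_occupancy_to_inhibitor=True` (the default) counts only scaffold-bound
inhibitor (C_eff,I uses bulk·f_I), since inhibitor left in solution is not
concentrated; `False` uses the plain bulk amount, the convention in which
the 26 µM / 0.8 µM values are quoted. Substrate competition is ignored in
V: activities are initial-slope readouts at fixed 2 µM substrate, so the
inhibitor enters only through θ.

The empirical *rise* of activity at receptor densities above 25%
(attributed to steric crowding of the DNA handles) is deliberately not
modelled; `density_scan` reports the monotone dilution behaviour only. The
model also predicts partial recovery already near 1% density (where
C_eff ≈ 1 µM < K_i), slightly earlier than the observed flatness down to
1%; the prediction is left as-is rather than tuned.

## Fitting

* `fit_inhibition`: 2-parameter (V_b, K_i,app) nonlinear least squares of
  the hyperbola, with V_0 ≡ 1 − V_b built in; K_i,app is fitted as
  log K_i,app for positivity, initialised from the half-amplitude crossing,
  V_b from the smallest activity. Standard errors are asymptotic (from the
  Jacobian). The default is *unweighted*: replicate standard deviations
  estimated from triplicates are themselves so noisy that 1/sd² weights
  make the reported standard errors anticonservative (coverage measurably
  below nominal); `weighted=True` opts in. Flat titrations and estimates
  pinned at the search bounds raise a fit-failure error instead of
  returning numbers.
* `fit_exchange`: one free parameter (the rate k, per hour) with both
  endpoints fixed from reference samples; k is fitted unconstrained so a
  negative estimate can be detected and flagged as failure;
  t½ = ln 2 / k by definition.
* `initial_rate`: ordinary least-squares slope over the initial window of a
  progress trace — first 10% of the (post-dead-time) duration or first 20
  points, whichever is larger — after discarding a configurable 2-minute
  instrument dead time. Invariant to constant baseline shifts.

## Kinetics and timescale separation

Progress traces integrate pseudo-first-order substrate decay
d[S]/dt = −(kcat/K_M)·E_active·[S] (2 µM substrate assumed ≪ K_M; K_M is
not separately known, so only the lumped kcat/K_M is exposed and its
default, 1e4 M⁻¹s⁻¹, is arbitrary — normalized activities are ratios of
initial rates and do not depend on it). Fluorescence is
F = F₀ + c·([S]₀ − [S]).

Slow monomer exchange between fibers appears as a fixed-endpoint single
exponential with default half-life 3 h. Fast protein redistribution is
governed by the 10-bp duplex off-rate (0.2 s⁻¹ reported for such duplexes),
giving an unbinding half-time of ~3.5 s; the package asserts, rather than
simulates, the resulting separation of timescales (seconds ≪ minutes ≪
hours) and treats redistribution as instantaneous. The minutes-scale
equilibration observed on mixing is a qualitative consequence, not a fitted
quantity.

## Synthetic data

Generators add Gaussian, homoscedastic noise on the normalized-activity
scale (default sd 0.03, an arbitrary magnitude chosen to resemble typical
triplicate error bars) or on raw fluorescence, average n replicates
(default 3) and report the sample s.d. per point. They are pure functions
of (parameters, seed). What they do *not* emulate: plate-reader drift,
photobleaching, inner-filter effects, heteroscedasticity, or correlated
replicate errors — so passing recovery tests demonstrate estimator
correctness under the stated noise model, not robustness to real-instrument
artifacts.

Monte-Carlo problem sizes used by the tests and consistency checks — a
12-point titration grid (0 and 0.5–100 nM), 10 time points over 0–5 h, and
200 seeded replicate datasets per recovery study — were chosen to mirror
the assays' own designs while keeping the full suite fast.

## Numerical choices and degenerate inputs

* Concentrations are mol/L, lengths nm; the single volume conversion
  (1 nm³ = 1e-24 L) lives in `geometry`.
* Zero recruiter: the bound fraction is reported as the dilute-tracer limit
  x/(K_d + x) and flagged in the equilibrium state's notes.
* Zero handle pool (receptors omitted): handled as f_E = 0 in the activity
  model rather than in the solver, whose precondition stays strict.
* A fully displaced recruiter yields protein scaffold fraction 0; a protein
  exceeding its recruiter (other than via displacement to zero) is an
  error, since that regime's protein–recruiter equilibrium is not modelled.
* Fit tolerances are set to 1e-14–1e-15 so noiseless closed loops recover
  parameters to ~1e-9 relative or better.

## Known limitations

The cylinder model's packing parameter is a one-anchor calibration, not a
structural measurement; all effective concentrations inherit that single
scale factor. Handle-duplex K_d is likewise calibrated from one bound
fraction, not predicted from sequence thermodynamics. The displacement
model is deliberately all-or-nothing and cannot reproduce cycling
attenuation. The activity model assumes enzyme and inhibitor sample the
whole fiber volume independently; cooperative, multivalent fiber–fiber
interactions are out of scope.
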