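# Methods

## The discrete-generation size map

The core object is the per-generation map in log-volume
*v* = log *V* (volumes in fL, natural logarithms throughout):

v_{i+1} = v_i + λ_i T_i − log n_i,

where λ is the specific volume growth rate (1/h; growth is exponential
within a cycle), T the cycle time (h), and n > 1 the division ratio —
the followed progeny receives the fraction 1/n of the division volume
(n = 2 for symmetric fission, n > 2 for budding-yeast daughters).  The
map is an identity for exponential single-cell growth; using the
natural log makes it exact rather than approximate, which is why the
balanced-growth condition is written ⟨λT⟩ = ⟨log n⟩.

With a constant cycle time, the per-cycle imbalance
ε = λT − log n is an i.i.d. increment and birth sizes perform a random
walk: across a population, Var(v_k) = k·σ_ε².  The simulator exposes
this limit directly (`simulate_random_walk_ensemble`) and the test
suite checks the linear variance law by Monte Carlo against the closed
form.

## Gradual (fixed-point) size control

Size control enters as a bounded, size-dependent cycle time.  We use a
logistic family

T(v) = T_min + (T_max − T_min) / (1 + exp((v − v_half)/width)),

smooth, bounded in [T_min, T_max], equal to the midpoint at v_half, and
**non-increasing** in v.  The direction matters: the fixed point v\* of
the map, defined by λT(v\*) = log n, is attracting exactly when the
per-generation multiplier m = 1 + λT′(v\*) has |m| < 1, which requires
T locally decreasing in v — small-born cells must cycle longer.  This
matches the classical observation that small-born daughters extend G1.
(Descriptions of this mechanism sometimes phrase the dependence as
cycle time increasing with birth volume; an increasing T(v) makes the
fixed point repelling, so the decreasing form is the one implemented,
and the choice is deliberate.)

Because T is bounded, the fixed point exists only when log n/λ lies
inside (T_min, T_max).  Outside that band homeostasis fails in one of
two ways:

* **type I** (λT_max < log n): every cycle loses volume; cells shrink
  indefinitely and arrest small;
* **type II** (λT_min > log n): every cycle gains volume; cells swell
  and arrest large.

`classify_regime` applies these inequalities and, in the homeostatic
band, attaches the fixed point (Brent root-finding on the monotone
residual λT(v) − log n, tolerance 1e−8) and its stability (central
finite difference, step 1e−5).  Exact boundary ties are classified with
the weak inequality on the arrest side, after a strict bracketing
margin of 1e−12 — a deterministic, testable tie-break.

## Checkpoint control and non-exponential growth

The threshold variant gates division on size: G1 lasts
max(T_G1_min, (v_crit − v_birth)/λ), optionally capped by a timer
tau_max (small cells may pass the checkpoint after waiting that long),
followed by a fixed budded phase T_budded.  Born below the critical
size, noiseless birth sizes become stationary after one cycle; born
above it with λ(T_G1_min + T_budded) > log n, size diverges upward —
the checkpoint can only correct in one direction, which is its
characteristic failure mode.

`non_exponential_update` covers growth laws other than exponential.
For linear volume growth V(t) = V0 + a·t with constant T and n, the
induced log-size map has a stable fixed point at V\* = aT/(n−1) with no
size-dependent cycle time at all — sub-exponential growth is itself a
size-control mechanism.

## Stochastic lineage and pedigree simulation

Noise is applied per cycle: multiplicative log-normal factors on λ and
T (σ_lam, σ_T) and Gaussian noise on log n (σ_n, truncated to keep
n > 1), assumed mutually independent.  Division conserves volume
exactly: the daughter takes v_end − log n, the mother keeps
v_end + log(1 − 1/n), and both re-enter the cycle under the same
mechanism (mother/daughter-specific rules were considered and left out;
one consistent rule is easier to reason about and suffices for every
behaviour studied here).  Events are processed on a queue ordered by
(division time, cell id), so a fixed seed reproduces tables
byte-for-byte.  A computed cycle time above T_cap (default 20 h — no
division within a typical experiment) records the cell as ARRESTED;
cycles cut off by the observation end or by the colony reaching
`max_cells` (the microfluidic trap filling) are CENSORED.

## The synthetic microfluidics generator

`sizecontrol.physiology` emulates glucose-decoupling experiments:
time-lapse imaging at 10-min frames of 1–3 colonies per position, each
founded by one cell, under genotype × external glucose × doxycycline
conditions, with 5% multiplicative log-normal measurement noise on
size.  Founders start at log(40 fL) ± 0.1 — the operating point of
maltose pre-growth — so adaptation to the new condition is emergent.

No mechanistic signalling model exists for this system; the generator
is the minimal bookkeeping that reproduces the qualitative regime
structure, with every coefficient exposed in `PhysiologyParams`:

* **Influx** J = Vmax·S/(Km + S); Km defaults to 10 mM (mid-affinity
  transporter).  Wild type has a high-capacity uptake system
  (Vmax 4.0, Km 3 mM); transporterless strains have Vmax = 0; single-HXT
  strains get Vmax from a saturating linear doxycycline ramp.
  % w/v glucose converts to mM with 180.16 g/mol.
* **Growth rate** λ = λ_sens(S) + (lam0 + c_J·Ĵ)·φ, where
  λ_sens = lam_max_gain·S/(K_sens + S) requires the Snf3/Rgt2 sensors
  (zero in sensorless genotypes), Ĵ = J/(J + j_half) is normalised
  influx, and φ ∈ [0, 1] is substrate availability: 1 while influx or
  the internal reserve covers demand, collapsing quadratically as the
  reserve empties.  Sensor-driven growth is deliberately *not*
  substrate-gated: it commandeers residual resources, which is what
  lets unsupplied cells swell (type II) while unsensed starving cells
  stop growing (type I).
* **Reserve** (per unit cell volume, so a condition-level quantity):
  dR/dt = J − y·λ_pot·(1 + demand_sens_amp·λ_sens), clipped to
  [0, R0].  Consumption scales with potential biomass production, and
  sensor drive amplifies it — high external glucose without matching
  influx drains the pool fastest, so divisions-before-arrest fall with
  glucose.  R0 = 6.8 flux·h sets the influx-free transient at ≈ 25 h.
* **Cycle time** T_eff(v) = T(v) · h(Ĵ) · g(R/R0).  The influx
  speed-up h = 1/(1 + 0.8·Ĵ) implements division-machinery dependence
  on internal glucose.  The starvation multiplier g = (gate/frac)^p
  below a reserve fraction of 0.4 lengthens cycles as the pool drains;
  its exponent p = 0.66 + 1.6·λ_sens/(λ_sens + 0.06) is
  sensor-coupled, so sensed cells lengthen their cycles (and keep
  growing — type II) while unsensed cells keep dividing at near-normal
  pace on dwindling reserves and shrink (type I).  Once the reserve
  falls below 10% no cycle can complete (famine); arrested cells keep
  swelling at their last growth rate for 8 h and then hold.

The sign flip of the steady-state size/division-rate correlation under
influx titration is a structural consequence, not a tuned accident: at
steady state the measured colony division rate is pinned to λ/log 2
(stationary sizes with volume growing as e^{λt} force counts to grow at
λ), so the dox series moves rates through the influx term c_J·Ĵ in λ.
The steady size solves λ·h(Ĵ)·T(v\*) = log n, and
d(λh)/dĴ ∝ c_J − c_h·(lam0 + λ_sens): negative when sensor drive is
present (size falls as rate rises — the inverse correlation), positive
without it (size and rate rise together).  Defaults satisfy
c_h·lam0 < c_J < c_h·(lam0 + λ_sens(0.1%)) with margin on both sides.

Calibration anchors (set once, from the physiology being emulated, not
fitted to any dataset): influx-free early division rate ≈ 0.3/h (via
T(v) at the founder size), influx-free transient ≈ 25 h (via R0), a
homeostatic band wide enough that wild type is steady from 0.01% to 2%
glucose, and a dox threshold between 60 and 250 ng/ml separating
large-cell arrest from steady growth at 0.1% glucose.  Division ratio
n = 2.2 (budding asymmetry) with σ_lam = 0.04, σ_T = 0.07,
σ_n = 0.04.

**What the generator does not emulate:** spatial trap geometry and
crowding, cell death, mother-age effects beyond the shared T(v),
transporter-specific kinetics at high substrate (uptake is monotone
Michaelis–Menten, so the loss of steady state seen when an intermediate
-affinity transporter meets 2% glucose — reduced effective influx at
high external glucose — is outside the model), transcriptional
adaptation, and absolute wild-type rates at rich glucose (the
calibration favours the influx-free anchors; wild-type rates at 2% run
high, ~0.9/h, while every cross-condition ordering is preserved).
Passing tests therefore certify the regime *structure* and the
quantification chain, not quantitative agreement with any particular
imaging dataset.

## Quantification

Re-implemented from standard microfluidics practice:

* **Growth curves**: cells counted per frame per colony from first
  appearance; counts are non-decreasing.
* **Division rate**: OLS slope of log₂ N(t) (scipy linregress), fit
  after a burn-in ending when the colony reaches 4 cells (two
  generations); R² reported; constant counts give rate 0 with R²
  flagged NaN.
* **Mean size**: per frame, over cells born at least 2 h earlier, so
  buds that have not reached final size are excluded; counts reported.
* **Steady state**: divisions must continue in the final window
  (default 4 h) and the relative OLS slope of mean size must be within
  ±2%/h of zero.
* **Arrest call**: a non-steady colony with no division in the final
  5 h is arrested; terminal mean size below 0.7× the early reference
  (hours 3–9) is TYPE_I, above 1.5× is TYPE_II, otherwise
  INDETERMINATE.  Divisions-to-arrest is the mean pedigree depth
  (ancestor divisions per cell).  The thresholds and windows are
  package defaults chosen to separate the generator's regimes with
  margin and are all exposed as arguments.  Multi-colony tables are
  classified per colony and aggregated by majority vote with a
  deterministic tie order.

## Problem sizes and numerics

The test suite and the acceptance script use: 1,000 random draws for
map exactness (tolerance 1e−12); 100-generation balanced-growth drift
(1e−9); 10,000 × 50 random-walk trajectories (variance within 5%);
fixed-point residual 1e−8 and convergence to 1e−3 within 200
generations; a 200-point regime grid excluding a ±0.02 margin around
the band edges (where a 2,000-iteration oracle could not settle);
division-rate recovery at 0.1–0.6/h over ≥ 5 doublings (within 2%);
and a 60-run generator benchmark (34 h observations, 10-min frames, 2
positions per run, colonies truncated at 1,500 cells) quantified blind
and scored against the analytic ground-truth regime of each condition.
The benchmark completes in about 15 s; the full suite in well under a
minute.
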