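# Methods

## The model

A synapse is a fixed array of release sites, partitioned into two classes:
`n_high` sites whose docked vesicle is released by one action potential with
probability `pv_high`, and `n_low` sites with `pv_low` ("reluctant" or
slowly releasing vesicles). A site holds at most one vesicle. The state of
the terminal is the occupancy of each class.

Per action potential, each class releases Binomial(occupancy, pv_eff)
vesicles, independently per site. Between events, each vacancy refills
independently with probability `1 − exp(−∫ α dt)` — first-order kinetics in
the vacant space, with a single unitary recruitment rate α shared by both
classes. During ongoing stimulation α is the constant `alpha_train`; after a
train ends it is elevated and relaxes during rest,

    α(t_rest) = α_inf + (α_0 − α_inf) · exp(−t_rest / τ_α),

so that the fraction of the pool recovered after a rest of length t is
`1 − exp(−∫₀ᵗ α(s) ds)` (closed form in `RecruitmentRateFunction`). A gap
between stimuli counts as a rest when it is at least `rest_threshold`
(default 100 ms); shorter gaps use `alpha_train`.

An optional facilitation state F (shared by both classes) multiplies pv:
`pv_eff = min(1, pv·(1+F))`; F increments by `facilitation_increment` after
each stimulus and decays exponentially with `facilitation_tau`. It is off by
default and exists to reproduce paired-pulse behaviour; whether facilitation
acts multiplicatively or additively on pv is not settled, and we chose the
multiplicative form for the usual reason that it preserves pv ≤ 1 gracefully
under scaling.

Deliberately *not* modelled: calcium-channel/sensor biophysics (pv values
are phenomenological); activity dependence of α within a train (one constant
`alpha_train` regardless of frequency — see Limitations); transitions of
vesicles between pv classes; postsynaptic receptor desensitization.

## Estimators

**Back-extrapolation ('S').** A least-squares line through cumulative quanta
vs time over a late steady-state window; the intercept at train onset is the
RRP content and the slope the recruitment rate. On regimes with substantial
recruitment this estimator is biased low — residual steady-state occupancy
and the early recruitment deficit both depress the intercept (about −25% for
a single-class pool with N=4000, pv=0.1, α=5/s at 300 Hz). We keep it
because it is the field's reference method; the test suite asserts its bias
direction rather than pretending it away.

**Vacancy-recruitment model ('M').** Nonlinear least squares of the
deterministic expectation recursion

    o_{i+1} = N(1−s) + o_i(1−pv)s,    s = exp(−αΔ),

against the per-stimulus quanta, with capacity N and pv free and α either
fixed or fitted jointly (`alpha='fit'`). On data generated by the model this
recovers N exactly; through the full render→measure pipeline with minis and
noise it recovers N within a few percent. Initialization comes from method
'S'; optimization uses `scipy.optimize.least_squares` with pv bounded in
(0, 1]. For the second train of a paired (recovery) protocol the pool starts
partially full, so the fit holds N fixed at the first-train estimate and
frees the initial occupancy instead (`capacity=` argument); refitting N
there would misattribute refilling toward a smaller pool.

**p̄v** is the quantal content of an isolated (rested) response divided by
the RRP content. The **unitary recruitment rate** is recovered from the
steady state as `−ln(1 − r_ss/v_ss)/Δ`, the per-interval refill fraction of
the fitted model's vacant space converted to a rate.

**Frequency jumps.** Conditioning at 50/100 Hz removes high-pv vesicles; a
300 Hz jump releases the standing low-pv population. The differential
release subtracts the time-averaged continued-conditioning control (treated
as a per-time flux, so one 300 Hz interval carries Δ_300/Δ_cond of a control
response). The standing RRP content is the total differential minus the
recruitment into the *excess* vacancies, computed by the observed-driven
recursion (`excess_recruitment`): the excess vacancy starts at zero at jump
onset, grows with each differential release and refills at rate α. That
recursion is exact for the excess bookkeeping precisely because the excess
vacancy has a known initial condition. p̄v of the standing pool is the first
differential response over the standing content, and the normalized
cumulative differential read against the recruitment-corrected theory curve
(offset to its rightmost point) intersects the ordinate at 1/p̄v.

**FM destaining.** Raw ROI fluorescence is normalized in four steps:
(1) divide by the mean background; (2) subtract the straight line fitted
over the rest preceding the final 20 Hz train, anchored to zero correction
at that rest's start, applied to all frames (rundown correction, per ROI);
(3) subtract F∞, the mean residual after the final train; (4) divide by F0,
the mean over the pre-stimulation window *computed after steps 1–3* (the
published order of operations is ambiguous on this point; computing F0 last
makes the pre-stimulation baseline exactly 1 and is covered by a round-trip
test). ΔF/F0 after an epoch is 1 minus the mean normalized value over the
last 3 frames (12 s at 0.25 Hz imaging) of the following rest. Group
summaries are means ± s.e.m. across preparations of within-preparation
medians. Note that because F∞ is subtracted before F0 is computed, ΔF/F0 is
a fraction of the *releasable* fluorescence range.

## Parameter sets and what they emulate

All defaults live in `vesiclekit/configs/*.yaml`, with comments separating
protocol-anchored values from implementer-chosen ones.

**Calyx (300 Hz × 300 ms, 90 APs).** N = 3200 sites (2880 high / 320 low),
pv_high = 0.36, pv_low = 0.12 (rested p̄v = 0.336), alpha_train = 5/s,
α₀ = 5.4/s, α_inf = 1.5/s, τ_α = 2 s, quantal size 0.1 pC (CV 0.3). These
were calibrated once against the regime's known phenomenology — near-empty
steady state of ~53 quanta/AP late in the train, RRP estimates below half of
the ~7000 quanta a full train releases, genotype convergence within the
first few action potentials and equal cumulative release by 150 ms when pv
is doubled — and then frozen. α_inf and τ_α are plausible defaults, not
measured values. The QKO-like variant doubles both pv values and changes
nothing else.

**Schaffer/culture (20 Hz, 6 s).** N = 400 (200/200), pv 0.2/0.05,
alpha_train = 0.25/s (about 20-fold slower recruitment than the calyx),
α₀ = 0.5/s, facilitation_increment = 0.45 with τ = 100 ms so that the
baseline paired-pulse ratio at 50 ms is mildly facilitating and doubling pv
occludes it. FM simulations use a well-mixed reserve 15× the RRP, 50%
stained after loading, imaging at 0.25 Hz, and a 60-s 0.2 Hz epoch — short
enough that fractional destaining stays in its linear range, followed by a
180-s 20 Hz train that destains the releasable pool essentially completely
so that F∞ is genotype-independent.

**Frequency-jump studies** use pv_high = 0.18, pv_low = 0.06 with a
low-dominated composition (160/3040) and alpha_train = 1.2/s. The
differential-release method assumes (i) conditioning long enough for the
standing pool to settle, (ii) elimination of high-pv vesicles, and (iii) a
modest refill-sustained residual at the end of the 200 ms jump; these
conditions bound α and the composition from both sides, and the chosen
values sit in the window where all three hold (the 100 Hz case uses its
750 ms variant, since 500 ms does not quite settle at these rates).

**Convergence index.** "Where two trains converge" is operationalized as the
first stimulus at which |q_a − q_b| ≤ 10% of their pairwise mean. The
deterministic model re-diverges mildly after the first crossing (the
pv-doubled synapse transiently undershoots while its standing occupancy
equilibrates) before both settle onto the same recruitment-limited steady
state; at experimental noise levels that transient is invisible, and the
first crossing is the quantity of interest.

## Synthetic data vs real recordings

The generator reproduces binomial quantal statistics, vacancy-limited
recruitment, facilitation, quantal-size variability, minis, measurement
noise, rundown and residual fluorescence. It does **not** reproduce:
between-animal variability (except where tests add it explicitly as
lognormal scatter in pool size), receptor desensitization and saturation,
electrotonic/series-resistance distortions of the recorded currents, more
than two pv classes or state transitions between them, or activity-dependent
recruitment within trains. Passing tests therefore demonstrate that the
estimators recover the parameters of *this* model class under realistic
noise — not that the model is a complete account of any real synapse.

## Numerical choices

- Fits: `np.polyfit` for lines, `scipy.optimize.least_squares` (bounded,
  'S'-initialized, `ftol=1e-12`) for the model; non-convergence raises
  `ConvergenceError` carrying the last iterate.
- Sweep rendering uses a difference-of-exponentials quantal kernel (rise
  0.1 ms, decay 0.5 ms) normalized to exactly unit charge on the sampling
  grid, and a 1 ms synaptic latency so that stimulus-artifact blanking
  (default 0.5 ms, linear interpolation) never clips the response.
- Response windows span the full inter-stimulus interval (charge, not peak);
  the last response reuses the final interval. Negative measured quanta are
  retained, not clipped, to keep estimators unbiased.
- Mini detection thresholds a high-passed trace at 4 robust (MAD-based) SDs
  with a 5 ms refractory, but quantifies amplitude and charge on the *raw*
  trace against a local median baseline, because high-pass filtering removes
  area from each event.
- One seeded `numpy.random.Generator` per simulation call; no global RNG
  state; identical seeds give bit-identical outputs. Sweep averages spawn
  child seeds via `SeedSequence`.
- Simulation sizes in tests (10,000 Monte-Carlo runs for oracle agreement,
  20 sweeps per preparation, 200 interleaved jump trials, 250 FM ROIs) were
  chosen to match the precision of the corresponding experimental designs.

## Known limitations

- A constant `alpha_train` cannot describe both a 300 Hz-exhausted terminal
  (where the end-of-train rate is ~5/s) and 50–100 Hz conditioning (where
  refill at that rate would outrun release and keep the pool nearly full).
  Real recruitment is activity-dependent; consequently the calyx-headline
  parameter set and the frequency-jump parameter set use different
  `alpha_train` values, each appropriate to its protocol.
- With shared per-vacancy refill, the steady-state standing pool during
  conditioning retains a high-pv contingent bounded below by the
  harmonic-type mean N/(Σ n_c/pv_c); a mostly-high-pv pool therefore cannot
  show a 3-fold drop from rested p̄v to jump p̄v in this model class,
  whatever α is. The jump analyses operate in the low-dominated regime where
  elimination genuinely occurs.
- Back-extrapolation ('S') is systematically low whenever recruitment is
  substantial; report it alongside 'M', not instead of it.
- The FM stage is trace-level only: image registration and ROI detection are
  out of scope, and the mean-field stained-count evolution ignores
  per-vesicle stochasticity (validated against a per-vesicle Monte-Carlo
  oracle in the tests).
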