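# Methods

This note documents the models, estimators, and numerical choices behind
`optopallidum`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal conventions

Voltage-clamp sweeps hold at −60 mV; excitatory currents are inward and
therefore negative, and amplitudes are reported as magnitudes. Current-clamp
sweeps are in mV. The sampling rate defaults to 20 kHz, and every conversion
from a time window to a sample count goes through one rounding function
(`model.n_samples`, round to nearest).

## oEPSC detection and measurement

Each sweep is smoothed with a 0.2 ms (4-sample) boxcar. The window is
trailing-aligned and the leading edge padded by holding the first sample, a
deterministic choice that conserves interior mass. Repeated trains share a
time base, so pulse-aligned averaging reduces to a point-wise mean.

Per pulse, the baseline is the mean of the preceding 50 ms and the
detection statistic is the most negative excursion of the smoothed average
within the search window (until the next pulse onset, capped at 90 ms); a
response is detected when that magnitude exceeds 3 × the baseline sample SD.
All amplitudes and kinetics are measured on the same smoothed trace the
criterion sees, so detection and measurement cannot disagree about the peak.

Onset is obtained by fitting a least-squares line to the samples between the
first 20% and first 80% amplitude crossings of the rising phase and
extrapolating to the baseline; latency is onset minus light onset. With
fewer than three rise samples the first threshold-crossing time is used and
flagged. An extrapolated onset earlier than the light onset (possible under
noise) is clamped to the light onset and flagged, which keeps latencies
non-negative. The 20–80% rise time uses linearly interpolated crossing
times; on a pure exponential rise it equals τ·ln 4, which the tests use as
an analytic anchor. The decay constant is a single-exponential
least-squares fit (log-linear initialization, positive-τ bounds) from the
peak to 10% of the peak, flagged if the window truncates the decay.

### Connection classification (stable-delay rule)

A single 3×SD extremum criterion applied to a ~90 ms search window detects
"something" in a large fraction of pure-noise windows — the expected
behavior of the maximum of ~10² effectively independent Gaussian draws, and
the tests verify our false-positive rate against exactly that Monte-Carlo
null. A usable *cell-level* connection call therefore requires what
experimenters require in practice: a response that repeats at a consistent
delay. A cell counts as connected when the first pulse is detected, at
least half the train pulses are detected, and the SD of the detected peak
latencies across pulses is ≤ 2 ms. True responses (latency jitter ≈ 0.3 ms)
pass essentially always; noise extrema, whose latencies are uniform over
the window, essentially never. This is the package's quantitative rendering
of the stable-delay requirement; per-pulse `detect_and_measure` remains the
plain 3×SD rule. The paired-pulse ratio divides the measured second-pulse
amplitude by the first even when pulse 2 falls below threshold (a
transmission failure then reads as a ratio near zero); it is undefined when
the first pulse is not detected.

## LIF membrane model

The simulator is a leaky integrate-and-fire neuron, not a conductance-based
model: the published phenotype constrains input resistance, time constant,
sag, spike shape and rates, none of which requires channel kinetics.
Exponential-Euler integration at dt = 1/20 kHz is exact for the passive
membrane, which is why the passive-limit tests can demand sub-percent
agreement with Ohm's law and the closed-form rheobase
I = ΔV_thr / (R_in·(1 − e^(−T/τ_m))).

Active mechanisms:

* **Sag** — a linear hyperpolarization-activated current
  I_h = g_sag · w, where w low-pass filters max(0, E_rest − V) with
  τ_sag = 400 ms (slow HCN-like activation). Because the current persists
  at steady state, the chord resistance seen by hyperpolarizing steps is
  R_in/(1 + g_sag·R_in). The preset factory therefore calibrates the leak
  resistance upward so the *chord* value equals the published input
  resistance — the quantity the linear-fit estimator measures — and sets
  g_sag so the full sag at the −100 pA step matches the published sag
  amplitude. τ_sag trades off two extraction biases (sag contamination of
  the τ_m fit versus incomplete sag at the steady-state window); 400 ms
  keeps both round-trip errors under ~4%.
* **Spike** — threshold crossing stamps a triangular waveform from V_thr to
  V_thr + height and down to V_reset, with the fall lengthened by
  (height + V_thr − V_reset)/height so the half-height width equals the
  configured spike width exactly. V_reset sits one published fAHP amplitude
  below threshold.
* **After-currents** — two alpha-kernel (t/τ·e^(1−t/τ)) hyperpolarizing
  currents per spike, a fast one (~1 ms) and a slow one (tens of ms),
  producing distinct fast and slow AHP troughs. Their amplitudes are
  qualitative choices; AHP extraction is validated against a dense-
  simulation oracle, not against published population values.
* **Pacemaker** — a tonic drive calibrated by bisection to the published
  spontaneous rate. With sag and a deep reset the cell can sustain firing
  above some minimal rate even at near-threshold drive; the slow
  after-current of the GP_CPu preset is sized so its low published rate
  (5.47 Hz) is reachable.

Passive-property protocols (hyperpolarizing steps, the −50 pA τ sweep,
brief-pulse rheobase) are simulated with the pacemaker drive offset to
zero, emulating a recording held at rest; the published mean membrane
potential serves as the resting potential of the silenced model. The
published f–I values at 100/500 pA are *not* calibration targets: the LIF
f–I curve is monotonic, whereas real GP_CPu neurons show depolarization
block; f–I extraction is tested for counting correctness only.

The −50 pA time-constant sweep is a dedicated sweep (−50 pA is absent from
the −20…−100 pA/20 pA grid). The τ fit iterates its window once (50 ms,
then 5·τ̂), restricted to 50 ms when the onset is non-monotonic (sag).
Steady state is the final 200 ms of the 1 s step; sag is measured on the
−100 pA step; spike height is threshold-to-peak; AHP amplitudes are
relative to threshold. Each of these conventions is fixed here because the
source analysis left it unstated.

## Synthetic oEPSCs and cohorts

The synaptic kernel is a difference of exponentials (τ_rise 0.8 ms,
τ_decay 8 ms by default) divided by its analytic maximum, so the configured
amplitude is the true peak — making amplitude recovery exactly testable.
Latency defaults to 3 ± 0.3 ms (plausible monosynaptic values; the source
prints no numeric latency). Per-pulse multiplicative plasticity factors
realize paired-pulse facilitation; Bernoulli failures are available.
Baseline noise is additive i.i.d. Gaussian (2 pA default).

Cohorts draw a Bernoulli innervation flag per cell at the published
type-dependent probabilities (M1→GP_CPu 28/35, M1→GP_STN 17/51,
M2→GP_CPu 23/27, M2→GP_STN 36/75) and give innervated cells log-normal
amplitudes. No per-group amplitude statistics were published, so the
defaults are order-of-magnitude choices: GP_STN median 30 pA; GP_CPu an
equal-weight two-component mixture (30 and 120 pA) reflecting its
apparently bimodal distribution; MSN 250 pA; STN 40 pA. The cohort
generator streams cells one at a time (2000 cells × 10 trains of 20 kHz
sweeps would otherwise need gigabytes), and the full-pipeline recovery test
runs 500 cells per group, checking each recovered probability within 3
binomial SDs.

Bouton counts are Poisson with mean density × ROI area/10⁴ µm², drawn from
mediolateral density fields whose peaks sit at the magnitudes of the
published per-animal maxima (broad GP tuning, sharp STN tuning). The
packaged table stores the published per-animal maxima as single
100 × 100 µm pseudo-ROIs, since only the maxima — not the ROI tiling —
were published. Recomputing the M1 STN-normalized ratio from that table
gives 0.471 ± 0.091 (and the 47% headline figure); the source's own prose
prints 0.496 ± 0.12 for this quantity, which does not follow from its
table — the table-derived value is treated as ground truth here.

## Statistics

Engines are scipy.stats; this module fixes conventions. The two-sided
Fisher exact test uses the point-probability rule (sum over tables with
probability ≤ observed), which the tests verify against full hypergeometric
enumeration for every table with total n ≤ 12. The planned-comparison
family for connection probabilities is the four tests (classes within each
area, areas within each class), Bonferroni-corrected — reproducing the
star levels 0.0125/0.0025/0.00025. Rank-sum and signed-rank tests use exact
nulls for combined n ≤ 20 without ties (verified against split/sign
enumeration) and tie-corrected normal approximations otherwise.
Kruskal–Wallis uses the chi-square reference by default and offers exact
permutation enumeration for total n ≤ 10. Tukey HSD after Kruskal–Wallis
mirrors the source's (statistically unconventional) pairing; both outputs
are reported so users can prefer either. Series-resistance gating estimates
Rs = |ΔV|/|I_peak| from the −10 mV/10 ms test pulse transient and fails at
Rs ≥ 25 MΩ (strict inequality).

## Problem sizes and determinism

The default test suite and the acceptance script use: 500 cells/group for
cohort recovery, 100 seeded runs for amplitude recovery, 40 s spontaneous
sweeps for rate extraction, 10× oversampled single sweeps for dense-oracle
checks, and exhaustive enumeration up to n = 12 for exact-test oracles.
These sizes make every stochastic criterion's Monte-Carlo error small
relative to its tolerance while keeping a full run in the minutes range on
one CPU. All randomness flows from explicit integer seeds through
numpy SeedSequence spawning; identical seeds reproduce identical sweeps,
tables, and cohorts bit-for-bit.

## Limitations

The generator omits several features of real recordings: light artifacts,
series-resistance filtering and compensation errors, slow baseline drift
beyond a linear term, correlated (1/f) noise, depolarization block and
spike-frequency adaptation, and channel-level sag kinetics. Passing
recovery tests therefore demonstrates internal consistency of the
generator/estimator pair and correctness of the statistical machinery —
not that the estimators are unbiased on arbitrary real data. Published
population values that depend on unavailable raw recordings (population
means of intrinsic features, amplitude-based p-values) are out of reach by
construction and are replaced by the property-based checks above.
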