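# Methods

This note documents the models, conventions and numerical choices behind
somnokit, and what the synthetic-data generator does and does not emulate.

## Data model and conventions

Recordings are epoch-scored hypnograms (default 4-s epochs; states wake
`W`, NREM `N`, REM `R`) with per-epoch artefact flags and an optional
theta-dominated-waking (TDW) flag on wake epochs.  Epochs are 0-based;
windows are half-open `[start, end)`; Zeitgeber time (ZT) is expressed in
decimal hours since lights-on of day 1.  Artefact epochs keep their state
label and are *included* in all state-time accounting but *excluded* from
spectral quantities — mixing these conventions is the most common source
of off-by-a-few-minutes discrepancies in this kind of analysis.

Per-minute hypnogram display uses the modal state of each minute's 15
epochs with the fixed tie-break priority W > N > R.  Any modal rule
slightly under-represents REM sleep, which occurs in short bouts; this is
a property of the display, not of the accounting functions.

Files are plain TSV (one row per epoch/sample) plus a YAML protocol
descriptor; floats are written at full precision and read back with
round-trip parsing, so write→read is bit-exact.

## Process S

S rises during waking and REM sleep toward the upper asymptote UA with
time constant τi and decays during NREM sleep toward the lower asymptote
LA with τd, iterated at the epoch step dt = 4 s:

    wake/REM: S' = UA − (UA − S)·e^(−dt/τi)
    NREM:     S' = LA + (S − LA)·e^(−dt/τd)

S is clamped to [LA, UA] after each step (tolerance 1e−12) purely to
guard floating-point overshoot.  Simulation over a bout of one state uses
the closed-form exponential for the whole run; this is algebraically
identical to per-epoch stepping and is what makes the exhaustive grid
search cheap.

**Warm-up.**  The reported trace starts from the steady-state level of S,
obtained by iterating over the first 24 h of the hypnogram starting at
S0 = 150% and *repeating that pass until the end-of-day level converges*
(tolerance 1e−9, < 10 passes in practice).  A single 24-h pass contracts
the initial spread only ~60-fold when τd ≈ 3 h, which leaves a ~1%
residual dependence on S0; iterating to the fixed point makes the
steady-state assumption exact and the seeded level genuinely independent
of S0.  The fixed point exists and is unique because each pass is a
monotone contraction of the interval [LA, UA].

**Asymptote estimation.**  UA is the 99th percentile of the per-epoch
NREM delta-power sample over the whole recording.  LA is the crossing of
the normalized NREM and REM delta-power frequency distributions: both are
histogrammed on a common grid (bin width 2% of reference), the REM mode
is located, the NREM mode is searched above it (this tie-breaks flat
histograms sensibly), and the crossing is the first bin between the modes
where the NREM frequency reaches the REM frequency, refined by linear
interpolation.  Distributions that never cross raise an error advising a
manual LA.  Note a structural limitation: under an undisturbed LD 12:12
sleep-wake distribution S never approaches UA, so the percentile
estimator sees the asymptote mainly through the multiplicative noise
tails of delta power — UA estimates are therefore only as good as the
noise model, whereas τi/τd recovery is robust to this.

**Percentile time course.**  Within each lighting block the artefact-free
NREM epochs are split into equal-count bins (12 per light period, 8 for
the post-SD remainder of the SD day's light period, 6 per dark period;
counts equal within ±1 by construction).  Bin values are means of
per-epoch delta power in % of the reference: the mean over the last 4 h
(ZT8–12) of the two baseline light periods, where delta power is lowest
and least influenced by prior sleep-wake history.  Bin timing is the
epoch-weighted midpoint.  NREM epochs inside the SD window are not
binned.

**Detrending.**  A straight line is least-squares fitted through the mean
bin values of ZT8–12 of baseline days 1 and 2 and recovery day 2 against
recording time; all bin values are divided by it and re-anchored so the
grand reference mean is 100%.  Division rather than subtraction because
delta power is a positive relative quantity.  When the three window means
are collinear (as for a pure multiplicative linear drift) they equalise
exactly; in general a line through three points leaves residuals.

**Grid search.**  τi ∈ [1, 25] h step 0.125, τd ∈ [0.1, 5.0] h step
0.025, endpoints inclusive — 193 × 197 = 38,021 combinations.  For every
grid point S is simulated (shared vectorised recursion across the whole
grid, iterating state runs) and averaged over the NREM epochs inside each
percentile bin — the same epochs that produced the observation; per-bin
sums accumulate analytically via geometric-series partial sums.  The MSE
against the bin values is minimised; ties break toward smaller (τi, τd)
lexicographically.  A 4×-coarsened grid (2,450 points) is provided for
quick exploratory fits.  A full-grid fit of a 4-day recording takes on
the order of a second.

## Spectral metrics

Per-epoch spectra are Hamming-windowed periodograms of consecutive 4-s
blocks (800 samples at 200 Hz → 401 bins, 0–100 Hz at 0.25 Hz).  Band
membership is by bin-centre inclusion on closed intervals, so 4.0 Hz
belongs to delta exactly once.  The normalization reference is the mean
over the three states of the state-mean total power (0.75–45 Hz) in the
48-h baseline — equal state weighting regardless of prevalence, so
animals with different sleep-wake distributions remain comparable.

Theta-peak frequency is the per-epoch argmax of power density within
6.5–12 Hz (TDW) or 5.5–12 Hz (REM), averaged over artefact-free epochs of
the state.  TDW classification flags a wake epoch when its theta-band
(6.5–12 Hz) to total (0.75–45 Hz) power ratio exceeds a threshold; the
default threshold is the equal-posterior point of a two-component
Gaussian mixture fitted to the wake ratio distribution (the valley of the
bimodal histogram), overridable by argument.  "Total" power is read as
0.75–45 Hz to match the reference band.

## Thermometry

The NTC conversion uses natural logarithms throughout:
β = T25·T37/(T25 − T37)·ln(R37/R25) with T in kelvin, and
t(°C) = [ln(Rt/R25)/β + 1/T25]⁻¹ − 273.15.  With these conventions the
conversion returns exactly 25 °C at Rt = R25 and 37 °C at Rt = R37 —
the natural-log reading is *required* for those identities.  Voltage
input uses Rt = V/I_const (I_const default 100 µA) with the per-epoch
median over 10-Hz samples.

Cohort QC reports each animal's daily amplitude (mean over baseline days
of the highest-minus-lowest hourly mean) and SD-window mean; animals
flagged for correction are shifted by the difference between their
SD-window mean and the remaining cohort's.  Amplitude outliers are
reported, never auto-dropped.

Transition profiles align temperature on state transitions whose flanking
bouts each last ≥ 8 epochs (> 32 s), relative to the anchor (mean of the
last pre- and first post-transition epoch), over at most ±90 s.  Each
transition's trace is truncated at its flanking bouts' ends, and profile
time points with fewer than 10 contributing traces are dropped — sparse
transition kinds therefore shorten naturally, and kinds with no
qualifying transitions are omitted.

Hourly association statistics: waking in min/h, LMA log2-transformed
(log2(counts + 1) where zeros occur).  Partial correlations come from the
pairwise-correlation formula (equivalent to residual-on-residual
correlation; the test suite checks both routes against each other and
against pingouin); Fisher-Z transforms are provided for cross-animal
comparison.  The residual sine fit is an ordinary least-squares fit of
b + A·sin(2π(t + φ)/24) — linear in (sin, cos, 1) — with A ≥ 0 and φ
normalised to [0, 24) h.  The nested mixed models (T ~ wake; + LMA/waking;
+ interaction) use a per-animal random intercept — the minimal structure
that accounts for individual variance — fitted by maximum likelihood with
sequential likelihood-ratio χ² tests and variance-decomposition marginal
and conditional R².  Singular fits are reported via a convergence flag,
never silently dropped.

## Recovery accounting

Accumulated recovery-minus-baseline curves difference minutes-in-state per
1-h interval from the end of SD, cumulatively summed.  Each recovery hour
is paired with the same clock hour of the corresponding baseline day
(REC1↔BL1, REC2↔BL2); a mean-of-baseline-days option exists.  LMA per
unit waking uses equal-waking bins (6 per light period, 12 per dark, 6
for the SD window, 3 for the post-SD light remainder); boundary minutes
are apportioned pro rata on the cumulative-waking axis — waking time and
movement counts alike — so bins carry equal waking time to float
precision (whole-minute cuts can differ by nearly two minutes when
minutes carry fractional waking).  MAD outlier flags use
|x − median|/(1.4826·MAD) > 3 by default; a zero MAD with non-identical
values flags any non-zero deviation.

## qPCR ratios

RQ = E^(Ct_mean − Ct) per gene; NRQ divides by the geometric mean of the
reference-gene RQs of the same sample (≥ 2 reference genes required) and
then rescales each gene's grand mean to 1.0 — normalize first, rescale
second.  log2(NRQ) is provided.  Genes with mean Ct > 30 are flagged
unreliable and can be filtered, never silently dropped.  The isoform
ratio is E^(Ct_comm − Ct_ext); it is multiplicative in ΔCt and exactly 1
at ΔCt = 0.

## The synthetic-data generator

The generator emulates a 96-h LD 12:12 recording with 6-h forced wake at
ZT0–6 of day 3:

- **Hypnogram.**  A semi-Markov chain (W↔N with N→R→{W,N} branching).
  Per-phase stationary time fractions are the study-scale targets
  (light: 260/389/70 min wake/NREM/REM per 12 h; dark: 512/189/19) and
  dwell times are mixtures of geometric distributions dominated by brief
  bouts, with branching probabilities derived from the fractions and mean
  dwells.  The brief-bout mixtures matter: they make the ≥8-epoch
  consolidation criterion prune most transitions, putting the consolidated
  wake→NREM census near the few tens per two baseline days seen in real
  recordings rather than in the hundreds.  The SD window alternates long
  wake stretches with brief NREM intrusions (~98.5% wake); the first 6 h
  after SD use sleep-biased rebound fractions (a phenomenological
  propensity change, deliberately independent of the Process S model
  under test).
- **Delta power.**  delta = S·ε on artefact-free NREM epochs, with S the
  ground-truth Process S (same steady-state warm-up convention as the
  analysis, computed by an independent per-epoch loop) and ε lognormal
  with mean 1.  The default CV of 0.4 reflects the estimation floor of a
  4-s band power (~13 bins × 2 DOF gives CV ≈ 0.28) plus biological
  modulation; REM epochs receive low values centred below LA so the
  asymptote-crossing estimator has a REM distribution to work with.
  Default truth: τi = 13 h, τd = 3 h, UA = 290%, LA = 45% (grid-aligned,
  study-scale values).
- **Spectra.**  Per-state templates on the 0.25-Hz grid (1/f background;
  delta bump at 2 Hz in NREM; theta peaks at 7.5 Hz in REM and 8.1 Hz in
  TDW) with lognormal jitter; stored float32.  Raw EEG waveforms are not
  synthesised.
- **Temperature / LMA.**  First-order relaxation toward state asymptotes
  (wake 36.7, NREM 35.8, REM 36.3 °C; τ 120/150/60 s) plus an
  LMA-coupled term and white step noise.  The REM time constant and
  asymptote gap put the mean rise 1.5 min after NREM→REM entries near
  0.4 °C.  LMA is Poisson per minute, gated on the minute's wake
  fraction, with light/dark rates calibrated to ~119/817 movements per
  12 h.
- **qPCR.**  Ct tables from known fold changes and efficiencies, two flat
  reference genes, and an ext/com primer pair with a known ratio.

Everything is deterministic under the config seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: circadian modulation *within* lighting phases
(fractions are phase-constant); realistic per-state 1/f exponents and
spectral shapes beyond single peaks; the initial temperature drop at
REM→wake transitions (a first-order relaxation cannot produce it);
technical drift in EEG gain (the detrending stage is validated on
constructed drift instead); EMG; scorer disagreement.  Single-animal
recovery-minus-baseline curves are dominated by genuine day-to-day
variability in dark-phase sleep (heavy-tailed wake bouts), as in real
single animals — cohort-scale rebound magnitudes require cohort-scale
averaging and are not asserted at single-animal scale.

## Problem sizes used in the test suite

Unit and end-to-end tests run on full-scale 4-day recordings (86,400
epochs) for hypnogram-level analyses, 1–2-day undisturbed recordings for
spectra- and temperature-heavy fixtures, the full 38,021-point grid for
noise-free and noisy parameter recovery (10 seeds), the 4×-coarsened grid
for the 12-animal cohort null, and 20 seeds per scenario for the
mixed-model selection checks.
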