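# Methods

## The anchored-parabola feature

The feature extractor fits, at every sample $(n, y(n))$, the one-parameter
parabola $y'(i) = a(n-i)^2 + y(n)$ over the closed window
$[n-w,\,n+w]$, $L = 2w+1$. The coefficient is chosen so that the fit
residuals sum to zero over the window:

$$\sum_i \big(a(n-i)^2 + y(n) - y(i)\big) = 0
\;\Rightarrow\;
a = C\big({-L\,y(n)} + \textstyle\sum_i y(i)\big),\quad
C = 3/\big(w(w+1)L\big).$$

Two properties worth stating precisely:

* **This is a moment-matching fit, not the least-squares minimizer.** The
  minimizer of $\tfrac12\sum_i e(i)^2$ with $e(i) = a(n-i)^2 + y(n) - y(i)$
  is $a^* = \sum_i k_i^2\,(y(i)-y(n)) \big/ \sum_i k_i^4$ (with
  $k_i = n-i$), which needs per-sample multiplications by $k^2$. The
  moment-matching form used here is instead the $1/k^2$-weighted
  least-squares solution; it coincides with $a^*$ for $w=1$ and whenever
  the data are exactly parabolic through the anchor, and it is what keeps
  the per-sample cost at $L+1$ additions and 2 multiplications with no
  divisions. The unit tests verify the implementation against a dense
  solve of the weighted system; the acceptance suite also carries the
  unweighted-least-squares comparison, which fails by construction on
  non-parabolic windows and is retained as documentation of this
  distinction.
* **Exact baseline invariance.** $a$ depends on the data only through
  $-L\,y(n) + \sum y(i)$, in which any additive constant cancels
  analytically, so no isoelectric-line estimation is needed. (In floating
  point the cancellation is exact only to rounding; the property tests
  allow ~1e-6 slack.)

The parabolic height $H = |a| w^2$ is the vertical span of the fitted
parabola; it is polarity-blind ($|a|$), so inverted R waves are detected
like upright ones. The first and last $w$ samples, where the window does
not fit, are assigned $H = 0$ and can never host a detection.

`height_series` computes the window sums with a prefix-sum sliding window
(one addition per incoming sample). The streaming detector accumulates the
same prefix sums in the same order, so batch and streaming paths produce
bit-identical $H$ and hence identical peak lists — the split-stream
equivalence tests assert exact equality, not approximate.

## The detection sweep

One pass over $n = w \dots N-1-w$:

1. $H > H_{th}$ marks a candidate; a candidate with $H > H_{best}$ becomes
   the best candidate (strict inequality, so the earliest sample of a
   flat-topped maximum wins).
2. When $n - n_{best} > n_{cand}$ with a candidate pending, $n_{best}$ is
   registered as an R peak; the threshold becomes
   $\mathrm{sat}(\alpha_H \bar H_M)$ where $\bar H_M$ is the unweighted
   mean of the last $M$ registered heights and $\mathrm{sat}$ clamps to
   $[H_{min}, H_{max}]$. $n_{cand}$ therefore acts as a refractory
   interval: consecutive registrations are always more than $n_{cand}$
   samples apart.
3. When $n - n_s > n_{th}$ with no registration, $H_{min}$ is pushed into
   the same average and the decay clock $n_s$ resets — after at most $M$
   such events on a silent stretch the threshold sits at its floor.

Initialization is not dictated by the sweep's definition, so the package
chooses conservatively: the history buffer starts filled with $H_{max}$ and
$H_{th} = \mathrm{sat}(\alpha_H H_{max})$; the decay clock starts at the
first valid sample. A high start suppresses early false positives on noisy
onsets and costs at most a few silence-decay intervals before small beats
are acquired.

A best candidate still pending when the record ends is registered by
default (a genuine final beat should not be dropped because the timeout
could not elapse); `final_flush=False` / `--no-final-flush` restores the
strict behavior.

### Parameters

| name | meaning | units | qtdb-250hz | mitdb-360hz |
|---|---|---|---|---|
| Hmin | threshold floor | mV | 0.3 | 0.45 |
| Hmax | threshold ceiling | mV | 1.1 | 0.9 |
| alphaH | average-to-threshold scale | — | 0.335 | 0.45 |
| ncand | candidate timeout / refractory | samples | 70 (280 ms) | 115 (319 ms) |
| nth | silence-decay interval | samples | 480 (1.92 s) | 691 (1.92 s) |
| L | fit window length | samples | 17 (64 ms) | 35 (97 ms) |
| M | height-history depth | beats | 4 | 4 |

The height thresholds are in the physical units the record declares (WFDB
gain applied — millivolts for the PhysioNet databases); both profiles were
tuned at their native sampling rate and no automatic rescaling across
rates is attempted, because the threshold-vs-window interaction does not
scale linearly with the sampling period.

## Evaluation

Matching is greedy and chronological: references in order, each taking the
earliest unmatched detection within the tolerance (40 ms by default —
10 samples at 250 Hz, 14 at 360 Hz, `round(0.040 fs)`). For this
uniform-tolerance interval structure the earliest-available rule attains
the maximum achievable number of matches; the tests confirm equality with
an optimal-assignment oracle on randomized small cases. A nearest-available
rule, by contrast, can steal a detection needed by the next reference and
is not used.

Metrics: $S = 100\,TP/(TP+FN)$, $P = 100\,TP/(TP+FP)$,
$DER = 100\,(FN+FP)/(TP+FN)$. The DER denominator is the number of true
beats: that convention reproduces the pooled database figures this package
checks against ($147/86{,}995 = 0.17\%$), whereas dividing by $TP+FP$ does
not. Ratios with a zero denominator are reported as absent (`None`), never
as 0. Pooling sums counts and recomputes ratios (micro-average); averaging
per-record percentages would weight short records up and is never done.

Database beat annotations frequently sit off the R apex, which would turn
a 40 ms scoring tolerance into a test of annotation placement. Before
scoring, each beat annotation is therefore moved to the sample maximizing
$|y - \mathrm{median}(y)|$ within ±40 ms (median over the same window), a
rule that finds the dominant local extremum for either polarity and is
unaffected by baseline offset. The ±40 ms search radius reuses the scoring
tolerance — one knob rather than two. The exact realignment rule is a
degree of freedom in any reproduction of published database figures;
differences in it move pooled percentages only in the last digit, which is
why the benchmark checks carry ±0.10–0.15 point tolerances.

## Synthetic data

The generator emulates what the detector's feature responds to, with
defaults chosen to sit in the regime the shipped thresholds expect:

* RR intervals $\sim \mathcal N(60/\mathrm{hr},\; 60\,\mathrm{hr_{sd}}/\mathrm{hr}^2)$ s,
  floored at 0.2 s; defaults 60 ± 3 bpm.
* Each beat: R wave as a Gaussian bump (1 mV, σ = 10 ms — a sharp,
  narrow apex), flanking Q and S dips (−12% / −18% of the R amplitude,
  σ = 8 ms at ∓28 ms), P wave (0.15 mV, σ = 25 ms at −160 ms), T wave
  (0.30 mV, σ = 55 ms at +300 ms).
* Per-beat R-amplitude jitter (5% multiplicative normal),
  sinusoidal baseline wander (0.1 mV at 0.3 Hz), optional white noise.
* Ground truth is the within-beat argmax of the clean signal (±50 ms
  around the nominal apex), recorded before broadband noise is added, so
  scoring against truth is exact.

AWGN uses the *measured* convention: noise variance
$= \overline{y^2} / 10^{\mathrm{SNR}/10}$ with the mean square taken over
all samples including DC, making sweep results comparable to experiments
driven by MATLAB's `awgn(y, SNR, 'measured')`.

What passing synthetic tests does **not** show: robustness to muscle
artifact, electrode motion, abrupt morphology changes (ectopy, paced
beats), or rate-dependent wave-shape coupling — none of which the
generator models. Clean-train recovery and AWGN degradation are necessary,
not sufficient, evidence; the database benchmarks (optional, data not
redistributed) are the real-data check.

## Numerical and I/O choices

* All amplitudes are float64 in the units the source declares; WFDB ADC
  values are converted as $(\mathrm{adc} - \mathrm{baseline})/\mathrm{gain}$.
* The WFDB codec is self-contained and covers headers, signal formats 212
  and 16, and MIT-format annotations — the formats the QT and MIT-BIH
  databases use; rarer formats and multi-segment records are rejected
  explicitly.
* Candidate comparisons are strict (`>`), making every sweep deterministic;
  there is no randomness anywhere in detection.
* Experiment problem sizes default to 60 s records, 20 Monte-Carlo seeds
  per SNR level, and 20-record equivalence batches — large enough that the
  binomial noise on a per-record sensitivity is well under one percentage
  point at the rates of interest.

## Known limitations

* Profiles are database-specific; applying `qtdb-250hz` to 360 Hz data (or
  vice versa) degrades detection and is not guarded against beyond the
  documentation, matching the tuning-per-database reality of the method.
* The moment-matching fit weights the window center more heavily than a
  true least-squares fit would; for QRS detection this is immaterial (the
  feature is thresholded, not interpreted), but $H$ should not be read as
  a calibrated amplitude estimate.
* The adaptive threshold reacts over $M$ beats; a sudden large amplitude
  drop can cost up to $M$ missed beats before the silence decay recovers,
  which is visible in noisy-record benchmarks.
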