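# Methods

## Background and scope

Single-fiber recordings (microneurography) of human C-fibers cannot, in
general, resolve individual chemically evoked action potentials: several
fibers are recorded at once and the signal-to-noise ratio defeats spike
sorting. The *marking technique* works around this. The fiber is driven
electrically at a fixed low rate (0.25 Hz) and its conduction latency is
tracked. Because unmyelinated axons slow down when they conduct additional
action potentials (activity-dependent slowing, ADS), any chemically evoked
discharge in the seconds before a test pulse appears as a sudden latency
increase — a *marking* — whose magnitude grows with the number of
intervening spikes. This package implements the full computational chain
around that measurement: a generative model of latency traces with exact
ground truth, marking detection and summary statistics, ADS-based fiber
classification, NRS psychophysics summaries, and the contingency and rank
tests used to compare responder counts.

## Generative model of latency traces

The simulator uses the minimal first-order mechanism that realizes the
marking premise. A dimensionless slowing state `S`:

* gains a fixed increment `eps` per conducted action potential (electrical
  test pulse or chemically evoked spike),
* decays exponentially with time constant `tau`,
* saturates at a cap `S_max` (default 0.8).

The latency recorded at test pulse `i` is
`L_i = L0 * (1 + S(t_i^-)) + jitter`, evaluated just before the pulse's own
spike, so a latency step reflects exactly the discharge since the previous
pulse. Gaussian jitter (default SD 0.1 ms) models measurement noise.
Chemically evoked spikes are explicit event times, never rates, so
per-interval ground-truth counts are exact and conserved.

Traces of chemical-stimulation runs start with `S` at the fixed point of
continuous 0.25 Hz tracking (`S0 = eps * exp(-dt/tau) / (1 - exp(-dt/tau))`).
A recorded fiber has been tracked for many minutes before any injection;
starting from rest instead lets slow-recovery fibers' baselines creep
upward throughout the recording, which is neither realistic nor compatible
with the "normalizing latency" definition of silence. Classification runs
start from rest because the rising-frequency protocol defines its own
initial latency from its first pulses.

### Fiber archetypes

Three archetypes are shipped. Their slowing parameters were chosen once so
that (a) the printed class criteria (ADS 5%, recovery 24% within 40 s)
separate the classes with a wide margin, and (b) a single evoked spike
shifts the next latency above the 0.5 ms marking floor:

| class | baseline (ms) | eps (per AP) | tau (s) | von Frey threshold (g) | distance (mm) |
|-------|---------------|--------------|---------|------------------------|---------------|
| CM    | 144           | 0.006        | 10      | 8                      | 100           |
| CMi   | 288           | 0.004        | 150     | none                   | 120           |
| VHT   | 250           | 0.0045       | 130     | 15                     | 110           |

At zero jitter these land at ADS 2.5% / recovery 59% (CM), 15.2% / 0.3%
(CMi) and 15.9% / 2.5% (VHT). Baseline latencies and conduction distances
sit inside the recorded ranges (53–180 mm, conduction velocity < 2 m/s);
the two baseline latencies of 144 and 288 ms are the stable latencies of
the published example traces. No quantitative ADS recovery curve is
published for these fibers, so the time constants are stand-ins; nothing
downstream depends on their exact values, only on the class regions they
occupy.

### Chemical discharge profiles

* **bursting** — `n` trains of evenly spaced spikes, each train at most 4 s
  long, separated by at least 20 s. By default trains are aligned to start
  just after a tracked stimulus so each falls into a single inter-stimulus
  interval; this makes ground-truth recovery exact.
* **tonic** — sustained discharge with an exponentially decaying rate
  envelope (default 2 AP/s decaying over 300 s, the time scale of the itch
  rating time courses). Two dispersions: `poisson` (realistic, irregular)
  and `regular` (deterministic per-interval counts rounded from the
  envelope, spikes evenly spaced). The regular train is the canonical
  non-bursting control: its per-interval counts never increase over time,
  so after the initial rise it cannot produce a latency step, and therefore
  cannot produce the bursting pattern, by construction.
* **none** — no evoked discharge; the trace stays at the tracking plateau.

### What the generator does not emulate

Conduction failures under extreme slowing, sympathetic co-recorded fibers,
electrode drift, multi-fiber cross-talk, mechanically evoked discharge
during von Frey testing, and any biophysics of axonal membranes (the
first-order state is a phenomenological stand-in, not a channel model).
Passing closed-loop tests therefore shows that the analysis recovers the
structure this model generates — not that it is robust to every artifact of
real recordings.

## Marking analysis

**Detection threshold.** The publications behind the marking technique do
not quantify "sudden increase". The policy used here is explicit and
configurable: a marking at stimulus `i` requires
`L_i - L_{i-1} > max(0.5 ms, 3 * sigma)`, with `sigma` the jitter SD
estimated from consecutive differences of the last 20 pre-application
latencies (`std(diff)/sqrt(2)`, robust to slow drift). Conduction failures
break adjacency: no comparison is made across a gap.

**Analysis window.** Markings count only after the injection needle is
removed (the event log's application end), for 300 s by default — matching
the 5-minute rating windows. Both bounds are configurable.

**Cumulative latency and activation.** The per-fiber response is the number
of markings and their summed shifts; a fiber counts as activated iff the
cumulative shift strictly exceeds 5 ms. The shift reference is the previous
stimulus's latency (local difference), not a global baseline, and no
correction is applied for recovery between stimuli — the raw step is the
measurement.

**Slow bursting pattern.** A repetition is one marking followed by at least
five consecutive conducted responses (20 s at 0.25 Hz) with no further
marking and non-increasing latencies within one jitter SD ("normalizing");
a conduction failure inside the run invalidates it (conservative). Three
or more repetitions make the pattern. Traces tracked at a frequency other
than 0.25 Hz are rejected unless explicitly overridden, because the
silence-in-seconds and silence-in-stimuli definitions would disagree.

**Inherent ambiguity of the method.** Two limitations are properties of
the marking technique itself, and the detector inherits them honestly:

1. Under *sustained* discharge the slowing state plateaus, so per-pulse
   steps vanish even though spikes keep arriving. Exact equivalence between
   detected markings and ground-truth active intervals therefore holds for
   train-like discharge (where latency renormalizes between trains), and
   the oracle-equivalence suite uses such profiles. For tonic discharge the
   method measures onsets and fluctuations, not presence.
2. A transient rate fluctuation inside irregular tonic discharge — a jump
   followed by relaxation toward the plateau — is observationally identical
   to a burst followed by silence. Burst-detector specificity is therefore
   asserted at 100% only on deterministic-rate tonic controls; on Poisson
   tonic discharge with default jitter it is measured, not asserted
   (roughly three quarters of strongly activated, jittered tonic CM traces
   are correctly rejected in the default cohort).

## Fiber classification

From the rising-frequency protocol (20 pulses at 0.125 Hz, 20 at 0.25 Hz,
30 at 0.5 Hz, then 0.25 Hz tracking): initial latency = mean of the first
3 responses (count configurable; the source protocol does not state one);
peak = response to the last protocol pulse; ADS% = 100 (peak − initial) /
initial; recovery is read at the first tracked stimulus at least 40 s after
the protocol ends.

**Recovery base.** "Normalization of latency of more than 24% within 40 s"
is read as the share of *accrued slowing* recovered:
`100 (peak − L40) / (peak − initial)`. The alternative reading — percent of
initial latency — is unsatisfiable for CM-fibers, whose ADS is below 5% of
initial latency to begin with; a fiber cannot recover 24% of its initial
latency out of a 5% excursion. This was a genuinely ambiguous sentence;
the chosen reading is the one that makes both CM criteria jointly
satisfiable.

**Strict boundaries.** The rule uses the printed strict comparators
(`< 5%`, `> 5%`, `> 24%` read as printed, `> 10 g`, `< 22 g`). Values
exactly on a boundary, and the uncovered region (e.g. ADS < 5% with
recovery < 24%), are labelled `unclassifiable` and surfaced, never coerced.

## Psychophysics

Ratings are prompted NRS values on a 10 s grid from {0, 0.5, 1, …, 10};
0.5 encodes "neither itch nor pain" and counts toward cumulative measures
but never toward responder status (threshold 1). The cumulative measure
(AUC) defaults to the plain sum of samples — the magnitudes reported with
the study's rating series are consistent with sample-summing, and no
downstream statistic depends on the choice — with a trapezoid-over-minutes
alternative; mixing methods in a comparison is an error. A *relevant
reduction* between conditions is a strict difference of more than 5
cumulative NRS points. Erythema area is supra-threshold pixel count times
pixel area, with the widespread flag at 1 cm²; the vendor's offline flare
analysis is not reproducible, so the operation is defined generically over
a flux matrix.

## Statistics

Pearson's chi-squared on 2×2 responder tables uses the closed-form
uncorrected statistic `N(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)]` with df = 1.
No Yates continuity correction is applied: recomputing every published
responder statistic from its own printed counts reproduces all of them
with the uncorrected formula and none with the correction. Zero-margin
tables are rejected with a pointer to Fisher's exact test. Fisher's exact
p is two-sided by the probability-mass rule; Wilcoxon matched-pairs drops
zero differences and uses the exact null for small tie-free samples;
Mann–Whitney U uses mid-ranks with the exact null when feasible. The three
exact tests are verified against brute-force enumeration of their null
distributions in the test suite. Degenerate inputs (all-zero differences,
one global tie group) short-circuit to p = 1 rather than dividing by a
zero variance.

One published value is knowingly excluded: the TRPV1-blockade contrast for
β-alanine is reported with a statistic that cannot arise from its own
counts (it duplicates a statistic reported elsewhere) and is treated as a
typographical error. A second value (28.23) appears to be truncated rather
than rounded from the exact 28.2353; the reproduction report accepts one
unit in the last printed digit.

## Synthetic cohort and problem sizes

The default cohort mirrors the study scale: 50 CM, 14 CMi and 7 VHT fibers,
each with one classification run and one chemically stimulated trace per
substance; per-class activation probabilities and CM bursting shares follow
the observed activation fractions. Matched rating cohorts use 24 subjects
per substance and mode, gamma-shaped mean time courses (peak near 90 s)
with subject-level noise snapped to the NRS grid, and responder
probabilities from the observed counts. Default problem sizes throughout
(50-fiber oracle suite, 200-run Monte Carlo classification, 30+90 burst
controls) keep the full test suite and the acceptance script in the
seconds range while leaving the Monte Carlo margins far from their
acceptance bounds. All randomness flows through a single seed; the full
pipeline writes a hash manifest and is byte-identical across reruns.

## Known limitations

* The ADS model is phenomenological; its parameters are not fitted to any
  published recovery curve.
* Marking detection under sustained discharge measures onsets, not
  presence (see above); bursting specificity under irregular tonic
  discharge is inherently imperfect.
* The AUC unit convention of the original rating analyses is not published;
  both implemented conventions are self-consistent but not verifiable
  against raw data.
* Repeated-measures ANOVA with post-hoc corrections on raw rating time
  courses is out of scope: the per-subject series needed to verify any
  implementation are not public.
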