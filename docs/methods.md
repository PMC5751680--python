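# Methods

`sealrhythm` quantifies the spontaneous vocal rhythm of a harbor seal
(*Phoca vitulina*) pup from an annotated audio recording. This note
documents the analysis model, the defaults and why they are what they
are, the synthetic-data generator used for validation, and the numerical
choices that a maintainer would otherwise have to reverse-engineer.

## The analysis model

The input is a mono WAV recording plus a Praat TextGrid with one interval
tier in which calls are labelled by category — mother-attraction calls
(`MAC`) versus anything else. Only the retained category (default `MAC`)
enters the analysis. From the ordered retained calls the pipeline derives
five series, all in milliseconds:

1. **duration** — `offset − onset` per call;
2. **IOI** (inter-onset interval) — `onset_{i+1} − onset_i`;
3. **IPI** (inter-peak interval) — `peak_{i+1} − peak_i`, where `peak_i`
   is the time of the call's maximum on an intensity contour;
4. **IOI_short** and **IPI_short** — the subsets of IOI and IPI no larger
   than a bout threshold, isolating timing *within* vocalization bouts
   from the pooled within-plus-between timing.

The bout threshold is adaptive by default: `k × min(series)` with
`k = 4`, computed independently for IOI and IPI. Seal pup calls last
about a second and cannot overlap, so the smallest interval sits near the
call-duration scale (~975 ms) and the cutoff lands near 3.9 s. A fixed
absolute cutoff (e.g. `--threshold-ms 3900`) is available because the
adaptive rule and the rounded constant differ when the realized minimum
moves. The boundary is inclusive (`v ≤ threshold`); a flag flips it to
strict, since a deposited dataset produced with the other convention
would differ by at most the boundary values.

Intervals are computed between consecutive *retained* calls even when an
excluded call lies between them. No break rule is applied: the retained
category is treated as the complete event sequence of interest.

### Intensity and peak location

Intensity frames are window-weighted mean squared amplitude in dB:
`10·log10(⟨x²⟩_w / p_ref²)` with `p_ref = 2·10⁻⁵` and full-scale
amplitude treated as 1.0, so a unit sinusoid sits at
`20·log10(0.70711/2·10⁻⁵) ≈ 90.97 dB`. The analysis window is a Kaiser
window (β = 20) of duration `3.2 / min_pitch` stepped by
`0.8 / min_pitch`; with the default `min_pitch = 100 Hz` that is a 32 ms
window every 8 ms — the Praat-style defaults for intensity analysis,
which is the natural reconstruction when no analysis settings are
reported. A Hann window is accepted as configuration; the contour is
insensitive to the choice at the 0.1 dB level for the signals involved.

A call's peak is the loudest frame whose centre lies in
`[onset, offset)`; ties break to the earliest frame (deterministic and
order-independent), silent frames take a −300 dB floor instead of −∞
(keeps arithmetic finite), and no parabolic interpolation is applied by
default (the peak is frame-quantized, so every peak time carries at most
half a frame step of quantization error; IPIs therefore match IOIs to
within one frame step when envelope shape is constant).

### Descriptive statistics and the KS test

Summaries report n, mean, sample SD (n − 1 denominator — the convention
in this literature; the choice is invisible above n ≈ 100 at the 0.1 ms
reporting precision), CV = SD/mean, min and max. With a single value, SD
and CV are reported as undefined rather than zero.

The two-sample Kolmogorov–Smirnov test is implemented from first
principles: D is the maximum of `|ECDF_a − ECDF_b|` over the pooled
sample points (right-continuous ECDFs, so ties are handled exactly), and
the p-value is the asymptotic Kolmogorov survival function
`Q(λ) = 2·Σ_{k≥1} (−1)^{k−1} e^{−2k²λ²}`, `λ = D·√(n₁n₂/(n₁+n₂))`,
clamped to [0, 1]. Below λ = 1 the equivalent Jacobi-theta form of the
CDF is used because the alternating series loses precision there. No
exact small-sample p and no continuity correction: at the sample sizes
involved (hundreds of intervals) the asymptotic form is standard, and
its type-I error at α = 0.05 calibrates to ≈ 0.03–0.05 in simulation
(slightly conservative, as expected of the asymptotic formula at n = 50).

The extraction report computes statistics and KS comparisons at the CSV
output precision (0.1 ms). This makes `extract` and a later `stats` run
on its own CSVs agree exactly, and removes false ECDF mismatches from
sub-nanosecond float noise when two series are substantively identical.

## The synthetic generator

Real validation data do not exist outside the original recording, so the
generator produces bout-structured sequences with known ground truth:
per bout, a fixed or shifted-Poisson number of calls; within a bout,
consecutive onsets differ by within-IOI draws; bouts are separated by
between-gap draws measured from the last offset. Every call carries a
true envelope-peak time at a fixed or Beta-distributed relative position.
Audio renders each call as a four-harmonic stack (f₀ = 350 Hz) under a
piecewise-linear envelope whose vertex is the true peak; harmonic phases
are drawn once per recording so identical calls render sample-identical.
Output is normalized to 0.9 full scale, 48 kHz / 24-bit by default
(16-bit and 8 kHz are used in the test suite for speed; the analysis is
rate-agnostic above ~4 kHz for these signals).

Defaults emulate the study animal's published timing:

| parameter | default | rationale |
|---|---|---|
| duration | Normal(976.1, 205.7) ms, > 100 ms | observed call-duration moments |
| within-bout IOI | Normal(1313.5, 1093.6) ms, floored at max(prev duration, 975 ms) | see below |
| between-bout gap | LogNormal(mean 8000, SD 3200) ms, ≥ 5000 ms | puts pooled-IOI CV near the observed ~0.9 while staying clear of the ~3.9 s bout cutoff |
| calls per bout | 5 | typical short bout; with 50 bouts it reproduces the two-timescale CV contrast |
| peak position | 0.3 of call duration | rising-then-falling call envelope |

The within-bout IOI needs care. Physically an IOI cannot be smaller than
the preceding call's duration, and the observed minimum interval was
~975 ms, so draws are rejected below `max(prev duration, 975 ms)`. A
Normal with the observed moments (1983.2, 722.1) truncated this way
would have a *realized* mean near 2100 ms — the generator would not
reproduce the animal it emulates. The underlying parameters are instead
solved (analytically, from the truncated-normal moment equations at the
975 ms floor) so that the realized post-truncation moments land at the
observed values. The residual approximations — the floor actually varies
with each duration draw, and the 4×min filter trims the > 3.9 s tail —
leave the realized within-bout mean at ≈ 1990–2030 ms and SD ≈ 660 ms
across seeds, within the CLT bounds the validation tests use.

What the generator does **not** emulate: seal-call spectra (formants,
fundamental contours, noisiness), amplitude variation across calls,
background noise structure (an optional flat noise floor ≥ 60 dB down is
the only provision), annotation error (onsets/offsets are exact), or
drift in bout tempo. Passing recovery tests therefore demonstrate that
the *extraction machinery* is unbiased and self-consistent on clean
bout-structured signals — not that annotation or peak detection would be
this accurate on noisy field recordings.

## Validation design

- **Closed forms**: sinusoid intensity level and gain shifts are checked
  against hand-derived values.
- **Oracles**: the KS D is checked against a brute-force pooled-ECDF
  evaluation and against scipy's independent implementation; the
  asymptotic p against the Kolmogorov distribution and by type-I
  calibration (2000 null replicates at n = 50; acceptance band
  [0.02, 0.09] absorbs the asymptotic conservatism).
- **Parameter recovery**: 50-bout fixtures over 10 seeds; pipeline
  estimates of mean duration and mean within-bout IOI must land within
  `3·SD/√n` of the generating targets; with constant envelope peak and
  duration, every IPI must equal its IOI within one 8 ms frame step.
- **Round trips**: TextGrid parse∘write identity on randomized
  millisecond-grid tiers; CSV write/read; truth JSON.

Problem sizes (8 kHz rendering, 50-bout fixtures, 2000 KS replicates)
keep the full suite under half a minute while leaving Monte-Carlo error
well below the tolerances tested.

## Known limitations

- Binary TextGrids are rejected; only the two text dialects are read.
- Multi-line interval labels (rare; Praat escapes embedded newlines) are
  not supported by the parser.
- The intensity contour is not bit-identical to Praat's (Praat's exact
  windowing differs in detail); peak *times* are robust to this, which is
  all the temporal analysis consumes.
- The KS p-value is asymptotic; for very small samples (n < ~20 per
  group) an exact method would differ noticeably.
- One annotation tier is analyzed at a time; multi-tier designs require
  separate runs.
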