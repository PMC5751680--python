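# sealrhythm

Timing and rhythm are underused dimensions of animal communication.
`sealrhythm` is a small analysis pipeline for quantifying the spontaneous
vocal rhythm of a harbor seal (*Phoca vitulina*) pup from an annotated
audio recording: it turns a WAV file plus a Praat TextGrid annotation
into call durations, inter-onset intervals, inter-peak intervals, their
within-bout subsets, descriptive statistics, and Kolmogorov–Smirnov
distribution comparisons. It is written for bioacousticians who have
annotated call onsets/offsets in Praat and want the temporal analysis —
and for anyone who needs a tested, reproducible reference implementation
of these measures.

## What it computes

For the ordered sequence of retained calls (by default those labelled
`MAC`, mother-attraction calls):

- **duration**: `offset_i − onset_i`
- **IOI** (inter-onset interval): `onset_{i+1} − onset_i`
- **IPI** (inter-peak interval): `peak_{i+1} − peak_i`, where `peak_i` is
  the time of call *i*'s maximum on a windowed-energy intensity contour
  (Kaiser window, 32 ms / 8 ms step at the default `min_pitch` 100 Hz)
- **IOI_short, IPI_short**: the intervals `≤ 4 × min(series)` — calls
  cannot overlap, so the minimum interval sits at the ~1 s call-duration
  scale and the cutoff (~3.9 s) isolates timing *within* vocalization
  bouts from the long gaps between them

Each series is summarized by n, mean, sample SD, CV = SD/mean (low CV
within bouts = regular rhythm), min and max; IOI-vs-IPI and
IOI_short-vs-IPI_short are compared with a two-sample
Kolmogorov–Smirnov test, `D = sup_x |F̂₁(x) − F̂₂(x)|`, with the
asymptotic p-value `Q(D·√(n₁n₂/(n₁+n₂)))`.

Because the original recording is not redistributable, the package
includes a synthetic generator (`sealrhythm simulate`) producing
bout-structured call sequences — WAV, TextGrid and ground-truth JSON —
whose timing distributions default to the published statistics of the
study animal, so the whole pipeline is testable end to end.

## Worked example

Generate a synthetic ten-bout recording and analyze it:

```sh
sealrhythm simulate --seed 4 --out fix
sealrhythm extract --audio fix/recording.wav \
    --textgrid fix/annotation.TextGrid --out results
```

The extract command writes `durations_all.csv`, `IOI_all.csv`,
`IPI_all.csv`, `IOI_short.csv`, `IPI_short.csv` and `report.json` into
`results/`, and prints the report:

```json
{
  "series": {
    "duration":  {"n": 50, "mean_ms": 961.2,  "sd_ms": 212.5,  "cv": 0.22, ...},
    "IOI":       {"n": 49, "mean_ms": 3264.7, "sd_ms": 2634.4, "cv": 0.81, ...},
    "IPI":       {"n": 49, "mean_ms": 3265.8, "sd_ms": 2661.5, "cv": 0.81, ...},
    "IOI_short": {"n": 40, "mean_ms": 2138.5, "sd_ms": 828.6,  "cv": 0.39, ...},
    "IPI_short": {"n": 40, "mean_ms": 2124.6, "sd_ms": 843.8,  "cv": 0.40, ...}
  },
  "ks": {
    "IOI_vs_IPI":             {"D": 0.06, "p": 1.0, "n1": 49, "n2": 49},
    "IOI_short_vs_IPI_short": {"D": 0.08, "p": 1.0, "n1": 40, "n2": 40}
  },
  "n_retained_calls": 50
}
```

Reading it: the 50 calls last ~0.96 s on average. Pooled intervals are
wildly variable (CV ≈ 0.8 — bouts separated by long gaps), while the 40
within-bout intervals are far more regular (CV ≈ 0.4, mean ≈ 2.1 s):
the two-timescale signature of bout-structured calling. Onset-based and
peak-based intervals tell the same story (KS D ≈ 0.06, p ≈ 1.0), i.e.
measuring from call onsets or from intensity peaks makes no distributional
difference.

`sealrhythm stats --csv results/IOI_all.csv ...` recomputes the report
from existing CSVs (no audio needed), and
`sealrhythm compare --a A.csv --b B.csv` runs a single KS comparison.
Everything is also available as a library:

```python
from sealrhythm import read_wav, read_textgrid, run_extraction
report = run_extraction("rec.wav", "rec.TextGrid", "out/")
```

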