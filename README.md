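# epochscore

Objective per-epoch quality scoring for resting-state M/EEG recordings,
plus the evaluation machinery to study how epoch selection affects
group-level contrasts.

The scorer cuts a continuous multichannel recording into fixed-length,
non-overlapping epochs, estimates one Welch power spectral density per
(epoch, channel), computes the Spearman rank correlation between the
spectra of every epoch pair within each channel, and averages twice —
over epochs (row means of each channel's similarity matrix), then over
channels — to give every epoch a single score in [−1, 1]. Sorting the
scores descending ranks epochs from most to least spectrally typical;
artifact-laden epochs fall to the bottom. No filtering or other
preprocessing happens inside the scorer.

The package also ships:

- **spectral features** — relative band power (default alpha, 8–13 Hz)
  per epoch/channel and channel-averaged ("global");
- **connectivity** — phase lag index (PLI) per epoch from band-passed
  analytic-signal phases;
- **evaluation** — exhaustive k-of-n epoch-selection sweeps (e.g. all
  495 ways to pick 4 of 12 epochs), paired Cohen's d and t statistics per
  selection, and percentile placement of the score-guided selection;
- **simulate** — a synthetic resting-EEG generator (1/f background,
  condition-dependent alpha, vigilance drift, injectable artifacts) with
  full ground truth, so everything above is testable offline;
- **io / cli** — a minimal EDF/EDF+ reader and EDF writer (no external
  EEG-IO dependency), delimited-table ingestion, deterministic JSON/TSV
  reports, and a `click` CLI.

## CLI

```bash
# make a synthetic 12-epoch recording with a corrupted epoch (0-based index 7)
epochscore simulate --out scratch/demo.edf --seed 3 --artifact 7:broadband_burst:120

# score its 5-second epochs in the 1–40 Hz band and write reports
epochscore score --input scratch/demo.edf --epoch-length 5 --fmin 1 --fmax 40 \
    --top-k 4 --output-dir scratch/reports

# eyes-open vs eyes-closed selection sweep over a cohort manifest
# (manifest: JSON list of {subject_id, eo_path, ec_path})
epochscore evaluate --manifest cohort.json --k 4 --feature alpha --output-dir scratch/sweep
```

Every flag can instead come from a JSON config file (`--config`); explicit
flags win on conflict. Human-facing output uses 1-based epoch indices;
programmatic structures are 0-based, and reports carry both.

## Library sketch

```python
import numpy as np
from epochscore import (
    Recording, score_epochs, segment_recording, welch_psd,
    relative_band_power, ALPHA_BAND,
)

rec = Recording(data=my_uv_array, fs=160.0)        # channels x samples
result = score_epochs(rec, epoch_length_s=5.0, freq_range=(1.0, 40.0))
result.scores          # one score per epoch, in [-1, 1]
result.ranking         # 0-based, best epoch first
result.top_k(4)        # suggested selection

psds = welch_psd(segment_recording(rec, 5.0), (1.0, 40.0))
alpha = relative_band_power(psds, ALPHA_BAND).per_epoch_global
```
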