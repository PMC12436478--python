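# echostrain

Automated left-atrial (LA) strain analysis and subclinical-AF risk
prediction from apical four-chamber echocardiography.

Atrial high-rate episodes (AHREs) — device-detected runs of atrial rate
≥ 170 bpm, also called subclinical atrial fibrillation — carry stroke risk
that scales with episode duration, and impaired LA reservoir strain is an
early marker of the underlying atrial myopathy. Measuring LA strain today
means tracing the endocardial border in semi-automated vendor software,
which is slow and operator-dependent. `echostrain` implements a fully
automated pipeline for researchers working on echo-based AF risk
stratification:

1. **Segmentation** — encoder–decoder networks (ResUNet++ with
   squeeze–excitation, ASPP bridge and attention skips; UNet variants; a
   DeepLab-like model) label each frame into background / LA cavity / LA
   wall, trained with soft Dice + cross-entropy under rotation/crop
   augmentation.
2. **Strain** — the LA endocardial border is the sub-pixel iso-contour of
   the cavity mask; with contour length `L_t` and base length `L_0` at the
   ECG R peak (LV end-diastole), the reservoir strain is

   `strain_t = (L_t − L_0) / L_0`,

   resampled to 30 equidistant frames; peak strain is the maximum.
3. **Classification** — a transformer encoder attends over the 30 strain
   samples plus a summary token built from ten clinical features (age, sex,
   BMI, BSA, CHA2DS2-VASc, MI, CAD, thyroid disease, DM, HTN) and predicts
   whether the longest AHRE reaches 6 minutes or 24 hours, trained with
   imbalance-weighted BCE.

Because clinical cine loops are private, the package ships first-class
synthetic generators: echo-like **phantoms** whose LA contour scales by a
known factor per frame (so true strain is analytic and the whole
mask→strain path is checkable to 0.01), degenerate fixtures for the five
image-quality exclusion criteria automated by the QC module, and a
**cohort simulator** calibrated to the published baseline table of a
117-patient CIED cohort (AHRE groups 64/40/13; LA peak strain
31.1 ± 11.0%, 27.2 ± 8.3%, 19.9 ± 9.0%). The neural networks run on a
small numpy autodiff engine included in the package, so everything trains
on a single CPU.

## Worked example

Generate a phantom with a known 25% peak strain, extract strain from its
ground-truth masks, and check agreement over a sweep of deformations:

```python
import numpy as np
from echostrain import PhantomParams, make_phantom, sequence_to_strain, bland_altman

params = PhantomParams(s_max=1.25, frames=40)          # true peak strain 0.25
seq, masks, truth = make_phantom(params, seed=7)
curve = sequence_to_strain(masks, r_peak_index=seq.r_peak_index)
print(f"frames: {seq.frame_count}, resampled curve length: {len(curve.values)}")
print(f"true peak strain : {truth.true_strain.max():.4f}")
print(f"extracted peak   : {curve.peak:.4f}")

peaks, truths = [], []
for i in range(20):
    s_max = 1.05 + 0.3 * i / 19
    sq, mk, tr = make_phantom(PhantomParams(s_max=s_max, frames=40), seed=i)
    peaks.append(sequence_to_strain(mk, r_peak_index=sq.r_peak_index).peak)
    truths.append(s_max - 1.0)
rep = bland_altman(peaks, truths)
print(f"Bland-Altman bias: {rep.bias:+.4f}, LOA [{rep.loa_low:+.4f}, {rep.loa_high:+.4f}]")
```

Output:

```
frames: 40, resampled curve length: 30
true peak strain : 0.2500
extracted peak   : 0.2539
Bland-Altman bias: +0.0033, LOA [+0.0004, +0.0062]
```

The extracted peak differs from the analytic truth only by rasterisation
(here 0.004 strain units), and across deformations the mean bias stays
within ±0.005 — the level at which the contour-length surrogate can be
trusted before any segmentation error enters.

The full pipeline (phantom simulation → QC → segmentation training →
inference → strain → cohort simulation → classifier evaluation) runs as

```bash
echostrain run --out demo_run --seed 7
```

writing masks, a strain table, checkpoints, an evaluation report and a
reproducibility manifest into `demo_run/`. Individual stages are exposed
as `echostrain simulate|train-seg|segment|qc|strain|train-clf|classify|evaluate`.

## Layout

- `src/echostrain/phantom.py` — synthetic echo sequences + QC fixtures
- `src/echostrain/qc.py` — automated exclusion criteria (a)–(e)
- `src/echostrain/segmentation.py` — the four segmenters, loss, augmentation
- `src/echostrain/strain.py` — contours, lengths, strain, resampling
- `src/echostrain/cohort.py` — baseline-table-calibrated patient simulator
- `src/echostrain/classifier.py` — transformer AHRE classifier
- `src/echostrain/metrics.py` — Dice, Bland-Altman, ROC/Youden, CV, t-test
- `src/echostrain/workflow.py` — splits, pipeline, manifests
- `src/echostrain/nn.py` — numpy reverse-mode autodiff + layers
- `docs/methods.md` — modelling assumptions, defaults and limitations
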