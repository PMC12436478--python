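"""Shared fixtures: expensive training experiments are session-scoped so the
segmentation run, the classifier cross-validation and the demo pipeline are
executed once and reused by the unit and acceptance tests."""

from dataclasses import replace

import numpy as np
import pytest

from echostrain import classifier as clf
from echostrain import cohort as coh
from echostrain import metrics as met
from echostrain import phantom as ph
from echostrain import segmentation as seg
from echostrain.workflow import RunConfig, run_pipeline

# scaled-down study conditions used across tests
SEG_IMAGE_SIZE = 64
SEG_TRAIN_FRAMES = 200
SEG_VAL_FRAMES = 50
SEG_EPOCHS = 20
CLF_N = 600
CLF_CONFIG = clf.ClfConfig(width=32, ff_width=64, epochs=25, batch_size=64,
                           dropout=0.2, seed=0)


def phantom_frames(n_frames: int, size: int, seed0: int):
    """(frame, mask) pairs drawn from consecutive-seed phantom sequences."""
    pairs = []
    s = seed0
    while len(pairs) < n_frames:
        sq, mk, _ = ph.make_phantom(
            ph.PhantomParams(size=size, frames=40), seed=s)
        pairs += list(zip(sq.frames, mk.masks))
        s += 1
    return pairs[:n_frames]


def strong_effect_cohort(n: int = CLF_N, seed: int = 1):
    """Cohort with the default per-group strain means but SDs halved."""
    spec = coh.DEFAULT_SPEC
    groups = tuple(
        replace(g, peak_strain_pct=(g.peak_strain_pct[0],
                                    g.peak_strain_pct[1] / 2.0))
        for g in spec.groups)
    strong = coh.CohortSpec(group_probs=spec.group_probs, groups=groups)
    return coh.simulate_cohort(n, strong, seed=seed)


@pytest.fixture(scope="session")
def seg_experiment():
    """Train a ResUNet++-style segmenter on 200 phantom frames (64 px,
    20 epochs) and evaluate Dice on 50 held-out frames."""
    train = phantom_frames(SEG_TRAIN_FRAMES, SEG_IMAGE_SIZE, seed0=0)
    val = phantom_frames(SEG_VAL_FRAMES, SEG_IMAGE_SIZE, seed0=50)
    cfg = seg.SegConfig(arch="resunetpp", input_size=SEG_IMAGE_SIZE,
                        epochs=SEG_EPOCHS, batch_size=8, seed=0)
    model = seg.train_segmenter(train, config=cfg)
    pred = seg.segment(model, ph.EchoSequence(frames=[v[0] for v in val]))
    dsc_cavity = [met.dice(p, v[1], 1) for p, v in zip(pred.masks, val)]
    dsc_wall = [met.dice(p, v[1], 2) for p, v in zip(pred.masks, val)]
    return {"model": model, "val": val,
            "dsc_cavity": np.array(dsc_cavity),
            "dsc_wall": np.array(dsc_wall)}


@pytest.fixture(scope="session")
def clf_recovery():
    """Fivefold CV of the transformer on a strong-strain-effect cohort at the
    24-h endpoint, plus a label-permuted null control."""
    records = strong_effect_cohort()
    S, F, y = clf.inputs_from_records(records, "24h")
    real = met.evaluate_classifier(S, F, y, CLF_CONFIG, protocol="cv5", seed=0)
    y_perm = np.random.default_rng(0).permutation(y)
    null = met.evaluate_classifier(S, F, y_perm, CLF_CONFIG, protocol="cv5",
                                   seed=0)
    return {"records": records, "real": real, "null": null,
            "inputs": (S, F, y)}


@pytest.fixture(scope="session")
def small_clf_model():
    """A quickly trained classifier for prediction-behaviour tests."""
    records = strong_effect_cohort(n=300, seed=2)
    S, F, y = clf.inputs_from_records(records, "24h")
    cfg = clf.ClfConfig(width=16, ff_width=32, heads=2, epochs=15,
                        batch_size=64, seed=0)
    model = clf.train_classifier(S, F, y, cfg)
    return {"model": model, "inputs": (S, F, y)}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One demo end-to-end pipeline run with its timing."""
    import time

    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(out_dir=str(out), seed=7)
    t0 = time.time()
    results = run_pipeline(cfg)
    elapsed = time.time() - t0
    return {"config": cfg, "results": results, "out_dir": str(out),
            "elapsed": elapsed}
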