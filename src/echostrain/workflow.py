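"""End-to-end orchestration: dataset splitting, stage sequencing, artifacts.

``run_pipeline`` executes the whole framework on synthetic data — phantom
simulation, QC filtering, segmentation training, inference, strain
extraction with agreement analysis against the analytic truth, cohort
simulation and AHRE classifier evaluation — writing every artifact plus a
reproducibility manifest (config hash, seeds) into an output directory.
Stages are resumable: with ``resume=True`` a stage whose artifact already
exists is skipped.

Splitting is patient-level and stratified: 80% development (itself split
80/20 into training and validation) and 20% test, so images from one
patient never cross splits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import cohort as coh
from . import metrics as met
from . import phantom as ph
from . import qc as qcmod
from . import segmentation as seg
from . import strain as st

__all__ = ["SplitSpec", "RunConfig", "split_patients", "run_pipeline",
           "derive_seed"]

log = logging.getLogger("echostrain")


@dataclass
class SplitSpec:
    """Patient-level stratified split: dev 80% (train 80 / val 20) + test 20%."""

    dev_fraction: float = 0.8
    train_within_dev: float = 0.8
    seed: int = 0


@dataclass
class RunConfig:
    """Flat, YAML-round-trippable settings for every pipeline stage."""

    out_dir: str = "run"
    seed: int = 0
    # phantom stage
    n_sequences: int = 12
    image_size: int = 64
    frames_per_sequence: int = 30
    s_max_range: tuple[float, float] = (1.10, 1.35)
    # segmentation stage
    seg_arch: str = "resunetpp"
    seg_epochs: int = 5
    seg_batch_size: int = 8
    seg_base_channels: int = 8
    # cohort + classifier stage
    cohort_n: int = 300
    clf_threshold: str = "24h"
    clf_epochs: int = 30
    clf_width: int = 32
    clf_ff_width: int = 64
    clf_batch_size: int = 64
    clf_protocol: str = "holdout"
    log_level: str = "INFO"

    def to_yaml(self, path: str):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["s_max_range"] = tuple(raw["s_max_range"])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31 - 1)


def split_patients(patient_ids, labels=None, spec: SplitSpec | None = None,
                   ) -> dict[str, list]:
    """Stratified patient-level split into train / val / test id lists."""
    spec = spec or SplitSpec()
    patient_ids = list(patient_ids)
    n = len(patient_ids)
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) > 1 and counts.min() < 5:
        raise ValueError("need at least 5 patients per class to stratify")
    if n < 5:
        raise ValueError("too few patients to split")
    rng = np.random.default_rng(spec.seed)
    train_ids, val_ids, test_ids = [], [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_c = len(idx)
        n_dev = int(round(spec.dev_fraction * n_c))
        n_train = int(round(spec.train_within_dev * n_dev))
        train_ids += [patient_ids[i] for i in idx[:n_train]]
        val_ids += [patient_ids[i] for i in idx[n_train:n_dev]]
        test_ids += [patient_ids[i] for i in idx[n_dev:]]
    return {"train": train_ids, "val": val_ids, "test": test_ids}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(config: RunConfig, name: str, artifact: str, fn, resume: bool):
    """Run one stage with timing and stage-named error context."""
    path = os.path.join(config.out_dir, artifact)
    if resume and os.path.exists(path):
        log.info("stage %s: artifact %s exists, skipping", name, artifact)
        return None
    t0 = time.time()
    log.info("stage %s: start", name)
    try:
        result = fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    log.info("stage %s: done in %.1fs", name, time.time() - t0)
    return result


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute simulate → qc → train-seg → segment → strain → train-clf →
    evaluate, writing artifacts and a manifest into ``config.out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    results: dict = {"config_digest": config.digest(), "seed": config.seed}

    # --- simulate phantoms -------------------------------------------------
    phantom_seed = derive_seed(config.seed, "phantom")
    rng = np.random.default_rng(phantom_seed)
    sequences = []
    for i in range(config.n_sequences):
        s_max = float(rng.uniform(*config.s_max_range))
        params = ph.PhantomParams(size=config.image_size,
                                  frames=config.frames_per_sequence,
                                  s_max=s_max)
        sequences.append(ph.make_phantom(params, seed=int(rng.integers(2 ** 31))))
    splits = split_patients([s[0].id for s in sequences],
                            spec=SplitSpec(seed=derive_seed(config.seed, "split")))
    by_id = {s[0].id: s for s in sequences}
    results["splits"] = {k: list(v) for k, v in splits.items()}

    # --- qc on development frames -----------------------------------------
    dev_pairs, dev_ids = [], []
    for pid in splits["train"] + splits["val"]:
        sq, mk, _ = by_id[pid]
        for j, (f, m) in enumerate(zip(sq.frames, mk.masks)):
            dev_pairs.append((f, m))
            dev_ids.append(f"{pid}/frame_{j:03d}")
    clean, reports = qcmod.apply_exclusions(dev_pairs, ids=dev_ids)
    qcmod.reports_to_frame(reports).to_csv(
        os.path.join(config.out_dir, "qc_report.csv"), index=False)
    results["qc"] = {"n_images": len(dev_pairs), "n_clean": len(clean)}

    # --- train segmenter ---------------------------------------------------
    seg_cfg = seg.SegConfig(arch=config.seg_arch, input_size=config.image_size,
                            epochs=config.seg_epochs,
                            batch_size=config.seg_batch_size,
                            base_channels=config.seg_base_channels,
                            seed=derive_seed(config.seed, "seg"))
    ckpt_path = os.path.join(config.out_dir, "seg_model.ckpt.npz")
    if resume and os.path.exists(ckpt_path):
        model = seg.load_checkpoint(ckpt_path)
    else:
        model = _stage(config, "train-seg", "seg_model.ckpt.npz",
                       lambda: seg.train_segmenter(clean, config=seg_cfg),
                       resume=False)
        seg.save_checkpoint(model, ckpt_path)
    results["seg"] = {"final_loss": model.loss_log[-1] if model.loss_log else None}

    # --- segment test sequences & extract strain ---------------------------
    rows = []
    extracted, truth_peaks = [], []
    for pid in splits["test"]:
        sq, mk_true, truth = by_id[pid]
        mk_pred = seg.segment(model, sq)
        curve = st.sequence_to_strain(mk_pred, r_peak_index=sq.r_peak_index)
        extracted.append(curve.peak)
        truth_peaks.append(float(truth.true_strain.max()))
        row = {"id": pid, "base_index": curve.base_index,
               "peak_strain": curve.peak,
               "true_peak_strain": truth_peaks[-1]}
        row.update({f"strain_t{i:02d}": v for i, v in enumerate(curve.values)})
        rows.append(row)
    strain_df = pd.DataFrame(rows)
    strain_df.to_csv(os.path.join(config.out_dir, "strain.csv"), index=False)
    agreement = met.bland_altman(extracted, truth_peaks)
    results["strain"] = {"bias": agreement.bias, "loa_low": agreement.loa_low,
                         "loa_high": agreement.loa_high, "n": agreement.n}

    # --- cohort + classifier ----------------------------------------------
    records = coh.simulate_cohort(config.cohort_n,
                                  seed=derive_seed(config.seed, "cohort"))
    coh.write_cohort_csv(records, os.path.join(config.out_dir, "cohort.csv"))
    S, F, y = clf.inputs_from_records(records, config.clf_threshold)
    clf_cfg = clf.ClfConfig(threshold=config.clf_threshold,
                            width=config.clf_width,
                            ff_width=config.clf_ff_width,
                            epochs=config.clf_epochs,
                            batch_size=config.clf_batch_size,
                            seed=derive_seed(config.seed, "clf"))
    evaluation = met.evaluate_classifier(S, F, y, clf_cfg,
                                         protocol=config.clf_protocol,
                                         seed=derive_seed(config.seed, "eval"))
    results["classification"] = {
        "protocol": evaluation["protocol"],
        "summary": {k: list(v) for k, v in evaluation["summary"].items()},
    }

    with open(os.path.join(config.out_dir, "evaluation.json"), "w") as fh:
        json.dump(results, fh, indent=2, default=str)
    manifest = {"config": asdict(config), "config_digest": config.digest(),
                "stage_seeds": {s: derive_seed(config.seed, s) for s in
                                ("phantom", "split", "seg", "cohort", "clf",
                                 "eval")}}
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
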