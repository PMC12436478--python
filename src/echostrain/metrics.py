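"""Evaluation statistics: Dice overlap, Bland-Altman agreement, ROC/AUC with
the Youden operating point, stratified k-fold cross-validation and the
independent t-test used for model comparison."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "AgreementReport",
    "RocReport",
    "dice",
    "bland_altman",
    "roc_auc",
    "youden_operating_point",
    "stratified_kfold",
    "independent_t_test",
    "roc_report",
    "summarize_reports",
]


@dataclass
class AgreementReport:
    """Bland-Altman bias and 95% limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class RocReport:
    """AUC plus the operating point chosen by Youden's J."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    curve: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {"auc": self.auc, "threshold": self.threshold,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "accuracy": self.accuracy}


def dice(pred_mask: np.ndarray, true_mask: np.ndarray,
         class_label: int | None = None) -> float:
    """Dice similarity coefficient 2|P∩T| / (|P|+|T|); 1.0 when both empty."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    if class_label is not None:
        p = p == class_label
        t = t == class_label
    else:
        p = p.astype(bool)
        t = t.astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def bland_altman(x, y) -> AgreementReport:
    """Agreement between extracted (x) and reference (y) values:
    bias = mean(x - y), LOA = bias ± 1.96 · sd(x - y) (sample sd)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd, n=d.size)


def roc_auc(scores, labels) -> float:
    """AUC; identical to the Mann-Whitney U probability with ties counted ½."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_operating_point(scores, labels) -> RocReport:
    """Operating point maximising J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores (plus one below the minimum and one above the maximum); a score is
    called positive when it is >= the threshold.  Ties in J resolve to the
    lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                            [uniq[-1] + 1.0]])
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for th in cands:
        pred = scores >= th
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, th, sens, spec)
    j, th, sens, spec = best
    pred = scores >= th
    acc = float((pred == (labels == 1)).mean())
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocReport(auc=roc_auc(scores, labels), threshold=float(th),
                     sensitivity=float(sens), specificity=float(spec),
                     accuracy=acc, curve=(fpr, tpr))


def roc_report(scores, labels) -> RocReport:
    """AUC, accuracy and the Youden-point sensitivity/specificity."""
    return youden_operating_point(scores, labels)


def stratified_kfold(labels, k: int = 5, seed: int = 0,
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold partitions as (train_idx, test_idx) pairs."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def independent_t_test(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default) on per-image scores."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def evaluate_classifier(strain, features, labels, config=None,
                        protocol: str = "cv5", seed: int = 0,
                        ) -> dict:
    """Train-and-evaluate the AHRE classifier under a protocol.

    ``holdout``: stratified 80/20 split, one report.  ``cv5``: stratified
    fivefold cross-validation, per-fold reports plus mean ± sd of each
    metric.  Returns {"protocol", "reports", "summary"}.
    """
    from .classifier import ClfConfig, predict_proba, train_classifier

    strain = np.asarray(strain, dtype=float)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    config = config or ClfConfig()
    if protocol == "holdout":
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(labels))
        tr, te = train_test_split(idx, test_size=0.2, stratify=labels,
                                  random_state=seed)
        splits = [(tr, te)]
    elif protocol == "cv5":
        splits = stratified_kfold(labels, k=5, seed=seed)
    else:
        raise ValueError("protocol must be 'holdout' or 'cv5'")

    reports = []
    for fold, (tr, te) in enumerate(splits):
        cfg = replace(config, seed=config.seed + fold)
        model = train_classifier(strain[tr], features[tr], labels[tr], cfg)
        scores = predict_proba(model, strain[te], features[te])
        reports.append(roc_report(scores, labels[te]))
    return {"protocol": protocol, "reports": reports,
            "summary": summarize_reports(reports)}


def summarize_reports(reports: list[RocReport]) -> dict:
    """Mean ± SD of each metric across cross-validation folds."""
    out = {}
    for key in ("auc", "accuracy", "sensitivity", "specificity"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        out[key] = (float(vals.mean()),
                    float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out
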