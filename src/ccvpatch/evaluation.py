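"""Metrics, PR/ROC curves and experiment orchestration.

The positive class is *abnormal* throughout, so sensitivity is the
proportion of abnormal (malignant) patches recovered and specificity the
proportion of normal patches recovered:

    ACC = (TP+TN)/(TP+FN+TN+FP)   SEN = R = TP/(TP+FN)
    SPE = TN/(TN+FP)              P = TP/(TP+FP)      F1 = 2PR/(P+R)

``run_experiment`` executes the full pipeline — generate/load patches,
bilateral filtering, feature extraction, sparse-contribution selection,
classifier training, CCV fitting and posterior adjustment — and reports
metrics and curves for every classifier with and without CCV.
"""

from __future__ import annotations

import contextlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from . import ccv as ccv_mod, sc_selection
from .base_classifiers import ABNORMAL, NORMAL, make_classifier, predict_initial
from .feature_bank import FeatureConfig, extract_all
from .preprocess import bilateral_filter, trace_contour
from .synth_patches import (
    ABNORMAL_SHAPE,
    ABNORMAL_TEXTURE,
    NORMAL_SHAPE,
    NORMAL_TEXTURE,
    PatchRecord,
    generate_dataset,
    load_dataset,
)

logger = logging.getLogger("ccvpatch")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextlib.contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-table counts with abnormal as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_labels(true: Sequence[str], pred: Sequence[str]) -> ConfusionCounts:
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise ValueError("label arrays differ in length")
    return ConfusionCounts(
        tp=int(np.sum((true == ABNORMAL) & (pred == ABNORMAL))),
        tn=int(np.sum((true == NORMAL) & (pred == NORMAL))),
        fp=int(np.sum((true == NORMAL) & (pred == ABNORMAL))),
        fn=int(np.sum((true == ABNORMAL) & (pred == NORMAL))),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Classification metrics; a metric with a zero denominator is None."""

    acc: float
    sen: float | None
    spe: float | None
    precision: float | None
    recall: float | None
    f1: float | None


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sen = ratio(counts.tp, counts.tp + counts.fn)
    spe = ratio(counts.tn, counts.tn + counts.fp)
    p = ratio(counts.tp, counts.tp + counts.fp)
    r = sen
    f1 = None
    if p is not None and r is not None and (p + r) > 0:
        f1 = 2 * p * r / (p + r)
    return MetricsReport(acc=(counts.tp + counts.tn) / counts.total,
                         sen=sen, spe=spe, precision=p, recall=r, f1=f1)


# ---------------------------------------------------------------------------
# curves

@dataclass(frozen=True)
class CurveData:
    """One threshold-swept curve: ROC (x=FPR, y=TPR) or PR (x=R, y=P)."""

    kind: str
    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray
    auc: float

    def to_csv(self, path: str | Path) -> None:
        xlab, ylab = (("fpr", "tpr") if self.kind == "roc" else ("recall", "precision"))
        n = len(self.x)
        thr = self.thresholds
        if len(thr) < n:  # sklearn omits the endpoint thresholds
            thr = np.concatenate([thr, [np.nan] * (n - len(thr))])
        pd.DataFrame({xlab: self.x, ylab: self.y, "threshold": thr[:n]}).to_csv(
            path, index=False)


def curves(scores: Sequence[float], labels: Sequence[str]) -> dict[str, CurveData]:
    """ROC and PR curves of abnormal-class scores, with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == ABNORMAL).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present for curves")
    fpr, tpr, roc_thr = roc_curve(y, scores)
    roc_auc = float(np.trapezoid(tpr, fpr))
    prec, rec, pr_thr = precision_recall_curve(y, scores)
    # precision_recall_curve returns recall in decreasing order
    order = np.argsort(rec)
    pr_auc = float(np.trapezoid(prec[order], rec[order]))
    return {
        "roc": CurveData(kind="roc", thresholds=roc_thr, x=fpr, y=tpr, auc=roc_auc),
        "pr": CurveData(kind="pr", thresholds=pr_thr, x=rec[::-1], y=prec[::-1],
                        auc=pr_auc),
    }


# ---------------------------------------------------------------------------
# experiment configuration and orchestration

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "dataset": {
        "kind": "synthetic",
        "n_train_per_class": 200,
        "n_test_per_class": 100,
        # for kind=directory:
        # "path": "...", "train_fraction": 0.7
    },
    "classifiers": ["elm", "svm", "rf"],
    "preprocess": {"sigma_spatial": 3.0, "sigma_range": 25.0},
    "selection": {"rho_max": 0.95, "delta1": None, "delta2": 0.05},
    "classifier_params": {"elm": {"L": 100}, "svm": {}, "rf": {}},
    "ccv": {"interval": 2},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _split_records(records: list[PatchRecord], train_fraction: float,
                   seed: int) -> tuple[list[PatchRecord], list[PatchRecord]]:
    """Stratified shuffle split of loaded records."""
    rng = np.random.default_rng(seed)
    train: list[PatchRecord] = []
    test: list[PatchRecord] = []
    for label in (NORMAL, ABNORMAL):
        group = [r for r in records if r.label == label]
        idx = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        train += [group[i] for i in idx[:n_train]]
        test += [group[i] for i in idx[n_train:]]
    return train, test


def _load_patches(cfg: dict, seed: int) -> tuple[list[PatchRecord], list[PatchRecord]]:
    ds = cfg["dataset"]
    if ds["kind"] == "synthetic":
        n_train = int(ds["n_train_per_class"])
        n_test = int(ds["n_test_per_class"])
        # one balanced pool per class, first n_train patches train, rest test
        pool = generate_dataset(n_train + n_test,
                                normal=(NORMAL_SHAPE, NORMAL_TEXTURE),
                                abnormal=(ABNORMAL_SHAPE, ABNORMAL_TEXTURE),
                                seed=seed)
        by_label = {NORMAL: [], ABNORMAL: []}
        for rec in pool:
            by_label[rec.label].append(rec)
        train = by_label[NORMAL][:n_train] + by_label[ABNORMAL][:n_train]
        test = by_label[NORMAL][n_train:] + by_label[ABNORMAL][n_train:]
        return train, test
    if ds["kind"] == "directory":
        records = load_dataset(ds["path"])
        return _split_records(records, float(ds.get("train_fraction", 0.7)), seed)
    raise ValueError(f"unknown dataset kind {ds['kind']!r}")


def _filtered(records: list[PatchRecord], pp: dict) -> list[PatchRecord]:
    out = []
    for rec in records:
        gray = bilateral_filter(rec.gray, sigma_spatial=pp["sigma_spatial"],
                                sigma_range=pp["sigma_range"])
        out.append(PatchRecord(gray=np.clip(np.rint(gray), 0, 255).astype(np.uint8),
                               mask=rec.mask, label=rec.label, id=rec.id))
    return out


def _metrics_dict(true: Sequence[str], pred: Sequence[str],
                  scores: Sequence[float]) -> tuple[dict, dict[str, CurveData]]:
    counts = confusion_from_labels(true, pred)
    rep = compute_metrics(counts)
    cv = curves(scores, true)
    return {
        "counts": asdict(counts),
        "metrics": asdict(rep),
        "auc_roc": cv["roc"].auc,
        "auc_pr": cv["pr"].auc,
    }, cv


def run_experiment(config: dict | None = None,
                   output_dir: str | Path | None = None) -> dict:
    """Run the full pipeline for every configured classifier, with and
    without CCV adjustment.  Returns (and optionally writes) the report."""
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])

    with _stage("dataset"):
        train, test = _load_patches(cfg, seed)
        y_train = [r.label for r in train]
        y_test = [r.label for r in test]

    with _stage("preprocess"):
        train_f = _filtered(train, cfg["preprocess"])
        test_f = _filtered(test, cfg["preprocess"])

    with _stage("features"):
        fconfig = FeatureConfig(**cfg.get("features", {}))
        fs_train = extract_all(train_f, fconfig)
        fs_test = extract_all(test_f, fconfig)

    with _stage("selection"):
        sel = cfg["selection"]
        model = sc_selection.fit(fs_train, y_train, rho_max=sel["rho_max"],
                                 delta1=sel["delta1"], delta2=sel["delta2"])
        X_train = sc_selection.transform(model, fs_train).values.T
        X_test = sc_selection.transform(model, fs_test).values.T

    with _stage("ccv_fit"):
        interval = int(cfg["ccv"]["interval"])
        ccv_train = [ccv_mod.ccv_of_contour(trace_contour(r.mask), interval)
                     for r in train]
        ccv_test = [ccv_mod.ccv_of_contour(trace_contour(r.mask), interval)
                    for r in test]
        ccv_model = ccv_mod.fit_ccv_model(ccv_train, y_train)

    report: dict = {
        "config": cfg,
        "n_train": len(train),
        "n_test": len(test),
        "selection": {
            "n_features_total": fs_train.m,
            "n_features_kept": len(model.kept_indices),
            "delta1": model.delta1,
            "delta2": model.delta2,
            "rho_max": model.rho_max,
        },
        "ccv_model": {"m1": ccv_model.m1, "m2": ccv_model.m2,
                      "valid": ccv_model.valid},
        "classifiers": {},
    }
    per_sample_rows = []
    all_curves: dict[tuple[str, str], dict[str, CurveData]] = {}
    ids_test = [r.id for r in test]

    for name in cfg["classifiers"]:
        with _stage(f"train_{name}"):
            clf = make_classifier(name, cfg["classifier_params"].get(name), seed=seed)
            clf.fit(X_train, y_train)
        with _stage(f"evaluate_{name}"):
            preds = predict_initial(clf, X_test, ids_test)
            base_scores = clf.predict_proba(X_test)[:, 1]  # abnormal column
            base_labels = [p.initial_label for p in preds]
            adjusted = ccv_mod.adjust_predictions(preds, ccv_test, ccv_model)
            adj_labels = [a.final_label for a in adjusted]
            adj_scores = [ccv_mod.adjusted_abnormal_score(a) for a in adjusted]
            base_entry, base_curves = _metrics_dict(y_test, base_labels, base_scores)
            ccv_entry, ccv_curves = _metrics_dict(y_test, adj_labels, adj_scores)
            report["classifiers"][name] = {"base": base_entry, "ccv": ccv_entry}
            all_curves[(name, "base")] = base_curves
            all_curves[(name, "ccv")] = ccv_curves
            for a, true in zip(adjusted, y_test):
                per_sample_rows.append({
                    "classifier": name, "id": a.sample_id, "true_label": true,
                    "ccv": a.ccv_value, "initial_label": a.initial_label,
                    "p_initial": a.p_initial, "omega": a.omega,
                    "p_final": a.p_final, "final_label": a.final_label,
                    "p_final_of_final_label": a.p_final_of_final_label,
                })

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        (output_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(per_sample_rows).to_csv(output_dir / "per_sample.csv",
                                             index=False)
        for (name, variant), cv in all_curves.items():
            for kind, curve in cv.items():
                curve.to_csv(output_dir / f"curve_{kind}_{name}_{variant}.csv")
    report["per_sample"] = per_sample_rows
    return report
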