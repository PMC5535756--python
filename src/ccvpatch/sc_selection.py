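"""Sparse-contribution (SC) feature selection.

A filter method for two-class (normal vs abnormal) feature matrices with
features in rows.  The fitted pipeline is:

1. min–max normalize each feature row to [0, 1]; drop constant rows; drop
   rows that are redundant with an earlier kept row (|Pearson ρ| ≥ ρ_max,
   greedy keep-first scan);
2. contrast-map each surviving row to [−1, 1] via x* = (x − μ)/(σ + ε),
   where μ, σ are the row mean and standard deviation and ε ≥ 0 is the
   smallest value that bounds |x*| by 1; score each row by its unit-circle
   contribution C(x): a sample at mapped value x contributes
   ±(1 − √(1 − x²)) — positive when it lies toward its own class mean —
   and C(x) is the sum over all samples.  Rows whose class means share a
   sign are removed; rows with C(x) < δ1 are removed;
3. entries of the selected, mapped matrix with |x| ≤ δ2 are set to zero,
   yielding a sparse final matrix.

The fitted state (kept rows, per-row min/max and (μ, σ, ε), class-mean
signs, contributions, thresholds) is reused verbatim at transform time;
out-of-range test values are clamped to [−1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .feature_bank import FeatureMatrix

NORMAL, ABNORMAL = "normal", "abnormal"


class SelectionError(ValueError):
    """No feature survives the selection thresholds."""


@dataclass
class SelectionModel:
    """Fitted state of the SC selection pipeline (indices refer to rows of
    the full fit-time feature matrix)."""

    kept_indices: list[int]
    feature_names: list[str]  # all fit-time feature names, for validation
    row_minmax: list[tuple[float, float]]  # per kept row, from step 1
    contrast_params: list[tuple[float, float, float]]  # (mu, sigma, eps) per kept row
    orientation: list[float]  # sign of the normal-class mean, per kept row
    contributions: list[float]  # C(x) per kept row
    delta1: float
    delta2: float
    rho_max: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kept_indices": self.kept_indices,
            "feature_names": self.feature_names,
            "row_minmax": self.row_minmax,
            "contrast_params": self.contrast_params,
            "orientation": self.orientation,
            "contributions": self.contributions,
            "delta1": self.delta1,
            "delta2": self.delta2,
            "rho_max": self.rho_max,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionModel":
        d = json.loads(Path(path).read_text())
        d["row_minmax"] = [tuple(t) for t in d["row_minmax"]]
        d["contrast_params"] = [tuple(t) for t in d["contrast_params"]]
        return cls(**d)


def normalize01(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min–max normalize each row to [0, 1].

    Returns (normalized, (min, max) per row, constant-row flags); constant
    rows map to all zeros and are flagged for removal.
    """
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    constant = hi == lo
    span = np.where(constant, 1.0, hi - lo)
    normed = (values - lo[:, None]) / span[:, None]
    normed[constant] = 0.0
    return normed, np.column_stack([lo, hi]), constant


def remove_redundant(values: np.ndarray, rho_max: float) -> list[int]:
    """Greedy redundancy pruning by Pearson correlation.

    Scanning rows in order, a row is dropped when |ρ| with any earlier kept
    row reaches ``rho_max``; the earlier row is retained.  Returns kept row
    indices (into ``values``).
    """
    if not 0 < rho_max <= 1:
        raise ValueError("rho_max must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if m == 0:
        return []
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    kept: list[int] = []
    for i in range(m):
        if all(abs(corr[i, j]) < rho_max for j in kept):
            kept.append(i)
    return kept


def contrast_map(row: np.ndarray) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Map one row to [−1, 1] via x* = (x − μ)/(σ + ε).

    ε is the smallest nonnegative value guaranteeing |x*| ≤ 1, i.e.
    ε = max(0, max|x − μ| − σ).  A constant row maps to zeros.
    """
    row = np.asarray(row, dtype=float)
    mu = float(row.mean())
    sigma = float(row.std())
    eps = max(0.0, float(np.max(np.abs(row - mu))) - sigma)
    denom = sigma + eps
    if denom == 0.0:  # constant row: numerator is identically zero
        denom = 1e-12
    return (row - mu) / denom, (mu, sigma, eps)


def contribution(mapped: np.ndarray, labels: Sequence[str]) -> float | None:
    """Unit-circle contribution score C(x) of one mapped feature row.

    Requires |x| ≤ 1.  With s the sign of the normal-class mean and
    y = √(1 − x²), a normal sample contributes s·sign(x)·(1 − y) and an
    abnormal sample −s·sign(x)·(1 − y); C(x) sums over all samples.
    Returns ``None`` (feature removed) when the class means do not lie on
    opposite sides of zero.
    """
    x = np.asarray(mapped, dtype=float)
    labels = np.asarray(labels)
    is_normal = labels == NORMAL
    is_abnormal = labels == ABNORMAL
    if not is_normal.any() or not is_abnormal.any():
        raise ValueError("both classes must be present")
    mean_n = x[is_normal].mean()
    mean_a = x[is_abnormal].mean()
    if mean_n * mean_a >= 0:
        return None
    s = np.sign(mean_n)
    y = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    per_sample = np.sign(x) * (1.0 - y)
    c = s * per_sample[is_normal].sum() - s * per_sample[is_abnormal].sum()
    return float(c)


def fit(
    fs: FeatureMatrix,
    labels: Sequence[str],
    rho_max: float = 0.95,
    delta1: float | None = None,
    delta2: float = 0.05,
) -> SelectionModel:
    """Fit the SC selection model on a training feature matrix.

    ``delta1=None`` uses the 60th percentile of the surviving contribution
    values; pass an explicit threshold to override.
    """
    labels = np.asarray(labels)
    if len(labels) != fs.n:
        raise ValueError("labels length must match sample count")

    normed, minmax, constant = normalize01(fs.values)
    nonconstant = np.flatnonzero(~constant)
    kept_local = remove_redundant(normed[nonconstant], rho_max)
    step1_indices = [int(nonconstant[i]) for i in kept_local]

    survivors: list[tuple[int, np.ndarray, tuple[float, float, float], float, float]] = []
    for idx in step1_indices:
        mapped, params = contrast_map(normed[idx])
        c = contribution(mapped, labels)
        if c is None:
            continue
        sign_n = float(np.sign(mapped[labels == NORMAL].mean()))
        survivors.append((idx, mapped, params, sign_n, c))
    if not survivors:
        raise SelectionError(
            "no feature has class means of opposite sign after contrast mapping")

    cs = np.array([s[4] for s in survivors])
    thr = float(np.percentile(cs, 60)) if delta1 is None else float(delta1)
    final = [s for s in survivors if s[4] >= thr]
    if not final:
        raise SelectionError(
            f"no contribution value reaches delta1={thr:g}; lower delta1")

    return SelectionModel(
        kept_indices=[s[0] for s in final],
        feature_names=list(fs.feature_names),
        row_minmax=[(float(minmax[s[0], 0]), float(minmax[s[0], 1])) for s in final],
        contrast_params=[tuple(map(float, s[2])) for s in final],
        orientation=[s[3] for s in final],
        contributions=[s[4] for s in final],
        delta1=thr,
        delta2=float(delta2),
        rho_max=float(rho_max),
    )


def transform(model: SelectionModel, fs: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted model: select rows, min–max + contrast map with the
    stored parameters, clamp to [−1, 1], zero entries with |x| ≤ δ2."""
    if list(fs.feature_names) != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    rows = []
    for idx, (lo, hi), (mu, sigma, eps) in zip(
        model.kept_indices, model.row_minmax, model.contrast_params
    ):
        row = fs.values[idx].astype(float)
        span = hi - lo if hi > lo else 1.0
        row01 = (row - lo) / span
        denom = sigma + eps
        if denom == 0.0:
            denom = 1e-12
        mapped = np.clip((row01 - mu) / denom, -1.0, 1.0)
        mapped[np.abs(mapped) <= model.delta2] = 0.0
        rows.append(mapped)
    values = np.vstack(rows)
    names = [fs.feature_names[i] for i in model.kept_indices]
    groups = [fs.groups[i] for i in model.kept_indices] if fs.groups else []
    return FeatureMatrix(values=values, feature_names=names,
                         sample_ids=list(fs.sample_ids), groups=groups)


def fit_transform(
    fs: FeatureMatrix,
    labels: Sequence[str],
    rho_max: float = 0.95,
    delta1: float | None = None,
    delta2: float = 0.05,
) -> tuple[SelectionModel, FeatureMatrix]:
    model = fit(fs, labels, rho_max=rho_max, delta1=delta1, delta2=delta2)
    return model, transform(model, fs)
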