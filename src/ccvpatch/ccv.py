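"""Concave-convex variation (CCV): contour-irregularity statistic and
posterior reweighting.

A normal nucleus outline is approximately convex, while malignant nuclei
show irregular, lobed contours.  CCV quantifies this as an inflection
count obtained without any analytic curve expression: the contour's
bounding box yields four tangent points, which split the contour into four
curves; each curve is sampled at a fixed pixel interval; slopes are taken
from the curve's first tangent point to every sampled point; and the number
of sign alternations in the successive slope differences is counted.  The
per-curve counts are summed over the four curves.

Classifier adjustment: from training contours the per-class mean CCVs
m1 = mean(CCV_normal) and m2 = mean(CCV_abnormal) are learned; a test
sample's initial class probability is multiplied by a piecewise-linear
weight ω ∈ [0.8, 1.2] that rewards agreement between the initial label and
the sample's CCV (small CCV supports "normal", large CCV supports
"abnormal"), and the label flips when the adjusted probability drops below
1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .base_classifiers import ProbPrediction
from .preprocess import Contour

NORMAL, ABNORMAL = "normal", "abnormal"


class DegenerateShapeError(ValueError):
    """Contour too degenerate for tangent-point construction."""


@dataclass(frozen=True)
class TangentQuad:
    """The four axis-extreme contour points, with their traversal indices."""

    left: tuple[int, int]
    right: tuple[int, int]
    top: tuple[int, int]
    bottom: tuple[int, int]
    indices: tuple[int, int, int, int]  # traversal index of each, same order


def tangent_points(contour: Contour) -> TangentQuad:
    """Points where the contour meets its axis-aligned bounding box.

    One extreme per direction; ties are broken by the smallest traversal
    index.  Extremes may coincide on shapes whose boundary touches a
    bounding-box corner; :func:`split_curves` then produces empty arcs.
    Contours too small to carry four extremes (e.g. a 1-pixel blob) raise
    a degenerate-shape error.
    """
    pts = np.asarray(contour.points)
    if len(pts) < 4:
        raise DegenerateShapeError(
            f"contour with {len(pts)} point(s) cannot carry four tangent points")
    cols, rows = pts[:, 0], pts[:, 1]
    i_left = int(np.argmin(cols))
    i_right = int(np.argmax(cols))
    i_top = int(np.argmin(rows))
    i_bottom = int(np.argmax(rows))
    quad = TangentQuad(
        left=tuple(pts[i_left]),
        right=tuple(pts[i_right]),
        top=tuple(pts[i_top]),
        bottom=tuple(pts[i_bottom]),
        indices=(i_left, i_right, i_top, i_bottom),
    )
    if len({quad.left, quad.right, quad.top, quad.bottom}) < 2:
        raise DegenerateShapeError(
            "contour collapses to fewer than two distinct extreme points")
    return quad


def split_curves(contour: Contour, quad: TangentQuad) -> list[np.ndarray]:
    """Split the closed contour into four arcs at the tangent points.

    Arcs run between consecutive tangent points in traversal order and
    include both endpoints; a pair of coincident tangent points yields a
    length-1 arc that contributes CCV 0.
    """
    pts = np.asarray(contour.points)
    n = len(pts)
    order = sorted(set(quad.indices))
    arcs = []
    for a, b in zip(order, order[1:] + [order[0] + n]):
        idx = np.arange(a, b + 1) % n
        arcs.append(pts[idx])
    return arcs


def sample_curve(curve: np.ndarray, interval: int = 2) -> np.ndarray:
    """Every ``interval``-th point along the curve, always keeping the
    first and last points."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    curve = np.asarray(curve)
    n = len(curve)
    if n == 0:
        return curve
    idx = list(range(0, n, interval))
    if idx[-1] != n - 1:
        idx.append(n - 1)
    return curve[idx]


def slope_vector(samples: np.ndarray) -> np.ndarray:
    """Slopes k = Δrow/Δcol from the first sample (the anchor tangent
    point) to each later sample; pairs with Δcol = 0 are skipped so the
    vector stays finite."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        return np.empty(0)
    anchor = samples[0]
    d = samples[1:] - anchor
    nonvertical = d[:, 0] != 0
    return d[nonvertical, 1] / d[nonvertical, 0]


def count_sign_alternations(deltas: Sequence[float]) -> int:
    """Number of adjacent opposite-sign pairs in a sequence of slope
    differences.  Zeros inherit the most recent nonzero sign (plateaus are
    not inflections) and are neutral before any nonzero entry."""
    s = np.sign(np.asarray(deltas, dtype=float))
    nz = s[s != 0]
    if len(nz) < 2:
        return 0
    return int(np.sum(nz[:-1] * nz[1:] < 0))


def alternation_count(K: Sequence[float]) -> int:
    """CCV count of one slope vector: sign alternations of ΔK, with
    Δk_n = k_{n+1} − k_n."""
    K = np.asarray(K, dtype=float)
    if len(K) < 3:
        return 0
    return count_sign_alternations(np.diff(K))


def ccv_of_contour(contour: Contour, interval: int = 2) -> int:
    """Total CCV of a contour: the four per-curve alternation counts
    summed."""
    quad = tangent_points(contour)
    total = 0
    for curve in split_curves(contour, quad):
        total += alternation_count(slope_vector(sample_curve(curve, interval)))
    return total


# ---------------------------------------------------------------------------
# class model and weights

@dataclass(frozen=True)
class CCVModel:
    """Per-class mean CCV of the training contours."""

    m1: float  # mean CCV of normal contours
    m2: float  # mean CCV of abnormal contours

    @property
    def valid(self) -> bool:
        return self.m1 < self.m2


def fit_ccv_model(
    contours_or_ccvs: Iterable[Contour | float | int],
    labels: Sequence[str],
    interval: int = 2,
) -> CCVModel:
    """Learn m1/m2 from labelled training contours (or precomputed CCVs).

    Warns when m1 >= m2 (the model then cannot be used for weighting).
    """
    values = []
    for item in contours_or_ccvs:
        if isinstance(item, Contour):
            values.append(float(ccv_of_contour(item, interval)))
        else:
            values.append(float(item))
    values = np.asarray(values)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("labels length must match contour count")
    norm = values[labels == NORMAL]
    abn = values[labels == ABNORMAL]
    if len(norm) == 0 or len(abn) == 0:
        raise ValueError("both classes must be present")
    model = CCVModel(m1=float(norm.mean()), m2=float(abn.mean()))
    if not model.valid:
        warnings.warn(
            f"CCV model degenerate: m1={model.m1:g} >= m2={model.m2:g}; "
            "contour irregularity does not separate the classes",
            stacklevel=2,
        )
    return model


def weight_normal(ccv: float, model: CCVModel) -> float:
    """Adjusting weight for samples initially classified normal.

    Continuous, monotone decreasing, piecewise linear in CCV: 1.2 up to
    m1, 1.0 at the midpoint, 0.8 from m2 on.
    """
    m1, m2 = model.m1, model.m2
    if m1 >= m2:
        raise ValueError("weight functions require m1 < m2")
    mid = (m1 + m2) / 2.0
    if ccv <= m1:
        return 1.2
    if ccv <= mid:
        return 1.2 + 0.4 * (ccv - m1) / (m1 - m2)
    if ccv < m2:
        return 0.8 + 0.4 * (ccv - m2) / (m1 - m2)
    return 0.8


def weight_abnormal(ccv: float, model: CCVModel) -> float:
    """Adjusting weight for samples initially classified abnormal; the
    mirror of :func:`weight_normal` (their pointwise sum is 2)."""
    m1, m2 = model.m1, model.m2
    if m1 >= m2:
        raise ValueError("weight functions require m1 < m2")
    mid = (m1 + m2) / 2.0
    if ccv <= m1:
        return 0.8
    if ccv <= mid:
        return 0.8 + 0.4 * (ccv - m1) / (m2 - m1)
    if ccv < m2:
        return 1.2 + 0.4 * (ccv - m2) / (m2 - m1)
    return 1.2


@dataclass(frozen=True)
class AdjustedPrediction:
    """CCV-adjusted prediction of one sample."""

    sample_id: str
    initial_label: str
    p_initial: float
    ccv_value: float
    omega: float
    p_final: float  # clip(p_initial * omega, 0, 1), prob. of the initial label
    final_label: str

    @property
    def p_final_of_final_label(self) -> float:
        """p_final re-expressed for the final label (1 − p_final after a
        flip)."""
        return self.p_final if self.final_label == self.initial_label else 1.0 - self.p_final


def adjust_predictions(
    preds: Sequence[ProbPrediction],
    ccvs: Sequence[float],
    model: CCVModel,
) -> list[AdjustedPrediction]:
    """Reweight initial predictions by contour irregularity.

    Initially-normal samples use ω_normal, initially-abnormal ω_abnormal;
    p_final = clip(p_initial · ω, 0, 1); the initial label is kept iff
    p_final ≥ 1/2, else flipped.
    """
    if len(preds) != len(ccvs):
        raise ValueError("one CCV value is required per prediction")
    out = []
    for pred, ccv in zip(preds, ccvs):
        if pred.initial_label == NORMAL:
            omega = weight_normal(ccv, model)
            other = ABNORMAL
        else:
            omega = weight_abnormal(ccv, model)
            other = NORMAL
        p_final = float(np.clip(pred.p_initial * omega, 0.0, 1.0))
        final = pred.initial_label if p_final >= 0.5 else other
        out.append(AdjustedPrediction(
            sample_id=pred.sample_id,
            initial_label=pred.initial_label,
            p_initial=pred.p_initial,
            ccv_value=float(ccv),
            omega=float(omega),
            p_final=p_final,
            final_label=final,
        ))
    return out


def adjusted_abnormal_score(adj: AdjustedPrediction) -> float:
    """Continuous abnormal-class score after adjustment, for PR/ROC sweeps."""
    if adj.initial_label == ABNORMAL:
        return adj.p_final
    return 1.0 - adj.p_final
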