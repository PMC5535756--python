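"""Hand-crafted feature extraction for single-nucleus patches.

Three groups of features are computed per patch and stacked into a named
feature matrix with features in rows and samples in columns:

* intensity — per-pixel gray-level summary statistics over the whole patch
  and within the nucleus mask;
* morphology — shape descriptors of the nucleus mask, including the
  nucleocytoplasmic ratio (mask area over patch area);
* texture — gray-level co-occurrence statistics (ASM, ENT, CON, COR, IDM),
  cellwise local-binary-pattern histograms, aggregated SIFT keypoint
  descriptors, and the three classical Tamura statistics.

All extractors are deterministic; every feature is finite for any valid
patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import SIFT
from skimage.measure import regionprops

from .synth_patches import PatchRecord

# ---------------------------------------------------------------------------
# configuration

#: co-occurrence offsets (dcol, drow) for distance 1 at 0°, 45°, 90°, 135°
DEFAULT_GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature bank.

    ``glcm_idm_literal`` switches the IDM denominator to the non-standard
    1+(i+j)^2 form; the default 1+(i-j)^2 is the homogeneity measure.
    ``lbp_bins`` is ``"raw"`` (256 codes per cell) or ``"uniform"``
    (58 uniform patterns + 1 catch-all per cell).
    """

    glcm_levels: int = 16
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_GLCM_OFFSETS
    glcm_idm_literal: bool = False
    lbp_bins: str = "raw"
    lbp_cell: int = 16
    tamura_windows: tuple[int, ...] = (1, 2, 4, 8, 16)
    #: no initial scale-space upsampling: the 64×64 patches are small and
    #: already sampled near the nucleus scale
    sift_upsampling: int = 1


@dataclass
class FeatureMatrix:
    """Feature matrix with features in rows and samples in columns."""

    values: np.ndarray  # (m, n)
    feature_names: list[str]
    sample_ids: list[str]
    groups: list[str] = field(default_factory=list)  # per-row feature group

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_names), len(self.sample_ids)):
            raise ValueError("values shape does not match names/ids")
        if not self.groups:
            self.groups = ["" for _ in self.feature_names]

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.feature_names,
                     columns=self.sample_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(float),
                   feature_names=[str(i) for i in df.index],
                   sample_ids=[str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# intensity

_STAT_NAMES = ("mean", "median", "var", "std", "skew", "kurt",
               "min", "max", "range", "q25", "q75")


def _summary_stats(values: np.ndarray) -> list[float]:
    v = np.asarray(values, dtype=float).ravel()
    mean = float(v.mean())
    centred = v - mean
    var = float(np.mean(centred**2))
    sd = float(np.sqrt(var))
    # Fisher skewness / excess kurtosis; zero on constant input
    skew = float(np.mean(centred**3) / sd**3) if sd > 0 else 0.0
    kurt = float(np.mean(centred**4) / var**2 - 3.0) if sd > 0 else 0.0
    q25, med, q75 = (float(x) for x in np.percentile(v, (25, 50, 75)))
    vmin, vmax = float(v.min()), float(v.max())
    return [mean, med, var, sd, skew, kurt, vmin, vmax, vmax - vmin, q25, q75]


def intensity_features(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Gray-level summary statistics over the whole patch and within the
    nucleus mask (Fisher skewness/kurtosis; zero on constant input)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    gray = np.asarray(gray, dtype=float)
    out: dict[str, float] = {}
    for scope, vals in (("patch", gray), ("nucleus", gray[mask])):
        for name, value in zip(_STAT_NAMES, _summary_stats(vals)):
            out[f"int_{scope}_{name}"] = value
    return out


# ---------------------------------------------------------------------------
# morphology

def morphology_features(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of the (single-component) nucleus mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    props = regionprops(mask.astype(np.uint8))[0]
    h, w = mask.shape
    cr, cc = props.centroid
    centroid_offset = float(np.hypot(cr - (h - 1) / 2, cc - (w - 1) / 2))
    return {
        "morph_area": float(props.area),
        "morph_perimeter": float(props.perimeter),
        "morph_equiv_diameter": float(props.equivalent_diameter_area),
        "morph_major_axis": float(props.axis_major_length),
        "morph_minor_axis": float(props.axis_minor_length),
        "morph_eccentricity": float(props.eccentricity),
        "morph_solidity": float(props.solidity),
        "morph_extent": float(props.extent),
        "morph_centroid_offset": centroid_offset,
        "morph_nc_ratio": float(mask.sum()) / float(mask.size),
    }


# ---------------------------------------------------------------------------
# GLCM

@dataclass(frozen=True)
class GLCMStats:
    """The five co-occurrence statistics of one normalized GLCM.

    ``degenerate`` flags a constant image, where the correlation is
    undefined (zero marginal variance) and reported as 0.
    """

    asm: float
    ent: float
    con: float
    cor: float
    idm: float
    degenerate: bool = False


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Quantize an 8-bit image onto ``levels`` equal-width gray bins."""
    gray = np.asarray(gray)
    return np.clip((gray.astype(int) * levels) // 256, 0, levels - 1)


def glcm_matrix(quantized: np.ndarray, levels: int,
                offset: tuple[int, int]) -> np.ndarray:
    """Symmetric, sum-normalized co-occurrence matrix for one (dcol, drow)
    offset."""
    dc, dr = offset
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quantized[r0:r1, c0:c1].ravel()
    b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    m = np.zeros((levels, levels), dtype=float)
    np.add.at(m, (a, b), 1.0)
    m = m + m.T
    total = m.sum()
    if total > 0:
        m /= total
    return m


def glcm_stats_from_matrix(p: np.ndarray, idm_literal: bool = False) -> GLCMStats:
    """ASM, ENT, CON, COR, IDM of a normalized co-occurrence matrix."""
    levels = p.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    asm = float(np.sum(p * p))
    nz = p > 0
    ent = float(-np.sum(p[nz] * np.log(p[nz])))
    con = float(np.sum((i - j) ** 2 * p))
    px = p.sum(axis=1)
    ux = float(np.sum(np.arange(levels) * px))
    sx = float(np.sqrt(np.sum((np.arange(levels) - ux) ** 2 * px)))
    # symmetric matrix: marginals coincide
    uy, sy = ux, sx
    degenerate = sx == 0 or sy == 0
    cor = 0.0 if degenerate else float((np.sum(i * j * p) - ux * uy) / (sx * sy))
    denom = 1.0 + ((i + j) ** 2 if idm_literal else (i - j) ** 2)
    idm = float(np.sum(p / denom))
    return GLCMStats(asm=asm, ent=ent, con=con, cor=cor, idm=idm,
                     degenerate=degenerate)


def glcm_stats(
    gray: np.ndarray,
    levels: int = 16,
    offsets: Sequence[tuple[int, int]] = DEFAULT_GLCM_OFFSETS,
    idm_literal: bool = False,
) -> dict[str, GLCMStats]:
    """Co-occurrence statistics per offset plus their mean (key ``"mean"``)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize_gray(gray, levels)
    out: dict[str, GLCMStats] = {}
    per = []
    for off in offsets:
        s = glcm_stats_from_matrix(glcm_matrix(q, levels, off), idm_literal)
        out[f"d{off[0]}_{off[1]}"] = s
        per.append(s)
    out["mean"] = GLCMStats(
        asm=float(np.mean([s.asm for s in per])),
        ent=float(np.mean([s.ent for s in per])),
        con=float(np.mean([s.con for s in per])),
        cor=float(np.mean([s.cor for s in per])),
        idm=float(np.mean([s.idm for s in per])),
        degenerate=any(s.degenerate for s in per),
    )
    return out


# ---------------------------------------------------------------------------
# LBP

# 8 neighbours clockwise from top-left, (drow, dcol); bit 7 (MSB) first
_LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """8-bit LBP code of every pixel: bit set when center < neighbour.

    Border pixels use edge-replicated neighbours (so a constant image maps
    to the all-zero code everywhere).
    """
    g = np.asarray(gray, dtype=float)
    pad = np.pad(g, 1, mode="edge")
    h, w = g.shape
    codes = np.zeros((h, w), dtype=np.uint8)
    for bit, (dr, dc) in enumerate(_LBP_OFFSETS):
        neigh = pad[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        codes |= ((g < neigh).astype(np.uint8) << (7 - bit))
    return codes


def _uniform_lookup() -> np.ndarray:
    """Map each 8-bit code to one of 59 bins: 58 uniform patterns (at most
    two 0/1 transitions around the ring) in ascending code order, plus a
    shared bin for the rest."""
    lut = np.zeros(256, dtype=int)
    uniform_codes = []
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        if transitions <= 2:
            uniform_codes.append(code)
    for rank, code in enumerate(uniform_codes):
        lut[code] = rank
    non_uniform_bin = len(uniform_codes)
    for code in range(256):
        if code not in uniform_codes:
            lut[code] = non_uniform_bin
    return lut


_UNIFORM_LUT = _uniform_lookup()


def lbp_histogram(gray: np.ndarray, cell: int = 16, bins: str = "raw") -> dict[str, float]:
    """Concatenated per-cell normalized LBP histograms.

    The patch is divided into non-overlapping ``cell``×``cell`` cells
    (16 cells for a 64×64 patch); each cell's code histogram is normalized
    to sum 1.
    """
    g = np.asarray(gray)
    h, w = g.shape
    if h % cell or w % cell:
        raise ValueError(f"patch {h}x{w} is not divisible into {cell}x{cell} cells")
    codes = lbp_codes(g)
    if bins == "raw":
        n_bins, mapped = 256, codes
    elif bins == "uniform":
        n_bins, mapped = 59, _UNIFORM_LUT[codes]
    else:
        raise ValueError("bins must be 'raw' or 'uniform'")
    out: dict[str, float] = {}
    for ci, r in enumerate(range(0, h, cell)):
        for cj, c in enumerate(range(0, w, cell)):
            block = mapped[r : r + cell, c : c + cell]
            hist = np.bincount(block.ravel(), minlength=n_bins).astype(float)
            hist /= hist.sum()
            for b in range(n_bins):
                out[f"lbp_c{ci}{cj}_b{b}"] = float(hist[b])
    return out


# ---------------------------------------------------------------------------
# SIFT

def gradient_magnitude_orientation(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient magnitude and orientation of a smoothed
    image: val = sqrt((L(x+1,y)−L(x−1,y))² + (L(x,y+1)−L(x,y−1))²) and
    dir = atan2 of the same differences.  Border pixels use edge padding."""
    L = np.asarray(L, dtype=float)
    pad = np.pad(L, 1, mode="edge")
    h, w = L.shape
    dx = pad[1 : 1 + h, 2 : 2 + w] - pad[1 : 1 + h, 0:w]
    dy = pad[2 : 2 + h, 1 : 1 + w] - pad[0:h, 1 : 1 + w]
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def sift_features(gray: np.ndarray, upsampling: int = 1) -> dict[str, float]:
    """Fixed-length aggregation of variable-count SIFT keypoints.

    Difference-of-Gaussian keypoints and 128-d descriptors come from the
    standard SIFT procedure; the aggregate is the keypoint count plus the
    per-dimension mean and standard deviation of the descriptors.  Zero
    keypoints yield the zero vector (count 0), not an error.
    """
    g = np.asarray(gray, dtype=float)
    detector = SIFT(upsampling=upsampling)
    descriptors = None
    try:
        detector.detect_and_extract(g)
        descriptors = detector.descriptors
    except RuntimeError:  # no keypoints found
        descriptors = None
    out = {}
    if descriptors is None or len(descriptors) == 0:
        out["sift_n_keypoints"] = 0.0
        mean = np.zeros(128)
        sd = np.zeros(128)
    else:
        d = descriptors.astype(float)
        out["sift_n_keypoints"] = float(len(d))
        mean = d.mean(axis=0)
        sd = d.std(axis=0)
    for k in range(128):
        out[f"sift_mean_{k}"] = float(mean[k])
    for k in range(128):
        out[f"sift_sd_{k}"] = float(sd[k])
    return out


# ---------------------------------------------------------------------------
# Tamura

def tamura_features(gray: np.ndarray,
                    windows: Sequence[int] = (1, 2, 4, 8, 16)) -> dict[str, float]:
    """Classical Tamura texture statistics.

    coarseness — per-pixel best window size among ``windows`` (the size
    maximizing the horizontal/vertical difference of window means at that
    distance), averaged over the image;
    contrast — sigma / (mu4/sigma^4)^(1/4), the 4th-moment-normalized
    standard deviation (0 for a constant image);
    directionality — concentration of the gradient-orientation histogram,
    measured as the magnitude-weighted circular resultant length of the
    doubled orientation angle (1 for perfect stripes, ~0 for isotropy).
    """
    g = np.asarray(gray, dtype=float)

    # coarseness
    best = np.zeros_like(g)
    best_size = np.ones_like(g)
    for size in windows:
        means = ndimage.uniform_filter(g, size=size, mode="reflect")
        half = max(size // 2, 1)
        eh = np.abs(np.roll(means, -half, axis=1) - np.roll(means, half, axis=1))
        ev = np.abs(np.roll(means, -half, axis=0) - np.roll(means, half, axis=0))
        e = np.maximum(eh, ev)
        better = e > best
        best = np.where(better, e, best)
        best_size = np.where(better, float(size), best_size)
    coarseness = float(best_size.mean())

    # contrast
    sd = g.std()
    if sd == 0:
        contrast = 0.0
    else:
        mu4 = np.mean((g - g.mean()) ** 4)
        kurt = mu4 / sd**4
        contrast = float(sd / kurt**0.25)

    # directionality
    val, direction = gradient_magnitude_orientation(g)
    total = val.sum()
    if total == 0:
        directionality = 0.0
    else:
        w = val / total
        c = float(np.sum(w * np.cos(2 * direction)))
        s = float(np.sum(w * np.sin(2 * direction)))
        directionality = float(np.hypot(c, s))

    return {"tamura_coarseness": coarseness,
            "tamura_contrast": contrast,
            "tamura_directionality": directionality}


# ---------------------------------------------------------------------------
# assembly

def extract_features(gray: np.ndarray, mask: np.ndarray,
                     config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """All features of one patch, in the fixed documented order
    (intensity, morphology, texture)."""
    out: dict[str, float] = {}
    out.update(intensity_features(gray, mask))
    out.update(morphology_features(mask))
    glcm = glcm_stats(gray, levels=config.glcm_levels, offsets=config.glcm_offsets,
                      idm_literal=config.glcm_idm_literal)
    for key, s in glcm.items():
        for stat in ("asm", "ent", "con", "cor", "idm"):
            out[f"glcm_{key}_{stat}"] = getattr(s, stat)
    out.update(lbp_histogram(gray, cell=config.lbp_cell, bins=config.lbp_bins))
    out.update(sift_features(gray, upsampling=config.sift_upsampling))
    out.update(tamura_features(gray, windows=config.tamura_windows))
    return out


def _group_of(name: str) -> str:
    if name.startswith("int_"):
        return "intensity"
    if name.startswith("morph_"):
        return "morphology"
    return "texture"


def extract_all(patches: Iterable[PatchRecord],
                config: FeatureConfig = FeatureConfig()) -> FeatureMatrix:
    """Assemble the feature matrix (features × samples) for a patch set."""
    patches = list(patches)
    if not patches:
        raise ValueError("no patches given")
    columns = []
    names: list[str] | None = None
    ids = []
    for rec in patches:
        try:
            feats = extract_features(rec.gray, rec.mask, config)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for patch {rec.id!r}: {exc}") from exc
        if names is None:
            names = list(feats.keys())
        columns.append([feats[k] for k in names])
        ids.append(rec.id)
    values = np.array(columns, dtype=float).T
    if not np.isfinite(values).all():
        bad = np.where(~np.isfinite(values))
        raise RuntimeError(
            f"non-finite feature {names[bad[0][0]]!r} in patch {ids[bad[1][0]]!r}")
    return FeatureMatrix(values=values, feature_names=names, sample_ids=ids,
                         groups=[_group_of(n) for n in names])
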