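"""Synthetic single-nucleus patch generator.

The classification pipeline in this package was developed for 64×64
grayscale patches, each containing one segmented cell nucleus together with
its binary mask.  Because no public set of such patches exists, this module
generates labelled stand-in data in the same layout: nuclei are star-convex
blobs defined by a polar radius function

    r(θ) = r_ellipse(θ) + A·sin(n_lobes·θ + φ) + ε(θ)

rasterised onto the grid.  Normal nuclei are smooth ellipses (``n_lobes=0``,
``boundary_noise_amp=0``); abnormal nuclei superimpose sinusoidal lobes and
smooth radial noise, giving contours with many concave/convex inflections —
the geometric signature the CCV statistic is built to detect.  Texture
differs by class through the mean nuclear gray level, the noise level and a
chromatin-like correlated component inside the nucleus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

PATCH_SIZE = 64
_BORDER_MARGIN = 2


class ShapeParamError(ValueError):
    """Shape parameters that cannot produce a valid in-frame nucleus."""


@dataclass(frozen=True)
class ShapeParams:
    """Polar-shape parameters of one nucleus.

    base_radius
        Mean radius in pixels of the (area-preserving) ellipse.
    eccentricity
        Ratio ≥ 1 of major to minor semi-axis; 1 gives a circle.
    boundary_noise_amp
        Amplitude in pixels of the boundary irregularity.  It is both the
        amplitude of the sinusoidal lobes (when ``n_lobes > 0``) and the
        scale of the smooth random radial perturbation.
    n_lobes
        Number of sinusoidal lobes around the contour; 0 disables lobes.
    center_jitter
        Maximum uniform displacement in pixels of the nucleus centre from
        the patch centre.
    """

    base_radius: float = 12.0
    eccentricity: float = 1.0
    boundary_noise_amp: float = 0.0
    n_lobes: int = 0
    center_jitter: float = 0.0

    def validate(self) -> None:
        if self.base_radius <= 0:
            raise ShapeParamError("base_radius must be positive")
        if self.eccentricity < 1:
            raise ShapeParamError("eccentricity must be >= 1")
        if self.boundary_noise_amp < 0:
            raise ShapeParamError("boundary_noise_amp must be >= 0")
        if self.boundary_noise_amp >= self.base_radius:
            raise ShapeParamError("boundary_noise_amp must be < base_radius")
        if self.n_lobes < 0 or int(self.n_lobes) != self.n_lobes:
            raise ShapeParamError("n_lobes must be a nonnegative integer")
        if self.center_jitter < 0:
            raise ShapeParamError("center_jitter must be >= 0")
        r_max = (
            self.base_radius * np.sqrt(self.eccentricity)
            + 2.0 * self.boundary_noise_amp
            + self.center_jitter
        )
        if r_max > PATCH_SIZE / 2 - _BORDER_MARGIN - 1:
            raise ShapeParamError(
                f"shape (max radial extent {r_max:.1f}px) cannot fit the "
                f"{PATCH_SIZE}x{PATCH_SIZE} frame with a {_BORDER_MARGIN}px margin"
            )


@dataclass(frozen=True)
class TextureParams:
    """Gray-level texture parameters of one patch.

    nucleus_mean_gray / background_mean_gray
        Target mean intensities (0–255) inside and outside the mask.
    noise_sd
        Gray-level standard deviation of the additive noise.
    chromatin_grain
        Correlation length in pixels of the chromatin-like texture inside
        the nucleus; 0 gives white noise inside as well.
    """

    nucleus_mean_gray: float = 90.0
    background_mean_gray: float = 190.0
    noise_sd: float = 8.0
    chromatin_grain: float = 1.5

    def validate(self) -> None:
        for name in ("nucleus_mean_gray", "background_mean_gray"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.chromatin_grain < 0:
            raise ValueError("chromatin_grain must be >= 0")


@dataclass(frozen=True)
class PatchRecord:
    """One labelled patch: grayscale image, nucleus mask and class label."""

    gray: np.ndarray  # (64, 64) uint8
    mask: np.ndarray  # (64, 64) bool
    label: str  # "normal" | "abnormal"
    id: str


#: Default per-class presets.  Normal nuclei are smooth near-circular
#: ellipses; abnormal nuclei are larger-amplitude 6-lobed shapes with extra
#: boundary noise, darker (hyperchromatic) and noisier in texture.
NORMAL_SHAPE = ShapeParams(
    base_radius=12.0, eccentricity=1.15, boundary_noise_amp=0.0, n_lobes=0, center_jitter=3.0
)
ABNORMAL_SHAPE = ShapeParams(
    base_radius=13.0, eccentricity=1.25, boundary_noise_amp=3.0, n_lobes=6, center_jitter=3.0
)
NORMAL_TEXTURE = TextureParams(
    nucleus_mean_gray=100.0, background_mean_gray=190.0, noise_sd=10.0, chromatin_grain=1.0
)
ABNORMAL_TEXTURE = TextureParams(
    nucleus_mean_gray=80.0, background_mean_gray=185.0, noise_sd=14.0, chromatin_grain=2.5
)


def _radius_function(shape: ShapeParams, rng: np.random.Generator):
    """Build r(θ) for one nucleus; consumes a fixed number of rng draws."""
    a = shape.base_radius * np.sqrt(shape.eccentricity)
    b = shape.base_radius / np.sqrt(shape.eccentricity)
    orient = rng.uniform(0.0, np.pi)
    lobe_phase = rng.uniform(0.0, 2.0 * np.pi)
    # smooth periodic radial noise: a handful of low-order random harmonics
    n_harm = 4
    amps = rng.normal(0.0, shape.boundary_noise_amp / 4.0, size=n_harm)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)
    orders = np.arange(2, 2 + n_harm)

    def r_grid(theta: np.ndarray) -> np.ndarray:
        t = theta - orient
        r_ell = (a * b) / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        r = r_ell
        if shape.n_lobes > 0:
            r = r + shape.boundary_noise_amp * np.sin(shape.n_lobes * theta + lobe_phase)
        if shape.boundary_noise_amp > 0:
            noise = np.zeros_like(theta)
            for amp, order, ph in zip(amps, orders, phases):
                noise += amp * np.sin(order * theta + ph)
            r = r + noise
        return np.maximum(r, 2.0)

    return r_grid


def generate_mask(shape: ShapeParams, seed: int) -> np.ndarray:
    """Rasterise one nucleus mask onto the 64×64 grid.

    Deterministic given (shape, seed).  The result has exactly one
    4-connected foreground component that does not touch the image border.
    """
    shape.validate()
    rng = np.random.default_rng(seed)
    center = PATCH_SIZE / 2 - 0.5 + rng.uniform(
        -shape.center_jitter, shape.center_jitter, size=2
    )  # (col, row)
    r_grid = _radius_function(shape, rng)

    rows, cols = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
    dx = cols - center[0]
    dy = rows - center[1]
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dx, dy)
    mask = dist <= r_grid(theta)

    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)  # 4-connectivity by default
    if n == 0:
        raise ShapeParamError("parameters produced an empty mask")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ShapeParamError("nucleus touches the patch border")
    return mask.astype(bool)


def generate_texture(mask: np.ndarray, tex: TextureParams, seed: int) -> np.ndarray:
    """Render a grayscale patch for ``mask``: flat class means plus noise.

    Outside the nucleus the noise is white; inside, when
    ``chromatin_grain > 0``, it is spatially correlated (Gaussian-filtered
    white noise rescaled to ``noise_sd``), mimicking chromatin clumping.
    Returns a uint8 image clipped to [0, 255].
    """
    tex.validate()
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    base = np.where(mask, tex.nucleus_mean_gray, tex.background_mean_gray).astype(float)
    white = rng.normal(0.0, 1.0, size=mask.shape)
    if tex.chromatin_grain > 0:
        grain = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=mask.shape),
                                        tex.chromatin_grain, mode="reflect")
        sd = grain.std()
        if sd > 0:
            grain = grain / sd
        noise = np.where(mask, grain, white)
    else:
        noise = white
    img = base + tex.noise_sd * noise
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _patch_seeds(master_seed: int, index: int) -> tuple[int, int]:
    """Per-patch (mask, texture) seeds split from the master seed.

    Uses an indexed SeedSequence spawn key so each patch's stream is
    independent of how many patches are generated (order independence).
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    s = ss.generate_state(2)
    return int(s[0] % (2**31)), int(s[1] % (2**31))


def generate_dataset(
    n_per_class: int,
    normal: tuple[ShapeParams, TextureParams] = (NORMAL_SHAPE, NORMAL_TEXTURE),
    abnormal: tuple[ShapeParams, TextureParams] = (ABNORMAL_SHAPE, ABNORMAL_TEXTURE),
    seed: int = 0,
) -> list[PatchRecord]:
    """Generate a balanced labelled dataset of 2·n_per_class patches."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    records: list[PatchRecord] = []
    specs = [("normal", *normal), ("abnormal", *abnormal)]
    index = 0
    for label, shape, tex in specs:
        for i in range(n_per_class):
            mask_seed, tex_seed = _patch_seeds(seed, index)
            mask = generate_mask(shape, mask_seed)
            gray = generate_texture(mask, tex, tex_seed)
            records.append(PatchRecord(gray=gray, mask=mask, label=label,
                                       id=f"{label}_{i:04d}"))
            index += 1
    return records


def save_dataset(records: Iterable[PatchRecord], directory: str | Path) -> None:
    """Write ``<id>_gray.png`` / ``<id>_mask.png`` pairs plus ``labels.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        iio.imwrite(directory / f"{rec.id}_gray.png", rec.gray)
        iio.imwrite(directory / f"{rec.id}_mask.png",
                    (rec.mask.astype(np.uint8) * 255))
        rows.append((rec.id, rec.label))
    with open(directory / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        writer.writerows(rows)


def load_dataset(directory: str | Path) -> list[PatchRecord]:
    """Read a dataset written by :func:`save_dataset` (or real data in the
    same layout).  8-bit masks are binarised at threshold 128."""
    directory = Path(directory)
    records = []
    with open(directory / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pid, label = row["id"], row["label"]
            gray = np.asarray(iio.imread(directory / f"{pid}_gray.png"))
            mask = np.asarray(iio.imread(directory / f"{pid}_mask.png")) >= 128
            records.append(PatchRecord(gray=gray.astype(np.uint8), mask=mask,
                                       label=label, id=pid))
    return records
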