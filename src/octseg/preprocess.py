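"""Preprocessing, cleaning, augmentation and boundary/region conversion.

The training pipeline applies, in order: per-A-scan attenuation-
compensating contrast enhancement (a dataset-level preprocess), 16 rows
of zero padding at the top of each image, and on-the-fly augmentation
when a sample is presented to the network (one of four equiprobable
cases: unchanged, left-right flipped, Gaussian-noisy, flipped + noisy,
with the noise variance drawn uniformly from [250, 1000] per
presentation on the 8-bit intensity scale).

Region maps use three classes: 0 = vitreous + padding, 1 = retina,
2 = choroid + sclera.  Rasterization of fractional boundary rows uses
floor(row) as the first row of the region below the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import BoundarySet

N_CLASSES = 3
PAD_ROWS_DEFAULT = 16

AUG_CASES = ("unchanged", "flipped", "noisy", "flipped_noisy")


def _as_pixels(image):
    """Accept a BScan or a bare 2-D array; return float64 pixels."""
    px = getattr(image, "pixels", image)
    return np.asarray(px, dtype=np.float64)


def enhance_contrast(image, energy_exponent: float = 2.0,
                     eps: float = 1e-8) -> np.ndarray:
    """Per-A-scan attenuation compensation with emphasis on the RPE.

    For each column j, ``E(i,j) = I(i,j)^n / (2 * sum_{k>=i} I(k,j)^n + eps)``,
    i.e. each pixel's energy is normalized by twice the energy remaining
    below it in the same A-scan, compensating depth attenuation.  The
    result is rescaled to [0, 255] by its global maximum (zeros stay
    zero) and returned as uint8.  Deterministic and column-local.
    """
    if energy_exponent <= 0:
        raise ValueError("energy exponent must be positive")
    I = _as_pixels(image)
    if I.size == 0:
        raise ValueError("empty image")
    En = I ** energy_exponent
    # cumulative energy from the bottom of the A-scan, inclusive of row i
    tail = np.cumsum(En[::-1], axis=0)[::-1]
    E = En / (2.0 * tail + eps)
    m = E.max()
    if m > 0:
        E = E * (255.0 / m)
    return np.round(E).astype(np.uint8)


def pad_top(image, boundaries: BoundarySet | None = None,
            n_rows: int = PAD_ROWS_DEFAULT):
    """Add ``n_rows`` of zero padding to the top; shift boundaries by +n_rows."""
    if n_rows < 0:
        raise ValueError("n_rows must be >= 0")
    px = _as_pixels(image)
    out = np.vstack([np.zeros((n_rows, px.shape[1]), dtype=px.dtype), px])
    if np.issubdtype(np.asarray(getattr(image, "pixels", image)).dtype, np.integer):
        out = out.astype(np.uint8)
    if boundaries is None:
        return out
    shifted = BoundarySet(boundaries.ilm_rows + n_rows,
                          boundaries.rpe_rows + n_rows,
                          boundaries.valid_start, boundaries.valid_end)
    return out, shifted


def clean_scan(image, boundaries: BoundarySet, start: int, end: int):
    """Retain pixels in columns [start, end]; zero the rest.

    Boundary rows outside the range are repeated and flattened to the
    edges (the value at the nearest retained endpoint); the valid column
    range is recorded on the returned BoundarySet.
    """
    px = _as_pixels(image)
    W = px.shape[1]
    if not (0 <= start <= end < W):
        raise ValueError(f"invalid clean range [{start}, {end}] for width {W}")
    out = np.zeros_like(px)
    out[:, start:end + 1] = px[:, start:end + 1]
    ilm = boundaries.ilm_rows.copy()
    rpe = boundaries.rpe_rows.copy()
    ilm[:start], ilm[end + 1:] = ilm[start], ilm[end]
    rpe[:start], rpe[end + 1:] = rpe[start], rpe[end]
    cleaned = BoundarySet(ilm, rpe, valid_start=start, valid_end=end)
    dtype = np.asarray(getattr(image, "pixels", image)).dtype
    return out.astype(dtype), cleaned


@dataclass
class AugmentConfig:
    """Augmentation cases and Gaussian-noise variance range."""

    case_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    noise_var_range: tuple = (250.0, 1000.0)

    def __post_init__(self):
        if len(self.case_probs) != 4 or abs(sum(self.case_probs) - 1.0) > 1e-9:
            raise ValueError("case probabilities must be 4 values summing to 1")
        lo, hi = self.noise_var_range
        if not (0 < lo <= hi):
            raise ValueError("noise variance range must be positive with low <= high")


def augment(image, boundaries: BoundarySet | None, cfg: AugmentConfig, rng,
            force_case: str | None = None):
    """Apply exactly one augmentation case to one sample presentation.

    A flip mirrors the columns of the image and of the boundary arrays;
    noise adds i.i.d. zero-mean Gaussian values (variance drawn uniformly
    from the configured range, on the 8-bit scale) and clips to [0, 255];
    noise never moves the boundaries.  Returns
    ``(image, boundaries, case)``.
    """
    px = _as_pixels(image)
    if force_case is not None:
        case = force_case
        if case not in AUG_CASES:
            raise ValueError(f"unknown augmentation case {case!r}")
    else:
        case = AUG_CASES[rng.choice(4, p=np.asarray(cfg.case_probs))]

    b = boundaries
    if "flipped" in case or case == "flipped_noisy":
        px = px[:, ::-1].copy()
        if b is not None:
            b = BoundarySet(b.ilm_rows[::-1].copy(), b.rpe_rows[::-1].copy(),
                            b.width - 1 - b.valid_end, b.width - 1 - b.valid_start)
    if "noisy" in case:
        var = rng.uniform(*cfg.noise_var_range)
        px = px + rng.normal(0.0, np.sqrt(var), size=px.shape)
        px = np.clip(px, 0.0, 255.0)
    return px, b, case


def boundaries_to_regions(boundaries: BoundarySet, height: int,
                          width: int) -> np.ndarray:
    """Rasterize boundaries to a per-pixel class map.

    Per column: rows < floor(ilm) -> 0 (vitreous + padding);
    floor(ilm) <= rows < floor(rpe) -> 1 (retina);
    rows >= floor(rpe) -> 2 (choroid + sclera).
    """
    if boundaries.width != width:
        raise ValueError("boundary width mismatch")
    boundaries.check_height(height)
    rows = np.arange(height)[:, None]
    ilm = np.floor(boundaries.ilm_rows)[None, :]
    rpe = np.floor(boundaries.rpe_rows)[None, :]
    labels = np.zeros((height, width), dtype=np.uint8)
    labels[(rows >= ilm) & (rows < rpe)] = 1
    labels[rows >= rpe] = 2
    return labels


def regions_to_boundaries(labels: np.ndarray) -> BoundarySet:
    """Invert :func:`boundaries_to_regions` (rows are the floors of the
    original fractional boundaries)."""
    labels = np.asarray(labels)
    H, W = labels.shape
    not_vitreous = labels >= 1
    choroid = labels == 2
    ilm = np.where(not_vitreous.any(axis=0), not_vitreous.argmax(axis=0), H)
    rpe = np.where(choroid.any(axis=0), choroid.argmax(axis=0), H)
    return BoundarySet(ilm.astype(np.float64), rpe.astype(np.float64))


def onehot_regions(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(H, W) int labels -> (n_classes, H, W) float32 one-hot."""
    labels = np.asarray(labels)
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out
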