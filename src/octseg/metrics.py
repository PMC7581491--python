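"""Clinical evaluation: boundary errors, Dice overlap, ETDRS thickness /
volume statistics and Bland--Altman agreement analysis.

Boundary errors follow the sign convention that positive mean error
means the prediction sits lower on the image (larger row index) than
the ground truth.  The ETDRS grid partitions the central 6 mm disc into
nine subfields: a 1 mm central disc, and inner (1--3 mm) and outer
(3--6 mm) rings split into superior / nasal / inferior / temporal
quadrants along the +-45 degree diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import BoundarySet

SUBFIELDS = (
    "central",
    "inner_superior", "inner_nasal", "inner_inferior", "inner_temporal",
    "outer_superior", "outer_nasal", "outer_inferior", "outer_temporal",
)


# ---------------------------------------------------------------------------
# boundary errors
# ---------------------------------------------------------------------------

def boundary_errors(pred: BoundarySet, truth: BoundarySet,
                    method: str = "") -> pd.DataFrame:
    """Per-boundary MAE / mean (signed) error in pixels for one scan.

    Comparison is restricted to the truth's valid column range.  Positive
    mean error = prediction below (larger row than) the truth.
    """
    if pred.width != truth.width:
        raise ValueError("prediction and truth widths differ")
    sl = slice(truth.valid_start, truth.valid_end + 1)
    rows = []
    for name, p, t in (("ILM", pred.ilm_rows, truth.ilm_rows),
                       ("RPE", pred.rpe_rows, truth.rpe_rows)):
        d = p[sl] - t[sl]
        rows.append({
            "boundary": name,
            "mae_px": float(np.mean(np.abs(d))),
            "me_px": float(np.mean(d)),
            "sd_px": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
            "n_columns": int(d.size),
            "method": method,
        })
    return pd.DataFrame(rows)


def aggregate_boundary_errors(per_scan_errors, method: str = "") -> pd.DataFrame:
    """Combine per-scan (pred, truth) column errors into one report.

    ``per_scan_errors``: iterable of (pred, truth) BoundarySet pairs.
    MAE/ME are computed over all compared columns pooled across scans;
    the SD is reported over columns, over per-scan means, and over
    per-scan MAEs, since conventions differ between studies.
    """
    cols = {"ILM": [], "RPE": []}
    for pred, truth in per_scan_errors:
        sl = slice(truth.valid_start, truth.valid_end + 1)
        cols["ILM"].append(pred.ilm_rows[sl] - truth.ilm_rows[sl])
        cols["RPE"].append(pred.rpe_rows[sl] - truth.rpe_rows[sl])
    rows = []
    for name, ds in cols.items():
        allc = np.concatenate(ds)
        scan_means = np.array([np.mean(d) for d in ds])
        scan_maes = np.array([np.mean(np.abs(d)) for d in ds])
        rows.append({
            "boundary": name,
            "mae_px": float(np.mean(np.abs(allc))),
            "me_px": float(np.mean(allc)),
            "sd_columns_px": float(np.std(allc, ddof=1)),
            "sd_scan_me_px": float(np.std(scan_means, ddof=1))
            if len(ds) > 1 else 0.0,
            "sd_scan_mae_px": float(np.std(scan_maes, ddof=1))
            if len(ds) > 1 else 0.0,
            "n_columns": int(allc.size),
            "n_scans": len(ds),
            "method": method,
        })
    return pd.DataFrame(rows)


def dice_overlap(pred_labels: np.ndarray, truth_labels: np.ndarray,
                 n_classes: int = 3) -> dict:
    """Hard Dice overlap 2|A n B| / (|A| + |B|) in percent per class.

    A class empty in both maps scores 100 (perfect agreement on
    absence).  ``overall`` is the mean over classes.
    """
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError("label map shapes differ")
    out = {}
    vals = []
    for c in range(n_classes):
        a = pred_labels == c
        b = truth_labels == c
        denom = a.sum() + b.sum()
        d = 100.0 if denom == 0 else 200.0 * np.logical_and(a, b).sum() / denom
        out[f"class_{c}"] = float(d)
        vals.append(d)
    out["overall"] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# thickness & ETDRS
# ---------------------------------------------------------------------------

@dataclass
class ThicknessMap:
    """En-face retinal thickness samples (um) on the acquisition grid."""

    values_um: np.ndarray  # (n_scans, width)
    x_mm: np.ndarray       # (width,) lateral positions of cell centres
    y_mm: np.ndarray       # (n_scans,) scan positions of cell centres
    cell_area_mm2: float

    def __post_init__(self):
        if np.any(self.values_um < 0):
            raise ValueError("negative thickness (boundary order violated upstream)")


def thickness_map(boundaries: list, axial_res_um: float, lateral_res_um: float,
                  scan_spacing_um: float, center_mm=(0.0, 0.0)) -> ThicknessMap:
    """Per-(scan, column) total retinal thickness from per-scan boundaries.

    thickness = (rpe_row - ilm_row) * axial resolution; en-face positions
    come from column x lateral resolution and scan index x scan spacing,
    centred on ``center_mm`` (the fovea).
    """
    if not boundaries:
        raise ValueError("no boundary sets given")
    W = boundaries[0].width
    vals = np.empty((len(boundaries), W))
    for i, b in enumerate(boundaries):
        if b.width != W:
            raise ValueError("inconsistent scan widths")
        vals[i] = (b.rpe_rows - b.ilm_rows) * axial_res_um
    n = len(boundaries)
    x = (np.arange(W) - (W - 1) / 2.0) * lateral_res_um / 1000.0 - center_mm[0]
    y = (np.arange(n) - (n - 1) / 2.0) * scan_spacing_um / 1000.0 - center_mm[1]
    return ThicknessMap(values_um=vals, x_mm=x, y_mm=y,
                        cell_area_mm2=(lateral_res_um / 1000.0)
                        * (scan_spacing_um / 1000.0))


@dataclass
class EtdrsGrid:
    """Nine-subfield ETDRS macular grid (1 / 3 / 6 mm diameter rings).

    Quadrant boundaries run along the +-45 degree diagonals through the
    grid centre; cells exactly on a diagonal belong to the vertical
    (superior/inferior) quadrants.  ``superior`` is the -y half-plane
    (lower scan indices); for a right eye (OD) nasal is +x, for a left
    eye (OS) nasal is -x.
    """

    center_mm: tuple = (0.0, 0.0)
    diameters_mm: tuple = (1.0, 3.0, 6.0)
    laterality: str = "OD"

    def __post_init__(self):
        d = self.diameters_mm
        if not (0 < d[0] < d[1] < d[2]):
            raise ValueError("ring diameters must be strictly increasing")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    def subfields(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Subfield name per cell centre ('' outside the 6 mm disc).

        ``x_mm``, ``y_mm``: broadcastable en-face coordinate arrays.
        """
        x = np.atleast_1d(np.asarray(x_mm, dtype=float)) - self.center_mm[0]
        y = np.atleast_1d(np.asarray(y_mm, dtype=float)) - self.center_mm[1]
        x, y = np.broadcast_arrays(x, y)
        r = np.hypot(x, y)
        r0, r1, r2 = (d / 2.0 for d in self.diameters_mm)
        out = np.full(x.shape, "", dtype=object)
        vertical = np.abs(y) >= np.abs(x)  # diagonals -> superior/inferior
        nasal_sign = 1.0 if self.laterality == "OD" else -1.0
        quad = np.where(vertical,
                        np.where(y <= 0, "superior", "inferior"),
                        np.where(nasal_sign * x > 0, "nasal", "temporal"))
        inner = (r > r0) & (r <= r1)
        outer = (r > r1) & (r <= r2)
        out[r <= r0] = "central"
        out[inner] = np.char.add("inner_", quad[inner].astype(str))
        out[outer] = np.char.add("outer_", quad[outer].astype(str))
        return out


def etdrs_stats(tmap: ThicknessMap, grid: EtdrsGrid | None = None) -> pd.DataFrame:
    """Mean thickness (um) and volume (mm^3) per ETDRS subfield + totals.

    Samples are assigned to subfields by cell-centre membership; the
    subfield volume is the sum of thickness x cell area over its cells.
    The final row ("total") aggregates the whole 6 mm disc.  Raises if
    the thickness map does not cover the disc.
    """
    grid = grid or EtdrsGrid()
    x = tmap.x_mm[None, :]
    y = tmap.y_mm[:, None]
    r2 = grid.diameters_mm[2] / 2.0
    half_x = np.sqrt(tmap.cell_area_mm2)  # nominal half-cell slack
    if (tmap.x_mm.min() - grid.center_mm[0] > -r2 + half_x
            or tmap.x_mm.max() - grid.center_mm[0] < r2 - half_x
            or tmap.y_mm.min() - grid.center_mm[1] > -r2 + half_x
            or tmap.y_mm.max() - grid.center_mm[1] < r2 - half_x):
        raise ValueError(
            "thickness map does not cover the 6 mm ETDRS disc: en-face extent "
            f"x [{tmap.x_mm.min():.2f}, {tmap.x_mm.max():.2f}] mm, "
            f"y [{tmap.y_mm.min():.2f}, {tmap.y_mm.max():.2f}] mm"
        )
    names = grid.subfields(x, y)
    rows = []
    disc_vals = []
    for sf in SUBFIELDS:
        mask = names == sf
        v = tmap.values_um[mask]
        disc_vals.append(v)
        rows.append({
            "subfield": sf,
            "mean_thickness_um": float(v.mean()) if v.size else np.nan,
            "volume_mm3": float(v.sum() * 1e-3 * tmap.cell_area_mm2),
            "n_cells": int(v.size),
        })
    allv = np.concatenate(disc_vals)
    rows.append({
        "subfield": "total",
        "mean_thickness_um": float(allv.mean()),
        "volume_mm3": float(allv.sum() * 1e-3 * tmap.cell_area_mm2),
        "n_cells": int(allv.size),
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bland--Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(values_a, values_b) -> BlandAltmanResult:
    """Agreement between paired series: mean difference and limits of
    agreement at +-1.96 SD (SD with n-1 denominator)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D series required")
    if a.size < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    d = a - b
    sd = float(np.std(d, ddof=1))
    m = float(np.mean(d))
    return BlandAltmanResult(mean_diff=m, loa_lower=m - 1.96 * sd,
                             loa_upper=m + 1.96 * sd, sd_diff=sd,
                             n=int(a.size), means=(a + b) / 2.0, diffs=d)
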