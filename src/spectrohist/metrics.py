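"""Region-local baseline correction and spectral band metrics.

For each of the (default 42) spectral regions the spectrum segment is
baseline-corrected with the rubber-band method — subtraction of the
piecewise-linear lower convex hull — and summarized by three metrics:

* ``max``  — largest corrected absorbance in the region,
* ``cog``  — center of gravity, the intensity-weighted mean wavenumber
  ``sum(nu_i * A_i) / sum(A_i)``,
* ``area`` — trapezoidal integral of the corrected segment.

All metrics are then normalized to the corresponding metric of the Amide I
band (1762-1585 cm^-1), which removes multiplicative section-thickness
("size") effects; the Amide I region's own, identically-one columns are
dropped.  A 42-region table therefore yields 3 * 41 = 123 features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numba import njit
from scipy.ndimage import binary_erosion

from .cube_io import HyperCube, RegionTable

logger = logging.getLogger(__name__)

__all__ = [
    "rubberband_baseline",
    "region_metrics",
    "build_feature_table",
    "exclude_edge_pixels",
    "default_region_table",
    "feature_column_names",
]

METRIC_NAMES = ("max", "cog", "area")


# ---------------------------------------------------------------------------
# Default region table

_NAMED_REGIONS = [
    ("amide_A_B", 3000.0, 3600.0, False),
    ("ch_stretch_high", 2900.0, 3000.0, False),
    ("ch_stretch_low", 2800.0, 2900.0, False),
    ("amide_I", 1585.0, 1762.0, True),
    ("amide_II", 1473.0, 1585.0, False),
    ("collagen_1337", 1325.0, 1346.0, False),
    ("carb_1140_1180", 1140.0, 1180.0, False),
    ("dna_rna_980_1180", 980.0, 1180.0, False),
]

_N_DEFAULT_REGIONS = 42


def default_region_table() -> RegionTable:
    """The package's default 42-region table.

    Contains the biochemically named regions (Amide A+B, Amide I as the
    normalization band, Amide II, the collagen 1337 cm^-1 band, the
    1180-1140 cm^-1 band and the carbohydrate / nucleic-acid 1180-980 cm^-1
    window, plus the C-H stretch window) and a contiguous tiling of the
    900-1473 cm^-1 fingerprint region.  Fully replaceable via a TSV with the
    same schema.
    """
    names = [r[0] for r in _NAMED_REGIONS]
    lo = [r[1] for r in _NAMED_REGIONS]
    hi = [r[2] for r in _NAMED_REGIONS]
    flags = [r[3] for r in _NAMED_REGIONS]
    n_tiles = _N_DEFAULT_REGIONS - len(_NAMED_REGIONS)
    edges = np.linspace(900.0, 1473.0, n_tiles + 1)
    for i in range(n_tiles):
        a, b = round(edges[i], 1), round(edges[i + 1], 1)
        names.append(f"fp_{a:.0f}_{b:.0f}")
        lo.append(a)
        hi.append(b)
        flags.append(False)
    return RegionTable(names=names, lo=np.array(lo), hi=np.array(hi),
                       is_amide1=np.array(flags))


def default_region_table_path() -> str:
    """Path of the shipped TSV copy of the default region table."""
    from importlib.resources import files

    return str(files("spectrohist") / "data" / "regions_default.tsv")


def feature_column_names(table: RegionTable) -> list[str]:
    """Normalized-metric column names, region-major, Amide I dropped."""
    a1 = table.amide1_index
    return [
        f"{name}_{metric}"
        for i, name in enumerate(table.names)
        if i != a1
        for metric in METRIC_NAMES
    ]


# ---------------------------------------------------------------------------
# Rubber-band baseline

def rubberband_baseline(values: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Lower-convex-hull ("rubber band") baseline of one spectrum segment.

    The baseline is the piecewise-linear interpolation through the vertices
    of the lower convex hull of ``(axis, values)``, anchored at both
    endpoints; it never exceeds the data, and the corrected segment
    ``values - baseline`` is zero at every hull vertex.
    """
    values = np.asarray(values, dtype=np.float64)
    axis = np.asarray(axis, dtype=np.float64)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least 2 points for a baseline")
    if axis.shape != values.shape:
        raise ValueError("axis and values must have equal length")
    if np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be strictly increasing")
    hull = _lower_hull_indices(values, axis)
    return np.interp(axis, axis[hull], values[hull])


def _lower_hull_indices(values: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain lower hull over x-sorted points; collinear dropped."""
    m = values.size
    stack = np.empty(m, dtype=np.int64)
    k = 0
    for i in range(m):
        while k >= 2:
            o, a = stack[k - 2], stack[k - 1]
            cross = (axis[a] - axis[o]) * (values[i] - values[o]) - (
                values[a] - values[o]
            ) * (axis[i] - axis[o])
            if cross <= 0:
                k -= 1
            else:
                break
        stack[k] = i
        k += 1
    return stack[:k]


@njit(cache=True)
def _metrics_batch(seg: np.ndarray, x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-spectrum rubber-band correction + (max, cog, area) over a batch.

    seg: (n_pixels, m) raw segment values; x: (m,) ascending wavenumbers.
    """
    n, m = seg.shape
    out = np.empty((n, 3))
    stack = np.empty(m, np.int64)
    corrected = np.empty(m)
    for p in range(n):
        v = seg[p]
        k = 0
        for i in range(m):
            while k >= 2:
                o = stack[k - 2]
                a = stack[k - 1]
                cross = (x[a] - x[o]) * (v[i] - v[o]) - (v[a] - v[o]) * (x[i] - x[o])
                if cross <= 0.0:
                    k -= 1
                else:
                    break
            stack[k] = i
            k += 1
        # piecewise-linear baseline between consecutive hull vertices
        for s in range(k - 1):
            i0 = stack[s]
            i1 = stack[s + 1]
            slope = (v[i1] - v[i0]) / (x[i1] - x[i0])
            for t in range(i0, i1 + 1):
                c = v[t] - (v[i0] + slope * (x[t] - x[i0]))
                corrected[t] = c if c > 0.0 else 0.0
        vmax = 0.0
        s0 = 0.0
        s1 = 0.0
        area = 0.0
        for t in range(m):
            c = corrected[t]
            if c > vmax:
                vmax = c
            s0 += c
            s1 += x[t] * c
            if t + 1 < m:
                area += 0.5 * (c + corrected[t + 1]) * (x[t + 1] - x[t])
        cog = s1 / s0 if s0 > 0.0 else 0.5 * (lo + hi)
        out[p, 0] = vmax
        out[p, 1] = cog
        out[p, 2] = area
    return out


def _region_slice(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.flatnonzero((axis >= lo) & (axis <= hi))
    if idx.size == 0:
        raise ValueError(f"region [{lo}, {hi}] lies outside the axis range")
    if idx.size < 3:
        raise ValueError(f"region [{lo}, {hi}] covers fewer than 3 grid points")
    return idx


def region_metrics(
    spectrum: np.ndarray, axis: np.ndarray, region: tuple[float, float]
) -> tuple[float, float, float]:
    """(max, cog, area) of one baseline-corrected region of one spectrum.

    ``cog`` falls back to the region midpoint when the corrected segment has
    zero mass (flat or linear segment), keeping every feature finite.
    """
    lo, hi = float(region[0]), float(region[1])
    axis = np.asarray(axis, dtype=np.float64)
    spectrum = np.asarray(spectrum, dtype=np.float64)
    idx = _region_slice(axis, lo, hi)
    x = axis[idx]
    v = spectrum[idx]
    baseline = rubberband_baseline(v, x)
    c = np.maximum(v - baseline, 0.0)
    vmax = float(c.max())
    s0 = float(c.sum())
    if s0 > 0:
        cog = float((x * c).sum() / s0)
    else:
        cog = 0.5 * (lo + hi)
        logger.debug("degenerate cog (zero corrected mass) in region [%g, %g]", lo, hi)
    area = float(np.trapezoid(c, x))
    return vmax, cog, area


def exclude_edge_pixels(labels: np.ndarray | None, tissue_mask: np.ndarray) -> np.ndarray:
    """Interior tissue pixels: the mask eroded by one pixel (8-connectivity).

    Spectra at the tissue border mix tissue and substrate (and carry
    uncorrected scattering edge effects), so border pixels are excluded from
    training and validation; prediction maps may still cover them.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    interior = binary_erosion(tissue_mask, structure=np.ones((3, 3), dtype=bool),
                              border_value=0)
    return interior


def build_feature_table(
    cube: HyperCube,
    labels: np.ndarray | None,
    region_table: RegionTable,
    normalize_cog: bool = True,
) -> pd.DataFrame:
    """Amide-I-normalized spectral metrics for every tissue pixel of a cube.

    Returns a DataFrame with id columns ``mouse_id, row, col, label``
    followed by ``3 * (n_regions - 1)`` feature columns named
    ``<region>_<metric>``.  Pixels whose Amide I area is not positive cannot
    be normalized; they are dropped and counted in ``df.attrs['n_excluded']``.
    ``normalize_cog=False`` leaves band positions (cog) un-normalized, in
    cm^-1, while max and area stay Amide-I ratios.
    """
    axis = np.asarray(cube.axis, dtype=np.float64)
    mask = cube.tissue_mask
    rows, cols = np.nonzero(mask)
    n_pix = rows.size
    if n_pix == 0:
        cols_out = ["mouse_id", "row", "col", "label"] + feature_column_names(region_table)
        df = pd.DataFrame(columns=cols_out)
        df.attrs["n_excluded"] = 0
        return df
    flat = np.asarray(cube.data, dtype=np.float64)[rows, cols, :]

    raw = np.empty((len(region_table), n_pix, 3))
    for i, (name, lo, hi, _) in enumerate(region_table.rows()):
        idx = _region_slice(axis, lo, hi)
        seg = np.ascontiguousarray(flat[:, idx])
        raw[i] = _metrics_batch(seg, axis[idx], lo, hi)

    a1 = region_table.amide1_index
    norm = raw[a1]  # (n_pix, 3)
    valid = norm[:, 2] > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("%d pixels with nonpositive Amide I area excluded", n_excluded)
    if not valid.any():
        raise ValueError("every pixel has nonpositive Amide I area")

    feature_cols = feature_column_names(region_table)
    n_regions = len(region_table)
    feats = np.empty((int(valid.sum()), 3 * (n_regions - 1)))
    j = 0
    for i in range(n_regions):
        if i == a1:
            continue
        feats[:, 3 * j : 3 * j + 3] = raw[i][valid] / norm[valid]
        if not normalize_cog:
            feats[:, 3 * j + 1] = raw[i][valid][:, 1]
        j += 1

    lab = labels[rows, cols] if labels is not None else np.zeros(n_pix, dtype=int)
    df = pd.DataFrame(feats, columns=feature_cols)
    df.insert(0, "mouse_id", cube.mouse_id)
    df.insert(1, "row", rows[valid])
    df.insert(2, "col", cols[valid])
    df.insert(3, "label", lab[valid].astype(int))
    df.attrs["n_excluded"] = n_excluded
    return df
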