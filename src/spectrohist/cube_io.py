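"""I/O for hyperspectral cubes, label masks, region tables and feature tables.

The in-memory currency of the pipeline is :class:`HyperCube`: an ``H x W x B``
absorbance array with a strictly monotone wavenumber axis (stored ascending)
and a boolean tissue mask.  Cubes are persisted canonically as HDF5
(datasets ``/cube``, ``/wavenumbers``, ``/mask``; attributes ``mouse_id``,
``genotype``); ENVI header/binary pairs are supported read-only for
interoperability with IR-imaging tooling.  Region and feature tables travel
as TSV, label masks as 8-bit indexed PNG.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LABEL_CODES",
    "CLASS_NAMES",
    "HyperCube",
    "read_cube",
    "write_cube",
    "read_envi_cube",
    "read_region_table",
    "write_region_table",
    "write_feature_table",
    "read_feature_table",
    "write_label_png",
    "read_label_png",
]

#: fixed label code map shared by every mask in the pipeline
LABEL_CODES: dict[str, int] = {
    "background": 0,
    "benign": 1,
    "cancer": 2,
    "PanIN": 3,
    "inflammation": 4,
    "fiber": 5,
    "blood": 6,
    "necrosis": 7,
}

#: tissue classes (nonbackground), in code order
CLASS_NAMES: tuple[str, ...] = (
    "benign",
    "cancer",
    "PanIN",
    "inflammation",
    "fiber",
    "blood",
    "necrosis",
)

CODE_TO_NAME = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class HyperCube:
    """H x W x B absorbance cube with ascending wavenumber axis.

    Parameters
    ----------
    data : ndarray, shape (H, W, B)
        Absorbance values.
    axis : ndarray, shape (B,)
        Wavenumbers in cm^-1, strictly increasing.
    tissue_mask : ndarray of bool, shape (H, W), optional
        True where a pixel participates in the analysis.  Defaults to all
        True.
    mouse_id, genotype_tag : str
        Specimen metadata.
    """

    data: np.ndarray
    axis: np.ndarray
    tissue_mask: np.ndarray | None = None
    mouse_id: str = ""
    genotype_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.axis.ndim != 1 or self.axis.size != self.data.shape[2]:
            raise ValueError(
                f"axis length {self.axis.size} != band count {self.data.shape[2]}"
            )
        d = np.diff(self.axis)
        if np.any(d < 0):
            # store ascending; permute bands consistently
            order = np.argsort(self.axis, kind="stable")
            self.axis = self.axis[order]
            self.data = self.data[:, :, order]
            d = np.diff(self.axis)
        if np.any(d <= 0):
            raise ValueError("wavenumber axis must be strictly monotone (duplicates found)")
        if self.tissue_mask is None:
            self.tissue_mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != self.data.shape[:2]:
                raise ValueError("tissue_mask shape must match (H, W)")
        if np.isnan(self.data).any():
            raise ValueError("cube contains NaN")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "HyperCube":
        return HyperCube(
            self.data.copy(),
            self.axis.copy(),
            self.tissue_mask.copy(),
            self.mouse_id,
            self.genotype_tag,
        )


def write_cube(cube: HyperCube, path: str | os.PathLike) -> None:
    """Write a cube (plus mask and metadata) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data)
        f.create_dataset("wavenumbers", data=cube.axis)
        f.create_dataset("mask", data=cube.tissue_mask.astype(np.uint8))
        f.attrs["mouse_id"] = cube.mouse_id
        f.attrs["genotype"] = cube.genotype_tag


def read_cube(path: str | os.PathLike) -> HyperCube:
    """Read a cube from HDF5 (or from an ENVI header if *path* ends in .hdr).

    The axis is re-sorted ascending with the band dimension permuted
    consistently, so a round-trip through a descending-axis file preserves
    every (pixel, wavenumber, value) triple.
    """
    p = str(path)
    if p.endswith(".hdr"):
        return read_envi_cube(p)
    with h5py.File(path, "r") as f:
        if "cube" not in f:
            raise ValueError("HDF5 container missing dataset '/cube'")
        if "wavenumbers" not in f:
            raise ValueError("HDF5 container missing dataset '/wavenumbers'")
        data = f["cube"][...]
        axis = f["wavenumbers"][...]
        if axis.shape[0] != data.shape[2]:
            raise ValueError(
                f"shape mismatch: /cube has {data.shape[2]} bands but "
                f"/wavenumbers has {axis.shape[0]}"
            )
        mask = f["mask"][...].astype(bool) if "mask" in f else None
        mouse_id = str(f.attrs.get("mouse_id", ""))
        genotype = str(f.attrs.get("genotype", ""))
    return HyperCube(data, axis, mask, mouse_id, genotype)


# ---------------------------------------------------------------------------
# ENVI (read-only)

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}


def _parse_envi_header(path: str) -> dict:
    text = open(path).read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1]
    # collapse { ... } blocks onto one logical line
    i = 0
    lines = []
    while i < len(body):
        j = body.find("\n", i)
        if j < 0:
            j = len(body)
        line = body[i:j]
        if "{" in line and "}" not in line:
            k = body.find("}", i)
            if k < 0:
                raise ValueError("unterminated { in ENVI header")
            line = body[i : k + 1].replace("\n", " ")
            j = body.find("\n", k)
            if j < 0:
                j = len(body)
        lines.append(line)
        i = j + 1
    for line in lines:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip().strip("{}").strip()
    return fields


def read_envi_cube(hdr_path: str | os.PathLike) -> HyperCube:
    """Read an ENVI header + flat-binary pair (BSQ, BIL or BIP interleave)."""
    hdr_path = str(hdr_path)
    h = _parse_envi_header(hdr_path)
    samples = int(h["samples"])  # W
    lines_n = int(h["lines"])    # H
    bands = int(h["bands"])      # B
    dtype = _ENVI_DTYPES[int(h["data type"])]
    interleave = h.get("interleave", "bsq").lower()
    offset = int(h.get("header offset", 0))
    byte_order = int(h.get("byte order", 0))
    base = hdr_path[:-4] if hdr_path.endswith(".hdr") else hdr_path
    for ext in (".dat", ".img", ".bin", ""):
        data_path = base + ext
        if os.path.exists(data_path) and data_path != hdr_path:
            break
    else:  # pragma: no cover - defensive
        raise FileNotFoundError(f"no ENVI binary found for {hdr_path}")
    raw = np.fromfile(data_path, dtype=dtype, offset=offset,
                      count=samples * lines_n * bands)
    if byte_order == 1:
        raw = raw.byteswap()
    if interleave == "bsq":
        data = raw.reshape(bands, lines_n, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines_n, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines_n, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    if "wavelength" not in h:
        raise ValueError("ENVI header missing 'wavelength' field")
    axis = np.array([float(x) for x in h["wavelength"].split(",")])
    return HyperCube(np.ascontiguousarray(data.astype(np.float64)), axis)


# ---------------------------------------------------------------------------
# Region tables


@dataclass
class RegionTable:
    """Ordered list of named wavenumber intervals; exactly one is Amide I."""

    names: list[str]
    lo: np.ndarray
    hi: np.ndarray
    is_amide1: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        n = len(self.names)
        if self.lo.shape != (n,) or self.hi.shape != (n,):
            raise ValueError("names, lo, hi must have equal length")
        if np.any(self.lo >= self.hi):
            bad = self.names[int(np.argmax(self.lo >= self.hi))]
            raise ValueError(f"region {bad!r} has lo >= hi")
        if self.is_amide1 is None:
            self.is_amide1 = np.zeros(n, dtype=bool)
        self.is_amide1 = np.asarray(self.is_amide1, dtype=bool)
        n_a1 = int(self.is_amide1.sum())
        if n_a1 != 1:
            raise ValueError(f"region table must flag exactly one Amide I row, found {n_a1}")
        if len(set(self.names)) != n:
            raise ValueError("duplicate region names")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def amide1_index(self) -> int:
        return int(np.flatnonzero(self.is_amide1)[0])

    def rows(self):
        for i, name in enumerate(self.names):
            yield name, float(self.lo[i]), float(self.hi[i]), bool(self.is_amide1[i])


def read_region_table(path: str | os.PathLike) -> RegionTable:
    """Read a region table TSV/CSV with columns name, lo_cm1, hi_cm1[, is_amide1]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip() for c in df.columns]
    for col in ("name", "lo_cm1", "hi_cm1"):
        if col not in df.columns:
            raise ValueError(f"region table missing column {col!r}")
    if "is_amide1" in df.columns:
        flags = df["is_amide1"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        ).to_numpy()
    else:
        flags = None
    return RegionTable(
        names=[str(n).strip() for n in df["name"]],
        lo=df["lo_cm1"].to_numpy(float),
        hi=df["hi_cm1"].to_numpy(float),
        is_amide1=flags,
    )


def write_region_table(table: RegionTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "name": table.names,
            "lo_cm1": table.lo,
            "hi_cm1": table.hi,
            "is_amide1": ["true" if f else "false" for f in table.is_amide1],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature tables

ID_COLUMNS = ("mouse_id", "row", "col", "label")


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a pixels x metrics table as TSV, 12 significant digits."""
    cols = list(table.columns)
    feat = [c for c in cols if c not in ID_COLUMNS]
    if len(set(feat)) != len(feat):
        raise ValueError("duplicate feature column names")
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    feat = [c for c in df.columns if c not in ID_COLUMNS]
    for c in feat:
        vals = pd.to_numeric(df[c], errors="coerce")
        if df[c].notna().any() and vals.isna().any() and len(df):
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(f"non-numeric value in feature column {c!r} at row {bad}")
        df[c] = vals
    return df


# ---------------------------------------------------------------------------
# Label masks as indexed PNG

_PALETTE = [
    (0, 0, 0),        # background
    (96, 200, 96),    # benign
    (220, 40, 40),    # cancer
    (250, 160, 30),   # PanIN
    (160, 90, 200),   # inflammation
    (70, 130, 220),   # fiber
    (150, 30, 30),    # blood
    (120, 120, 120),  # necrosis
]


def write_label_png(labels: np.ndarray, path: str | os.PathLike) -> None:
    from PIL import Image

    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 7:
        raise ValueError("label codes must be in [0, 7]")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    pal: list[int] = []
    for rgb in _PALETTE:
        pal.extend(rgb)
    img.putpalette(pal + [0] * (768 - len(pal)))
    img.save(path)


def read_label_png(path: str | os.PathLike) -> np.ndarray:
    from PIL import Image

    img = Image.open(path)
    return np.asarray(img, dtype=np.int32)
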