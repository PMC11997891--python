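"""Synthetic hyperspectral phantoms of pancreatic tissue sections.

This module generates cohorts of mouse-like specimens with the statistical
structure the downstream pipeline assumes: per-class mid-IR absorbance
spectra built from Gaussian bands (Amide A+B, Amide I, Amide II, collagen
1337 cm^-1, carbohydrate / nucleic-acid bands), spatially contiguous class
regions, a multiplicative thickness ("size") field, smooth baseline drift,
spatially correlated plus white noise, and a per-mouse multiplicative batch
effect on band amplitudes.  Genotype tags follow the murine models of
pancreatic neoplasia: ``control`` animals carry no lesions, ``KC`` animals
carry PanIN (pancreatic intraepithelial neoplasia), and ``KPC`` animals
carry both PanIN and invasive cancer.

Every phantom also stores its noise-free cube so denoising quality can be
measured against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .cube_io import CLASS_NAMES, LABEL_CODES, HyperCube

__all__ = [
    "ClassSpectrumModel",
    "PhantomParams",
    "MousePhantom",
    "Cohort",
    "default_class_models",
    "scale_separability",
    "make_class_spectrum",
    "make_label_mask",
    "make_phantom",
    "make_cohort",
    "DEFAULT_GENOTYPE_MIX",
]

AXIS_LO, AXIS_HI = 900.0, 3850.0
AMIDE1_LO, AMIDE1_HI = 1585.0, 1762.0

#: absorbance of background (off-tissue) pixels before noise
BACKGROUND_LEVEL = 0.02


@dataclass(frozen=True)
class ClassSpectrumModel:
    """Gaussian-band spectral model for one tissue class.

    ``bands`` is a list of ``(center_cm1, width_cm1, amplitude)`` Gaussian
    components (width is the Gaussian sigma); ``baseline_coeffs`` are
    polynomial coefficients of a smooth drift evaluated on the axis mapped
    to [0, 1] (constant term first).
    """

    class_name: str
    bands: tuple[tuple[float, float, float], ...]
    baseline_coeffs: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("band list must not be empty")
        amide1 = False
        for c, w, a in self.bands:
            if a < 0:
                raise ValueError(f"negative amplitude in class {self.class_name!r}")
            if not (AXIS_LO <= c <= AXIS_HI):
                raise ValueError(
                    f"band center {c} outside [{AXIS_LO}, {AXIS_HI}] "
                    f"in class {self.class_name!r}"
                )
            if w <= 0:
                raise ValueError("band width must be positive")
            if AMIDE1_LO <= c <= AMIDE1_HI and a > 0:
                amide1 = True
        if not amide1:
            raise ValueError(
                f"class {self.class_name!r} lacks an Amide I component "
                f"(center in [{AMIDE1_LO}, {AMIDE1_HI}], amplitude > 0)"
            )


# Shared band skeleton: (name, center, sigma).  Classes differ only in
# amplitudes, which keeps between-class contrast a single interpolatable dial.
_BAND_SKELETON: tuple[tuple[str, float, float], ...] = (
    ("amide_AB", 3290.0, 110.0),
    ("ch3_stretch", 2958.0, 18.0),
    ("ch2_stretch", 2925.0, 16.0),
    ("ester_carbonyl", 1742.0, 12.0),
    ("amide_I", 1655.0, 28.0),
    ("amide_II", 1548.0, 26.0),
    ("ch_bend", 1455.0, 18.0),
    ("coo_sym", 1395.0, 16.0),
    ("collagen_1337", 1337.0, 11.0),
    ("amide_III", 1240.0, 22.0),
    ("collagen_1204", 1204.0, 12.0),
    ("carb_1160", 1160.0, 13.0),
    ("po2_1080", 1080.0, 20.0),
    ("carb_1030", 1030.0, 16.0),
)

# Per-class band amplitudes (absorbance at band center).  Benign acinar
# tissue is the reference; the others shift protein, collagen, lipid,
# carbohydrate and nucleic-acid contributions the way the corresponding
# histological classes do qualitatively.
_CLASS_AMPLITUDES: dict[str, dict[str, float]] = {
    "benign": dict(
        amide_AB=0.55, ch3_stretch=0.10, ch2_stretch=0.12, ester_carbonyl=0.04,
        amide_I=1.00, amide_II=0.55, ch_bend=0.18, coo_sym=0.14,
        collagen_1337=0.06, amide_III=0.14, collagen_1204=0.02,
        carb_1160=0.08, po2_1080=0.12, carb_1030=0.10,
    ),
    "cancer": dict(
        amide_AB=0.57, ch3_stretch=0.09, ch2_stretch=0.10, ester_carbonyl=0.03,
        amide_I=1.00, amide_II=0.66, ch_bend=0.17, coo_sym=0.12,
        collagen_1337=0.05, amide_III=0.19, collagen_1204=0.03,
        carb_1160=0.05, po2_1080=0.26, carb_1030=0.04,
    ),
    "PanIN": dict(
        amide_AB=0.55, ch3_stretch=0.10, ch2_stretch=0.11, ester_carbonyl=0.04,
        amide_I=1.00, amide_II=0.58, ch_bend=0.18, coo_sym=0.13,
        collagen_1337=0.06, amide_III=0.15, collagen_1204=0.02,
        carb_1160=0.14, po2_1080=0.17, carb_1030=0.20,
    ),
    "inflammation": dict(
        amide_AB=0.60, ch3_stretch=0.10, ch2_stretch=0.12, ester_carbonyl=0.04,
        amide_I=1.00, amide_II=0.52, ch_bend=0.16, coo_sym=0.10,
        collagen_1337=0.04, amide_III=0.13, collagen_1204=0.02,
        carb_1160=0.07, po2_1080=0.19, carb_1030=0.07,
    ),
    "fiber": dict(
        amide_AB=0.52, ch3_stretch=0.09, ch2_stretch=0.08, ester_carbonyl=0.03,
        amide_I=1.00, amide_II=0.60, ch_bend=0.19, coo_sym=0.15,
        collagen_1337=0.16, amide_III=0.22, collagen_1204=0.10,
        carb_1160=0.13, po2_1080=0.08, carb_1030=0.08,
    ),
    "blood": dict(
        amide_AB=0.62, ch3_stretch=0.08, ch2_stretch=0.09, ester_carbonyl=0.02,
        amide_I=1.05, amide_II=0.65, ch_bend=0.15, coo_sym=0.10,
        collagen_1337=0.03, amide_III=0.10, collagen_1204=0.01,
        carb_1160=0.04, po2_1080=0.06, carb_1030=0.04,
    ),
    "necrosis": dict(
        amide_AB=0.45, ch3_stretch=0.14, ch2_stretch=0.18, ester_carbonyl=0.12,
        amide_I=0.90, amide_II=0.45, ch_bend=0.17, coo_sym=0.11,
        collagen_1337=0.04, amide_III=0.11, collagen_1204=0.02,
        carb_1160=0.06, po2_1080=0.09, carb_1030=0.06,
    ),
}

_CLASS_BASELINES: dict[str, tuple[float, ...]] = {
    "benign": (0.020, 0.010, 0.0),
    "cancer": (0.025, 0.012, -0.005),
    "PanIN": (0.022, 0.008, 0.004),
    "inflammation": (0.018, 0.014, 0.0),
    "fiber": (0.024, 0.006, 0.006),
    "blood": (0.030, 0.015, -0.008),
    "necrosis": (0.016, 0.009, 0.002),
}


def default_class_models() -> list[ClassSpectrumModel]:
    """Spectral models for the seven tissue classes, benign as reference."""
    models = []
    for name in CLASS_NAMES:
        amps = _CLASS_AMPLITUDES[name]
        bands = tuple(
            (center, width, amps[bname]) for bname, center, width in _BAND_SKELETON
        )
        models.append(
            ClassSpectrumModel(name, bands, _CLASS_BASELINES[name])
        )
    return models


def scale_separability(
    models: list[ClassSpectrumModel], separability: float
) -> list[ClassSpectrumModel]:
    """Interpolate class band amplitudes toward the benign reference.

    ``separability=1`` returns the models unchanged; ``separability=0``
    collapses every class onto the benign spectrum, driving downstream
    pixel classification to chance.
    """
    ref = {m.class_name: m for m in models}["benign"]
    out = []
    for m in models:
        bands = tuple(
            (c, w, ra + separability * (a - ra))
            for (c, w, a), (_, _, ra) in zip(m.bands, ref.bands)
        )
        out.append(replace(m, bands=bands))
    return out


@dataclass
class PhantomParams:
    """Generation parameters for one cohort of phantoms.

    Defaults emulate the measurement geometry of a 64 x 64 focal-plane-array
    FT-IR acquisition over 3850-900 cm^-1.  The 4 cm^-1 axis spacing is the
    effective point spacing of an 8 cm^-1-resolution interferogram with one
    level of zero filling.
    """

    image_size: tuple[int, int] = (64, 64)
    axis_range: tuple[float, float] = (AXIS_LO, AXIS_HI)
    axis_spacing: float = 4.0
    class_fractions: dict[str, float] | None = None
    thickness_range: tuple[float, float] = (0.6, 1.4)
    noise_sigma_white: float = 0.008
    noise_sigma_corr: float = 0.004
    noise_corr_length: float = 3.0
    mouse_effect_sigma: float = 0.05
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_spacing <= 0:
            raise ValueError("axis_spacing must be positive")
        for s in (self.noise_sigma_white, self.noise_sigma_corr, self.mouse_effect_sigma):
            if s < 0:
                raise ValueError("noise/batch sigmas must be nonnegative")
        if self.class_fractions is not None:
            fr = self.class_fractions
            if any(v < 0 for v in fr.values()):
                raise ValueError("class fractions must be nonnegative")
            if sum(fr.values()) > 1 + 1e-12:
                raise ValueError("class fractions must sum to <= 1")
        if self.thickness_range[0] > self.thickness_range[1]:
            raise ValueError("thickness_range must be (lo, hi) with lo <= hi")

    def wavenumber_axis(self) -> np.ndarray:
        lo, hi = self.axis_range
        n = int(np.floor((hi - lo) / self.axis_spacing)) + 1
        return lo + self.axis_spacing * np.arange(n)


@dataclass
class MousePhantom:
    mouse_id: str
    genotype_tag: str
    cube: HyperCube
    labels: np.ndarray
    clean_cube: HyperCube

    def __post_init__(self) -> None:
        if self.labels.shape != self.cube.data.shape[:2]:
            raise ValueError("labels and cube must share (H, W)")
        if self.clean_cube.data.shape != self.cube.data.shape:
            raise ValueError("clean_cube must match cube shape")


@dataclass
class Cohort:
    mice: list[MousePhantom]
    tissue_truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.mouse_id for m in self.mice]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mouse_id in cohort")
        if not self.tissue_truth:
            self.tissue_truth = {m.mouse_id: _truth_from_labels(m.labels) for m in self.mice}
        missing = set(ids) - set(self.tissue_truth)
        if missing:
            raise ValueError(f"tissue_truth missing mice: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.mice)


def _truth_from_labels(labels: np.ndarray) -> str:
    path_codes = (LABEL_CODES["cancer"], LABEL_CODES["PanIN"])
    return "pathological" if np.isin(labels, path_codes).any() else "healthy"


def make_class_spectrum(model: ClassSpectrumModel, axis: np.ndarray) -> np.ndarray:
    """Evaluate a class model on a wavenumber axis: sum of Gaussians + drift."""
    axis = np.asarray(axis, dtype=np.float64)
    if axis.ndim != 1 or axis.size == 0:
        raise ValueError("axis must be a nonempty 1-D array")
    d = np.diff(axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be strictly monotone")
    if axis.min() < AXIS_LO - 1e-9 or axis.max() > AXIS_HI + 1e-9:
        raise ValueError(f"axis outside supported range [{AXIS_LO}, {AXIS_HI}]")
    spec = np.zeros_like(axis)
    for c, w, a in model.bands:
        spec += a * np.exp(-0.5 * ((axis - c) / w) ** 2)
    t = (axis - AXIS_LO) / (AXIS_HI - AXIS_LO)
    drift = np.zeros_like(axis)
    for p, coeff in enumerate(model.baseline_coeffs):
        drift += coeff * t**p
    return np.maximum(spec + drift, 0.0)


def make_label_mask(
    shape: tuple[int, int],
    class_fractions: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Seeded contiguous class blobs grown by dilation; remainder is background.

    Each class ends up with exactly ``round(fraction * H * W)`` pixels, so
    the realized area matches the requested fraction to well within 2%.
    """
    H, W = shape
    total = H * W
    if sum(class_fractions.values()) > 1 + 1e-12:
        raise ValueError("class fractions sum to > 1")
    targets = {c: int(round(f * total)) for c, f in class_fractions.items() if f > 0}
    if sum(targets.values()) > total:
        raise ValueError("image too small to honor requested fractions")
    for c in targets:
        if c not in LABEL_CODES:
            raise ValueError(f"unknown class {c!r}")
    labels = np.zeros((H, W), dtype=np.int16)
    struct = np.ones((3, 3), dtype=bool)
    # seed each class at a random interior position, largest classes first so
    # small ones are not starved of space
    order = sorted(targets, key=lambda c: -targets[c])
    counts = dict.fromkeys(order, 0)
    margin_h, margin_w = max(1, H // 8), max(1, W // 8)
    for c in order:
        for _ in range(200):
            r = int(rng.integers(margin_h, H - margin_h))
            q = int(rng.integers(margin_w, W - margin_w))
            if labels[r, q] == 0:
                labels[r, q] = LABEL_CODES[c]
                counts[c] = 1
                break
        else:  # pragma: no cover - only on absurdly full images
            raise ValueError("could not place class seed; image too full")
    active = [c for c in order if counts[c] < targets[c]]
    while active:
        for c in list(active):
            need = targets[c] - counts[c]
            if need <= 0:
                active.remove(c)
                continue
            blob = labels == LABEL_CODES[c]
            grown = binary_dilation(blob, structure=struct) & (labels == 0)
            cand = np.flatnonzero(grown.ravel())
            if cand.size == 0:
                # enclosed blob: restart growth from a fresh unassigned pixel
                free = np.flatnonzero(labels.ravel() == 0)
                if free.size == 0:
                    raise ValueError("image too small to honor requested fractions")
                pick = free[int(rng.integers(free.size))]
                labels.ravel()[pick] = LABEL_CODES[c]
                counts[c] += 1
                continue
            if cand.size > need:
                cand = rng.choice(cand, size=need, replace=False)
            labels.ravel()[cand] = LABEL_CODES[c]
            counts[c] += cand.size
    return labels


def _smooth_field(
    shape: tuple[int, int], rng: np.random.Generator, corr_length: float
) -> np.ndarray:
    f = rng.standard_normal(shape)
    f = gaussian_filter(f, sigma=corr_length, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def make_phantom(
    params: PhantomParams,
    class_models: list[ClassSpectrumModel],
    mouse_id: str,
    genotype_tag: str,
    rng: np.random.Generator,
) -> MousePhantom:
    """Generate one specimen: labels, clean cube and noisy cube.

    Per-pixel spectrum = thickness x (class spectrum with per-mouse band
    amplitude perturbation) + correlated noise + white noise.  The clean
    cube keeps the thickness- and batch-scaled signal without noise.
    """
    if params.class_fractions is None:
        raise ValueError("params.class_fractions must be set for make_phantom")
    models = {m.class_name: m for m in class_models}
    unknown = set(params.class_fractions) - set(models)
    if unknown:
        raise ValueError(f"class_fractions reference unknown models: {sorted(unknown)}")
    H, W = params.image_size
    axis = params.wavenumber_axis()
    B = axis.size

    labels = make_label_mask((H, W), params.class_fractions, rng)
    tissue = labels > 0

    # per-mouse batch effect: one log-normal factor per band component,
    # shared across classes (the skeleton aligns components across classes)
    n_comp = len(class_models[0].bands)
    batch = np.exp(params.mouse_effect_sigma * rng.standard_normal(n_comp))

    spectra = np.zeros((8, B))
    spectra[0] = BACKGROUND_LEVEL
    for name, model in models.items():
        if len(model.bands) == n_comp:
            perturbed = replace(
                model,
                bands=tuple(
                    (c, w, a * f) for (c, w, a), f in zip(model.bands, batch)
                ),
            )
        else:  # models with non-aligned band lists: perturb uniformly
            perturbed = replace(
                model,
                bands=tuple((c, w, a * batch[0]) for c, w, a in model.bands),
            )
        spectra[LABEL_CODES[name]] = make_class_spectrum(perturbed, axis)

    lo, hi = params.thickness_range
    if hi > lo:
        f = _smooth_field((H, W), rng, corr_length=max(H, W) / 8)
        fmin, fmax = f.min(), f.max()
        thickness = lo + (hi - lo) * (f - fmin) / (fmax - fmin)
    else:
        thickness = np.full((H, W), lo)
    thickness = np.where(tissue, thickness, 1.0)

    clean = spectra[labels] * thickness[:, :, None]
    clean = clean.astype(np.float32)

    data = clean.copy()
    if params.noise_sigma_corr > 0:
        noise = rng.standard_normal((H, W, B)).astype(np.float32)
        for b in range(0, B, 64):  # chunked spatial smoothing to bound memory
            noise[:, :, b : b + 64] = gaussian_filter(
                noise[:, :, b : b + 64],
                sigma=(params.noise_corr_length, params.noise_corr_length, 0),
                mode="reflect",
            )
        s = noise.std()
        if s > 0:
            data += (params.noise_sigma_corr / s) * noise
        del noise
    if params.noise_sigma_white > 0:
        data += params.noise_sigma_white * rng.standard_normal((H, W, B)).astype(
            np.float32
        )

    cube = HyperCube(data, axis, tissue.copy(), mouse_id, genotype_tag)
    clean_cube = HyperCube(clean, axis, tissue.copy(), mouse_id, genotype_tag)
    return MousePhantom(mouse_id, genotype_tag, cube, labels, clean_cube)


#: class area fractions by genotype; remainder of the frame is background
GENOTYPE_FRACTIONS: dict[str, dict[str, float]] = {
    "control": {"benign": 0.50, "fiber": 0.05, "inflammation": 0.04, "blood": 0.03},
    "KC": {
        "benign": 0.34, "PanIN": 0.12, "fiber": 0.08,
        "inflammation": 0.06, "blood": 0.03,
    },
    "KPC": {
        "benign": 0.22, "cancer": 0.13, "PanIN": 0.08, "fiber": 0.10,
        "inflammation": 0.05, "blood": 0.03, "necrosis": 0.04,
    },
}

#: 19-mouse default cohort composition
DEFAULT_GENOTYPE_MIX: dict[str, int] = {"control": 5, "KC": 7, "KPC": 7}


def make_cohort(
    n_mice: int = 19,
    genotype_mix: dict[str, int] | None = None,
    params: PhantomParams | None = None,
    seed: int = 0,
    class_models: list[ClassSpectrumModel] | None = None,
) -> Cohort:
    """Generate a cohort of phantoms with per-mouse seeds derived from *seed*."""
    if n_mice < 2:
        raise ValueError("need at least 2 mice for cross-validation")
    if genotype_mix is None:
        genotype_mix = dict(DEFAULT_GENOTYPE_MIX)
    if sum(genotype_mix.values()) != n_mice:
        raise ValueError("genotype_mix counts must sum to n_mice")
    if params is None:
        params = PhantomParams(seed=seed)
    if class_models is None:
        class_models = default_class_models()
    if params.separability != 1.0:
        class_models = scale_separability(class_models, params.separability)

    ss = np.random.SeedSequence([seed, 0x5FC7])
    child_seeds = ss.spawn(n_mice)
    mice: list[MousePhantom] = []
    i = 0
    for tag in ("control", "KC", "KPC"):
        for _ in range(genotype_mix.get(tag, 0)):
            p = replace(
                params,
                class_fractions=(
                    params.class_fractions
                    if params.class_fractions is not None
                    else dict(GENOTYPE_FRACTIONS[tag])
                ),
            )
            rng = np.random.default_rng(child_seeds[i])
            mice.append(make_phantom(p, class_models, f"m{i + 1:02d}", tag, rng))
            i += 1
    for tag in genotype_mix:
        if tag not in ("control", "KC", "KPC"):
            raise ValueError(f"unknown genotype tag {tag!r}")
    return Cohort(mice=mice)
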