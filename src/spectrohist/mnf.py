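"""Minimum Noise Fraction (MNF) denoising of hyperspectral cubes.

MNF orders linear spectral components by signal-to-noise ratio via the
generalized eigenproblem of the data covariance against a noise covariance
estimated from neighbor-pixel spectral differences (shift-difference
estimator).  Truncating to the top components and inverting the transform
removes noise while retaining the spectral structure; 20 retained bands is
the pipeline default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .cube_io import HyperCube

__all__ = ["MnfModel", "estimate_noise_covariance", "fit_mnf", "mnf_denoise"]


@dataclass
class MnfModel:
    """Fitted MNF transform for one cube.

    ``forward`` maps mean-centered spectra (rows) to MNF scores
    (``scores = X_c @ forward``); ``inverse`` maps scores back
    (``X_c = scores @ inverse``).  ``eigvals`` are the per-component
    signal-to-noise eigenvalues, descending.
    """

    noise_cov: np.ndarray
    data_cov: np.ndarray
    eigvals: np.ndarray
    forward: np.ndarray
    inverse: np.ndarray
    mean_spectrum: np.ndarray


def estimate_noise_covariance(cube: HyperCube, mask: np.ndarray | None = None) -> np.ndarray:
    """Noise covariance from horizontal/vertical neighbor-difference spectra.

    The difference of two adjacent pixels cancels (locally constant) signal
    and doubles noise variance, so the covariance of differences over all
    fully-masked pairs, divided by 2, estimates the per-band noise
    covariance.  Symmetric PSD by construction.
    """
    data = np.asarray(cube.data, dtype=np.float64)
    if mask is None:
        mask = cube.tissue_mask
    mask = np.asarray(mask, dtype=bool)
    dh = data[:, 1:, :] - data[:, :-1, :]
    mh = mask[:, 1:] & mask[:, :-1]
    dv = data[1:, :, :] - data[:-1, :, :]
    mv = mask[1:, :] & mask[:-1, :]
    diffs = np.concatenate([dh[mh], dv[mv]], axis=0)
    if diffs.shape[0] < 1:
        raise ValueError("mask admits no adjacent pixel pairs for noise estimation")
    diffs = diffs - diffs.mean(axis=0, keepdims=True)
    n = diffs.shape[0]
    denom = max(n - 1, 1)
    cov = (diffs.T @ diffs) / denom / 2.0
    return (cov + cov.T) / 2.0


def fit_mnf(cube: HyperCube, mask: np.ndarray | None = None) -> MnfModel:
    """Fit the MNF transform on masked pixels of a cube."""
    if mask is None:
        mask = cube.tissue_mask
    mask = np.asarray(mask, dtype=bool)
    X = np.asarray(cube.data, dtype=np.float64)[mask]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 masked pixels to fit MNF")
    B = X.shape[1]
    mean = X.mean(axis=0)
    Xc = X - mean
    data_cov = (Xc.T @ Xc) / max(X.shape[0] - 1, 1)
    data_cov = (data_cov + data_cov.T) / 2.0
    noise_cov = estimate_noise_covariance(cube, mask)

    # ridge keeps the generalized eigenproblem well-posed when phantom noise
    # is (near-)singular; scaled to the problem so MNF stays linear in the data
    ridge = 1e-10 * np.trace(noise_cov) / B + 1e-12 * np.trace(data_cov) / B
    if ridge == 0.0:
        # perfectly constant cube: identity transform
        eye = np.eye(B)
        return MnfModel(noise_cov, data_cov, np.zeros(B), eye, eye, mean)
    noise_reg = noise_cov + ridge * np.eye(B)

    eigvals, vecs = scipy.linalg.eigh(data_cov, noise_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    vecs = vecs[:, order]  # columns normalized so V.T @ noise_reg @ V = I
    inverse = np.linalg.inv(vecs)
    return MnfModel(noise_cov, data_cov, eigvals, vecs, inverse, mean)


def mnf_denoise(
    cube: HyperCube,
    mask: np.ndarray | None = None,
    k: int = 20,
    model: MnfModel | None = None,
) -> HyperCube:
    """Project masked pixels onto the top-*k* MNF components and back.

    Unmasked pixels pass through unchanged.  ``k`` equal to the band count
    reproduces the input (up to floating point).
    """
    B = cube.data.shape[2]
    if not (1 <= k <= B):
        raise ValueError(f"k must be in [1, {B}], got {k}")
    if mask is None:
        mask = cube.tissue_mask
    mask = np.asarray(mask, dtype=bool)
    if model is None:
        model = fit_mnf(cube, mask)
    X = np.asarray(cube.data, dtype=np.float64)[mask]
    Xc = X - model.mean_spectrum
    scores = Xc @ model.forward[:, :k]
    recon = scores @ model.inverse[:k, :] + model.mean_spectrum
    out = cube.data.astype(np.float64, copy=True)
    out[mask] = recon
    return HyperCube(
        out.astype(cube.data.dtype) if cube.data.dtype != np.float64 else out,
        cube.axis.copy(),
        cube.tissue_mask.copy(),
        cube.mouse_id,
        cube.genotype_tag,
    )
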