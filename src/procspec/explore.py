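"""Exploratory diagnostics: wavelength-wise moisture correlation and trajectory PCA.

Two diagnostics motivate the calibration strategy. First, the Pearson
correlation of each spectral variable with the reference moisture content:
in this process every wavelength correlates strongly with moisture — not just
the water bands — because water alters the powder's refractive properties and
shifts the whole spectrum. Time-domain smoothing removes turbulence noise and
makes the correlation still more distinct. Second, PCA of the augmented
(row-concatenated) multi-batch matrix places all batch trajectories in one
factor space; the first component tracks moisture while the second describes
turbulence, and the near-identity of their loadings is the spectral
fingerprint of the scatter/moisture entanglement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .dataset import PairedData, ProcessDataset, pair_campaign

__all__ = [
    "CorrelationSpectrum",
    "SpectralPCA",
    "correlation_spectrum",
    "fit_pca",
    "scores_vs_time",
    "loading_similarity",
]


@dataclass
class CorrelationSpectrum:
    """Pearson r between moisture and intensity, per wavelength.

    ``r`` is NaN where the correlation is undefined (zero variance in that
    spectral variable); undefined is reported as missing, never as 0.
    """

    wavelengths: np.ndarray
    r: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength_nm": self.wavelengths, "r": self.r})


def correlation_spectrum(
    data: PairedData | ProcessDataset,
    smoother=None,
    batch_ids=None,
) -> CorrelationSpectrum:
    """Wavelength-wise Pearson correlation between LOD and spectral intensity.

    Pass a :class:`ProcessDataset` to smooth each batch stream before pairing
    (``smoother`` = odd window width k or a TimeSmoother); pass a
    :class:`PairedData` to correlate as-is (``smoother`` must then be None,
    because pairing has already discarded the stream).
    """
    if isinstance(data, ProcessDataset):
        paired = pair_campaign(data, smoother=smoother, batch_ids=batch_ids)
    else:
        if smoother is not None:
            raise ValueError(
                "smoothing needs the full batch streams: pass a ProcessDataset"
            )
        paired = data
    n = paired.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 paired samples, got {n}")
    y = paired.lod - paired.lod.mean()
    sy = np.sqrt(y @ y)
    if sy == 0:
        raise ValueError("zero variance in LOD values: correlation undefined")
    Xc = paired.spectra - paired.spectra.mean(axis=0)
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ y) / (sx * sy)
    r[sx == 0] = np.nan
    return CorrelationSpectrum(wavelengths=paired.wavelengths, r=r, n=n)


class SpectralPCA(BaseEstimator):
    """Column-mean-centered PCA of a spectra matrix with a fixed sign convention.

    The sign of each component is chosen so that the loading element of
    largest magnitude is positive, making scores and loadings reproducible
    across SVD implementations.

    Attributes
    ----------
    mean_ : ndarray (p,) — center spectrum.
    loadings_ : ndarray (A, p) — orthonormal loading vectors p_a.
    scores_ : ndarray (n, A) — training scores t_a.
    explained_variance_pct_ : ndarray (A,) — % of centered X-variance per PC.
    """

    def __init__(self, n_components: int = 7):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-d, got shape {X.shape}")
        limit = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= self.n_components <= limit:
            raise ValueError(
                f"n_components={self.n_components} out of range [1, {limit}] "
                f"for X of shape {X.shape}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        loadings = pca.components_
        # deterministic sign: largest-|.| loading element positive per PC
        flip = np.sign(loadings[np.arange(loadings.shape[0]),
                                np.abs(loadings).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.loadings_ = loadings * flip[:, None]
        self.scores_ = scores * flip[None, :]
        self.mean_ = pca.mean_
        self.explained_variance_pct_ = pca.explained_variance_ratio_ * 100.0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.mean_.size:
            raise ValueError("wavelength grid mismatch with fitted PCA")
        return (X - self.mean_) @ self.loadings_.T

    def reconstruct(self, scores=None) -> np.ndarray:
        """Back-project scores (training scores by default) to the spectra space."""
        t = self.scores_ if scores is None else np.asarray(scores, dtype=float)
        return self.mean_ + t @ self.loadings_


def fit_pca(X, n_components: int) -> SpectralPCA:
    """Thin functional wrapper: centered PCA with the fixed sign convention."""
    return SpectralPCA(n_components=n_components).fit(X)


def scores_vs_time(model: SpectralPCA, labels: pd.DataFrame) -> pd.DataFrame:
    """Tabulate per-batch score trajectories: (batch_id, time_s, t_1..t_A).

    ``labels`` is the (batch_id, time_s) frame from
    :func:`~procspec.dataset.augment_batches`, aligned row-by-row with the
    fitted scores. Plotting is a thin layer over this table.
    """
    scores = model.scores_
    if len(labels) != scores.shape[0]:
        raise ValueError(
            f"label rows ({len(labels)}) do not match score rows ({scores.shape[0]})"
        )
    out = labels.reset_index(drop=True).copy()
    for a in range(scores.shape[1]):
        out[f"t_{a + 1}"] = scores[:, a]
    return out


def loading_similarity(a, b, absolute: bool = False) -> float:
    """Pearson correlation of two loading (or any equal-length) vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return abs(r) if absolute else r
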