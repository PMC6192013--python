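"""Spectral preprocessing: time-domain variable smoothing and scatter correction.

In-line diffuse-reflectance spectra of a fluidized bed carry strong stochastic
whole-spectrum intensity fluctuations ("scatter effect") from density
turbulence around the probe, plus a wavelength-flat offset that is itself
correlated with moisture (water changes the powder's refractive properties and
hence light penetration depth). Conventional scatter corrections (MSC, SNV,
derivatives) remove the turbulence noise but destroy that informative flat
component with it. The alternative implemented here smooths each spectral
variable *along the time axis* instead: turbulence averages out while any
moisture-correlated trend — flat or band-shaped — survives.

All methods are scikit-learn transformers so they compose with pipelines and
are cloned per cross-validation fold where they learn parameters (MSC).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TimeSmoother",
    "MultiplicativeScatterCorrection",
    "StandardNormalVariate",
    "SavitzkyGolayDerivative",
    "time_smooth",
    "smoothing_delay",
    "msc",
    "snv",
    "savgol_derivative",
    "parse_method",
]


def _check_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-d matrix, got shape {X.shape}")
    return X


def _check_odd(k: int) -> int:
    if not isinstance(k, (int, np.integer)) or k < 1 or k % 2 == 0:
        raise ValueError(f"window width k must be an odd integer >= 1, got {k!r}")
    return int(k)


def time_smooth(X, k: int) -> np.ndarray:
    """Moving-average smoothing of each spectral variable along the time axis.

    Row ``i`` of each column becomes the centered mean over ``k`` consecutive
    time points. The ``(k-1)/2`` points at either end of the series, at
    ordinal ``l`` from the end (``l = 1`` being the end point itself), use a
    reduced symmetric window of ``(l-1)*2 + 1`` points, so end points pass
    through unchanged. ``k = 1`` is the identity.

    Parameters
    ----------
    X : ndarray, shape (n_times, n_wavelengths)
        One batch's spectra, time-ordered. Never smooth across batch
        boundaries: batches are separate processes.
    k : int
        Odd window width in points.
    """
    X = _check_matrix(X)
    k = _check_odd(k)
    n = X.shape[0]
    h = (k - 1) // 2
    if h == 0:
        return X.copy()
    # cumulative sums give every centered window mean in O(n p)
    S = np.vstack([np.zeros((1, X.shape[1])), np.cumsum(X, axis=0)])
    out = np.empty_like(X)
    idx = np.arange(n)
    # per-row half-width: full h in the interior, reduced to the distance
    # from the nearer end so the window stays symmetric and inside the data
    hw = np.minimum(h, np.minimum(idx, n - 1 - idx))
    lo = idx - hw
    hi = idx + hw + 1
    out[:] = (S[hi] - S[lo]) / (hi - lo)[:, None]
    return out


def smoothing_delay(k: int, dt: float) -> tuple[float, float]:
    """In-line availability delay of the centered smoother.

    A centered window of width ``k`` cannot emit point ``i`` until
    ``(k-1)/2`` later points have arrived, so the smoothed trajectory lags
    the process by ``(k-1)/2 * dt`` seconds; the full window spans
    ``(k-1) * dt`` seconds. For the 15-point window on a 5-s acquisition
    grid this is a 35 s delay and a 70 s full span.

    Returns
    -------
    (delay_s, full_span_s)
    """
    k = _check_odd(k)
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return (k - 1) / 2 * dt, (k - 1) * dt


class TimeSmoother(BaseEstimator, TransformerMixin):
    """Sklearn transformer wrapper around :func:`time_smooth`.

    Stateless; ``fit`` only validates. Apply once per batch stream, before
    any pairing with reference values.
    """

    def __init__(self, k: int = 15):
        self.k = k

    def fit(self, X, y=None):
        _check_odd(self.k)
        self.n_features_in_ = _check_matrix(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return time_smooth(X, self.k)

    def delay(self, dt: float) -> tuple[float, float]:
        return smoothing_delay(self.k, dt)


# ---------------------------------------------------------------------------
# Conventional scatter corrections (the comparison baselines)
# ---------------------------------------------------------------------------

def msc(X, ref=None) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum ``x`` is regressed on the reference spectrum by ordinary
    least squares over wavelengths, ``x ~ a + b * ref``, and corrected to
    ``(x - a) / b``. If ``ref`` is None it is the column-wise mean of ``X``
    (fit mode); pass the returned reference to correct new data consistently.
    """
    X = _check_matrix(X)
    if ref is None:
        ref = X.mean(axis=0)
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError(f"reference length {ref.shape} does not match {X.shape[1]} channels")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom < 1e-24 or not np.all(np.isfinite(ref)):
        raise ValueError("MSC reference spectrum is constant or non-finite")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    bad = np.abs(b) < 1e-12
    if np.any(bad):
        raise ValueError(
            f"MSC slope numerically zero for row(s) {np.flatnonzero(bad).tolist()}"
        )
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None], ref


class MultiplicativeScatterCorrection(BaseEstimator, TransformerMixin):
    """MSC with the reference learned from the fitting set (its mean spectrum).

    Attributes
    ----------
    reference_ : ndarray, shape (n_wavelengths,)
        Mean spectrum of the data seen by :meth:`fit`; reused on new data so
        calibration and prediction spectra are corrected against the same
        reference.
    """

    def fit(self, X, y=None):
        X = _check_matrix(X)
        ref = X.mean(axis=0)
        if np.ptp(ref) == 0:
            raise ValueError("MSC reference spectrum is constant")
        self.reference_ = ref
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        corrected, _ = msc(X, self.reference_)
        return corrected


def snv(X) -> np.ndarray:
    """Standard normal variate: each spectrum to mean 0, sample SD 1 (n-1)."""
    X = _check_matrix(X)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = sd[:, 0] == 0
    if np.any(bad):
        raise ValueError(f"SNV undefined for constant row(s) {np.flatnonzero(bad).tolist()}")
    return (X - mean) / sd


class StandardNormalVariate(BaseEstimator, TransformerMixin):
    """Stateless SNV transformer."""

    def fit(self, X, y=None):
        self.n_features_in_ = _check_matrix(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return snv(X)


def savgol_derivative(X, window: int = 15, polyorder: int = 2, deriv: int = 1) -> np.ndarray:
    """Savitzky–Golay derivative along the wavelength axis of each spectrum.

    The derivative is in units per channel index, not per nm. Edges are
    handled by the polynomial fit within the truncated window
    (``mode="interp"``).
    """
    X = _check_matrix(X)
    window = _check_odd(window)
    if polyorder >= window:
        raise ValueError(f"polyorder ({polyorder}) must be < window ({window})")
    if deriv > polyorder:
        raise ValueError(f"deriv ({deriv}) must be <= polyorder ({polyorder})")
    if X.shape[1] < window:
        raise ValueError(f"window ({window}) exceeds {X.shape[1]} channels")
    return savgol_filter(X, window_length=window, polyorder=polyorder, deriv=deriv, axis=1, mode="interp")


class SavitzkyGolayDerivative(BaseEstimator, TransformerMixin):
    """Stateless Savitzky–Golay derivative transformer (default 1D2.15: first
    derivative, second-order polynomial, 15-point window)."""

    def __init__(self, window: int = 15, polyorder: int = 2, deriv: int = 1):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv

    def fit(self, X, y=None):
        self.n_features_in_ = _check_matrix(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return savgol_derivative(X, self.window, self.polyorder, self.deriv)


# ---------------------------------------------------------------------------
# Method-spec parsing shared by CLI and scripts
# ---------------------------------------------------------------------------

def parse_method(spec: str) -> tuple[int, BaseEstimator | None]:
    """Parse a preprocessing label into (stream smoother width k, sample transformer).

    Labels: ``none``, ``s15``/``s47`` (time smoothing with that window),
    ``smooth:k``, ``msc``, ``snv``, ``sg:<deriv>:<polyorder>:<window>``
    (``sg:1:2:15`` is the 1D2.15 configuration).
    """
    s = spec.strip().lower()
    if s in ("none", "raw"):
        return 1, None
    if s.startswith("s") and s[1:].isdigit():
        return _check_odd(int(s[1:])), None
    if s.startswith("smooth:"):
        return _check_odd(int(s.split(":", 1)[1])), None
    if s == "msc":
        return 1, MultiplicativeScatterCorrection()
    if s == "snv":
        return 1, StandardNormalVariate()
    if s.startswith("sg:"):
        parts = s.split(":")
        if len(parts) != 4:
            raise ValueError(f"expected sg:<deriv>:<polyorder>:<window>, got {spec!r}")
        deriv, polyorder, window = (int(p) for p in parts[1:])
        return 1, SavitzkyGolayDerivative(window=window, polyorder=polyorder, deriv=deriv)
    raise ValueError(f"unknown preprocessing method {spec!r}")
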