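"""Synthetic fluidized-bed-drying NIR campaign generator.

No public dataset of in-line drying spectra with LOD references exists, so the
package ships a generative model reproducing the statistical structure the
analysis methods rely on:

* an exponentially decaying moisture trajectory m(t) = m_end + (m0 - m_end) e^{-t/tau};
* a clean spectrum built from a fixed smooth baseline, two Gaussian water
  absorption bands near 1440 and 1930 nm (the long-wave band ~3x stronger)
  whose depth follows a mildly saturating function of moisture, and a
  wavelength-flat "watermark" term alpha*m(t) — the refractive-index effect
  by which wetter powder absorbs more light at every wavelength;
* observation noise A = f_t * A0 + o_t + eps with a lognormal multiplicative
  factor f_t (the turbulence "scatter effect"), a flat additive offset o_t,
  and iid channel noise eps;
* reference sampling: a few stratified LOD measurements per batch with the
  gravimetric analyzer's reproducibility noise (SD 0.06%).

Everything is deterministic given a seed; per-batch streams derive child
seeds from the master seed so any one batch is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import ProcessDataset, ReferenceSet, SpectraBatch

__all__ = ["SimParams", "SimBatch", "simulate_batch", "sample_references", "simulate_campaign"]


@dataclass
class SimParams:
    """Generator constants; defaults are the studied campaign's geometry.

    Units: wavelengths nm, times s, moisture % w/w (LOD), intensities lg(1/R).
    """

    n_channels: int = 256
    wavelength_min: float = 1091.8
    wavelength_max: float = 2106.5
    dt: float = 5.0
    n_spectra_range: tuple[int, int] = (396, 1213)
    moisture_start_range: tuple[float, float] = (24.0, 26.0)
    moisture_end_range: tuple[float, float] = (2.4, 3.5)
    # drying time constant; None -> duration/4 so every batch reaches its dry end
    tau_s: float | None = None
    band_centers_nm: tuple[float, float] = (1440.0, 1930.0)
    band_widths_nm: tuple[float, float] = (45.0, 55.0)
    # lg(1/R) per % LOD; the 1930 nm band ~3x the 1440 nm band
    band_amplitudes: tuple[float, float] = (0.004, 0.012)
    # saturation scale of the band response, %: depth ~ m_sat*(1-exp(-m/m_sat));
    # mildly sub-linear, as strong NIR bands are
    band_saturation_lod: float = 200.0
    # flat "watermark" slope, lg(1/R) per % LOD
    alpha: float = 0.004
    sigma_f: float = 0.022  # lognormal sigma of the multiplicative scatter factor
    sigma_o: float = 0.0095  # SD of the flat additive offset, lg(1/R)
    sigma_eps: float = 0.003  # SD of iid channel noise, lg(1/R)
    n_references_range: tuple[int, int] = (5, 26)
    lod_noise_sd: float = 0.06  # reference-method reproducibility, % LOD

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if not self.wavelength_min < self.wavelength_max:
            raise ValueError("wavelength span must be non-empty")
        for c in self.band_centers_nm:
            if not self.wavelength_min <= c <= self.wavelength_max:
                raise ValueError(f"band center {c} nm outside the wavelength span")
        if self.tau_s is not None and self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        for name in ("sigma_f", "sigma_o", "sigma_eps", "lod_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_min, self.wavelength_max, self.n_channels)


@dataclass
class SimBatch:
    """A simulated batch plus its ground truth.

    ``moisture`` is the true trajectory m(t) aligned with ``batch.times`` —
    the quantity reference sampling and parameter-recovery tests measure
    against.
    """

    batch: SpectraBatch
    moisture: np.ndarray
    references: ReferenceSet | None = None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Fixed matrix absorbance: upward slope plus broad moisture-independent
    features. The static structure matters: it anchors the MSC regression
    slope the way real excipient bands do, so scatter correction behaves
    comparably to practice rather than degenerating."""
    s = (wl - wl[0]) / (wl[-1] - wl[0])
    return (
        0.35
        + 0.25 * s
        + 0.12 * np.exp(-0.5 * ((s - 0.30) / 0.10) ** 2)
        + 0.10 * np.exp(-0.5 * ((s - 0.75) / 0.08) ** 2)
        - 0.08 * np.exp(-0.5 * ((s - 0.55) / 0.12) ** 2)
    )


def _band_shape(params: SimParams) -> np.ndarray:
    wl = params.wavelengths
    shape = np.zeros_like(wl)
    for c, w, a in zip(params.band_centers_nm, params.band_widths_nm,
                       params.band_amplitudes):
        shape += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return shape


def clean_spectra(params: SimParams, moisture: np.ndarray) -> np.ndarray:
    """Noise-free spectra A0(lambda, t) for a moisture trajectory."""
    wl = params.wavelengths
    m = np.asarray(moisture, dtype=float)[:, None]
    msat = params.band_saturation_lod
    band_response = msat * (1.0 - np.exp(-m / msat))  # ~m for m << msat
    return _baseline(wl)[None, :] + params.alpha * m + band_response * _band_shape(params)[None, :]


def simulate_batch(
    params: SimParams,
    seed,
    batch_id: str = "SIM",
    n_spectra: int | None = None,
) -> SimBatch:
    """Generate one batch: trajectory, clean spectra, turbulence and noise."""
    rng = _rng(seed)
    if n_spectra is None:
        n_spectra = int(rng.integers(params.n_spectra_range[0],
                                     params.n_spectra_range[1] + 1))
    if n_spectra < 2:
        raise ValueError("n_spectra must be >= 2")
    times = np.arange(n_spectra, dtype=float) * params.dt
    duration = times[-1]
    # default tau scales with batch length (runs end near their dry endpoint);
    # the jittered divisor varies the drying dynamics between batches
    tau = params.tau_s if params.tau_s is not None else duration / rng.uniform(3.5, 4.5)
    m0 = rng.uniform(*params.moisture_start_range)
    m_end = rng.uniform(*params.moisture_end_range)
    moisture = m_end + (m0 - m_end) * np.exp(-times / tau)

    a0 = clean_spectra(params, moisture)
    f = np.exp(rng.normal(0.0, params.sigma_f, size=n_spectra)) if params.sigma_f > 0 \
        else np.ones(n_spectra)
    o = rng.normal(0.0, params.sigma_o, size=n_spectra) if params.sigma_o > 0 \
        else np.zeros(n_spectra)
    eps = rng.normal(0.0, params.sigma_eps, size=a0.shape) if params.sigma_eps > 0 \
        else 0.0
    intensities = f[:, None] * a0 + o[:, None] + eps

    batch = SpectraBatch(batch_id=batch_id, times=times,
                         wavelengths=params.wavelengths, intensities=intensities)
    return SimBatch(batch=batch, moisture=moisture)


def sample_references(
    sim: SimBatch,
    n: int,
    lod_noise_sd: float | None = None,
    seed=None,
) -> ReferenceSet:
    """Draw n stratified reference samples from the true trajectory.

    Sampling times are stratified uniform over the batch span (one draw per
    equal time stratum), the realistic pattern for manual sampling during a
    run. LOD = m(t) + N(0, sd^2), truncated at 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    times = sim.batch.times
    if n > times.size:
        raise ValueError(f"n={n} exceeds the {times.size} available spectra")
    rng = _rng(seed)
    sd = 0.06 if lod_noise_sd is None else lod_noise_sd
    # one index drawn per stratum of roughly equal size
    edges = np.linspace(0, times.size, n + 1).astype(int)
    idx = np.array([int(rng.integers(lo, hi)) for lo, hi in zip(edges[:-1], edges[1:])])
    lod = sim.moisture[idx] + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    lod = np.maximum(lod, 0.0)
    return ReferenceSet(batch_id=sim.batch.batch_id, sample_times=times[idx], lod_values=lod)


def simulate_campaign(
    params: SimParams | None = None,
    n_batches: int = 25,
    validation_batches: int = 8,
    seed: int = 0,
) -> ProcessDataset:
    """Generate a multi-batch campaign with per-batch condition jitter.

    Batch moisture endpoints and drying time constants are drawn per batch
    (within the parameter ranges) so batches differ as real runs do. The last
    ``validation_batches`` batch ids are assigned the ``validation`` role,
    the rest ``calibration``. Per-batch child seeds come from the master
    seed, so batch i is identical across runs and independent of n_batches.
    """
    params = params or SimParams()
    if not 0 <= validation_batches < n_batches:
        raise ValueError("need 0 <= validation_batches < n_batches")
    batches, references, roles = [], [], {}
    for i in range(n_batches):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        bid = f"B{i + 1:02d}"
        sim = simulate_batch(params, rng, batch_id=bid)
        n_refs = int(rng.integers(params.n_references_range[0],
                                  params.n_references_range[1] + 1))
        refs = sample_references(sim, n_refs, lod_noise_sd=params.lod_noise_sd, seed=rng)
        batches.append(sim.batch)
        references.append(refs)
        roles[bid] = "validation" if i >= n_batches - validation_batches else "calibration"
    return ProcessDataset(batches=batches, references=references, roles=roles)
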