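"""Calibration strategy: window-width optimization, range models, dynamic focusing.

Three levers raise in-line accuracy beyond a single full-range model:

* scanning the smoothing window width k over all odd values in a range and
  preferring the lightest smoothing whose cross-validated RMSE is within a
  small tolerance of the best — heavier smoothing costs in-line delay
  ((k-1)/2 acquisition steps) for little accuracy gain;
* fitting a family of PLS models on nested moisture ranges (full data, then
  LOD < 20, < 15, < 10 %): prediction error shrinks with the upper moisture
  bound, so the critical final drying stage can be monitored most accurately;
* "dynamic focusing" at prediction time — a cascade that starts with the
  full-range model and switches one-way to the next, drier-range model once
  predictions have stayed below its threshold for a few consecutive points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PairedData, ProcessDataset, SpectraBatch, pair_campaign, restrict_range
from .plsmodel import NIPALSPLS, lbo_cv, loo_cv
from .preprocess import time_smooth

__all__ = [
    "WindowScanResult",
    "CascadeStage",
    "ModelCascade",
    "window_scan",
    "build_cascade",
    "dynamic_predict",
]


@dataclass
class WindowScanResult:
    """RMSE per candidate window width and the selected k.

    ``chosen_k`` is the smallest k whose RMSE is within ``tolerance``
    (relative) of the global minimum — light smoothing is technically
    preferred because the in-line delay grows with k.
    """

    table: pd.DataFrame  # columns: k, rmse
    chosen_k: int
    tolerance: float

    @property
    def best_k(self) -> int:
        return int(self.table.loc[self.table["rmse"].idxmin(), "k"])


def _scheme_rmse(paired: PairedData, scheme: str, n_components: int, chain) -> float:
    if scheme == "lbo":
        return lbo_cv(paired, n_components=n_components, chain=chain).rmse
    if scheme == "loo":
        return loo_cv(paired, n_components=n_components, chain=chain).rmse
    raise ValueError(f"unknown scan scheme {scheme!r}")


def window_scan(
    dataset: ProcessDataset,
    k_min: int = 3,
    k_max: int = 101,
    n_components: int = 7,
    scheme: str = "lbo",
    max_lod: float | None = None,
    tolerance: float = 0.02,
    chain=None,
    max_gap: float = 60.0,
) -> WindowScanResult:
    """Evaluate the full pipeline for every odd k in [k_min, k_max].

    For each candidate width the batch streams are smoothed, paired with
    references, optionally restricted to ``lod < max_lod``, and validated
    with the chosen scheme at ``n_components`` latent variables.
    """
    if k_min % 2 == 0 or k_max % 2 == 0 or k_min < 1 or k_min > k_max:
        raise ValueError(f"k bounds must be odd with k_min <= k_max, got ({k_min}, {k_max})")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ks = np.arange(k_min, k_max + 1, 2)
    rmses = np.empty(ks.size)
    for i, k in enumerate(ks):
        paired = restrict_range(
            pair_campaign(dataset, smoother=int(k), max_gap=max_gap), max_lod
        )
        rmses[i] = _scheme_rmse(paired, scheme, n_components, chain)
    table = pd.DataFrame({"k": ks, "rmse": rmses})
    best = rmses.min()
    within = ks[rmses <= best * (1.0 + tolerance)]
    return WindowScanResult(table=table, chosen_k=int(within.min()), tolerance=tolerance)


@dataclass
class CascadeStage:
    """One focusing stage: a PLS model valid up to ``upper_lod`` % moisture.

    ``upper_lod`` is None for the full-range entry stage.
    """

    upper_lod: float | None
    model: NIPALSPLS
    n_train: int = 0


@dataclass
class ModelCascade:
    """Ordered range models for dynamic focusing, wettest range first.

    ``smoother_k`` is the shared time-smoothing window applied to the
    incoming stream; ``debounce`` is the number of consecutive predictions
    below the next stage's threshold required before switching.
    """

    stages: list[CascadeStage]
    smoother_k: int = 15
    debounce: int = 3

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("cascade needs at least one stage")
        thresholds = [s.upper_lod for s in self.stages]
        for a, b in zip(thresholds, thresholds[1:]):
            if b is None or (a is not None and b >= a):
                raise ValueError(
                    f"stage thresholds must be strictly decreasing, got {thresholds}"
                )
        if self.debounce < 1:
            raise ValueError("debounce must be >= 1")

    # -- JSON round-trip (plain text, so cascades can ship between runs) ----

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "smoother_k": self.smoother_k,
            "debounce": self.debounce,
            "stages": [
                {
                    "upper_lod": s.upper_lod,
                    "n_train": s.n_train,
                    "n_components": int(s.model.x_weights_.shape[1]),
                    "x_mean": s.model.x_mean_.tolist(),
                    "y_mean": s.model.y_mean_,
                    "coef": s.model.coef_.tolist(),
                }
                for s in self.stages
            ],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "ModelCascade":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        doc = json.loads(text)
        stages = []
        for s in doc["stages"]:
            model = NIPALSPLS.__new__(NIPALSPLS)
            model.n_components = s["n_components"]
            model.x_mean_ = np.asarray(s["x_mean"], dtype=float)
            model.y_mean_ = float(s["y_mean"])
            model.coef_ = np.asarray(s["coef"], dtype=float)
            # only the prediction state survives serialization
            model.x_weights_ = np.zeros((model.x_mean_.size, s["n_components"]))
            stages.append(CascadeStage(upper_lod=s["upper_lod"], model=model,
                                       n_train=s.get("n_train", 0)))
        return ModelCascade(stages=stages, smoother_k=doc["smoother_k"],
                            debounce=doc["debounce"])


def build_cascade(
    dataset: ProcessDataset,
    thresholds=(None, 20.0, 15.0, 10.0),
    n_components: int = 7,
    smoother_k: int = 15,
    debounce: int = 3,
    batch_ids=None,
    max_gap: float = 60.0,
) -> ModelCascade:
    """Fit one PLS model per moisture range and assemble the cascade.

    ``thresholds`` lists the stages' upper LOD bounds, full range (None)
    first, then strictly decreasing; each model is fit on the smoothed,
    paired training data restricted to its range.
    """
    thresholds = list(thresholds)
    paired = pair_campaign(dataset, smoother=smoother_k, batch_ids=batch_ids,
                           max_gap=max_gap)
    stages = []
    for thr in thresholds:
        part = restrict_range(paired, thr)
        if part.n_samples < n_components + 2:
            label = "full range" if thr is None else f"lod < {thr:g}%"
            raise ValueError(
                f"range {label} has only {part.n_samples} samples; "
                f"need at least {n_components + 2}"
            )
        model = NIPALSPLS(n_components=n_components).fit(part.spectra, part.lod)
        stages.append(CascadeStage(upper_lod=thr, model=model, n_train=part.n_samples))
    return ModelCascade(stages=stages, smoother_k=smoother_k, debounce=debounce)


def dynamic_predict(cascade: ModelCascade, stream: SpectraBatch) -> pd.DataFrame:
    """Run the focusing cascade over one batch stream.

    The stream is time-smoothed with the cascade's window; in-line, a
    centered window means each smoothed point becomes available only
    (k-1)/2 acquisition steps after its nominal time (start-of-stream points
    use the reduced symmetric end windows). Prediction starts at stage 0 and
    advances one-way: once ``debounce`` consecutive predictions fall below
    the next stage's threshold, that drier-range model takes over. One row
    is emitted per input spectrum: (time_s, predicted, stage).
    """
    if stream.n_spectra == 0:
        raise ValueError("empty stream")
    X = time_smooth(stream.intensities, cascade.smoother_k)
    n_stages = len(cascade.stages)
    active = 0
    below = 0
    y_out = np.empty(stream.n_spectra)
    stage_out = np.empty(stream.n_spectra, dtype=int)
    for i in range(stream.n_spectra):
        y = float(cascade.stages[active].model.predict(X[i:i + 1])[0])
        y_out[i] = y
        stage_out[i] = active
        if active + 1 < n_stages:
            if y < cascade.stages[active + 1].upper_lod:
                below += 1
                if below >= cascade.debounce:
                    active += 1
                    below = 0
            else:
                below = 0
    return pd.DataFrame({"time_s": stream.times, "predicted": y_out, "stage": stage_out})
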