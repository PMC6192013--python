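"""Domain containers and I/O for in-line NIR drying campaigns.

A drying campaign is a set of batches. Each batch carries a time-ordered
matrix of diffuse-reflectance spectra in lg(1/R) units on a shared
wavelength grid, plus a handful of time-stamped loss-on-drying (LOD)
reference moisture measurements taken from the process. Calibration works
on (spectrum, reference) pairs obtained by nearest-in-time matching.

On-disk formats are deliberately plain text: wide CSV for spectra
(``time_s`` column + one column per wavelength), a three-column CSV for
references, and a YAML manifest tying batch files and roles together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpectraBatch",
    "ReferenceSet",
    "PairedData",
    "ProcessDataset",
    "PairingWarning",
    "load_spectra",
    "write_spectra",
    "load_references",
    "write_references",
    "load_manifest",
    "write_manifest",
    "match_references",
    "pair_campaign",
    "augment_batches",
    "restrict_range",
]


class PairingWarning(UserWarning):
    """A reference sample fell outside the batch span or far from any spectrum."""


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class SpectraBatch:
    """One batch's time-ordered spectra on a shared wavelength axis.

    Attributes
    ----------
    batch_id : str
        Label of the batch (e.g. ``"B03"``).
    times : ndarray, shape (n_spectra,)
        Seconds from batch start, strictly increasing.
    wavelengths : ndarray, shape (n_channels,)
        Wavelength grid in nm, strictly increasing.
    intensities : ndarray, shape (n_spectra, n_channels)
        Spectral intensities in lg(1/R) units.
    """

    batch_id: str
    times: np.ndarray
    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times", 1)
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths", 1)
        self.intensities = _as_float_array(self.intensities, "intensities", 2)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"batch {self.batch_id!r}: times must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError(
                f"batch {self.batch_id!r}: wavelengths must be strictly increasing"
            )
        if self.intensities.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"batch {self.batch_id!r}: intensity matrix shape "
                f"{self.intensities.shape} inconsistent with axes "
                f"({self.times.size}, {self.wavelengths.size})"
            )

    @property
    def n_spectra(self) -> int:
        return self.times.size

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size


@dataclass
class ReferenceSet:
    """Time-stamped LOD reference moisture measurements for one batch.

    ``excluded`` is a manual per-sample outlier flag: flagged samples are
    skipped by pairing but kept on disk so exclusions stay auditable.
    """

    batch_id: str
    sample_times: np.ndarray
    lod_values: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_times = _as_float_array(self.sample_times, "sample_times", 1)
        self.lod_values = _as_float_array(self.lod_values, "lod_values", 1)
        if self.excluded is None:
            self.excluded = np.zeros(self.sample_times.size, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.lod_values.shape != self.sample_times.shape:
            raise ValueError("sample_times and lod_values must have equal length")
        if self.excluded.shape != self.sample_times.shape:
            raise ValueError("excluded must have the same length as sample_times")
        if np.any(self.lod_values < 0):
            bad = int(np.argmax(self.lod_values < 0))
            raise ValueError(
                f"batch {self.batch_id!r}: negative LOD value "
                f"{self.lod_values[bad]} at row {bad}"
            )

    @property
    def n_samples(self) -> int:
        return self.sample_times.size


@dataclass
class PairedData:
    """(spectrum, reference) rows across one or many batches.

    Produced by :func:`match_references`; each row keeps its batch label so
    leave-a-batch-out cross-validation can form folds.
    """

    batch_ids: np.ndarray  # (n,) object/str
    sample_times: np.ndarray  # (n,)
    spectra: np.ndarray  # (n, p)
    lod: np.ndarray  # (n,)
    wavelengths: np.ndarray  # (p,)
    pairing_gaps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.batch_ids = np.asarray(self.batch_ids, dtype=object)
        self.sample_times = _as_float_array(self.sample_times, "sample_times", 1)
        self.spectra = _as_float_array(self.spectra, "spectra", 2)
        self.lod = _as_float_array(self.lod, "lod", 1)
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths", 1)
        n = self.sample_times.size
        if self.pairing_gaps is None:
            self.pairing_gaps = np.zeros(n)
        else:
            self.pairing_gaps = _as_float_array(self.pairing_gaps, "pairing_gaps", 1)
        if not (
            self.batch_ids.size == n
            and self.lod.size == n
            and self.pairing_gaps.size == n
            and self.spectra.shape == (n, self.wavelengths.size)
        ):
            raise ValueError("inconsistent PairedData row/axis sizes")

    @property
    def n_samples(self) -> int:
        return self.lod.size

    def subset(self, mask: np.ndarray) -> "PairedData":
        mask = np.asarray(mask)
        return PairedData(
            batch_ids=self.batch_ids[mask],
            sample_times=self.sample_times[mask],
            spectra=self.spectra[mask],
            lod=self.lod[mask],
            wavelengths=self.wavelengths,
            pairing_gaps=self.pairing_gaps[mask],
        )

    @staticmethod
    def concat(parts: Sequence["PairedData"]) -> "PairedData":
        if not parts:
            raise ValueError("cannot concatenate zero PairedData parts")
        wl = parts[0].wavelengths
        for p in parts[1:]:
            if p.wavelengths.shape != wl.shape or not np.array_equal(p.wavelengths, wl):
                raise ValueError("wavelength grids differ between PairedData parts")
        return PairedData(
            batch_ids=np.concatenate([p.batch_ids for p in parts]),
            sample_times=np.concatenate([p.sample_times for p in parts]),
            spectra=np.vstack([p.spectra for p in parts]),
            lod=np.concatenate([p.lod for p in parts]),
            wavelengths=wl,
            pairing_gaps=np.concatenate([p.pairing_gaps for p in parts]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: batch_id, sample_time_s, lod_percent, then one column per nm."""
        df = pd.DataFrame(self.spectra, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "lod_percent", self.lod)
        df.insert(0, "sample_time_s", self.sample_times)
        df.insert(0, "batch_id", self.batch_ids)
        return df


@dataclass
class ProcessDataset:
    """A campaign: spectra batches, their reference sets, and optional roles.

    Roles split the campaign into ``calibration`` and ``validation`` batches
    for external validation; ``roles`` maps batch_id -> role.
    """

    batches: list[SpectraBatch]
    references: list[ReferenceSet]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [b.batch_id for b in self.batches]
        if len(set(ids)) != len(ids):
            raise ValueError("batch_ids must be unique")
        ref_ids = {r.batch_id for r in self.references}
        missing = ref_ids - set(ids)
        if missing:
            raise ValueError(f"ReferenceSet(s) without a matching SpectraBatch: {sorted(missing)}")
        for role in self.roles.values():
            if role not in ("calibration", "validation"):
                raise ValueError(f"unknown batch role {role!r}")

    @property
    def batch_ids(self) -> list[str]:
        return [b.batch_id for b in self.batches]

    def batch(self, batch_id: str) -> SpectraBatch:
        for b in self.batches:
            if b.batch_id == batch_id:
                return b
        raise KeyError(batch_id)

    def references_for(self, batch_id: str) -> ReferenceSet:
        for r in self.references:
            if r.batch_id == batch_id:
                return r
        raise KeyError(batch_id)

    def ids_with_role(self, role: str) -> list[str]:
        return [b for b in self.batch_ids if self.roles.get(b) == role]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_spectra(path: str | Path, batch_id: str | None = None) -> SpectraBatch:
    """Load a wide-CSV spectra file (``time_s`` + one column per wavelength).

    Rows are re-sorted by time if needed. The batch id defaults to the file
    stem with a trailing ``_spectra`` stripped.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed wavelength header: {exc}") from exc
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            if not np.issubdtype(df.dtypes.iloc[j], np.number):
                raise ValueError(f"{path}: non-numeric cell(s) in column {col!r}")
    if batch_id is None:
        batch_id = path.stem.removesuffix("_spectra")
    order = np.argsort(values[:, 0], kind="stable")
    return SpectraBatch(
        batch_id=batch_id,
        times=values[order, 0],
        wavelengths=wavelengths,
        intensities=values[order, 1:],
    )


def write_spectra(batch: SpectraBatch, path: str | Path) -> None:
    """Write a batch as wide CSV; numeric round-trip is lossless to 1e-12."""
    df = pd.DataFrame(batch.intensities, columns=[f"{w:.17g}" for w in batch.wavelengths])
    df.insert(0, "time_s", batch.times)
    df.to_csv(path, index=False, float_format="%.17g")


def load_references(path: str | Path, batch_id: str | None = None) -> ReferenceSet:
    """Load a reference CSV: ``sample_time_s, lod_percent[, excluded]``."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"sample_time_s", "lod_percent"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: reference CSV needs columns {sorted(required)}")
    if batch_id is None:
        batch_id = path.stem.removesuffix("_references").removesuffix("_refs")
    excluded = (
        df["excluded"].to_numpy().astype(bool) if "excluded" in df.columns else None
    )
    return ReferenceSet(
        batch_id=batch_id,
        sample_times=df["sample_time_s"].to_numpy(dtype=float),
        lod_values=df["lod_percent"].to_numpy(dtype=float),
        excluded=excluded,
    )


def write_references(refs: ReferenceSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_time_s": refs.sample_times,
            "lod_percent": refs.lod_values,
            "excluded": refs.excluded.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_manifest(dataset: ProcessDataset, directory: str | Path) -> Path:
    """Write a campaign to ``directory``: per-batch CSVs plus ``manifest.yaml``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for batch in dataset.batches:
        spath = f"{batch.batch_id}_spectra.csv"
        rpath = f"{batch.batch_id}_references.csv"
        write_spectra(batch, directory / spath)
        write_references(dataset.references_for(batch.batch_id), directory / rpath)
        entry = {"id": batch.batch_id, "spectra": spath, "references": rpath}
        if batch.batch_id in dataset.roles:
            entry["role"] = dataset.roles[batch.batch_id]
        entries.append(entry)
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"batches": entries}, fh, sort_keys=False)
    return manifest


def load_manifest(path: str | Path) -> ProcessDataset:
    """Load a campaign manifest YAML; file paths are relative to the manifest."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "batches" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'batches' list")
    batches, references, roles = [], [], {}
    for entry in doc["batches"]:
        bid = str(entry["id"])
        batches.append(load_spectra(path.parent / entry["spectra"], batch_id=bid))
        references.append(load_references(path.parent / entry["references"], batch_id=bid))
        if "role" in entry:
            roles[bid] = entry["role"]
    return ProcessDataset(batches=batches, references=references, roles=roles)


# ---------------------------------------------------------------------------
# Pairing, augmentation, range restriction
# ---------------------------------------------------------------------------

def match_references(
    batch: SpectraBatch, refs: ReferenceSet, max_gap: float = 60.0
) -> PairedData:
    """Pair each non-excluded reference with the nearest-in-time spectrum.

    Ties (a sample equidistant between two spectra) resolve to the earlier
    spectrum — the one already observed when the sample was drawn. A pairing
    gap above ``max_gap`` seconds, or a sample outside the batch time span,
    raises a :class:`PairingWarning` but keeps the row.
    """
    if batch.n_spectra == 0:
        raise ValueError("empty batch")
    keep = ~refs.excluded
    if refs.n_samples == 0 or not np.any(keep):
        raise ValueError("no non-excluded reference samples to pair")
    if batch.batch_id != refs.batch_id:
        raise ValueError(
            f"batch_id mismatch: spectra {batch.batch_id!r} vs references {refs.batch_id!r}"
        )
    t_spec = batch.times
    t_samp = refs.sample_times[keep]
    lod = refs.lod_values[keep]

    outside = (t_samp < t_spec[0]) | (t_samp > t_spec[-1])
    if np.any(outside):
        warnings.warn(
            f"batch {batch.batch_id!r}: {int(outside.sum())} reference sample(s) "
            "outside the batch time span",
            PairingWarning,
            stacklevel=2,
        )

    # nearest index with earlier-on-tie: right insertion point, then compare
    idx_hi = np.searchsorted(t_spec, t_samp, side="left")
    idx_hi = np.clip(idx_hi, 0, t_spec.size - 1)
    idx_lo = np.clip(idx_hi - 1, 0, t_spec.size - 1)
    d_hi = np.abs(t_spec[idx_hi] - t_samp)
    d_lo = np.abs(t_spec[idx_lo] - t_samp)
    idx = np.where(d_lo <= d_hi, idx_lo, idx_hi)  # tie -> earlier
    gaps = np.abs(t_spec[idx] - t_samp)

    big = gaps > max_gap
    if np.any(big):
        warnings.warn(
            f"batch {batch.batch_id!r}: {int(big.sum())} pairing gap(s) exceed "
            f"{max_gap:g} s (max {gaps.max():g} s); rows kept",
            PairingWarning,
            stacklevel=2,
        )
    return PairedData(
        batch_ids=np.array([batch.batch_id] * t_samp.size, dtype=object),
        sample_times=t_samp,
        spectra=batch.intensities[idx],
        lod=lod,
        wavelengths=batch.wavelengths,
        pairing_gaps=gaps,
    )


def pair_campaign(
    dataset: ProcessDataset,
    smoother=None,
    batch_ids: Iterable[str] | None = None,
    max_gap: float = 60.0,
) -> PairedData:
    """Pair every batch of a campaign, optionally time-smoothing each stream first.

    ``smoother`` is an odd window width ``k`` or a fitted/unfitted
    :class:`~procspec.preprocess.TimeSmoother`. Smoothing is applied to each
    batch's full spectral stream *before* pairing and never across batch
    boundaries; it uses no reference values, so it cannot leak between
    cross-validation folds.
    """
    from .preprocess import TimeSmoother  # local import to avoid a cycle

    batch_ids = dataset.batch_ids if batch_ids is None else list(batch_ids)
    if isinstance(smoother, int):
        smoother = TimeSmoother(k=smoother)
    parts = []
    for bid in batch_ids:
        batch = dataset.batch(bid)
        if smoother is not None and smoother.k > 1:
            batch = SpectraBatch(
                batch_id=batch.batch_id,
                times=batch.times,
                wavelengths=batch.wavelengths,
                intensities=smoother.fit_transform(batch.intensities),
            )
        parts.append(match_references(batch, dataset.references_for(bid), max_gap=max_gap))
    return PairedData.concat(parts)


def augment_batches(
    dataset: ProcessDataset, selection: Iterable[str] | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Row-wise concatenate selected batches' spectra for trajectory PCA.

    Returns the augmented matrix and a (batch_id, time_s) label frame whose
    rows align with it; within-batch time order and the stated batch order
    are preserved.
    """
    ids = list(selection) if selection is not None else dataset.batch_ids
    if not ids:
        raise ValueError("no batches selected")
    wl = dataset.batch(ids[0]).wavelengths
    blocks, labels = [], []
    for bid in ids:
        b = dataset.batch(bid)
        if b.wavelengths.shape != wl.shape or not np.array_equal(b.wavelengths, wl):
            raise ValueError(f"batch {bid!r}: wavelength grid differs from {ids[0]!r}")
        blocks.append(b.intensities)
        labels.append(pd.DataFrame({"batch_id": bid, "time_s": b.times}))
    return np.vstack(blocks), pd.concat(labels, ignore_index=True)


def restrict_range(paired: PairedData, max_lod: float | None) -> PairedData:
    """Keep rows with ``lod < max_lod`` (strict); ``None`` keeps everything.

    Implements the moisture-range model families: the full set D and its
    restrictions D20/D15/D10 to LOD below 20, 15 and 10%.
    """
    if max_lod is None:
        return paired
    if max_lod <= 0:
        raise ValueError(f"max_lod must be positive, got {max_lod}")
    return paired.subset(paired.lod < max_lod)
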