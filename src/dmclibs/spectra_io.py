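"""Spectrum containers and delimited-text I/O.

A dataset is stored on disk as one wide delimited table (rows = spectra,
columns = wavelengths in nm, first column = ``sample_id``) plus a side-car
manifest mapping each ``sample_id`` to its class label and tablet group.
CSV vs TSV is auto-detected from the file extension.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectralDataset", "read_dataset", "write_dataset",
           "default_manifest_path", "DatasetError"]


class DatasetError(ValueError):
    """Raised for malformed spectra, manifests or grids."""


@dataclass
class Spectrum:
    """One laser shot: a wavelength grid (nm) and detector counts."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    shot_index: int = 0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise DatasetError(
                f"spectrum {self.sample_id!r}: wavelength/intensity length "
                f"mismatch ({len(self.wavelengths)} vs {len(self.intensities)})")
        if len(self.wavelengths) >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise DatasetError(
                f"spectrum {self.sample_id!r}: wavelength grid not strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise DatasetError(f"spectrum {self.sample_id!r}: non-finite intensities")
        if self.shot_index < 0:
            raise DatasetError(f"spectrum {self.sample_id!r}: negative shot_index")

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class SpectralDataset:
    """A labelled spectrum collection sharing one wavelength grid.

    Intensities are held as an ``(n_spectra, n_points)`` matrix for speed;
    ``spectra`` iterates lazily as :class:`Spectrum` views.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    groups: np.ndarray = None          # tablet identifier per spectrum
    sample_ids: list[str] = None
    shot_indices: np.ndarray = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.intensities.shape[0]
        if self.intensities.size and self.intensities.shape[1] != len(self.wavelengths):
            raise DatasetError("intensity matrix width does not match the grid")
        if len(self.labels) != n:
            raise DatasetError(f"{len(self.labels)} labels for {n} spectra")
        if len(self.wavelengths) >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise DatasetError("wavelength grid not strictly increasing")
        if self.intensities.size and not np.all(np.isfinite(self.intensities)):
            raise DatasetError("non-finite intensities in dataset")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise DatasetError("labels must index into class_names")
        if self.groups is None:
            self.groups = np.array([f"g{i}" for i in range(n)], dtype=object)
        else:
            self.groups = np.asarray(self.groups, dtype=object)
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:05d}" for i in range(n)]
        if self.shot_indices is None:
            self.shot_indices = np.zeros(n, dtype=int)
        else:
            self.shot_indices = np.asarray(self.shot_indices, dtype=int)
        if len(self.groups) != n or len(self.sample_ids) != n or len(self.shot_indices) != n:
            raise DatasetError("metadata arrays must have one entry per spectrum")

    def __len__(self) -> int:
        return self.intensities.shape[0] if self.intensities.size else len(self.labels)

    @property
    def n_points(self) -> int:
        return len(self.wavelengths)

    @property
    def spectra(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield Spectrum(self.wavelengths, self.intensities[i],
                           self.sample_ids[i], int(self.shot_indices[i]))

    def subset(self, indices) -> "SpectralDataset":
        indices = np.asarray(indices, dtype=int)
        return SpectralDataset(
            wavelengths=self.wavelengths,
            intensities=self.intensities[indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
            groups=self.groups[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            shot_indices=self.shot_indices[indices],
        )

    def with_intensities(self, intensities: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(
            wavelengths=self.wavelengths, intensities=intensities,
            labels=self.labels, class_names=list(self.class_names),
            groups=self.groups, sample_ids=list(self.sample_ids),
            shot_indices=self.shot_indices)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def default_manifest_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_manifest" + path.suffix)


def write_dataset(ds: SpectralDataset, path, manifest: "Path | str | None" = None) -> None:
    """Write the wide spectra table and its manifest.

    Numbers are serialised with shortest round-trip precision so that
    ``read_dataset(write_dataset(ds))`` is bitwise identity on values.
    """
    path = Path(path)
    manifest = Path(manifest) if manifest is not None else default_manifest_path(path)
    sep = _sep_for(path)
    try:
        with open(path, "w") as fh:
            fh.write("sample_id" + sep
                     + sep.join(repr(float(w)) for w in ds.wavelengths) + "\n")
            for i in range(len(ds)):
                fh.write(ds.sample_ids[i] + sep
                         + sep.join(repr(float(v)) for v in ds.intensities[i]) + "\n")
        with open(manifest, "w") as fh:
            fh.write("sample_id,class,tablet,shot\n")
            for i in range(len(ds)):
                fh.write(f"{ds.sample_ids[i]},{ds.class_names[ds.labels[i]]},"
                         f"{ds.groups[i]},{ds.shot_indices[i]}\n")
    except OSError as exc:
        raise DatasetError(f"cannot write dataset to {path}: {exc}") from exc


def read_dataset(path, manifest: "Path | str | None" = None) -> SpectralDataset:
    """Read a wide spectra table plus manifest back into a dataset.

    Raises :class:`DatasetError` naming the offending sample when a manifest
    entry is missing, and rejects non-monotone wavelength grids.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"spectra table not found: {path}")
    manifest = Path(manifest) if manifest is not None else default_manifest_path(path)
    if not manifest.exists():
        raise DatasetError(f"manifest not found: {manifest}")
    sep = _sep_for(path)
    table = pd.read_csv(path, sep=sep, header=0, dtype={0: str},
                        float_precision="round_trip")
    wavelengths = np.array([float(c) for c in table.columns[1:]])
    if len(wavelengths) >= 2 and not np.all(np.diff(wavelengths) > 0):
        raise DatasetError(f"{path}: wavelength grid not strictly increasing")
    sample_ids = table.iloc[:, 0].astype(str).tolist()
    intensities = table.iloc[:, 1:].to_numpy(dtype=float)

    man = pd.read_csv(manifest, dtype={"sample_id": str, "tablet": str})
    for col in ("sample_id", "class", "tablet", "shot"):
        if col not in man.columns:
            raise DatasetError(f"{manifest}: missing manifest column {col!r}")
    man = man.set_index("sample_id")
    if man.index.has_duplicates:
        dup = man.index[man.index.duplicated()][0]
        raise DatasetError(f"{manifest}: duplicate manifest entry for {dup!r}")
    missing = [sid for sid in sample_ids if sid not in man.index]
    if missing:
        raise DatasetError(f"{manifest}: no manifest entry for sample {missing[0]!r}")

    # class order = first appearance in the manifest, so read∘write is identity
    class_names = list(dict.fromkeys(man["class"].astype(str)))
    name_to_idx = {c: i for i, c in enumerate(class_names)}
    rows = man.loc[sample_ids]
    labels = np.array([name_to_idx[str(c)] for c in rows["class"]])
    groups = rows["tablet"].astype(str).to_numpy(dtype=object)
    shots = rows["shot"].astype(int).to_numpy()
    if intensities.size == 0:
        intensities = np.empty((0, len(wavelengths)))
    return SpectralDataset(wavelengths=wavelengths, intensities=intensities,
                           labels=labels, class_names=class_names, groups=groups,
                           sample_ids=sample_ids, shot_indices=shots)
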