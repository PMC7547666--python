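"""Spectra dataset container, CSV I/O and block-stratified splits.

A :class:`SpectraDataset` holds ``n`` absorbance spectra measured on a common
wavenumber axis of length ``p`` together with one reference concentration per
sample (mmol/L).  All downstream modelling and wavelength-selection code
consumes this container.

The validation/test splits implemented here are *block-stratified*: samples
are sorted by concentration, partitioned into contiguous blocks of (near)
equal size, and one sample is drawn uniformly at random from each block.
This guarantees that every held-out set spans the full concentration range,
which matters for small calibration sets where a plain random split can
easily miss the extremes.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParseError",
    "SpectraDataset",
    "SplitIndices",
    "read_spectra_csv",
    "write_spectra_csv",
    "block_stratified_split",
    "representative_test_split",
    "save_split",
    "load_split",
]

#: significant digits used when writing CSV; lossless for absorbance and
#: concentration magnitudes encountered here
CSV_SIG_DIGITS = 10


class ParseError(ValueError):
    """Raised when a spectra CSV file violates the expected dialect."""


@dataclass
class SpectraDataset:
    """Absorbance spectra with a shared wavenumber axis and reference values.

    Parameters
    ----------
    wavenumbers : array of shape (p,)
        Strictly increasing wavenumber axis in cm^-1.
    absorbance : array of shape (n, p)
        Absorbance (AU); row ``i`` belongs to sample ``i``.
    concentration : array of shape (n,)
        Reference analyte concentration in mmol/L, non-negative.
    sample_ids : sequence of str, length n
        External sample identity; purely informational.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    concentration: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float).ravel()
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 2:
            raise ValueError("wavenumbers must be 1-D and absorbance 2-D")
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {p} columns but axis has {self.wavenumbers.size}"
            )
        if n < 2 or p < 2:
            raise ValueError(f"need n >= 2 and p >= 2, got n={n}, p={p}")
        if self.concentration.size != n:
            raise ValueError("concentration length must match number of spectra")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match number of spectra")
        for name, arr in (
            ("wavenumbers", self.wavenumbers),
            ("absorbance", self.absorbance),
            ("concentration", self.concentration),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def n(self) -> int:
        return self.absorbance.shape[0]

    @property
    def p(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices) -> "SpectraDataset":
        """Row subset (copy) keeping the full wavenumber axis."""
        idx = np.asarray(indices, dtype=int)
        return SpectraDataset(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[idx].copy(),
            concentration=self.concentration[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class SplitIndices:
    """Disjoint calibration/validation index sets covering ``0..n-1``."""

    calibration: np.ndarray
    validation: np.ndarray

    def __post_init__(self) -> None:
        self.calibration = np.asarray(self.calibration, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        if np.intersect1d(self.calibration, self.validation).size:
            raise ValueError("calibration and validation sets overlap")


def read_spectra_csv(path) -> SpectraDataset:
    """Read a spectra table from CSV.

    Expected dialect: UTF-8, comma-separated, header row
    ``sample_id,concentration_mmol_L,<wn1>,<wn2>,...`` with wavenumbers in
    cm^-1, then one row per sample.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 4 or header[0] != "sample_id" or header[1] != "concentration_mmol_L":
            raise ParseError(
                f"{path}: malformed header; expected "
                "'sample_id,concentration_mmol_L,<wn1>,...'"
            )
        try:
            wn = np.array([float(v) for v in header[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric wavenumber in header: {exc}") from None
        if np.unique(wn).size != wn.size:
            raise ParseError(f"{path}: duplicated wavenumber in header")
        if np.any(np.diff(wn) <= 0):
            raise ParseError(f"{path}: wavenumber header is not strictly increasing")

        ids: list[str] = []
        conc: list[float] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: row {lineno} has {len(row)} fields, expected {len(header)}"
                )
            ids.append(row[0])
            values = []
            for col, value in enumerate(row[1:], start=1):
                try:
                    values.append(float(value))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell at row {lineno}, "
                        f"column '{header[col]}'"
                    ) from None
            conc.append(values[0])
            rows.append(values[1:])
    try:
        return SpectraDataset(
            wavenumbers=wn,
            absorbance=np.array(rows, dtype=float),
            concentration=np.array(conc, dtype=float),
            sample_ids=ids,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _fmt(x: float) -> str:
    return f"{x:.{CSV_SIG_DIGITS}g}"


def write_spectra_csv(ds: SpectraDataset, path) -> None:
    """Write a dataset in the CSV dialect of :func:`read_spectra_csv`.

    Numbers are printed with 10 significant digits, so a written file read
    back yields values identical at that precision.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "concentration_mmol_L"] + [_fmt(w) for w in ds.wavenumbers]
        )
        for i in range(ds.n):
            writer.writerow(
                [ds.sample_ids[i], _fmt(ds.concentration[i])]
                + [_fmt(v) for v in ds.absorbance[i]]
            )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def block_sizes(n: int, n_v: int) -> list[int]:
    """Sizes of the ``n_v`` contiguous blocks: equal or one less, larger first."""
    base, rem = divmod(n, n_v)
    return [base + 1] * rem + [base] * (n_v - rem)


def block_stratified_split(concentration, n_v: int, seed) -> SplitIndices:
    """Representative validation split by concentration-sorted blocks.

    Samples are sorted by concentration (ties broken by ascending original
    index), partitioned into ``n_v`` contiguous blocks whose sizes differ by
    at most one (larger blocks first), and exactly one sample per block is
    drawn uniformly at random into the validation set.

    Parameters
    ----------
    concentration : array of shape (n,)
    n_v : int
        Number of validation samples, ``1 <= n_v <= n``.
    seed : int or numpy.random.Generator
    """
    y = np.asarray(concentration, dtype=float).ravel()
    n = y.size
    if not 1 <= n_v <= n:
        raise ValueError(f"n_v must be in [1, {n}], got {n_v}")
    rng = _as_rng(seed)
    order = np.argsort(y, kind="stable")  # stable => ties by original index
    sizes = block_sizes(n, n_v)
    validation = []
    start = 0
    for size in sizes:
        block = order[start : start + size]
        validation.append(block[rng.integers(size)])
        start += size
    validation = np.sort(np.asarray(validation, dtype=int))
    calibration = np.setdiff1d(np.arange(n), validation)
    return SplitIndices(calibration=calibration, validation=validation)


def representative_test_split(ds: SpectraDataset, n_t: int, seed) -> SplitIndices:
    """Hold out ``n_t`` test samples with the block-stratified scheme.

    The returned ``validation`` field is the test set; ``calibration`` is the
    training remainder, to be used for all selection and modelling steps.
    """
    split = block_stratified_split(ds.concentration, n_t, seed)
    if split.calibration.size == 0:
        warnings.warn("test split consumed every sample; calibration set is empty")
    return split


def save_split(split: SplitIndices, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "calibration": split.calibration.tolist(),
                "validation": split.validation.tolist(),
            },
            fh,
        )


def load_split(path) -> SplitIndices:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return SplitIndices(
        calibration=np.asarray(obj["calibration"], dtype=int),
        validation=np.asarray(obj["validation"], dtype=int),
    )
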