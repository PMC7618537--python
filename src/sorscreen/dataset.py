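"""Core containers: wavenumber grids, spectra, SORS pairs and labelled sets.

A SORS measurement of a sealed vial yields two spectra: one acquired with the
collection zone coincident with the laser spot (*zero offset*, dominated by
the container wall) and one with the collection zone laterally displaced
(*offset*, enriched in sub-surface content signal).  Downstream modules
operate either on matched pairs (:class:`SorsPair`) or on a labelled spectra
matrix sharing one wavenumber axis (:class:`LabeledSpectraSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateDataError",
    "PairingError",
    "WavenumberGrid",
    "Spectrum",
    "SorsPair",
    "LabeledSpectraSet",
    "build_grid",
]


class DegenerateDataError(ValueError):
    """Raised when an input is structurally valid but numerically degenerate
    (zero variance, all-zero reference signal, singular covariance)."""


class PairingError(ValueError):
    """Raised when zero-offset and offset spectra cannot be matched up."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly increasing Raman-shift axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumber values")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        step = d.mean()
        if np.max(np.abs(d - step)) > 1e-9 * max(abs(step), 1.0):
            raise ValueError("grid spacing must be uniform (1e-9 rel. tol.)")

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return int(self.values.size)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with ``lo <= wavenumber <= hi`` (inclusive)."""
        if lo > hi:
            raise ValueError(f"window lo={lo} exceeds hi={hi}")
        return (self.values >= lo) & (self.values <= hi)

    def covers(self, wavenumber: float) -> bool:
        return self.lo <= wavenumber <= self.hi

    def same_axis(self, other: "WavenumberGrid", tol: float = 1e-6) -> bool:
        """Axes are considered identical when equal after rounding to `tol` cm⁻¹."""
        return len(self) == len(other) and bool(
            np.all(np.abs(self.values - other.values) <= tol)
        )


def build_grid(lo: float, hi: float, step: float) -> WavenumberGrid:
    """Uniform wavenumber grid from ``lo`` to ``hi`` inclusive (within one step).

    Parameters
    ----------
    lo, hi : float
        Grid endpoints in cm⁻¹; ``lo < hi`` required.
    step : float
        Grid spacing in cm⁻¹, must be positive.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if lo >= hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return WavenumberGrid(lo + step * np.arange(n))


@dataclass
class Spectrum:
    """One intensity vector on a wavenumber grid plus acquisition metadata.

    ``role`` records the acquisition geometry (``"zero-offset"``/``"offset"``)
    or the processing stage (e.g. ``"content"`` after separation).
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    role: str = ""
    spectrum_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.grid),):
            raise ValueError(
                f"intensities shape {y.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        self.intensities = y

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid, self.intensities.copy(), self.role,
                        self.spectrum_id, dict(self.meta))


@dataclass
class SorsPair:
    """Matched zero-offset / offset acquisition of one vial measurement."""

    zero_offset: Spectrum
    offset: Spectrum
    vial_id: str = ""
    class_label: str = ""
    batch: str = ""
    measurement_id: str = ""

    def __post_init__(self) -> None:
        if not self.zero_offset.grid.same_axis(self.offset.grid):
            raise ValueError("zero-offset and offset spectra must share one grid")

    @property
    def grid(self) -> WavenumberGrid:
        return self.zero_offset.grid


@dataclass
class LabeledSpectraSet:
    """Spectra matrix (n_spectra × n_channels) with class/batch/vial labels."""

    grid: WavenumberGrid
    matrix: np.ndarray
    labels: np.ndarray
    batches: np.ndarray
    vials: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix shape {m.shape} incompatible with grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(m)):
            raise ValueError("spectra matrix contains non-finite entries")
        self.matrix = m
        for name in ("labels", "batches", "vials"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (m.shape[0],):
                raise ValueError(f"{name} length {arr.shape} != n_spectra {m.shape[0]}")
            setattr(self, name, arr)

    @property
    def n_spectra(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.matrix.shape[1])

    def copy(self) -> "LabeledSpectraSet":
        return LabeledSpectraSet(
            self.grid,
            self.matrix.copy(),
            self.labels.copy(),
            self.batches.copy(),
            self.vials.copy(),
            list(self.provenance),
        )

    def with_matrix(self, matrix: np.ndarray, grid: WavenumberGrid | None = None,
                    step: dict | None = None) -> "LabeledSpectraSet":
        """New set with the same labels but a replaced matrix (and optionally grid),
        appending `step` to the provenance record."""
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return LabeledSpectraSet(
            grid if grid is not None else self.grid,
            matrix, self.labels.copy(), self.batches.copy(), self.vials.copy(), prov,
        )

    def select(self, rows: Sequence[int] | np.ndarray) -> "LabeledSpectraSet":
        rows = np.asarray(rows)
        return LabeledSpectraSet(
            self.grid, self.matrix[rows], self.labels[rows],
            self.batches[rows], self.vials[rows], list(self.provenance),
        )

    def class_rows(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def stack_spectra(
    grid: WavenumberGrid,
    spectra: Iterable[np.ndarray],
    labels: Iterable[str],
    batches: Iterable[str],
    vials: Iterable[str],
    provenance: list | None = None,
) -> LabeledSpectraSet:
    """Assemble a :class:`LabeledSpectraSet` from per-spectrum vectors."""
    matrix = np.vstack([np.asarray(s, dtype=float) for s in spectra])
    return LabeledSpectraSet(
        grid, matrix,
        np.asarray(list(labels), dtype=object),
        np.asarray(list(batches), dtype=object),
        np.asarray(list(vials), dtype=object),
        provenance or [],
    )
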