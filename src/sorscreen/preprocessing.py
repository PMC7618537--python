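"""Spectral conditioning: truncation, polynomial background removal, SNV,
mean centering.

The canonical chain for vial screening is: truncate to 760–1720 cm⁻¹ (drops
the residual glass-fluorescence region and the silent high-shift end), remove
the residual background per spectrum with a 5th-order polynomial, normalise
each spectrum to zero mean and unit standard deviation (standard normal
variate, SNV — removes multiplicative intensity effects), then mean-centre
the columns.  Centering is switchable because unsupervised inspection of a
single homogeneous sample set (e.g. degradation studies) is run without it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dataset import DegenerateDataError, LabeledSpectraSet, WavenumberGrid

__all__ = [
    "PreprocessConfig",
    "truncate",
    "polynomial_detrend",
    "snv",
    "mean_center",
    "preprocess_set",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain; defaults reproduce the
    screening pipeline (truncation bounds inclusive)."""

    truncate_lo: float = 760.0
    truncate_hi: float = 1720.0
    poly_order: int = 5
    poly_mode: str = "iterative"
    do_snv: bool = True
    do_mean_center: bool = True

    def __post_init__(self) -> None:
        if self.truncate_lo >= self.truncate_hi:
            raise ValueError("truncate_lo must be < truncate_hi")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.poly_mode not in ("plain", "iterative"):
            raise ValueError(f"unknown poly_mode {self.poly_mode!r}")


def truncate(sset: LabeledSpectraSet, lo: float, hi: float) -> LabeledSpectraSet:
    """Keep exactly the channels with ``lo <= wavenumber <= hi`` (inclusive)."""
    mask = sset.grid.window_mask(lo, hi)
    if not mask.any():
        raise ValueError(
            f"truncation window [{lo}, {hi}] does not overlap grid "
            f"[{sset.grid.lo}, {sset.grid.hi}]"
        )
    new_grid = WavenumberGrid(sset.grid.values[mask])
    return sset.with_matrix(
        sset.matrix[:, mask], grid=new_grid,
        step={"step": "truncate", "lo": lo, "hi": hi},
    )


def _polyfit(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    # least-squares fit in a shifted/scaled (numerically stable) basis;
    # the contract is the fit itself, not the basis
    return np.polynomial.Polynomial.fit(x, y, order).__call__(x)


def polynomial_detrend(
    spectrum: np.ndarray,
    grid: WavenumberGrid | np.ndarray,
    order: int = 5,
    mode: str = "iterative",
    max_iter: int = 100,
    rel_tol: float = 1e-6,
):
    """Remove a smooth polynomial background from one spectrum.

    ``plain`` subtracts the order-``order`` least-squares polynomial fit.
    ``iterative`` uses modified polynomial fitting: repeatedly fit, then clip
    the working spectrum to ``min(spectrum, fit)``, until the maximum change
    is below ``rel_tol`` relative to the input scale (or ``max_iter``).  The
    clipping keeps genuine peaks from dragging the baseline upward, so peak
    heights survive baseline removal.

    Returns ``(corrected, baseline)`` with ``corrected = spectrum − baseline``.
    """
    y = np.asarray(spectrum, dtype=float)
    x = grid.values if isinstance(grid, WavenumberGrid) else np.asarray(grid, float)
    if y.shape != x.shape:
        raise ValueError("spectrum and grid lengths differ")
    if y.size <= order + 1:
        raise ValueError(
            f"need more than order+1 = {order + 1} channels, got {y.size}"
        )
    if mode not in ("plain", "iterative"):
        raise ValueError(f"unknown detrend mode {mode!r}")

    if mode == "plain":
        baseline = _polyfit(x, y, order)
        return y - baseline, baseline

    scale = max(np.max(np.abs(y)), np.finfo(float).tiny)
    work = y.copy()
    baseline = _polyfit(x, work, order)
    for _ in range(max_iter):
        clipped = np.minimum(work, baseline)
        change = np.max(np.abs(clipped - work)) / scale
        work = clipped
        baseline = _polyfit(x, work, order)
        if change < rel_tol:
            break
    return y - baseline, baseline


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum ``(x − mean) / sd`` with the
    n−1 denominator.  Zero-variance input raises :class:`DegenerateDataError`."""
    y = np.asarray(spectrum, dtype=float)
    if y.size < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = y.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("SNV undefined for a constant spectrum")
    return (y - y.mean()) / sd


def mean_center(sset: LabeledSpectraSet):
    """Subtract each column's mean; returns ``(centered set, mean vector)``."""
    mu = sset.matrix.mean(axis=0)
    centered = sset.with_matrix(sset.matrix - mu, step={"step": "mean_center"})
    return centered, mu


def preprocess_set(
    sset: LabeledSpectraSet, config: PreprocessConfig | None = None
) -> LabeledSpectraSet:
    """Apply the full conditioning chain in fixed order: truncate →
    per-row polynomial detrend → per-row SNV → column mean-centering.

    The order matters (SNV before centering is not the same map as centering
    before SNV); the chain and its parameters are appended to the output's
    provenance.
    """
    config = config or PreprocessConfig()
    out = truncate(sset, config.truncate_lo, config.truncate_hi)
    if config.poly_order > 0:
        rows = np.empty_like(out.matrix)
        for i in range(out.n_spectra):
            rows[i], _ = polynomial_detrend(
                out.matrix[i], out.grid, order=config.poly_order, mode=config.poly_mode
            )
        out = out.with_matrix(rows, step={"step": "polynomial_detrend",
                                          "order": config.poly_order,
                                          "mode": config.poly_mode})
    if config.do_snv:
        rows = np.vstack([snv(r) for r in out.matrix])
        out = out.with_matrix(rows, step={"step": "snv"})
    if config.do_mean_center:
        out, _ = mean_center(out)
    out.provenance.append({"step": "preprocess_set", "config": asdict(config)})
    return out
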