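"""Readers and writers for spectra collections.

CSV is the canonical interchange format, in two dialects:

* **wide** — first column ``wavenumber``, one column per spectrum, spectrum
  ids as headers; all spectra share the axis.
* **long** — columns ``wavenumber, intensity, spectrum_id``; each spectrum is
  a contiguous block and may declare its own axis (differing axes are
  interpolated onto the first spectrum's grid with a warning).

Per-spectrum metadata (acquisition role, vial, class, batch, measurement)
travels in a sidecar CSV (``<name>.meta.csv`` next to the spectra file by
default).  A minimal read-only JCAMP-DX parser covers the common AFFN
``(X++(Y..Y))`` and ``(XY..XY)`` data forms produced by spectrometer export
software.

Numeric round-trips are lossless: intensities are written with 17
significant digits.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    LabeledSpectraSet,
    PairingError,
    SorsPair,
    Spectrum,
    WavenumberGrid,
)

__all__ = [
    "write_pairs_csv",
    "read_pairs_csv",
    "write_set_csv",
    "read_set_csv",
    "read_jcamp",
    "default_meta_path",
]

_FLOAT_FMT = "%.17g"
_AXIS_TOL = 1e-6  # cm⁻¹; axes equal after rounding to this are "the same"


def default_meta_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.csv")


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Coerce to float, reporting the first offending cell with its line."""
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise ValueError(
            f"{path}: non-numeric value {df.iloc[r, c]!r} in column "
            f"{df.columns[c]!r}, data line {r + 2}"
        ) from None


def _frame_to_blocks(path, dialect: str):
    """Read a spectra file into (spectrum_id -> (wavenumbers, intensities))."""
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 2 or df.columns[0] != "wavenumber":
            raise ValueError(
                f"{path}: wide dialect needs a leading 'wavenumber' column"
            )
        df = _check_numeric(df, path)
        wn = df["wavenumber"].to_numpy()
        return {c: (wn, df[c].to_numpy()) for c in df.columns[1:]}
    if dialect == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        needed = {"wavenumber", "intensity", "spectrum_id"}
        if not needed <= set(df.columns):
            raise ValueError(f"{path}: long dialect needs columns {sorted(needed)}")
        num = _check_numeric(df[["wavenumber", "intensity"]], path)
        blocks = {}
        for sid, g in df.assign(
            wavenumber=num["wavenumber"], intensity=num["intensity"]
        ).groupby("spectrum_id", sort=False):
            blocks[str(sid)] = (g["wavenumber"].to_numpy(), g["intensity"].to_numpy())
        return blocks
    raise ValueError(f"unknown dialect {dialect!r}")


def _common_axis(blocks: dict):
    """Put all blocks on one grid; interpolate (with a warning) if axes differ."""
    ids = list(blocks)
    ref_wn = blocks[ids[0]][0]
    grid = WavenumberGrid(ref_wn)
    out = {}
    for sid in ids:
        wn, y = blocks[sid]
        if wn.size == ref_wn.size and np.all(np.abs(wn - ref_wn) <= _AXIS_TOL):
            out[sid] = y
        else:
            warnings.warn(
                f"spectrum {sid!r} has a different wavenumber axis; "
                "interpolating onto the first spectrum's grid",
                RuntimeWarning,
                stacklevel=3,
            )
            out[sid] = np.interp(ref_wn, wn, y)
    return grid, out


def _read_meta(meta_path) -> pd.DataFrame:
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    meta = pd.read_csv(meta_path, dtype=str).fillna("")
    if "spectrum_id" not in meta.columns:
        raise ValueError(f"{meta_path}: metadata needs a 'spectrum_id' column")
    return meta.set_index("spectrum_id")


# ---------------------------------------------------------------------------
# SORS pairs
# ---------------------------------------------------------------------------

def write_pairs_csv(pairs, path, dialect: str = "wide", meta_path=None) -> Path:
    """Write SORS pairs (both roles per measurement) plus a metadata sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else default_meta_path(path)
    if not pairs:
        raise ValueError("no pairs to write")
    grid = pairs[0].grid
    columns, meta_rows = {}, []
    for i, p in enumerate(pairs):
        mid = p.measurement_id or f"m{i + 1:04d}"
        for role, spec in (("zero-offset", p.zero_offset), ("offset", p.offset)):
            sid = f"{mid}|{role}"
            columns[sid] = spec.intensities
            meta_rows.append(
                {"spectrum_id": sid, "role": role, "vial": p.vial_id,
                 "class": p.class_label, "batch": p.batch, "measurement": mid}
            )
    _write_blocks(grid, columns, path, dialect)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return path


def read_pairs_csv(path, dialect: str = "wide", meta_path=None):
    """Read SORS pairs, matching zero-offset/offset spectra per measurement.

    Raises :class:`PairingError` naming every measurement that lacks its
    partner spectrum.
    """
    path = Path(path)
    meta = _read_meta(meta_path or default_meta_path(path))
    grid, data = _common_axis(_frame_to_blocks(path, dialect))

    groups: dict = {}
    for sid, y in data.items():
        if sid not in meta.index:
            raise ValueError(f"spectrum {sid!r} missing from metadata sidecar")
        row = meta.loc[sid]
        groups.setdefault(row.get("measurement", sid), {})[row["role"]] = (sid, y, row)
    unpaired = sorted(m for m, roles in groups.items()
                      if {"zero-offset", "offset"} - set(roles))
    if unpaired:
        details = []
        for m in unpaired:
            row = next(iter(groups[m].values()))[2]
            details.append(f"{m} (vial {row.get('vial', '?')})")
        raise PairingError(
            "measurements missing a role partner: " + ", ".join(details)
        )
    pairs = []
    for mid, roles in groups.items():
        zid, zy, zrow = roles["zero-offset"]
        oid, oy, _ = roles["offset"]
        pairs.append(
            SorsPair(
                Spectrum(grid, zy, role="zero-offset", spectrum_id=zid),
                Spectrum(grid, oy, role="offset", spectrum_id=oid),
                vial_id=zrow.get("vial", ""), class_label=zrow.get("class", ""),
                batch=zrow.get("batch", ""), measurement_id=str(mid),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Labelled sets
# ---------------------------------------------------------------------------

def write_set_csv(sset: LabeledSpectraSet, path, dialect: str = "wide",
                  meta_path=None, role: str = "content") -> Path:
    """Write a labelled spectra set (one column/block per row) plus metadata."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else default_meta_path(path)
    columns, meta_rows = {}, []
    for i in range(sset.n_spectra):
        sid = f"s{i + 1:04d}"
        columns[sid] = sset.matrix[i]
        meta_rows.append(
            {"spectrum_id": sid, "role": role, "vial": sset.vials[i],
             "class": sset.labels[i], "batch": sset.batches[i], "measurement": sid}
        )
    _write_blocks(sset.grid, columns, path, dialect)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return path


def read_set_csv(path, dialect: str = "wide", meta_path=None) -> LabeledSpectraSet:
    path = Path(path)
    meta = _read_meta(meta_path or default_meta_path(path))
    grid, data = _common_axis(_frame_to_blocks(path, dialect))
    rows, labels, batches, vials = [], [], [], []
    for sid, y in data.items():
        if sid not in meta.index:
            raise ValueError(f"spectrum {sid!r} missing from metadata sidecar")
        m = meta.loc[sid]
        rows.append(y)
        labels.append(m.get("class", ""))
        batches.append(m.get("batch", ""))
        vials.append(m.get("vial", ""))
    return LabeledSpectraSet(
        grid, np.vstack(rows),
        np.asarray(labels, dtype=object),
        np.asarray(batches, dtype=object),
        np.asarray(vials, dtype=object),
        provenance=[{"step": "read_set_csv", "path": str(path), "dialect": dialect}],
    )


def _write_blocks(grid: WavenumberGrid, columns: dict, path: Path, dialect: str):
    if dialect == "wide":
        df = pd.DataFrame({"wavenumber": grid.values} | {k: v for k, v in columns.items()})
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif dialect == "long":
        frames = [
            pd.DataFrame({"wavenumber": grid.values, "intensity": y, "spectrum_id": sid})
            for sid, y in columns.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format=_FLOAT_FMT
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only)
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^##([^=]+)=\s*(.*)$")


def read_jcamp(path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (AFFN ``(X++(Y..Y))`` or
    ``(XY..XY)`` data tables) into a :class:`Spectrum`.

    Applies ``XFACTOR``/``YFACTOR`` scaling; the wavenumber axis must come
    out uniform and ascending (descending tables are reversed).
    """
    path = Path(path)
    labels: dict = {}
    xs: list = []
    ys: list = []
    mode = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            m = _LDR.match(line)
            if m:
                key = m.group(1).strip().upper().replace(" ", "")
                val = m.group(2).split("$$")[0].strip()
                if key == "XYDATA":
                    mode = "xydata"
                elif key in ("XYPOINTS", "PEAKTABLE"):
                    mode = "xypoints"
                elif key == "END":
                    mode = None
                else:
                    labels[key] = val
                    mode = None
                continue
            if mode is None:
                continue
            nums = re.split(r"[,\s;]+", line)
            try:
                vals = [float(v) for v in nums if v]
            except ValueError as err:
                raise ValueError(f"{path}: bad numeric value on line {lineno}") from err
            if mode == "xydata":
                # (X++(Y..Y)): first number is X of the first Y on the line
                if len(vals) < 2:
                    raise ValueError(f"{path}: truncated XYDATA line {lineno}")
                xs.append((vals[0], len(vals) - 1))
                ys.extend(vals[1:])
            else:
                if len(vals) % 2:
                    raise ValueError(f"{path}: odd pair count on line {lineno}")
                xs.extend(vals[0::2])
                ys.extend(vals[1::2])
                mode = "xypoints"
    if not ys:
        raise ValueError(f"{path}: no spectral data found")
    xfac = float(labels.get("XFACTOR", 1.0))
    yfac = float(labels.get("YFACTOR", 1.0))
    if xs and isinstance(xs[0], tuple):  # reconstruct X++(Y..Y) axis
        first_x = xs[0][0] * xfac
        if "DELTAX" in labels:
            dx = float(labels["DELTAX"]) * xfac
        else:
            last_x = float(labels.get("LASTX", xs[-1][0])) * xfac
            dx = (last_x - first_x) / max(len(ys) - 1, 1)
        wn = first_x + dx * np.arange(len(ys))
    else:
        wn = np.asarray(xs, dtype=float) * xfac
    inten = np.asarray(ys, dtype=float) * yfac
    if wn.size > 1 and wn[1] < wn[0]:
        wn, inten = wn[::-1], inten[::-1]
    return Spectrum(
        WavenumberGrid(wn), inten,
        role=str(labels.get("DATATYPE", "")).lower(),
        spectrum_id=str(labels.get("TITLE", path.stem)),
    )
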