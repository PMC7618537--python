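"""Synthetic SORS spectra generator for vaccine-authentication studies.

The forward model is a two-layer linear mixture.  Every acquisition sees a
*surface* signal S (broad glass-wall fluorescence peaking near 675 cm⁻¹) and
a *content* signal C (sum of excipient Raman bands), but with different
weights depending on the collection geometry::

    zero_offset = α_s·S + α_c·C + ε      offset = β_s·S + β_c·C + ε'

with the SORS contrast β_c/β_s > α_c/α_s: displacing the collection zone
enriches the sub-surface content signal relative to the wall.  Noise ε is
heteroscedastic Gaussian with standard deviation σ·sqrt(max(signal, 1)) per
channel, a shot-noise approximation adequate at high photon counts.

Band positions follow the excipient assignments observable through glass
vials — water ~1640 cm⁻¹ (broad), ethanol ~880 cm⁻¹, sucrose multiplets in
800–1460 cm⁻¹ — while dissolved NaCl is Raman-silent (dissociated atomic
ions have no intramolecular vibrations), so saline content is water-only.
Band *amplitudes* are free parameters of the generator: real formulation
concentrations are not public.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import LabeledSpectraSet, SorsPair, Spectrum, WavenumberGrid, build_grid

__all__ = [
    "RamanBand",
    "SubstanceModel",
    "InstrumentModel",
    "SUBSTANCES",
    "CLASS_LIBRARY",
    "substance_spectrum",
    "class_content",
    "glass_background",
    "simulate_pair",
    "generate_dataset",
    "inject_outlier",
    "default_grid",
]

# Tilt of the glass-fluorescence profile: small linear term anchored at a
# fixed pivot so the profile does not depend on the grid extent.  The slope is
# kept well below the Gaussian curvature at the peak so the argmax stays at
# glass_peak on a 1 cm⁻¹ grid.
_GLASS_SLOPE_PER_UNIT_AMP = 1e-5  # intensity per cm⁻¹ per unit glass amplitude
_GLASS_SLOPE_PIVOT = 2200.0  # cm⁻¹

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RamanBand:
    """One vibrational band: centre and FWHM in cm⁻¹, peak amplitude in
    arbitrary intensity units, Gaussian or Lorentzian profile."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be nonnegative, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            sigma = self.fwhm * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * (d / sigma) ** 2)
        hwhm = self.fwhm / 2.0
        return self.amplitude * hwhm**2 / (d**2 + hwhm**2)


@dataclass(frozen=True)
class SubstanceModel:
    """A dissolved substance as a list of Raman bands.

    A Raman-silent substance (NaCl) has an empty band list.  The
    ``concentration_scale`` multiplies all band amplitudes and is the handle
    used for per-vial concentration jitter.
    """

    name: str
    bands: tuple = ()
    concentration_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.concentration_scale < 0:
            raise ValueError("concentration_scale must be nonnegative")

    def scaled(self, factor: float) -> "SubstanceModel":
        return replace(self, concentration_scale=self.concentration_scale * factor)


@dataclass(frozen=True)
class InstrumentModel:
    """Two-layer mixing weights, noise level and glass-fluorescence shape.

    ``surface_zero``/``content_zero`` (α_s, α_c) weight the surface and
    content signals in the zero-offset acquisition; ``surface_offset``/
    ``content_offset`` (β_s, β_c) in the offset acquisition.  The SORS
    contrast requires β_c/β_s > α_c/α_s.
    """

    surface_zero: float = 1.0
    content_zero: float = 0.2
    surface_offset: float = 0.4
    content_offset: float = 0.3
    noise_scale: float = 0.2
    glass_peak: float = 675.0
    glass_fwhm: float = 300.0
    glass_amplitude: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("surface_zero", "content_zero", "surface_offset", "content_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.glass_fwhm <= 0 or self.glass_amplitude < 0:
            raise ValueError("glass_fwhm must be positive and glass_amplitude nonnegative")
        if self.content_offset / self.surface_offset <= self.content_zero / self.surface_zero:
            raise ValueError(
                "offset enrichment violated: need "
                "content_offset/surface_offset > content_zero/surface_zero"
            )


def default_grid() -> WavenumberGrid:
    """200–2000 cm⁻¹ at 1 cm⁻¹: covers the 675 cm⁻¹ nulling window and the
    760–1720 cm⁻¹ analysis window."""
    return build_grid(200.0, 2000.0, 1.0)


def substance_spectrum(model: SubstanceModel, grid: WavenumberGrid) -> np.ndarray:
    """Noiseless Raman spectrum of one substance: sum of its band profiles
    times ``concentration_scale``.  An empty band list yields all zeros."""
    y = np.zeros(len(grid))
    for band in model.bands:
        y += band.profile(grid.values)
    return model.concentration_scale * y


def class_content(substances, grid: WavenumberGrid) -> np.ndarray:
    """Noiseless content spectrum of a mixture (sum over substances)."""
    y = np.zeros(len(grid))
    for s in substances:
        y += substance_spectrum(s, grid)
    return y


def glass_background(instrument: InstrumentModel, grid: WavenumberGrid) -> np.ndarray:
    """Broad glass-fluorescence surface profile, unimodal with its maximum at
    ``instrument.glass_peak`` (default 675 cm⁻¹): a wide Gaussian plus a
    gentle downward tilt toward higher wavenumbers."""
    if not grid.covers(instrument.glass_peak):
        raise ValueError(
            f"grid [{grid.lo}, {grid.hi}] does not cover glass peak "
            f"{instrument.glass_peak} cm⁻¹"
        )
    sigma = instrument.glass_fwhm * _FWHM_TO_SIGMA
    hump = np.exp(-0.5 * ((grid.values - instrument.glass_peak) / sigma) ** 2)
    slope = _GLASS_SLOPE_PER_UNIT_AMP * np.maximum(_GLASS_SLOPE_PIVOT - grid.values, 0.0)
    return instrument.glass_amplitude * (hump + slope)


def simulate_pair(
    content: np.ndarray,
    instrument: InstrumentModel,
    grid: WavenumberGrid,
    seed,
    *,
    vial_id: str = "",
    class_label: str = "",
    batch: str = "",
    measurement_id: str = "",
) -> SorsPair:
    """Forward-simulate one SORS acquisition pair from a content spectrum.

    Both spectra are the two-layer mixture of the glass background and
    ``content`` under the instrument weights, with independent heteroscedastic
    Gaussian noise (sd = noise_scale·sqrt(max(signal, 1)) per channel).  The
    same seed reproduces the pair bit for bit.
    """
    content = np.asarray(content, dtype=float)
    if content.shape != (len(grid),):
        raise ValueError("content vector must be defined on the grid")
    surface = glass_background(instrument, grid)
    rng = np.random.default_rng(seed)

    def acquire(ws: float, wc: float, role: str) -> Spectrum:
        clean = ws * surface + wc * content
        noise = rng.standard_normal(len(grid)) * (
            instrument.noise_scale * np.sqrt(np.maximum(clean, 1.0))
        )
        return Spectrum(grid, clean + noise, role=role,
                        spectrum_id=f"{measurement_id}|{role}" if measurement_id else "")

    zero = acquire(instrument.surface_zero, instrument.content_zero, "zero-offset")
    off = acquire(instrument.surface_offset, instrument.content_offset, "offset")
    return SorsPair(zero, off, vial_id=vial_id, class_label=class_label,
                    batch=batch, measurement_id=measurement_id)


# ---------------------------------------------------------------------------
# Excipient / surrogate band library.
#
# Positions follow typical literature assignments; amplitudes are free
# defaults chosen so that, after separation, excipient bands sit clearly
# above the default noise floor (real relative concentrations are not
# public).  Water is broad; NaCl and the mM-level PBS salts contribute no
# observable bands.
# ---------------------------------------------------------------------------

WATER = SubstanceModel("water", (RamanBand(1640.0, 90.0, 100.0),))
ETHANOL = SubstanceModel("ethanol", (RamanBand(880.0, 20.0, 40.0),))
SUCROSE = SubstanceModel(
    "sucrose",
    (
        RamanBand(835.0, 25.0, 30.0),
        RamanBand(1065.0, 25.0, 25.0),
        RamanBand(1130.0, 25.0, 35.0),
        RamanBand(1340.0, 30.0, 20.0),
        RamanBand(1460.0, 30.0, 20.0),
    ),
)
HISTIDINE = SubstanceModel(
    "l-histidine",
    (RamanBand(1000.0, 18.0, 3.0), RamanBand(1570.0, 25.0, 3.0)),
)
SODIUM_CHLORIDE = SubstanceModel("sodium chloride", ())
GLUCOSE = SubstanceModel(
    "glucose",
    (
        RamanBand(915.0, 25.0, 25.0),
        RamanBand(1060.0, 25.0, 30.0),
        RamanBand(1125.0, 25.0, 30.0),
        RamanBand(1365.0, 30.0, 20.0),
    ),
)
MANNITOL = SubstanceModel(
    "mannitol",
    (
        RamanBand(875.0, 22.0, 30.0),
        RamanBand(1035.0, 25.0, 30.0),
        RamanBand(1260.0, 28.0, 20.0),
    ),
)
HYALURONIC_ACID = SubstanceModel(
    "hyaluronic acid serum",
    (
        RamanBand(1045.0, 30.0, 20.0),
        RamanBand(1125.0, 30.0, 18.0),
        RamanBand(1410.0, 35.0, 15.0),
    ),
)
AMIKACIN = SubstanceModel(
    "amikacin",
    (
        RamanBand(975.0, 25.0, 30.0),
        RamanBand(1100.0, 28.0, 25.0),
        RamanBand(1460.0, 30.0, 15.0),
    ),
)
GENTAMICIN = SubstanceModel(
    "gentamicin",
    (
        RamanBand(965.0, 25.0, 25.0),
        RamanBand(1050.0, 28.0, 25.0),
        RamanBand(1385.0, 30.0, 15.0),
    ),
)

SUBSTANCES = {
    s.name: s
    for s in (
        WATER, ETHANOL, SUCROSE, HISTIDINE, SODIUM_CHLORIDE,
        GLUCOSE, MANNITOL, HYALURONIC_ACID, AMIKACIN, GENTAMICIN,
    )
}

#: Content composition per sample class.  The genuine vaccine carries water,
#: sucrose, ethanol and weak L-histidine; aqueous-salt surrogates (saline,
#: PBS) are spectroscopically water-only.
CLASS_LIBRARY: dict = {
    "genuine": (WATER, SUCROSE, ETHANOL, HISTIDINE),
    "water": (WATER,),
    "saline": (WATER, SODIUM_CHLORIDE),
    "pbs": (WATER, SODIUM_CHLORIDE),
    "sucrose": (WATER, SUCROSE),
    "glucose": (WATER, GLUCOSE),
    "mannitol": (WATER, MANNITOL),
    "hyaluronic_acid": (WATER, HYALURONIC_ACID),
    "amikacin": (WATER, AMIKACIN),
    "gentamicin": (WATER, GENTAMICIN),
}

#: Default batch plan: genuine vials cycle through six production batches
#: (five from one site, one from a second); surrogates carry a single tag.
DEFAULT_GENUINE_BATCHES = ("B1", "B2", "B3", "B4", "B5", "B6")


def _resolve_classes(classes) -> dict:
    if classes is None:
        classes = ("genuine", "saline")
    if isinstance(classes, dict):
        return {str(k): tuple(v) for k, v in classes.items()}
    resolved = {}
    for name in classes:
        if name not in CLASS_LIBRARY:
            raise ValueError(
                f"unknown class {name!r}; known: {sorted(CLASS_LIBRARY)}"
            )
        resolved[name] = CLASS_LIBRARY[name]
    return resolved


def generate_dataset(
    classes=None,
    n_vials: int = 10,
    replicates: int = 6,
    batch_plan: dict | None = None,
    instrument: InstrumentModel | None = None,
    grid: WavenumberGrid | None = None,
    seed=0,
    jitter_sd: float = 0.02,
) -> list:
    """Generate SORS pairs for a multi-class vial study.

    Parameters
    ----------
    classes
        Class names from :data:`CLASS_LIBRARY`, or a mapping of class name to
        a sequence of :class:`SubstanceModel` (custom mixtures).
    n_vials, replicates
        Vials per class and measurements per vial (default six, measured at
        different vial positions).
    batch_plan
        Mapping class name → sequence of batch tags cycled over that class's
        vials.  Defaults to six batches for ``"genuine"`` and a single tag
        otherwise.  Unknown class names raise ``ValueError``.
    jitter_sd
        Standard deviation of the multiplicative log-normal per-vial
        concentration jitter (applied once per vial per substance; the vial's
        replicates share the same content realisation and differ only by
        noise).
    seed
        Single seed for all randomness (jitter and noise).

    Returns
    -------
    list of :class:`SorsPair`, ``n_classes · n_vials · replicates`` in total.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n_vials < 1:
        raise ValueError("n_vials must be >= 1")
    class_map = _resolve_classes(classes)
    if not class_map:
        raise ValueError("at least one class is required")
    if batch_plan is not None:
        unknown = set(batch_plan) - set(class_map)
        if unknown:
            raise ValueError(f"batch plan names unknown classes: {sorted(unknown)}")
    instrument = instrument or InstrumentModel()
    grid = grid or default_grid()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pairs: list = []
    for cls, substances in class_map.items():
        if batch_plan and cls in batch_plan:
            batches = tuple(batch_plan[cls])
        elif cls == "genuine":
            batches = DEFAULT_GENUINE_BATCHES
        else:
            batches = ("B1",)
        for v in range(n_vials):
            vial_id = f"{cls}-v{v + 1:02d}"
            batch = batches[v % len(batches)]
            jittered = [
                s.scaled(float(np.exp(rng.normal(0.0, jitter_sd)))) if jitter_sd > 0 else s
                for s in substances
            ]
            content = class_content(jittered, grid)
            for r in range(replicates):
                pair_seed = int(rng.integers(0, 2**31 - 1))
                pairs.append(
                    simulate_pair(
                        content, instrument, grid, pair_seed,
                        vial_id=vial_id, class_label=cls, batch=batch,
                        measurement_id=f"{vial_id}-r{r + 1}",
                    )
                )
    return pairs


def inject_outlier(
    sset: LabeledSpectraSet,
    row: int,
    mode: str = "spike",
    seed=0,
    magnitude: float = 5.0,
) -> LabeledSpectraSet:
    """Return a copy of the set with one corrupted row.

    ``spike`` adds a large narrow Gaussian spike (height ``magnitude`` × the
    row's max absolute intensity) at a seeded random position; ``scaled-
    baseline`` multiplies the whole row by ``magnitude``.  All other rows are
    untouched; the same seed reproduces the corruption exactly.
    """
    if not 0 <= row < sset.n_spectra:
        raise IndexError(f"row {row} out of range for {sset.n_spectra} spectra")
    if mode not in ("spike", "scaled-baseline"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    out = sset.copy()
    rng = np.random.default_rng(seed)
    y = out.matrix[row]
    if mode == "spike":
        center = float(rng.uniform(sset.grid.lo, sset.grid.hi))
        height = magnitude * max(np.max(np.abs(y)), 1.0)
        width = 3.0 * sset.grid.step
        out.matrix[row] = y + height * np.exp(
            -0.5 * ((sset.grid.values - center) / width) ** 2
        )
    else:
        out.matrix[row] = magnitude * y
    out.provenance = list(out.provenance) + [
        {"step": "inject_outlier", "row": int(row), "mode": mode, "seed": seed}
    ]
    return out
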