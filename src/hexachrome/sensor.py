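"""Forward model of the hexa-chromatic stacked-photodiode image sensor.

The sensor combines two ideas borrowed from the mantis-shrimp visual system:

* every pixel holds **three vertically stacked photodiodes** in silicon, whose
  wavelength-dependent absorption depth turns the stack into three broad
  spectral observations (blue-ish top, green/red middle, red/NIR bottom);
* a **checkerboard of pixelated short-pass (SP) / long-pass (LP) filters**
  splits the array into visible pixels and NIR pixels.

Together they give six spectral channels from a single chip: three visible
(SP x {top, middle, bottom}) and three near-infrared (LP x {top, middle,
bottom}).  This module turns a spectral scene (photon radiance per pixel and
wavelength) into a raw mosaic digital-number frame with realistic quantum
efficiency, filter leakage, photon shot noise, additive read noise, full-well
clipping and quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "FILTERS",
    "LAYERS",
    "WAVELENGTH_GRID",
    "QuantumEfficiencyModel",
    "SensorConfig",
    "MosaicFrame",
    "silicon_absorption",
    "filter_transmission",
    "build_default_qe",
    "expose",
    "max_snr_db",
]

FILTERS = ("SP", "LP")
LAYERS = ("top", "middle", "bottom")

#: Default simulation wavelength grid, 1 nm from 400 to 1000 nm.  Fine enough
#: to resolve the 17 nm FWHM monochromator bands used in spectral tests.
WAVELENGTH_GRID = np.arange(400.0, 1001.0, 1.0)

# Absorption coefficient of crystalline silicon at room temperature,
# (wavelength nm, alpha cm^-1).  Standard reference data; interpolated
# log-linearly in between.
_SI_ALPHA_TABLE = np.array(
    [
        (400.0, 9.52e4),
        (425.0, 4.00e4),
        (450.0, 2.55e4),
        (475.0, 1.68e4),
        (500.0, 1.11e4),
        (525.0, 8.30e3),
        (550.0, 7.05e3),
        (575.0, 5.39e3),
        (600.0, 4.14e3),
        (625.0, 3.43e3),
        (650.0, 2.81e3),
        (675.0, 2.29e3),
        (700.0, 1.90e3),
        (725.0, 1.58e3),
        (750.0, 1.30e3),
        (775.0, 1.06e3),
        (800.0, 8.50e2),
        (825.0, 6.80e2),
        (850.0, 5.35e2),
        (875.0, 4.16e2),
        (900.0, 3.06e2),
        (925.0, 2.24e2),
        (950.0, 1.57e2),
        (975.0, 1.03e2),
        (1000.0, 6.40e1),
    ]
)


class ValidationError(ValueError):
    """Raised when a model input violates its contract."""


def silicon_absorption(wavelengths: np.ndarray) -> np.ndarray:
    """Absorption coefficient of silicon in um^-1 on ``wavelengths`` (nm).

    Log-linear interpolation of the built-in reference table.  Silicon
    absorbs blue light within a fraction of a micron but needs tens of
    microns in the NIR — the physical basis of the stacked-photodiode
    spectral response.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() < _SI_ALPHA_TABLE[0, 0] or wl.max() > _SI_ALPHA_TABLE[-1, 0]:
        raise ValidationError(
            "wavelength grid extends beyond the silicon absorption table "
            f"({_SI_ALPHA_TABLE[0, 0]:.0f}-{_SI_ALPHA_TABLE[-1, 0]:.0f} nm)"
        )
    log_alpha = np.interp(wl, _SI_ALPHA_TABLE[:, 0], np.log(_SI_ALPHA_TABLE[:, 1]))
    return np.exp(log_alpha) * 1e-4  # cm^-1 -> um^-1


def filter_transmission(
    wavelengths: np.ndarray,
    kind: str,
    od: float = 4.0,
    sp_edge: float = 662.0,
    lp_edge: float = 668.0,
    edge_width: float = 3.0,
    peak: float = 0.95,
) -> np.ndarray:
    """Transmission of the pixelated SP or LP interference filter.

    A logistic band edge with in-band transmission ``peak`` and out-of-band
    transmission ``peak * 10**-od``.  The SP filter passes the visible band
    and blocks the NIR; the LP filter is the complement with its cut-on just
    above the SP cut-off.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if kind not in FILTERS:
        raise ValidationError(f"unknown filter kind {kind!r}; expected one of {FILTERS}")
    floor = 10.0 ** (-float(od))
    if kind == "SP":
        s = 1.0 / (1.0 + np.exp((wl - sp_edge) / edge_width))
    else:
        s = 1.0 / (1.0 + np.exp(-(wl - lp_edge) / edge_width))
    return peak * (floor + (1.0 - floor) * s)


@dataclass(frozen=True)
class QuantumEfficiencyModel:
    """Six quantum-efficiency curves of the hexa-chromatic sensor.

    ``qe`` has shape (2, 3, L): axis 0 is the pixelated filter (SP, LP),
    axis 1 the photodiode layer (top, middle, bottom), axis 2 the wavelength
    sample.  All values lie in [0, 1].
    """

    wavelengths: np.ndarray
    qe: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        qe = np.asarray(self.qe, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be 1-D and strictly increasing")
        if qe.shape != (2, 3, wl.size):
            raise ValidationError(
                f"qe must have shape (2, 3, {wl.size}); got {qe.shape}"
            )
        if np.any(qe < 0) or np.any(qe > 1):
            raise ValidationError("QE values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "qe", qe)

    def curve(self, filt: str, layer: str) -> np.ndarray:
        """One QE curve, e.g. ``curve('LP', 'bottom')``."""
        return self.qe[FILTERS.index(filt), LAYERS.index(layer)]

    def to_csv(self, directory) -> None:
        """Write each curve as a 2-column (nm, QE) CSV file."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, filt in enumerate(FILTERS):
            for j, layer in enumerate(LAYERS):
                out = np.column_stack([self.wavelengths, self.qe[i, j]])
                np.savetxt(
                    d / f"qe_{filt}_{layer}.csv",
                    out,
                    delimiter=",",
                    header="wavelength_nm,qe",
                    comments="",
                )

    @classmethod
    def from_csv(cls, directory) -> "QuantumEfficiencyModel":
        """Read the six ``qe_<FILT>_<layer>.csv`` curves written by to_csv."""
        import pathlib

        d = pathlib.Path(directory)
        wl = None
        qe = None
        for i, filt in enumerate(FILTERS):
            for j, layer in enumerate(LAYERS):
                arr = np.loadtxt(d / f"qe_{filt}_{layer}.csv", delimiter=",", skiprows=1)
                if wl is None:
                    wl = arr[:, 0]
                    qe = np.zeros((2, 3, wl.size))
                elif not np.array_equal(arr[:, 0], wl):
                    raise ValidationError("QE CSV files disagree on the wavelength grid")
                qe[i, j] = arr[:, 1]
        return cls(wavelengths=wl, qe=qe)


def build_default_qe(
    layer_depths=(0.6, 2.0, 10.0),
    silicon_absorption_um=None,
    filter_od: float = 4.0,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
    collection_efficiency: float = 0.95,
) -> QuantumEfficiencyModel:
    """Default QE model from a three-layer Beer-Lambert absorber stack.

    ``layer_depths`` are the cumulative bottom boundaries (um) of the top,
    middle and bottom photodiode collection volumes, measured from the
    illuminated surface; they must be strictly increasing.  The fraction of
    photons absorbed within layer i spanning [d_{i-1}, d_i] is

        exp(-alpha * d_{i-1}) - exp(-alpha * d_i)

    with alpha the silicon absorption coefficient.  Each layer fraction is
    multiplied by the SP or LP pixelated-filter transmission and by a flat
    carrier collection efficiency.  The defaults reproduce the qualitative
    behaviour of the physical chip: the top diode favours blue, the bottom
    diode favours red, and in the NIR the LP-bottom curve dominates because
    NIR photons penetrate deep into silicon before being absorbed.

    Parameters
    ----------
    silicon_absorption_um:
        Optional per-wavelength absorption coefficients (um^-1) matching
        ``wavelengths``; defaults to the built-in silicon table.
    """
    depths = np.asarray(layer_depths, dtype=float)
    if depths.ndim != 1 or depths.size != 3:
        raise ValidationError("layer_depths must contain three cumulative depths")
    if depths[0] <= 0 and depths[0] != 0.0:
        raise ValidationError("layer depths must be non-negative")
    if np.any(np.diff(np.concatenate([[0.0], depths])) < 0):
        raise ValidationError("layer_depths must be non-decreasing from the surface")
    if np.any(np.diff(depths) < 0):
        raise ValidationError("layer_depths must be non-decreasing")

    wl = np.asarray(wavelengths, dtype=float)
    if silicon_absorption_um is None:
        alpha = silicon_absorption(wl)
    else:
        alpha = np.asarray(silicon_absorption_um, dtype=float)
        if alpha.shape != wl.shape:
            raise ValidationError("absorption table does not cover the wavelength grid")

    boundaries = np.concatenate([[0.0], depths])
    decay = np.exp(-np.outer(boundaries, alpha))  # (4, L)
    layer_fraction = decay[:-1] - decay[1:]  # (3, L), absorbed per layer

    qe = np.zeros((2, 3, wl.size))
    for i, filt in enumerate(FILTERS):
        t = filter_transmission(wl, filt, od=filter_od)
        qe[i] = collection_efficiency * layer_fraction * t
    return QuantumEfficiencyModel(wavelengths=wl, qe=np.clip(qe, 0.0, 1.0))


def _default_notch_ods() -> dict:
    return {665.0: 6.5, 785.0: 6.5}


@dataclass(frozen=True)
class SensorConfig:
    """Electro-optical operating point of the sensor.

    Units: ``read_noise`` and ``full_well`` in electrons, ``dark_offset`` in
    digital numbers (DN), ``gain`` in electrons per DN, ``exposure`` in
    seconds.  ``mosaic_origin`` gives the parity of (row + col) carrying the
    SP filter.  The default gain maps the full well onto the digital ceiling
    above the dark offset, so saturation and quantization ceilings coincide.
    """

    read_noise: float = 70.0
    full_well: float = 100_000.0
    bit_depth: int = 12
    dark_offset: float = 64.0
    gain: float | None = None
    exposure: float = 0.2
    filter_od: float = 4.0
    notch_ods: Mapping[float, float] = field(default_factory=_default_notch_ods)
    mosaic_origin: int = 0

    def __post_init__(self) -> None:
        if self.read_noise < 0:
            raise ValidationError("read_noise must be >= 0")
        if self.full_well <= 0:
            raise ValidationError("full_well must be > 0")
        if not 8 <= int(self.bit_depth) <= 16:
            raise ValidationError("bit_depth must be between 8 and 16")
        if self.mosaic_origin not in (0, 1):
            raise ValidationError("mosaic_origin must be 0 or 1")
        if self.gain is None:
            object.__setattr__(
                self, "gain", self.full_well / (self.digital_ceiling - self.dark_offset)
            )
        if self.gain <= 0:
            raise ValidationError("gain must be > 0")
        # allow half a DN of rounding headroom at the ceiling
        if self.dark_offset + self.full_well / self.gain > self.digital_ceiling + 0.5:
            raise ValidationError(
                "dark_offset + full_well/gain exceeds the digital ceiling"
            )

    @property
    def digital_ceiling(self) -> int:
        return 2 ** int(self.bit_depth) - 1

    def sp_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of SP (visible) pixels for an H x W frame."""
        rr, cc = np.indices(shape)
        return (rr + cc) % 2 == self.mosaic_origin


@dataclass
class MosaicFrame:
    """Raw sensor read-out: three stacked-photodiode planes on one mosaic.

    ``data`` has shape (3, H, W) ordered (top, middle, bottom); every pixel
    carries all three layers, but its spectral filter (SP or LP) is set by
    the checkerboard parity in ``config``.
    """

    data: np.ndarray
    config: SensorConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape[0] != 3:
            raise ValidationError("frame data must have shape (3, H, W)")
        if d.min() < 0 or d.max() > self.config.digital_ceiling:
            raise ValidationError("digital numbers outside [0, 2^bit_depth - 1]")
        self.data = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def _expected_electrons(scene, qe: QuantumEfficiencyModel, config: SensorConfig) -> np.ndarray:
    """Noise-free expected electrons, shape (3, H, W), honouring the mosaic."""
    radiance = scene.radiance  # (H, W, L)
    if radiance.shape[-1] != qe.wavelengths.size or not np.allclose(
        scene.wavelengths, qe.wavelengths
    ):
        raise ValidationError("scene wavelength grid does not match the QE grid")
    if np.any(radiance < 0):
        raise ValidationError("scene radiance must be non-negative")
    if config.exposure <= 0:
        raise ValidationError("exposure must be > 0")
    dl = np.gradient(qe.wavelengths)
    # per-filter band integrals: (2 filters, 3 layers, H, W)
    weighted = np.einsum("hwl,fkl->fkhw", radiance * dl, qe.qe, optimize=True)
    sp = config.sp_mask(radiance.shape[:2])
    electrons = np.where(sp[None, :, :], weighted[0], weighted[1])
    return config.exposure * electrons


def expose(
    scene,
    qe: QuantumEfficiencyModel,
    config: SensorConfig,
    seed: int | None = None,
    noise: bool = True,
) -> MosaicFrame:
    """Image a spectral scene onto the sensor and return a raw mosaic frame.

    Expected electrons per pixel and layer are the exposure-weighted band
    integral of scene radiance times the QE curve selected by the pixel's
    checkerboard parity.  With ``noise=True`` (default) Poisson shot noise
    and Gaussian read noise are applied; a ``seed`` is then mandatory so
    every simulated frame is reproducible.  Electrons are clipped to the
    full well, converted to digital numbers via gain and dark offset, and
    quantized to the sensor bit depth.
    """
    electrons = _expected_electrons(scene, qe, config)
    if noise:
        if seed is None:
            raise ValidationError("a seed is required when noise is enabled")
        rng = np.random.default_rng(int(seed))
        electrons = rng.poisson(electrons).astype(float)
        if config.read_noise > 0:
            electrons = electrons + rng.normal(0.0, config.read_noise, electrons.shape)
    electrons = np.clip(electrons, None, config.full_well)
    dn = config.dark_offset + electrons / config.gain
    dn = np.clip(np.rint(dn), 0, config.digital_ceiling)
    meta = {
        "scene_id": getattr(scene, "scene_id", None),
        "seed": seed,
        "exposure": config.exposure,
        "noise": bool(noise),
    }
    return MosaicFrame(data=dn.astype(np.uint16), config=config, meta=meta)


def max_snr_db(config) -> float:
    """Shot-noise-limited SNR ceiling of the sensor in decibels.

    At full well the signal is ``full_well`` electrons and the shot noise is
    its square root, so the ceiling is ``20 log10(sqrt(full_well))``.  The
    default 100 ke- full well gives 50 dB.
    """
    full_well = config.full_well if isinstance(config, SensorConfig) else float(config)
    if full_well <= 0:
        raise ValidationError("full_well must be > 0")
    return 20.0 * np.log10(np.sqrt(full_well))


def dark_config(config: SensorConfig) -> SensorConfig:
    """Copy of ``config`` with read noise disabled (useful for oracles)."""
    return replace(config, read_noise=0.0)
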