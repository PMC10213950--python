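"""Synthetic spectral scenes with known ground truth.

Everything the analysis pipeline is validated against is generated here:
fluorophore vial phantoms (serial dilutions, volumetric-ratio mixtures),
tumour/background phantoms, monochromator band sweeps, USAF-1951 resolution
charts and tilted depth-of-focus bar targets, plus the chromatic-aberration
blur that distinguishes the NIR-optimised endoscope (EIS mode) from a
conventional scope whose NIR focal plane is shifted (KS mode).

A scene is a photon radiance cube (H, W, lambda) on the sensor wavelength
grid together with ground-truth region masks and labels.  Radiance units are
photons / (s * pixel * nm) at the sensor plane; the absolute scale is an
empirical radiometric constant calibrated so that the default vial and band
scenes land in the instrument's working range (hundreds to thousands of DN
at the default 200 ms exposure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import skewnorm

from .sensor import WAVELENGTH_GRID, ValidationError

__all__ = [
    "EmissionSpectrum",
    "FLUOROPHORES",
    "Region",
    "SceneSpec",
    "SpectralScene",
    "make_vial_scene",
    "make_ratio_series",
    "make_usaf_chart",
    "make_dof_target",
    "apply_chromatic_blur",
    "band_sweep",
]

#: Photons / (s * pixel * nm-integrated) emitted per uM of dye per mW/cm^2
#: of excitation irradiance.  Empirical radiometric scale of the simulator.
EMISSION_SCALE = 1.3e4

#: Relative amplitude of the excitation laser line reflected into the camera
#: before the notch filters.
LASER_REFLECTANCE = 0.05

#: Flat visible radiance per mW/cm^2 of white LED illumination.
WHITE_SCALE = 50.0

VISIBLE_NIR_SPLIT = 660.0  # nm; SP/LP crossover used to classify bands


@dataclass(frozen=True)
class EmissionSpectrum:
    """Parametric fluorophore emission model.

    A skew-normal spectral shape with the given ``peak`` (mode, nm) and
    ``fwhm`` (nm), normalised so the grid integral equals
    ``quantum_yield_scale`` — a relative brightness factor folding together
    quantum yield and extinction.  ``excitation_efficiency`` maps laser
    wavelength (nm) to the relative excitation strength in [0, 1].
    """

    name: str
    peak: float
    fwhm: float
    quantum_yield_scale: float = 1.0
    skew: float = 3.0
    excitation_efficiency: dict = field(default_factory=dict)

    def spectrum(self, wavelengths: np.ndarray = WAVELENGTH_GRID) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        scale = self.fwhm / 2.355  # FWHM -> sigma of the underlying normal
        shape = skewnorm.pdf(wl, self.skew, loc=self.peak - 0.3 * scale, scale=scale * 1.2)
        # shift so the mode sits at `peak`
        mode = wl[np.argmax(shape)]
        shape = skewnorm.pdf(
            wl, self.skew, loc=self.peak - (mode - (self.peak - 0.3 * scale)), scale=scale * 1.2
        )
        integral = np.trapezoid(shape, wl)
        if integral <= 0:
            raise ValidationError(f"emission spectrum of {self.name} vanishes on the grid")
        return self.quantum_yield_scale * shape / integral


#: Registered probes.  Peaks/widths follow vendor emission spectra for the
#: IRDye conjugates and aqueous ICG; quantum_yield_scale encodes the relative
#: brightness ordering (IRDye 680RD conjugates are markedly brighter than
#: ICG at matched concentration and irradiance).
FLUOROPHORES: dict[str, EmissionSpectrum] = {
    "IR680-integrin": EmissionSpectrum(
        name="IR680-integrin",
        peak=694.0,
        fwhm=36.0,
        quantum_yield_scale=1.0,
        excitation_efficiency={665.0: 0.90, 785.0: 0.01},
    ),
    "IR800-EGF": EmissionSpectrum(
        name="IR800-EGF",
        peak=794.0,
        fwhm=40.0,
        quantum_yield_scale=0.35,
        excitation_efficiency={665.0: 0.15, 785.0: 0.90},
    ),
    "ICG": EmissionSpectrum(
        name="ICG",
        peak=815.0,
        fwhm=55.0,
        quantum_yield_scale=0.28,
        excitation_efficiency={665.0: 0.10, 785.0: 0.85},
    ),
}


@dataclass(frozen=True)
class Region:
    """One labelled scene region: a disk, rectangle, or the background.

    ``mix`` maps fluorophore name to concentration in uM.  ``attenuation``
    is a single multiplicative factor standing in for overlying-tissue
    absorption/scattering losses.
    """

    name: str
    geometry: dict
    mix: dict = field(default_factory=dict)
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.mix.values()):
            raise ValidationError(f"region {self.name!r} has a negative concentration")
        if self.attenuation < 0:
            raise ValidationError("attenuation must be >= 0")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        kind = self.geometry.get("kind")
        if kind == "disk":
            rr, cc = np.indices(shape)
            r0, c0 = self.geometry["center"]
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.geometry["radius"] ** 2
        if kind == "rect":
            m = np.zeros(shape, dtype=bool)
            r0, r1, c0, c1 = self.geometry["bounds"]
            m[r0:r1, c0:c1] = True
            return m
        if kind == "background":
            return np.ones(shape, dtype=bool)
        raise ValidationError(f"unknown region geometry {kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a phantom scene.

    ``illumination`` maps source name ("white", "665", "785") to irradiance
    in mW/cm^2.  Regions are rendered in order; later regions overwrite
    earlier ones where they overlap, so a background region goes first.
    """

    shape: tuple[int, int]
    regions: tuple
    illumination: dict = field(default_factory=dict)
    scene_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.illumination.values()):
            raise ValidationError("illumination irradiance must be >= 0")


@dataclass
class SpectralScene:
    """Photon radiance cube plus ground truth."""

    radiance: np.ndarray  # (H, W, L), photons / (s px nm)
    wavelengths: np.ndarray
    ground_truth: dict = field(default_factory=dict)
    scene_id: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.radiance)
        if r.ndim != 3:
            raise ValidationError("radiance must have shape (H, W, L)")
        if r.shape[-1] != np.asarray(self.wavelengths).size:
            raise ValidationError("radiance depth does not match the wavelength grid")
        if r.min() < 0:
            raise ValidationError("radiance must be non-negative")
        self.radiance = r

    @property
    def shape(self) -> tuple[int, int]:
        return self.radiance.shape[:2]


def _laser_lines(illumination: dict, wavelengths: np.ndarray, notch_od: float) -> np.ndarray:
    """Residual excitation-laser radiance after the camera notch filters."""
    wl = np.asarray(wavelengths, dtype=float)
    spectrum = np.zeros_like(wl)
    for name, irradiance in illumination.items():
        if name == "white" or irradiance <= 0:
            continue
        line = float(name)
        sigma = 0.8  # nm laser linewidth
        shape = np.exp(-0.5 * ((wl - line) / sigma) ** 2)
        shape /= np.trapezoid(shape, wl)
        spectrum += irradiance * EMISSION_SCALE * LASER_REFLECTANCE * shape
    return spectrum * 10.0 ** (-notch_od)


def make_vial_scene(
    spec: SceneSpec,
    fluorophores: dict | None = None,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
    notch_od: float = 6.5,
) -> SpectralScene:
    """Render a region-based phantom (vials, tumour/background) to radiance.

    Each region emits the concentration-weighted sum of its fluorophores'
    emission spectra, scaled by excitation efficiency and laser irradiance
    (linear photophysics: no inner-filter effect or quenching).  A white
    source adds a flat visible reflectance term; residual laser lines are
    added across the frame and attenuated by the camera notch filters.
    """
    registry = FLUOROPHORES if fluorophores is None else fluorophores
    wl = np.asarray(wavelengths, dtype=float)
    H, W = spec.shape
    radiance = np.zeros((H, W, wl.size), dtype=np.float32)
    masks: dict[str, np.ndarray] = {}
    labels: dict[str, dict] = {}

    lasers = {k: v for k, v in spec.illumination.items() if k != "white"}
    for region in spec.regions:
        emission = np.zeros(wl.size)
        for probe, conc in region.mix.items():
            if probe not in registry:
                raise ValidationError(
                    f"unknown fluorophore {probe!r}; registered: {sorted(registry)}"
                )
            dye = registry[probe]
            drive = sum(
                irr * dye.excitation_efficiency.get(float(src), 0.0)
                for src, irr in lasers.items()
            )
            emission = emission + conc * drive * EMISSION_SCALE * dye.spectrum(wl)
        emission = emission * region.attenuation
        if spec.illumination.get("white", 0) > 0:
            visible = (wl >= 420) & (wl <= VISIBLE_NIR_SPLIT)
            emission = emission + spec.illumination["white"] * WHITE_SCALE * visible
        m = region.mask((H, W))
        radiance[m] = emission.astype(np.float32)
        masks[region.name] = m
        labels[region.name] = dict(region.mix)

    # earlier-region masks must not claim pixels overwritten later
    claimed = np.zeros((H, W), dtype=bool)
    for name in reversed([r.name for r in spec.regions]):
        masks[name] = masks[name] & ~claimed
        claimed |= masks[name]

    radiance += _laser_lines(spec.illumination, wl, notch_od)[None, None, :].astype(np.float32)
    return SpectralScene(
        radiance=radiance,
        wavelengths=wl,
        ground_truth={"masks": masks, "mixes": labels, "spec": spec},
        scene_id=spec.scene_id,
    )


def make_ratio_series(
    fractions=None,
    stock_uM: float = 1.0,
    shape: tuple[int, int] = (24, 24),
    illumination: dict | None = None,
) -> list[SceneSpec]:
    """Vial specs for a volumetric-ratio series of IR680-integrin : IR800-EGF.

    Default fractions follow the six-step series 10:0, 8:2, ... 0:10 with
    both stocks at the same molar concentration and both excitation lasers
    on simultaneously, so a vial's concentrations are the volumetric
    fractions times the stock concentration (total volume constant).
    """
    if fractions is None:
        fractions = [(10, 0), (8, 2), (6, 4), (4, 6), (2, 8), (0, 10)]
    if illumination is None:
        illumination = {"665": 50.0, "785": 150.0}
    specs = []
    H, W = shape
    for a, b in fractions:
        if a < 0 or b < 0:
            raise ValidationError("volumetric fractions must be non-negative")
        if a + b == 0:
            raise ValidationError("a ratio cannot be 0:0")
        fa = a / (a + b)
        region = Region(
            name=f"vial_{a}:{b}",
            geometry={"kind": "disk", "center": (H // 2, W // 2), "radius": min(H, W) // 2 - 2},
            mix={"IR680-integrin": fa * stock_uM, "IR800-EGF": (1 - fa) * stock_uM},
        )
        specs.append(
            SceneSpec(
                shape=shape,
                regions=(region,),
                illumination=dict(illumination),
                scene_id=f"ratio_{a}:{b}",
                meta={"fraction_ir680": fa},
            )
        )
    return specs


def usaf_line_width_um(group: int, element: int) -> float:
    """Bar width in um of a USAF-1951 element: 500 / (2^(g+(e-1)/6)) um."""
    return 500.0 / (2.0 ** (group + (element - 1) / 6.0))


def _illumination_spectrum(kind: str, wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if kind == "white":
        band = ((wl >= 420) & (wl <= VISIBLE_NIR_SPLIT)).astype(float)
    elif kind == "nir":
        sigma = 10.0 / 2.355
        band = np.exp(-0.5 * ((wl - 785.0) / sigma) ** 2)
    elif kind == "broadband":
        band = ((wl >= 420) & (wl <= 900)).astype(float)
    else:
        raise ValidationError(f"unknown illumination kind {kind!r}")
    integral = np.trapezoid(band, wl)
    return band / integral


def make_usaf_chart(
    groups=None,
    um_per_px: float = 2.0,
    illumination: str = "broadband",
    photons_per_px_s: float = 2.0e5,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
) -> SpectralScene:
    """Back-illuminated USAF-1951 bar raster with per-element metadata.

    Each requested (group, element) is drawn as three bright vertical bars
    (bar width = gap width = 500/lpmm um, bar length 5x width) on a dark
    background, stacked down the chart.  Ground truth records, per element,
    the line-pair frequency and the pixel positions of bar and gap centres
    along the horizontal profile through the bars.
    """
    if groups is None:
        groups = [(5, e) for e in range(1, 7)]
    wl = np.asarray(wavelengths, dtype=float)

    elements = []
    widths_px = []
    for g, e in groups:
        if not 1 <= e <= 6:
            raise ValidationError("USAF element must be in 1..6")
        w_px = usaf_line_width_um(g, e) / um_per_px
        if w_px < 2.0:
            raise ValidationError(
                f"element ({g},{e}) is {w_px:.2f} px per line; "
                "need >= 2 px per line to be representable"
            )
        widths_px.append(w_px)
    margin = max(6, int(round(max(widths_px))))
    width = int(math.ceil(5 * max(widths_px))) + 2 * margin
    height = margin
    layout = []
    for (g, e), w_px in zip(groups, widths_px):
        bar_len = int(round(5 * w_px))
        layout.append((g, e, w_px, height, height + bar_len))
        height += bar_len + margin

    mask = np.zeros((height, width), dtype=np.float32)
    for g, e, w_px, r0, r1 in layout:
        c_left = margin
        bar_centers = []
        gap_centers = []
        for k in range(3):
            b0 = c_left + 2 * k * w_px
            b1 = b0 + w_px
            cols = np.arange(width)
            # anti-aliased bar edges: fractional coverage per column
            cover = np.clip(np.minimum(b1, cols + 1) - np.maximum(b0, cols), 0, 1)
            mask[r0:r1, :] = np.maximum(mask[r0:r1, :], cover[None, :])
            bar_centers.append((b0 + b1) / 2.0)
            if k < 2:
                gap_centers.append(b1 + w_px / 2.0)
        elements.append(
            {
                "group": g,
                "element": e,
                "lpmm": 1000.0 / (2 * usaf_line_width_um(g, e)),
                "bar_width_px": w_px,
                "row_range": (r0, r1),
                "profile_row": (r0 + r1) // 2,
                "bar_centers": bar_centers,
                "gap_centers": gap_centers,
                "orientation": "vertical",
            }
        )

    spectrum = (photons_per_px_s * _illumination_spectrum(illumination, wl)).astype(np.float32)
    radiance = mask[:, :, None] * spectrum[None, None, :]
    return SpectralScene(
        radiance=radiance,
        wavelengths=wl,
        ground_truth={"usaf_elements": elements, "um_per_px": um_per_px},
        scene_id="usaf_chart",
    )


def make_dof_target(
    tilt_deg: float = 45.0,
    frequency: float = 15.0,
    um_per_px: float = 15.0,
    shape: tuple[int, int] = (64, 240),
    illumination: str = "broadband",
    photons_per_px_s: float = 2.0e5,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
) -> SpectralScene:
    """Tilted depth-of-focus bar target.

    Horizontal bars at ``frequency`` lp/mm fill the frame; the chart plane is
    tilted by ``tilt_deg`` so object depth increases linearly across the
    columns (depth = column * um_per_px * tan(tilt)).  The per-column depth
    labels drive depth-dependent defocus in :func:`apply_chromatic_blur`.
    """
    if not 0.0 < tilt_deg < 90.0:
        raise ValidationError("tilt must be strictly between 0 and 90 degrees")
    wl = np.asarray(wavelengths, dtype=float)
    H, W = shape
    period_px = 1000.0 / frequency / um_per_px  # one line pair in px
    if period_px < 4:
        raise ValidationError("bar frequency unrepresentable at this pixel scale")
    rows = np.arange(H)
    bars = (np.sin(2 * np.pi * rows / period_px) > 0).astype(np.float32)
    mask = np.repeat(bars[:, None], W, axis=1)
    depths_mm = np.arange(W) * um_per_px * math.tan(math.radians(tilt_deg)) / 1000.0

    spectrum = (photons_per_px_s * _illumination_spectrum(illumination, wl)).astype(np.float32)
    radiance = mask[:, :, None] * spectrum[None, None, :]
    return SpectralScene(
        radiance=radiance,
        wavelengths=wl,
        ground_truth={
            "dof": {
                "depths_mm": depths_mm,
                "frequency_lpmm": frequency,
                "period_px": period_px,
                "um_per_px": um_per_px,
                "tilt_deg": tilt_deg,
            }
        },
        scene_id="dof_target",
    )


#: Optical parameters of the two endoscope emulations.  EIS focuses visible
#: and NIR on the same plane; KS carries a chromatic focal-plane shift that
#: defocuses the NIR band when focus is set with white light.
ENDOSCOPE_MODES = {
    "EIS": {"sigma0": 0.5, "defocus_slope": 1.5, "nir_focal_shift_mm": 0.0},
    "KS": {"sigma0": 0.5, "defocus_slope": 1.5, "nir_focal_shift_mm": 3.0},
}


def apply_chromatic_blur(
    scene: SpectralScene,
    mode: str = "EIS",
    psf_sigma: dict | None = None,
    focus_depth_mm: float | None = None,
    depth_bins: int = 12,
) -> SpectralScene:
    """Gaussian chromatic/defocus blur per spectral band.

    With an explicit ``psf_sigma`` mapping {"visible": s, "nir": s} each
    band is convolved with that normalised Gaussian PSF.  Otherwise the
    endoscope ``mode`` sets the optics: defocus blur grows linearly with
    distance from the focal plane, and in KS mode the NIR focal plane is
    shifted relative to the visible one, so NIR is blurred wherever the
    visible image is sharp.  Scenes carrying depth-of-focus column labels
    get depth-dependent blur (piecewise over ``depth_bins`` column bands).
    """
    wl = scene.wavelengths
    vis = wl < VISIBLE_NIR_SPLIT
    bands = {"visible": vis, "nir": ~vis}
    out = scene.radiance.astype(np.float32).copy()

    if psf_sigma is not None:
        for band, sel in bands.items():
            s = float(psf_sigma.get(band, 0.0))
            if s < 0:
                raise ValidationError("PSF sigma must be >= 0")
            if s > 0:
                out[:, :, sel] = ndimage.gaussian_filter(
                    out[:, :, sel], sigma=(s, s, 0), mode="nearest"
                )
        gt = dict(scene.ground_truth)
        gt["blur"] = {"psf_sigma": dict(psf_sigma)}
        return SpectralScene(out, wl, gt, scene.scene_id)

    if mode not in ENDOSCOPE_MODES:
        raise ValidationError(f"unknown endoscope mode {mode!r}; use EIS or KS")
    p = ENDOSCOPE_MODES[mode]
    shifts = {"visible": 0.0, "nir": p["nir_focal_shift_mm"]}

    dof = scene.ground_truth.get("dof")
    if dof is None:
        for band, sel in bands.items():
            s = math.hypot(p["sigma0"], p["defocus_slope"] * shifts[band])
            out[:, :, sel] = ndimage.gaussian_filter(
                out[:, :, sel], sigma=(s, s, 0), mode="nearest"
            )
    else:
        depths = np.asarray(dof["depths_mm"], dtype=float)
        focus = float(np.median(depths) if focus_depth_mm is None else focus_depth_mm)
        edges = np.linspace(0, depths.size, depth_bins + 1).astype(int)
        src = scene.radiance.astype(np.float32)
        for band, sel in bands.items():
            for b0, b1 in zip(edges[:-1], edges[1:]):
                if b0 == b1:
                    continue
                d = depths[(b0 + b1) // 2]
                s = math.hypot(
                    p["sigma0"], p["defocus_slope"] * (abs(d - focus) + shifts[band])
                )
                blurred = ndimage.gaussian_filter(src[:, :, sel], sigma=(s, s, 0), mode="nearest")
                out[:, b0:b1, sel] = blurred[:, b0:b1]
    gt = dict(scene.ground_truth)
    gt["blur"] = {"mode": mode}
    return SpectralScene(out, wl, gt, scene.scene_id)


def band_sweep(
    start: float = 680.0,
    stop: float = 820.0,
    step: float = 20.0,
    fwhm: float = 17.0,
    shape: tuple[int, int] = (12, 12),
    photons_per_px_s: float = 4.5e4,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
) -> list[SpectralScene]:
    """Monochromator sweep: one narrow-band flat field per centre wavelength.

    Every scene is a Gaussian band of the given FWHM, numerically normalised
    so all scenes carry exactly the same integrated photon radiance
    (intensity-matched, as in a monochromator calibration where exposure is
    adjusted until the recorded levels agree).
    """
    if start > stop:
        raise ValidationError("start must be <= stop")
    if step <= 0:
        raise ValidationError("step must be > 0")
    wl = np.asarray(wavelengths, dtype=float)
    sigma = fwhm / 2.355
    scenes = []
    centers = np.arange(start, stop + step / 2, step)
    for c in centers:
        band = np.exp(-0.5 * ((wl - c) / sigma) ** 2)
        band = photons_per_px_s * band / np.trapezoid(band, wl)
        radiance = np.broadcast_to(
            band.astype(np.float32)[None, None, :], (*shape, wl.size)
        ).copy()
        scenes.append(
            SpectralScene(
                radiance=radiance,
                wavelengths=wl,
                ground_truth={"band_center_nm": float(c), "fwhm_nm": float(fwhm)},
                scene_id=f"band_{c:.0f}nm",
            )
        )
    return scenes
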