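"""End-to-end study workflows built from the simulator and analysis modules.

Each function reproduces one bench experiment in silico: narrow-band
spectral discrimination, the volumetric-ratio calibration, USAF / depth-of-
focus resolution scoring, and the dilution-series limit of detection.  They
are the engine behind the command-line interface and the reproduction
script; tests call them directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demosaic import demosaic_frame, split_mosaic
from .resolution import (
    DEFAULT_CONTRAST_THRESHOLD,
    element_contrast,
    extract_line_profile,
    finest_resolved_element,
    dof_contrast_curve,
)
from .scenes import (
    SceneSpec,
    Region,
    apply_chromatic_blur,
    band_sweep,
    make_dof_target,
    make_ratio_series,
    make_usaf_chart,
    make_vial_scene,
)
from .sensor import SensorConfig, build_default_qe, expose
from .spectral import (
    HueSatPoint,
    RatioLine,
    circular_mean_deg,
    clusters_separable,
    fit_ratio_line,
    fit_tolerance_ellipse,
    limit_of_detection,
    nir_to_huesat,
    roi_huesat,
    roi_mfi,
)

__all__ = [
    "frame_seeds",
    "simulate_band_clusters",
    "max_separable_level",
    "simulate_ratio_clusters",
    "calibrate_ratio_line",
    "estimate_mixture_fraction",
    "usaf_resolution",
    "dof_analysis",
    "lod_simulation",
]


def frame_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-frame child seeds (kept below 2^31)."""
    return np.random.SeedSequence(int(seed)).generate_state(n) & 0x7FFFFFFF


def _interior_mask(shape: tuple[int, int], margin: int = 2) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[margin : shape[0] - margin, margin : shape[1] - margin] = True
    return m


def simulate_band_clusters(
    centers=(680, 700, 720, 740, 760, 780, 800, 820),
    n_frames: int = 100,
    shape: tuple[int, int] = (12, 12),
    seed: int = 0,
    qe=None,
    config: SensorConfig | None = None,
    noise: bool = True,
    fwhm: float = 17.0,
    photons_per_px_s: float = 4.5e4,
) -> dict:
    """Hue-saturation clusters of a simulated monochromator sweep.

    For every band centre, ``n_frames`` noisy frames of an intensity-matched
    narrow-band flat field pass through expose -> demosaic -> per-pixel
    hue-saturation; each frame contributes its ROI summary point (circular
    mean hue, mean saturation over interior pixels), emulating replicate
    measurements.  Returns {centre: (hues, sats)} arrays of length
    ``n_frames``.
    """
    qe = build_default_qe() if qe is None else qe
    config = SensorConfig() if config is None else config
    seeds = frame_seeds(seed, len(centers) * n_frames)
    roi = _interior_mask(shape)
    clusters = {}
    for bi, c in enumerate(centers):
        scene = band_sweep(c, c, 20.0, fwhm, shape=shape, photons_per_px_s=photons_per_px_s)[0]
        hues = np.empty(n_frames)
        sats = np.empty(n_frames)
        for k in range(n_frames):
            frame = expose(scene, qe, config, seed=int(seeds[bi * n_frames + k]), noise=noise)
            pt = roi_huesat(demosaic_frame(frame).nir, roi)
            hues[k], sats[k] = pt.hue, pt.sat
        clusters[float(c)] = (hues, sats)
    return clusters


def max_separable_level(
    clusters: dict,
    centers=None,
    levels=None,
) -> float | None:
    """Highest tolerance level at which all adjacent-band ellipses stay
    pairwise disjoint; ``None`` if they overlap even at the lowest level
    probed.  Disjointness is monotone in the level (larger quantile, larger
    ellipse), so a descending scan returns the supremum on the grid."""
    if centers is None:
        centers = sorted(clusters)
    if levels is None:
        levels = np.arange(0.999, 0.499, -0.005)
    for level in levels:
        ellipses = [
            fit_tolerance_ellipse(*clusters[float(c)], level=float(level)) for c in centers
        ]
        if all(
            clusters_separable(a, b, n_boundary=1024)
            for a, b in zip(ellipses[:-1], ellipses[1:])
        ):
            return float(level)
    return None


def _vial_cluster(scene, mask, qe, config, seeds, noise=True):
    hues = np.empty(len(seeds))
    sats = np.empty(len(seeds))
    for k, s in enumerate(seeds):
        frame = expose(scene, qe, config, seed=int(s), noise=noise)
        pt = roi_huesat(demosaic_frame(frame).nir, mask)
        hues[k], sats[k] = pt.hue, pt.sat
    return hues, sats


def simulate_ratio_clusters(
    fractions=None,
    n_frames: int = 30,
    seed: int = 0,
    shape: tuple[int, int] = (24, 24),
    stock_uM: float = 1.0,
    qe=None,
    config: SensorConfig | None = None,
    noise: bool = True,
) -> dict:
    """Hue-saturation clusters for the IR680:IR800 volumetric-ratio vials.

    Returns {IR680 fraction: (hues, sats)} with one ROI summary point per
    simulated frame, vials excited by both lasers simultaneously.
    """
    qe = build_default_qe() if qe is None else qe
    config = SensorConfig() if config is None else config
    specs = make_ratio_series(fractions, stock_uM=stock_uM, shape=shape)
    seeds = frame_seeds(seed, len(specs) * n_frames)
    clusters = {}
    for i, spec in enumerate(specs):
        scene = make_vial_scene(spec)
        mask = next(iter(scene.ground_truth["masks"].values()))
        clusters[spec.meta["fraction_ir680"]] = _vial_cluster(
            scene, mask, qe, config, seeds[i * n_frames : (i + 1) * n_frames], noise
        )
    return clusters


def calibrate_ratio_line(clusters: dict) -> RatioLine:
    """Fit the unmixing line to the ratio-series cluster means."""
    means = {
        float(f): HueSatPoint(circular_mean_deg(h), float(np.mean(s)), True)
        for f, (h, s) in clusters.items()
    }
    return fit_ratio_line(means)


def estimate_mixture_fraction(
    fraction_ir680: float,
    line: RatioLine,
    seed: int = 0,
    n_frames: int = 10,
    stock_uM: float = 1.0,
    shape: tuple[int, int] = (24, 24),
    qe=None,
    config: SensorConfig | None = None,
) -> float:
    """Image a fresh mixture vial and read its IR680 fraction off the line."""
    from .spectral import estimate_ratio

    qe = build_default_qe() if qe is None else qe
    config = SensorConfig() if config is None else config
    a = round(10 * fraction_ir680, 6)
    spec = make_ratio_series([(a, 10 - a)], stock_uM=stock_uM, shape=shape)[0]
    scene = make_vial_scene(spec)
    mask = next(iter(scene.ground_truth["masks"].values()))
    hues, sats = _vial_cluster(scene, mask, qe, config, frame_seeds(seed, n_frames))
    point = HueSatPoint(circular_mean_deg(hues), float(np.mean(sats)), True)
    return estimate_ratio(point, line)


def usaf_resolution(
    mode: str = "EIS",
    seed: int = 1,
    noise: bool = True,
    threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    groups=None,
    um_per_px: float = 2.0,
    qe=None,
    config: SensorConfig | None = None,
) -> dict:
    """Score USAF-chart resolution of one endoscope mode in both spectra.

    The chart is imaged twice, as on the bench: once under white light
    (scored on the summed visible channels) and once under 785 nm
    illumination with focus untouched (scored on the summed NIR channels).
    Returns per-band finest resolved element plus a tidy results table.
    """
    qe = build_default_qe() if qe is None else qe
    config = SensorConfig() if config is None else config
    seeds = frame_seeds(seed, 2)
    results: dict = {"mode": mode}
    rows = []
    for s, (band, illum) in zip(
        seeds, (("visible", "white"), ("nir", "nir"))
    ):
        scene = make_usaf_chart(groups, um_per_px=um_per_px, illumination=illum)
        scene = apply_chromatic_blur(scene, mode=mode)
        frame = expose(scene, qe, config, seed=int(s), noise=noise)
        dm = demosaic_frame(frame)
        img = dm.visible.sum(axis=-1) if band == "visible" else dm.nir.sum(axis=-1)
        meta = scene.ground_truth["usaf_elements"]
        for m in meta:
            c = element_contrast(extract_line_profile(img, m))
            rows.append(
                {
                    "band": band,
                    "group": m["group"],
                    "element": m["element"],
                    "lpmm": m["lpmm"],
                    "contrast": c,
                    "resolved": bool(c >= threshold),
                }
            )
        results[band] = finest_resolved_element(img, meta, threshold)
    results["table"] = pd.DataFrame(rows)
    return results


def dof_analysis(
    mode: str = "EIS",
    seed: int = 1,
    noise: bool = True,
    qe=None,
    config: SensorConfig | None = None,
    **target_kwargs,
) -> dict:
    """Contrast-versus-depth curves of the tilted bar target, per spectrum."""
    qe = build_default_qe() if qe is None else qe
    config = SensorConfig() if config is None else config
    seeds = frame_seeds(seed, 2)
    out: dict = {"mode": mode}
    for s, (band, illum) in zip(seeds, (("visible", "white"), ("nir", "nir"))):
        scene = make_dof_target(illumination=illum, **target_kwargs)
        blurred = apply_chromatic_blur(scene, mode=mode)
        frame = expose(blurred, qe, config, seed=int(s), noise=noise)
        dm = demosaic_frame(frame)
        img = dm.visible.sum(axis=-1) if band == "visible" else dm.nir.sum(axis=-1)
        depths, contrasts = dof_contrast_curve(img, scene.ground_truth)
        out[band] = (depths, contrasts)
    return out


_PROBE_LASER = {
    "IR680-integrin": {"665": 50.0},
    "IR800-EGF": {"785": 150.0},
    "ICG": {"785": 150.0},
}


def lod_simulation(
    probe: str = "IR680-integrin",
    concentrations=(0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_reps: int = 3,
    seed: int = 7,
    shape: tuple[int, int] = (24, 24),
    qe=None,
    config: SensorConfig | None = None,
) -> dict:
    """Simulated dilution-series sensitivity experiment for one probe.

    Triplicate vials per concentration plus a PBS negative control; the MFI
    is the mean raw digital value of the LP-parity bottom-photodiode pixels
    inside the vial ROI.  Returns the replicate table, the background
    replicates and the resulting limit of detection.
    """
    qe = build_default_qe() if qe is None else qe
    config = SensorConfig() if config is None else config
    illumination = _PROBE_LASER[probe]
    all_concs = [0.0] + sorted(concentrations)
    seeds = frame_seeds(seed, len(all_concs) * n_reps)
    H, W = shape
    series = []
    background = None
    for i, conc in enumerate(all_concs):
        region = Region(
            name="vial",
            geometry={"kind": "disk", "center": (H // 2, W // 2), "radius": min(H, W) // 2 - 2},
            mix={probe: conc} if conc > 0 else {},
        )
        spec = SceneSpec(
            shape=shape, regions=(region,), illumination=dict(illumination),
            scene_id=f"{probe}_{conc}uM",
        )
        scene = make_vial_scene(spec)
        roi = scene.ground_truth["masks"]["vial"]
        mfis = []
        for k in range(n_reps):
            frame = expose(scene, qe, config, seed=int(seeds[i * n_reps + k]))
            _, lp = split_mosaic(frame)
            lp_mask = ~frame.config.sp_mask(frame.shape)
            mfis.append(roi_mfi(lp[2], roi & lp_mask))
        if conc == 0:
            background = mfis
        else:
            series.append((conc, mfis))
    return {
        "probe": probe,
        "series": series,
        "background": background,
        "lod_uM": limit_of_detection(series, background),
    }
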