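"""Spectral discrimination of NIR fluorophores in hue-saturation space.

The three stacked-photodiode NIR channels give every pixel a spectral
triplet.  Mapping the triplet to pseudo-RGB and taking the chromatic part of
the standard hexagonal HSV transform (hue and saturation, discarding value)
yields an intensity-invariant spectral signature: scaling the triplet by any
positive factor — brighter illumination, longer exposure, deeper probe
accumulation — leaves the (hue, saturation) point unchanged.  Fluorophore
populations then form clusters in this plane; tolerance ellipses scaled by
chi-square(2 df) quantiles quantify their spread, disjoint ellipses mean the
probes are spectrally separable at that confidence level, and a best-fit
line through the cluster means of a volumetric-ratio calibration series
turns an observed point into an estimated mixing fraction.

Also here: the scalar ROI statistics of the fluorescence workflow — mean
fluorescence intensity (MFI), limit of detection of a dilution series, and
tumour-to-background ratio (TBR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .sensor import ValidationError

__all__ = [
    "HueSatPoint",
    "ToleranceEllipse",
    "RatioLine",
    "nir_to_huesat",
    "roi_huesat",
    "roi_mfi",
    "limit_of_detection",
    "fit_tolerance_ellipse",
    "clusters_separable",
    "fit_ratio_line",
    "estimate_ratio",
    "tumor_background_ratio",
]

#: Saturation is rescaled to percent wherever hue (degrees) and saturation
#: share a plane, so the two axes have comparable magnitude.
SAT_SCALE = 100.0


@dataclass(frozen=True)
class HueSatPoint:
    """Chromatic coordinates of a spectral triplet.

    ``hue`` in degrees [0, 360), ``sat`` in [0, 1].  ``valid`` is False when
    the triplet was all-zero, in which case hue is undefined (flagged, not
    an exception).  Fields may be arrays for per-pixel maps.
    """

    hue: np.ndarray | float
    sat: np.ndarray | float
    valid: np.ndarray | bool = True


def _wrap_deg(delta):
    """Wrap angle differences to (-180, 180]."""
    return (np.asarray(delta) + 180.0) % 360.0 - 180.0


def circular_mean_deg(hues, weights=None) -> float:
    h = np.radians(np.asarray(hues, dtype=float))
    w = np.ones_like(h) if weights is None else np.asarray(weights, dtype=float)
    ang = np.arctan2(np.sum(w * np.sin(h)), np.sum(w * np.cos(h)))
    return float(np.degrees(ang) % 360.0)


def nir_to_huesat(triplet) -> HueSatPoint:
    """Hue-saturation transform of NIR triplet(s) (top, middle, bottom).

    Channels map to pseudo-RGB in order of silicon penetration depth:
    bottom -> R, middle -> G, top -> B.  The standard hexagonal HSV
    transform then gives hue and saturation; the value component is
    discarded.  Accepts a single triplet or an (..., 3) array; triplets must
    be offset-subtracted and non-negative.  All-zero triplets yield an
    undefined-hue flag rather than an exception.
    """
    t = np.asarray(triplet, dtype=float)
    if t.shape[-1] != 3:
        raise ValidationError("expected (..., 3) NIR triplet(s)")
    if np.any(t < 0):
        raise ValidationError("triplets must be non-negative (offset-subtracted)")
    scalar = t.ndim == 1
    t = np.atleast_2d(t)
    r, g, b = t[..., 2], t[..., 1], t[..., 0]

    mx = np.max(t, axis=-1)
    mn = np.min(t, axis=-1)
    c = mx - mn
    valid = mx > 0
    safe_c = np.where(c > 0, c, 1.0)

    hue = np.zeros_like(mx)
    is_r = (mx == r) & (c > 0)
    is_g = (mx == g) & (c > 0) & ~is_r
    is_b = (c > 0) & ~is_r & ~is_g
    hue[is_r] = 60.0 * ((g - b)[is_r] / safe_c[is_r])
    hue[is_g] = 60.0 * ((b - r)[is_g] / safe_c[is_g] + 2.0)
    hue[is_b] = 60.0 * ((r - g)[is_b] / safe_c[is_b] + 4.0)
    hue = hue % 360.0
    sat = np.where(valid, c / np.where(valid, mx, 1.0), 0.0)

    if scalar:
        return HueSatPoint(float(hue[0]), float(sat[0]), bool(valid[0]))
    return HueSatPoint(hue, sat, valid)


def roi_huesat(nir_image: np.ndarray, mask: np.ndarray | None = None) -> HueSatPoint:
    """ROI summary point: per-pixel transform, then circular-mean hue and
    mean saturation over the (valid) masked pixels."""
    img = np.asarray(nir_image, dtype=float)
    pts = nir_to_huesat(img)
    if mask is None:
        mask = np.ones(img.shape[:-1], dtype=bool)
    sel = np.asarray(mask, dtype=bool) & np.atleast_1d(pts.valid)
    if not np.any(sel):
        return HueSatPoint(0.0, 0.0, False)
    hue = circular_mean_deg(np.asarray(pts.hue)[sel])
    sat = float(np.mean(np.asarray(pts.sat)[sel]))
    return HueSatPoint(hue, sat, True)


def roi_mfi(plane: np.ndarray, mask: np.ndarray) -> float:
    """Mean fluorescence intensity: arithmetic mean over the masked pixels."""
    p = np.asarray(plane, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if p.shape != m.shape:
        raise ValidationError("plane and mask shapes differ")
    if not m.any():
        raise ValidationError("ROI mask is empty")
    return float(p[m].mean())


def limit_of_detection(series, background) -> float | None:
    """Limit of detection of a dilution series against a negative control.

    ``series`` is a sequence of (concentration, replicate MFIs) sorted by
    ascending concentration; ``background`` the replicate MFIs of the
    negative control.  The detection threshold is the background mean plus
    two background standard deviations (a 95% confidence bound), and the LOD
    is the smallest concentration whose mean MFI exceeds it with every
    larger concentration also exceeding it; ``None`` if no such suffix
    exists.
    """
    bg = np.asarray(list(background), dtype=float)
    if bg.size < 2:
        raise ValidationError("need at least two background replicates")
    concs = np.asarray([c for c, _ in series], dtype=float)
    if np.any(np.diff(concs) <= 0):
        raise ValidationError("series must be sorted by strictly ascending concentration")
    threshold = bg.mean() + 2.0 * bg.std(ddof=1)
    means = np.asarray([np.mean(np.asarray(m, dtype=float)) for _, m in series])
    above = means > threshold
    # smallest concentration starting an all-above suffix
    for i in range(len(series)):
        if above[i:].all() and above[i]:
            return float(concs[i])
    return None


@dataclass(frozen=True)
class ToleranceEllipse:
    """Tolerance ellipse of a hue-saturation cluster.

    Coordinates are (hue degrees, saturation percent) in a locally planar
    frame centred on the cluster's circular-mean hue.  The boundary is the
    set of points at squared Mahalanobis distance ``scale`` from the centre,
    with ``scale`` the chi-square(2 df) quantile at ``level`` (population
    form).
    """

    center: tuple[float, float]  # (hue deg, sat percent)
    covariance: np.ndarray  # 2x2, (deg, percent) units
    level: float
    scale: float
    degenerate: bool = False
    n: int = 0

    def _precision(self) -> np.ndarray:
        cov = np.asarray(self.covariance, dtype=float)
        if self.degenerate:
            return np.linalg.pinv(cov)
        return np.linalg.inv(cov)

    def mahalanobis2(self, hue, sat) -> np.ndarray:
        """Squared Mahalanobis distance of (hue deg, sat in [0,1]) points."""
        dx = _wrap_deg(np.asarray(hue, dtype=float) - self.center[0])
        dy = np.asarray(sat, dtype=float) * SAT_SCALE - self.center[1]
        p = self._precision()
        return p[0, 0] * dx * dx + 2 * p[0, 1] * dx * dy + p[1, 1] * dy * dy

    def contains(self, hue, sat) -> np.ndarray:
        return self.mahalanobis2(hue, sat) <= self.scale

    def boundary(self, n: int = 512) -> np.ndarray:
        """(n, 2) boundary points as (hue deg, sat in [0,1])."""
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        vals, vecs = np.linalg.eigh(np.asarray(self.covariance, dtype=float))
        radii = np.sqrt(np.clip(vals, 0, None) * self.scale)
        xy = (vecs * radii) @ np.stack([np.cos(theta), np.sin(theta)])
        hue = (self.center[0] + xy[0]) % 360.0
        sat = (self.center[1] + xy[1]) / SAT_SCALE
        return np.stack([hue, sat], axis=1)


def fit_tolerance_ellipse(hues, sats, level: float = 0.95) -> ToleranceEllipse:
    """Fit a chi-square-scaled tolerance ellipse to hue-saturation points.

    The centre is the circular-mean hue and mean saturation; the covariance
    is the sample covariance of (hue residual, saturation) with hue
    residuals wrapped into (-180, 180] around the centre, avoiding 0/360
    artefacts for clusters near the wrap point.  Degenerate (rank-deficient)
    clusters are returned flagged with a zero minor axis rather than
    raising.
    """
    h = np.asarray(hues, dtype=float).ravel()
    s = np.asarray(sats, dtype=float).ravel() * SAT_SCALE
    if h.size != s.size or h.size < 3:
        raise ValidationError("need at least three (hue, sat) points")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0, 1)")
    mu_h = circular_mean_deg(h)
    dx = _wrap_deg(h - mu_h)
    mu_x = float(dx.mean())
    mu_s = float(s.mean())
    pts = np.stack([dx - mu_x, s - mu_s])
    cov = pts @ pts.T / (h.size - 1)
    degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-12) < 2)
    return ToleranceEllipse(
        center=((mu_h + mu_x) % 360.0, mu_s),
        covariance=cov,
        level=float(level),
        scale=float(chi2.ppf(level, df=2)),
        degenerate=degenerate,
        n=int(h.size),
    )


def clusters_separable(a: ToleranceEllipse, b: ToleranceEllipse, n_boundary: int = 4096) -> bool:
    """True iff the interiors of the two same-level ellipses are disjoint.

    Two convex ellipses overlap exactly when the boundary of one enters the
    other or one contains the other's centre; both conditions are checked
    with a dense boundary parametrisation in each direction.
    """
    if abs(a.level - b.level) > 1e-12:
        raise ValidationError("ellipses must share the same tolerance level")
    for first, second in ((a, b), (b, a)):
        if second.contains(first.center[0], first.center[1] / SAT_SCALE):
            return False
        bd = first.boundary(n_boundary)
        if np.any(second.mahalanobis2(bd[:, 0], bd[:, 1]) < second.scale):
            return False
    return True


@dataclass
class RatioLine:
    """Calibrated unmixing line in the hue-saturation plane.

    Total-least-squares line through the cluster means of a volumetric-ratio
    series, parametrised by arc length ``s`` along the unit ``direction``
    from ``anchor``.  ``s0``/``s1`` are the projections of the pure-IR800
    (fraction 0) and pure-IR680 (fraction 1) cluster means; ``calibration``
    holds (fraction, s) pairs for piecewise-affine interpolation between
    calibration ratios.
    """

    anchor: np.ndarray  # (2,) in (deg, percent)
    direction: np.ndarray  # (2,) unit vector
    s0: float
    s1: float
    hue_center: float
    calibration: list = field(default_factory=list)
    monotone: bool = True
    residual: float = 0.0

    def project(self, hue, sat) -> np.ndarray:
        """Signed line parameter of (hue deg, sat in [0,1]) points."""
        x = _wrap_deg(np.asarray(hue, dtype=float) - self.hue_center) + self.hue_center
        y = np.asarray(sat, dtype=float) * SAT_SCALE
        d = np.stack([x - self.anchor[0], y - self.anchor[1]])
        return self.direction @ d

    def to_json(self) -> str:
        return json.dumps(
            {
                "anchor": list(map(float, self.anchor)),
                "direction": list(map(float, self.direction)),
                "s0": self.s0,
                "s1": self.s1,
                "hue_center": self.hue_center,
                "calibration": [[float(f), float(s)] for f, s in self.calibration],
                "monotone": self.monotone,
                "residual": self.residual,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RatioLine":
        d = json.loads(text)
        return cls(
            anchor=np.asarray(d["anchor"]),
            direction=np.asarray(d["direction"]),
            s0=d["s0"],
            s1=d["s1"],
            hue_center=d["hue_center"],
            calibration=[tuple(p) for p in d["calibration"]],
            monotone=d["monotone"],
            residual=d.get("residual", 0.0),
        )


def fit_ratio_line(cluster_means: dict) -> RatioLine:
    """Fit the unmixing line to {volumetric fraction: HueSatPoint} means.

    Requires at least the two pure endpoints (fractions 0 and 1).  The line
    minimises the total (orthogonal) least-squares residual in the
    (hue degrees, saturation percent) plane; its direction is oriented so
    the parameter increases with the IR680 fraction.
    """
    if not (0.0 in cluster_means and 1.0 in cluster_means) or len(cluster_means) < 2:
        raise ValidationError("calibration requires cluster means at fractions 0 and 1")
    fracs = sorted(cluster_means)
    hues = np.array([cluster_means[f].hue for f in fracs], dtype=float)
    sats = np.array([cluster_means[f].sat for f in fracs], dtype=float)
    hue_center = circular_mean_deg(hues)
    x = _wrap_deg(hues - hue_center) + hue_center
    y = sats * SAT_SCALE
    pts = np.stack([x, y])  # (2, n)

    p0 = pts[:, fracs.index(0.0)]
    p1 = pts[:, fracs.index(1.0)]
    if np.allclose(p0, p1, atol=1e-9):
        raise ValidationError("pure-probe cluster means coincide; probes indistinguishable")

    anchor = pts.mean(axis=1)
    centred = pts - anchor[:, None]
    if pts.shape[1] == 2:
        direction = p1 - p0
    else:
        _, svals, vt = np.linalg.svd(centred.T, full_matrices=False)
        direction = vt[0]
    direction = direction / np.linalg.norm(direction)

    s = direction @ centred
    i0, i1 = fracs.index(0.0), fracs.index(1.0)
    if s[i1] < s[i0]:
        direction = -direction
        s = -s
    resid2 = float(np.sum(centred**2) - np.sum(s**2))
    calibration = [(float(f), float(sv)) for f, sv in zip(fracs, s)]
    monotone = bool(np.all(np.diff([sv for _, sv in calibration]) > 0))
    return RatioLine(
        anchor=anchor,
        direction=direction,
        s0=float(s[i0]),
        s1=float(s[i1]),
        hue_center=hue_center,
        calibration=calibration,
        monotone=monotone,
        residual=np.sqrt(max(resid2, 0.0)),
    )


def estimate_ratio(point: HueSatPoint, line: RatioLine) -> float:
    """IR680 volumetric fraction of a hue-saturation point, in [0, 1].

    The point is orthogonally projected onto the calibrated line; its
    parameter is mapped to a fraction by piecewise-affine interpolation
    between the calibration ratios (falling back to the single affine map
    through the pure endpoints if the calibration parameters are not
    monotone), then clamped to [0, 1].
    """
    if not np.all(np.atleast_1d(point.valid)) or np.any(np.atleast_1d(point.sat) == 0):
        raise ValidationError("cannot estimate a ratio for an undefined-hue (gray) point")
    s = line.project(point.hue, point.sat)
    if line.monotone and len(line.calibration) > 2:
        fr = [f for f, _ in line.calibration]
        sv = [v for _, v in line.calibration]
        est = np.interp(s, sv, fr)
    else:
        est = (s - line.s0) / (line.s1 - line.s0)
    return float(np.clip(est, 0.0, 1.0))


def tumor_background_ratio(
    nir_plane: np.ndarray,
    tumor_mask: np.ndarray,
    background_mask: np.ndarray,
    offset: float = 0.0,
) -> float:
    """Tumour-to-background ratio of a fluorescence plane.

    Mean intensity over the tumour ROI divided by the mean over the adjacent
    healthy-tissue ROI, after subtracting ``offset`` from both (use the dark
    level if the plane is not already offset-subtracted).
    """
    t = np.asarray(tumor_mask, dtype=bool)
    b = np.asarray(background_mask, dtype=bool)
    if np.any(t & b):
        raise ValidationError("tumor and background masks must be disjoint")
    tumor = roi_mfi(nir_plane, t) - offset
    background = roi_mfi(nir_plane, b) - offset
    if background <= 0:
        raise ValidationError("background MFI is non-positive; ratio undefined")
    return float(tumor / background)
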