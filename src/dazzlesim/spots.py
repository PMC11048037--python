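"""Laser-spot bionic image pipeline.

Three stages mirror how the eye's view of a laser spot is rebuilt from a
raw detector frame:

1. extraction -- binarize the frame, trace the spot edge (from-scratch
   Canny), and measure centroid and equivalent-area radius;
2. compensation -- fill acquisition defects with the largest inscribed
   ellipse, enhance contrast with a power-law (gamma) transform, and fit
   a 2-D Gaussian by least squares to pin the centre;
3. biomimetic overlay -- superimpose a glare halo (a radial veiling-
   luminance profile) centred on the fitted spot.

A seeded synthetic-spot generator provides ground-truth test inputs with
configurable defects and noise.

Coordinates are 0-based cell indices with cell-centre convention,
x rightward (columns), y downward (rows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpotImage:
    """A grayscale spot frame with its physical scale (um per grid cell)."""

    data: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("spot image must be a 2-D grid")
        if not np.all(np.isfinite(arr)):
            raise ValueError("spot image must contain finite values")
        object.__setattr__(self, "data", arr)


@dataclass(frozen=True)
class SpotGeometry:
    """Centroid (x, y), equivalent-area circle radius, and the edge curve."""

    centroid: tuple[float, float]
    radius: float
    boundary: np.ndarray | None = None


@dataclass(frozen=True)
class GaussianSpotModel:
    """Elliptical 2-D Gaussian: A exp(-((x-x0)^2/2sx^2 + (y-y0)^2/2sy^2)) + c."""

    amplitude: float
    center: tuple[float, float]
    sigmas: tuple[float, float]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.sigmas[0] <= 0 or self.sigmas[1] <= 0:
            raise ValueError("sigmas must be positive")

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        x0, y0 = self.center
        sx, sy = self.sigmas
        return self.amplitude * np.exp(
            -((xx - x0) ** 2 / (2 * sx**2) + (yy - y0) ** 2 / (2 * sy**2))
        ) + self.offset


# ---------------------------------------------------------------------------
# Stage 1: extraction
# ---------------------------------------------------------------------------

def binarize(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Global-threshold foreground mask (Otsu by default)."""
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() == img.min():
        logger.warning("constant image: empty mask")
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(img) if threshold is None else threshold
    return img > thr


def canny_edges(
    image: np.ndarray,
    sigma: float = 1.4,
    low: float = 0.1,
    high: float = 0.3,
) -> np.ndarray:
    """Canny edge detector, implemented from first principles.

    Gaussian smoothing (``sigma``), Sobel gradients, non-maximum
    suppression along the quantized gradient direction, then
    double-threshold hysteresis: ``low`` and ``high`` are fractions of
    the maximum gradient magnitude, and weak edges survive only when
    8-connected to a strong edge.  Output edges are one pixel wide.
    """
    if not (0 <= low < high):
        raise ValueError("thresholds must satisfy 0 <= low < high")
    img = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(img, sigma)
    gx = ndimage.sobel(smoothed, axis=1)
    gy = ndimage.sobel(smoothed, axis=0)
    mag = np.hypot(gx, gy)
    if mag.max() == 0:
        return np.zeros(img.shape, dtype=bool)

    # non-maximum suppression: quantize direction into 4 sectors
    angle = np.mod(np.arctan2(gy, gx), np.pi)
    sector = np.floor((angle + np.pi / 8) / (np.pi / 4)).astype(int) % 4
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    padded = np.pad(mag, 1, mode="constant")
    ny, nx = mag.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    nms = np.zeros_like(mag, dtype=bool)
    for s, (dy, dx) in offsets.items():
        sel = sector == s
        ahead = padded[yy[sel] + 1 + dy, xx[sel] + 1 + dx]
        behind = padded[yy[sel] + 1 - dy, xx[sel] + 1 - dx]
        m = mag[sel]
        nms[yy[sel], xx[sel]] = (m >= ahead) & (m >= behind) & (m > 0)

    strong = nms & (mag >= high * mag.max())
    weak = nms & (mag >= low * mag.max())
    labels, _ = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    keep = np.unique(labels[strong])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def spot_geometry(
    mask: np.ndarray,
    image: np.ndarray | None = None,
    mode: str = "mask",
) -> SpotGeometry:
    """Centroid and equivalent-area radius of the foreground spot.

    ``mode='mask'`` uses the mask first moment; ``mode='intensity'``
    weights the centroid by image intensity inside the mask.  Radius is
    the radius of the circle with the mask's area, sqrt(area/pi).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty foreground")
    ys, xs = np.nonzero(mask)
    if mode == "intensity":
        if image is None:
            raise ValueError("intensity mode requires the image")
        w = np.asarray(image, dtype=float)[ys, xs]
        if w.sum() <= 0:
            raise ValueError("non-positive intensity weight")
        cx, cy = float(np.average(xs, weights=w)), float(np.average(ys, weights=w))
    elif mode == "mask":
        cx, cy = float(xs.mean()), float(ys.mean())
    else:
        raise ValueError(f"unknown centroid mode {mode!r}")
    radius = math.sqrt(mask.sum() / math.pi)
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len)[:, ::-1] if contours else None  # (x, y)
    return SpotGeometry(centroid=(cx, cy), radius=radius, boundary=boundary)


# ---------------------------------------------------------------------------
# Stage 2: compensation
# ---------------------------------------------------------------------------

def _ellipse_inside(mask, cx, cy, a, b, phi, n_test=256) -> bool:
    """True when the ellipse boundary lies entirely in the foreground."""
    t = np.linspace(0, 2 * np.pi, n_test, endpoint=False)
    ct, st = np.cos(phi), np.sin(phi)
    ex = cx + a * np.cos(t) * ct - b * np.sin(t) * st
    ey = cy + a * np.cos(t) * st + b * np.sin(t) * ct
    ix = np.round(ex).astype(int)
    iy = np.round(ey).astype(int)
    ny, nx = mask.shape
    if (ix < 0).any() or (ix >= nx).any() or (iy < 0).any() or (iy >= ny).any():
        return False
    return bool(mask[iy, ix].all())


def _grow_axes(mask, cx, cy, phi, seed_r=1.0, rounds=3, tol=0.05):
    """Largest feasible semi-axes for a fixed centre and orientation.

    Grows both axes together, then each alone, by binary search on the
    boundary-containment test; returns None when even the seed circle
    does not fit.
    """
    max_dim = float(max(mask.shape))
    a = b = min(seed_r, max_dim)
    if not _ellipse_inside(mask, cx, cy, a, b, phi):
        return None

    def grow(a0, b0, da, db):
        lo, hi = 0.0, max_dim
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _ellipse_inside(mask, cx, cy, a0 + da * mid, b0 + db * mid, phi):
                lo = mid
            else:
                hi = mid
        return a0 + da * lo, b0 + db * lo

    for _ in range(rounds):
        a, b = grow(a, b, 1.0, 1.0)
        a, b = grow(a, b, 1.0, 0.0)
        a, b = grow(a, b, 0.0, 1.0)
    return a, b


def inscribe_ellipse(mask: np.ndarray) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Largest-area ellipse inscribed in the foreground region.

    Candidate centres (distance-transform maximum and foreground
    centroid) are combined with a grid of orientations; for each the
    semi-axes are grown to the feasibility limit by binary search, and
    the best centre is polished by local shifts.  The result is a local
    maximum of the search, not a certified global optimum.

    Returns ``(center_xy, semi_axes, rotation_rad)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty foreground")
    dist = ndimage.distance_transform_edt(mask)
    if dist.max() < 1.0:
        raise ValueError("region too thin for an inscribed ellipse")
    dy, dx = np.unravel_index(np.argmax(dist), dist.shape)
    ys, xs = np.nonzero(mask)
    centers = {(float(dx), float(dy)), (round(xs.mean(), 1), round(ys.mean(), 1))}
    angles = np.deg2rad(np.arange(0.0, 180.0, 15.0))

    best = None  # (area, cx, cy, a, b, phi)
    for cx, cy in centers:
        for phi in angles:
            axes = _grow_axes(mask, cx, cy, phi)
            if axes and (best is None or axes[0] * axes[1] > best[0]):
                best = (axes[0] * axes[1], cx, cy, axes[0], axes[1], phi)
    if best is None:
        raise ValueError("region too thin for an inscribed ellipse")

    # polish: local centre shifts with axis regrowth
    for step in (2.0, 1.0, 0.5):
        moved = True
        while moved:
            moved = False
            _, cx, cy, a, b, phi = best
            for ddx, ddy in ((step, 0), (-step, 0), (0, step), (0, -step)):
                axes = _grow_axes(mask, cx + ddx, cy + ddy, phi)
                if axes and axes[0] * axes[1] > best[0] + 1e-6:
                    best = (axes[0] * axes[1], cx + ddx, cy + ddy, axes[0], axes[1], phi)
                    moved = True
    _, cx, cy, a, b, phi = best
    return (cx, cy), (a, b), float(phi)


def fill_ellipse(shape, center, semi_axes, rotation) -> np.ndarray:
    """Boolean mask of a filled rotated ellipse."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = center
    a, b = semi_axes
    ct, st = np.cos(rotation), np.sin(rotation)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def radial_profile_render(
    image: np.ndarray, center: tuple[float, float], n_bins: int = 32
) -> np.ndarray:
    """Angular-median radial intensity profile rendered over the grid.

    The median over angle at each radius is robust to defects occupying
    less than half of the circumference, so the rendering estimates the
    intact rotationally symmetric spot.  The profile is forced
    non-increasing outward (spots peak centrally).
    """
    img = np.asarray(image, dtype=float)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    r = np.hypot(xx - center[0], yy - center[1])
    rmax = max(r.max(), 1e-9)
    bins = np.minimum((r / rmax * n_bins).astype(int), n_bins - 1)
    profile = np.zeros(n_bins)
    for k in range(n_bins):
        sel = bins == k
        if sel.any():
            profile[k] = np.median(img[sel])
    profile = np.maximum.accumulate(profile[::-1])[::-1]
    return np.interp(r / rmax * n_bins, np.arange(n_bins) + 0.5, profile)


def detect_defects(
    image: np.ndarray, center: tuple[float, float], deficit: float = 0.5
) -> np.ndarray:
    """Cells darker than ``deficit`` times the angular-median radial profile.

    Flags coherent acquisition defects (notches, occlusions) inside the
    spot; the far background, where the profile itself is insignificant,
    is never flagged.
    """
    img = np.asarray(image, dtype=float)
    render = radial_profile_render(img, center)
    significant = render >= 0.1 * img.max()
    return (img < deficit * render) & significant


def compensate_spot(
    image: np.ndarray,
    mask: np.ndarray,
    center: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replenish acquisition defects in the spot.

    The largest inscribed ellipse models the intact spot support; the
    refill region is that ellipse plus any defect cells detected against
    the angular-median radial profile (centred on ``center``, default
    the intensity-weighted foreground centroid).  Deficits are
    replenished by the elementwise maximum of the image and the profile
    rendering, which never darkens good pixels.  Returns the compensated
    image and its re-binarized foreground.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    ell_center, axes, rot = inscribe_ellipse(mask)
    ell = fill_ellipse(image.shape, ell_center, axes, rot)
    if center is None:
        ys, xs = np.nonzero(mask)
        w = image[ys, xs]
        if w.sum() > 0:
            center = (float(np.average(xs, weights=w)), float(np.average(ys, weights=w)))
        else:
            center = ell_center
    render = radial_profile_render(image, center)
    region = ell | detect_defects(image, center)
    out = image.copy()
    out[region] = np.maximum(out[region], render[region])
    comp_mask = binarize(out) | mask | ell
    return out, comp_mask


def gamma_transform(image: np.ndarray, gamma: float, gain: float = 1.0) -> np.ndarray:
    """Power-law contrast enhancement s = gain * r^gamma on [0, 1] images."""
    img = np.asarray(image, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image must be normalized to [0, 1]")
    return np.clip(gain * img**gamma, 0.0, 1.0)


def fit_gaussian(
    image: np.ndarray,
    init: GaussianSpotModel | None = None,
    exclude: np.ndarray | None = None,
    loss: str = "soft_l1",
    max_nfev: int = 2000,
) -> GaussianSpotModel:
    """Nonlinear least-squares fit of an elliptical 2-D Gaussian.

    Initialized from image moments when ``init`` is absent.  ``exclude``
    masks out cells (e.g. detected acquisition defects); the default
    soft-L1 loss keeps residual coherent outliers from biasing the fit.
    Raises on non-convergence with solver diagnostics.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    keep = np.ones(img.shape, dtype=bool) if exclude is None else ~np.asarray(exclude, bool)
    if not keep.any():
        raise ValueError("exclusion mask removes every cell")
    ks_y, ks_x = np.nonzero(keep)
    vals = img[ks_y, ks_x]

    if init is None:
        offset0 = float(np.percentile(vals, 5))
        w = np.clip(vals - offset0, 0, None)
        if w.sum() <= 0:
            raise ValueError("image has no signal above background")
        x0 = float(np.average(ks_x, weights=w))
        y0 = float(np.average(ks_y, weights=w))
        sx = math.sqrt(max(np.average((ks_x - x0) ** 2, weights=w), 0.25))
        sy = math.sqrt(max(np.average((ks_y - y0) ** 2, weights=w), 0.25))
        amp0 = float(vals.max() - offset0)
        p0 = [amp0, x0, y0, sx, sy, offset0]
    else:
        p0 = [
            init.amplitude,
            init.center[0],
            init.center[1],
            init.sigmas[0],
            init.sigmas[1],
            init.offset,
        ]

    def residuals(p):
        amp, x0, y0, sx, sy, off = p
        model = amp * np.exp(
            -((ks_x - x0) ** 2 / (2 * sx**2) + (ks_y - y0) ** 2 / (2 * sy**2))
        ) + off
        return model - vals

    lb = [1e-12, -nx, -ny, 1e-3, 1e-3, -np.inf]
    ub = [np.inf, 2 * nx, 2 * ny, 10 * nx, 10 * ny, np.inf]
    f_scale = max(0.05 * float(vals.max() - vals.min()), 1e-12)
    res = least_squares(
        residuals, p0, bounds=(lb, ub), loss=loss, f_scale=f_scale, max_nfev=max_nfev
    )
    if not res.success:
        raise RuntimeError(
            f"Gaussian fit did not converge: {res.message} "
            f"(nfev={res.nfev}, cost={res.cost:.3g})"
        )
    amp, x0, y0, sx, sy, off = res.x
    model = GaussianSpotModel(
        amplitude=float(amp),
        center=(float(x0), float(y0)),
        sigmas=(float(sx), float(sy)),
        offset=float(off),
    )
    object.__setattr__(model, "residual", float(res.cost))
    return model


# ---------------------------------------------------------------------------
# Stage 3: biomimetic halo overlay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaloProfile:
    """Radial veiling-luminance profile mapped to image radii.

    ``radii`` in grid cells (ascending), ``values`` the non-negative,
    non-increasing veil samples; ``mode`` selects the compositing
    operator (``additive`` or ``screen``).
    """

    radii: np.ndarray
    values: np.ndarray
    mode: str = "additive"

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if radii.shape != values.shape or radii.ndim != 1:
            raise ValueError("radii and values must be matching 1-D arrays")
        if np.any(values < 0):
            raise ValueError("halo values must be non-negative")
        if np.any(np.diff(values) > 1e-12):
            raise ValueError("halo values must be non-increasing with radius")
        if self.mode not in ("additive", "screen"):
            raise ValueError("mode must be 'additive' or 'screen'")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "values", values)

    def evaluate(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self.radii, self.values, right=self.values[-1])


def halo_profile_from_glare(
    observer,
    scene,
    exposure,
    calib=None,
    um_per_degree: float = 291.0,
    scale_um: float = 1.0,
    max_radius_cells: float = 512.0,
    n_samples: int = 256,
    mode: str = "additive",
) -> HaloProfile:
    """Build a halo profile from the glare model's veiling luminance.

    Maps glare angle to image radius through the eye's retinal scale
    (``um_per_degree``, ~291 um/deg for a 60 D eye) and the image cell
    size ``scale_um``.
    """
    from . import glare as _glare

    calib = calib or _glare.DEFAULT_CALIBRATION
    radii = np.linspace(1.0, max_radius_cells, n_samples)
    theta = radii * scale_um / um_per_degree
    values = np.array(
        [
            _glare.veiling_luminance(t, observer, scene, exposure, calib)
            for t in theta
        ]
    )
    return HaloProfile(radii=radii, values=values, mode=mode)


def overlay_halo(
    compensated_spot: np.ndarray,
    model: GaussianSpotModel,
    halo: HaloProfile,
    scale: float = 1.0,
) -> np.ndarray:
    """Composite the glare halo onto the compensated spot.

    The halo is centred on the fitted spot centre, composited in linear
    intensity (additively, or with a screen operator after
    normalization) and min-max tone-mapped to [0, 1].
    """
    img = np.asarray(compensated_spot, dtype=float)
    ny, nx = img.shape
    x0, y0 = model.center
    if not (0 <= x0 < nx and 0 <= y0 < ny):
        raise ValueError("fitted centre lies outside the image")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - x0, yy - y0)
    halo_img = halo.evaluate(r)
    if halo.mode == "additive":
        out = img + halo_img
    else:  # screen
        def norm(a):
            return a / a.max() if a.max() > 0 else a

        a, b = norm(img), norm(halo_img)
        out = 1.0 - (1.0 - a) * (1.0 - b)
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)


# ---------------------------------------------------------------------------
# Synthetic spot generation
# ---------------------------------------------------------------------------

def generate_synthetic_spot(
    truth: GaussianSpotModel,
    shape: tuple[int, int] = (128, 128),
    defects: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
) -> tuple[SpotImage, dict]:
    """Render a ground-truth Gaussian spot with optional defects and noise.

    ``defects`` may contain:

    * ``notch``: ``{"angle_deg", "width_deg", "depth"}`` -- an angular
      sector bite removed from the spot, starting at ``depth`` (fraction
      of the truth sigma) out from the centre;
    * ``occlusion``: ``{"x", "y", "w", "h"}`` -- a rectangle zeroed out.

    Deterministic for a fixed seed; the returned record carries the full
    ground truth for recovery tests.
    """
    img = truth.evaluate(shape)
    record = {
        "amplitude": truth.amplitude,
        "center": truth.center,
        "sigmas": truth.sigmas,
        "offset": truth.offset,
        "radius_equiv": math.sqrt(2.0 * truth.sigmas[0] * truth.sigmas[1]),
        "defects": defects or {},
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    if defects:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        x0, y0 = truth.center
        if "notch" in defects:
            spec = defects["notch"]
            ang = np.rad2deg(np.arctan2(yy - y0, xx - x0)) % 360.0
            a0 = spec["angle_deg"] % 360.0
            half = spec["width_deg"] / 2.0
            dang = np.minimum(np.abs(ang - a0), 360.0 - np.abs(ang - a0))
            rr = np.hypot(xx - x0, yy - y0)
            rmin = spec.get("depth", 0.5) * min(truth.sigmas)
            img[(dang <= half) & (rr >= rmin)] = truth.offset
        if "occlusion" in defects:
            spec = defects["occlusion"]
            x, y, w, h = spec["x"], spec["y"], spec["w"], spec["h"]
            img[y : y + h, x : x + w] = truth.offset
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)
    return SpotImage(data=img, scale=scale), record


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def process_spot(
    image: np.ndarray,
    gamma: float = 0.8,
    canny_sigma: float = 1.4,
    centroid_mode: str = "mask",
) -> dict:
    """Run extraction + compensation on a spot frame.

    Returns a dict with the binary mask, edge map, raw geometry,
    compensated image/mask and the fitted Gaussian model.
    """
    img = np.asarray(image, dtype=float)
    mask = binarize(img)
    if not mask.any():
        raise ValueError("no foreground found in spot image")
    edges = canny_edges(img, sigma=canny_sigma)
    geometry = spot_geometry(mask, img, mode=centroid_mode)
    peak = img.max()
    enhanced = gamma_transform(img / peak if peak > 0 else img, gamma=gamma)
    # first pass pins the centre; defect cells flagged against the
    # angular-median profile are excluded from the refined fit
    fit0 = fit_gaussian(enhanced)
    defects = detect_defects(enhanced, fit0.center)
    fit = fit_gaussian(enhanced, exclude=defects) if defects.any() else fit0
    comp_img, comp_mask = compensate_spot(img, mask, center=fit.center)
    comp_geometry = spot_geometry(comp_mask)
    return {
        "mask": mask,
        "edges": edges,
        "geometry": geometry,
        "compensated": comp_img,
        "compensated_mask": comp_mask,
        "compensated_geometry": comp_geometry,
        "enhanced": enhanced,
        "defects": defects,
        "fit": fit,
    }
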