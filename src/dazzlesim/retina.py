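"""Retina-like foveated CMOS detector simulation.

The detector is a disc of pixels arranged on concentric rings: a fovea of
fine rings with constant radial pitch, surrounded by peripheral rings
whose radial extents grow geometrically to fill the photosensitive
radius, each carrying a fixed number of pixels.  Pixels respond
logarithmically to luminance, mimicking the eye's intensity response.

The default configuration mirrors the reference detector: 50 foveal
rings (6306 pixels), 88 peripheral rings of 520 pixels each (45,760
pixels), 138 rings and 52,066 pixels in total, minimum pixel size 14 um,
photosensitive radius 5113 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq


def default_fovea_schedule(n_rings: int = 50, total_pixels: int = 6306) -> list[int]:
    """Per-ring foveal pixel counts proportional to ring circumference.

    Ring k (1-based) receives ~ total * (2k-1) / n^2 pixels (the area of
    an annulus of constant width grows with 2k-1), rounded with a
    largest-remainder correction so the schedule sums exactly to
    ``total_pixels``.
    """
    k = np.arange(1, n_rings + 1)
    ideal = total_pixels * (2 * k - 1) / n_rings**2
    counts = np.floor(ideal).astype(int)
    counts = np.maximum(counts, 1)
    remainder = total_pixels - counts.sum()
    if remainder < 0:
        raise ValueError("schedule cannot sum to total_pixels")
    order = np.argsort(-(ideal - np.floor(ideal)))
    for i in range(remainder):
        counts[order[i % n_rings]] += 1
    assert counts.sum() == total_pixels
    return counts.tolist()


@dataclass(frozen=True)
class RingDetectorConfig:
    """Geometry of the foveated ring detector (lengths in micrometres)."""

    n_fovea_rings: int = 50
    n_periph_rings: int = 88
    min_pixel_size: float = 14.0
    photosensitive_radius: float = 5113.0
    periph_pixels_per_ring: int = 520
    fovea_ring_schedule: tuple[int, ...] = field(
        default_factory=lambda: tuple(default_fovea_schedule())
    )
    #: published reference metadata, not enforced invariants
    reference_counts: dict = field(
        default_factory=lambda: {
            "fovea_pixels": 6306,
            "periph_pixels": 45760,
            "total_pixels": 52066,
            "R": 7.07,
            "Q": 731,
        }
    )

    def __post_init__(self) -> None:
        if self.n_fovea_rings < 1 or self.n_periph_rings < 0:
            raise ValueError("ring counts must be positive")
        if len(self.fovea_ring_schedule) != self.n_fovea_rings:
            raise ValueError(
                "fovea_ring_schedule length must equal n_fovea_rings"
            )
        if any(c < 1 for c in self.fovea_ring_schedule):
            raise ValueError("all per-ring pixel counts must be positive")
        if self.n_periph_rings > 0 and self.periph_pixels_per_ring < 1:
            raise ValueError("periph_pixels_per_ring must be positive")
        if self.photosensitive_radius <= self.n_fovea_rings * self.min_pixel_size:
            raise ValueError(
                "photosensitive radius must exceed the foveal extent"
            )


@dataclass(frozen=True)
class LogPixelModel:
    """Logarithmic photoresponse: r(v) = dark_offset + gain*log1p(min(v, sat)).

    Monotone non-decreasing, r(0) = dark_offset; invertible below
    saturation via ``decode``.
    """

    dark_offset: float = 0.0
    gain: float = 1.0
    saturation_input: float = np.inf

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def encode(self, value):
        v = np.minimum(np.asarray(value, dtype=float), self.saturation_input)
        if np.any(v < 0):
            raise ValueError("luminance input must be non-negative")
        return self.dark_offset + self.gain * np.log1p(v)

    def decode(self, response):
        r = np.asarray(response, dtype=float)
        return np.expm1((r - self.dark_offset) / self.gain)

    def __call__(self, value):
        return self.encode(value)


class RingDetectorLayout:
    """Concrete pixel mosaic built from a :class:`RingDetectorConfig`.

    Per-ring arrays: inner/outer radius and pixel count; per-pixel arrays
    (flattened ring-major): ring index, angular index, centre polar
    coordinates and extents.  Pixels within a ring share the radial
    extent, and the angular spans of a ring tile 2*pi exactly.
    """

    def __init__(self, config: RingDetectorConfig):
        self.config = config
        n_f, n_p = config.n_fovea_rings, config.n_periph_rings
        w0 = config.min_pixel_size
        fovea_radius = n_f * w0

        widths = [w0] * n_f
        if n_p > 0:
            span = config.photosensitive_radius - fovea_radius

            def total(ratio: float) -> float:
                # sum_{j=1..n_p} w0 * ratio^j
                if abs(ratio - 1.0) < 1e-12:
                    return w0 * n_p
                return w0 * ratio * (ratio**n_p - 1.0) / (ratio - 1.0)

            if total(1.0) > span:
                raise ValueError(
                    "peripheral span too small for the ring count"
                )
            ratio = brentq(lambda r: total(r) - span, 1.0, 2.0, xtol=1e-12)
            widths += [w0 * ratio ** (j + 1) for j in range(n_p)]
            self.growth_ratio = ratio
        else:
            self.growth_ratio = 1.0

        self.ring_widths = np.asarray(widths)
        self.ring_outer = np.cumsum(self.ring_widths)
        self.ring_inner = self.ring_outer - self.ring_widths
        counts = list(config.fovea_ring_schedule) + [
            config.periph_pixels_per_ring
        ] * n_p
        self.ring_counts = np.asarray(counts, dtype=int)
        self.n_rings = n_f + n_p
        self.n_pixels = int(self.ring_counts.sum())
        self.pixel_offset = np.concatenate([[0], np.cumsum(self.ring_counts)])

        ring_idx = np.repeat(np.arange(self.n_rings), self.ring_counts)
        ang_idx = np.concatenate([np.arange(c) for c in self.ring_counts])
        spans = 2.0 * np.pi / self.ring_counts[ring_idx]
        self.pixel_ring = ring_idx
        self.pixel_angular_index = ang_idx
        self.pixel_center_radius = 0.5 * (
            self.ring_inner[ring_idx] + self.ring_outer[ring_idx]
        )
        self.pixel_center_angle = (ang_idx + 0.5) * spans
        self.pixel_radial_extent = self.ring_widths[ring_idx]
        self.pixel_arc_extent = self.pixel_center_radius * spans

    # -- summary -----------------------------------------------------------

    def summary(self) -> dict:
        """Layout bookkeeping plus the emergent R and Q metrics.

        Pixel size is taken as the larger of the radial and arc extents;
        R = max/min pixel size over the array, Q = detector diameter over
        the minimum pixel size.
        """
        size = np.maximum(self.pixel_radial_extent, self.pixel_arc_extent)
        cfg = self.config
        return {
            "n_rings": self.n_rings,
            "n_fovea_rings": cfg.n_fovea_rings,
            "n_periph_rings": cfg.n_periph_rings,
            "fovea_pixels": int(sum(cfg.fovea_ring_schedule)),
            "periph_pixels": int(cfg.n_periph_rings * cfg.periph_pixels_per_ring),
            "total_pixels": self.n_pixels,
            "R": float(size.max() / size.min()),
            "Q": float(2.0 * cfg.photosensitive_radius / cfg.min_pixel_size),
        }

    # -- point -> pixel mapping -------------------------------------------

    def pixel_index(self, x_um, y_um):
        """Map Cartesian points (um, origin at disc centre) to pixel ids.

        Returns -1 for points outside the photosensitive disc.
        """
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        r = np.hypot(x, y)
        theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)
        ring = np.searchsorted(self.ring_outer, r, side="left")
        inside = ring < self.n_rings
        ring_c = np.clip(ring, 0, self.n_rings - 1)
        counts = self.ring_counts[ring_c]
        ang = np.minimum((theta / (2.0 * np.pi) * counts).astype(int), counts - 1)
        idx = self.pixel_offset[ring_c] + ang
        return np.where(inside, idx, -1)

    # -- CSV round-trip ----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ring": self.pixel_ring,
                "index": self.pixel_angular_index,
                "r_center_um": self.pixel_center_radius,
                "theta_center_rad": self.pixel_center_angle,
                "dr_um": self.pixel_radial_extent,
                "arc_um": self.pixel_arc_extent,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def build_layout(config: RingDetectorConfig | None = None) -> RingDetectorLayout:
    """Build the pixel mosaic for a detector configuration (default: reference)."""
    return RingDetectorLayout(config or RingDetectorConfig())


# ---------------------------------------------------------------------------
# Sampling and reconstruction
# ---------------------------------------------------------------------------

def _grid_coordinates(shape, scale_um):
    """Cell-centre coordinates (um) of an image grid centred on the disc."""
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * scale_um
    x = (np.arange(nx) - (nx - 1) / 2.0) * scale_um
    return np.meshgrid(x, y)


def sample(
    image: np.ndarray,
    layout: RingDetectorLayout,
    pixel_model: LogPixelModel,
    scale_um: float,
    oversample: int = 4,
) -> np.ndarray:
    """Sample a Cartesian luminance image onto the ring mosaic.

    Each detector pixel responds with ``pixel_model`` applied to the mean
    luminance over its footprint, estimated on an ``oversample``-times
    finer grid.  The image (cell size ``scale_um`` um) must cover the
    photosensitive disc.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    half_extent = min(nx, ny) / 2.0 * scale_um
    if half_extent < layout.config.photosensitive_radius:
        raise ValueError(
            "image footprint smaller than the photosensitive disc: "
            f"{half_extent:.0f} um < {layout.config.photosensitive_radius:.0f} um"
        )
    fine = np.repeat(np.repeat(image, oversample, axis=0), oversample, axis=1)
    xx, yy = _grid_coordinates(fine.shape, scale_um / oversample)
    idx = layout.pixel_index(xx, yy).ravel()
    vals = fine.ravel()
    keep = idx >= 0
    sums = np.bincount(idx[keep], weights=vals[keep], minlength=layout.n_pixels)
    counts = np.bincount(idx[keep], minlength=layout.n_pixels)
    if np.any(counts == 0):
        raise ValueError(
            "some pixels received no samples; increase oversample or image "
            "resolution"
        )
    return pixel_model.encode(sums / counts)


def reconstruct(
    responses: np.ndarray,
    layout: RingDetectorLayout,
    output_grid_shape: tuple[int, int],
    pixel_model: LogPixelModel | None = None,
    background: float = 0.0,
    scale_um: float | None = None,
) -> np.ndarray:
    """Paint pixel responses back onto a Cartesian grid for display.

    Each output cell takes the value of the pixel whose footprint
    contains it (decoded through ``pixel_model`` when given); cells
    outside the photosensitive disc are filled with ``background``.
    ``scale_um`` fixes the output cell size; by default the disc fills
    the grid.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (layout.n_pixels,):
        raise ValueError("responses length does not match layout")
    ny, nx = output_grid_shape
    scale = scale_um or 2.0 * layout.config.photosensitive_radius / min(nx, ny)
    xx, yy = _grid_coordinates(output_grid_shape, scale)
    idx = layout.pixel_index(xx, yy)
    values = responses if pixel_model is None else pixel_model.decode(responses)
    out = np.full(output_grid_shape, background, dtype=float)
    inside = idx >= 0
    out[inside] = values[idx[inside]]
    return out
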