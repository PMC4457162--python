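"""Image calibration: linearisation against grey standards, normalisation
to the 40% standard, and region measurement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as _MplPath

STANDARD_REFLECTANCE = 0.40


@dataclass(frozen=True)
class GreyStandardSet:
    """Nominal reflectances of the in-frame standards and their measured
    raw digital counts, one row of counts per standard per channel."""

    nominal_reflectance: np.ndarray  # (n,), strictly increasing in (0, 1]
    measured_value: np.ndarray  # (n, n_channels) mean raw counts

    def __post_init__(self) -> None:
        nom = np.asarray(self.nominal_reflectance, dtype=float)
        meas = np.atleast_2d(np.asarray(self.measured_value, dtype=float))
        object.__setattr__(self, "nominal_reflectance", nom)
        object.__setattr__(self, "measured_value", meas)
        if np.any(np.diff(nom) <= 0):
            raise ValueError("nominal reflectances must be strictly increasing")
        if np.any(nom <= 0) or np.any(nom > 1):
            raise ValueError("nominal reflectances must lie in (0, 1]")
        if not np.any(np.isclose(nom, STANDARD_REFLECTANCE)):
            raise ValueError("standard set must include the 0.40 standard")
        if meas.shape[0] != nom.size:
            raise ValueError("one measured row per standard required")


@dataclass(frozen=True)
class LinearisationModel:
    """Per-channel power-law transfer raw = a * linear**b, fit on logs.

    ``linearise`` inverts the response; residuals are log-domain fit
    residuals per standard per channel, kept for QC.
    """

    a: np.ndarray  # (n_channels,)
    b: np.ndarray  # (n_channels,)
    residuals: np.ndarray  # (n_standards, n_channels)

    def linearise(self, raw: np.ndarray) -> np.ndarray:
        """Invert the fitted response channel-wise; raw may be (..., C)."""
        raw = np.asarray(raw, dtype=float)
        if raw.shape[-1] != self.a.size:
            raise ValueError("channel count mismatch with fitted model")
        out = np.zeros_like(raw)
        pos = raw > 0
        scaled = np.where(pos, raw / self.a, 1.0)
        out = np.where(pos, np.power(scaled, 1.0 / self.b), 0.0)
        return out


def fit_linearisation(standards: GreyStandardSet) -> LinearisationModel:
    """Least-squares power-law fit of measured counts on nominal reflectance.

    Requires at least three standards and strictly monotone measured values
    (a non-monotone series indicates a broken exposure series).
    """
    nom = standards.nominal_reflectance
    meas = standards.measured_value
    if nom.size < 3:
        raise ValueError("need at least 3 grey standards to fit")
    if np.any(meas <= 0):
        raise ValueError("measured standard values must be positive")
    if np.any(np.diff(meas, axis=0) <= 0):
        raise ValueError("measured standard values must increase with "
                         "nominal reflectance (fit-quality error)")
    x = np.log(nom)
    Y = np.log(meas)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    a = np.exp(beta[0])
    b = beta[1]
    resid = Y - X @ beta
    return LinearisationModel(a, b, resid)


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside a polygon.

    Polygon vertices are (row, col) in 0-based pixel coordinates; containment
    is tested at pixel centres (integer coordinates).
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must have >= 3 vertices")
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    mask = _MplPath(poly).contains_points(pts)
    return mask.reshape(h, w)


def measure_standards(channel_stack: np.ndarray,
                      standard_polygons: dict[float, np.ndarray]
                      ) -> GreyStandardSet:
    """Mean raw counts of each in-frame grey standard patch."""
    noms = sorted(standard_polygons)
    rows = []
    for g in noms:
        mask = polygon_mask(standard_polygons[g], channel_stack.shape[:2])
        rows.append(channel_stack[mask].mean(axis=0))
    return GreyStandardSet(np.asarray(noms), np.vstack(rows))


def linearise_and_normalise(channel_stack: np.ndarray,
                            model: LinearisationModel,
                            standard_polygon: np.ndarray,
                            standard_reflectance: float = STANDARD_REFLECTANCE
                            ) -> np.ndarray:
    """Raw image -> reflectance image, anchored to the in-frame standard.

    Per channel: linear(pixel) / linear(standard) * standard_reflectance,
    so a value of 1.0 means 100% reflectance.  Raises if the standard patch
    is clipped at 255 in any channel.
    """
    stack = np.asarray(channel_stack, dtype=float)
    mask = polygon_mask(standard_polygon, stack.shape[:2])
    if not mask.any():
        raise ValueError("standard region is empty")
    std_raw = stack[mask]
    if np.any(std_raw >= 255):
        raise ValueError("grey standard is saturated (raw counts at 255)")
    std_linear = model.linearise(std_raw.mean(axis=0)[None, :])[0]
    linear = model.linearise(stack)
    return linear / std_linear * standard_reflectance


@dataclass(frozen=True)
class RegionMeasurement:
    region: str
    mean: np.ndarray  # per-channel mean reflectance
    n_pixels: int
    clipped_fraction: float = 0.0


def measure_region(image: np.ndarray, polygon: np.ndarray,
                   region: str = "", trim_top_percentile: float | None = None
                   ) -> RegionMeasurement:
    """Per-channel mean reflectance over a polygon's interior pixels.

    ``trim_top_percentile`` optionally drops the brightest pixels (by channel
    mean) before averaging, a stand-in for manual specular-highlight
    exclusion; default off.
    """
    mask = polygon_mask(polygon, image.shape[:2])
    if not mask.any():
        raise ValueError("mask selects no pixels")
    vals = image[mask]
    if trim_top_percentile is not None:
        bright = vals.mean(axis=1)
        keep = bright <= np.percentile(bright, 100.0 - trim_top_percentile)
        if keep.any():
            vals = vals[keep]
    clipped = float(np.mean(np.any(vals >= 1.0, axis=1)))
    return RegionMeasurement(region, vals.mean(axis=0), int(vals.shape[0]),
                             clipped)
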