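"""Spectral building blocks: illuminant, receptor templates, camera channels.

The default viewer sensitivities ship as a packaged CSV built from
peak-parameterised visual-pigment templates (alpha + beta band) combined
with a logistic long-pass stand-in for oil-droplet filtering.  Every curve
is replaceable via CSV at the CLI / API level; the templates here exist so
the defaults are reproducible from code.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: default wavelength grid, nm
DEFAULT_WAVELENGTHS = np.arange(300.0, 701.0, 5.0)

#: nominal channel peaks of the UV-converted camera, nm (UV, SW, MW, LW)
CAMERA_PEAKS = {"camUV": 366.0, "camSW": 465.0, "camMW": 522.0, "camLW": 667.0}
#: half-bandwidths chosen so channel support matches the stated pass bands
CAMERA_SIGMAS = {"camUV": 14.0, "camSW": 45.0, "camMW": 55.0, "camLW": 42.0}
CAMERA_CHANNELS = tuple(CAMERA_PEAKS)

#: viewer single-cone pigment peaks (nm) and oil-droplet cut-offs (nm)
VIEWER_PIGMENT_PEAKS = {"UV": 371.0, "SW": 448.0, "MW": 503.0, "LW": 563.0,
                        "DBL": 563.0}
VIEWER_DROPLET_CUTS = {"UV": None, "SW": 414.0, "MW": 508.0, "LW": 567.0,
                       "DBL": 413.0}


def pigment_template(wavelengths: np.ndarray, peak: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha plus beta band).

    Standard rhodopsin nomogram parameterised only by the peak wavelength;
    returns values normalised to a maximum of 1.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = peak / wl
    a = 0.8795 + 0.0459 * np.exp(-((peak - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    beta_peak = 189.0 + 0.315 * peak
    beta_band = -40.5 + 0.195 * peak
    beta = 0.26 * np.exp(-(((wl - beta_peak) / beta_band) ** 2))
    s = alpha + beta
    return s / s.max()


def droplet_longpass(wavelengths: np.ndarray, cut: float,
                     slope_nm: float = 8.0) -> np.ndarray:
    """Logistic long-pass transmission approximating an oil droplet."""
    wl = np.asarray(wavelengths, dtype=float)
    return 1.0 / (1.0 + np.exp(-(wl - cut) / slope_nm))


def build_viewer_sensitivities(
        wavelengths: np.ndarray = DEFAULT_WAVELENGTHS) -> pd.DataFrame:
    """Default viewer (small passerine) cone sensitivities on a grid."""
    out = {"wavelength_nm": np.asarray(wavelengths, dtype=float)}
    for name, peak in VIEWER_PIGMENT_PEAKS.items():
        s = pigment_template(wavelengths, peak)
        cut = VIEWER_DROPLET_CUTS[name]
        if cut is not None:
            s = s * droplet_longpass(wavelengths, cut)
        out[name] = s / s.max()
    return pd.DataFrame(out)


def build_camera_channels(
        wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
        peaks: dict[str, float] | None = None,
        sigmas: dict[str, float] | None = None) -> pd.DataFrame:
    """Gaussian camera channel sensitivities at the nominal peaks."""
    peaks = dict(CAMERA_PEAKS if peaks is None else peaks)
    sigmas = dict(CAMERA_SIGMAS if sigmas is None else sigmas)
    wl = np.asarray(wavelengths, dtype=float)
    out = {"wavelength_nm": wl}
    for name, peak in peaks.items():
        out[name] = np.exp(-0.5 * ((wl - peak) / sigmas[name]) ** 2)
    return pd.DataFrame(out)


from functools import lru_cache


@lru_cache(maxsize=None)
def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("aposcan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_d65() -> pd.DataFrame:
    """CIE standard daylight illuminant D65, relative spectral power."""
    return _load_packaged_csv("d65.csv")


def load_viewer_sensitivities() -> pd.DataFrame:
    """Packaged default viewer cone sensitivity curves."""
    return _load_packaged_csv("viewer_cones.csv")


def d65_on(wavelengths: np.ndarray) -> np.ndarray:
    """D65 spectral power interpolated onto ``wavelengths``."""
    tbl = load_d65()
    return np.interp(np.asarray(wavelengths, dtype=float),
                     tbl["wavelength_nm"].to_numpy(),
                     tbl["power"].to_numpy())
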