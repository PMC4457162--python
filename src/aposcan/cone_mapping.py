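"""Quantum catches from spectra and the camera-to-cone polynomial mapping.

``compute_cone_catch`` is the ground-truth route: trapezoidal integration of
reflectance x illuminant x sensitivity, normalised to a perfect reflector.
``fit_polynomial_mapping`` / ``apply_mapping`` reproduce the image route:
predicting viewer cone catches from calibrated camera channel values with a
per-receptor polynomial regression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import (
    DEFAULT_WAVELENGTHS,
    build_camera_channels,
    d65_on,
    load_viewer_sensitivities,
)
from .types import SINGLE_CONES, ConeCatch, ReflectanceSpectrum

EPSILON_CATCH = 1e-6  # floor for non-positive predicted catches (log safety)


@dataclass(frozen=True)
class SpectralSensitivity:
    """A named receptor or camera-channel sensitivity curve."""

    receptor_name: str
    wavelengths: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.sensitivity, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sensitivity", s)
        if np.any(s < 0):
            raise ValueError("sensitivity must be non-negative")
        if s.shape != wl.shape:
            raise ValueError("sensitivity and wavelengths must align")

    def on(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.interp(wavelengths, self.wavelengths, self.sensitivity,
                         left=0.0, right=0.0)


def viewer_sensitivities(
        wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
) -> dict[str, SpectralSensitivity]:
    """The packaged viewer cone set resampled onto a grid."""
    tbl = load_viewer_sensitivities()
    wl_src = tbl["wavelength_nm"].to_numpy()
    out = {}
    for name in ("UV", "SW", "MW", "LW", "DBL"):
        s = np.interp(wavelengths, wl_src, tbl[name].to_numpy())
        out[name] = SpectralSensitivity(name, np.asarray(wavelengths, float), s)
    return out


def camera_sensitivities(
        wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
) -> dict[str, SpectralSensitivity]:
    """The default 4-channel camera resampled onto a grid."""
    tbl = build_camera_channels(wavelengths)
    return {
        name: SpectralSensitivity(name, np.asarray(wavelengths, float),
                                  tbl[name].to_numpy())
        for name in tbl.columns if name != "wavelength_nm"
    }


def compute_cone_catch(spectrum: ReflectanceSpectrum,
                       sensitivity: SpectralSensitivity,
                       illuminant: np.ndarray | None = None) -> float:
    """Quantum catch of one receptor for one surface under an illuminant.

    q = integral(R * I * S) / integral(I * S) with trapezoidal quadrature, so
    a perfect reflector gives q = 1 for any receptor (von-Kries-style
    normalisation).  ``illuminant`` is resolved on the spectrum's grid and
    defaults to D65.
    """
    wl = spectrum.wavelengths
    s = sensitivity.on(wl)
    if not np.any(s > 0):
        raise ValueError(
            f"sensitivity '{sensitivity.receptor_name}' does not overlap the "
            "spectrum's wavelength range")
    illum = d65_on(wl) if illuminant is None else np.asarray(illuminant, float)
    if illum.shape != wl.shape:
        raise ValueError("illuminant must be sampled on the spectrum grid")
    denom = np.trapezoid(illum * s, wl)
    if denom <= 0:
        raise ValueError("illuminant x sensitivity integrates to zero")
    return float(np.trapezoid(spectrum.reflectance * illum * s, wl) / denom)


def catch_matrix(sensitivities: dict[str, SpectralSensitivity],
                 wavelengths: np.ndarray,
                 illuminant: np.ndarray | None = None) -> tuple[list[str], np.ndarray]:
    """Linear operator mapping a reflectance vector to catches (vectorised route).

    Returns (receptor names, matrix W) with q = W @ R for R sampled on
    ``wavelengths``.  Exact for trapezoidal quadrature because the catch is
    linear in reflectance.
    """
    wl = np.asarray(wavelengths, dtype=float)
    illum = d65_on(wl) if illuminant is None else np.asarray(illuminant, float)
    # trapezoidal quadrature weights on a (possibly non-uniform) grid
    tw = np.zeros_like(wl)
    tw[1:] += np.diff(wl) / 2
    tw[:-1] += np.diff(wl) / 2
    names, rows = [], []
    for name, sens in sensitivities.items():
        s = sens.on(wl)
        denom = np.sum(tw * illum * s)
        rows.append(tw * illum * s / denom)
        names.append(name)
    return names, np.vstack(rows)


def spectrum_cone_catch(spectrum: ReflectanceSpectrum,
                        sensitivities: dict[str, SpectralSensitivity] | None = None,
                        illuminant: np.ndarray | None = None) -> ConeCatch:
    """Full viewer ConeCatch (four singles + double) for one spectrum."""
    sens = viewer_sensitivities(spectrum.wavelengths) if sensitivities is None \
        else sensitivities
    q = {name: compute_cone_catch(spectrum, s, illuminant)
         for name, s in sens.items()}
    return ConeCatch(q["UV"], q["SW"], q["MW"], q["LW"], q.get("DBL"))


# ---------------------------------------------------------------------------
# polynomial mapping camera channels -> cone catches


def _monomial_terms(channels: tuple[str, ...], degree: int) -> list[tuple[str, ...]]:
    terms: list[tuple[str, ...]] = [()]  # intercept
    for d in range(1, degree + 1):
        terms.extend(combinations_with_replacement(channels, d))
    return terms


def _design(values: np.ndarray, channels: tuple[str, ...],
            terms: list[tuple[str, ...]]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(channels)}
    cols = []
    for term in terms:
        col = np.ones(values.shape[0])
        for c in term:
            col = col * values[:, idx[c]]
        cols.append(col)
    return np.column_stack(cols)


@dataclass
class MappingModel:
    """Per-receptor polynomial mapping from camera channels to cone catches."""

    channels: tuple[str, ...]
    degree: int
    terms: list[tuple[str, ...]]
    coefficients: dict[str, np.ndarray]
    r_squared: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": list(self.channels),
            "degree": self.degree,
            "terms": [list(t) for t in self.terms],
            "coefficients": {k: list(map(float, v))
                             for k, v in self.coefficients.items()},
            "r_squared": self.r_squared,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MappingModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            channels=tuple(payload["channels"]),
            degree=int(payload["degree"]),
            terms=[tuple(t) for t in payload["terms"]],
            coefficients={k: np.asarray(v, dtype=float)
                          for k, v in payload["coefficients"].items()},
            r_squared={k: float(v) for k, v in payload["r_squared"].items()},
        )


def fit_polynomial_mapping(camera_values: np.ndarray,
                           cone_values: np.ndarray,
                           channels: tuple[str, ...],
                           receptors: tuple[str, ...],
                           degree: int = 2) -> MappingModel:
    """Least-squares polynomial fit of each receptor on camera monomials.

    ``camera_values``: (n, n_channels); ``cone_values``: (n, n_receptors).
    Requires at least 10x more training pairs than polynomial terms.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    cam = np.asarray(camera_values, dtype=float)
    cone = np.asarray(cone_values, dtype=float)
    terms = _monomial_terms(channels, degree)
    if cam.shape[0] < 10 * len(terms):
        raise ValueError(
            f"need >= {10 * len(terms)} training pairs for {len(terms)} terms, "
            f"got {cam.shape[0]}")
    X = _design(cam, channels, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear monomials via pivoted-QR style diagnostics
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [".".join(t) or "1" for t, d in zip(terms, diag)
               if d < 1e-8 * diag.max()]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    coefs, r2 = {}, {}
    for j, rec in enumerate(receptors):
        beta, _, _, _ = np.linalg.lstsq(X, cone[:, j], rcond=None)
        resid = cone[:, j] - X @ beta
        ss_tot = float(np.sum((cone[:, j] - cone[:, j].mean()) ** 2))
        coefs[rec] = beta
        r2[rec] = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return MappingModel(tuple(channels), degree, terms, coefs, r2)


def apply_mapping(model: MappingModel, camera_values: np.ndarray,
                  clip_floor: float | None = EPSILON_CATCH) -> pd.DataFrame:
    """Predict cone catches for camera channel vectors.

    Negative / zero predictions are floored at ``clip_floor`` with a warning,
    keeping downstream log-ratio contrasts defined; pass ``None`` to get the
    raw polynomial values.
    """
    cam = np.atleast_2d(np.asarray(camera_values, dtype=float))
    if cam.shape[1] != len(model.channels):
        raise ValueError(
            f"expected {len(model.channels)} channels {model.channels}, "
            f"got {cam.shape[1]}")
    X = _design(cam, model.channels, model.terms)
    out = {}
    n_floored = 0
    for rec, beta in model.coefficients.items():
        pred = X @ beta
        if clip_floor is not None:
            n_floored += int(np.sum(pred < clip_floor))
            pred = np.maximum(pred, clip_floor)
        out[rec] = pred
    if n_floored:
        warnings.warn(f"floored {n_floored} non-positive predicted catches at "
                      f"{clip_floor}", stacklevel=2)
    return pd.DataFrame(out)


def predicted_cone_catch(model: MappingModel,
                         camera_values: np.ndarray) -> ConeCatch:
    """Convenience: one camera vector -> one ConeCatch."""
    df = apply_mapping(model, np.atleast_2d(camera_values))
    row = df.iloc[0]
    return ConeCatch(*(float(row[c]) for c in SINGLE_CONES),
                     float(row["DBL"]) if "DBL" in df.columns else None)
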