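"""Core value types shared across the pipeline.

All spectral quantities are wavelength-indexed in nanometres on the
300-700 nm range; quantum catches are normalised so that a perfect
(Lambertian, 100% reflective) surface has a catch of 1 in every receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical single-cone receptor order used throughout the package
SINGLE_CONES = ("UV", "SW", "MW", "LW")
DOUBLE_CONE = "DBL"


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Reflectance of a surface patch on a uniform wavelength grid."""

    wavelengths: np.ndarray  # nm, strictly increasing, uniform step
    reflectance: np.ndarray  # fraction in [0, 1]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if r.shape != wl.shape:
            raise ValueError("reflectance and wavelengths must have equal length")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("wavelength step must be uniform")
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise ValueError("reflectance must lie within [0, 1]")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def interp(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation onto another grid (zero outside support)."""
        return np.interp(wavelengths, self.wavelengths, self.reflectance,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class ConeCatch:
    """Quantum catches of the four avian single cones plus the double cone."""

    q_UV: float
    q_SW: float
    q_MW: float
    q_LW: float
    q_DBL: float | None = None

    def singles(self) -> np.ndarray:
        """The four single-cone catches in canonical (UV, SW, MW, LW) order."""
        return np.array([self.q_UV, self.q_SW, self.q_MW, self.q_LW], dtype=float)

    def as_dict(self) -> dict[str, float]:
        d = {"UV": self.q_UV, "SW": self.q_SW, "MW": self.q_MW, "LW": self.q_LW}
        if self.q_DBL is not None:
            d[DOUBLE_CONE] = self.q_DBL
        return d

    @classmethod
    def from_array(cls, singles: np.ndarray, dbl: float | None = None) -> "ConeCatch":
        u, s, m, l = (float(v) for v in np.asarray(singles, dtype=float))
        return cls(u, s, m, l, None if dbl is None else float(dbl))

    def scaled(self, factor: float) -> "ConeCatch":
        return ConeCatch(
            self.q_UV * factor, self.q_SW * factor, self.q_MW * factor,
            self.q_LW * factor,
            None if self.q_DBL is None else self.q_DBL * factor,
        )


@dataclass(frozen=True)
class ReceptorNoise:
    """Receptor noise for the modelled viewer.

    ``relative_abundance`` maps each single cone to its relative abundance;
    the Weber fraction ``weber_fraction`` applies to the most abundant cone,
    and per-channel noise is ``omega_i = weber / sqrt(eta_i / eta_max)``.
    """

    relative_abundance: dict[str, float] = field(
        default_factory=lambda: {"UV": 0.37, "SW": 0.70, "MW": 0.99, "LW": 1.00})
    weber_fraction: float = 0.05
    weber_dbl: float = 0.05

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.relative_abundance.values()):
            raise ValueError("cone abundances must be strictly positive")
        if self.weber_fraction <= 0 or self.weber_dbl <= 0:
            raise ValueError("Weber fractions must be strictly positive")

    def omegas(self, cones: tuple[str, ...] = SINGLE_CONES) -> np.ndarray:
        eta = np.array([self.relative_abundance[c] for c in cones], dtype=float)
        eta_max = max(self.relative_abundance.values())
        return self.weber_fraction / np.sqrt(eta / eta_max)


@dataclass(frozen=True)
class BioassayRecord:
    """Dead-out-of-n Daphnia counts for one vial at one check time."""

    specimen_id: str
    dilution: float  # fraction of stock extract in [0, 1]
    time: float  # hours
    dead: int
    n: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.dilution <= 1:
            raise ValueError("dilution must lie within [0, 1]")
        if not 0 <= self.dead <= self.n:
            raise ValueError("dead count must lie within [0, n]")


@dataclass(frozen=True)
class PredationRecord:
    """One artificial model's outcome in the field experiment."""

    model_id: str
    colour_label: str
    block: str
    time: float  # hours on the check grid
    event: bool  # True = attacked, False = censored
    censor_reason: str = "none"  # none|rodent|degraded|slime|administrative

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("observation time must be positive")
        if not self.event and self.censor_reason == "none":
            raise ValueError("censored records need a censor_reason")
        if self.event and self.censor_reason != "none":
            raise ValueError("attacked records cannot carry a censor_reason")
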