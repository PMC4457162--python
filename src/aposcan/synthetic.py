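"""Synthetic world generation: spectra, camera images, bioassays, predation.

Every generator is a pure function of its seed, so each downstream stage of
the pipeline has a recovery test against known ground truth.  Defaults
mirror the study design: six species archetypes, seven extract dilutions,
ten Daphnia per vial, 4 h field checks over 48 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .cone_mapping import camera_sensitivities, catch_matrix, viewer_sensitivities
from .spectral import CAMERA_CHANNELS, DEFAULT_WAVELENGTHS
from .types import BioassayRecord, ConeCatch, PredationRecord, ReflectanceSpectrum

DEFAULT_DILUTIONS = (1.0, 0.8, 0.6, 0.5, 0.4, 0.2, 0.0)
DEFAULT_ASSAY_TIMES = (1.0, 3.0, 24.0)
DEFAULT_BACKGROUND_MORTALITY = 0.02  # per hour, control-water death rate

# ---------------------------------------------------------------------------
# reflectance spectra


def generate_reflectance_library(n: int, smoothness: float = 50.0,
                                 seed: int | np.random.Generator = 0,
                                 wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
                                 ) -> list[ReflectanceSpectrum]:
    """Random smooth reflectance spectra squashed into [0, 1].

    Band-limited Gaussian noise (correlation length ``smoothness`` nm) with a
    random overall level, passed through a logistic squash.  As smoothness
    grows the curves flatten towards constant lines.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wl = np.asarray(wavelengths, dtype=float)
    step = wl[1] - wl[0]
    sigma_pts = max(smoothness / step, 1e-6)
    out = []
    for _ in range(n):
        white = rng.standard_normal(wl.size)
        sm = gaussian_filter1d(white, sigma_pts, mode="nearest")
        # restore ~unit marginal variance so the library stays diverse
        sm = sm * np.sqrt(2.0 * np.sqrt(np.pi) * sigma_pts)
        level = rng.normal(0.0, 1.2)
        refl = expit(level + 1.2 * sm)
        out.append(ReflectanceSpectrum(wl, refl))
    return out


def _sigmoid_step(wl: np.ndarray, cut: float, width: float,
                  low: float, high: float) -> np.ndarray:
    return low + (high - low) * expit((wl - cut) / width)


def _leaf(wl: np.ndarray, centre: float = 550.0, amp: float = 0.33) -> np.ndarray:
    return 0.05 + amp * np.exp(-0.5 * ((wl - centre) / 45.0) ** 2)


def archetype_base_spectra(wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
                           ) -> dict[str, dict[str, np.ndarray]]:
    """Reference (elytra, spot, background) reflectances per species archetype."""
    wl = np.asarray(wavelengths, dtype=float)
    red = _sigmoid_step(wl, 600.0, 12.0, 0.04, 0.62)
    orange = _sigmoid_step(wl, 570.0, 14.0, 0.05, 0.60)
    yellow = _sigmoid_step(wl, 520.0, 16.0, 0.05, 0.55)
    brown = _sigmoid_step(wl, 560.0, 80.0, 0.06, 0.28)
    black = np.full_like(wl, 0.05)
    dark = np.full_like(wl, 0.06)
    return {
        "red": {"elytra": red, "spot": black, "background": _leaf(wl, 548.0)},
        "black-morph": {"elytra": dark, "spot": red, "background": _leaf(wl, 548.0)},
        "orange": {"elytra": orange, "spot": black, "background": _leaf(wl, 552.0)},
        "black": {"elytra": black, "spot": 0.04 + 0.3 * expit((wl - 600) / 15),
                  "background": _leaf(wl, 545.0, 0.28)},
        "yellow": {"elytra": yellow, "spot": black, "background": _leaf(wl, 555.0)},
        "brown": {"elytra": brown, "spot": brown * 0.7,
                  "background": _leaf(wl, 550.0, 0.30)},
    }


# ---------------------------------------------------------------------------
# world configuration


@dataclass(frozen=True)
class SpeciesArchetype:
    name: str
    elytra_catch: ConeCatch
    spot_catch: ConeCatch
    background_catch: ConeCatch
    true_toxicity: float

    def __post_init__(self) -> None:
        for c in (self.elytra_catch, self.spot_catch, self.background_catch):
            if np.any(c.singles() <= 0):
                raise ValueError("archetype catches must be strictly positive")
        if self.true_toxicity < 0:
            raise ValueError("true_toxicity must be >= 0")


@dataclass(frozen=True)
class SyntheticWorldConfig:
    seed: int = 0
    species_archetypes: tuple[SpeciesArchetype, ...] = ()
    honesty_slope: float = 0.0  # toxicity units per JND of chromatic contrast
    camera_gamma: float = 2.2
    hazard_coefficient: float = 0.0  # log-hazard change per JND
    admin_censor_time: float = 48.0
    background_mortality: float = DEFAULT_BACKGROUND_MORTALITY

    def __post_init__(self) -> None:
        if self.camera_gamma <= 0:
            raise ValueError("camera_gamma must be > 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")


#: default baseline toxicities ordered as in the study's summary figure
DEFAULT_TOXICITY = {"orange": 8.0, "red": 6.0, "black-morph": 6.0,
                    "black": 4.0, "yellow": 2.5, "brown": 0.8}


def default_archetypes(wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
                       ) -> tuple[SpeciesArchetype, ...]:
    """Six species archetypes with catches computed from reference spectra."""
    sens = viewer_sensitivities(wavelengths)
    base = archetype_base_spectra(wavelengths)

    def catch_of(refl: np.ndarray) -> ConeCatch:
        from .cone_mapping import spectrum_cone_catch
        return spectrum_cone_catch(ReflectanceSpectrum(wavelengths, refl), sens)

    out = []
    for name, parts in base.items():
        out.append(SpeciesArchetype(
            name,
            catch_of(parts["elytra"]),
            catch_of(parts["spot"]),
            catch_of(parts["background"]),
            DEFAULT_TOXICITY[name],
        ))
    return tuple(out)


def default_world_config(seed: int = 0, honesty_slope: float = 0.0,
                         hazard_coefficient: float = 0.0,
                         camera_gamma: float = 2.2) -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        seed=seed,
        species_archetypes=default_archetypes(),
        honesty_slope=honesty_slope,
        camera_gamma=camera_gamma,
        hazard_coefficient=hazard_coefficient,
    )


def jitter_spectrum(base: np.ndarray, rng: np.random.Generator,
                    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
                    level_sd: float = 0.15, wiggle_sd: float = 0.05,
                    smoothness: float = 60.0) -> ReflectanceSpectrum:
    """Individual variation around a reference spectrum (in logit space)."""
    wl = np.asarray(wavelengths, dtype=float)
    step = wl[1] - wl[0]
    sigma_pts = smoothness / step
    wiggle = gaussian_filter1d(rng.standard_normal(wl.size), sigma_pts,
                               mode="nearest")
    wiggle = wiggle * np.sqrt(2.0 * np.sqrt(np.pi) * sigma_pts) * wiggle_sd
    logit = np.log(np.clip(base, 1e-4, 1 - 1e-4) /
                   (1 - np.clip(base, 1e-4, 1 - 1e-4)))
    refl = expit(logit + rng.normal(0.0, level_sd) + wiggle)
    return ReflectanceSpectrum(wl, refl)


# ---------------------------------------------------------------------------
# camera image simulation


@dataclass
class CameraImagePair:
    """Raw VIS + UV image pair with region and grey-standard geometry.

    ``vis`` holds (H, W, 3) values for channels (camLW, camMW, camSW);
    ``uv`` holds (H, W) values for camUV.  Polygons are (n, 2) arrays of
    (row, col) vertices in 0-based pixel coordinates.
    """

    vis: np.ndarray
    uv: np.ndarray
    region_polygons: dict[str, np.ndarray]
    standard_polygons: dict[float, np.ndarray]
    gamma: float

    def channel_stack(self) -> np.ndarray:
        """(H, W, 4) raw values in canonical (camUV, camSW, camMW, camLW) order."""
        return np.stack([self.uv.astype(float),
                         self.vis[..., 2].astype(float),
                         self.vis[..., 1].astype(float),
                         self.vis[..., 0].astype(float)], axis=-1)

    def region_mask(self, polygon: np.ndarray) -> np.ndarray:
        from .calibration import polygon_mask
        return polygon_mask(polygon, self.uv.shape)


def _rect(r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
    # half-open pixel rectangle expressed as a polygon of pixel-centre bounds
    return np.array([[r0 - 0.5, c0 - 0.5], [r0 - 0.5, c1 - 0.5],
                     [r1 - 0.5, c1 - 0.5], [r1 - 0.5, c0 - 0.5]])


def simulate_camera_image(spectra_by_region: dict[str, ReflectanceSpectrum],
                          camera_gamma: float = 2.2,
                          grey_standards: tuple[float, ...] = (0.02, 0.05, 0.1,
                                                               0.2, 0.4, 0.6,
                                                               0.8, 0.99),
                          noise_sd: float = 0.0,
                          seed: int | np.random.Generator = 0,
                          patch_px: int = 12,
                          quantise: bool = True) -> CameraImagePair:
    """Render a raw VIS+UV image pair for a set of surface regions.

    Each region's linear signal per camera channel is the channel's quantum
    catch of its spectrum relative to a perfect reflector; the sensor applies
    raw = 255 * linear**(1/gamma) + noise, clipped to [0, 255].  Flat-spectrum
    grey standards (which must include 0.40) are embedded along the bottom
    row of the frame.
    """
    if camera_gamma <= 0:
        raise ValueError("camera_gamma must be > 0")
    if not spectra_by_region:
        raise ValueError("region map must not be empty")
    if not any(abs(g - 0.40) < 1e-9 for g in grey_standards):
        raise ValueError("grey standards must include the 0.40 standard")
    rng = np.random.default_rng(seed)

    regions = list(spectra_by_region)
    wl = spectra_by_region[regions[0]].wavelengths
    cam = camera_sensitivities(wl)
    names, W = catch_matrix({c: cam[c] for c in CAMERA_CHANNELS}, wl)
    refl = np.stack([spectra_by_region[r].reflectance for r in regions])
    linear = refl @ W.T  # (n_regions, 4) in CAMERA_CHANNELS order

    ncols = max(len(regions), len(grey_standards))
    height = 2 * patch_px + 2
    width = ncols * patch_px + 2
    lin_img = np.zeros((height, width, 4))

    region_polys: dict[str, np.ndarray] = {}
    for i, r in enumerate(regions):
        r0, c0 = 1, 1 + i * patch_px
        lin_img[r0:r0 + patch_px, c0:c0 + patch_px] = linear[i]
        region_polys[r] = _rect(r0, c0, r0 + patch_px, c0 + patch_px)

    std_polys: dict[float, np.ndarray] = {}
    for i, g in enumerate(grey_standards):
        r0, c0 = 1 + patch_px, 1 + i * patch_px
        lin_img[r0:r0 + patch_px, c0:c0 + patch_px] = g
        std_polys[float(g)] = _rect(r0, c0, r0 + patch_px, c0 + patch_px)

    raw = 255.0 * np.power(lin_img, 1.0 / camera_gamma, where=lin_img > 0,
                           out=np.zeros_like(lin_img))
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, raw.shape)
    raw = np.clip(raw, 0.0, 255.0)
    if quantise:
        raw = np.rint(raw).astype(np.uint8)
    # VIS stores (camLW, camMW, camSW); UV stores camUV
    vis = np.stack([raw[..., 3], raw[..., 2], raw[..., 1]], axis=-1)
    uv = raw[..., 0]
    return CameraImagePair(vis, uv, region_polys, std_polys, camera_gamma)


# ---------------------------------------------------------------------------
# bioassay simulation


def mortality_probability(dose: float, time: float, true_toxicity: float,
                          slope: float = 2.0,
                          background_rate: float = DEFAULT_BACKGROUND_MORTALITY,
                          reference_dose: float = 0.5,
                          potency: float = 0.1) -> float:
    """Per-animal death probability by ``time`` hours at extract ``dose``.

    A constant per-hour kill hazard, logistic in log-dose and proportional to
    the specimen's true toxicity, on top of a background mortality rate:
    monotone non-decreasing in both dose and time.
    """
    if not 0 <= dose <= 1:
        raise ValueError("dilution must lie within [0, 1]")
    dose_effect = 0.0 if dose == 0 else expit(
        slope * (np.log(dose) - np.log(reference_dose)))
    rate = background_rate + potency * true_toxicity * dose_effect
    return float(1.0 - np.exp(-rate * time))


def simulate_bioassay(true_toxicity: float,
                      dilutions: tuple[float, ...] = DEFAULT_DILUTIONS,
                      n_daphnia: int = 10,
                      slope: float = 2.0,
                      times: tuple[float, ...] = DEFAULT_ASSAY_TIMES,
                      seed: int | np.random.Generator = 0,
                      specimen_id: str = "S0",
                      background_rate: float = DEFAULT_BACKGROUND_MORTALITY
                      ) -> list[BioassayRecord]:
    """Binomial dead counts per dilution per check time for one extract.

    Counts are cumulative within a vial, so they never decrease over time.
    """
    if true_toxicity < 0:
        raise ValueError("true_toxicity must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for dose in dilutions:
        if not 0 <= dose <= 1:
            raise ValueError("dilution must lie within [0, 1]")
        dead = 0
        p_prev = 0.0
        for t in sorted(times):
            p_now = mortality_probability(dose, t, true_toxicity, slope,
                                          background_rate)
            # conditional probability a survivor dies in (t_prev, t]
            p_inc = 0.0 if p_prev >= 1 else (p_now - p_prev) / (1 - p_prev)
            dead += rng.binomial(n_daphnia - dead, np.clip(p_inc, 0.0, 1.0))
            p_prev = p_now
            records.append(BioassayRecord(specimen_id, dose, t, int(dead),
                                          n_daphnia))
    return records


# ---------------------------------------------------------------------------
# field predation simulation

CENSOR_REASONS = ("rodent", "degraded", "slime")


def simulate_field_predation(models: list[tuple[str, float]],
                             hazard_coefficient: float = 0.0,
                             baseline_hazard: float = 0.02,
                             check_interval: float = 4.0,
                             admin_censor_time: float = 48.0,
                             censor_fraction: float = 0.0,
                             seed: int | np.random.Generator = 0,
                             n_blocks: int = 15) -> list[PredationRecord]:
    """Interval-checked attack times for artificial models in the field.

    Each model's attack time is exponential with log-hazard
    ``log(baseline_hazard) - hazard_coefficient * jnd`` and is rounded UP to
    the next check; models surviving past ``admin_censor_time`` are
    right-censored.  A ``censor_fraction`` of records is withdrawn early at a
    random check time (rodent damage / degradation / slug slime).
    """
    if baseline_hazard < 0:
        raise ValueError("baseline_hazard must be >= 0")
    if check_interval <= 0 or admin_censor_time <= 0:
        raise ValueError("check grid must be positive")
    n_checks = admin_censor_time / check_interval
    if abs(n_checks - round(n_checks)) > 1e-9:
        raise ValueError("check_interval must divide admin_censor_time")
    rng = np.random.default_rng(seed)
    records = []
    for i, (label, jnd) in enumerate(models):
        block = f"T{(i % n_blocks) + 1:02d}"
        model_id = f"M{i:04d}"
        if baseline_hazard == 0:
            records.append(PredationRecord(model_id, label, block,
                                           admin_censor_time, False,
                                           "administrative"))
            continue
        rate = baseline_hazard * np.exp(-hazard_coefficient * jnd)
        t_attack = rng.exponential(1.0 / rate)
        t_grid = np.ceil(t_attack / check_interval) * check_interval
        if rng.random() < censor_fraction:
            last = min(t_grid, admin_censor_time)
            k = rng.integers(1, int(round(last / check_interval)) + 1)
            records.append(PredationRecord(
                model_id, label, block, k * check_interval, False,
                str(rng.choice(CENSOR_REASONS))))
        elif t_grid > admin_censor_time:
            records.append(PredationRecord(model_id, label, block,
                                           admin_censor_time, False,
                                           "administrative"))
        else:
            records.append(PredationRecord(model_id, label, block,
                                           float(t_grid), True))
    return records


# ---------------------------------------------------------------------------
# a full synthetic world (specimens with spectra, covariates and bioassays)


@dataclass
class SyntheticWorld:
    """Ground-truth dataset for one simulated study."""

    config: SyntheticWorldConfig
    specimens: "object"  # pandas DataFrame: id, species, size, weight, ...
    elytra_spectra: dict[str, ReflectanceSpectrum]
    spot_spectra: dict[str, ReflectanceSpectrum]
    background_spectra: dict[str, list[ReflectanceSpectrum]]
    bioassay: list[BioassayRecord] = field(default_factory=list)


def generate_world(config: SyntheticWorldConfig,
                   n_per_species: int = 36,
                   n_leaves: int = 10,
                   wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
                   toxicity_noise_sd: float = 0.3) -> SyntheticWorld:
    """Simulate specimens for every archetype, with honesty built in.

    Each specimen's true toxicity is its species baseline plus
    ``honesty_slope`` times its own chromatic contrast against its species'
    background (centred on the grand mean contrast across all specimens),
    plus noise — so the generated toxicity~contrast association has a known
    slope both within and between species.
    """
    import pandas as pd

    from .discriminability import chromatic_jnd
    from .cone_mapping import spectrum_cone_catch
    from .types import ReceptorNoise

    if not config.species_archetypes:
        raise ValueError("config must declare at least one species archetype")
    rng = np.random.default_rng(config.seed)
    base = archetype_base_spectra(wavelengths)
    sens = viewer_sensitivities(wavelengths)
    noise = ReceptorNoise()

    rows = []
    elytra_spectra: dict[str, ReflectanceSpectrum] = {}
    spot_spectra: dict[str, ReflectanceSpectrum] = {}
    background_spectra: dict[str, list[ReflectanceSpectrum]] = {}
    bioassay: list[BioassayRecord] = []

    for arch in config.species_archetypes:
        parts = base[arch.name]
        leaves = [jitter_spectrum(parts["background"], rng, wavelengths,
                                  level_sd=0.08, wiggle_sd=0.02)
                  for _ in range(n_leaves)]
        background_spectra[arch.name] = leaves
        bg_catches = [spectrum_cone_catch(s, sens) for s in leaves]
        mean_bg = ConeCatch.from_array(
            np.mean([c.singles() for c in bg_catches], axis=0),
            float(np.mean([c.q_DBL for c in bg_catches])))

        for k in range(n_per_species):
            sid = f"{arch.name}-{k:03d}"
            ely = jitter_spectrum(parts["elytra"], rng, wavelengths)
            spot = jitter_spectrum(parts["spot"], rng, wavelengths,
                                   level_sd=0.10)
            elytra_spectra[sid] = ely
            spot_spectra[sid] = spot
            catch = spectrum_cone_catch(ely, sens)
            jnd = chromatic_jnd(catch, mean_bg, noise)
            size = rng.normal(5.0, 0.6)  # mm
            weight = rng.normal(0.035, 0.006)  # g
            rows.append({"specimen_id": sid, "species": arch.name,
                         "base_toxicity": arch.true_toxicity,
                         "size_mm": size, "weight_g": max(weight, 0.005),
                         "true_jnd": jnd})

    # second pass: toxicity responds to contrast relative to the grand mean,
    # so the slope acts both within and between species
    grand_mean_jnd = float(np.mean([r["true_jnd"] for r in rows]))
    for r in rows:
        r["true_toxicity"] = max(
            0.0, r.pop("base_toxicity")
            + config.honesty_slope * (r["true_jnd"] - grand_mean_jnd)
            + rng.normal(0.0, toxicity_noise_sd))
        bioassay.extend(simulate_bioassay(
            r["true_toxicity"], seed=rng, specimen_id=r["specimen_id"],
            background_rate=config.background_mortality))

    specimens = pd.DataFrame(rows)
    return SyntheticWorld(config, specimens, elytra_spectra, spot_spectra,
                          background_spectra, bioassay)
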