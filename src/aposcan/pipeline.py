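"""End-to-end glue: synthetic world -> images -> calibration -> cone mapping
-> colour metrics -> JNDs -> toxicity summaries -> specimen table.

This is the replayable path used by the recovery tests: every stage consumes
only the artefacts a real study would have (raw images, grey standards,
bioassay counts), never the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    fit_linearisation,
    linearise_and_normalise,
    measure_region,
    measure_standards,
)
from .colour_metrics import luminance, pattern_area, saturation, to_tetrahedral
from .cone_mapping import (
    MappingModel,
    camera_sensitivities,
    catch_matrix,
    fit_polynomial_mapping,
    predicted_cone_catch,
    viewer_sensitivities,
)
from .discriminability import background_contrast, internal_contrast
from .honesty import HonestyFit, fit_honesty_model
from .spectral import CAMERA_CHANNELS, DEFAULT_WAVELENGTHS
from .synthetic import SyntheticWorld, generate_reflectance_library, simulate_camera_image
from .toxicity import summarise_toxicity
from .types import ConeCatch, ReceptorNoise, ReflectanceSpectrum

VIEWER_RECEPTORS = ("UV", "SW", "MW", "LW", "DBL")


def train_mapping(n_spectra: int = 200, degree: int = 2,
                  seed: int = 0, smoothness: float = 80.0,
                  wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
                  ) -> MappingModel:
    """Fit the camera->cone polynomial on a synthetic spectral library."""
    library = generate_reflectance_library(n_spectra, smoothness, seed,
                                           wavelengths)
    refl = np.stack([s.reflectance for s in library])
    cam = camera_sensitivities(wavelengths)
    _, Wc = catch_matrix({c: cam[c] for c in CAMERA_CHANNELS}, wavelengths)
    view = viewer_sensitivities(wavelengths)
    _, Wv = catch_matrix({r: view[r] for r in VIEWER_RECEPTORS}, wavelengths)
    return fit_polynomial_mapping(refl @ Wc.T, refl @ Wv.T,
                                  CAMERA_CHANNELS, VIEWER_RECEPTORS,
                                  degree=degree)


def image_route_catches(spectra_by_region: dict[str, ReflectanceSpectrum],
                        mapping: MappingModel,
                        camera_gamma: float = 2.2,
                        noise_sd: float = 0.0,
                        seed: int | np.random.Generator = 0
                        ) -> dict[str, ConeCatch]:
    """Photograph regions, calibrate the frame, and map to cone catches."""
    img = simulate_camera_image(spectra_by_region, camera_gamma,
                                noise_sd=noise_sd, seed=seed)
    stack = img.channel_stack()
    standards = measure_standards(stack, img.standard_polygons)
    lin_model = fit_linearisation(standards)
    refl_img = linearise_and_normalise(stack, lin_model,
                                       img.standard_polygons[0.40])
    out = {}
    for region, poly in img.region_polygons.items():
        meas = measure_region(refl_img, poly, region)
        out[region] = predicted_cone_catch(mapping, meas.mean)
    return out


@dataclass
class PipelineResult:
    specimen_table: pd.DataFrame
    honesty: HonestyFit
    mapping: MappingModel


def build_specimen_table(world: SyntheticWorld,
                         mapping: MappingModel | None = None,
                         noise: ReceptorNoise | None = None,
                         image_noise_sd: float = 1.0,
                         patch_px: int = 12) -> pd.DataFrame:
    """Measure every specimen through the full image route.

    Leaves of each species' background plant are photographed in one frame
    per species; each specimen's elytra and spot share a frame.  The pattern
    area is taken from the elytra polygon with a per-photo pixel scale set
    by the specimen's body length.
    """
    noise = noise or ReceptorNoise()
    mapping = mapping or train_mapping(seed=world.config.seed)
    gamma = world.config.camera_gamma
    rng = np.random.default_rng(world.config.seed + 1)

    bg_catches: dict[str, list[ConeCatch]] = {}
    for species, leaves in world.background_spectra.items():
        regions = {f"leaf{i}": s for i, s in enumerate(leaves)}
        catches = image_route_catches(regions, mapping, gamma,
                                      image_noise_sd, rng)
        bg_catches[species] = [catches[f"leaf{i}"] for i in range(len(leaves))]

    tox_by_specimen: dict[str, list] = {}
    for rec in world.bioassay:
        tox_by_specimen.setdefault(rec.specimen_id, []).append(rec)

    rows = []
    for row in world.specimens.itertuples():
        sid = row.specimen_id
        catches = image_route_catches(
            {"elytra": world.elytra_spectra[sid],
             "spot": world.spot_spectra[sid]},
            mapping, gamma, image_noise_sd, rng)
        ely, spot = catches["elytra"], catches["spot"]
        mean_bg, _ = background_contrast(ely, bg_catches[row.species], noise,
                                         sid, row.species)
        # elytra patch rendered at patch_px; px-per-cm follows body length
        poly = np.array([[0, 0], [0, patch_px], [patch_px, patch_px],
                         [patch_px, 0]], dtype=float)
        scale = patch_px / (row.size_mm / 10.0)
        summary = summarise_toxicity(tox_by_specimen[sid])
        rows.append({
            "specimen_id": sid,
            "species": row.species,
            "size_mm": row.size_mm,
            "weight_g": row.weight_g,
            "luminance": luminance(ely),
            "saturation": saturation(to_tetrahedral(ely)),
            "area_cm2": pattern_area(poly, scale),
            "bg_chromatic_jnd": mean_bg.chromatic_jnd,
            "bg_achromatic_jnd": mean_bg.achromatic_jnd,
            "internal_dl": internal_contrast(ely, spot, noise),
            "log_toxicity": summary.log_toxicity,
        })
    return pd.DataFrame(rows)


def run_pipeline(world: SyntheticWorld,
                 mapping: MappingModel | None = None,
                 image_noise_sd: float = 1.0,
                 select: bool = False) -> PipelineResult:
    """World -> specimen table -> honesty model, entirely via the image route."""
    mapping = mapping or train_mapping(seed=world.config.seed)
    table = build_specimen_table(world, mapping, image_noise_sd=image_noise_sd)
    fit = fit_honesty_model(table, select=select)
    return PipelineResult(table, fit, mapping)
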