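"""Headline analysis: does conspicuousness predict toxicity, and does it
predict survival in the field?

The toxicity model is a plain linear model with the study's fixed-effect
structure (species, size, weight, luminance, saturation, pattern area,
background contrasts, plus species x contrast and saturation x contrast
interactions), simplified backwards by AIC.  All continuous predictors are
z-scored for comparability of coefficients.  Tests are two-sided.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .survival import CoxFit, fit_cox
from .types import PredationRecord

#: continuous predictors of the specimen table, in reporting order
CONTINUOUS_PREDICTORS = ("size_mm", "weight_g", "luminance", "saturation",
                         "area_cm2", "bg_chromatic_jnd", "bg_achromatic_jnd",
                         "internal_dl")

REQUIRED_COLUMNS = ("specimen_id", "species", "log_toxicity") \
    + CONTINUOUS_PREDICTORS


def validate_specimen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check structure and report (never silently drop) missing values."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"specimen table missing columns: {missing_cols}")
    if table["specimen_id"].duplicated().any():
        dupes = table.loc[table["specimen_id"].duplicated(), "specimen_id"]
        raise ValueError(f"duplicate specimen ids: {sorted(set(dupes))[:5]}")
    na_counts = table[list(REQUIRED_COLUMNS)].isna().sum()
    na_counts = na_counts[na_counts > 0]
    if len(na_counts):
        warnings.warn(f"specimen table has missing values: "
                      f"{na_counts.to_dict()}; affected rows are excluded "
                      "from model fits", stacklevel=2)
    return table


def _standardise(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in CONTINUOUS_PREDICTORS:
        sd = out[col].std(ddof=0)
        if not np.isfinite(sd) or sd < 1e-12:
            warnings.warn(f"predictor {col!r} has (near-)zero variance; "
                          "left unscaled", stacklevel=2)
            out[col] = out[col] - out[col].mean()
        else:
            out[col] = (out[col] - out[col].mean()) / sd
    return out


FULL_TERMS = ["C(species, Sum)", "size_mm", "weight_g", "luminance", "saturation",
              "area_cm2", "bg_chromatic_jnd", "bg_achromatic_jnd",
              "internal_dl", "C(species, Sum):bg_chromatic_jnd",
              "saturation:bg_chromatic_jnd"]


def _formula(terms: list[str]) -> str:
    return "log_toxicity ~ " + " + ".join(terms) if terms \
        else "log_toxicity ~ 1"


def _hierarchy_ok(term: str, terms: list[str]) -> bool:
    """A main effect may only be dropped if no retained interaction uses it."""
    if ":" in term:
        return True
    return not any(":" in t and term in t.split(":") for t in terms)


@dataclass
class HonestyFit:
    full_model: "sm.regression.linear_model.RegressionResultsWrapper"
    selected_model: "sm.regression.linear_model.RegressionResultsWrapper"
    retained_terms: list[str]
    dropped_terms: list[str]
    contrast_slope: float
    contrast_p: float
    n: int
    config_hash: str = ""

    def coefficients(self) -> pd.DataFrame:
        res = self.selected_model
        return pd.DataFrame({"coef": res.params, "se": res.bse,
                             "t": res.tvalues, "p": res.pvalues})


def fit_honesty_model(table: pd.DataFrame,
                      terms: list[str] | None = None,
                      select: bool = True) -> HonestyFit:
    """Linear model of log toxicity on the signal attributes.

    The full model is always fitted and reported; when ``select`` is true the
    model is additionally simplified by backward AIC steps that respect
    marginality (interactions drop before their main effects).  The
    ``contrast_slope`` / ``contrast_p`` fields carry the full-model
    background chromatic contrast coefficient — the headline honesty term.
    """
    table = validate_specimen_table(table)
    if table["species"].nunique() < 2:
        raise ValueError("need >= 2 species")
    data = _standardise(table).dropna(subset=list(REQUIRED_COLUMNS))
    terms = list(FULL_TERMS if terms is None else terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.ols(_formula(terms), data=data).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        aliased = [n for n, b in zip(full.model.exog_names,
                                     np.isnan(full.params) | (full.bse > 1e6))
                   if b]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    current = list(terms)
    model = full
    dropped: list[str] = []
    while select and current:
        candidates = [t for t in current if _hierarchy_ok(t, current)]
        best_aic, best_term, best_model = model.aic, None, None
        for t in candidates:
            trial = [u for u in current if u != t]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = smf.ols(_formula(trial), data=data).fit()
            if m.aic < best_aic - 1e-9:
                best_aic, best_term, best_model = m.aic, t, m
        if best_term is None:
            break
        current.remove(best_term)
        dropped.append(best_term)
        model = best_model

    slope = float(full.params.get("bg_chromatic_jnd", np.nan))
    p = float(full.pvalues.get("bg_chromatic_jnd", np.nan))
    return HonestyFit(full, model, current, dropped, slope, p, int(len(data)))


@dataclass
class WithinSpeciesResult:
    per_species: pd.DataFrame
    pooled_slope: float
    pooled_se: float
    pooled_p: float
    excluded_species: list[str] = field(default_factory=list)


def within_species_saturation_test(table: pd.DataFrame,
                                   min_per_species: int = 5
                                   ) -> WithinSpeciesResult:
    """Within-species association between saturation and toxicity.

    Both variables are centred within species (removing all between-species
    differences); species-centred saturation is regressed on species-centred
    log toxicity, pooled across species and per species.
    """
    table = validate_specimen_table(table)
    counts = table.groupby("species").size()
    excluded = sorted(counts[counts < min_per_species].index)
    if excluded:
        warnings.warn(f"species excluded (<{min_per_species} specimens): "
                      f"{excluded}", stacklevel=2)
    data = table[~table["species"].isin(excluded)].copy()
    if data.empty:
        raise ValueError("no species with enough specimens")
    for col in ("saturation", "log_toxicity"):
        data[f"c_{col}"] = data[col] - data.groupby("species")[col].transform("mean")
    rows = []
    for sp, grp in data.groupby("species"):
        res = stats.linregress(grp["c_log_toxicity"], grp["c_saturation"])
        rows.append({"species": sp, "slope": res.slope, "p": res.pvalue,
                     "n": len(grp)})
    pooled = sm.OLS(data["c_saturation"],
                    sm.add_constant(data["c_log_toxicity"])).fit()
    return WithinSpeciesResult(pd.DataFrame(rows),
                               float(pooled.params.iloc[1]),
                               float(pooled.bse.iloc[1]),
                               float(pooled.pvalues.iloc[1]), excluded)


@dataclass
class RobustnessReport:
    per_exclusion: pd.DataFrame
    stable_sign: bool
    reference_slope: float


def leave_one_species_out(table: pd.DataFrame) -> RobustnessReport:
    """Re-fit the honesty model dropping each species in turn.

    Flags the association unstable when the contrast slope's sign flips (or
    its significance at 0.05 vanishes) under some exclusion.
    """
    table = validate_specimen_table(table)
    species = sorted(table["species"].unique())
    if len(species) < 3:
        raise ValueError("need >= 3 species for leave-one-out robustness")
    ref = fit_honesty_model(table, select=False)
    rows = []
    for sp in species:
        sub = table[table["species"] != sp]
        fit = fit_honesty_model(sub, select=False)
        rows.append({"excluded": sp, "contrast_slope": fit.contrast_slope,
                     "contrast_p": fit.contrast_p,
                     "same_sign": np.sign(fit.contrast_slope)
                     == np.sign(ref.contrast_slope),
                     "significant": fit.contrast_p < 0.05})
    df = pd.DataFrame(rows)
    return RobustnessReport(df, bool(df["same_sign"].all()),
                            ref.contrast_slope)


@dataclass
class ConspicuousnessReport:
    logistic_slope: float
    logistic_se: float
    logistic_p: float
    direction: str
    cox_fit: CoxFit | None
    cox_jnd_coef: float | None
    cox_jnd_p: float | None
    n_models: int


def survival_vs_conspicuousness(records: list[PredationRecord],
                                jnd_by_model: dict[str, float],
                                block_adjust: bool = True,
                                cox_crosscheck: bool = True
                                ) -> ConspicuousnessReport:
    """Relate attack within the observation window to measured contrast.

    Primary route: logistic regression of the attack indicator on JND (with
    block fixed effects when ``block_adjust``); cross-check: the Cox fit
    with JND as covariate, stratified on block.
    """
    unmatched = [r.model_id for r in records if r.model_id not in jnd_by_model]
    if unmatched:
        raise ValueError(f"models without JND measurements: {unmatched[:5]}")
    jnd = np.array([jnd_by_model[r.model_id] for r in records])
    if np.ptp(jnd) < 1e-12:
        warnings.warn("JND is constant across models; association undefined",
                      stacklevel=2)
        return ConspicuousnessReport(np.nan, np.nan, np.nan, "undefined",
                                     None, None, None, len(records))
    y = np.array([1.0 if r.event else 0.0 for r in records])
    cols = {"jnd": jnd}
    if block_adjust:
        blocks = pd.get_dummies([r.block for r in records], drop_first=True,
                                dtype=float)
        for c in blocks.columns:
            cols[f"block_{c}"] = blocks[c].to_numpy()
    X = sm.add_constant(pd.DataFrame(cols))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    slope = float(res.params["jnd"])
    se = float(res.bse["jnd"])
    p = float(res.pvalues["jnd"])
    direction = "none" if p >= 0.05 else ("negative" if slope < 0 else "positive")

    cox, cox_coef, cox_p = None, None, None
    if cox_crosscheck:
        try:
            usable = [r for r in records
                      if r.censor_reason in ("none", "administrative")]
            X_j = np.array([[jnd_by_model[r.model_id]] for r in usable])
            from .survival import cox_fit_matrix
            cox = cox_fit_matrix(X_j,
                                 np.array([r.time for r in usable]),
                                 np.array([r.event for r in usable]),
                                 np.array([r.block for r in usable]),
                                 names=["jnd"])
            cox_coef = float(cox.coef[0])
            cox_p = float(cox.p[0])
        except Exception as exc:
            warnings.warn(f"Cox cross-check failed: {exc}", stacklevel=2)
    return ConspicuousnessReport(slope, se, p, direction, cox, cox_coef,
                                 cox_p, len(records))


def config_hash(config: object) -> str:
    """Stable short hash of a configuration object for replayable reports."""
    payload = json.dumps(config, default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
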