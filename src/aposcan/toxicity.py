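"""Bioassay summaries: 3 h mean mortality (log-transformed) and LC50.

The headline toxicity response is ln(mean dead at 3 h + 1); the +1 keeps
zero-mortality specimens finite and is documented as this artifact's
zero-handling convention.  LC50 is estimated by a maximum-likelihood
logistic (optionally probit) fit of mortality on log-dose; it is reported
alongside but not consumed by the honesty stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import BioassayRecord

SUMMARY_TIME_H = 3.0


@dataclass(frozen=True)
class ToxicitySummary:
    specimen_id: str
    mean_dead_3h: float
    log_toxicity: float
    lc50: float | None = None
    lc50_ci: tuple[float, float] | None = None


def summarise_toxicity(records: list[BioassayRecord],
                       time_h: float = SUMMARY_TIME_H) -> ToxicitySummary:
    """Mean dead count across dilutions at 3 h, log(x + 1) transformed."""
    recs = [r for r in records if np.isclose(r.time, time_h)]
    if not recs:
        raise ValueError(f"no records at t = {time_h} h")
    sids = {r.specimen_id for r in recs}
    if len(sids) != 1:
        raise ValueError(f"records span multiple specimens: {sorted(sids)}")
    mean_dead = float(np.mean([r.dead for r in recs]))
    return ToxicitySummary(recs[0].specimen_id, mean_dead,
                           float(np.log1p(mean_dead)))


@dataclass(frozen=True)
class LC50Estimate:
    lc50: float | None
    ci: tuple[float, float] | None
    slope: float | None
    defined: bool
    reason: str = ""


def estimate_lc50(doses: np.ndarray, dead: np.ndarray, n: np.ndarray,
                  link: str = "logit") -> LC50Estimate:
    """ML dose-response fit; LC50 is the dose where mortality crosses 0.5.

    Fits mortality on log-dose with a binomial GLM (zero doses are controls
    and excluded from the regression).  Degenerate patterns (all dead / none
    dead / fewer than 3 positive doses) are flagged undefined rather than
    extrapolated.  CI by the delta method on log-LC50.
    """
    doses = np.asarray(doses, dtype=float)
    dead = np.asarray(dead, dtype=float)
    n = np.asarray(n, dtype=float)
    pos = doses > 0
    if np.unique(doses[pos]).size < 3:
        raise ValueError("need >= 3 distinct positive doses")
    d, k, m = doses[pos], dead[pos], n[pos]
    if k.sum() == 0:
        return LC50Estimate(None, None, None, False, "no mortality observed")
    if np.all(k == m):
        return LC50Estimate(None, None, None, False, "complete mortality at "
                            "all doses")
    fam_link = sm.families.links.Logit() if link == "logit" \
        else sm.families.links.Probit()
    X = sm.add_constant(np.log(d))
    model = sm.GLM(np.column_stack([k, m - k]), X,
                   family=sm.families.Binomial(link=fam_link))
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover - defensive
        return LC50Estimate(None, None, None, False, f"fit failed: {exc}")
    b0, b1 = res.params
    if b1 <= 0:
        return LC50Estimate(None, None, None, False,
                            "non-increasing dose response")
    log_lc50 = -b0 / b1
    cov = res.cov_params()
    # delta method for g = -b0/b1
    grad = np.array([-1.0 / b1, b0 / b1**2])
    se = float(np.sqrt(grad @ cov @ grad))
    z = stats.norm.ppf(0.975)
    lo, hi = np.exp(log_lc50 - z * se), np.exp(log_lc50 + z * se)
    return LC50Estimate(float(np.exp(log_lc50)), (float(lo), float(hi)),
                        float(b1), True)


def lc50_from_records(records: list[BioassayRecord],
                      time_h: float = SUMMARY_TIME_H,
                      link: str = "logit") -> LC50Estimate:
    recs = [r for r in records if np.isclose(r.time, time_h)]
    if not recs:
        raise ValueError(f"no records at t = {time_h} h")
    return estimate_lc50(np.array([r.dilution for r in recs]),
                         np.array([r.dead for r in recs]),
                         np.array([r.n for r in recs]), link=link)


def compare_controls(water: list[BioassayRecord],
                     methanol: list[BioassayRecord],
                     extract: list[BioassayRecord],
                     time_h: float = SUMMARY_TIME_H) -> pd.DataFrame:
    """Rank water / methanol-blank / extract mortality with pairwise tests.

    Returns one row per group (mean mortality fraction, totals, rank) plus
    two-sample proportion-test p-values against each other group; groups
    whose mortality does not differ are given tied ranks.
    """
    groups = {"water": water, "methanol": methanol, "extract": extract}
    for name, recs in groups.items():
        if not recs:
            raise ValueError(f"missing control group: {name}")
    summary = {}
    for name, recs in groups.items():
        recs_t = [r for r in recs if np.isclose(r.time, time_h)]
        if not recs_t:
            raise ValueError(f"group {name!r} has no records at t = {time_h}")
        dead = sum(r.dead for r in recs_t)
        total = sum(r.n for r in recs_t)
        summary[name] = (dead, total, dead / total)
    rows = []
    names = list(groups)
    for name in names:
        dead, total, frac = summary[name]
        pvals = {}
        for other in names:
            if other == name:
                continue
            d2, t2, _ = summary[other]
            table = np.array([[dead, total - dead], [d2, t2 - d2]])
            pvals[f"p_vs_{other}"] = float(
                stats.fisher_exact(table)[1]) if table.min() < 5 else float(
                stats.chi2_contingency(table)[1])
        rows.append({"group": name, "dead": dead, "total": total,
                     "mortality": frac, **pvals})
    out = pd.DataFrame(rows).sort_values("mortality").reset_index(drop=True)
    # only claim an ordering between groups that actually differ
    out["rank"] = out["mortality"].rank(method="min")
    return out
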