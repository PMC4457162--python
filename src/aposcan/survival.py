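"""Survival analysis for field predation: Kaplan-Meier product-limit
estimation, stratified Cox proportional hazards (Breslow ties), pairwise
group contrasts and the overall attack rate.

Both estimators are implemented from first principles here; the test suite
cross-checks them against an independent library implementation.  Block
(transect) heterogeneity is handled by stratification rather than a random
effect — a deliberate, documented stand-in targeting the same confounder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import PredationRecord


def _to_time_event(records) -> tuple[np.ndarray, np.ndarray]:
    times, events = [], []
    for r in records:
        if isinstance(r, PredationRecord):
            times.append(r.time)
            events.append(r.event)
        else:
            t, e = r
            times.append(float(t))
            events.append(bool(e))
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t <= 0):
        raise ValueError("observation times must be positive")
    return t, np.asarray(events, dtype=bool)


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with Greenwood variance.

    Censoring at an event time keeps the censored subject at risk through
    that event (standard convention).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray  # Greenwood variance of S(t) at each event time

    def at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(records) -> SurvivalCurve:
    """Kaplan-Meier estimator over (time, event) pairs or PredationRecords."""
    t, e = _to_time_event(records)
    event_times = np.unique(t[e])
    surv, var_terms = [], []
    s = 1.0
    greenwood = 0.0
    at_risk, n_ev = [], []
    for ti in event_times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & e))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            greenwood += d_i / (n_i * (n_i - d_i))
        at_risk.append(n_i)
        n_ev.append(d_i)
        surv.append(s)
        var_terms.append(s**2 * greenwood)
    return SurvivalCurve(event_times, np.asarray(surv), np.asarray(at_risk),
                         np.asarray(n_ev), np.asarray(var_terms))


# ---------------------------------------------------------------------------
# Cox proportional hazards, Breslow tie handling, optional strata


class SeparationError(RuntimeError):
    """Monotone partial likelihood: a covariate perfectly orders events."""


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    reference_level: str | None = None
    strata: str | None = None
    levels: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def hazard_ratios(self) -> dict[str, float]:
        return {n: float(np.exp(c)) for n, c in zip(self.names, self.coef)}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se, "z": self.z,
                             "p": self.p,
                             "hr": np.exp(self.coef)}, index=self.names)


def _breslow_loglik(beta: np.ndarray, X: np.ndarray, t: np.ndarray,
                    e: np.ndarray, strata: np.ndarray
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    eta = X @ beta
    w = np.exp(eta)
    for s in np.unique(strata):
        in_s = strata == s
        ts, es, Xs, ws = t[in_s], e[in_s], X[in_s], w[in_s]
        for ti in np.unique(ts[es]):
            at_risk = ts >= ti
            d_mask = (ts == ti) & es
            d = int(d_mask.sum())
            s_vec = Xs[d_mask].sum(axis=0)
            wr = ws[at_risk]
            Xr = Xs[at_risk]
            w_sum = wr.sum()
            m = (wr @ Xr) / w_sum
            ll += float(s_vec @ beta - d * np.log(w_sum))
            grad += s_vec - d * m
            v = (Xr * wr[:, None]).T @ Xr / w_sum - np.outer(m, m)
            hess -= d * v
    return ll, grad, hess


def cox_fit_matrix(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                   strata: np.ndarray | None = None,
                   names: list[str] | None = None,
                   max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximisation of the Breslow partial likelihood."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    strata = np.zeros(t.size) if strata is None else np.asarray(strata)
    if e.sum() == 0:
        raise ValueError("no events: Cox model is not identifiable")
    beta = np.zeros(X.shape[1])
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik(beta, X, t, e, strata)
        if np.linalg.norm(beta) > 30:
            raise SeparationError(
                "coefficients diverging; a covariate separates events from "
                "non-events (monotone partial likelihood)")
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta_new = beta - step
        # step-halving for stability
        ll_new, _, _ = _breslow_loglik(beta_new, X, t, e, strata)
        halvings = 0
        while ll_new < ll and halvings < 10:
            step /= 2.0
            beta_new = beta - step
            ll_new, _, _ = _breslow_loglik(beta_new, X, t, e, strata)
            halvings += 1
        beta = beta_new
        if abs(ll_new - ll_prev) < tol:
            ll_prev = ll_new
            break
        ll_prev = ll_new
    ll, grad, hess = _breslow_loglik(beta, X, t, e, strata)
    info = -hess
    eigs = np.linalg.eigvalsh(info)
    if eigs.min() < 1e-6:
        raise SeparationError(
            "information matrix (near-)singular at the optimum; a covariate "
            "separates events from non-events (monotone partial likelihood)")
    cov = np.linalg.inv(info)
    return CoxFit(names or [f"x{i}" for i in range(X.shape[1])], beta, cov,
                  float(ll), int(t.size), int(e.sum()))


def fit_cox(records: list[PredationRecord],
            jnd_by_model: dict[str, float] | None = None,
            stratify_by_block: bool = True,
            include_ambiguous_censored: bool = False) -> CoxFit:
    """Cox PH fit of attack hazard on colour (and optional per-model JND).

    Colour enters as indicator contrasts against the alphabetically first
    level; the block (transect) is a stratum.  Records censored for
    ambiguous, non-predator reasons (rodent / degraded / slime) are excluded
    by default, mirroring the field protocol's main analysis; pass
    ``include_ambiguous_censored=True`` to keep them as censored.
    """
    recs = [r for r in records
            if include_ambiguous_censored
            or r.censor_reason in ("none", "administrative")]
    if not recs:
        raise ValueError("no usable records")
    levels = sorted({r.colour_label for r in recs})
    ref = levels[0]
    for lvl in levels:
        if not any(r.event for r in recs if r.colour_label == lvl):
            raise ValueError(f"colour level {lvl!r} has no events; "
                             "coefficients would not be identifiable")
    names = [f"colour[{lvl}]" for lvl in levels[1:]]
    cols = [np.array([1.0 if r.colour_label == lvl else 0.0 for r in recs])
            for lvl in levels[1:]]
    if jnd_by_model is not None:
        missing = [r.model_id for r in recs if r.model_id not in jnd_by_model]
        if missing:
            raise ValueError(f"models without JND measurements: {missing[:5]}")
        cols.append(np.array([jnd_by_model[r.model_id] for r in recs]))
        names.append("jnd")
    X = np.column_stack(cols) if cols else np.zeros((len(recs), 0))
    t = np.array([r.time for r in recs])
    e = np.array([r.event for r in recs])
    strata = np.array([r.block for r in recs]) if stratify_by_block else None
    fit = cox_fit_matrix(X, t, e, strata, names)
    fit.reference_level = ref
    fit.strata = "block" if stratify_by_block else None
    fit.levels = levels
    return fit


def pairwise_survival(fit: CoxFit,
                      pairs: list[tuple[str, str]] | None = None
                      ) -> pd.DataFrame:
    """Pairwise colour contrasts from the fitted coefficients.

    Contrast(a, b) is the log hazard-ratio of a relative to b; p-values are
    unadjusted Wald tests (pass the table through a multiplicity correction
    yourself if required).
    """
    if len(fit.levels) < 2:
        raise ValueError("need a fit with >= 2 colour levels")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(fit.levels)
                 for b in fit.levels[i + 1:]]
    # full coefficient vector including the reference at 0
    idx = {f"colour[{lvl}]": i for i, lvl in enumerate(fit.levels[1:])}
    rows = []
    for a, b in pairs:
        for lvl in (a, b):
            if lvl not in fit.levels:
                raise ValueError(f"unknown colour level: {lvl!r}")
        c = np.zeros(len(fit.coef))
        if a != fit.reference_level:
            c[idx[f"colour[{a}]"]] += 1.0
        if b != fit.reference_level:
            c[idx[f"colour[{b}]"]] -= 1.0
        coef = float(c @ fit.coef)
        se = float(np.sqrt(c @ fit.cov @ c))
        z = coef / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"a": a, "b": b, "coef": coef, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AttackRate:
    n_attacked: int
    n_total: int
    rate: float
    ci: tuple[float, float]  # exact (Clopper-Pearson) 95% interval


def attack_rate(records: list[PredationRecord]) -> AttackRate:
    """Fraction of models attacked, with an exact binomial 95% CI."""
    if not records:
        raise ValueError("need at least one record")
    k = sum(r.event for r in records)
    n = len(records)
    ci = stats.binomtest(k, n).proportion_ci(method="exact")
    return AttackRate(k, n, k / n, (float(ci.low), float(ci.high)))
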