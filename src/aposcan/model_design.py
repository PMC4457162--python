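"""Artificial-prey colour design: candidate grids around a target catch and
viewer-matched selection.

The print specification is an opaque payload (device colour space and
coating are physical concerns); matching operates purely on measured cone
catches under the modelled predator's vision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .discriminability import achromatic_jnd, chromatic_jnd
from .types import ConeCatch, ReceptorNoise

DEFAULT_MODEL_SIZE_MM = 5.0  # printed model body length
UV_WARN_THRESHOLD = 0.05  # relative UV catch above which printing is advised against


@dataclass(frozen=True)
class ColourCandidate:
    candidate_id: str
    print_spec: dict
    measured_catch: ConeCatch

    def __post_init__(self) -> None:
        if np.any(self.measured_catch.singles() <= 0):
            raise ValueError("measured catches must be strictly positive")


def generate_colour_grid(target: ConeCatch, n_steps: int = 3,
                         spread: float = 0.2) -> list[ColourCandidate]:
    """Deterministic grid of candidate colours bracketing a target catch.

    Each single-cone channel is varied multiplicatively over
    ``n_steps`` values spanning (1 - spread, 1 + spread); the double-cone
    catch scales with the mean channel factor.  Candidate count is
    ``n_steps ** 4``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if spread < 0:
        raise ValueError("spread must be non-negative")
    base = target.singles()
    factors = np.linspace(1.0 - spread, 1.0 + spread, n_steps)
    out = []
    for i, combo in enumerate(product(factors, repeat=4)):
        singles = base * np.asarray(combo)
        dbl = None if target.q_DBL is None \
            else target.q_DBL * float(np.mean(combo))
        out.append(ColourCandidate(
            f"C{i:04d}",
            {"channel_factors": list(map(float, combo))},
            ConeCatch.from_array(singles, dbl)))
    return out


@dataclass(frozen=True)
class MatchReport:
    best: ColourCandidate
    best_jnd: float
    runner_up: ColourCandidate | None
    runner_up_jnd: float | None
    flagged: bool  # True when even the winner is > 3 JND from the target


def select_best_match(candidates: list[ColourCandidate], target: ConeCatch,
                      noise: ReceptorNoise | None = None) -> MatchReport:
    """Candidate minimising chromatic JND to the target.

    Ties break on achromatic JND, then on candidate id, so the result is
    order-independent.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    noise = noise or ReceptorNoise()

    def key(c: ColourCandidate):
        dj = chromatic_jnd(c.measured_catch, target, noise)
        if c.measured_catch.q_DBL is not None and target.q_DBL is not None:
            dl = achromatic_jnd(c.measured_catch, target, noise)
        else:
            dl = np.inf
        return (dj, dl, c.candidate_id)

    ranked = sorted(candidates, key=key)
    best = ranked[0]
    best_jnd = chromatic_jnd(best.measured_catch, target, noise)
    runner = ranked[1] if len(ranked) > 1 else None
    runner_jnd = None if runner is None \
        else chromatic_jnd(runner.measured_catch, target, noise)
    flagged = best_jnd > 3.0
    if flagged:
        warnings.warn(f"best candidate is {best_jnd:.2f} JND from target "
                      "(> 3; likely discriminable)", stacklevel=2)
    return MatchReport(best, float(best_jnd), runner, runner_jnd, flagged)


def uv_policy_check(target: ConeCatch,
                    threshold: float = UV_WARN_THRESHOLD) -> dict:
    """Advise whether an un-pigmented (UV-dark) print can match the target.

    Printed models omit UV-matched pigments by design; warns when the
    target's relative UV catch exceeds ``threshold``.
    """
    singles = target.singles()
    total = singles.sum()
    if total <= 0:
        raise ValueError("target catches must be positive")
    uv_rel = float(singles[0] / total)
    ok = uv_rel <= threshold
    advisory = ("ok: target UV share {:.3f} <= {:.3f}".format(uv_rel, threshold)
                if ok else
                "warning: target UV share {:.3f} exceeds {:.3f}; a printed "
                "model will misrepresent the UV signal".format(uv_rel,
                                                               threshold))
    if not ok:
        warnings.warn(advisory, stacklevel=2)
    return {"uv_relative_catch": uv_rel, "threshold": threshold, "pass": ok,
            "advisory": advisory}
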