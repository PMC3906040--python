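"""Net reclassification improvement of a biomarker model over a PRISM baseline.

The NRI measures how much predicted risks move in the *correct* direction
when a baseline model (here, a univariable logistic regression of 28-day
mortality on the PRISM physiology score) is replaced by an augmented model
(the biomarker tree's terminal-node probability).  In the category-free
form,

    NRI = [P(up | event) - P(down | event)]
        + [P(down | nonevent) - P(up | nonevent)]

where "up" means the new predicted risk exceeds the baseline risk; ties
count as neither.  The statistic is bounded in [-2, 2]: +2 when every
subject is reclassified correctly, -2 when every subject is reclassified
wrongly, 0 when nothing changes.  A categorical variant over the ordered
low < intermediate < high strata is provided as well.

The standard error is the asymptotic multinomial form

    SE^2 = [p_up^e + p_down^e - (p_up^e - p_down^e)^2] / n_events
         + [p_up^ne + p_down^ne - (p_down^ne - p_up^ne)^2] / n_nonevents

and the p-value is the two-sided normal test of NRI = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "RiskPair",
    "NRIResult",
    "baseline_probabilities",
    "nri_continuous",
    "nri_categorical",
]

_CATEGORY_ORDER = {"low": 0, "intermediate": 1, "high": 2}


@dataclass(frozen=True)
class RiskPair:
    """Baseline and new predicted risks for one subject, with outcome."""

    p_baseline: float
    p_new: float
    event: bool

    def __post_init__(self) -> None:
        for name in ("p_baseline", "p_new"):
            p = getattr(self, name)
            if not (math.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError(f"{name} = {p!r} outside [0, 1]")


@dataclass(frozen=True)
class NRIResult:
    nri: float
    event_component: float
    nonevent_component: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    n_nonevents: int

    def to_dict(self) -> dict:
        return {
            "nri": self.nri,
            "event_component": self.event_component,
            "nonevent_component": self.nonevent_component,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "n_nonevents": self.n_nonevents,
        }


def baseline_probabilities(
    prism_scores: Sequence[float], outcomes: Sequence[bool]
) -> np.ndarray:
    """Per-subject event probabilities from a logistic fit of outcome on PRISM.

    Complete-case input is expected: callers drop subjects without a PRISM
    score before fitting.  A constant PRISM column yields the intercept-only
    fit (every probability equals the event prevalence).  If the maximum-
    likelihood fit fails to converge (e.g. perfect separation), a ridge-
    penalized fit is used as fallback and a warning is emitted.
    """
    x = np.asarray(prism_scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("prism_scores and outcomes must be equal-length 1-D")
    if np.any(~np.isfinite(x)):
        raise ValueError("prism_scores contain missing/non-finite values; "
                         "drop incomplete records before fitting")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least two subjects in each outcome class")
    if np.ptp(x) == 0.0:
        return np.full_like(x, y.mean())
    design = sm.add_constant(x)
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(disp=0, maxiter=200)
            converged = bool(result.mle_retvals.get("converged", False))
        except Exception:
            converged = False
            result = None
    if result is None or not converged or not np.all(np.isfinite(result.params)):
        warnings.warn(
            "logistic fit did not converge (possible perfect separation); "
            "falling back to a ridge-penalized fit",
            stacklevel=2,
        )
        result = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0)
    return np.asarray(result.predict(design), dtype=float)


def _nri_from_moves(
    up: np.ndarray, down: np.ndarray, event: np.ndarray, conf: float
) -> NRIResult:
    n_ev = int(event.sum())
    n_ne = int((~event).sum())
    if n_ev == 0 or n_ne == 0:
        raise ValueError("both outcome classes must be present")
    p_up_ev = float(up[event].mean())
    p_down_ev = float(down[event].mean())
    p_up_ne = float(up[~event].mean())
    p_down_ne = float(down[~event].mean())
    ev_comp = p_up_ev - p_down_ev
    ne_comp = p_down_ne - p_up_ne
    nri = ev_comp + ne_comp
    var = (p_up_ev + p_down_ev - ev_comp**2) / n_ev + (
        p_up_ne + p_down_ne - ne_comp**2
    ) / n_ne
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    if se > 0:
        p_value = 2.0 * stats.norm.sf(abs(nri) / se)
    else:
        p_value = 1.0 if nri == 0 else 0.0
    return NRIResult(
        nri=nri,
        event_component=ev_comp,
        nonevent_component=ne_comp,
        se=se,
        ci_low=nri - z * se,
        ci_high=nri + z * se,
        p_value=p_value,
        n_events=n_ev,
        n_nonevents=n_ne,
    )


def nri_continuous(pairs: Sequence[RiskPair], conf: float = 0.95) -> NRIResult:
    """Category-free NRI over per-subject (baseline, new) risk pairs.

    "Up" means p_new > p_baseline; exact ties contribute to neither
    direction.
    """
    if len(pairs) == 0:
        raise ValueError("no risk pairs")
    p_base = np.asarray([p.p_baseline for p in pairs], dtype=float)
    p_new = np.asarray([p.p_new for p in pairs], dtype=float)
    event = np.asarray([p.event for p in pairs], dtype=bool)
    return _nri_from_moves(p_new > p_base, p_new < p_base, event, conf)


def nri_categorical(
    class_baseline: Sequence[str],
    class_new: Sequence[str],
    outcomes: Sequence[bool],
    conf: float = 0.95,
) -> NRIResult:
    """NRI over the ordered risk strata low < intermediate < high.

    "Up" is a move to a strictly higher ordered category.
    """
    if not (len(class_baseline) == len(class_new) == len(outcomes)):
        raise ValueError("inputs must have equal length")
    try:
        base = np.asarray([_CATEGORY_ORDER[c] for c in class_baseline])
        new = np.asarray([_CATEGORY_ORDER[c] for c in class_new])
    except KeyError as exc:
        raise ValueError(f"unknown risk category {exc.args[0]!r}") from None
    event = np.asarray(outcomes, dtype=bool)
    return _nri_from_moves(new > base, new < base, event, conf)
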