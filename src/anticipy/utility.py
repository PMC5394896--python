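"""Risk sensitivity from certainty equivalents via exponential utility.

Each cue is a small lottery over monetary outcomes; a subject's stated
certainty equivalent c for a cue is modelled through the exponential
utility u(c) = (1 - exp(-c a)) / a with risk-sensitivity parameter a
(1/currency; a > 0 risk-averse, a < 0 risk-seeking, a -> 0 the linear,
risk-neutral limit).  Per subject, a is estimated by least squares on
the certainty equivalents and the fit is compared by AIC against the
zero-parameter model that predicts the true expected value of each cue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import aic_from_rss

__all__ = [
    "exponential_utility",
    "certainty_equivalent",
    "UtilityFit",
    "fit_risk_sensitivity",
]

_A_EPS = 1e-8
_A_BOUNDS = (-5.0, 5.0)
_MULTISTART = (-1.0, -0.1, 0.0, 0.1, 1.0)


def exponential_utility(c, a: float):
    """u(c) = (1 - exp(-c a)) / a, with the linear limit u(c) = c at |a| <= 1e-8."""
    c = np.asarray(c, float)
    with np.errstate(over="ignore"):
        if abs(a) <= _A_EPS:
            out = c.copy()
        else:
            # -expm1(-ca)/a avoids cancellation for small |a c|
            out = -np.expm1(-c * a) / a
    if not np.all(np.isfinite(out)):
        raise OverflowError("utility overflow; |a*c| too large")
    return out if out.ndim else float(out)


def certainty_equivalent(a: float, outcomes) -> float:
    """The sure amount with the same utility as the lottery's expected utility."""
    outcomes = np.asarray(outcomes, float)
    eu = float(np.mean(exponential_utility(outcomes, a)))
    if abs(a) <= _A_EPS:
        return eu
    if a * eu >= 1.0:
        raise OverflowError("expected utility outside the range of u")
    return -math.log1p(-a * eu) / a


@dataclass
class UtilityFit:
    per_subject: pd.DataFrame  # subject, a, rss, rss_ev, aic, aic_ev, converged
    group_mean_a: float
    group_sd_a: float
    t_stat: float
    t_p: float
    df: int
    aic_utility: float  # summed across converged subjects
    aic_expected_value: float

    @property
    def delta_aic(self) -> float:
        """AIC(expected value) - AIC(exponential utility); positive favours utility."""
        return self.aic_expected_value - self.aic_utility


def _subject_loss(a, ce, outcome_sets):
    try:
        pred = np.array([certainty_equivalent(a, o) for o in outcome_sets])
    except OverflowError:
        return np.inf
    return float(np.sum((ce - pred) ** 2))


def fit_risk_sensitivity(ce_table: pd.DataFrame, outcome_sets: dict) -> UtilityFit:
    """Estimate the risk-sensitivity parameter a per subject.

    ce_table needs columns subject, cue, certainty_equivalent;
    outcome_sets maps cue -> outcome list.  a is found by bounded 1-D
    least squares with multistart; the exponential-utility model (k=1) is
    compared against the true-expected-value model (k=0) by AIC, and a
    one-sample t test of a against 0 summarises the group.
    """
    required = {"subject", "cue", "certainty_equivalent"}
    if not required.issubset(ce_table.columns):
        raise ValueError(f"ce_table must have columns {sorted(required)}")
    rows = []
    for s, grp in ce_table.groupby("subject"):
        ce = grp["certainty_equivalent"].to_numpy(float)
        sets = [np.asarray(outcome_sets[c], float) for c in grp["cue"]]
        if len(ce) < 2:
            raise ValueError(f"subject {s} has fewer than 2 cues")
        ev = np.array([o.mean() for o in sets])

        best_a, best_loss = 0.0, np.inf
        converged = False
        for a0 in _MULTISTART:
            lo = max(_A_BOUNDS[0], a0 - 1.5)
            hi = min(_A_BOUNDS[1], a0 + 1.5)
            res = optimize.minimize_scalar(
                _subject_loss,
                bounds=(lo, hi),
                args=(ce, sets),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if res.success and res.fun < best_loss:
                best_a, best_loss, converged = float(res.x), float(res.fun), True
        rss_ev = float(np.sum((ce - ev) ** 2))
        n = len(ce)
        floor = n * 1e-24  # guard: AIC needs rss > 0 on noiseless fixtures
        aic_u = aic_from_rss(max(best_loss, floor), n, 1)
        aic_ev = aic_from_rss(max(rss_ev, floor), n, 0)
        rows.append(
            {
                "subject": s,
                "a": best_a,
                "rss": best_loss,
                "rss_ev": rss_ev,
                "aic": aic_u,
                "aic_ev": aic_ev,
                "converged": converged,
            }
        )
    per_subject = pd.DataFrame(rows)
    ok = per_subject["converged"]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} subject(s) failed to converge; excluded from group stats",
            stacklevel=2,
        )
    a_vals = per_subject.loc[ok, "a"].to_numpy(float)
    if len(a_vals) >= 2 and np.ptp(a_vals) > 0:
        t_stat, t_p = stats.ttest_1samp(a_vals, 0.0)
    else:
        t_stat, t_p = np.nan, np.nan
    return UtilityFit(
        per_subject=per_subject,
        group_mean_a=float(a_vals.mean()),
        group_sd_a=float(a_vals.std(ddof=1)) if len(a_vals) > 1 else 0.0,
        t_stat=float(t_stat),
        t_p=float(t_p),
        df=len(a_vals) - 1,
        aic_utility=float(per_subject.loc[ok, "aic"].sum()),
        aic_expected_value=float(per_subject.loc[ok, "aic_ev"].sum()),
    )
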