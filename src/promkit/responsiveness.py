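"""Univariate internal-responsiveness statistics.

For a paired pre/post cohort with Spearman correlation *r* between the
pre- and post-operative scores:

* naive ratio         ``mean(change) / sd(change)``
* paired-data SRM     ``(mean(change)/sd(change)) / (sqrt(2) * sqrt(1 - r))``
* SES                 ``|mean(pre, all) - mean(post, improved)| / sd(pre, improved)``
* RI                  ``(mean change "a little better" - mean change "about
  the same") / sd(change, "about the same")``

The SRM denominator rescales the paired ratio to the dispersion it would
have had between independent groups; at r = 0.5 the two coincide. The
SES and RI anchor the change to the patients' own transition rating.
Confidence intervals are nonparametric patient-level bootstrap
percentiles (the analytic distribution of these composites is awkward,
and the bootstrap is assumption-free and reproducible under a seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import IMPROVED_LEVELS, STABLE_LEVEL, TRANSITION_LEVELS, PairedCohort
from .errors import DegenerateStatisticError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "ResponsivenessSummary",
    "spearman_with_ci",
    "srm_paired",
    "ses",
    "ri",
    "classify_effect",
    "summarize",
    "summaries_to_frame",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class ResponsivenessSummary:
    """Point estimates (and optional bootstrap CIs) for one stratum."""

    stratum: str  # "total" or a transition level
    n: int
    pre_mean: float
    post_mean: float
    change_mean: float
    change_sd: float
    r: float
    srm_naive: float
    srm_paired: float
    ses: float | None = None
    ri: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "stratum": self.stratum,
            "n": self.n,
            "pre_mean": self.pre_mean,
            "post_mean": self.post_mean,
            "change_mean": self.change_mean,
            "change_sd": self.change_sd,
            "r": self.r,
            "srm_naive": self.srm_naive,
            "srm_paired": self.srm_paired,
            "ses": self.ses,
            "ri": self.ri,
        }
        for stat, (lo, hi) in self.ci.items():
            out[f"{stat}_ci_low"], out[f"{stat}_ci_high"] = lo, hi
        return out


def spearman_with_ci(pre, post, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation with a Fisher-z confidence interval.

    The interval uses the normal approximation on arctanh(r) with
    standard error 1/sqrt(n - 3), back-transformed.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length vectors")
    n = pre.size
    if n < 4:
        raise InsufficientDataError(f"need at least 4 pairs, got {n}")
    if np.ptp(pre) == 0 or np.ptp(post) == 0:
        raise DegenerateStatisticError("correlation undefined for a constant vector")
    r = float(stats.spearmanr(pre, post).statistic)
    if abs(r) >= 1.0:
        return r, (r, r)
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / math.sqrt(n - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


def srm_paired(change_mean: float, change_sd: float, r: float) -> float:
    """Paired-data standardized response mean.

    ``(change_mean / change_sd) / (sqrt(2) * sqrt(1 - r))`` where *r* is
    the pre/post correlation; undefined at r = 1.
    """
    if change_sd <= 0:
        raise DegenerateStatisticError("change_sd must be positive")
    if r >= 1:
        raise DegenerateStatisticError("paired SRM undefined at r = 1")
    return (change_mean / change_sd) / (SQRT2 * math.sqrt(1.0 - r))


def ses(pre_mean_all: float, improved_post_mean: float, improved_pre_sd: float) -> float:
    """Standardized effect size, anchored on the self-rated improved group.

    Absolute difference between the whole cohort's pre-operative mean and
    the post-operative mean of the improved subjects, scaled by the
    improved subjects' pre-operative SD.
    """
    if improved_pre_sd <= 0:
        raise DegenerateStatisticError("improved_pre_sd must be positive")
    return abs(pre_mean_all - improved_post_mean) / improved_pre_sd


def ri(mcid_anchor: float, stable_change_sd: float) -> float:
    """Responsiveness index: anchor-based MCID over the stable-group change SD.

    The anchor-based MCID is the difference in mean change between
    patients rating themselves "a little better" and "about the same";
    the denominator is the change-score SD of the "about the same" group.
    """
    if stable_change_sd <= 0:
        raise DegenerateStatisticError("stable_change_sd must be positive")
    return mcid_anchor / stable_change_sd


def classify_effect(value: float) -> str:
    """Cohen's practical-effect label: <0.5 small, 0.5-0.8 moderate, >0.8 large."""
    if not np.isfinite(value):
        raise ValueError("effect size must be finite")
    v = abs(value)
    if v < 0.5:
        return "small"
    if v <= 0.8:
        return "moderate"
    return "large"


# ---------------------------------------------------------------------------
# cohort-level summaries


def _anchor_stats(change: np.ndarray, transition: np.ndarray) -> tuple[float, float] | None:
    """(anchor MCID numerator, stable change SD) or None if a stratum is empty."""
    little = change[transition == TRANSITION_LEVELS[1]]
    stable = change[transition == STABLE_LEVEL]
    if little.size < 2 or stable.size < 2:
        return None
    sd = stable.std(ddof=1)
    if sd <= 0:
        return None
    return float(little.mean() - stable.mean()), float(sd)


def _improved_stats(
    pre: np.ndarray, post: np.ndarray, transition: np.ndarray
) -> tuple[float, float] | None:
    """(post mean, pre SD) of the anchor-rated improved subjects."""
    mask = np.isin(transition, IMPROVED_LEVELS)
    if mask.sum() < 2:
        return None
    sd = pre[mask].std(ddof=1)
    if sd <= 0:
        return None
    return float(post[mask].mean()), float(sd)


def _ratio(cm: float, cs: float) -> float:
    # a cohort with no change at all has, by convention, zero responsiveness
    if cs > 0:
        return cm / cs
    return 0.0 if cm == 0 else np.nan


def _total_stats(pre: np.ndarray, post: np.ndarray, transition: np.ndarray) -> dict:
    change = post - pre
    cm, cs = change.mean(), change.std(ddof=1)
    degenerate = np.ptp(pre) == 0 or np.ptp(post) == 0
    r = np.nan if degenerate else float(stats.spearmanr(pre, post).statistic)
    naive = _ratio(cm, cs)
    out = {
        "pre_mean": pre.mean(),
        "post_mean": post.mean(),
        "change_mean": cm,
        "change_sd": cs,
        "r": r,
        "srm_naive": naive,
        "srm_paired": srm_paired(cm, cs, r)
        if cs > 0 and np.isfinite(r) and r < 1
        else np.nan,
        "ses": np.nan,
        "ri": np.nan,
    }
    imp = _improved_stats(pre, post, transition)
    if imp is not None:
        out["ses"] = ses(pre.mean(), imp[0], imp[1])
    anchor = _anchor_stats(change, transition)
    if anchor is not None:
        out["ri"] = ri(*anchor)
    return out


def _stratum_stats(
    pre: np.ndarray,
    post: np.ndarray,
    pre_mean_all: float,
    denom_sd: float | None,
    ses_denominator: str,
) -> dict:
    change = post - pre
    cm, cs = change.mean(), change.std(ddof=1)
    degenerate = np.ptp(pre) == 0 or np.ptp(post) == 0
    r = np.nan if degenerate else float(stats.spearmanr(pre, post).statistic)
    sd = pre.std(ddof=1) if ses_denominator == "stratum" else denom_sd
    return {
        "pre_mean": pre.mean(),
        "post_mean": post.mean(),
        "change_mean": cm,
        "change_sd": cs,
        "r": r,
        "srm_naive": _ratio(cm, cs),
        "srm_paired": srm_paired(cm, cs, r) if cs > 0 and not np.isnan(r) and r < 1 else np.nan,
        "ses": ses(pre_mean_all, post.mean(), sd) if sd and sd > 0 else np.nan,
        "ri": np.nan,
    }


_BOOT_STATS = ("change_mean", "change_sd", "r", "srm_naive", "srm_paired", "ses", "ri")


def _bootstrap_ci(
    stat_fn, n: int, n_boot: int, rng: np.random.Generator, level: float
) -> dict[str, tuple[float, float]]:
    reps = {k: [] for k in _BOOT_STATS}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        vals = stat_fn(idx)
        for k in _BOOT_STATS:
            reps[k].append(vals.get(k, np.nan))
    alpha = (1 - level) / 2
    ci = {}
    for k, v in reps.items():
        arr = np.asarray(v, float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            ci[k] = (
                float(np.percentile(arr, 100 * alpha)),
                float(np.percentile(arr, 100 * (1 - alpha))),
            )
    return ci


def summarize(
    cohort: PairedCohort,
    by_transition: bool = False,
    n_boot: int = 1000,
    seed: int | None = 0,
    ci_level: float = 0.95,
    ses_denominator: str = "improved",
) -> list[ResponsivenessSummary]:
    """Responsiveness summaries for the whole cohort and, optionally, per
    transition stratum.

    The RI is computed for the total only (it consumes two strata by
    construction). ``ses_denominator`` selects the pre-operative SD used
    for stratum-level SES: the pooled improved-subjects SD (default) or
    each stratum's own SD. ``n_boot = 0`` skips confidence intervals;
    strata with fewer than 2 records are reported absent with a warning.
    """
    if ses_denominator not in ("improved", "stratum"):
        raise ValueError("ses_denominator must be 'improved' or 'stratum'")
    pre, post = cohort.pre, cohort.post
    transition = cohort.transition.to_numpy()
    n = len(cohort)
    if n < 2:
        raise InsufficientDataError("need at least 2 records")
    rng = np.random.default_rng(seed)

    vals = _total_stats(pre, post, transition)
    total = ResponsivenessSummary(
        stratum="total",
        n=n,
        **{k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in vals.items()},
    )
    if n_boot > 0:
        total.ci = _bootstrap_ci(
            lambda idx: _total_stats(pre[idx], post[idx], transition[idx]),
            n, n_boot, rng, ci_level,
        )
    out = [total]
    if not by_transition:
        return out

    imp = _improved_stats(pre, post, transition)
    denom_sd = imp[1] if imp is not None else None
    pre_mean_all = float(pre.mean())
    for level in TRANSITION_LEVELS:
        mask = transition == level
        n_s = int(mask.sum())
        if n_s < 2:
            logger.warning("stratum %r has %d record(s); summary omitted", level, n_s)
            continue
        p_s, q_s = pre[mask], post[mask]
        vals = _stratum_stats(p_s, q_s, pre_mean_all, denom_sd, ses_denominator)
        summary = ResponsivenessSummary(
            stratum=level,
            n=n_s,
            **{k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in vals.items()},
        )
        if n_boot > 0:
            summary.ci = _bootstrap_ci(
                lambda idx: _stratum_stats(
                    p_s[idx], q_s[idx], pre_mean_all, denom_sd, ses_denominator
                ),
                n_s, n_boot, rng, ci_level,
            )
        out.append(summary)
    return out


def summaries_to_frame(summaries: list[ResponsivenessSummary]) -> pd.DataFrame:
    """Long-format frame: one row per (stratum, statistic)."""
    rows = []
    for s in summaries:
        d = s.to_dict()
        for stat in ("pre_mean", "post_mean", "change_mean", "change_sd", "r",
                     "srm_naive", "srm_paired", "ses", "ri"):
            if d.get(stat) is None:
                continue
            rows.append(
                {
                    "stratum": s.stratum,
                    "n": s.n,
                    "statistic": stat,
                    "value": d[stat],
                    "ci_low": d.get(f"{stat}_ci_low"),
                    "ci_high": d.get(f"{stat}_ci_high"),
                }
            )
    return pd.DataFrame(rows)
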