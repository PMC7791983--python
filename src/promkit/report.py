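"""Observed vs predicted improvement reporting and discrimination.

Assembles the end products of the analysis: improvement percentages at a
chosen threshold (total and per transition level), AUC discrimination of
model predictions against observed improvement, a two-period sensitivity
comparison, and a machine/human-readable report document.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .boxcox import PredictionResult
from .cohort import PERIODS, TRANSITION_LEVELS, PairedCohort
from .errors import ConfigurationError, DegenerateStatisticError, InsufficientDataError
from .responsiveness import ResponsivenessSummary, summaries_to_frame, summarize
from .thresholds import McidSet, classify_improved

logger = logging.getLogger(__name__)

__all__ = [
    "AucResult",
    "ImprovementReport",
    "observed_improvement",
    "auc",
    "period_sensitivity",
    "build_report",
]


def observed_improvement(
    cohort: PairedCohort, threshold: float, by_transition: bool = True
) -> dict:
    """Percentage of records with change >= threshold, with counts.

    Returns ``{"total": cell, "by_transition": {level: cell | None}}``
    where a cell is ``{"n", "n_improved", "pct"}``; empty strata are
    reported absent (None) with a warning.
    """
    improved = classify_improved(cohort.change, threshold)

    def cell(mask: np.ndarray) -> dict:
        k = int(improved[mask].sum())
        m = int(mask.sum())
        return {"n": m, "n_improved": k, "pct": 100.0 * k / m}

    out = {"total": cell(np.ones(len(cohort), bool))}
    if by_transition:
        transition = cohort.transition.to_numpy()
        table: dict[str, dict | None] = {}
        for level in TRANSITION_LEVELS:
            mask = transition == level
            if mask.any():
                table[level] = cell(mask)
            else:
                logger.warning("stratum %r empty; observed cell absent", level)
                table[level] = None
        out["by_transition"] = table
    return out


@dataclass(frozen=True)
class AucResult:
    value: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_pos: int
    n_neg: int


def auc(scores, labels, ci_method: str = "hanley-mcneil", level: float = 0.95) -> AucResult:
    """Area under the ROC curve with a confidence interval.

    The AUC is the pairwise concordance probability (ties credited 0.5).
    ``ci_method="hanley-mcneil"`` uses the classic normal approximation to
    the AUC's standard error; ``"binomial-exact"`` treats the concordant
    share of the n_pos*n_neg pairs as binomial successes and returns a
    Clopper-Pearson interval (a conservative reading of an "exact
    binomial" interval for a concordance probability).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateStatisticError("AUC undefined with a single class")
    a = float(roc_auc_score(labels, scores))
    alpha = 1 - level
    if ci_method == "hanley-mcneil":
        q1 = a / (2 - a)
        q2 = 2 * a**2 / (1 + a)
        var = (
            a * (1 - a)
            + (n_pos - 1) * (q1 - a**2)
            + (n_neg - 1) * (q2 - a**2)
        ) / (n_pos * n_neg)
        half = stats.norm.ppf(1 - alpha / 2) * math.sqrt(max(var, 0.0))
        lo, hi = a - half, a + half
    elif ci_method == "binomial-exact":
        pairs = n_pos * n_neg
        successes = int(round(a * pairs))
        lo = stats.beta.ppf(alpha / 2, successes, pairs - successes + 1) if successes else 0.0
        hi = (
            stats.beta.ppf(1 - alpha / 2, successes + 1, pairs - successes)
            if successes < pairs
            else 1.0
        )
    else:
        raise ValueError("ci_method must be 'hanley-mcneil' or 'binomial-exact'")
    return AucResult(a, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)),
                     ci_method, n_pos, n_neg)


def period_sensitivity(
    cohort: PairedCohort,
    n_boot: int = 200,
    seed: int = 0,
    statistics: tuple[str, ...] = ("change_mean", "srm_naive", "srm_paired", "ses", "ri"),
) -> pd.DataFrame:
    """Compare responsiveness statistics between the two collection periods.

    Runs the total summary on each period subset and reports per-statistic
    differences (period 2 minus period 1) with bootstrap percentile CIs
    from within-period patient resampling. Judgment of what counts as a
    material difference is left to the reader; the CIs are reported as-is.
    """
    subsets = {}
    for period in PERIODS:
        mask = (cohort.df["period"] == period).to_numpy()
        if mask.sum() < 4:
            raise InsufficientDataError(f"period {period!r} absent or too small")
        subsets[period] = cohort.subset(mask)

    def totals(c: PairedCohort) -> dict:
        s = summarize(c, n_boot=0)[0]
        return {k: getattr(s, k) for k in statistics}

    p1, p2 = (totals(subsets[p]) for p in PERIODS)
    reps: dict[str, list[float]] = {k: [] for k in statistics}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        frames = {p: subsets[p] for p in PERIODS}
        for _ in range(n_boot):
            b = {}
            for p, sub in frames.items():
                idx = rng.integers(0, len(sub), len(sub))
                resampled = PairedCohort(
                    sub.df.iloc[idx].reset_index(drop=True), sub.instrument, sub.joint
                )
                b[p] = totals(resampled)
            for stat in statistics:
                v1, v2 = b[PERIODS[0]].get(stat), b[PERIODS[1]].get(stat)
                if v1 is not None and v2 is not None:
                    reps[stat].append(v2 - v1)

    rows = []
    for stat in statistics:
        v1, v2 = p1.get(stat), p2.get(stat)
        diff = None if v1 is None or v2 is None else v2 - v1
        row = {
            "statistic": stat,
            PERIODS[0]: v1,
            PERIODS[1]: v2,
            "difference": diff,
            "ci_low": None,
            "ci_high": None,
        }
        if reps[stat]:
            arr = np.asarray(reps[stat], float)
            arr = arr[np.isfinite(arr)]
            if arr.size:
                row["ci_low"] = float(np.percentile(arr, 2.5))
                row["ci_high"] = float(np.percentile(arr, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report assembly


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return None if not np.isfinite(x) else round(float(x), nd)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


@dataclass
class ImprovementReport:
    """The assembled report: responsiveness, thresholds, improvement, AUC."""

    instrument: str
    joint: str
    threshold: float
    n: int
    responsiveness: list[dict]
    thresholds: dict
    observed: dict
    predicted: dict[str, dict]
    auc_total: AucResult | None
    auc_by_transition: dict[str, AucResult | None]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def auc_dict(a: AucResult | None):
            if a is None:
                return None
            return {
                "value": a.value,
                "ci_low": a.ci_low,
                "ci_high": a.ci_high,
                "ci_method": a.ci_method,
            }

        return _round(
            {
                "instrument": self.instrument,
                "joint": self.joint,
                "threshold": self.threshold,
                "n": self.n,
                "responsiveness": self.responsiveness,
                "thresholds": self.thresholds,
                "improvement": {
                    "observed": self.observed,
                    "predicted": self.predicted,
                    "auc_total": auc_dict(self.auc_total),
                    "auc_by_transition": {
                        k: auc_dict(v) for k, v in self.auc_by_transition.items()
                    },
                },
                "meta": self.meta,
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self, path=None) -> str:
        d = self.to_dict()
        lines = [
            f"# Improvement report — {self.instrument} ({self.joint})",
            "",
            f"- records: {self.n}",
            f"- improvement threshold (paired MCID): {self.threshold:g}",
            "",
            "## Responsiveness",
            "",
            "| stratum | n | change mean (SD) | r | SRM | SES | RI |",
            "|---|---|---|---|---|---|---|",
        ]
        for row in self.responsiveness:
            fmt = lambda v, nd=1: "-" if v is None else f"{v:.{nd}f}"
            cells = [
                str(row["stratum"]),
                str(row["n"]),
                f"{fmt(row.get('change_mean'))} ({fmt(row.get('change_sd'))})",
                fmt(row.get("r"), 2),
                fmt(row.get("srm_paired")),
                fmt(row.get("ses")),
                fmt(row.get("ri")),
            ]
            lines.append("| " + " | ".join(cells) + " |")
        thr = d["thresholds"]
        lines += [
            "",
            "## Thresholds",
            "",
            f"- paired MCID: {thr['paired_mcid']:g} "
            f"(reported: {thr['paired_mcid_rounded']:g})",
            *(
                f"- independent MCID (d = {k}): {v:g}"
                for k, v in thr["independent_mcid_d"].items()
            ),
            f"- MDC (ICC {thr['icc']:g}): {thr['mdc']:g}",
            "",
            "## Improvement (%)",
            "",
            "| measure | total | " + " | ".join(TRANSITION_LEVELS) + " |",
            "|---|---|" + "---|" * len(TRANSITION_LEVELS),
        ]

        def pct(cell):
            if cell is None:
                return "-"
            v = cell["pct"] if isinstance(cell, dict) else cell
            return "-" if v is None else f"{v:.0f}%"

        obs = d["improvement"]["observed"]
        lines.append(
            "| observed | "
            + pct(obs["total"])
            + " | "
            + " | ".join(pct(obs["by_transition"][lv]) for lv in TRANSITION_LEVELS)
            + " |"
        )
        for name, block in d["improvement"]["predicted"].items():
            lines.append(
                f"| predicted ({name}) | "
                + pct(block["total"])
                + " | "
                + " | ".join(pct(block["by_transition"][lv]) for lv in TRANSITION_LEVELS)
                + " |"
            )
        au = d["improvement"]["auc_total"]
        aub = d["improvement"]["auc_by_transition"]
        fmt_auc = lambda a: "-" if a is None else f"{a['value']:.1f}"
        lines.append(
            "| AUC | "
            + fmt_auc(au)
            + " | "
            + " | ".join(fmt_auc(aub[lv]) for lv in TRANSITION_LEVELS)
            + " |"
        )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_report(
    cohort: PairedCohort,
    summaries: list[ResponsivenessSummary],
    mcids: McidSet,
    predictions: dict[str, PredictionResult],
    threshold: float | None = None,
    auc_method: str = "hanley-mcneil",
    auc_predictor: str | None = None,
) -> ImprovementReport:
    """Assemble one report document from the pipeline's pieces.

    ``predictions`` maps model labels (e.g. ``"pre-op"`` and
    ``"pre-op+covariates"``) to their prediction results; all inputs must
    describe the same instrument and joint or the merge is refused. The
    AUC predictor is the predicted change of ``auc_predictor`` (default:
    the last predictions entry), scored against observed improvement.
    """
    if mcids.instrument is not None and mcids.instrument != cohort.instrument.name:
        raise ConfigurationError(
            f"threshold set computed for {mcids.instrument}, cohort is "
            f"{cohort.instrument.name}"
        )
    for name, pr in predictions.items():
        if len(pr.predictions) != len(cohort):
            raise ConfigurationError(f"predictions {name!r} do not match cohort size")
    if threshold is None:
        threshold = mcids.paired_mcid_rounded

    observed = observed_improvement(cohort, threshold, by_transition=True)
    predicted = {
        name: {
            "total": pr.pct_total,
            "by_transition": pr.pct_by_transition,
            "n_undefined": pr.n_undefined,
        }
        for name, pr in predictions.items()
    }

    auc_total = None
    auc_by: dict[str, AucResult | None] = {lv: None for lv in TRANSITION_LEVELS}
    if predictions:
        key = auc_predictor if auc_predictor is not None else list(predictions)[-1]
        scores = predictions[key].predictions["predicted_change"].to_numpy(float)
        labels = classify_improved(cohort.change, threshold)
        ok = np.isfinite(scores)
        try:
            auc_total = auc(scores[ok], labels[ok], ci_method=auc_method)
        except DegenerateStatisticError:
            logger.warning("total AUC undefined (single class)")
        transition = cohort.transition.to_numpy()
        for lv in TRANSITION_LEVELS:
            mask = (transition == lv) & ok
            if mask.sum() < 4:
                continue
            try:
                auc_by[lv] = auc(scores[mask], labels[mask], ci_method=auc_method)
            except DegenerateStatisticError:
                pass

    resp_rows = []
    for s in summaries:
        d = s.to_dict()
        resp_rows.append({k: d.get(k) for k in (
            "stratum", "n", "pre_mean", "post_mean", "change_mean", "change_sd",
            "r", "srm_naive", "srm_paired", "ses", "ri")})

    meta = {
        "generator": cohort.meta.get("generator"),
        "clipped_fraction": cohort.meta.get("clipped_fraction"),
        "auc_method": auc_method,
        "summary_frame": summaries_to_frame(summaries).to_dict("records"),
    }
    return ImprovementReport(
        instrument=cohort.instrument.name,
        joint=cohort.joint,
        threshold=float(threshold),
        n=len(cohort),
        responsiveness=resp_rows,
        thresholds=mcids.to_dict(),
        observed=observed,
        predicted=predicted,
        auc_total=auc_total,
        auc_by_transition=auc_by,
        meta=meta,
    )
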