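"""Improvement thresholds: paired MCID, Cohen's-d independent MCID, MDC.

The paired-data MCID inverts the paired SRM identity —
``srm_paired * sqrt(2) * sqrt(1 - r) * sd(change)`` — which collapses
algebraically to the cohort's mean change score; computing it through
the identity keeps the threshold consistent with whatever SRM variant
produced the summary. Oxford thresholds are rounded *up* to the 1-point
instrument resolution by default (a patient must clear the full capacity
of benefit), EQ-5D thresholds are left unrounded at the index's 0.001
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import PairedCohort
from .errors import DegenerateStatisticError, InsufficientDataError
from .instruments import InstrumentSpec
from .responsiveness import SQRT2, ResponsivenessSummary, _anchor_stats

__all__ = [
    "McidSet",
    "paired_mcid",
    "independent_mcid",
    "mdc",
    "classify_improved",
    "fraction_improved",
    "compute_mcid_set",
]


@dataclass
class McidSet:
    """The family of improvement thresholds for one cohort."""

    paired_mcid: float
    paired_mcid_rounded: float
    independent_mcid_d: dict[float, float]
    mdc: float | None = None
    anchor_mcid: float | None = None
    anchor_mean_change: float | None = None
    icc: float | None = None
    instrument: str | None = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "paired_mcid": self.paired_mcid,
            "paired_mcid_rounded": self.paired_mcid_rounded,
            "independent_mcid_d": {str(k): v for k, v in self.independent_mcid_d.items()},
            "mdc": self.mdc,
            "icc": self.icc,
            "anchor_mcid": self.anchor_mcid,
            "anchor_mean_change": self.anchor_mean_change,
            "notes": self.notes,
        }


def _ceil_to_resolution(value: float, resolution: float) -> float:
    # tolerate float fuzz so e.g. 22.000000001 does not ceil to 23
    steps = value / resolution
    return round(math.ceil(steps - 1e-9) * resolution, 9)


def paired_mcid(
    summary: ResponsivenessSummary,
    rounding: str = "none",
    resolution: float = 1.0,
) -> float:
    """Paired-data MCID from a responsiveness summary.

    Evaluates ``srm_paired * sqrt(2) * sqrt(1 - r) * change_sd`` (equal to
    the mean change score up to floating error). ``rounding="ceil"``
    rounds up to the instrument resolution.
    """
    if summary.srm_paired is None or summary.r is None or summary.r >= 1:
        raise DegenerateStatisticError("summary lacks a valid paired SRM")
    value = summary.srm_paired * SQRT2 * math.sqrt(1.0 - summary.r) * summary.change_sd
    if rounding == "ceil":
        return _ceil_to_resolution(value, resolution)
    if rounding != "none":
        raise ValueError("rounding must be 'none' or 'ceil'")
    return value


def independent_mcid(d: float, r: float, change_sd: float) -> float:
    """Cohen's-d based MCID for independent data: ``d*sqrt(2)*sqrt(1-r)*sd``."""
    if d < 0:
        raise ValueError("d must be non-negative")
    if r >= 1:
        raise DegenerateStatisticError("undefined at r = 1")
    if change_sd <= 0:
        raise DegenerateStatisticError("change_sd must be positive")
    return d * SQRT2 * math.sqrt(1.0 - r) * change_sd


def mdc(baseline_sd: float, icc: float) -> float:
    """Minimal detectable change at 95% confidence.

    ``1.96 * sqrt(2) * baseline_sd * sqrt(1 - icc)`` — the smallest change
    exceeding test-retest measurement error at reliability ``icc``.
    """
    if baseline_sd <= 0:
        raise DegenerateStatisticError("baseline_sd must be positive")
    if not 0 < icc < 1:
        raise ValueError("icc must lie strictly between 0 and 1")
    return 1.96 * SQRT2 * baseline_sd * math.sqrt(1.0 - icc)


def classify_improved(change_score, threshold: float):
    """Improved iff change >= threshold (boundary counts as improved)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.asarray(change_score, float) >= threshold - 1e-9


def fraction_improved(cohort: PairedCohort, threshold: float) -> float:
    flags = classify_improved(cohort.change, threshold)
    return float(flags.mean())


def compute_mcid_set(
    cohort: PairedCohort,
    summary: ResponsivenessSummary,
    d_values: tuple[float, ...] = (0.5, 0.8),
    icc: float = 0.9,
    rounding: str | None = None,
    anchor_mcid_metadata: float | None = None,
) -> McidSet:
    """Assemble the threshold family for a cohort.

    ``rounding=None`` picks the instrument default: ceil for integer-step
    Oxford scores, none for the EQ-5D index. The MDC uses the improved
    subjects' pre-operative SD as its baseline dispersion. An externally
    sourced anchor-based MCID may be attached as metadata only (no
    standard computation exists for the "short distance" variant).
    """
    instrument: InstrumentSpec = cohort.instrument
    if rounding is None:
        rounding = "ceil" if instrument.resolution >= 1 else "none"
    raw = paired_mcid(summary, rounding="none")
    rounded = (
        _ceil_to_resolution(raw, instrument.resolution) if rounding == "ceil" else raw
    )
    independents = {
        d: independent_mcid(d, summary.r, summary.change_sd) for d in d_values
    }

    change = cohort.change
    transition = cohort.transition.to_numpy()
    anchor = _anchor_stats(change, transition)
    if anchor is None:
        raise InsufficientDataError(
            "anchor strata ('a little better' / 'about the same') too small"
        )
    anchor_diff, _ = anchor
    little_mean = float(change[transition == "a little better"].mean())

    pre = cohort.pre
    improved = np.isin(transition, ("much better", "a little better"))
    baseline_sd = float(pre[improved].std(ddof=1))

    return McidSet(
        paired_mcid=raw,
        paired_mcid_rounded=rounded,
        independent_mcid_d=independents,
        mdc=mdc(baseline_sd, icc),
        icc=icc,
        anchor_mcid=anchor_mcid_metadata,
        anchor_mean_change=little_mean,
        instrument=instrument.name,
        notes={
            "rounding": rounding,
            "anchor_level_difference": anchor_diff,
            "mdc_baseline_sd": baseline_sd,
            "anchor_mcid_source": "user-supplied metadata"
            if anchor_mcid_metadata is not None
            else "not computed",
        },
    )
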