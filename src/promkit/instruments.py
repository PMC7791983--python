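"""Instrument definitions and Oxford item scoring.

Three patient-reported outcome measures are supported:

* **OHS** / **OKS** — Oxford Hip / Knee Score: 12 Likert items, each coded
  0 (worst) to 4 (best) and summed to an integer score in [0, 48].
* **EQ-5D-3L** — a single preference-based utility index in [-0.59, 1]
  (UK value set range), consumed directly at summary level.

Higher scores always indicate better health, so the change score
``post - pre`` is positive for patients who improve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "InstrumentSpec",
    "OHS",
    "OKS",
    "EQ5D3L",
    "INSTRUMENTS",
    "score_oxford_items",
]

N_OXFORD_ITEMS = 12


@dataclass(frozen=True)
class InstrumentSpec:
    """Score range, resolution and direction of a PROM instrument.

    Parameters
    ----------
    name : str
        Instrument label (``"OHS"``, ``"OKS"`` or ``"EQ5D3L"``).
    min_score, max_score : float
        Attainable score range.
    resolution : float
        Smallest meaningful increment (1 for Oxford scores, 0.001 for the
        EQ-5D-3L index).
    higher_is_better : bool
        Direction of the scale; all supported instruments are ascending.
    """

    name: str
    min_score: float
    max_score: float
    resolution: float
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if not self.min_score < self.max_score:
            raise ValidationError(
                f"{self.name}: min_score {self.min_score} must be below "
                f"max_score {self.max_score}"
            )
        if self.resolution <= 0:
            raise ValidationError(f"{self.name}: resolution must be positive")

    @property
    def decimals(self) -> int:
        """Number of decimals needed to serialize scores losslessly."""
        return max(0, int(round(-np.log10(self.resolution))))

    def clip(self, scores):
        """Clip scores into the attainable range."""
        return np.clip(scores, self.min_score, self.max_score)

    def quantize(self, scores):
        """Round scores to the instrument resolution (after clipping)."""
        snapped = np.round(np.asarray(scores, dtype=float) / self.resolution)
        return np.round(snapped * self.resolution, self.decimals)

    def in_range(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return (s >= self.min_score - 1e-9) & (s <= self.max_score + 1e-9)


OHS = InstrumentSpec("OHS", 0.0, 48.0, 1.0)
OKS = InstrumentSpec("OKS", 0.0, 48.0, 1.0)
EQ5D3L = InstrumentSpec("EQ5D3L", -0.59, 1.0, 0.001)

INSTRUMENTS: dict[str, InstrumentSpec] = {i.name: i for i in (OHS, OKS, EQ5D3L)}


def score_oxford_items(item_responses) -> int:
    """Sum the 12 Oxford item responses into a 0-48 score.

    Each item is an ordinal response coded from 'None' = 4 down to
    'Severe' = 0; the instrument score is their plain sum, so higher
    values indicate greater health status. Missing or out-of-range
    responses are rejected (complete-case policy, no imputation).
    """
    responses = list(item_responses)
    if len(responses) != N_OXFORD_ITEMS:
        raise ValidationError(
            f"expected {N_OXFORD_ITEMS} item responses, got {len(responses)}"
        )
    total = 0
    for i, r in enumerate(responses):
        if r is None:
            raise ValidationError(f"item {i + 1}: missing response")
        try:
            v = int(r)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"item {i + 1}: non-integer response {r!r}") from exc
        if v != r or v not in (0, 1, 2, 3, 4):
            raise ValidationError(f"item {i + 1}: response {r!r} not in 0..4")
        total += v
    return total
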