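"""Exhaustive enumeration of the instrument's score space.

The final score factors through the lead and air bands, so the full
response space that matters for scoring is the cross product

    5 lead bands x 3 air bands x Q3(4) x Q4(3) x Q5(3) x Q6(4) x Q7(3)
    x Q8(3) x Q9(3)  =  58,320 combinations.

Enumerating all of them certifies the printed design properties: the
attainable range is exactly [1.3, 9.4] (no perfect 10, no demoralizing 1.0),
and improving any single answer — including moving Q8 toward fewer products
at a fixed Q9 — never lowers the final score.

The sweep is a numpy broadcast over a 9-axis integer array and runs in
milliseconds; results are independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import LEAD_BANDS
from .scoring import MODIFIER_MATRIX, round_tenths_half_up
from .survey import Instrument, load_instrument

#: Axis labels in enumeration order (Q9 option order: all_the_time, sometimes, never).
AXES: tuple[str, ...] = ("lead", "air", "Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "Q9")


@dataclass(frozen=True)
class EnumerationSummary:
    n_outcomes: int
    min_score: float
    max_score: float
    histogram: dict[str, int]  # rounded 1-dp score (or exact mean) -> count
    monotonicity_violations: int

    def to_dict(self) -> dict:
        return {
            "n_outcomes": self.n_outcomes,
            "min_score": self.min_score,
            "max_score": self.max_score,
            "histogram": self.histogram,
            "monotonicity_violations": self.monotonicity_violations,
        }


def _axis_scores(instrument: Instrument) -> list[np.ndarray]:
    """Per-axis additive contributions to the eight-domain sum.

    Q8/Q9 are handled as two axes whose joint contribution is the
    personal-care matrix; every other axis contributes its own subscore.
    """
    lead = np.array([s for _, s in LEAD_BANDS])
    air = np.array([9, 5, 1])
    per_question = [
        np.array([o.raw_score for o in instrument.question(qid).options])
        for qid in ("Q3", "Q4", "Q5", "Q6", "Q7")
    ]
    return [lead, air, *per_question]


def _personal_care_matrix(instrument: Instrument) -> np.ndarray:
    """3x3 array indexed [Q8 option order, Q9 option order]."""
    q8_mods = [o.modifier for o in instrument.question("Q8").options]
    q9_opts = [o.option_id for o in instrument.question("Q9").options]
    return np.array([[MODIFIER_MATRIX[opt][mod] for opt in q9_opts] for mod in q8_mods])


def enumerate_scores(
    instrument: Instrument | None = None, raw_means: bool = False
) -> EnumerationSummary:
    """Score every combination of bands and options; summarize the space.

    With ``raw_means=True`` the histogram is keyed by the exact (unrounded)
    eight-domain mean instead of the one-decimal score users see.
    """
    if instrument is None:
        instrument = load_instrument()

    axes = _axis_scores(instrument)
    pc = _personal_care_matrix(instrument)

    # Broadcast the 7 single-domain axes plus the joint Q8xQ9 axes into a
    # 9-D array of eight-domain sums.
    n_axes = 9
    total = np.zeros((1,) * n_axes, dtype=np.int64)
    for i, scores in enumerate(axes):
        shape = [1] * n_axes
        shape[i] = len(scores)
        total = total + scores.reshape(shape)
    total = total + pc.reshape((1,) * 7 + pc.shape)

    # Exact integer tenths of round-half-up(total/8, 1dp).
    tenths = (20 * total + 8) // 16

    # Single-option monotonicity: option order is worst-ward along every
    # axis (raw scores non-increasing; every matrix row/column decreasing),
    # so scores must be non-increasing along each axis.
    violations = 0
    for axis in range(n_axes):
        violations += int(np.sum(np.diff(tenths, axis=axis) > 0))

    flat_sums = total.ravel()
    if raw_means:
        keys, counts = np.unique(flat_sums, return_counts=True)
        histogram = {f"{k / 8:.3f}": int(c) for k, c in zip(keys, counts)}
    else:
        keys, counts = np.unique(tenths.ravel(), return_counts=True)
        histogram = {f"{k / 10:.1f}": int(c) for k, c in zip(keys, counts)}

    return EnumerationSummary(
        n_outcomes=int(flat_sums.size),
        min_score=round_tenths_half_up(int(flat_sums.min())),
        max_score=round_tenths_half_up(int(flat_sums.max())),
        histogram=histogram,
        monotonicity_violations=violations,
    )
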