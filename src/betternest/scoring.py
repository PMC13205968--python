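"""BetterNest Score computation: subscores, modifier matrix, aggregation.

The final index is the unweighted arithmetic mean of eight domain subscores —
lead, air, tobacco, cleaning, pesticides, plastics, produce, personal care —
rounded half-up to one decimal. Question 8 (daily personal-care product
volume) never enters the mean itself; it modifies Question 9 (ingredient
checking) through a fixed 3×3 lookup, so heavy product use attenuates the
credit earned by screening behaviors.

All arithmetic is exact: the mean is an integer sum over 8, and the single
rounding step is round-half-away-from-zero on the tenths digit. Half-up is
forced by the instrument's printed floor: the worst attainable sum is 10,
10/8 = 1.25, and the index floor is 1.3 (banker's rounding would give 1.2).
Higher scores mean lower environmental risk; the attainable range is
1.3–9.4 by construction, leaving room for improvement at the top without
demoralizing at the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .errors import UnknownOption
from .geodata import CountyRecord, GeoTable, air_subscore, lead_subscore, resolve
from .survey import Instrument, ResponseSet

#: The eight mean-contributing domains, in instrument (macro-to-micro) order.
DOMAIN_ORDER: tuple[str, ...] = (
    "lead",
    "air",
    "tobacco",
    "cleaning",
    "pesticides",
    "plastics",
    "produce",
    "personal_care",
)

#: Best attainable subscore per domain (used by the report's contribution
#: summary): band maxima for lead/air, top option scores otherwise.
DOMAIN_MAXIMA: dict[str, int] = {
    "lead": 9, "air": 9, "tobacco": 10, "cleaning": 9,
    "pesticides": 9, "plastics": 10, "produce": 9, "personal_care": 10,
}

#: Q9 personal-care lookup: option -> {Q8 modifier -> subscore}. Each row is
#: increasing in the modifier, so using fewer products never hurts.
MODIFIER_MATRIX: dict[str, dict[int, int]] = {
    "all_the_time": {9: 10, 5: 7, 1: 5},
    "sometimes": {9: 8, 5: 6, 1: 3},
    "never": {9: 7, 5: 3, 1: 1},
}


@dataclass(frozen=True)
class SubscoreVector:
    """The eight domain subscores feeding the mean, each an integer in [1, 10]."""

    lead: int
    air: int
    tobacco: int
    cleaning: int
    pesticides: int
    plastics: int
    produce: int
    personal_care: int

    _ALLOWED = {
        "lead": {1, 3, 5, 7, 9},
        "air": {1, 5, 9},
        "tobacco": {1, 3, 6, 10},
        "cleaning": {2, 6, 9},
        "pesticides": {1, 5, 9},
        "plastics": {1, 3, 7, 10},
        "produce": {2, 5, 9},
        "personal_care": {1, 3, 5, 6, 7, 8, 10},
    }

    def __post_init__(self) -> None:
        for domain in DOMAIN_ORDER:
            value = getattr(self, domain)
            if value not in self._ALLOWED[domain]:
                raise ValueError(
                    f"{domain} subscore {value!r} not attainable "
                    f"(allowed: {sorted(self._ALLOWED[domain])})"
                )

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, d) for d in DOMAIN_ORDER)

    def items(self) -> list[tuple[str, int]]:
        return [(d, getattr(self, d)) for d in DOMAIN_ORDER]


@dataclass(frozen=True)
class BetterNestScore:
    """Final rounded index (one decimal, attainable range 1.3–9.4) + subscores."""

    value: float
    subscores: SubscoreVector

    @property
    def exact_mean(self) -> Fraction:
        return Fraction(sum(self.subscores.as_tuple()), 8)

    @property
    def display(self) -> str:
        return f"{self.value:.1f} / 10"


def personal_care_subscore(q8_modifier: int, q9_option: str) -> int:
    """Personal-care domain subscore from the printed Q8→Q9 lookup matrix."""
    if q9_option not in MODIFIER_MATRIX:
        raise UnknownOption("Q9", q9_option)
    row = MODIFIER_MATRIX[q9_option]
    if q8_modifier not in row:
        raise ValueError(f"Q8 modifier must be one of {{9, 5, 1}}, got {q8_modifier!r}")
    return row[q8_modifier]


def compute_subscores(
    responses: ResponseSet, county: CountyRecord, instrument: Instrument
) -> SubscoreVector:
    """Assemble the eight-domain subscore vector for one respondent.

    Lead and air come from banding the county's measures; tobacco, cleaning,
    pesticides, plastics and produce take the selected option's raw score;
    personal care is looked up from the Q8 modifier and Q9 option. Q8
    contributes no ninth entry.
    """
    raw: dict[str, int] = {}
    for qid in ("Q3", "Q4", "Q5", "Q6", "Q7"):
        question = instrument.question(qid)
        option = question.option(responses.answers[qid])
        raw[question.domain_key] = option.raw_score  # type: ignore[assignment]
    q8 = instrument.question("Q8").option(responses.answers["Q8"])
    return SubscoreVector(
        lead=lead_subscore(county.pct_pre1980_housing),
        air=air_subscore(county.pm25_annual),
        tobacco=raw["tobacco"],
        cleaning=raw["cleaning"],
        pesticides=raw["pesticides"],
        plastics=raw["plastics"],
        produce=raw["produce"],
        personal_care=personal_care_subscore(q8.modifier, responses.answers["Q9"]),
    )


def round_tenths_half_up(total: int) -> float:
    """Round ``total / 8`` half-away-from-zero to one decimal, exactly.

    Works in integer tenths: floor(10*total/8 + 1/2) = (20*total + 8) // 16,
    so no floating-point step can perturb a half-way case.
    """
    return ((20 * total + 8) // 16) / 10.0


def aggregate(subscores: SubscoreVector) -> BetterNestScore:
    """Unweighted eight-domain mean, rounded half-up to the tenths."""
    return BetterNestScore(
        value=round_tenths_half_up(sum(subscores.as_tuple())), subscores=subscores
    )


def score(responses: ResponseSet, geo: GeoTable, instrument: Instrument) -> BetterNestScore:
    """Full pipeline: resolve county → compute subscores → aggregate."""
    county = resolve(responses.postal_code, geo)
    return aggregate(compute_subscores(responses, county, instrument))
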