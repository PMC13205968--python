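"""The nine-question BetterNest instrument: definitions and response validation.

The instrument is packaged static data (``data/instrument.yaml``) validated on
load against the schema below. Q1 selects the life stage (it routes the Q4/Q6
wording but is never scored), Q2 collects a ZIP code scored from county data,
Q3–Q7 carry raw option scores, Q8 carries a modifier that contextualizes Q9,
and Q9 is scored through the Q8-modifier lookup matrix.

Responses arrive as a flat record::

    {"life_stage": "currently_pregnant", "postal_code": "07043",
     "Q3": "never_public", ..., "Q9": "sometimes"}

and are validated into a :class:`ResponseSet`. Partial response sets are
rejected outright: the index is an unweighted eight-domain mean, and silently
averaging fewer domains would change its meaning.
"""

from __future__ import annotations

import re
from enum import Enum
from importlib import resources
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import (
    BadPostalCode,
    InstrumentError,
    MissingAnswer,
    UnknownField,
    UnknownOption,
)

QuestionId = Literal["Q1", "Q2", "Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "Q9"]

#: Questions that must carry an answer in a valid response set. Q1 is captured
#: separately as ``life_stage``; Q2 as ``postal_code``.
ANSWER_QIDS: tuple[str, ...] = ("Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "Q9")

_POSTAL_RE = re.compile(r"^[0-9]{5}$")


class LifeStage(str, Enum):
    """Q1's three audiences; selects the Q4/Q6 wording variant."""

    considering_pregnancy = "considering_pregnancy"
    currently_pregnant = "currently_pregnant"
    child_at_home = "child_at_home"


class OptionDef(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    option_id: str
    text: str
    raw_score: Optional[int] = Field(default=None, ge=1, le=10)
    modifier: Optional[int] = None


class QuestionDef(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    qid: QuestionId
    domain_key: Literal[
        "life_stage",
        "location",
        "tobacco",
        "cleaning",
        "pesticides",
        "plastics",
        "produce",
        "product_volume",
        "ingredient_check",
    ]
    kind: Literal["na", "geo", "raw", "modifier", "matrix"]
    prompt: str
    prompt_child_at_home: Optional[str] = None
    options: tuple[OptionDef, ...]

    @model_validator(mode="after")
    def _check_scoring_kind(self) -> "QuestionDef":
        if self.kind == "raw" and any(o.raw_score is None for o in self.options):
            raise ValueError(f"{self.qid}: raw-scored question with unscored option")
        if self.kind == "modifier":
            mods = [o.modifier for o in self.options]
            if sorted(m for m in mods if m is not None) != [1, 5, 9]:
                raise ValueError(f"{self.qid}: modifier values must be exactly {{1,5,9}}")
        if self.kind in ("na", "geo", "matrix") and any(
            o.raw_score is not None or o.modifier is not None for o in self.options
        ):
            raise ValueError(f"{self.qid}: {self.kind} question must not carry scores")
        return self

    def prompt_for(self, stage: LifeStage) -> str:
        """The wording shown to a respondent at this life stage.

        Only Q4 and Q6 have a child-at-home variant; considering/currently
        pregnant respondents share the pregnancy wording.
        """
        if stage is LifeStage.child_at_home and self.prompt_child_at_home:
            return self.prompt_child_at_home
        return self.prompt

    def option(self, option_id: str) -> OptionDef:
        for o in self.options:
            if o.option_id == option_id:
                return o
        raise UnknownOption(self.qid, option_id)

    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(o.option_id for o in self.options)


class Instrument(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    version: str
    questions: tuple[QuestionDef, ...]

    @model_validator(mode="after")
    def _check_shape(self) -> "Instrument":
        qids = [q.qid for q in self.questions]
        if qids != [f"Q{i}" for i in range(1, 10)]:
            raise ValueError(f"instrument must hold Q1..Q9 in order, got {qids}")
        kinds = {q.qid: q.kind for q in self.questions}
        expected = {
            "Q1": "na", "Q2": "geo", "Q3": "raw", "Q4": "raw", "Q5": "raw",
            "Q6": "raw", "Q7": "raw", "Q8": "modifier", "Q9": "matrix",
        }
        if kinds != expected:
            raise ValueError(f"question scoring kinds mismatch: {kinds}")
        for q in self.questions:
            if q.kind == "raw":
                scores = [o.raw_score for o in q.options]
                if scores != sorted(scores, reverse=True):
                    raise ValueError(
                        f"{q.qid}: option scores must be non-increasing in display order"
                    )
            if q.kind == "modifier":
                mods = [o.modifier for o in q.options]
                if mods != sorted(mods, reverse=True):
                    raise ValueError(f"{q.qid}: modifiers must be non-increasing")
            if q.prompt_child_at_home is not None and q.qid not in ("Q4", "Q6"):
                raise ValueError(f"{q.qid}: only Q4 and Q6 have life-stage wording variants")
            if len({o.option_id for o in q.options}) != len(q.options):
                raise ValueError(f"{q.qid}: duplicate option ids")
        return self

    def question(self, qid: str) -> QuestionDef:
        for q in self.questions:
            if q.qid == qid:
                return q
        raise KeyError(qid)

    def __getattr__(self, name: str):
        # Convenience accessors instrument.Q3 etc.
        if re.fullmatch(r"Q[1-9]", name):
            return self.question(name)
        return super().__getattr__(name)


class ResponseSet(BaseModel):
    """One respondent's validated answers plus postal code and life stage."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    life_stage: LifeStage
    postal_code: str = Field(pattern=r"^[0-9]{5}$")
    answers: Mapping[str, str]


def load_instrument() -> Instrument:
    """Load and validate the packaged nine-question instrument."""
    raw = resources.files("betternest.data").joinpath("instrument.yaml").read_text("utf-8")
    try:
        return Instrument.model_validate(yaml.safe_load(raw))
    except (ValidationError, ValueError) as exc:
        raise InstrumentError(f"packaged instrument failed validation: {exc}") from exc


def validate_responses(instrument: Instrument, raw: Mapping[str, object]) -> ResponseSet:
    """Validate a flat response record into a :class:`ResponseSet`.

    Raises :class:`MissingAnswer`, :class:`UnknownOption`,
    :class:`BadPostalCode` or :class:`UnknownField`; unknown keys are
    rejected rather than ignored so typos cannot silently drop an answer.
    """
    allowed = {"life_stage", "postal_code", *ANSWER_QIDS}
    for key in raw:
        if key not in allowed:
            raise UnknownField(str(key))

    if "life_stage" not in raw:
        raise MissingAnswer("Q1")
    stage_value = raw["life_stage"]
    try:
        stage = LifeStage(stage_value)
    except ValueError:
        raise UnknownOption("Q1", stage_value) from None

    if "postal_code" not in raw:
        raise MissingAnswer("Q2")
    postal = raw["postal_code"]
    if not isinstance(postal, str) or not _POSTAL_RE.fullmatch(postal):
        raise BadPostalCode(postal)

    answers: dict[str, str] = {}
    for qid in ANSWER_QIDS:
        if qid not in raw or raw[qid] in (None, ""):
            raise MissingAnswer(qid)
        value = raw[qid]
        question = instrument.question(qid)
        if value not in question.option_ids:
            raise UnknownOption(qid, value)
        answers[qid] = str(value)

    return ResponseSet(life_stage=stage, postal_code=postal, answers=answers)
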