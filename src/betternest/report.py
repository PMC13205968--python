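"""Score report assembly and rendering (JSON dict and plain text)."""

from __future__ import annotations

from .recommendations import Recommendation, select_recommendations
from .scoring import DOMAIN_MAXIMA, BetterNestScore
from .survey import Instrument, LifeStage, ResponseSet


def build_report(
    result: BetterNestScore,
    instrument: Instrument,
    factsheet_url: str | None = None,
    include_contributions: bool = False,
) -> dict:
    """Assemble the report payload: score, subscores, three recommendations.

    ``include_contributions`` adds a per-domain table of how far each
    subscore sits below its best attainable value — the "which exposures
    contribute most" summary users asked for; largest gaps first.
    """
    recs = select_recommendations(result.subscores, factsheet_url)
    report = {
        "score": result.value,
        "display": result.display,
        "subscores": dict(result.subscores.items()),
        "recommendations": [_rec_dict(r) for r in recs],
        "instrument_version": instrument.version,
    }
    if include_contributions:
        gaps = [
            {"domain": d, "subscore": v, "room_to_improve": DOMAIN_MAXIMA[d] - v}
            for d, v in result.subscores.items()
        ]
        gaps.sort(key=lambda g: -g["room_to_improve"])  # stable: ties keep domain order
        report["contributions"] = gaps
    return report


def _rec_dict(rec: Recommendation) -> dict:
    return {
        "domain": rec.domain_key,
        "subscore": rec.subscore,
        "text": rec.text,
        "link": rec.link_slot,
    }


def render_text(report: dict) -> str:
    """Plain-text rendering mirroring the JSON report."""
    lines = [
        f"BetterNest Score: {report['display']}",
        "(higher scores mean lower environmental risk)",
        "",
        "Domain subscores:",
    ]
    for domain, value in report["subscores"].items():
        lines.append(f"  {domain:<14} {value:>2}")
    lines += ["", "Your top three recommendations:"]
    for i, rec in enumerate(report["recommendations"], start=1):
        lines.append(f"  {i}. [{rec['domain']}] {rec['text']}")
    if "contributions" in report:
        lines += ["", "What contributes most to your score (largest room to improve first):"]
        for gap in report["contributions"]:
            lines.append(
                f"  {gap['domain']:<14} subscore {gap['subscore']:>2}, "
                f"room to improve {gap['room_to_improve']}"
            )
    return "\n".join(lines) + "\n"


def wording_for(instrument: Instrument, stage: LifeStage) -> dict[str, str]:
    """The per-question prompt texts a respondent at this life stage saw."""
    return {q.qid: q.prompt_for(stage) for q in instrument.questions}


def responses_record(responses: ResponseSet) -> dict:
    """Flat JSON-ready record, re-scoreable via ``validate_responses``."""
    return {
        "life_stage": responses.life_stage.value,
        "postal_code": responses.postal_code,
        **dict(responses.answers),
    }
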