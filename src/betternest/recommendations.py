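"""Personalized recommendations: the three lowest-scoring domains.

The three domains with the lowest subscores (lowest = most risk) are
selected and returned in ascending-subscore order; ties break by instrument
order (macro-to-micro), so a tie favors the broader environmental domain.
Message texts follow motivational-interviewing framing: non-judgmental,
autonomy-supportive, never fear-based — enforced here by a small lexicon
blocklist — and every message ends with a factsheet pointer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .scoring import SubscoreVector

#: Default link slot: the literal placeholder the launched tool prints.
DEFAULT_LINK_SLOT = "link to factsheets"

#: Fear-framing lexicon recommendations must never contain (case-insensitive).
TONE_BLOCKLIST: tuple[str, ...] = (
    "danger",
    "deadly",
    "poison",
    "toxic to your baby",
    "harm your baby",
    "warning",
    "beware",
)


@dataclass(frozen=True)
class Recommendation:
    domain_key: str
    subscore: int
    text: str
    link_slot: str


@lru_cache(maxsize=1)
def _templates() -> dict[str, dict]:
    raw = resources.files("betternest.data").joinpath("templates.yaml").read_text("utf-8")
    return yaml.safe_load(raw)


def is_canonical(domain_key: str) -> bool:
    """True for the domains whose template is the launched tool's verbatim text."""
    return bool(_templates()[domain_key]["canonical"])


def render(domain_key: str, subscore: int, factsheet_url: str | None = None) -> Recommendation:
    """Render the packaged template for one domain.

    ``factsheet_url`` fills the link slot; by default the literal
    placeholder "link to factsheets" is kept, matching the launched wording.
    """
    templates = _templates()
    if domain_key not in templates:
        raise KeyError(f"no recommendation template for domain {domain_key!r}")
    link = factsheet_url if factsheet_url is not None else DEFAULT_LINK_SLOT
    text = templates[domain_key]["text"].format(factsheet_url=link)
    lowered = text.lower()
    for phrase in TONE_BLOCKLIST:
        if phrase in lowered:
            raise ValueError(
                f"template for {domain_key!r} violates tone policy (contains {phrase!r})"
            )
    return Recommendation(domain_key=domain_key, subscore=subscore, text=text, link_slot=link)


def select_domains(subscores: SubscoreVector) -> list[str]:
    """The three lowest-scoring domains, ascending, instrument-order ties."""
    ordered = sorted(subscores.items(), key=lambda item: item[1])  # stable: keeps DOMAIN_ORDER ties
    return [domain for domain, _ in ordered[:3]]


def select_recommendations(
    subscores: SubscoreVector, factsheet_url: str | None = None
) -> list[Recommendation]:
    """Exactly three recommendations for the three most at-risk domains."""
    values = dict(subscores.items())
    return [
        render(domain, values[domain], factsheet_url)
        for domain in select_domains(subscores)
    ]
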