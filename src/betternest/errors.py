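"""Exception taxonomy for the BetterNest scoring pipeline.

Validation errors (bad survey responses) and geodata errors (postal code /
CSV problems) are kept distinct so the CLI can map them to different exit
codes. All exceptions carry enough context to name the offending field.
"""

from __future__ import annotations


class BetterNestError(Exception):
    """Base class for all package errors."""


class ResponseValidationError(BetterNestError):
    """A submitted response set violates the instrument's contract."""


class MissingAnswer(ResponseValidationError):
    def __init__(self, qid: str):
        self.qid = qid
        super().__init__(f"missing answer for required question {qid}")


class UnknownOption(ResponseValidationError):
    def __init__(self, qid: str, value: object):
        self.qid = qid
        self.value = value
        super().__init__(f"{qid}: {value!r} is not a valid option id")


class BadPostalCode(ResponseValidationError):
    def __init__(self, value: object):
        self.value = value
        super().__init__(
            f"postal code {value!r} is not a 5-digit ZIP code (expected ^[0-9]{{5}}$)"
        )


class UnknownField(ResponseValidationError):
    def __init__(self, key: str):
        self.key = key
        super().__init__(f"unknown field {key!r} in response record")


class GeoError(BetterNestError):
    """Problems resolving or loading county environmental data."""


class UnknownPostalCode(GeoError):
    def __init__(self, postal_code: str):
        self.postal_code = postal_code
        super().__init__(
            f"postal code {postal_code!r} has no county in the crosswalk; "
            "cannot score lead/air domains without county data"
        )


class MalformedGeoCSV(GeoError):
    def __init__(self, path: str, detail: str, row: int | None = None):
        self.path = path
        self.row = row
        where = f"{path}" + (f", row {row}" if row is not None else "")
        super().__init__(f"malformed geodata CSV ({where}): {detail}")


class DanglingCrosswalk(GeoError):
    def __init__(self, postal_code: str, county_id: str):
        self.postal_code = postal_code
        self.county_id = county_id
        super().__init__(
            f"crosswalk maps {postal_code!r} to county {county_id!r}, "
            "which is absent from the counties table"
        )


class InstrumentError(BetterNestError):
    """The packaged instrument definition fails its own schema."""
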