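"""Exception hierarchy for airwaymorph."""


class AirwayMorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AirwayMorphError):
    """A value violates a documented invariant (e.g. nonpositive diameter)."""


class FormatError(AirwayMorphError):
    """An input table cannot be parsed (missing column, bad dialect)."""


class IntegrityError(AirwayMorphError):
    """A structural inconsistency: duplicate keys, dangling parents, cycles."""
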