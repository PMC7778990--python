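"""Exception hierarchy for the toolkit."""


class TboxKitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(TboxKitError):
    """A file could not be parsed (message names the offending record/line)."""


class StructureFormatError(TboxKitError):
    """A secondary-structure string or alignment is malformed or inconsistent."""


class UnsupportedStructureError(TboxKitError):
    """A structure is syntactically valid but outside the supported class
    (e.g. pseudoknotted)."""


class WindowError(TboxKitError):
    """The specifier window cannot be placed (bulge too close to the 5' end)."""


class FixtureSpecError(TboxKitError):
    """A synthetic-fixture specification is internally inconsistent."""
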