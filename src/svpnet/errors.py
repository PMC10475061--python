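"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class SvpnetError(Exception):
    """Base class for all package errors."""


class DataError(SvpnetError):
    """Problem with user-supplied data (empty mask, bad file, empty split)."""


class GeometryError(DataError):
    """Geometry constraint violated (e.g. disc not interior to the frame)."""


class ContractError(SvpnetError):
    """Interface contract violated (shapes, frame counts, config values)."""


class NoDiscFoundError(DataError):
    """The localizer produced no foreground pixels in any frame."""
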