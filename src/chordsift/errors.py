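"""Exception hierarchy shared across the package."""


class ChordsiftError(Exception):
    """Base class for package errors."""


class FixtureError(ChordsiftError):
    """A bundled or user-supplied variant table could not be loaded."""


class ConfigurationError(ChordsiftError):
    """A configuration document (panel, filter, run) is invalid."""


class InputError(ChordsiftError):
    """An input value violates a documented precondition."""
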