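"""Exception hierarchy.

Exit-code mapping used by the CLI: input/format problems -> 2, model-state
problems -> 3.
"""


class PetsegError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PetsegError):
    """Missing files, malformed images, invalid parameter values."""

    exit_code = 2


class FormatError(InputError):
    """A file exists but is not in the expected format (e.g. 4D NIfTI)."""


class AlignmentError(InputError):
    """Grids that must share shape/spacing do not."""


class SizeError(InputError):
    """A lesion does not fit in the requested bounding box."""


class ConfigError(InputError):
    """Inconsistent phantom or training configuration."""


class StateError(PetsegError):
    """Operation requires a trained/configured model that is absent."""

    exit_code = 3
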