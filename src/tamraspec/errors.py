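"""Exception hierarchy.

``TamraspecError`` is the common base; callers that only care about
"this input was bad" vs "this package is broken" can catch
``InputError`` vs anything else.
"""


class TamraspecError(Exception):
    """Base class for all package errors."""


class InputError(TamraspecError, ValueError):
    """Invalid user-supplied value or file (exit code 2 in the CLI)."""


class DomainError(InputError):
    """A numeric argument lies outside the operation's domain."""


class GridError(InputError):
    """Wavelength grids are malformed or incompatible."""


class NoPeakError(InputError):
    """Peak detection on a spectrum with no usable maximum."""


class GeometryError(InputError):
    """Degenerate Cartesian geometry (e.g. collinear torsion atoms)."""


class CoverageError(InputError):
    """Sample values fall outside the supplied bin coverage."""


class ConfigError(InputError):
    """Invalid run or broadening configuration."""


class FormatError(InputError):
    """Structurally invalid input file."""


class SchemaError(FormatError):
    """A delimited file is missing required columns."""


class ParseError(FormatError):
    """Unparseable content; carries a location when known."""


class IntegrityError(TamraspecError):
    """Packaged calibration data failed its checksum."""
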