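"""Exception hierarchy. Every error raised by the package derives from PocketPCAError."""


class PocketPCAError(Exception):
    """Base class for all pocketpca errors."""


class AlphabetError(PocketPCAError):
    """A sequence contains a symbol outside the 20-amino-acid + gap alphabet."""


class AlignmentShapeError(PocketPCAError):
    """Alignment rows are not all the same length."""


class ContractError(PocketPCAError):
    """An operation was called with arguments violating its contract."""


class InsufficientDataError(PocketPCAError):
    """Too few sequences to estimate a covariance (M < 2)."""


class StructureParseError(PocketPCAError):
    """A structure file could not be parsed."""


class SelectionError(PocketPCAError):
    """An atom/residue selection matched nothing."""


class MappingError(PocketPCAError):
    """A structure residue could not be mapped to an alignment column."""


class OrientationError(PocketPCAError):
    """An axis-orientation feature matched no records."""


class GeometryError(PocketPCAError):
    """A structural operation is impossible on the given residue/atoms."""


class SyntheticSpecError(PocketPCAError):
    """A synthetic-data specification is internally inconsistent."""


class ConfigError(PocketPCAError):
    """A pipeline configuration file is invalid."""
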