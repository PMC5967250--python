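"""Exception hierarchy for distalblock."""


class DistalBlockError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(DistalBlockError):
    """A coordinate file contained no standard protein ATOM records."""


class DegenerateGeometryError(DistalBlockError):
    """A torsion/frame computation was requested on (near-)collinear atoms."""


class BuildError(DistalBlockError):
    """The conformer builder was asked for something it cannot build."""


class GenerationError(DistalBlockError):
    """Ensemble sampling could not produce a clash-free conformer within the retry cap."""


class EmptyProfileError(DistalBlockError):
    """A density profile or histogram was requested for zero observations."""


class NormalizationError(DistalBlockError):
    """A reference profile with zero peak density cannot normalize anything."""


class UndefinedRatioError(DistalBlockError):
    """Population ratio against an empty histogram cell."""


class RecordsParseError(DistalBlockError):
    """A feature-record table could not be parsed."""
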