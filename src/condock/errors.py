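"""Exception hierarchy for the condock package."""


class CondockError(Exception):
    """Base class for all condock-specific errors."""


class FormatError(CondockError):
    """A file could not be parsed in the expected format."""


class EmptyStructureError(CondockError):
    """No polymer residues remained after filtering a structure."""


class PoseEnergyError(CondockError):
    """A docked pose lacks a parseable, finite energy score."""


class MappingError(CondockError):
    """Conservation scores could not be mapped onto the structure."""


class EmptySiteError(CondockError):
    """A binding site with zero residues cannot be scored."""


class MissingConservationError(CondockError):
    """No conservation value is available for any site residue."""


class ScenarioError(CondockError):
    """A synthetic scenario could not be generated as specified."""
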