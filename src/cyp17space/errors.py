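"""Exception hierarchy shared across the pipeline."""


class Cyp17SpaceError(Exception):
    """Base class for all package errors."""


class StructureError(Cyp17SpaceError, ValueError):
    """A SMILES/SDF structure could not be parsed or processed."""


class ConfigurationError(Cyp17SpaceError, ValueError):
    """Invalid user configuration (columns, fractions, widths, groups...)."""


class EmptyDatasetError(Cyp17SpaceError, ValueError):
    """An operation received no usable records."""


class CapabilityError(Cyp17SpaceError, RuntimeError):
    """A requested capability needs extra data (e.g. a substructure key table)."""


class DegenerateFeaturesError(Cyp17SpaceError, ValueError):
    """Feature selection removed every column."""


class DegenerateLabelError(Cyp17SpaceError, ValueError):
    """Training data contains a single class."""
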