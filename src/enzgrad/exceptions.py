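"""Exception hierarchy for enzgrad."""


class EnzgradError(Exception):
    """Base class for all enzgrad errors."""


class StructureParseError(EnzgradError):
    """The PDB text could not be parsed into any usable residues."""


class ChainNotFoundError(EnzgradError, KeyError):
    """A requested chain is absent from the structure."""


class CenterError(EnzgradError):
    """A residue has neither side-chain atoms nor a C-alpha."""


class AnnotationError(EnzgradError):
    """A catalytic-residue annotation does not resolve against the structure."""


class RateFormatError(EnzgradError):
    """A rate file is malformed (bad line or non-consecutive positions)."""


class NormalizationError(EnzgradError):
    """Rates cannot be normalized (zero mean)."""


class MetricError(EnzgradError):
    """A per-site metric cannot be computed (coincident centers, bad radius...)."""


class ModelError(EnzgradError):
    """A linear model cannot be fit (rank deficiency, too few sites...)."""


class RecoveryError(EnzgradError):
    """The active-site scan cannot run (constant rates, empty input...)."""


class PackingError(EnzgradError):
    """Synthetic structure generation failed to place all residues."""


class SchemaError(EnzgradError):
    """A tabular input does not match the expected column schema."""
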