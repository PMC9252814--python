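"""Exception hierarchy for phdelta."""


class PhdeltaError(Exception):
    """Base class for all phdelta errors."""


class UnknownResidueError(PhdeltaError):
    """A sequence contains a residue code outside the accepted alphabet."""


class SequenceError(PhdeltaError):
    """Invalid protein sequence input (empty, duplicate ids, over cap)."""


class StructureParseError(PhdeltaError):
    """PDB input could not be parsed into a usable structure model."""


class PkaParseError(PhdeltaError):
    """A pKa predictor output file could not be parsed or matched."""


class PredictorNotFoundError(PhdeltaError):
    """The external pKa predictor executable is not available."""


class PredictorRunError(PhdeltaError):
    """The external pKa predictor ran but failed."""


class ConfigError(PhdeltaError):
    """Invalid run configuration (pH range, thresholds, missing inputs)."""
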