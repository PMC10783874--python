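"""Exception hierarchy for the package.

Every failure mode raised by the library derives from :class:`BatmanNetError`
so callers can catch one base class at CLI boundaries.
"""


class BatmanNetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BatmanNetError):
    """SMILES string could not be parsed into a molecular graph."""


class SchemaError(BatmanNetError):
    """Feature schema does not match the graph or checkpoint it is used with."""


class MaskError(BatmanNetError):
    """Mask plan indices are inconsistent with the graph they are applied to."""


class ConfigError(BatmanNetError):
    """Invalid model or training configuration."""


class ShapeError(BatmanNetError):
    """Array shapes inconsistent with the declared configuration."""


class NumericalError(BatmanNetError):
    """Non-finite values encountered where finite numbers are required."""


class EncodeError(BatmanNetError):
    """Encoder invoked on an empty visible set."""


class ReorderError(BatmanNetError):
    """Feature reordering received colliding or out-of-range positions."""


class LossError(BatmanNetError):
    """Reconstruction loss requested with nothing to reconstruct."""


class DataError(BatmanNetError):
    """Empty or unusable training corpus."""


class ReadoutError(BatmanNetError):
    """Readout of an empty embedding set."""


class PerturbError(BatmanNetError):
    """Structural perturbation impossible (e.g. single-atom molecule)."""


class FormatError(BatmanNetError):
    """Malformed input file (missing columns, bad header)."""


class ChecksumError(BatmanNetError):
    """Checkpoint payload does not match its recorded checksum."""
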