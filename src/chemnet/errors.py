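"""Exception hierarchy for chemnet.

All package errors derive from :class:`ChemnetError` so callers can catch one
base type at CLI boundaries.
"""


class ChemnetError(Exception):
    """Base class for all chemnet errors."""


class ConfigurationError(ChemnetError):
    """Invalid configuration: bad probabilities, unknown linkage, mismatched
    architecture fields, vocabulary hash mismatch, negative augmentation k."""


class FormatError(ChemnetError):
    """Malformed input file: missing columns, non-integer scores."""


class InputError(ChemnetError):
    """Semantically invalid input to an operation (too few profiles,
    single-class training set, length mismatches)."""


class SmilesParseError(ChemnetError):
    """SMILES string failed to parse; carries the offending input."""

    def __init__(self, smiles: str, message: str = "could not parse SMILES"):
        self.smiles = smiles
        super().__init__(f"{message}: {smiles!r}")


class TokenizationError(ChemnetError):
    """SMILES could not be tokenized (e.g. unmatched bracket)."""


class LengthError(ChemnetError):
    """Sequence exceeds the configured maximum length."""


class ClusterLookupError(ChemnetError):
    """Unknown cluster id."""
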