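"""Exception hierarchy shared across the package."""


class ElectrumError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedElementError(ElectrumError):
    """Raised for element symbols missing from the configuration table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unsupported element symbol: {symbol!r}")


class SmilesParseError(ElectrumError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class MissingMetalError(ElectrumError):
    """Raised when a complex contains no atom from the metal set."""


class MultinuclearError(ElectrumError):
    """Raised when a complex contains more than one metal atom."""


class SchemaError(ElectrumError):
    """Raised when a tabular input lacks a required column."""
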