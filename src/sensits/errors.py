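"""Exception hierarchy shared across the package."""


class SensitsError(Exception):
    """Base class for all package-specific errors."""


class MoleculeParseError(SensitsError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class ValidationError(SensitsError, ValueError):
    """An input value violates a documented precondition."""


class SchemaError(SensitsError, ValueError):
    """A tabular input file is missing mandatory columns."""

    def __init__(self, missing: list[str], path: str = ""):
        self.missing = list(missing)
        where = f" in {path}" if path else ""
        super().__init__(f"missing mandatory column(s){where}: {', '.join(self.missing)}")


class TableRowError(SensitsError, ValueError):
    """A specific row of a tabular input could not be interpreted."""

    def __init__(self, row_index: int, detail: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {detail}")
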