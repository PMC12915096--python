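"""Exception hierarchy shared across the toolkit."""


class FluorscreenError(Exception):
    """Base class for all toolkit errors."""


class InvalidStructureError(FluorscreenError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"invalid structure: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class DomainError(FluorscreenError):
    """A numeric argument lies outside its admissible domain."""


class ConfigurationError(FluorscreenError):
    """An invalid or inconsistent configuration value."""


class TaskMismatchError(ConfigurationError):
    """A model configured for one task was used for the other."""


class DataError(FluorscreenError):
    """Input data unusable for the requested operation (empty, too short...)."""


class DivergenceError(FluorscreenError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class FitFailureError(FluorscreenError):
    """Nonlinear fit failed to converge from every starting point."""


class DegenerateFitError(FitFailureError):
    """The data carry no signal for the model (e.g. flat titration curve)."""
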