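"""Exception hierarchy shared across the package."""


class PharmnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PharmnetError):
    """A file could not be interpreted in the requested format."""


class ChemistryError(PharmnetError):
    """A molecular structure could not be parsed or processed."""


class EmbeddingError(ChemistryError):
    """3-D conformer generation failed for a molecule."""


class ModelError(PharmnetError):
    """A pharmacophore model violates its invariants (e.g. infeasible
    distance matrix)."""


class OrientationError(PharmnetError):
    """Too few points to define a rigid superposition."""


class DomainError(PharmnetError):
    """An input value lies outside the operation's domain."""


class ConfigError(PharmnetError):
    """Unknown or invalid configuration key."""


class NetValidationError(PharmnetError):
    """A Petri net failed structural validation."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("net validation failed: " + "; ".join(self.violations))


class StructuralError(PharmnetError):
    """A rate law is incompatible with the net structure."""


class SimulationError(PharmnetError):
    """The ODE solver did not converge."""


class GenerationError(PharmnetError):
    """Synthetic-data generation could not satisfy its constraints."""
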