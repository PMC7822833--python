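"""Exception types shared across the pipeline."""


class MacroGDError(Exception):
    """Base class for all package-specific errors."""


class NoRecordsRetainedError(MacroGDError):
    """Inclusion filtering removed every record."""


class ZeroVarianceError(MacroGDError):
    """A quantity that must vary is constant (e.g. heterozygosity within a marker type)."""


class DomainError(MacroGDError):
    """An argument lies outside the mathematical domain of an operation."""


class RankDeficiencyError(MacroGDError):
    """The fixed-effect design matrix is rank deficient; carries the aliased columns."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class ConvergenceError(MacroGDError):
    """The mixed-model optimizer failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


class GeometryError(MacroGDError):
    """Invalid range geometry or a point outside the range beyond tolerance."""


class EnumerationCapError(MacroGDError):
    """Submodel enumeration would exceed the configured cap."""


class ConfigError(MacroGDError):
    """Invalid pipeline or simulation configuration."""
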