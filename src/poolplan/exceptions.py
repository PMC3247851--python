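"""Exception hierarchy for poolplan."""


class PoolplanError(Exception):
    """Base class for all poolplan errors."""


class BeadTableParseError(PoolplanError):
    """A bead-level TSV could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ParameterError(PoolplanError, ValueError):
    """A numeric parameter is outside its valid domain."""


class ConfigurationError(PoolplanError):
    """Inconsistent or incomplete configuration (missing metadata, bad scales map...)."""


class DegenerateStripError(PoolplanError):
    """A strip has no SNP with enough beads to compute a mean frequency."""


class NonNormalizableStripError(PoolplanError):
    """No red-channel scale can bring the strip mean frequency to 0.5."""


class InsufficientOverlapError(PoolplanError):
    """Two frequency tables share too few SNPs (need more than 2) to compare."""


class InsufficientReplicatesError(PoolplanError):
    """Fewer than two replicate arrays: array variance cannot be estimated."""


class MisuseError(PoolplanError):
    """An estimator was called on inputs of the wrong kind (e.g. non-replicate pools)."""


class UnreachableError(PoolplanError):
    """A search target (RSS or power level) cannot be attained."""
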