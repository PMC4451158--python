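"""Exception hierarchy.

Validation errors (bad inputs, malformed files) are distinct from
computation errors (e.g. saturated distances) so callers — and the CLI
exit-code mapping — can treat them differently.
"""


class BarcodeError(Exception):
    """Base class for all package errors."""


class ValidationError(BarcodeError):
    """Input data violates a contract (alphabet, duplicate ids, geometry...)."""


class FastaParseError(ValidationError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class PrimerNotFoundError(ValidationError):
    def __init__(self, which: str, max_mismatch: int):
        self.which = which
        super().__init__(
            f"{which} primer not found within {max_mismatch} mismatch(es)"
        )


class PrimerGeometryError(ValidationError):
    """Primer matches overlap or are out of order on the amplicon."""


class TooShortError(ValidationError):
    """Amplicon shorter than the minimum annotatable length."""


class UndefinedGCError(ValidationError):
    """Region contains no unambiguous A/C/G/T base."""


class ComputationError(BarcodeError):
    """A numeric stage could not produce a finite result."""


class SaturatedDistanceError(ComputationError):
    """K2P logarithm argument non-positive: divergence beyond correction."""

    def __init__(self, P: float, Q: float, pair: tuple[str, str] | None = None):
        self.P, self.Q, self.pair = P, Q, pair
        where = f" for pair {pair}" if pair else ""
        super().__init__(f"saturated K2P distance{where}: P={P:.4f}, Q={Q:.4f}")


class NoOverlapError(ComputationError):
    """No comparable site remains after pairwise deletion."""


class ConfigError(BarcodeError):
    """Infeasible or inconsistent configuration."""
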