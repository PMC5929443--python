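"""Exception hierarchy shared across the package."""


class EmstateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmstateError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ParseError(EmstateError, ValueError):
    """Malformed input file; carries file path and (1-based) line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class SignatureMismatchError(EmstateError, ValueError):
    """No overlap between a gene signature and the expression matrix."""


class PanelMismatchError(EmstateError, ValueError):
    """No qPCR panel gene present in the table."""


class ReferenceSampleError(EmstateError, ValueError):
    """Required 100-cell reference group missing or unusable."""


class GatingDegeneracyError(EmstateError, ValueError):
    """A cytometry channel shows no resolvable bimodality."""


class NumericalDegeneracyError(EmstateError, ValueError):
    """Zero-variance submatrix or otherwise degenerate numerics."""


class ScanDomainError(EmstateError, ValueError):
    """No admissible cutoff in the best-cutoff scan."""


class StratumEmptyError(EmstateError, ValueError):
    """Requested subtype stratum contains no patients."""

    def __init__(self, requested: str, available: dict[str, int]):
        super().__init__(
            f"subtype stratum {requested!r} is empty; available strata: "
            + ", ".join(f"{k} (n={v})" for k, v in sorted(available.items()))
        )
        self.requested = requested
        self.available = available


class UndefinedStatisticError(EmstateError, ValueError):
    """Test statistic undefined (e.g. logrank with zero variance)."""
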