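"""Exception hierarchy shared across the package."""


class CModelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CModelError):
    """A mapped column is absent from the CSV header."""


class ConfigError(CModelError):
    """Invalid simulation or column-mapping configuration."""


class EmptyTableError(CModelError):
    """No classifiable records to tabulate."""


class IncompleteRecordError(CModelError):
    """A record lacks covariates required by the requested model version."""

    def __init__(self, indices):
        self.indices = tuple(sorted(indices))
        super().__init__(
            "missing covariates: " + ", ".join(f"x{i}" for i in self.indices)
        )


class NoModelError(CModelError):
    """Even the smallest model version cannot be computed from the data."""

    def __init__(self, missing_fields):
        self.missing_fields = tuple(sorted(missing_fields))
        super().__init__(
            "fields required by v1.0 are absent: " + ", ".join(self.missing_fields)
        )


class DegenerateInputError(CModelError):
    """Statistical input with a single outcome class or otherwise unusable."""


class SeparationError(CModelError):
    """Perfect separation detected during logistic fitting."""


class RankError(CModelError):
    """Singular or rank-deficient design matrix."""
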