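"""Exception hierarchy shared by the package."""


class FretquantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FretquantError):
    """A parameter set is missing a field required by the requested operation."""


class DomainError(FretquantError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class FitError(FretquantError):
    """A fit failed to converge or the data are degenerate."""


class SchemaError(FretquantError):
    """A file or table does not match the expected layout."""

    def __init__(self, message: str, *, path=None, field=None, row=None):
        self.path, self.field, self.row = path, field, row
        loc = ", ".join(
            f"{k}={v}" for k, v in
            [("file", path), ("field", field), ("row", row)] if v is not None
        )
        super().__init__(f"{message}" + (f" ({loc})" if loc else ""))
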