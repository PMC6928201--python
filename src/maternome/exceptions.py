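"""Exception hierarchy shared across the pipeline."""


class MaternomeError(Exception):
    """Base class for all package errors."""


class FormatError(MaternomeError, ValueError):
    """An input file or table violates its format contract."""


class SchemaError(MaternomeError, ValueError):
    """Result rows do not share a schema / required columns missing."""


class ConfigError(MaternomeError, ValueError):
    """Pipeline configuration is missing or inconsistent."""


class AnalysisError(MaternomeError, ValueError):
    """An analysis precondition is violated (axes mismatch, too few samples, ...)."""
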