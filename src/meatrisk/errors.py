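"""Error taxonomy shared across the package.

Validation failures (bad values, broken invariants) and configuration
failures (missing blocks, unknown strata) are kept distinct so the CLI can
map them to exit codes: 2 for anything a user can fix in a config file,
3 for I/O problems.
"""


class MeatriskError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MeatriskError, ValueError):
    """A domain-type invariant is violated (names the field and the rule)."""


class ConfigurationError(MeatriskError):
    """A config file is missing a required block or references unknown entities."""


class SchemaError(ValidationError):
    """Two objects that must share a stratum layout do not."""


class CalibrationError(ValidationError):
    """Risk calibration received unusable inputs (e.g. zero workers)."""
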