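"""Exception hierarchy shared across the package."""


class ClaimsError(Exception):
    """Base class for all package errors."""


class ConfigError(ClaimsError):
    """A configuration object or file is invalid."""


class SchemaError(ClaimsError):
    """An input table does not match the expected column schema."""


class DataError(ClaimsError):
    """Input data violate an invariant (e.g. cases exceed denominator)."""


class IncompatibleAlgorithmError(ClaimsError):
    """Algorithm variant cannot be applied to the requested cancer site.

    Raised e.g. when a surgery-required variant is applied to prostate
    cancer, for which no surgical confirmatory procedure class is defined.
    """
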