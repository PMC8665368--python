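"""Exception hierarchy shared across the package."""


class MolemstatError(Exception):
    """Base class for all package errors."""


class SchemaError(MolemstatError, ValueError):
    """Invalid schema configuration or unknown class label."""


class DataError(MolemstatError, ValueError):
    """Malformed or inconsistent ratings data."""


class InsufficientDataError(MolemstatError, ValueError):
    """Not enough ratings to compute the requested statistic."""


class DegenerateScaleError(MolemstatError, ValueError):
    """The rating scale collapses to a single effective category."""


class ConstructionError(MolemstatError, ValueError):
    """A deterministic fixture cannot be built from the given counts."""
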