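"""Exception hierarchy shared across the audit pipeline."""


class AfispError(Exception):
    """Base class for all package errors."""


class SchemaError(AfispError):
    """A feature schema is inconsistent or a column/feature is undeclared."""


class DataError(AfispError):
    """Input data violates a declared contract (bad outcome coding, unknown
    category value, scores outside [0, 1], ...)."""


class ConfigurationError(AfispError):
    """A run configuration is infeasible (e.g. more folds than rows)."""


class UndefinedMetricError(AfispError):
    """The requested metric is undefined on the given rows, e.g. AUROC on a
    single-class sample."""


class DegenerateEffectError(AfispError):
    """An effect size is undefined because the pooled spread is zero (or an
    embedding input is constant)."""
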