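"""Exception hierarchy shared across the package.

All errors raised by dxcover derive from :class:`DxCoverError` so callers can
catch the package's failures with a single except clause.
"""


class DxCoverError(Exception):
    """Base class for all dxcover errors."""


class LoadError(DxCoverError):
    """A required input file or table is missing or unreadable."""


class SchemaError(DxCoverError):
    """A table is present but its columns do not match the dialect."""


class IntegrityError(DxCoverError):
    """A reference (finding/explanation id) does not resolve."""


class ValidationError(DxCoverError):
    """A knowledge-base invariant is violated in strict loading."""


class EncodingError(DxCoverError):
    """A textual frequency description could not be mapped to a weight."""


class QueryError(DxCoverError):
    """A patient case refers to findings unknown to the knowledge base."""


class IneligibleExplanationError(DxCoverError):
    """An operation required an eligible explanation but got a filtered one."""


class ConfigError(DxCoverError):
    """A synthetic-data configuration is infeasible or inconsistent."""


class GenerationError(DxCoverError):
    """Synthetic data cannot be generated from the given knowledge base."""
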