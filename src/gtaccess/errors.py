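"""Exception hierarchy shared across the pipeline."""


class GtAccessError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GtAccessError, ValueError):
    """Invalid user-supplied configuration (probabilities, lexicon, paths)."""


class ContractError(GtAccessError, ValueError):
    """An operation was called with inputs violating its preconditions."""


class BackendError(GtAccessError, RuntimeError):
    """A classifier backend failed to produce a response."""
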