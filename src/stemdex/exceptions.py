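"""Exception hierarchy for stemdex."""


class StemdexError(Exception):
    """Base class for all stemdex errors."""


class ConfigError(StemdexError):
    """Invalid configuration (bad parameter values, missing files, schema violations)."""


class DataError(StemdexError):
    """Invalid or insufficient input data (non-finite values, missing genes, bad purity)."""


class AnalysisError(StemdexError):
    """A statistical stage cannot be run on the given inputs (empty groups, degenerate splits)."""
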