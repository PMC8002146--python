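"""Exception types shared across the package."""


class ZmanovaError(Exception):
    """Base class for package errors."""


class ConfigError(ZmanovaError):
    """A configuration file or column mapping is invalid."""


class HarmonizationError(ZmanovaError):
    """Summary statistics could not be reconciled with the reference map.

    Raised, for example, when the rsid intersection with the reference is
    empty — the usual cause is summary statistics on a different genome
    assembly than the reference SNP map.
    """


class IllConditionedError(ZmanovaError):
    """The trait correlation matrix is numerically near-singular."""
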