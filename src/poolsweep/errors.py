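"""Exception hierarchy for the poolsweep package."""


class PoolsweepError(Exception):
    """Base class for all package-specific errors."""


class PileupParseError(PoolsweepError):
    """A pileup column could not be decoded; the message names chrom:pos."""


class ConfigError(PoolsweepError):
    """Invalid configuration (bad thresholds, missing paths, empty whitelist)."""


class DataError(PoolsweepError):
    """Inconsistent input data (unsorted sites, mixed chromosomes, missing chrom)."""
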