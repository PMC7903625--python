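"""Exception hierarchy shared across the toolkit."""


class VarbenchError(Exception):
    """Base class for all toolkit errors."""


class ParseError(VarbenchError):
    """A malformed input file (VCF/BED/TSV); message names the location."""


class ConfigurationError(VarbenchError):
    """Inconsistent or impossible run configuration."""


class ReferenceMismatchError(VarbenchError):
    """A variant's REF allele disagrees with the reference sequence."""


class InconsistentClusterError(VarbenchError):
    """Two alleles assigned to one haplotype have overlapping footprints."""
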