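"""Exception hierarchy shared across the pipeline stages."""


class MultikError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(MultikError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(MultikError):
    """A malformed input record (FASTQ/FASTA/SAM/BLAST/RepeatMasker)."""


class IntegrityError(MultikError):
    """Cross-file inconsistency, e.g. a declared length that disagrees with
    the sequence, or an alignment referencing an unknown transcript."""


class DomainError(MultikError):
    """An operation applied to a value outside its mathematical domain."""
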