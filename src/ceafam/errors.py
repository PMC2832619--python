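"""Exception hierarchy shared across the package."""


class CeafamError(Exception):
    """Base class for all package errors."""


class FormatError(CeafamError):
    """Malformed input file (FASTA, TSV, newick)."""


class IdentityError(CeafamError):
    """Duplicate or empty sequence identifier."""


class AlignmentError(CeafamError):
    """Rows of unequal length or otherwise unusable alignment."""


class ExcludedCodonError(CeafamError):
    """Stop or ambiguous codon passed where a sense codon is required."""


class SaturationError(CeafamError):
    """Observed proportion outside the domain of a distance correction."""


class EmptyOverlapError(CeafamError):
    """No usable codon/site shared by a sequence pair."""


class UndefinedSummaryError(CeafamError):
    """No pair with a defined omega to summarize."""


class InapplicableTestError(CeafamError):
    """Statistic carries no information (e.g. identical sequences)."""


class ContractError(CeafamError):
    """Caller violated an operation precondition."""


class StructureError(CeafamError):
    """Gene model misses a required exon or is malformed."""


class ConfigError(CeafamError):
    """Invalid run or simulation configuration."""


class GenerationError(CeafamError):
    """Synthetic-data rejection sampling exhausted its attempt budget."""


class ParseError(FormatError):
    """Unparseable newick text."""
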