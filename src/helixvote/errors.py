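"""Exception hierarchy for helixvote."""


class HelixvoteError(Exception):
    """Base class for all helixvote errors."""


class FastaParseError(HelixvoteError):
    """A FASTA file could not be parsed; the message names the offending line."""


class ValidationError(HelixvoteError):
    """An input object violates a domain invariant (alphabet, ids, spans...)."""


class ConfigurationError(HelixvoteError):
    """Operations were combined with inconsistent or missing configuration."""
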