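"""Exception hierarchy shared across the package."""


class SynthActionError(Exception):
    """Base class for all package errors."""


class EmptyInput(SynthActionError):
    """Input text was empty after trimming."""


class UnknownAction(SynthActionError):
    """A clause keyword is not one of the 28 action types (strict mode)."""


class MalformedClause(SynthActionError):
    """A clause keyword is valid but its payload violates the action grammar."""


class InvalidSequence(SynthActionError):
    """An action sequence violates a structural invariant."""


class ConfigError(SynthActionError):
    """A configuration value is missing, inconsistent, or out of range."""


class SizeError(SynthActionError):
    """A dataset is too small for the requested operation."""


class AugmentError(SynthActionError):
    """A slot named in a pair's provenance is absent from one side."""


class CorpusTooSmall(SynthActionError):
    """Tokenizer training corpus below the minimum size."""


class VocabTooLarge(SynthActionError):
    """Requested subword vocabulary exceeds the attainable piece count."""


class InvalidId(SynthActionError):
    """A token id outside the tokenizer vocabulary was passed to decode."""


class DataError(SynthActionError):
    """Training data violates a precondition (empty split, bad labels...)."""


class TokenizerMismatch(SynthActionError):
    """Model and tokenizer vocabularies are inconsistent."""


class LengthMismatch(SynthActionError):
    """Paired evaluation inputs differ in length."""


class EmptyCorpus(SynthActionError):
    """An evaluation corpus has no segments."""


class EmptyLabels(SynthActionError):
    """A label collection is empty."""


class EmptyText(SynthActionError):
    """A metric received an untokenizable empty text."""


class DictError(SynthActionError):
    """A name->SMILES dictionary file is malformed."""


class StageError(SynthActionError):
    """A pipeline stage failed; carries the stage name and record id."""

    def __init__(self, stage: str, record_id: str, message: str):
        super().__init__(f"[{stage}] {record_id}: {message}")
        self.stage = stage
        self.record_id = record_id
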