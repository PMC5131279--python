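"""Exception hierarchy shared across g4kit modules."""


class G4KitError(Exception):
    """Base class for all g4kit errors."""


class AlphabetError(G4KitError):
    """A sequence contains a character outside the allowed nucleotide alphabet."""


class FastaParseError(G4KitError):
    """A FASTA file is structurally malformed."""


class StoreValidationError(G4KitError):
    """An interaction record (or a file of them) violates the store schema."""
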