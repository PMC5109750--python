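"""Package exception hierarchy.

Every validation failure raises a named subclass of :class:`NitrocodonError`
so callers (and the CLI) can distinguish bad input data from usage errors.
"""


class NitrocodonError(Exception):
    """Base class for all package errors."""


class InvalidCodonError(NitrocodonError):
    """A codon is not three characters over {A, C, G, T, U}."""


class InvalidResidueError(NitrocodonError):
    """An amino-acid letter is not one of the 20 standard residues."""


class InvalidSequenceError(NitrocodonError):
    """A nucleotide sequence contains a character outside {A, C, G, T, U, -}."""


class EmptyInputError(NitrocodonError):
    """An operation received no usable records or values."""


class DegenerateDataError(NitrocodonError):
    """Input is structurally valid but carries no information for the operation
    (e.g. all paired differences zero, constant sample for a density)."""


class MissingTaiError(NitrocodonError):
    """A model variant includes translational selection but no tAI table was given."""


class TranslationMismatchError(NitrocodonError):
    """A CDS does not translate to the protein row it should back-fill."""


class UnknownSpeciesError(NitrocodonError):
    """A species label is absent from the group assignment."""


class ScoreLengthError(NitrocodonError):
    """A per-column score vector does not match the alignment width."""
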