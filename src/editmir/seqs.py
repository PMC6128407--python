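"""Small sequence utilities shared across modules."""

from __future__ import annotations

from .errors import AlphabetError

DNA_ALPHABET = frozenset("ACGT")
RNA_DNA_ALPHABET = frozenset("ACGUT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


def check_alphabet(seq: str, alphabet: frozenset = RNA_DNA_ALPHABET, what: str = "sequence") -> str:
    """Uppercase *seq* and raise :class:`AlphabetError` on foreign characters."""
    seq = seq.upper()
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(
            f"{what} contains characters outside {{{','.join(sorted(alphabet))}}}: "
            f"{','.join(sorted(bad))}"
        )
    return seq
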