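"""Seed-match scanning of paired edited/unedited windows.

The core comparison of the analysis: every miRNA's 7-nt seed (mature
positions 2-8) is reverse-complemented into DNA space and slid across each
201-nt window in both editing states, recording every offset at which the
seed reverse-complement occurs exactly.  A seed match in the mRNA sense
strand is by definition an occurrence of the seed's reverse complement, so
one scan direction suffices once windows are transcript-sense.

Two count modes exist:

``center-overlapping``
    Only occurrences whose 7-mer covers the central (edited) base are
    counted — offsets in ``[center-6, center]``.  This is the mode in which
    a single A→G change can create or destroy a match, and the default.
``all-positions``
    Every occurrence anywhere in the window is counted.

Matching is exact string equality after uppercasing; ``N`` never matches
(it is outside the match alphabet).  No G:U wobble pairing is considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import (
    InvalidParameterError,
    MirnaLookupError,
    SequenceLengthError,
)
from .seqs import RNA_DNA_ALPHABET, check_alphabet, revcomp, rna_to_dna

SEED_START = 2  # 1-based position on the mature miRNA
SEED_LENGTH = 7

CENTER_OVERLAPPING = "center-overlapping"
ALL_POSITIONS = "all-positions"
COUNT_MODES = (CENTER_OVERLAPPING, ALL_POSITIONS)

STATES = ("unedited", "edited")


def seed_rc(mature: str, seed_start: int = SEED_START, seed_length: int = SEED_LENGTH) -> str:
    """Reverse complement (DNA alphabet) of the seed region of a mature miRNA.

    Parameters
    ----------
    mature
        Mature miRNA sequence, RNA or DNA alphabet, any case.
    seed_start, seed_length
        1-based start and length of the seed on the mature sequence;
        defaults give the canonical positions 2-8 heptamer.
    """
    mature = check_alphabet(mature, RNA_DNA_ALPHABET, "mature sequence")
    if len(mature) < seed_start + seed_length - 1:
        raise SequenceLengthError(
            f"mature sequence of length {len(mature)} too short for a "
            f"{seed_length}-nt seed starting at position {seed_start}"
        )
    seed = rna_to_dna(mature[seed_start - 1 : seed_start - 1 + seed_length])
    return revcomp(seed)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA with its derived seed reverse-complement."""

    name: str
    accession: str
    mature: str
    seed_rc: str = field(default="")

    def __post_init__(self):
        if len(self.mature) < 8:
            raise SequenceLengthError(
                f"{self.name}: mature sequence must be >= 8 nt, got {len(self.mature)}"
            )
        if not self.seed_rc:
            object.__setattr__(self, "seed_rc", seed_rc(self.mature))

    @property
    def mature_dna(self) -> str:
        return rna_to_dna(self.mature)


def read_mirna_fasta(path) -> list[MiRNA]:
    """Read a miRBase-style mature FASTA.

    Headers look like ``>hsa-miR-140-3p MIMAT0004597 Homo sapiens ...``;
    the first token is the name, the second (when present) the accession.
    """
    catalog = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        accession = tokens[1] if len(tokens) > 1 else ""
        catalog.append(MiRNA(name=rec.id, accession=accession, mature=str(rec.seq).upper()))
    return catalog


def scan_window(window: str, seed_rc_seq: str) -> list[int]:
    """All 0-based offsets where *seed_rc_seq* occurs exactly in *window*.

    Overlapping occurrences are all reported, in ascending order.
    """
    if len(seed_rc_seq) != SEED_LENGTH:
        raise SequenceLengthError(
            f"seed reverse-complement must be {SEED_LENGTH} nt, got {len(seed_rc_seq)}"
        )
    window = window.upper()
    seed_rc_seq = seed_rc_seq.upper()
    if "N" in seed_rc_seq:
        return []  # N is ambiguity, not a base: it never matches
    offsets = []
    o = window.find(seed_rc_seq)
    while o != -1:
        offsets.append(o)
        o = window.find(seed_rc_seq, o + 1)  # step 1 => overlaps counted
    return offsets


@dataclass
class MatchTable:
    """Per-(miRNA, state) seed-match offsets across a window dataset.

    ``offsets[(name, state)]`` maps window id -> tuple of 0-based match
    offsets; windows without matches are omitted from the inner mapping.
    """

    mode: str
    window_length: int
    center: int
    mirnas: list[str]
    window_ids: list[str]
    offsets: dict[tuple[str, str], dict[str, tuple[int, ...]]]

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)

    def window_offsets(self, mirna: str, state: str, window_id: str) -> tuple[int, ...]:
        self._check(mirna, state)
        return self.offsets.get((mirna, state), {}).get(window_id, ())

    def total(self, mirna: str, state: str) -> int:
        self._check(mirna, state)
        return sum(len(v) for v in self.offsets.get((mirna, state), {}).values())

    def _check(self, mirna: str, state: str) -> None:
        if mirna not in self._mirna_set():
            raise MirnaLookupError(f"miRNA {mirna!r} not in match table")
        if state not in STATES:
            raise InvalidParameterError(f"state must be one of {STATES}, got {state!r}")

    def _mirna_set(self) -> set:
        if not hasattr(self, "_mset"):
            self._mset = set(self.mirnas)
        return self._mset


def center_offset_range(center: int) -> range:
    """The 7 offsets whose 7-mer covers the central base."""
    return range(center - SEED_LENGTH + 1, center + 1)


def scan_dataset(pairs, catalog: list[MiRNA], mode: str = CENTER_OVERLAPPING) -> MatchTable:
    """Scan every window pair against every miRNA seed reverse-complement.

    miRNAs sharing a seed reverse-complement are scanned once per unique
    seed and the result fanned out, which is observationally identical to
    scanning each (identical seeds imply identical offsets everywhere).
    """
    if mode not in COUNT_MODES:
        raise InvalidParameterError(f"count mode must be one of {COUNT_MODES}, got {mode!r}")
    if not catalog:
        raise InvalidParameterError("miRNA catalog is empty")
    pairs = list(pairs)

    by_seed: dict[str, list[str]] = {}
    for mir in catalog:
        by_seed.setdefault(mir.seed_rc, []).append(mir.name)

    if pairs:
        window_length = len(pairs[0].unedited)
        center = pairs[0].center
    else:
        window_length, center = 0, 0

    offsets: dict[tuple[str, str], dict[str, tuple[int, ...]]] = {}
    for pair in pairs:
        lo, hi = pair.center - SEED_LENGTH + 1, pair.center
        for state, seq in (("unedited", pair.unedited), ("edited", pair.edited)):
            for seed, names in by_seed.items():
                hits = scan_window(seq, seed)
                if mode == CENTER_OVERLAPPING:
                    hits = [o for o in hits if lo <= o <= hi]
                if not hits:
                    continue
                tup = tuple(hits)
                for name in names:
                    offsets.setdefault((name, state), {})[pair.window_id] = tup

    return MatchTable(
        mode=mode,
        window_length=window_length,
        center=center,
        mirnas=[m.name for m in catalog],
        window_ids=[p.window_id for p in pairs],
        offsets=offsets,
    )


def position_profile(table: MatchTable, mirna: str, state: str) -> np.ndarray:
    """Histogram of match counts per window offset (the Fig-4-style profile).

    Entry ``o`` counts the windows with a match starting at offset ``o``;
    in all-positions mode the profile sums to the state total.
    """
    table._check(mirna, state)
    n = max(table.window_length - SEED_LENGTH + 1, 0)
    profile = np.zeros(n, dtype=int)
    for hits in table.offsets.get((mirna, state), {}).values():
        for o in hits:
            profile[o] += 1
    return profile
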