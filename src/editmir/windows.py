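"""Paired unedited/edited transcript-sense windows around edit sites.

Each edit site yields two 201-nt sequences (center ± 100-nt flanks by
default): an unedited version matching the reference and an edited version
with the single central base changed.  Windows are oriented transcript-
sense — reverse-strand sites are reverse-complemented — so the center
always reads 'A' unedited and 'G' edited and one scan direction suffices
downstream.

Sites too close to a sequence end are skipped (not padded): padding with N
would manufacture artificial non-matches.  When two edit sites fall within
one flank of each other each still gets its own window with only its own
central base edited; co-editing of neighbours is a known limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .edit_calling import EditSite
from .errors import MissingSequenceError, OutOfBoundsError, ReferenceMismatchError
from .seqs import revcomp

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 100


@dataclass(frozen=True)
class WindowPair:
    """The unedited/edited transcript-sense window for one edit site."""

    window_id: str
    unedited: str
    edited: str
    center: int  # 0-based offset of the edited base (= flank size)
    site: EditSite | None = None

    def __post_init__(self):
        if len(self.unedited) != len(self.edited):
            raise ReferenceMismatchError(
                f"{self.window_id}: state sequences differ in length"
            )
        if self.unedited[self.center] != "A" or self.edited[self.center] != "G":
            raise ReferenceMismatchError(
                f"{self.window_id}: center must read A (unedited) / G (edited), "
                f"got {self.unedited[self.center]}/{self.edited[self.center]}"
            )


def _get_slice(reference, name: str, start0: int, end0: int) -> str:
    """Fetch reference[name][start0:end0] from a dict of strings or a pyfaidx Fasta."""
    try:
        record = reference[name]
    except KeyError as exc:
        raise MissingSequenceError(f"reference has no sequence named {name!r}") from exc
    return str(record[start0:end0]).upper()


def _seq_length(reference, name: str) -> int:
    try:
        return len(reference[name])
    except KeyError as exc:
        raise MissingSequenceError(f"reference has no sequence named {name!r}") from exc


def extract_window(reference, site: EditSite, flank: int = DEFAULT_FLANK) -> WindowPair:
    """Build the window pair for one edit site.

    For '+' strand sites the genomic slice is used directly; for '-' strand
    sites it is reverse-complemented into transcript sense.  Raises
    :class:`OutOfBoundsError` if fewer than *flank* bases exist on either
    side, and :class:`ReferenceMismatchError` if the transcript-sense
    center base is not 'A'.
    """
    length = _seq_length(reference, site.seq)
    if site.pos - flank < 1 or site.pos + flank > length:
        raise OutOfBoundsError(
            f"{site.seq}:{site.pos}: needs {flank}-nt flanks inside 1..{length}"
        )
    genome = _get_slice(reference, site.seq, site.pos - flank - 1, site.pos + flank)
    window = genome if site.strand == "+" else revcomp(genome)
    center = flank
    if window[center] != "A":
        raise ReferenceMismatchError(
            f"{site.seq}:{site.pos}({site.strand}): transcript-sense center base is "
            f"{window[center]!r}, expected 'A'"
        )
    edited = window[:center] + "G" + window[center + 1 :]
    return WindowPair(
        window_id=f"{site.seq}:{site.pos}:{site.strand}",
        unedited=window,
        edited=edited,
        center=center,
        site=site,
    )


def build_dataset(
    reference, sites: list[EditSite], flank: int = DEFAULT_FLANK
) -> tuple[list[WindowPair], list[tuple[EditSite, str]]]:
    """Window pairs for every buildable site, plus (site, reason) skips.

    Record order follows the input site order and is identical between the
    two states (index i is the same site in both output FASTA files).
    """
    pairs, skipped = [], []
    for site in sites:
        try:
            pairs.append(extract_window(reference, site, flank))
        except MissingSequenceError:
            raise
        except (OutOfBoundsError, ReferenceMismatchError) as exc:
            logger.warning("skipping %s:%d:%s — %s", site.seq, site.pos, site.strand, exc)
            skipped.append((site, str(exc)))
    logger.info("build_dataset: %d windows built, %d sites skipped", len(pairs), len(skipped))
    return pairs, skipped
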