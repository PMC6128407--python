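"""miRNA expression from small-RNA reads.

Reads are assigned to mature miRNAs by mismatch-bounded ungapped
containment: the shorter of (read, mature) must align end-anchored inside
the longer with at most ``max_mismatches`` substitutions and identity of
at least ``min_identity`` over the aligned span.  The best-scoring miRNA
(most matching bases, then highest identity) wins; exact ties go to the
lexicographically first name so assignment is deterministic.  The default
is the strict criterion (zero mismatches, i.e. 100% identity); the looser
one-mismatch / >99%-identity criterion is available through the
parameters.

Expression is reported as reads per million (RPM), normalized by default
to the total library size (assigned + unassigned reads); a miRNA is called
expressed in a sample when its RPM strictly exceeds the threshold
(default 50).
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyLibraryError,
    InvalidParameterError,
    SampleLookupError,
)
from .seed_scan import MiRNA

DEFAULT_RPM_THRESHOLD = 50.0


def _containment_alignments(read: str, mature: str):
    """Yield (mismatches, overlap) for each ungapped containment alignment."""
    if len(read) <= len(mature):
        short, long_ = read, mature
    else:
        short, long_ = mature, read
    n = len(short)
    for shift in range(len(long_) - n + 1):
        window = long_[shift : shift + n]
        mm = sum(1 for a, b in zip(short, window) if a != b)
        yield mm, n


def _best_alignment(read: str, mature: str, max_mismatches: int, min_identity: float):
    """Best valid (matches, identity) of read vs mature, or None."""
    best = None
    if max_mismatches == 0:
        # exact containment fast path
        short, long_ = (read, mature) if len(read) <= len(mature) else (mature, read)
        if short in long_:
            best = (len(short), 1.0)
        return best
    for mm, overlap in _containment_alignments(read, mature):
        identity = (overlap - mm) / overlap
        if mm <= max_mismatches and identity >= min_identity:
            cand = (overlap - mm, identity)
            if best is None or cand > best:
                best = cand
    return best


def assign_reads(
    reads,
    catalog: list[MiRNA],
    max_mismatches: int = 0,
    min_identity: float = 0.99,
) -> tuple[Counter, int]:
    """Assign each read to its best-matching miRNA.

    Parameters
    ----------
    reads
        Iterable of sequences or of ``(read_id, sequence)`` pairs.
    catalog
        Mature miRNA catalog; comparison is in DNA space (U→T).

    Returns ``(per-miRNA Counter, unassigned count)``; the two always sum
    to the number of reads presented.
    """
    if not catalog:
        raise ConfigurationError("assign_reads needs a non-empty miRNA catalog")
    if max_mismatches < 0 or not 0 < min_identity <= 1:
        raise InvalidParameterError(
            f"bad matching parameters: max_mismatches={max_mismatches}, "
            f"min_identity={min_identity}"
        )
    matures = sorted((m.name, m.mature_dna) for m in catalog)
    counts: Counter = Counter()
    unassigned = 0
    for read in reads:
        seq = (read[1] if isinstance(read, tuple) else read).upper().replace("U", "T")
        best_name, best_score = None, None
        for name, mature in matures:  # sorted => first hit wins ties
            score = _best_alignment(seq, mature, max_mismatches, min_identity)
            if score is not None and (best_score is None or score > best_score):
                best_name, best_score = name, score
        if best_name is None:
            unassigned += 1
        else:
            counts[best_name] += 1
    return counts, unassigned


def compute_rpm(counts: Counter | dict, total_reads: int) -> pd.DataFrame:
    """Reads-per-million table from per-miRNA counts.

    ``total_reads`` is the normalization denominator (library size).  It
    must be positive and at least the sum of assigned counts.
    """
    if total_reads == 0:
        raise EmptyLibraryError("cannot compute RPM for an empty library")
    assigned = sum(counts.values())
    if total_reads < assigned or total_reads < 0:
        raise InvalidParameterError(
            f"total_reads ({total_reads}) smaller than assigned reads ({assigned})"
        )
    names = sorted(counts)
    return pd.DataFrame(
        {
            "miRNA": names,
            "count": [counts[n] for n in names],
            "rpm": [counts[n] * 1_000_000 / total_reads for n in names],
        }
    )


def filter_expressed(
    tables: dict[str, pd.DataFrame],
    threshold: float = DEFAULT_RPM_THRESHOLD,
    require_all: bool = True,
    samples: list[str] | None = None,
) -> list[str]:
    """miRNAs whose RPM strictly exceeds *threshold* in the required samples.

    ``tables`` maps sample name → RPM table from :func:`compute_rpm`.
    With ``require_all`` the miRNA must pass in every requested sample,
    otherwise in at least one.  A miRNA absent from a sample's table
    counts as 0 RPM there.
    """
    if not tables:
        raise InvalidParameterError("filter_expressed needs at least one sample table")
    if samples is None:
        samples = sorted(tables)
    missing = [s for s in samples if s not in tables]
    if missing:
        raise SampleLookupError(f"no expression table for sample(s): {missing}")
    rpm_by_sample = {
        s: dict(zip(tables[s]["miRNA"], tables[s]["rpm"])) for s in samples
    }
    all_mirnas = sorted({m for d in rpm_by_sample.values() for m in d})
    keep = []
    for mir in all_mirnas:
        passes = [rpm_by_sample[s].get(mir, 0.0) > threshold for s in samples]
        if (all(passes) if require_all else any(passes)):
            keep.append(mir)
    return keep
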