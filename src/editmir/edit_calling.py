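"""Calling putative A-to-I edit sites from per-site pileup evidence.

A-to-I deamination is read by sequencers as guanosine, so an edit appears
in genome orientation as A→G on the forward strand or T→C on the reverse
strand.  A site is retained when, in order:

1. its substitution is A→G or T→C (all other changes are discarded);
2. it is absent from the known-SNP mask (dbSNP-style positional exclusion);
3. total read depth at the site is at least ``min_depth`` (default 30);
4. the edited-read fraction is at least ``min_fraction`` (default 0.10).

Both thresholds are inclusive.  Depth means total reads covering the site
(reference plus every alternative base); edited reads are specifically the
G count at an A reference (forward) or the C count at a T reference
(reverse) — other alternative bases at the same site never count as edited.
Coordinates are 1-based throughout; BED input is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import (
    ConflictError,
    EmptyGroupError,
    FormatError,
    InvalidParameterError,
    MalformedRecordError,
)

logger = logging.getLogger(__name__)

#: genome-orientation substitution per transcript strand
CHANGE_FOR_STRAND = {"+": "A>G", "-": "T>C"}
COUNT_COLUMNS = ("count_A", "count_C", "count_G", "count_T")


@dataclass(frozen=True)
class EditSite:
    """One putative A-to-I deamination event.

    ``strand`` is the transcript strand the edit arose from: '+' pairs with
    an A→G change in genome orientation, '-' with T→C.  ``labels`` carries
    the sample / cell-line names the site was observed in.
    """

    seq: str
    pos: int  # 1-based
    strand: str
    change: str
    depth: int
    edited_reads: int
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.strand not in CHANGE_FOR_STRAND:
            raise InvalidParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.change != CHANGE_FOR_STRAND[self.strand]:
            raise InvalidParameterError(
                f"strand {self.strand!r} requires change "
                f"{CHANGE_FOR_STRAND[self.strand]!r}, got {self.change!r}"
            )
        if self.depth <= 0 or not 0 < self.edited_reads <= self.depth:
            raise InvalidParameterError(
                f"need 0 < edited_reads <= depth, got {self.edited_reads}/{self.depth}"
            )

    @property
    def edited_fraction(self) -> float:
        return self.edited_reads / self.depth

    @property
    def key(self) -> tuple:
        return (self.seq, self.pos, self.strand)


def call_edits(
    pileup: pd.DataFrame,
    snp_mask: set | None = None,
    min_depth: int = 30,
    min_fraction: float = 0.10,
    label: str = "",
) -> list[EditSite]:
    """Apply the edit-calling filters to a pileup table.

    Parameters
    ----------
    pileup
        DataFrame with columns ``seq, pos, ref, depth, count_A, count_C,
        count_G, count_T`` (as written by the synthetic generator or
        converted from VCF by :func:`editmir.io.read_variants_vcf`).
    snp_mask
        Set of ``(seq, pos)`` 1-based pairs to exclude; ``None`` disables
        the SNP filter.  Matching is by position only, not allele.
    label
        Sample name attached to every retained site.

    Returns the retained sites ordered by (seq, pos).  Filter-by-filter
    removal counts are logged so the calling funnel is auditable.
    """
    if min_depth < 1 or not 0 < min_fraction <= 1:
        raise InvalidParameterError(
            f"min_depth must be >=1 and 0 < min_fraction <= 1, "
            f"got {min_depth}, {min_fraction}"
        )
    snp_mask = snp_mask or set()
    required = {"seq", "pos", "ref", "depth", *COUNT_COLUMNS}
    missing = required - set(pileup.columns)
    if missing:
        raise MalformedRecordError(f"pileup table missing columns: {sorted(missing)}")
    if len(pileup):
        bad_ref = ~pileup["ref"].astype(str).str.upper().isin(list("ACGT"))
        if bad_ref.any():
            row = pileup[bad_ref].iloc[0]
            raise MalformedRecordError(
                f"unknown reference base {row['ref']!r} at {row['seq']}:{row['pos']}"
            )
        counts = pileup[list(COUNT_COLUMNS) + ["depth"]]
        if (counts.to_numpy() < 0).any():
            raise MalformedRecordError("negative count in pileup table")

    n_in = len(pileup)
    ref = pileup["ref"].astype(str).str.upper()
    # filter 1: only A->G (forward) / T->C (reverse) substitutions qualify
    fwd = pileup[ref == "A"].assign(strand="+", edited=lambda d: d["count_G"])
    rev = pileup[ref == "T"].assign(strand="-", edited=lambda d: d["count_C"])
    cand = pd.concat([fwd, rev]) if len(fwd) or len(rev) else fwd
    cand = cand[cand["edited"] > 0]
    logger.info("call_edits[%s]: %d records in, %d with an A>G/T>C signal", label, n_in, len(cand))

    masked = cand.apply(lambda r: (r["seq"], int(r["pos"])) in snp_mask, axis=1) if len(cand) else pd.Series(dtype=bool)
    cand = cand[~masked] if len(cand) else cand
    logger.info("call_edits[%s]: %d after SNP mask", label, len(cand))

    cand = cand[cand["depth"] >= min_depth]
    logger.info("call_edits[%s]: %d after depth >= %d", label, len(cand), min_depth)

    cand = cand[cand["edited"] / cand["depth"] >= min_fraction]
    logger.info("call_edits[%s]: %d after fraction >= %g", label, len(cand), min_fraction)

    labels = frozenset({label}) if label else frozenset()
    sites = [
        EditSite(
            seq=str(r.seq),
            pos=int(r.pos),
            strand=r.strand,
            change=CHANGE_FOR_STRAND[r.strand],
            depth=int(r.depth),
            edited_reads=int(r.edited),
            labels=labels,
        )
        for r in cand.itertuples()
    ]
    sites.sort(key=lambda s: (s.seq, s.pos, s.strand))
    return sites


def load_snp_mask(path) -> set:
    """Load a known-SNP positional mask from a VCF 4.x or BED file.

    Returns a set of ``(seq, pos)`` pairs, 1-based.  BED's half-open
    0-based intervals are expanded to every covered position.  The format
    is chosen by extension (``.vcf`` / ``.bed``), falling back to content
    sniffing for other names.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if path.endswith(".vcf") or first.startswith("##fileformat=VCF"):
        return _snp_mask_from_vcf(path)
    return _snp_mask_from_bed(path)


def _snp_mask_from_vcf(path: str) -> set:
    from pysam import VariantFile

    mask = set()
    try:
        with VariantFile(path) as vcf:
            for rec in vcf:
                mask.add((rec.chrom, rec.pos))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    return mask


def _snp_mask_from_bed(path: str) -> set:
    mask = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"BED line has {len(fields)} fields, need >=3", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-integer BED coordinates: {exc}", lineno) from exc
            if end < start:
                raise FormatError("BED end before start", lineno)
            for pos0 in range(start, end):
                mask.add((fields[0], pos0 + 1))
    return mask


def merge_site_sets(labeled_sets: dict[str, list[EditSite]]) -> list[EditSite]:
    """Union of per-sample site lists, de-duplicated on (seq, pos, strand).

    Each merged site keeps the labels of every contributing list (plus the
    dict key of the list it came from).  The same coordinate annotated with
    conflicting strands across lists is an error.
    """
    if not labeled_sets:
        raise InvalidParameterError("merge_site_sets needs at least one site list")
    by_key: dict[tuple, EditSite] = {}
    strand_at: dict[tuple, str] = {}
    for set_label, sites in labeled_sets.items():
        for site in sites:
            coord = (site.seq, site.pos)
            if coord in strand_at and strand_at[coord] != site.strand:
                raise ConflictError(
                    f"conflicting strand annotations at {site.seq}:{site.pos} "
                    f"({strand_at[coord]} vs {site.strand})"
                )
            strand_at[coord] = site.strand
            labels = site.labels | ({set_label} if set_label else set())
            if site.key in by_key:
                prior = by_key[site.key]
                by_key[site.key] = replace(prior, labels=prior.labels | labels)
            else:
                by_key[site.key] = replace(site, labels=frozenset(labels))
    return sorted(by_key.values(), key=lambda s: (s.seq, s.pos, s.strand))


def edit_fraction_summary(sites: list[EditSite], labels: list[str] | None = None) -> dict[str, float]:
    """Arithmetic mean edited fraction per sample label.

    With ``labels=None`` every label present in the sites is summarized;
    requesting a label with no member sites is an error.
    """
    groups: dict[str, list[float]] = {}
    for site in sites:
        for lab in site.labels:
            groups.setdefault(lab, []).append(site.edited_fraction)
    if labels is None:
        labels = sorted(groups)
    out = {}
    for lab in labels:
        if not groups.get(lab):
            raise EmptyGroupError(f"no sites carry label {lab!r}")
        vals = groups[lab]
        out[lab] = sum(vals) / len(vals)
    return out
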