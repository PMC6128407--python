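"""Readers and writers for the standard formats at the pipeline boundary.

TSV is the canonical tabular interchange (every table has a header row and
stable column order); FASTA/FASTQ/VCF/BED sit at the sequence and variant
boundaries.  All coordinates in TSV outputs are 1-based; BED output is
0-based half-open per the format.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .edit_calling import CHANGE_FOR_STRAND, EditSite
from .errors import FormatError, MalformedRecordError
from .seed_scan import STATES, MatchTable
from .synthetic import SyntheticTruth
from .windows import WindowPair

PILEUP_COLUMNS = ["seq", "pos", "ref", "depth", "count_A", "count_C", "count_G", "count_T"]


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write reads with a fixed high quality ('I' = Q40)."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ------------------------------------------------------------------- pileups

def write_pileup_tsv(pileup: pd.DataFrame, path) -> None:
    pileup.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"pileup TSV {path} missing columns {sorted(missing)}")
    return df


def write_pileup_vcf(pileup: pd.DataFrame, path, reference_name: str = "synthetic") -> None:
    """Minimal VCF 4.2 with per-base depths in an AD-style sample column.

    Only sites with at least one non-reference read become records (a VCF
    is a variant list, not a pileup); ALT lists every observed non-reference
    base, AD carries ref then alt counts in ALT order.
    """
    base_cols = {"A": "count_A", "C": "count_C", "G": "count_G", "T": "count_T"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=editmir\n##reference={reference_name}\n")
        for name, length in _contig_extents(pileup):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for row in pileup.itertuples():
            ref = str(row.ref).upper()
            alts = [
                b
                for b in "ACGT"
                if b != ref and getattr(row, base_cols[b]) > 0
            ]
            if not alts:
                continue
            ad = [str(getattr(row, base_cols[ref]))] + [
                str(getattr(row, base_cols[b])) for b in alts
            ]
            fh.write(
                f"{row.seq}\t{row.pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t"
                f"DP={row.depth}\tGT:AD:DP\t./.:{','.join(ad)}:{row.depth}\n"
            )


def _contig_extents(pileup: pd.DataFrame) -> list[tuple[str, int]]:
    if not len(pileup):
        return []
    g = pileup.groupby("seq")["pos"].max()
    return [(str(name), int(mx)) for name, mx in g.items()]


def read_variants_vcf(path) -> pd.DataFrame:
    """Convert a VCF 4.x with AD/DP counts into a pileup-shaped DataFrame.

    Positions absent from the VCF are absent from the result (a VCF holds
    variant sites only), so edit calling on this table sees exactly the
    variant evidence.
    """
    from pysam import VariantFile

    rows = []
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref.upper()
            if len(ref) != 1:
                continue  # indel records are out of scope
            counts = dict.fromkeys("ACGT", 0)
            sample = rec.samples[0] if rec.samples else None
            ad = sample.get("AD") if sample else None
            if ad is None:
                raise MalformedRecordError(
                    f"VCF record {rec.chrom}:{rec.pos} lacks AD counts"
                )
            alleles = (rec.ref,) + tuple(rec.alts or ())
            for allele, count in zip(alleles, ad):
                allele = (allele or "").upper()
                if len(allele) == 1 and allele in counts and count is not None:
                    counts[allele] += int(count)
            depth = rec.info.get("DP", sum(counts.values()))
            rows.append(
                {
                    "seq": rec.chrom,
                    "pos": rec.pos,
                    "ref": ref,
                    "depth": int(depth),
                    **{f"count_{b}": counts[b] for b in "ACGT"},
                }
            )
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


# ---------------------------------------------------------------- edit sites

def write_sites_tsv(sites: list[EditSite], path) -> None:
    pd.DataFrame(
        {
            "seq": [s.seq for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "change": [s.change for s in sites],
            "depth": [s.depth for s in sites],
            "edited_reads": [s.edited_reads for s in sites],
            "edited_fraction": [round(s.edited_fraction, 6) for s in sites],
            "labels": [",".join(sorted(s.labels)) for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[EditSite]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    sites = []
    for row in df.itertuples():
        labels = frozenset(str(row.labels).split(",")) if row.labels else frozenset()
        sites.append(
            EditSite(
                seq=str(row.seq),
                pos=int(row.pos),
                strand=str(row.strand),
                change=CHANGE_FOR_STRAND[str(row.strand)],
                depth=int(row.depth),
                edited_reads=int(row.edited_reads),
                labels=labels,
            )
        )
    return sites


def write_sites_bed(sites: list[EditSite], path) -> None:
    """BED6: 0-based half-open, name = change, score = round(1000 * fraction)."""
    with open(path, "w") as fh:
        for s in sites:
            score = round(1000 * s.edited_fraction)
            fh.write(
                f"{s.seq}\t{s.pos - 1}\t{s.pos}\t{s.change}\t{score}\t{s.strand}\n"
            )


# ------------------------------------------------------------------ windows

def write_window_fastas(pairs: list[WindowPair], prefix) -> tuple[Path, Path]:
    """Paired FASTA files ``<prefix>_unedited.fa`` / ``<prefix>_edited.fa``.

    Record order is identical in both files; headers carry the window id
    and center offset.
    """
    prefix = Path(prefix)
    paths = (
        prefix.parent / f"{prefix.name}_unedited.fa",
        prefix.parent / f"{prefix.name}_edited.fa",
    )
    for state, path in zip(STATES, paths):
        records = [
            SeqRecord(
                Seq(getattr(p, state)),
                id=p.window_id,
                description=f"center={p.center} state={state}",
            )
            for p in pairs
        ]
        SeqIO.write(records, str(path), "fasta")
    return paths


def read_window_fastas(unedited_path, edited_path) -> list[WindowPair]:
    unedited = list(SeqIO.parse(str(unedited_path), "fasta"))
    edited = list(SeqIO.parse(str(edited_path), "fasta"))
    if [r.id for r in unedited] != [r.id for r in edited]:
        raise FormatError("paired window FASTAs disagree in record ids/order")
    pairs = []
    for ru, re_ in zip(unedited, edited):
        center = None
        for token in ru.description.split():
            if token.startswith("center="):
                center = int(token.split("=", 1)[1])
        if center is None:
            center = len(ru.seq) // 2
        pairs.append(
            WindowPair(
                window_id=ru.id,
                unedited=str(ru.seq).upper(),
                edited=str(re_.seq).upper(),
                center=center,
            )
        )
    return pairs


# -------------------------------------------------------------- match tables

def write_match_table(table: MatchTable, path) -> None:
    """Long-format match TSV with a metadata comment line for round-tripping."""
    rows = []
    for (mirna, state), windows in sorted(table.offsets.items()):
        for window_id, offsets in sorted(windows.items()):
            for o in offsets:
                rows.append((mirna, state, window_id, o))
    with open(path, "w") as fh:
        fh.write(
            f"# mode={table.mode}\twindow_length={table.window_length}\t"
            f"center={table.center}\tn_windows={table.n_windows}\t"
            f"mirnas={','.join(table.mirnas)}\n"
        )
        pd.DataFrame(rows, columns=["miRNA", "state", "window", "offset"]).to_csv(
            fh, sep="\t", index=False
        )


def read_match_table(path) -> MatchTable:
    """Rebuild a :class:`MatchTable` written by :func:`write_match_table`.

    Window ids of match-free windows are not recorded in the file, so the
    reconstructed ``window_ids`` are placeholders preserving only the
    window count (which is what downstream expectation models need).
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# mode="):
            raise FormatError(f"{path} lacks the match-table metadata line", line=1)
        meta = dict(item.split("=", 1) for item in header[2:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t")
    offsets: dict[tuple[str, str], dict[str, tuple[int, ...]]] = {}
    for (mirna, state, window), group in df.groupby(["miRNA", "state", "window"]):
        offsets.setdefault((mirna, state), {})[window] = tuple(
            sorted(int(o) for o in group["offset"])
        )
    n_windows = int(meta["n_windows"])
    matched_ids = sorted({w for d in offsets.values() for w in d})
    window_ids = matched_ids + [
        f"_unmatched{i}" for i in range(n_windows - len(matched_ids))
    ]
    return MatchTable(
        mode=meta["mode"],
        window_length=int(meta["window_length"]),
        center=int(meta["center"]),
        mirnas=meta["mirnas"].split(",") if meta.get("mirnas") else [],
        window_ids=window_ids,
        offsets=offsets,
    )


def write_match_totals(table: MatchTable, path) -> None:
    rows = [
        (mirna, table.total(mirna, "edited"), table.total(mirna, "unedited"))
        for mirna in table.mirnas
    ]
    pd.DataFrame(rows, columns=["miRNA", "targets_edited", "targets_unedited"]).to_csv(
        path, sep="\t", index=False
    )


def write_profile(profile, path) -> None:
    pd.DataFrame({"offset": range(len(profile)), "count": profile}).to_csv(
        path, sep="\t", index=False
    )


# -------------------------------------------------------------------- truth

def write_truth_tsv(truth: SyntheticTruth, prefix) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        [(e.seq, e.pos, e.strand, e.fraction) for e in truth.edit_sites],
        columns=["seq", "pos", "strand", "fraction"],
    ).to_csv(prefix.parent / f"{prefix.name}_edits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(s.seq, s.pos, s.alt, s.zygosity) for s in truth.snp_sites],
        columns=["seq", "pos", "alt", "zygosity"],
    ).to_csv(prefix.parent / f"{prefix.name}_snps.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m.window_id, m.mirna, m.offset, m.state) for m in truth.planted_matches],
        columns=["window", "miRNA", "offset", "state"],
    ).to_csv(prefix.parent / f"{prefix.name}_matches.tsv", sep="\t", index=False)


def write_site_changes(changes, path_tsv, path_bed=None) -> None:
    pd.DataFrame(
        [(c.window_id, c.mirna, c.offset, c.direction) for c in changes],
        columns=["window", "miRNA", "offset", "direction"],
    ).to_csv(path_tsv, sep="\t", index=False)
    if path_bed is not None:
        with open(path_bed, "w") as fh:
            for c in changes:
                seq, pos, strand = _window_id_coords(c.window_id)
                if seq is None:
                    continue
                fh.write(
                    f"{seq}\t{pos - 1}\t{pos}\t{c.mirna}:{c.direction}\t0\t{strand}\n"
                )


def _window_id_coords(window_id: str):
    parts = window_id.rsplit(":", 2)
    if len(parts) == 3 and parts[1].isdigit():
        return parts[0], int(parts[1]), parts[2]
    return None, None, None
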