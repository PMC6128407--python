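"""Synthetic data with the statistical structure the analysis assumes.

The generators stand in for the study inputs that would otherwise require
sequencing archives and genome-scale references: random reference
chromosomes, planted A-to-I edit sites (on both strands) and SNP decoys,
a per-site pileup with binomial edited-read sampling and sequencing error,
paired windows whose central base deliberately creates or destroys miRNA
seed matches, and small-RNA reads drawn from a miRNA catalog at chosen
abundances.

Background sequence is i.i.d. nucleotides with configurable GC content —
the simplest model sufficient to exercise string-matching stages.  The
Alu-repeat context real edit sites live in is a biological property of the
data, not an algorithmic requirement of any stage, so it is deliberately
not emulated.  SNP decoys are simulated at heterozygous (0.5) or
homozygous (1.0) alternative-allele fraction so that the known-SNP mask,
not the edited-fraction filter, is what removes them.

All randomness flows from one explicit integer seed per generator call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    CatalogMismatchError,
    InfeasiblePlantError,
    InvalidParameterError,
    ReferenceMismatchError,
)
from .seed_scan import SEED_LENGTH, MiRNA, scan_window
from .seqs import revcomp
from .windows import WindowPair

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedEdit:
    seq: str
    pos: int  # 1-based, genome orientation
    strand: str  # '+' (A reference) or '-' (T reference)
    fraction: float  # true edited-read fraction


@dataclass(frozen=True)
class PlantedSNP:
    seq: str
    pos: int
    alt: str
    zygosity: float  # alternative-allele fraction: 0.5 het, 1.0 hom


@dataclass(frozen=True)
class PlantedMatch:
    window_id: str
    mirna: str
    offset: int  # 0-based offset of the seed-RC occurrence
    state: str  # the editing state in which the match exists


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic dataset.

    Edit and SNP positions are disjoint by construction; every edit site's
    transcript-sense reference base is 'A'.
    """

    edit_sites: list[PlantedEdit] = field(default_factory=list)
    snp_sites: list[PlantedSNP] = field(default_factory=list)
    planted_matches: list[PlantedMatch] = field(default_factory=list)

    def snp_mask(self) -> set:
        """The (seq, pos) mask a caller would build from a SNP catalog."""
        return {(s.seq, s.pos) for s in self.snp_sites}

    def match_counts(self) -> dict[str, dict[str, int]]:
        """Per-miRNA planted match counts per state."""
        out: dict[str, dict[str, int]] = {}
        for m in self.planted_matches:
            out.setdefault(m.mirna, {"edited": 0, "unedited": 0})[m.state] += 1
        return out


def make_reference(
    n_sequences: int, length: int, gc_fraction: float, rng_seed: int
) -> dict[str, str]:
    """Random i.i.d. reference sequences named chr1..chrN.

    Base probabilities are (1-gc)/2 each for A/T and gc/2 each for C/G.
    """
    if n_sequences < 1 or length < 201:
        raise InvalidParameterError(
            f"need n_sequences >= 1 and length >= 201, got {n_sequences}, {length}"
        )
    if not 0 <= gc_fraction <= 1:
        raise InvalidParameterError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(rng_seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    return {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=length, p=p))
        for i in range(n_sequences)
    }


def plant_sites(
    reference: dict[str, str],
    n_edits: int,
    n_snps: int,
    fraction_range: tuple[float, float],
    rng_seed: int,
    flank: int = 100,
) -> SyntheticTruth:
    """Plant edit sites and SNP decoys at distinct eligible positions.

    Edit sites go on positions whose transcript-sense base is 'A': genome
    'A' for '+' strand sites, genome 'T' for '-' strand sites.  Every
    planted position keeps at least *flank* bases on each side so windows
    can be built later.  True edited fractions are drawn uniformly from
    ``fraction_range``.
    """
    low, high = fraction_range
    if not (0 <= low <= high <= 1):
        raise InvalidParameterError(f"bad fraction_range {fraction_range}")
    if n_edits < 0 or n_snps < 0:
        raise InvalidParameterError("site counts must be non-negative")
    rng = np.random.default_rng(rng_seed)

    edit_pool: list[tuple[str, int, str]] = []
    snp_pool: list[tuple[str, int]] = []
    for name, seq in reference.items():
        for pos0 in range(flank, len(seq) - flank):
            base = seq[pos0]
            if base == "A":
                edit_pool.append((name, pos0 + 1, "+"))
            elif base == "T":
                edit_pool.append((name, pos0 + 1, "-"))
            snp_pool.append((name, pos0 + 1))

    if len(edit_pool) < n_edits:
        raise CapacityError(
            f"requested {n_edits} edit sites but only {len(edit_pool)} eligible "
            f"'A' (transcript-sense) positions with {flank}-nt flanks exist "
            f"(short by {n_edits - len(edit_pool)})"
        )
    edit_idx = rng.choice(len(edit_pool), size=n_edits, replace=False)
    edits = [
        PlantedEdit(
            seq=edit_pool[i][0],
            pos=edit_pool[i][1],
            strand=edit_pool[i][2],
            fraction=float(rng.uniform(low, high)),
        )
        for i in edit_idx
    ]

    taken = {(e.seq, e.pos) for e in edits}
    snp_candidates = [c for c in snp_pool if c not in taken]
    if len(snp_candidates) < n_snps:
        raise CapacityError(
            f"requested {n_snps} SNP decoys but only {len(snp_candidates)} free "
            f"positions remain (short by {n_snps - len(snp_candidates)})"
        )
    snp_idx = rng.choice(len(snp_candidates), size=n_snps, replace=False)
    snps = []
    for i in snp_idx:
        name, pos = snp_candidates[i]
        ref_base = reference[name][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        zyg = float(rng.choice([0.5, 1.0]))
        snps.append(PlantedSNP(seq=name, pos=pos, alt=alt, zygosity=zyg))

    return SyntheticTruth(edit_sites=edits, snp_sites=snps)


def simulate_pileup(
    reference: dict[str, str],
    truth: SyntheticTruth,
    mean_depth,
    error_rate: float,
    rng_seed: int,
) -> pd.DataFrame:
    """Per-site base counts over the whole reference.

    ``mean_depth`` is either an int — per-site depth is Poisson(mean_depth)
    floored at 1 — or a ``(low, high)`` tuple — depth uniform over the
    closed integer range.  At edit sites the edited-base count (genome G on
    '+' sites, genome C on '-' sites) is Binomial(depth, true fraction);
    at SNP sites the alt count is Binomial(depth, zygosity); elsewhere each
    read shows a non-reference base with probability ``error_rate``
    (uniform over the three alternatives).

    Returns a DataFrame with columns
    ``seq, pos, ref, depth, count_A, count_C, count_G, count_T``.
    """
    if not 0 <= error_rate < 0.25:
        raise InvalidParameterError(f"error_rate must be in [0, 0.25), got {error_rate}")
    for collection in (truth.edit_sites, truth.snp_sites):
        for site in collection:
            if site.seq not in reference:
                raise ReferenceMismatchError(
                    f"truth references unknown sequence {site.seq!r}"
                )
    rng = np.random.default_rng(rng_seed)

    def draw_depths(n: int) -> np.ndarray:
        if isinstance(mean_depth, tuple):
            lo, hi = mean_depth
            if lo < 1 or hi < lo:
                raise InvalidParameterError(f"bad depth range {mean_depth}")
            return rng.integers(lo, hi + 1, size=n)
        if mean_depth <= 0:
            raise InvalidParameterError(f"mean_depth must be > 0, got {mean_depth}")
        return np.maximum(rng.poisson(mean_depth, size=n), 1)

    edit_at = {(e.seq, e.pos): e for e in truth.edit_sites}
    snp_at = {(s.seq, s.pos): s for s in truth.snp_sites}

    frames = []
    base_index = {b: i for i, b in enumerate("ACGT")}
    for name, seq in reference.items():
        n = len(seq)
        depth = draw_depths(n)
        counts = np.zeros((n, 4), dtype=int)
        ref_idx = np.array([base_index[b] for b in seq])
        # sequencing error split evenly across the three non-reference bases
        n_err = rng.binomial(depth, error_rate) if error_rate > 0 else np.zeros(n, dtype=int)
        counts[np.arange(n), ref_idx] = depth - n_err
        if error_rate > 0:
            err_split = rng.multinomial(n_err, [1 / 3] * 3)
            for col in range(4):
                others = [c for c in range(4) if c != col]
                rows = ref_idx == col
                counts[np.ix_(rows, others)] += err_split[rows]
        for pos0 in range(n):
            key = (name, pos0 + 1)
            planted = edit_at.get(key) or snp_at.get(key)
            if planted is None:
                continue
            d = int(depth[pos0])
            ref_b = seq[pos0]
            if isinstance(planted, PlantedEdit):
                alt_b = "G" if planted.strand == "+" else "C"
                p_alt = planted.fraction
            else:
                alt_b = planted.alt
                p_alt = planted.zygosity
            n_alt = int(rng.binomial(d, p_alt))
            row = np.zeros(4, dtype=int)
            n_other = d - n_alt
            if error_rate > 0 and n_other > 0:
                n_err_site = int(rng.binomial(n_other, error_rate))
                split = rng.multinomial(n_err_site, [1 / 3] * 3)
                others = [c for c in range(4) if c != base_index[ref_b]]
                row[others] += split
                n_other -= n_err_site
            row[base_index[ref_b]] += n_other
            row[base_index[alt_b]] += n_alt
            counts[pos0] = row
        frames.append(
            pd.DataFrame(
                {
                    "seq": name,
                    "pos": np.arange(1, n + 1),
                    "ref": list(seq),
                    "depth": depth,
                    "count_A": counts[:, 0],
                    "count_C": counts[:, 1],
                    "count_G": counts[:, 2],
                    "count_T": counts[:, 3],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _center_hits(seq: str, seed: str, center: int) -> list[int]:
    lo, hi = center - SEED_LENGTH + 1, center
    return [o for o in scan_window(seq, seed) if lo <= o <= hi]


def plant_seed_windows(
    mirna_catalog: list[MiRNA],
    n_created: int,
    n_destroyed: int,
    n_neutral: int,
    rng_seed: int,
    flank: int = 100,
    n_mirnas_created: int = 1,
    n_mirnas_destroyed: int = 1,
    max_tries: int = 2000,
) -> tuple[list[WindowPair], SyntheticTruth]:
    """Window pairs whose central edit deliberately creates or destroys matches.

    * created windows contain the assigned miRNA's seed reverse-complement
      overlapping the center only in the edited state (the seed RC's 'G'
      sits on the center, which reads 'A' unedited);
    * destroyed windows contain it only in the unedited state (an 'A' in
      the seed RC sits on the center, broken by the edit to 'G');
    * neutral windows contain no occurrence of any catalog seed RC
      overlapping the center in either state, and none of their assigned
      miRNA's seed RC anywhere.

    Created/destroyed windows are distributed round-robin over
    ``n_mirnas_created`` / ``n_mirnas_destroyed`` distinct miRNAs (a miRNA
    needs at least the fold-threshold's worth of windows to classify as
    biased downstream, so callers control the windows-per-miRNA ratio).
    Background sequence is rejection-sampled so no stray catalog seed
    occurrence overlaps the center, and the planted miRNA's seed occurs
    nowhere else in either state — planted matches are therefore exactly
    what a scan recovers.
    """
    if min(n_created, n_destroyed, n_neutral) < 0:
        raise InvalidParameterError("window counts must be non-negative")
    if not mirna_catalog:
        raise InvalidParameterError("miRNA catalog is empty")
    if flank < SEED_LENGTH:
        raise InvalidParameterError(f"flank must be >= {SEED_LENGTH}, got {flank}")
    rng = np.random.default_rng(rng_seed)
    length = 2 * flank + 1
    center = flank

    creatable = [m for m in mirna_catalog if "G" in m.seed_rc]
    destroyable = [m for m in mirna_catalog if "A" in m.seed_rc]
    if n_created > 0 and len(creatable) < n_mirnas_created:
        raise InfeasiblePlantError(
            f"need {n_mirnas_created} miRNAs with a 'G' in their seed RC for "
            f"created planting, found {len(creatable)}"
        )
    if n_destroyed > 0 and len(destroyable) < n_mirnas_destroyed:
        raise InfeasiblePlantError(
            f"need {n_mirnas_destroyed} miRNAs with an 'A' in their seed RC for "
            f"destroyed planting, found {len(destroyable)}"
        )
    created_mirs = creatable[:n_mirnas_created] if n_created else []
    destroyed_mirs = [
        m for m in destroyable if m not in created_mirs
    ][:n_mirnas_destroyed] if n_destroyed else []
    if n_destroyed > 0 and len(destroyed_mirs) < n_mirnas_destroyed:
        raise InfeasiblePlantError(
            "not enough distinct destroyable miRNAs left after created assignment"
        )
    seeds = sorted({m.seed_rc for m in mirna_catalog})

    def clean(unedited: str, edited: str, planted: tuple[str, int, str] | None, own_seed: str) -> bool:
        for seed in seeds:
            for state, seq in (("unedited", unedited), ("edited", edited)):
                hits = _center_hits(seq, seed, center)
                expected = (
                    [planted[1]]
                    if planted is not None and planted[0] == seed and planted[2] == state
                    else []
                )
                if hits != expected:
                    return False
        # the assigned miRNA's own seed must not occur off-plant anywhere
        for state, seq in (("unedited", unedited), ("edited", edited)):
            hits = scan_window(seq, own_seed)
            expected = (
                [planted[1]]
                if planted is not None and planted[0] == own_seed and planted[2] == state
                else []
            )
            if hits != expected:
                return False
        return True

    pairs: list[WindowPair] = []
    matches: list[PlantedMatch] = []

    def build(kind: str, index: int, mir: MiRNA) -> None:
        for _ in range(max_tries):
            bg = list(_random_seq(rng, length))
            planted = None
            if kind == "created":
                g_positions = [i for i, b in enumerate(mir.seed_rc) if b == "G"]
                g = int(rng.choice(g_positions))
                offset = center - g
                edited_l = bg.copy()
                edited_l[offset : offset + SEED_LENGTH] = mir.seed_rc
                edited_l[center] = "G"  # == seed_rc[g]
                unedited_l = edited_l.copy()
                unedited_l[center] = "A"
                planted = (mir.seed_rc, offset, "edited")
            elif kind == "destroyed":
                a_positions = [i for i, b in enumerate(mir.seed_rc) if b == "A"]
                a = int(rng.choice(a_positions))
                offset = center - a
                unedited_l = bg.copy()
                unedited_l[offset : offset + SEED_LENGTH] = mir.seed_rc
                unedited_l[center] = "A"  # == seed_rc[a]
                edited_l = unedited_l.copy()
                edited_l[center] = "G"
                planted = (mir.seed_rc, offset, "unedited")
            else:
                unedited_l = bg.copy()
                unedited_l[center] = "A"
                edited_l = unedited_l.copy()
                edited_l[center] = "G"
            unedited, edited = "".join(unedited_l), "".join(edited_l)
            if not clean(unedited, edited, planted, mir.seed_rc):
                continue
            window_id = f"synth:{kind}:{index}"
            pairs.append(
                WindowPair(window_id=window_id, unedited=unedited, edited=edited, center=center)
            )
            if planted is not None:
                matches.append(
                    PlantedMatch(
                        window_id=window_id, mirna=mir.name, offset=planted[1], state=planted[2]
                    )
                )
            return
        raise CapacityError(
            f"could not build a clean {kind} window in {max_tries} tries "
            f"(catalog of {len(seeds)} seeds may be too dense)"
        )

    for i in range(n_created):
        build("created", i, created_mirs[i % len(created_mirs)])
    for i in range(n_destroyed):
        build("destroyed", i, destroyed_mirs[i % len(destroyed_mirs)])
    neutral_pool = mirna_catalog
    for i in range(n_neutral):
        build("neutral", i, neutral_pool[i % len(neutral_pool)])

    return pairs, SyntheticTruth(planted_matches=matches)


def simulate_small_rna(
    mirna_catalog: list[MiRNA],
    abundances: dict[str, int],
    error_rate: float,
    rng_seed: int,
) -> list[tuple[str, str]]:
    """Small-RNA reads drawn from mature sequences at chosen abundances.

    Each read is its source mature sequence (DNA alphabet) with independent
    per-base substitution errors at ``error_rate``.  Returns ``(read_id,
    sequence)`` pairs; total read count equals the sum of abundances.
    """
    if not 0 <= error_rate < 1:
        raise InvalidParameterError(f"error_rate must be in [0, 1), got {error_rate}")
    by_name = {m.name: m for m in mirna_catalog}
    unknown = [name for name in abundances if name not in by_name]
    if unknown:
        raise CatalogMismatchError(f"abundances name unknown miRNAs: {unknown}")
    if any(n < 0 for n in abundances.values()):
        raise InvalidParameterError("abundances must be non-negative")
    rng = np.random.default_rng(rng_seed)
    reads = []
    for name in sorted(abundances):
        template = by_name[name].mature_dna
        for i in range(abundances[name]):
            seq = list(template)
            if error_rate > 0:
                err_at = np.nonzero(rng.random(len(seq)) < error_rate)[0]
                for j in err_at:
                    seq[j] = str(rng.choice([b for b in "ACGT" if b != seq[j]]))
            reads.append((f"{name}_read{i}", "".join(seq)))
    return reads
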