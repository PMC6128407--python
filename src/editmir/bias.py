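"""Classifying miRNAs whose target repertoires are created or destroyed by editing.

A miRNA is *created*-biased when its seed-match total across the edited
windows is at least ``fold_threshold`` times its unedited total, and
*destroyed*-biased in the converse case (default threshold 10).  Zero
denominators are handled by dividing by ``max(count, 1)`` so an (n, 0) row
with n >= threshold qualifies — many published biased miRNAs have zero
matches in one state, so infinite folds must count.  The two classes are
mutually exclusive for any threshold > 1, and (0, 0) is always unbiased.

No hypothesis test is layered on top of the fold rule, and no minimum
count floor is applied by default (a configurable floor exists); the
classification is the fold criterion alone.

Site-level changes (gained/lost target sites per window, aggregable to
genes through a user-supplied window→gene map) require a center-overlapping
match table: only matches covering the edited base can appear or vanish
with the edit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, InvalidParameterError, ModeError
from .seed_scan import (
    CENTER_OVERLAPPING,
    SEED_LENGTH,
    MatchTable,
    MiRNA,
)

CREATED = "created"
DESTROYED = "destroyed"
UNBIASED = "unbiased"

DEFAULT_FOLD_THRESHOLD = 10.0


@dataclass(frozen=True)
class BiasRow:
    mirna: str
    accession: str
    seed_rc: str
    targets_edited: int
    targets_unedited: int
    fold: float
    bias_class: str
    expected: float


@dataclass(frozen=True)
class SiteChange:
    window_id: str
    mirna: str
    offset: int
    direction: str  # 'gained' or 'lost'


def classify_bias(
    targets_edited: int,
    targets_unedited: int,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_count: int = 0,
) -> str:
    """Fold-rule class of one (edited, unedited) count pair."""
    if targets_edited < 0 or targets_unedited < 0:
        raise InvalidParameterError(
            f"counts must be non-negative, got ({targets_edited}, {targets_unedited})"
        )
    if fold_threshold <= 1:
        raise InvalidParameterError(f"fold_threshold must be > 1, got {fold_threshold}")
    if targets_edited >= min_count and targets_edited / max(targets_unedited, 1) >= fold_threshold:
        return CREATED
    if targets_unedited >= min_count and targets_unedited / max(targets_edited, 1) >= fold_threshold:
        return DESTROYED
    return UNBIASED


def fold_ratio(targets_edited: int, targets_unedited: int) -> float:
    """Edited/unedited ratio with the same max(count, 1) zero-guard, >= 1 flipped."""
    up = targets_edited / max(targets_unedited, 1)
    down = targets_unedited / max(targets_edited, 1)
    return max(up, down)


def expected_matches(
    window_count: int,
    seed_rc: str,
    model: str = "uniform",
    base_freqs: dict[str, float] | None = None,
    center_state: str | None = None,
) -> float:
    """Expected center-overlapping seed matches under a background model.

    ``uniform``
        ``window_count * 7 * (1/4)**7`` — every base equiprobable at the 7
        offsets whose 7-mer covers the center.
    ``composition``
        Sum over the 7 center-overlapping alignments of the product of
        position-independent background frequencies of the seed RC
        letters; with uniform frequencies this reduces to the uniform
        model.  Passing ``center_state`` ('edited' or 'unedited') instead
        conditions on the known center base (G or A): the center-aligned
        factor becomes an indicator, so e.g. a seed RC without any 'G'
        has expectation 0 in the edited state.

    This is a documented stand-in background model, not a reproduction of
    any published expectation column.
    """
    if window_count < 0:
        raise InvalidParameterError(f"window_count must be >= 0, got {window_count}")
    if model == "uniform":
        return window_count * SEED_LENGTH * 0.25**SEED_LENGTH
    if model != "composition":
        raise ConfigurationError(f"unknown background model {model!r}")
    freqs = base_freqs or {b: 0.25 for b in "ACGT"}
    total = 0.0
    for k in range(SEED_LENGTH):  # alignment k: seed index 6-k sits on the center
        center_index = SEED_LENGTH - 1 - k
        prob = 1.0
        for j, letter in enumerate(seed_rc):
            if center_state is not None and j == center_index:
                center_base = "G" if center_state == "edited" else "A"
                prob *= 1.0 if letter == center_base else 0.0
            else:
                prob *= freqs[letter]
        total += prob
    return window_count * total


def bias_table(
    table: MatchTable,
    catalog: list[MiRNA],
    background_model: str = "uniform",
    base_freqs: dict[str, float] | None = None,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_count: int = 0,
) -> pd.DataFrame:
    """One classified row per catalog miRNA.

    Columns mirror the published layout — miR, miRBase ID, Seed (RC),
    Targets(Edited), Targets(Unedited), Expected — plus the fold ratio and
    class.  Rows are sorted by targets_edited descending, ties by name, so
    the created view is the natural head of the table; re-sort by
    targets_unedited for the destroyed view.
    """
    rows = []
    for mir in catalog:
        te = table.total(mir.name, "edited")
        tu = table.total(mir.name, "unedited")
        rows.append(
            BiasRow(
                mirna=mir.name,
                accession=mir.accession,
                seed_rc=mir.seed_rc,
                targets_edited=te,
                targets_unedited=tu,
                fold=fold_ratio(te, tu),
                bias_class=classify_bias(te, tu, fold_threshold, min_count),
                expected=expected_matches(
                    table.n_windows, mir.seed_rc, background_model, base_freqs
                ),
            )
        )
    df = pd.DataFrame(
        {
            "miR": [r.mirna for r in rows],
            "miRBase ID": [r.accession for r in rows],
            "Seed (RC)": [r.seed_rc for r in rows],
            "Targets(Edited)": [r.targets_edited for r in rows],
            "Targets(Unedited)": [r.targets_unedited for r in rows],
            "Expected": [r.expected for r in rows],
            "fold": [r.fold for r in rows],
            "class": [r.bias_class for r in rows],
        }
    )
    return df.sort_values(
        ["Targets(Edited)", "miR"], ascending=[False, True], ignore_index=True
    )


def site_changes(pairs, mirna: MiRNA | str, table: MatchTable) -> list[SiteChange]:
    """Per-window gained/lost target sites for one miRNA.

    Gained offsets are present in the edited state only, lost offsets in
    the unedited state only.  Requires a center-overlapping table: in
    all-positions mode off-center matches are identical between states and
    gained/lost would be polluted by them.
    """
    if table.mode != CENTER_OVERLAPPING:
        raise ModeError(
            f"site_changes needs a {CENTER_OVERLAPPING} match table, got {table.mode}"
        )
    name = mirna.name if isinstance(mirna, MiRNA) else mirna
    changes = []
    for pair in pairs:
        edited = set(table.window_offsets(name, "edited", pair.window_id))
        unedited = set(table.window_offsets(name, "unedited", pair.window_id))
        for o in sorted(edited - unedited):
            changes.append(SiteChange(pair.window_id, name, o, "gained"))
        for o in sorted(unedited - edited):
            changes.append(SiteChange(pair.window_id, name, o, "lost"))
    return changes


def summarize_site_changes(
    changes: list[SiteChange], gene_map: dict[str, str] | None = None
) -> dict:
    """Counts of gained/lost sites, distinct windows, and distinct genes.

    ``gene_map`` maps window id → gene name; windows absent from the map
    are counted as windows but not attributed to any gene.
    """
    gained = [c for c in changes if c.direction == "gained"]
    lost = [c for c in changes if c.direction == "lost"]
    out = {
        "n_gained": len(gained),
        "n_lost": len(lost),
        "n_windows_gained": len({c.window_id for c in gained}),
        "n_windows_lost": len({c.window_id for c in lost}),
    }
    if gene_map is not None:
        out["n_genes_gained"] = len(
            {gene_map[c.window_id] for c in gained if c.window_id in gene_map}
        )
        out["n_genes_lost"] = len(
            {gene_map[c.window_id] for c in lost if c.window_id in gene_map}
        )
    return out
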