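#!/usr/bin/env python
"""Build windows, scan seeds, classify editing bias.

Extracts the 201-nt unedited/edited window pair around every called edit
site, scans both states against the miRNA catalog's seed
reverse-complements (center-overlapping mode), and classifies each miRNA
by the 10-fold rule.  Writes the window FASTAs, the match table, the
classified bias table and per-state position profiles for every biased
miRNA under results/.
"""

from pathlib import Path

import pyfaidx

from editmir import (
    CENTER_OVERLAPPING,
    bias_table,
    build_dataset,
    position_profile,
    read_mirna_fasta,
    scan_dataset,
    site_changes,
    summarize_site_changes,
)
from editmir import io as eio

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "analysis_data"


def main():
    sites = eio.read_sites_tsv(RESULTS / "edit_sites.tsv")
    reference = pyfaidx.Fasta(str(DATA / "reference.fa"))
    pairs, skipped = build_dataset(reference, sites, flank=100)
    eio.write_window_fastas(pairs, RESULTS / "windows")
    print(f"windows: {len(pairs)} pairs built, {len(skipped)} sites skipped")

    catalog = read_mirna_fasta(DATA / "mirnas.fa")
    table = scan_dataset(pairs, catalog, CENTER_OVERLAPPING)
    eio.write_match_table(table, RESULTS / "matches.tsv")
    df = bias_table(table, catalog)
    df.to_csv(RESULTS / "bias_table.tsv", sep="\t", index=False)
    biased = df[df["class"] != "unbiased"]
    print(f"scan:    {len(catalog)} miRNAs x {len(pairs)} windows, "
          f"{int(df['Targets(Edited)'].sum())} edited / "
          f"{int(df['Targets(Unedited)'].sum())} unedited center matches")
    print(f"bias:    {len(biased)} biased miRNAs "
          f"({int((biased['class'] == 'created').sum())} created, "
          f"{int((biased['class'] == 'destroyed').sum())} destroyed)")

    profile_dir = RESULTS / "profiles"
    profile_dir.mkdir(exist_ok=True)
    changes = []
    for name in biased["miR"]:
        for state in ("unedited", "edited"):
            eio.write_profile(position_profile(table, name, state),
                              profile_dir / f"{name}_{state}.tsv")
        changes.extend(site_changes(pairs, name, table))
    eio.write_site_changes(changes, RESULTS / "site_changes.tsv",
                           RESULTS / "site_changes.bed")
    print(f"sites:   {summarize_site_changes(changes)}")
    print(f"wrote {RESULTS / 'bias_table.tsv'}")


if __name__ == "__main__":
    main()
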