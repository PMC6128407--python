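#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes a two-chromosome reference, 120 planted A-to-I edit sites and 30
SNP decoys, the corresponding pileup (depths 10-200, error-free), a
known-SNP mask, a 12-miRNA catalog, and small-RNA reads for two samples
into scratch/analysis_data/.  Everything downstream (02-04) reads from there, so
rerunning this script regenerates the whole analysis deterministically.
"""

from pathlib import Path

from editmir import io as eio
from editmir import make_reference, plant_sites, simulate_pileup, simulate_small_rna
from editmir.seed_scan import MiRNA

import numpy as np

SEED = 20180425
OUT = Path(__file__).resolve().parent.parent / "scratch" / "analysis_data"


def catalog_of(n=12, seed=2, length=22):
    rng = np.random.default_rng(seed)
    return [
        MiRNA(f"mir-{i:02d}", f"MIMAT{i:07d}", "".join(rng.choice(list("ACGU"), size=length)))
        for i in range(n)
    ]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    reference = make_reference(2, 15000, 0.45, SEED)
    truth = plant_sites(reference, 120, 30, (0.05, 0.95), SEED + 1)
    pileup = simulate_pileup(reference, truth, (10, 200), 0.0, SEED + 2)
    catalog = catalog_of()
    abundances = {
        "MCF7": {catalog[0].name: 900, catalog[1].name: 200, catalog[2].name: 40},
        "MDA231": {catalog[0].name: 700, catalog[1].name: 45, catalog[2].name: 350},
    }

    eio.write_fasta(reference, OUT / "reference.fa")
    eio.write_pileup_tsv(pileup, OUT / "pileup.tsv")
    eio.write_pileup_vcf(pileup, OUT / "pileup.vcf")
    eio.write_fasta({f"{m.name} {m.accession}": m.mature for m in catalog}, OUT / "mirnas.fa")
    with open(OUT / "snp_mask.bed", "w") as fh:
        for s in truth.snp_sites:
            fh.write(f"{s.seq}\t{s.pos - 1}\t{s.pos}\n")
    for sample, ab in abundances.items():
        reads = simulate_small_rna(catalog, ab, 0.005, SEED + 10 + len(sample))
        eio.write_fastq(reads, OUT / f"reads_{sample}.fastq")
    eio.write_truth_tsv(truth, OUT / "truth")

    print(f"reference: 2 x 15000 nt (GC 0.45)")
    print(f"planted:   {len(truth.edit_sites)} edit sites, {len(truth.snp_sites)} SNP decoys")
    print(f"catalog:   {len(catalog)} miRNAs; small-RNA reads for {', '.join(abundances)}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
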