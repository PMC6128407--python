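"""End-to-end orchestration: pileup evidence → candidate miRNA table.

The pipeline chains the stages in analysis order — edit calling, window
building, seed scanning, bias classification, expression filtering — and
writes every intermediate as TSV/FASTA/BED into one output directory,
together with the verbatim run configuration and a log recording record
counts into and out of each stage.  Outputs are deterministic for fixed
inputs and configuration, and each stage's outputs are written as soon as
the stage finishes so a later failure leaves them intact.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as eio
from .bias import bias_table, site_changes, summarize_site_changes
from .edit_calling import call_edits, edit_fraction_summary, load_snp_mask, merge_site_sets
from .errors import ConfigurationError
from .expression import assign_reads, compute_rpm, filter_expressed
from .seed_scan import (
    CENTER_OVERLAPPING,
    COUNT_MODES,
    position_profile,
    read_mirna_fasta,
    scan_dataset,
)
from .windows import build_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Threshold defaults are the analysis defaults: depth >= 30 reads and
    edited fraction >= 10% for edit calling, 100-nt flanks, 10-fold bias
    threshold, > 50 RPM expression in every sample, exact read matching.
    """

    reference_fasta: str = ""
    pileup: str = ""  # pileup TSV or VCF 4.2 (chosen by extension)
    snp_mask: str | None = None
    mirna_fasta: str = ""
    small_rna_fastq: dict[str, str] = field(default_factory=dict)  # sample -> FASTQ
    external_sites: dict[str, str] = field(default_factory=dict)  # label -> sites TSV
    sample_label: str = "sample"
    min_depth: int = 30
    min_fraction: float = 0.10
    flank: int = 100
    fold_threshold: float = 10.0
    rpm_threshold: float = 50.0
    max_mismatches: int = 0
    min_identity: float = 0.99
    count_mode: str = CENTER_OVERLAPPING
    rng_seed: int = 0
    outdir: str = "editmir_out"

    def validate(self) -> None:
        if self.count_mode not in COUNT_MODES:
            raise ConfigurationError(
                f"count_mode must be one of {COUNT_MODES}, got {self.count_mode!r}"
            )
        if not 0 < self.min_fraction <= 1:
            raise ConfigurationError(f"min_fraction must be in (0, 1], got {self.min_fraction}")
        positive = {
            "min_depth": self.min_depth,
            "flank": self.flank,
            "fold_threshold": self.fold_threshold,
            "rpm_threshold": self.rpm_threshold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.max_mismatches < 0:
            raise ConfigurationError(f"max_mismatches must be >= 0, got {self.max_mismatches}")
        for label, path in [("reference_fasta", self.reference_fasta),
                            ("pileup", self.pileup),
                            ("mirna_fasta", self.mirna_fasta)]:
            if not path:
                raise ConfigurationError(f"config is missing required path {label!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("editmir")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a name → path map of the written outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    outputs: dict[str, Path] = {"log": outdir / "pipeline.log"}
    try:
        config.to_yaml(outdir / "run_config.yaml")
        outputs["config"] = outdir / "run_config.yaml"

        # ---- edit calling ------------------------------------------------
        if config.pileup.endswith(".vcf"):
            pileup = eio.read_variants_vcf(config.pileup)
        else:
            pileup = eio.read_pileup_tsv(config.pileup)
        mask = load_snp_mask(config.snp_mask) if config.snp_mask else set()
        logger.info("loaded %d pileup records, %d masked positions", len(pileup), len(mask))
        sites = call_edits(
            pileup,
            snp_mask=mask,
            min_depth=config.min_depth,
            min_fraction=config.min_fraction,
            label=config.sample_label,
        )
        site_sets = {config.sample_label: sites}
        for label, path in config.external_sites.items():
            external = eio.read_sites_tsv(path)
            logger.info("external site list %s: %d sites", label, len(external))
            site_sets[label] = external
        merged = merge_site_sets(site_sets)
        logger.info("merged site set: %d sites", len(merged))
        for label, mean in edit_fraction_summary(merged).items():
            logger.info("mean edited fraction [%s]: %.3f", label, mean)
        eio.write_sites_tsv(merged, outdir / "edit_sites.tsv")
        eio.write_sites_bed(merged, outdir / "edit_sites.bed")
        outputs["edit_sites"] = outdir / "edit_sites.tsv"

        # ---- windows -----------------------------------------------------
        import pyfaidx

        reference = pyfaidx.Fasta(config.reference_fasta)
        pairs, skipped = build_dataset(reference, merged, flank=config.flank)
        eio.write_window_fastas(pairs, outdir / "windows")
        outputs["windows_unedited"] = outdir / "windows_unedited.fa"
        outputs["windows_edited"] = outdir / "windows_edited.fa"
        if skipped:
            with open(outdir / "skipped_sites.tsv", "w") as fh:
                fh.write("seq\tpos\tstrand\treason\n")
                for site, reason in skipped:
                    fh.write(f"{site.seq}\t{site.pos}\t{site.strand}\t{reason}\n")
            outputs["skipped_sites"] = outdir / "skipped_sites.tsv"

        # ---- seed scan ---------------------------------------------------
        catalog = read_mirna_fasta(config.mirna_fasta)
        logger.info("catalog: %d miRNAs, %d unique seeds",
                    len(catalog), len({m.seed_rc for m in catalog}))
        table = scan_dataset(pairs, catalog, mode=config.count_mode)
        eio.write_match_table(table, outdir / "matches.tsv")
        eio.write_match_totals(table, outdir / "match_totals.tsv")
        outputs["matches"] = outdir / "matches.tsv"
        outputs["match_totals"] = outdir / "match_totals.tsv"

        # ---- bias --------------------------------------------------------
        bias = bias_table(table, catalog, fold_threshold=config.fold_threshold)
        bias.to_csv(outdir / "bias_table.tsv", sep="\t", index=False)
        outputs["bias_table"] = outdir / "bias_table.tsv"
        biased = bias[bias["class"] != "unbiased"]
        logger.info(
            "biased miRNAs: %d (%d created, %d destroyed)",
            len(biased),
            int((biased["class"] == "created").sum()),
            int((biased["class"] == "destroyed").sum()),
        )
        profiles_dir = outdir / "profiles"
        all_changes = []
        if len(biased) and config.count_mode == CENTER_OVERLAPPING:
            profiles_dir.mkdir(exist_ok=True)
            for name in biased["miR"]:
                for state in ("unedited", "edited"):
                    eio.write_profile(
                        position_profile(table, name, state),
                        profiles_dir / f"{name}_{state}.tsv",
                    )
                all_changes.extend(site_changes(pairs, name, table))
            eio.write_site_changes(
                all_changes, outdir / "site_changes.tsv", outdir / "site_changes.bed"
            )
            outputs["site_changes"] = outdir / "site_changes.tsv"
            logger.info("site changes: %s", summarize_site_changes(all_changes))

        # ---- expression --------------------------------------------------
        expressed: list[str] | None = None
        if config.small_rna_fastq:
            tables = {}
            frames = []
            for sample, fastq in sorted(config.small_rna_fastq.items()):
                reads = eio.read_fastq(fastq)
                counts, unassigned = assign_reads(
                    reads,
                    catalog,
                    max_mismatches=config.max_mismatches,
                    min_identity=config.min_identity,
                )
                logger.info(
                    "expression[%s]: %d reads, %d assigned, %d unassigned",
                    sample, len(reads), sum(counts.values()), unassigned,
                )
                rpm = compute_rpm(counts, len(reads))
                tables[sample] = rpm
                frames.append(rpm.assign(sample=sample))
            expressed = filter_expressed(tables, threshold=config.rpm_threshold)
            import pandas as pd

            expr = pd.concat(frames, ignore_index=True)
            expr["expressed"] = expr.apply(
                lambda r: r["rpm"] > config.rpm_threshold, axis=1
            )
            expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
            outputs["expression"] = outdir / "expression.tsv"

            candidates = biased[biased["miR"].isin(expressed)]
            candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            outputs["candidates"] = outdir / "candidates.tsv"
            logger.info(
                "%d expressed miRNAs, %d biased-and-expressed candidates",
                len(expressed), len(candidates),
            )
    finally:
        logging.getLogger("editmir").removeHandler(handler)
        handler.close()
    return outputs
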