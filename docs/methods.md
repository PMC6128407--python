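# Methods

## Model and assumptions

The analysis treats A-to-I editing as a point substitution observable in
RNA-Seq pileups: inosine is read as guanosine, so a forward-strand edit is
an A→G mismatch against the genome and a reverse-strand edit a T→C
mismatch. Editing state at a site is summarized by the edited fraction
`g/d` (edited-base reads over total depth); no read-level haplotype or
co-editing structure is modeled. miRNA targeting is reduced to exact
7-mer seed complementarity: a target site is an occurrence of
`revcomp(mature[2..8])` (U→T) in the transcript-sense mRNA window. No
G:U wobble, no 8mer/7mer-A1 site-class distinctions, and no
thermodynamic or context scoring — one exact-match definition in both
editing states, which makes "created" and "destroyed" sites exactly
complementary notions.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 30 reads | minimum total coverage for a callable site |
| `min_fraction` | 0.10 | minimum edited-read fraction (inclusive, like the depth bound) |
| `flank` | 100 nt | half-window; windows are 2·flank+1 = 201 nt |
| `fold_threshold` | 10 | fold rule for created/destroyed bias |
| `rpm_threshold` | 50 RPM | strict lower bound for "expressed" |
| `max_mismatches` / `min_identity` | 0 / 0.99 | read-assignment criterion |
| count mode | center-overlapping | offsets `[center−6, center]` only |

Threshold notes:

* Both calling thresholds are inclusive (≥); depth means all reads
  covering the site, not reference+edited only. Other alternative bases at
  an A reference never count as edited — the edit is one specific
  substitution.
* The fold rule divides by `max(count, 1)` so an (n, 0) pair is biased
  whenever n ≥ threshold; biased rows with zero matches in one state are
  common and must qualify. No minimum-count floor is applied on top
  (`min_count` exists, default 0), and no hypothesis test: the
  classification is the fold criterion alone, so the created and destroyed
  sets are provably disjoint for any threshold > 1.
* The expression filter is strict-greater (50 RPM exactly does not pass)
  and requires every sample by default. The RPM denominator is the total
  library size (assigned + unassigned reads); normalizing per
  miRNA-mapped read is available by passing that total instead.
* Read assignment defaults to the strict criterion (exact ungapped
  containment). The looser one-mismatch criterion is exposed through
  `max_mismatches`/`min_identity`; note that for typical ~22-nt reads a
  single mismatch already drops identity to ~0.95, so using it requires
  lowering `min_identity` accordingly.

## Count modes

Center-overlapping counting (default) admits only the 7 offsets whose
7-mer covers the edited base. Those are the only matches a single central
edit can create or destroy; away from the center the two states are
identical, so all-positions counting adds state-independent background to
both totals and dilutes fold ratios. All-positions mode is retained
because a full scan is the natural reading of "every possible 7-mer", and
the two modes are related by a tested locality invariant: outside
`[center−6, center]` the offset sets of the two states are equal.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the stages consume:
i.i.d. background sequence with configurable GC, planted edits on both
strands with ≥100-nt flanks and uniform true fractions, SNP decoys at
het/hom allele fractions (0.5/1.0) so that the SNP mask — not the
fraction filter — is what removes them, binomial edited-read sampling,
uniform-split sequencing error, and window pairs whose only
center-overlapping seed occurrence is the planted one (background is
rejection-sampled until clean, and the planted miRNA's seed occurs
nowhere else in either state, so scans recover the planting exactly).

It deliberately does not emulate: Alu-repeat context (a biological,
not algorithmic, property of real edit sites), read-level alignment
artifacts (BAM), quality-score structure, indels, isomiRs, or co-edited
neighboring sites. Passing tests therefore demonstrate correctness of the
filters, scanning, classification and bookkeeping — not robustness to
alignment artifacts or repeat-induced mismapping, which upstream tools
must handle.

Planted-window classes need enough windows per miRNA to clear the fold
rule (≥ threshold matched windows for a created call), so the generator
distributes the requested created/destroyed windows round-robin over
`n_mirnas_created`/`n_mirnas_destroyed` distinct miRNAs and records the
planting per miRNA; tests compare classifications against the truth's own
counts rather than assuming a class.

## Background expectation model

The expected center-overlapping match count per miRNA is a configurable
stand-in, not a fitted quantity: the `uniform` model is
`n_windows · 7 · (1/4)^7`; the `composition` model replaces `1/4` with
position-independent background base frequencies, and reduces to the
uniform model when those frequencies are uniform. An optional
`center_state` argument conditions on the known center base (G edited, A
unedited), turning the center-aligned factor into an indicator — under it
a seed RC with no G has zero edited-state expectation. The default leaves
the center unconditioned so the limiting-case identity holds.

## Numerical and procedural choices

* Coordinates are 1-based internally; BED converts at the boundary.
* Scanning uppercases input; `N` never matches (it is ambiguity, not a base).
* Duplicate seed RCs are scanned once and fanned out — observationally
  identical to scanning each miRNA, and tested as an invariant.
* Read-assignment ties (equal score) go to the lexicographically first
  miRNA name; determinism over biological arbitrariness.
* Site merging de-duplicates on (sequence, position, strand) and unions
  sample labels; the same coordinate with conflicting strands is an error
  rather than a silent duplicate.
* Windows with incomplete flanks are skipped with a logged reason, not
  N-padded (padding would manufacture artificial non-matches). When two
  edits fall within one flank, each window edits only its own center;
  co-editing is a known limitation.
* All generators consume one explicit integer seed; the acceptance script
  derives per-stage child seeds (< 2^31) from a single `--seed` via
  `numpy.random.SeedSequence`.

## Problem sizes

The bundled analysis and acceptance runs use two 12–15 kb chromosomes,
120–200 planted edits, 30–50 decoys, catalogs of 10–15 miRNAs and
libraries of ~10³ reads. These sizes were chosen so every recovery check
is exact and the whole analysis reruns in seconds; every stage is linear
(or near-linear) in sequence length, window count and catalog size, so
genome-scale inputs are a matter of runtime, not algorithm.

## Known limitations

* Strand must be supplied with the evidence (pileup ref base orientation);
  no inference from gene annotation or read orientation.
* dbSNP masking is positional, not allele-aware.
* The 20-entry published-catalog fixture carries synthetic stand-in mature
  sequences constrained to the published seed regions (only miR-140-3p's
  mature is the verbatim catalog sequence); it validates the seed
  derivation convention, not full-length mature sequences.
* The fold rule is a ratio test without uncertainty; with small counts a
  single match can flip a class. Callers needing calibrated significance
  should layer a count model on top of the reported totals.
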