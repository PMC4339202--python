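# Methods

## Coordinate and sentinel conventions

All intervals are 0-based, half-open; the GFF3 reader/writer converts from
and to the 1-based inclusive convention at the boundary, and BED output is
native. "No BLAST hit" is the IEEE `+inf` sentinel in memory, serialised as
`NA`; every E-value filter treats it as failing, which avoids the ambiguity
of large-number placeholders. All E-value threshold comparisons are strict
("lower than"): a value exactly at the threshold fails the filter.

## The staged loss screen

Stage 1 consumes *orthology calls* (one2one / one2many / many2many / none),
not raw E-values, mirroring how orthology-database queries differ from
BLAST: a gene passes with any non-`none` call in every Dikarya taxon —
one2many is accepted because a lineage-specific duplication of a shared
ancestral gene is not a loss — and `none` in both bilaterian seed taxa.
Stages 2–4 use the E-value matrix: E < 1e-30 in the primary choanoflagellate,
E < 1e-10 in each secondary holozoan, and no animal E-value better than the
non-animal holozoans. The last comparison is ambiguous in ordinary prose
("better than any"): the default reads it as *better than the best*
holozoan value; `stage4_mode="worst"` switches to the alternative reading
(better than the worst), which drops strictly more genes. Residual-hit
classification takes precomputed inputs (full-database best taxon,
reciprocal-best family) rather than issuing live queries, so the pipeline
has no network dependency; a full-scale run supplies these from saved BLAST
reports.

Paralog collapse treats the supplied groups as a partition; a function is
named by its surviving members joined with `/`, so the operation is
idempotent and `|functions| <= |genes|`. The PFAM-complement screen's
presence/absence E-value criterion is not recorded anywhere authoritative;
the default 1e-30 is a package choice and is stated in output metadata.
Enrichment p-values are upper-tail hypergeometric (SciPy), reported raw, with
Benjamini–Hochberg adjustment available when several categories are tested.

## Motif models and scanning

Degenerate consensus patterns accept `.` as an alias for N and the IUPAC
one-letter codes. Scanning matches the pattern on the forward strand and its
reverse complement for minus-strand hits; overlapping occurrences are all
reported. A palindromic pattern (the perfect HSE4 is its own reverse
complement) matches both strands at identical intervals; such pairs collapse
to one locus with strand `+`, because locus counts — not strand-matches —
are what the precision metric uses. Same-model hits whose starts differ by
fewer than 5 bp can be merged (`merge_nearby_hits`) since N-runs otherwise
inflate locus counts with 1-bp-shifted duplicates; the raw scanner never
merges, so it stays comparable to a per-window oracle.

PWMs are additive count matrices plus a uniform pseudocount Ψ; no published
scoring rule exists for the printed digit matrices, so the match threshold
is calibrated to the minimum training-site score. This guarantees training
sites are always recovered, at the cost of making locus lists for the
PWM-based models approximate; reports state the threshold used. The printed
`T:…, C:…, G:…, A:…` digit-row syntax is parsed verbatim into weights.

HSE arrays are modelled as alternating TTC/GAA triplets with 2-bp gaps
(unit i at offset 5i). A "skip" maps a unit to the number of leading triplet
bases kept (0–2), which covers both fully skipped triplets
(`TTCnnGAAnnnnnnnGAA`) and partially retained ones
(`TTC..GAA..TTC..G....TTC`); end-clipping trims bases off either end
(`CnnGAAnnTTCnnG`). At least three intact triplets are required, matching
the biology of Hsf1 trimer binding.

Promoter assignment: a CDS overlap wins outright; otherwise a hit is
assigned to the nearest gene whose strand-aware upstream window contains it
(default 1000 bp — the source analyses never state a window; the dot-plot
regions were 320 bp). Distance is the gap in bp between the hit's 3' end and
the ORF start; an abutting hit (gap 0) counts as promoter. Ties break by
distance then lexicographic gene id. Precision = promoter loci in the
curated set / (distinct promoter genes + CDS hits); intergenic hits are not
loci. Adding a CDS hit can only lower precision.

## Composite architecture search and dot plots

A window of `window_len` (default 160 bp) qualifies when it contains at
least `min_stre` (default 3) STRE matches — counted on both strands at
distinct start positions, overlapping occurrences each counting — and one
match to any HSE alternative (defaults: the skipped HSE4 and the end-clipped
HSE4). Qualifying windows are reduced to their *evidence span* (from the
leftmost matched element to the rightmost) before merging, so a reported
locus never spills into a neighbouring CDS merely because the sliding window
did. Merged spans are assigned to loci with the promoter rules above.

Dot plots index `word_size`-mers (default 8) of one sequence and find
maximal diagonal runs of exact word matches, forward or
reverse-complemented; a block is kept when it spans at least `min_block` bp
(run length + word_size − 1). The serial-alignment test asks whether two or
more forward blocks are collinear (x and y orders agree), the signature of a
shared ordered promoter architecture. The original comparison was
BLASTN-based with unstated parameters, so block coordinates here are
qualitative, not bit-exact reproductions.

## Co-expression meta-analysis

Per dataset, Pearson r between a gene and the query profile over shared
finite samples (pairwise deletion; fewer than 3 shared samples or zero
variance excludes the dataset for that gene). r is clipped to
±(1 − 1e-12) before z = atanh(r). Combined score = mean z across usable
datasets; multi-gene queries use the mean of the per-gene standardised
profiles. The published "Adjusted Correlation Scores" come from the SPELL
service, whose query-driven dataset weighting is not specified in the source
material; uniform weights are the default (an optional variance-based weight
exists), so rankings are comparable but scores are not numerically identical
to SPELL's — SPELL score values are therefore never used as targets. Under
independence z·sqrt(n−3) is approximately standard normal, which the tests
use as an analytic null.

## Residue analysis

A column is family-specific when each family's non-gap residues are
conserved at ≥ `conservation` frequency (default 1.0, strict identity, as
full shading in annotated alignments implies) and the two consensus residues
differ. The hydrophobic set defaults to {V,L,I,M,F,W,C}; alanine is classed
with the small-neutral residues {G,A,S,P} rather than the hydrophobics, and
both sets are configurable with the scheme stated in outputs. Published
counts of 12/29 and 41.4% depend on an alignment annotation that is not
machine-readable, so they are soft checks only; the package verifies the
fraction arithmetic and exact recovery on generated alignments instead.

## Synthetic data: what it emulates and what it does not

`gen_evalue_matrix` plants five gene classes: retained everywhere, lost in
animals, lost with a contaminant animal cell, lost in choanoflagellates too,
and absent from a Dikarya taxon (defaults 5% lost, 20% of those with
contaminants, 5% each for the two filter-exercising classes, 5% paralog
duplication). Retained/lost cells draw log10 E uniformly in [−180, −40],
contaminant cells in [−60, −20]; the contaminant draw is truncated to stay
strictly worse than the gene's best non-animal holozoan value so that screen
recovery is exact for every seed — without the truncation a rare contaminant
could legitimately beat the holozoans and be (correctly) removed at stage 4,
making exactness impossible. Paralog duplicates jitter log10 E by ±2.
The generator does not emulate assembly gaps, annotation errors, or E-value
correlation across related taxa, so exact recovery here shows the filter
logic is right, not that real screens are error-free.

`gen_genome_with_motifs` lays out genes (600 bp CDS, random strand)
separated by intergenic stretches (default 500 bp) of i.i.d. background at
the given GC (default 0.38, a yeast-like value). Planted instances are
sampled from their model's degenerate pattern, resampled if they would
accidentally spell a *different* planted model's consensus (matches logically
implied by pattern nesting — every perfect HSE4 contains an end-clipped HSE4
— are sanctioned and kept). Background windows matching any planted model on
either strand are redrawn until none remain, so consensus scans equal the
truth table exactly. Architecture plants place one HSE alternative plus
`min_stre` STREs at 13-bp spacing within the window. No higher-order
sequence structure (codon bias, nucleosome-free regions) is simulated.

`gen_expression_compendium` gives regulon genes sqrt(rho)·f + sqrt(1−rho)·ε
with a dataset-specific standard-normal factor f, so the pairwise regulon
correlation is rho at unit noise; non-regulon genes are independent noise.
Gaussianity makes the Fisher-z null analytic. Real compendia have
heavy-tailed, batch-structured noise that this does not model.

`gen_labeled_alignment` fixes `n_specific` columns at differing residues per
family (a chosen fraction of family-A residues hydrophobic) and fills the
rest with a shared residue, sparsely mutated in single rows to break
conservation without creating spurious family-specific columns. No gaps or
phylogenetic correlation are simulated.

## Problem sizes and determinism

The automated checks use: 1,000-gene matrices × 10 seeds for screen
recovery; 20 random degenerate patterns × 10,000 windows against a
brute-force per-window oracle; 100-gene genomes with 10 perfect-HSE4 and 3
architecture plants × 10 seeds; 10,000 genes × 20 samples for null
calibration (expected one-sided 1.96 exceedance 2.5%); 100 compendium seeds
(20 datasets × 100 genes × 10 samples, rho 0.7) for regulon recovery; and
exhaustive enumeration for every enrichment background of size ≤ 12. Every
generator takes an explicit seed and is byte-deterministic given it;
`scripts/acceptance.py` derives all sub-seeds from its `--seed` argument.

## Known limitations

- Orthology calls are inputs, not recomputed; tree-based orthology
  inference, phylogenetic tree building and live database/taxonomy queries
  are out of scope.
- PWM locus lists depend on the calibrated-threshold rule above and are not
  expected to reproduce published PWM model counts exactly.
- Whether bidirectional promoters should count as one locus or two is
  unresolved in the source analyses; this package counts one locus per
  assigned gene, so a divergent promoter shared by two genes yields one
  locus per gene only if separately matched.
- Dot-plot blocks are exact-word matches, not gapped alignments.
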