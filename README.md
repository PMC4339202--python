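# lossmark

Phylogenetic gene-loss screening and heat-shock-element (HSE) regulon
analysis.

## The problem

The origin of animals was accompanied not only by new developmental genes
but by the *loss* of genes that their closest relatives — choanoflagellates,
filastereans and fungi — still carry. Two linked analyses identify and
characterise such losses:

1. **A staged phylogenetic-profiling screen.** Starting from a fungal
   reference proteome, genes are kept that (i) have orthology calls in a
   Dikarya panel but none in two well-assembled bilaterians (lineage-specific
   duplications accepted), (ii) hit the primary choanoflagellate proteome
   with BLASTP E < 1e-30 (strict), (iii) are detectable (E < 1e-10) in the
   secondary holozoans, and (iv) have no animal match better than the best
   non-animal holozoan match. Survivors collapse into *genetic functions* by
   merging lineage-specific paralog pairs, and residual animal matches are
   classified as contamination/horizontal transfer (closest full-database
   relative is non-opisthokont), non-orthologs (reciprocal match belongs to a
   different family), or possible orthologs. A PFAM-complement screen adds
   families absent from the reference proteome itself.

2. **Regulatory analysis of the jointly lost ClpB disaggregases** (cytosolic
   HSP104, mitochondrial HSP78). Their promoters share an Hsf1-binding HSE
   built from inverted 5'-nGAAn repeats. The package models this signature as
   a degenerate IUPAC consensus (e.g. the perfect HSE4
   `TTCYRGAAnnTTCYRGAA`), an additive position weight matrix with
   pseudocount (weight(b,i) = count(b,i) + Ψ, threshold calibrated to the
   weakest training site), a skipped/clipped nGAAn array, or a composite
   architecture (an HSE plus ≥3 stress-response elements `CCCCT` within a
   160 bp window). Genome scans report both strands, assign hits to
   promoters/CDS, and score each model by its **regulon precision**: the
   fraction of matched loci whose gene belongs to a curated proteostasis set
   (CDS hits count in the denominator). Co-regulation is corroborated by
   Fisher-z co-expression meta-analysis — per-dataset Pearson r, z =
   atanh(r), combined by averaging across a compendium — and by the
   hydrophobic fraction of family-specific residues in candidate client
   proteins (exposed hydrophobics are what disaggregases recognise).

Because the full analysis normally needs genome downloads, the package ships
first-class synthetic-data generators that plant known structure — lost
genes, promoter motifs, a co-regulated regulon, family-specific alignment
columns — and return machine-readable truth tables, so every stage is
testable for *exact* recovery. The genome generator removes chance motif
matches by rejection resampling, making planted-truth comparisons exact
rather than probabilistic.

## Worked example

```python
import lossmark as lm

matrix, truth = lm.gen_evalue_matrix(500, loss_fraction=0.05,
                                     contaminant_rate=0.2, seed=0)
result = lm.run_screen(matrix, paralog_groups=lm.truth_paralog_groups(truth))
print("survivors:", len(result.final))
print("functions:", len(result.functions))
```

prints

```
survivors: 26
functions: 25
```

26 genes survive all four stages and collapse into 25 genetic functions (one
surviving paralog pair, reported as a single `a/b` function). Their residual
animal hits split into 21 `no_hit` and 5 `contaminant_or_hgt` — exactly the
planted contaminants, whose best full-database relatives are
non-opisthokont. The same objects are available from the shell:

```sh
lossmark simulate screen --n-genes 500 --seed 0 --out-dir sim/
lossmark screen --evalues sim/evalues.tsv --ortho-flags sim/ortho_flags.tsv \
    --out screen.tsv
lossmark motif-scan --genome genome.fa --gff genome.gff3 \
    --model "TTCYRGAAnnTTCYRGAA" --annotation-set proteostasis.txt
```

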