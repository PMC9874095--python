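# viromescope

Case–control analysis of the human gut virome, built as a tested, fully
reproducible pipeline with a synthetic community generator for ground-truth
validation.

Gut viromes are profiled from two kinds of shotgun libraries: **bulk**
metagenomes (total fecal DNA) and **VLP** metagenomes (virus-like particles
physically enriched before sequencing). Starting from assembled contigs and
per-contig detector evidence, `viromescope` reproduces the full downstream
analysis of a 16-patient / 31-control study design:

1. **Viral-contig triage.** Bulk contigs (≥ 2 kbp) are viral when they pass
   *all* gates: CheckV-style gene screen (removed only if viral genes <
   microbial genes), DeepVirFinder thresholds (*p* < 0.01 and score > 0.90)
   OR a VIBRANT call, and a CheckV tier in {complete, high, medium}. VLP
   contigs use the *disjunction* of the three criteria with no tier removal.
   Contigs with a BUSCO ratio ≥ 5% (bacterial single-copy orthologs / total
   genes) are removed as contamination.
2. **vOTU dereplication.** Sequences sharing ≥ 95% nucleotide identity over
   ≥ 75% of the (shorter) sequence are greedily clustered into viral
   operational taxonomic units (vOTUs), longest-first, using a built-in
   seed-and-extend local aligner (word size 20, merged HSPs).
3. **Taxonomy & host prediction.** Family by protein-hit plurality vote
   (query/subject cover ≥ 50, identity ≥ 30, bit ≥ 50; assigned when > ¼ of
   proteins agree); hosts by prophage matches (≥ 90% identity over ≥ 30% of
   the virus) and CRISPR-spacer matches (built-in exact-repeat array
   detector, ≥ 2 repeats; blastn-short scoring, bit-score ≥ 45).
4. **Community statistics.** Shannon diversity H = −Σ pᵢ ln pᵢ, rarefaction
   over samples, Bray–Curtis distances, PERMANOVA (1000 permutations,
   pseudo-F from the Gower-centred partition), dbRDA ordination, Wilcoxon
   rank-sum differential abundance with Benjamini–Hochberg FDR and log₂
   fold classes, per-feature effect sizes, and the Spearman vOTU × genus
   network (|ρ| > 0.6, adjusted *p* < 0.05).
5. **Classification.** 1000-tree random forest, rank-formula ROC/AUC with
   stratified-bootstrap CI, and the importance-ranked top-k feature-subset
   AUC curve.

The **synthetic community generator** plants every signal the pipeline is
supposed to find — viral/non-viral contig labels, prophages and CRISPR
spacers that are verbatim substrings of their source virus, group effects
of known log₂ magnitude, and virus–bacterium pairs with a target Spearman
ρ — so every stage is tested against exact ground truth.

## Worked example

```python
from viromescope import PipelineConfig, run_all

report = run_all(PipelineConfig(seed=1), "out/")
print(report.metrics["triage_accuracy_pct"])   # 97.207
print(report.counts["n_votus"])                # 17
print(report.metrics["permanova_R2_pct"],      # 10.893
      report.metrics["permanova_p"])           # 0.000999...
print(report.metrics["rf_oob_auc"])            # 0.998
print(report.counts["best_k"])                 # 20
```

Reading the numbers: with moderate detector noise the triage rules label
97.2% of 752 synthetic contigs correctly; the 357 retained viral contigs
dereplicate into 17 vOTUs; disease state explains 10.9% of Bray–Curtis
variance (PERMANOVA *p* ≈ 0.001, the 1/1001 permutation floor); and the
out-of-bag AUC of the 1000-tree forest on the vOTU profile is 0.998, with
the best feature subset at k = 20 vOTUs. All stage artifacts (decision
tables, vOTU membership, host assignments, profiles, distance matrices, a
Cytoscape-loadable edge list, ROC points) are written under `out/`.

The same run is available from the shell:

```bash
viromescope all --seed 1 --out out/
```

and each stage also runs standalone on files, e.g.

```bash
viromescope triage --mode bulk --contigs contigs.fasta --evidence evidence.tsv --out triaged/
viromescope derep --fasta triaged/retained.fasta --id 95 --cov 0.75 --out votus/
```

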