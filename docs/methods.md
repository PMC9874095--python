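# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Study design and seeding

The default design is 16 cases ("SLE") versus 31 controls, the layout the
pipeline is built around. A single global seed fans out to per-stage seeds
via `numpy.random.SeedSequence([seed, stage_index])` with a fixed stage
order, so stages are individually reproducible and never share a stream;
all derived seeds stay below 2³¹. Two runs with identical config and seed
produce byte-identical artifacts.

## Viral-contig triage

Bulk and VLP libraries use different decision rules (conjunctive versus
disjunctive; see the README), reflecting that bulk assemblies are
dominated by bacterial sequence while VLP assemblies are virus-enriched.
Boundary conventions follow the printed inequalities literally: the
DeepVirFinder gates are strict (*p* < 0.01, score > 0.90), the bulk gene
screen removes only when viral genes are strictly fewer than microbial
genes (ties are kept, and the asymmetric VLP criterion requires strictly
more), and the BUSCO contamination boundary is inclusive at exactly 5%.
A contig with a missing evidence row raises an error rather than being
imputed — silent imputation would corrupt the downstream counts.

## Local alignment engine

Dereplication and host prediction share a seed-and-extend local aligner:

* exact *k*-mer seeds (word size 20 for contig-scale work, 8 for spacers)
  locate candidate diagonals;
* on each diagonal, match/mismatch scores (+1/−2; +2/−3 for spacers) are
  accumulated and **all** maximal-scoring ungapped segments are extracted
  with the Ruzzo–Tompa algorithm over run-length-compressed scores;
* HSPs are merged on the query axis with overlaps counted once (the
  higher-scoring HSP keeps contested columns); identity is length-weighted
  across merged segments and aligned fractions are merged covered length
  over sequence length.

Extension is deliberately **ungapped**: the synthetic divergence model is
substitution-only, where ungapped segments recover the optimal local
alignment, and the test suite holds the engine to within 1 identity point
and 0.02 coverage of a full affine-gap Smith–Waterman oracle on planted
pairs. Real indel-rich homology would be underestimated; that is a known
limitation, not a target use. There is no E-value: spurious-hit control
comes from the seed length plus a minimum merged alignment length of 100
columns (two unrelated random 3 kb sequences share an exact 20-mer with
probability ≈ L²/4²⁰ ≪ 1). The engine aligns the given strands only; a
reverse-complement pass would be needed for real data, where orientation
is arbitrary.

## vOTU clustering

Greedy, representative-based: sequences sorted by (length descending, id
ascending) join the first representative they match at ≥ 95% identity
over ≥ 75% coverage, else found a new cluster; the representative is the
founding (longest) member with lexicographic tie-break, making the
partition deterministic. "75% of the sequence" is resolved as the aligned
fraction of the **shorter** sequence (the common convention for viral
dereplication); the denominator is a config option (`shorter` | `query` |
`subject`). Bulk and VLP contigs are clustered jointly as one pool.
Membership is verified against representatives only — a property test
asserts post hoc that every member passes both thresholds against its
representative.

## Taxonomy and host prediction

The family vote counts **proteins, not hits**: hits are filtered (query
and subject cover ≥ 50, identity ≥ 30, bit ≥ 50), reduced to the best
bit-score hit per protein, and a family is assigned only when strictly
more than a quarter of the virus's proteins agree. A tied plurality is
`unclassified` — the rule presumes a unique family and ambiguous evidence
should not invent one.

The CRISPR detector anchors on minimal-length (23-mer) exact repeats,
chains occurrences at spacings compatible with repeat length 23–47 nt and
spacer length 26–50 nt, requires ≥ 2 repeat copies, and fixes the repeat
boundary by extending while *all* copies agree. Exact-repeat detection
cannot place the boundary when all spacers begin (or end) with the same
base; the generator therefore plants arrays whose consecutive spacers
differ in first and last base (sampled from the source virus, so spacers
stay verbatim substrings), making boundaries exactly identifiable. A
`max_mismatches=1` knob relaxes both chaining and extension for
degenerate repeats.

Spacer matches are scored with blastn-short conventions (reward +2,
penalty −3) and converted to bits with the Karlin–Altschul constants
λ = 0.625, K = 0.41, so for a perfect n-base match bit(n) =
(0.625·2n + 0.8916)/0.6931 and the ≥ 45-bit threshold corresponds to a
≈ 24-base exact match. Prophage assignments require ≥ 90% merged identity
covering ≥ 30% of the **viral** sequence. A virus whose assignments span
more than one host genus is counted once in the `multi-host` census
category.

## Profiling and statistics

Counts are closed per sample to relative abundances; all-zero samples are
preserved and flagged. Taxon aggregation sums within taxa (missing
assignments pool into `unclassified`) and commutes with normalisation.
No length normalisation is applied before closure (flagged config-level
choice; the upstream quantification is out of scope and the generator
emits count tables directly).

* Shannon diversity uses natural log (the vegan default).
* PERMANOVA uses the hat-matrix trace form of the distance-based linear
  model (SS_model = tr(HGH) with G the Gower-centred squared-distance
  matrix), which reduces to the classic two-group pseudo-F — verified
  against an independent implementation and exhaustive permutation oracles
  — and also accepts a single continuous constraint; that continuous form
  is how per-feature effect sizes (variance of one community explained by
  one feature of the other) are computed. Permutation p-values use the
  +1/+1 convention and can therefore never be 0 (floor 1/(n_perm+1)).
* dbRDA embeds the distance matrix by principal coordinates, discards
  negative eigenvalues with a warning (no Lingoes/Cailliez correction),
  and regresses the coordinates on the centred group indicator; reported
  axes are the first constrained and first residual axis.
* The Wilcoxon rank-sum test uses exact enumeration when both groups have
  fewer than 8 samples and no ties, otherwise the normal approximation
  with tie correction. BH adjustment runs across all features at the
  tested taxonomic level (the widest defensible family); for the network,
  across all vOTU × genus pairs. The fold-change pseudocount is half the
  smallest nonzero relative abundance in the table (scale-adaptive, keeps
  zero-mean folds finite). Volcano classes use |log₂ fold| > 2 and
  q < 0.05; significance stars are q < 0.05/0.01/0.001, all strict.
* Network edges require |ρ| > 0.6 (strict) AND BH q < 0.05; ρ uses
  tie-corrected ranks and the t-approximation for p. Fewer than 4 shared
  samples is an error (the p-value is meaningless below that).

## Classification

Random forest with 1000 trees (scikit-learn, impurity importances). AUC
is the rank (Mann–Whitney) formula with half credit for ties, identical
to the trapezoidal area under the empirical ROC; the 95% CI is a
stratified bootstrap percentile interval (2000 resamples), a documented
deviation from the DeLong interval of pROC. Because the evaluation scheme
dominates at this sample size, out-of-bag (OOB), resubstitution and
5-fold CV are all available and the pipeline reports OOB and
resubstitution side by side; none is presented as "the" published value.

Two optimisms are surfaced rather than hidden: the subset curve ranks
features on the full model and then retrains on top-k, so subset AUCs
share information with the ranking (the result carries a note); and OOB
scoring is *pessimistic* under the null — a sample's own label never
informs the trees that score it, so label-shuffled OOB AUCs centre around
≈ 0.45 with wide per-seed scatter rather than exactly 0.5. Ties in the
best subset AUC resolve to the smallest k.

## Synthetic generator: what it emulates, and what it does not

Emulated: the bulk/VLP viral-fraction asymmetry (defaults 0.3 vs 0.8);
detector evidence that separates viral from non-viral contigs (Beta(8,2)
vs Beta(2,8) scores, p = (1−score)², tier and gene-count distributions),
with a noise `level` interpolating to a deterministic perfectly separated
limit at 0; planted prophages and spacers as verbatim substrings;
log-normal abundances (per-feature means N(0, 1.5), unit log-noise)
closed to relative abundances; group effects with a pre-noise log₂ ratio
of `effect_log2` (default 2, i.e. 4-fold) on 16 of 120 vOTUs; and
correlated pairs sharing a Gaussian noise component whose weight is
chosen so the pair's latent Spearman ρ is `rho_target` (default 0.9)
without inflating marginal variances. Pairs sit on the study-associated
(differential) vOTUs, and the partner genus shares the disease shift —
otherwise the group effect is pair-incoherent variance that attenuates
the realised correlation well below its target after closure.

Not emulated: read-level sequencing (FASTQ), sequencing error, assembly
artifacts, repeat structure beyond the planted elements, strand
orientation, indel divergence, and compositional phenomena beyond what
closure of independent log-normals induces. Passing tests therefore show
that the *rules and statistics* are implemented correctly and recover
planted truth under controlled conditions — not that the upstream
detectors themselves would perform this well on real sequencing data.

## Problem sizes

The default end-to-end study (also used by `scripts/acceptance.py`) runs
47 samples × 8 contigs per library type (752 contigs), 8 viral and 4 host
genomes, 120 vOTUs × 40 genera in the abundance study, 1000 PERMANOVA
permutations and 1000 trees — about 35 s on one CPU. Calibration tests
use reduced feature counts (e.g. 15 features for the 500-simulation
PERMANOVA type-I-error sweep) and the oracle-equivalence tests use 30
sequences in 8 planted families plus 100 planted pairs ≤ 2.5 kb; these
sizes are the package's own test-design choices and are fixed in the
tests themselves.

## Known limitations

* Ungapped extension and single-strand alignment (see above).
* The CRISPR detector requires exact repeat copies by default; MinCED-like
  degeneracy tolerance is limited to one mismatch.
* The evidence model treats detector outputs as exchangeable surrogates;
  it does not model correlations between detectors on real contigs.
* Relative-abundance statistics inherit the usual compositional caveats;
  no CLR/SparCC-style correction is applied (out of scope by design).
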