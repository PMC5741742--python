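# Methods

## Problem and model

`hybridtx` analyses gene-expression matrices from cell-fusion experiments
in which an ES-cell line and a fibroblast line are fused and the
resulting hybrid clones adopt one of the two parental phenotypes. Because
the hybrids are near-tetraploid, tetraploid subclones of both parents
serve as the ploidy-matched reference; the diploid parents are carried
along for clustering and for an alternative diploid-referenced
classification (`reference_ploidy="2N"`).

All decisions run on replicate-mean FPKM with three fixed constants:

| parameter | default | meaning |
|---|---|---|
| `fpkm_floor` | 10 FPKM | below this a gene counts as unexpressed |
| `fold_threshold` T | 2 | "differential" between parents; also the half-width of the "at the level of a parent" proximity band |
| `pseudocount` ψ | 1 FPKM | added before log ratios; matches the log10(FPKM+1) display transform and stabilises near-zero values |

### Pool partition

Pool a requires the line mean below the floor in both reference parents
and in *every* hybrid clone (a per-line statement, not per-replicate).
Among the remaining genes, the parental contrast is tested per gene with
a Welch t-test on log2(FPKM+ψ) across replicates, Benjamini–Hochberg
adjusted over all tested genes at `alpha = 0.05`. Significant genes with
|log2 ratio| > log2 T are pool d, significant genes at or below it pool
c, non-significant genes pool b. The source workflow separates "equal"
from "minor difference" without stating a criterion; a replicate-level
significance test is the natural reading of its expression-difference
testing, and a fold-only mode (pool b iff fold ≤ `equal_fold`, default
1.2) is provided for designs without replicates. Zero-variance gene pairs
(possible with noiseless synthetic replicates) take the limiting p-value:
0 when the means differ, 1 when equal — without this, exact recovery on
noiseless data would be undefined.

### Dominance groups

For a pool-d gene in a clone with hybrid mean h, match-parent mean m
(the parent whose phenotype the clone adopted) and other-parent mean o,
distances are d_M = |log2((h+ψ)/(m+ψ))| and d_O likewise; "within band"
means ≤ log2 T. The staged rule — low first, then band membership, then
the between/outside split — is equivalent to six disjoint regions
(verified against a brute-force region evaluation in the tests). Two
deliberate choices:

* when the parental ratio is between T and T² the bands overlap and the
  hybrid can be within both; the nearer parent wins, exact ties go to
  group 1 (deterministic, symmetric; ties are measure-zero);
* group 2 requires being outside *both* bands, not merely between the
  parents, keeping groups 1/3 and 2 disjoint by construction.

Statistical gating of group 4 beyond the band rule is off by default (the
source's wording mixes fold and significance language); the band rule is
the only criterion used. Pool-a genes whose hybrid mean reaches the floor
can be listed separately (`evaluate_low_pool=True`) as
"activated-from-low"; they never enter the group counts because they have
no parental contrast to classify against.

Summaries report percentages over groups 1–4 only, with low-in-clone
counted but excluded from the denominator, rounded half-up to
`rounding` (default 1) decimals — the convention of the published
summary tables this mirrors.

### Parental origin

Informative SNPs must be homozygous-divergent between the parental
transcriptomes: per parent (replicates pooled) coverage ≥ 10 and foreign
allele ≤ 5% of reads. Per clone, replicate reads are pooled per SNP
before calling — coverage at a single site is low enough that splitting
replicates would only inflate NO_DATA calls. A SNP is biallelic when each
allele has ≥ 2 reads and the minor allele is ≥ 10% of coverage; these
per-SNP thresholds are this package's own (none are published for the
workflow it mirrors) and are argument-exposed. A gene is BOTH if all its
called SNPs are biallelic, ONE_PARENT if all are monoallelic — including
discordant ONE_ES/ONE_FIB mixtures, read as "only from one of the
parental genomes" per SNP; `strict=True` reclassifies discordant
mixtures as MIXED — and MIXED otherwise. Genes with only NO_DATA calls
are excluded from summaries.

### Clustering

Profiles are log10(FPKM+1); distance 1 − Pearson with average linkage by
default (the workflow mirrored here names neither; correlation distance
matches its similarity language, and both are configurable, as is
`level="sample"` to cluster replicates instead of line means). Constant
profiles make correlation undefined and raise an error naming the
profile. Newick export carries branch lengths (cophenetic heights).

## Synthetic data generator

The generator emulates the study design — 2 parents × {2N, 4N}, four
hybrid clones (two per phenotype), triplicates — with defaults taken from
the motivating experiment wherever it states them:

* pool proportions 14794 : 2274 : 2988 : 2848 (a:b:c:d over 22,904);
* dominance-group proportions per phenotype from the observed per-clone
  subgroup counts (ES-like 933/607/293/460/555, fibroblast-like
  828/704/391/488/437 over 2,848);
* origin proportions 1.1% one-parent, 96.8% both, 2.1% mixed; biallelic
  allele fraction 0.5 (1:1 parental genomes);
* default clone ids and parental line names follow the same experiment.

Where the source is silent, values were chosen once as field-plausible:
expressed-gene means log-normal around ~60 FPKM (log10 loc 1.8, scale
0.4, floored at 20); pool-d lower parent log-uniform on [15, 200] FPKM
with |log2 fold| uniform on [1.2, 5]; pool-c |log2 fold| uniform on
[0.3, 0.8]; replicate noise multiplicative lognormal with `noise_sd`
(natural-log sd) 0.05; ~2 informative SNPs per gene (Poisson); ~100×
coverage per SNP per sample (Poisson), zeroed where the line mean is
below 1 FPKM so silent genes yield empty count rows.

Truth labels are realised geometrically so that the noiseless dataset is
exactly classifiable (a property the tests enforce by running the
classifier as the oracle): group 1 at the match parent, group 2 at the
geometric midpoint, group 3 at the other parent, group 4 at
`group4_fold` (default 4×) above the higher parent (a "down" placement
below the lower parent exists but falls back to "up" whenever it would
cross the expression floor), low-in-clone log-uniform on [0.5, 4] FPKM.
Genes slated for group 2 in any clone have their parental fold resampled
to |log2| ≥ 3 (`group2_min_log2_fold`): the midpoint of a barely-4-fold
pair sits exactly on both proximity bands, which would make
"intermediate" a knife-edge label rather than a distinct expression
state. A fold too small for a requested geometry is never emitted with an
inconsistent label.

Same-phenotype clones share a per-gene label that each clone re-draws
independently with probability `label_resample_prob = 0.2` from its own
proportions. Fully independent labels would contradict the mirrored
experiment, where memory and novel behaviour recur across clones of a
phenotype and same-phenotype clones cluster together; the re-draw
preserves each clone's marginal proportions.

What the generator does **not** emulate: read-level artifacts (GC bias,
mapping error), isoforms, count-based mean–variance relationships,
correlated gene modules beyond the shared labels, aneuploidy drift, or
ploidy-dependent nonlinear expression (a per-gene 2N distortion factor
exists, `ploidy_distortion_sd`, default off). Passing recovery tests
therefore demonstrates correctness of the decision rules and their
implementation under the stated noise model — not robustness to every
failure mode of real RNA-seq.

## Numerical choices and degenerate inputs

* Rounding of reported percentages is decimal half-up (banker's rounding
  would disagree with the printed tables this mirrors).
* Determinism: all randomness flows from `numpy.random.default_rng`
  seeded with `[seed, stream]`; identical config + seed reproduce
  byte-identical fixtures across processes.
* Agglomeration ties are resolved by scipy's lowest-index convention;
  trees are deterministic for fixed input.
* Empty gene sets write header-only files; genes with zero informative
  SNPs are absent from origin output rather than guessed.
* `classify_gene` refuses non-differential parental pairs (the decision
  regions are undefined there) — note the pseudocount can pull a raw
  ratio slightly above 2 below the effective gate at low expression.

## Problem sizes

Recovery and clustering checks run on 5,000-gene simulations (hundreds of
pool-d genes per run, ~10,000 SNPs), with 100 seeded replicates for the
sister-clade frequency — large enough for stable fractions while keeping
a full test-plus-acceptance cycle around a minute.

## Known limitations

* The published absolute gene counts (23,361 analysed genes, 27,962
  informative SNPs, 2,848 differential genes) depend on the original raw
  data and are inputs here, not reproduction targets; one published
  clone row (tme17) sums to 2,818 rather than 2,848 and one of its
  bracketed percentages is inconsistent with its printed counts — both
  are treated as documented inconsistencies, not mimicked.
* The equal-vs-minor split is significance-based by design choice; other
  reasonable operationalisations (posterior fold bounds, TOST) would move
  genes between pools b and c.
* Origin calling assumes the 1:1 genome ratio holds per gene; allelic
  imbalance within biallelic genes is not modelled or detected.
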