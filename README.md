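# hybridtx

Transcriptome classification for somatic cell-fusion hybrids. When an
embryonic stem (ES) cell is fused with a fibroblast, the resulting hybrid
clone adopts one parental phenotype (ES-like or fibroblast-like), but its
transcriptome is a mosaic: some genes follow the adopted phenotype, some
stay at an intermediate level, some "remember" the other parent, and some
take values seen in neither parent. `hybridtx` implements that
classification as a reusable pipeline for gene × sample FPKM matrices with
parental lines (diploid and tetraploid, as ploidy-matched references for
near-tetraploid hybrids) and hybrid clones, plus SNP-based parental-origin
calling and hierarchical clustering — and a synthetic-data generator that
emulates the whole study design with known ground truth.

## The classification

Let `m_ES` and `m_FIB` be a gene's replicate-mean FPKM in the two
reference (tetraploid) parental lines, with pseudocount ψ = 1 and
thresholds `floor = 10` FPKM, `T = 2`-fold. Genes are first partitioned
into pools:

* **a (low)** — mean FPKM < 10 in both parents and every hybrid clone;
* **b (equal)** — expressed, no significant parental difference
  (Welch t-test on log2(FPKM+1), Benjamini–Hochberg across genes);
* **c (minor)** — significant but |log2((m_ES+1)/(m_FIB+1))| ≤ log2 T;
* **d (differential)** — significant and more than T-fold apart.

For each pool-d gene and each hybrid clone with mean `h`, writing `m` for
the phenotype-matching parent and `o` for the other, and calling `h`
"at the level of" a parent when it is within T-fold of it in pseudocounted
log space:

1. `h < 10` → **low in clone**;
2. at the level of `m` (only, or nearer than `o`) → **group 1**
   (phenotype-consistent);
3. at the level of `o` → **group 3** (parental memory);
4. at neither level, strictly between the parents → **group 2**
   (intermediate);
5. at neither level, outside the parental range → **group 4** (novel).

Parental origin of transcripts is called from strain-distinguishing SNPs:
sites heterozygous in either parental transcriptome are filtered out, each
remaining SNP is called biallelic when both alleles reach 2 reads and 10%
of coverage, and a gene is expressed from ONE_PARENT / BOTH / MIXED
according to whether its SNP calls are all monoallelic, all biallelic, or
a mixture.

## Worked example

```sh
hybridtx --seed 5 --out-dir demo all
```

simulates the full design (two parents in 2N and 4N, four hybrid clones,
triplicates, 5,000 genes) into `demo/fixture/`, then runs every stage.
Re-running the classification stage on that fixture,
`hybridtx --out-dir demo classify --data-dir demo/fixture`, prints per
clone:

```
tme14:
              label  n_genes  percent
  GROUP1_CONSISTENT      205     42.0
GROUP2_INTERMEDIATE      123     25.2
      GROUP3_MEMORY       66     13.5
       GROUP4_NOVEL       94     19.3
       LOW_IN_CLONE      132      NaN
```

i.e. of this clone's differentially expressed genes that are expressed in
the clone, 42.0% follow the ES-like phenotype, 25.2% are intermediate,
13.5% retain the fibroblast parent's level and 19.3% are novel;
percentages are over groups 1–4 only (low-in-clone genes are counted but
excluded from the denominator). `demo/` also contains `pools.tsv`,
`table2.tsv` (the group summary for all clones), `table1.tsv` (origin
summary — here 97.2% of tme14's informative genes are expressed from both
parental genomes, as expected at a 1:1 genome ratio), `clusters.nwk` (the
dendrogram, in which same-phenotype clones are sisters) and a run
manifest.

The same stages are available as library functions
(`partition_pools`, `classify_clone`, `filter_informative_snps`,
`call_clone_snps`, `gene_origin_table`, `cluster_samples`,
`simulate_expression`, ...) on pandas DataFrames.

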