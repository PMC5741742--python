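import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridtx import (
    call_clone_snps,
    call_snp,
    classify_gene_origin,
    filter_informative_snps,
    gene_origin_table,
    read_snp_vcf,
    summarize_origin,
)
from hybridtx.origin import BOTH, MIXED, NO_DATA, ONE_ES, ONE_FIB, ONE_PARENT


def _meta(samples):
    rows = []
    for sid, line, role in samples:
        rows.append(dict(sample_id=sid, line_id=line, role=role, ploidy="4N",
                         phenotype="NA" if role != "hybrid" else "ES_like", replicate=1))
    return pd.DataFrame(rows)


PARENT_META = _meta([("es1", "tauGFP4N", "parent_ES"), ("fib1", "m5S4N8", "parent_FIB"),
                     ("hy1", "tme14", "hybrid")])


def _sites(n):
    return pd.DataFrame(
        dict(snp_id=[f"s{i}" for i in range(n)], chromosome="chr1",
             position=range(100, 100 + n), gene_id=[f"g{i}" for i in range(n)],
             allele_ES="A", allele_FIB="G")
    )


def _counts(rows):
    return pd.DataFrame(rows, columns=["snp_id", "sample_id", "reads_ES_allele", "reads_FIB_allele"])


class TestFilterInformative:
    def test_homozygous_divergent_site_retained(self):
        sites = _sites(1)
        counts = _counts([("s0", "es1", 50, 0), ("s0", "fib1", 0, 40)])
        kept = filter_informative_snps(sites, counts, PARENT_META)
        assert kept["snp_id"].tolist() == ["s0"]

    def test_heterozygous_parent_filtered(self):
        sites = _sites(1)
        counts = _counts([("s0", "es1", 30, 25), ("s0", "fib1", 0, 40)])
        assert filter_informative_snps(sites, counts, PARENT_META).empty

    def test_low_parent_coverage_filtered(self):
        sites = _sites(1)
        counts = _counts([("s0", "es1", 5, 0), ("s0", "fib1", 0, 40)])
        assert filter_informative_snps(sites, counts, PARENT_META).empty

    def test_site_without_parental_rows_excluded(self):
        sites = _sites(2)
        counts = _counts([("s0", "es1", 50, 0), ("s0", "fib1", 0, 40)])
        kept = filter_informative_snps(sites, counts, PARENT_META)
        assert kept["snp_id"].tolist() == ["s0"]

    def test_injected_heterozygous_sites_exactly_removed(self):
        """With a 5% heterozygous-in-parent injection, the filter removes
        exactly the injected sites (among well-covered genes)."""
        from hybridtx import SimulationConfig, simulate_allele_counts, simulate_expression

        cfg = SimulationConfig(n_genes=400, noise_sd=0.0, parent_het_rate=0.05, seed=77)
        _, meta, truth = simulate_expression(cfg)
        counts = simulate_allele_counts(cfg, truth)
        kept = filter_informative_snps(truth.sites, counts, meta)
        covered = counts.groupby("snp_id")[["reads_ES_allele", "reads_FIB_allele"]].sum().sum(axis=1) > 0
        candidates = truth.sites[covered.reindex(truth.sites["snp_id"]).to_numpy()]
        expected = set(candidates.loc[candidates["informative"], "snp_id"])
        assert set(kept["snp_id"]) == expected


class TestCallSnp:
    @pytest.mark.parametrize(
        "es,fib,expected",
        [
            (48, 52, BOTH),
            (60, 1, ONE_ES),  # minor fraction 0.016 < 0.1
            (1, 60, ONE_FIB),
            (0, 0, NO_DATA),
            (1, 0, NO_DATA),  # below the 2-read floor
            (2, 0, ONE_ES),
        ],
    )
    def test_examples(self, es, fib, expected):
        assert call_snp(es, fib) == expected

    @settings(deadline=None, max_examples=200)
    @given(major=st.integers(2, 500), minor=st.integers(0, 500), add=st.integers(0, 100))
    def test_monotonic_in_minor_reads(self, major, minor, add):
        """Adding minor-allele reads can promote ONE_x to BOTH but never
        demote BOTH, as long as the allele stays the minor one."""
        minor = min(minor, major)
        boosted = min(minor + add, major)
        before = call_snp(major, minor)
        after = call_snp(major, boosted)
        if before == BOTH:
            assert after == BOTH


class TestGeneOrigin:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([BOTH, BOTH, BOTH], BOTH),
            ([ONE_ES, ONE_ES], ONE_PARENT),
            ([BOTH, ONE_FIB], MIXED),
            ([ONE_ES, ONE_FIB], ONE_PARENT),  # per-SNP monoallelic mixture
            ([NO_DATA, BOTH], BOTH),
        ],
    )
    def test_aggregation(self, calls, expected):
        assert classify_gene_origin(calls)["origin"] == expected

    def test_strict_mode_flags_discordant_monoallelic(self):
        assert classify_gene_origin([ONE_ES, ONE_FIB], strict=True)["origin"] == MIXED

    def test_counts_invariant(self):
        res = classify_gene_origin([BOTH, ONE_ES, NO_DATA])
        assert res == {"origin": MIXED, "n_snps_informative": 2, "n_snps_biallelic": 1}

    def test_no_data_gene_excluded(self):
        assert classify_gene_origin([NO_DATA, NO_DATA]) is None
        calls = pd.DataFrame(
            dict(snp_id=["s0"], gene_id=["g0"], clone_id=["tme14"], call=[NO_DATA])
        )
        assert gene_origin_table(calls).empty


class TestSummarize:
    def test_counts_path(self):
        df = summarize_origin({ONE_PARENT: 0, BOTH: 5, MIXED: 0})
        by = df.set_index("origin")["percent"]
        assert by[BOTH] == 100.0 and by[ONE_PARENT] == 0.0 and by[MIXED] == 0.0

    def test_percentages_partition(self, zero_noise_run):
        _, matrix, meta, truth, counts = zero_noise_run
        kept = filter_informative_snps(truth.sites, counts, meta)
        calls = call_clone_snps(kept, counts, meta, "tmf2")
        genes = gene_origin_table(calls)
        summary = summarize_origin(genes)
        assert summary["n_genes"].sum() == len(genes)
        assert abs(summary["percent"].sum() - 100.0) <= 0.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_origin({})


def test_biallelic_recall_at_high_coverage(zero_noise_run):
    """At ~100x coverage and a 1:1 allele ratio, biallelic genes are
    recalled essentially always."""
    _, matrix, meta, truth, counts = zero_noise_run
    kept = filter_informative_snps(truth.sites, counts, meta)
    calls = call_clone_snps(kept, counts, meta, "tme14")
    genes = gene_origin_table(calls).set_index("gene_id")
    want = truth.origins.query("clone_id == 'tme14'").set_index("gene_id")["origin"]
    common = genes.index.intersection(want.index)
    both_true = [g for g in common if want[g] == BOTH]
    recall = (genes.loc[both_true, "origin"] == BOTH).mean()
    assert recall >= 0.99


def test_vcf_dialect_round_trip(tmp_path):
    vcf = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allelic depths">\n'
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tes1\thy1\n"
        "chr1\t100\tsnp1\tA\tG\t.\t.\tGENE=gx\tAD\t50,0\t25,25\n"
        "chr1\t200\tsnp2\tC\tT\t.\t.\tGENE=gy\tAD\t10,1\t0,40\n"
    )
    path = tmp_path / "sites.vcf"
    path.write_text(vcf)
    sites, counts = read_snp_vcf(path)
    assert sites["gene_id"].tolist() == ["gx", "gy"]
    assert sites["position"].tolist() == [100, 200]
    assert sites["allele_ES"].tolist() == ["A", "C"]
    row = counts.query("snp_id == 'snp1' and sample_id == 'hy1'").iloc[0]
    assert (row["reads_ES_allele"], row["reads_FIB_allele"]) == (25, 25)
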