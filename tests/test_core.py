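"""Data model, GTF/site-table I/O and site-region classification."""

import numpy as np
import pytest

from epicrosstalk.core import (
    GenomicInterval,
    GeneModel,
    GtfParseError,
    ModificationSite,
    SiteTableError,
    classify_site_region,
    read_gtf,
    read_site_table,
    write_gtf,
    write_site_table,
)
from epicrosstalk.simulate import SimulationConfig, generate_annotation

from .oracles import brute_force_region


def _gene(tss=10_000, strand="+", length=4_000, chrom="chr1", biotype="protein_coding"):
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length + 1, tss + 1
    body = GenomicInterval(chrom, start, end, strand)
    a = length // 5
    exons = (
        GenomicInterval(chrom, start, start + a, strand),
        GenomicInterval(chrom, start + 2 * a, start + 3 * a, strand),
        GenomicInterval(chrom, start + 4 * a, end, strand),
    )
    if biotype == "lncRNA":
        return GeneModel("G1", biotype, body, exons)
    utr3 = exons[2] if strand == "+" else exons[0]
    return GeneModel("G1", biotype, body, exons, cds=(exons[1],), utr3=(utr3,))


def _site(start, end, chrom="chr1", mod="H3K4me1", fc=2.0, p=0.01):
    return ModificationSite(GenomicInterval(chrom, start, end, "."), mod, fc, p)


class TestGenomicTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_tss_strand_awareness(self):
        plus = _gene(tss=1000, strand="+", length=1000)
        assert plus.body.start == 1000 and plus.tss == 1000
        minus = _gene(tss=1999, strand="-", length=1000)
        assert minus.body == GenomicInterval("chr1", 1000, 2000, "-")
        assert minus.tss == 1999

    def test_site_invariants(self):
        with pytest.raises(ValueError):
            _site(0, 10, p=0.0)
        with pytest.raises(ValueError):
            _site(0, 10, mod="H3K9me3")


class TestGtfIO:
    def test_coordinate_conversion_both_strands(self, tmp_path):
        # 1-based closed [1001, 2000] -> 0-based half-open [1000, 2000)
        gtf = tmp_path / "t.gtf"
        lines = []
        for gid, strand in (("GP", "+"), ("GM", "-")):
            attrs = f'gene_id "{gid}"; gene_type "protein_coding";'
            lines.append(f"chr1\tx\tgene\t1001\t2000\t.\t{strand}\t.\t{attrs}")
            lines.append(f"chr1\tx\texon\t1001\t2000\t.\t{strand}\t.\t{attrs}")
        gtf.write_text("\n".join(lines) + "\n")
        genes = {g.gene_id: g for g in read_gtf(gtf)}
        assert genes["GP"].body == GenomicInterval("chr1", 1000, 2000, "+")
        assert genes["GP"].tss == 1000
        assert genes["GM"].tss == 1999

    def test_three_gene_fixture_field_by_field(self, tmp_path):
        expected = [
            _gene(tss=10_000, strand="+", length=2_000),
            _gene(tss=30_999, strand="-", length=3_000),
            _gene(tss=50_000, strand="+", length=2_500, biotype="lncRNA"),
        ]
        expected = [
            GeneModel(f"G{i + 1}", g.biotype, g.body, g.exons, g.cds, g.utr3)
            for i, g in enumerate(expected)
        ]
        path = tmp_path / "three.gtf"
        write_gtf(expected, path)
        parsed = read_gtf(path)
        assert [g.biotype for g in parsed] == ["protein_coding", "protein_coding", "lncRNA"]
        for got, exp in zip(parsed, expected):
            assert got.gene_id == exp.gene_id
            assert got.body == exp.body
            assert got.exons == exp.exons
            assert got.cds == exp.cds
            assert got.utr3 == exp.utr3

    def test_round_trip_identity(self, tmp_path):
        genes = generate_annotation(
            SimulationConfig(seed=3, n_genes=40, set1_size=8, set2_size=6)
        )
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(genes, p1)
        again = read_gtf(p1)
        write_gtf(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert again == genes

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\tgene\t100\t200\t.\t+\t.\tgene_id "G"; gene_type "protein_coding";\n'
            "chr1\tonly three fields\n"
        )
        with pytest.raises(GtfParseError, match="line 2"):
            read_gtf(path)

    def test_gene_without_exons_skipped_with_warning(self, tmp_path):
        path = tmp_path / "noexon.gtf"
        path.write_text(
            'chr1\tx\tgene\t100\t200\t.\t+\t.\tgene_id "G"; gene_type "protein_coding";\n'
        )
        with pytest.warns(UserWarning, match="no exons"):
            assert read_gtf(path) == []


class TestSiteTable:
    def test_read_valid_and_sorted(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text(
            "chrom\tstart\tend\tstrand\tfold_change\tp_value\n"
            "chr1\t500\t600\t.\t2.0\t0.01\n"
            "chr1\t100\t200\t.\t-1.5\t0.02\n"
        )
        sites = read_site_table(path, "H3K4me3")
        assert len(sites) == 2
        assert sites[0].interval.start == 100
        assert all(s.mod_type == "H3K4me3" for s in sites)

    def test_p_value_zero_is_row_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tstart\tend\tstrand\tfold_change\tp_value\nchr1\t1\t2\t.\t2\t0.0\n"
        )
        with pytest.raises(SiteTableError, match="row 0"):
            read_site_table(path, "m6A")

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tstart\tend\tstrand\tfold_change\nchr1\t1\t2\t.\t2\n")
        with pytest.raises(SiteTableError, match="p_value"):
            read_site_table(path, "m6A")

    def test_shuffled_rows_give_identical_output(self, tmp_path, rng):
        sites = [
            _site(int(s), int(s) + 100, fc=float(f), p=0.01)
            for s, f in zip(rng.integers(0, 100_000, 30), rng.normal(0, 2, 30))
        ]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_site_table(sites, a)
        perm = [sites[i] for i in rng.permutation(len(sites))]
        write_site_table(perm, b)
        assert read_site_table(a, "m6A") == read_site_table(b, "m6A")


class TestClassifySiteRegion:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (9_500, 9_600, "promoter_lt1kb"),  # 400 bp upstream of TSS
            (11_500, 11_600, "promoter_1to2kb"),  # 1.5 kb downstream
            (12_100, 12_200, "promoter_2to3kb"),  # 2.1 kb downstream
            (6_000, 6_100, "distal"),  # beyond the 3 kb window, before gene
        ],
    )
    def test_promoter_bins_by_distance(self, start, end, expected):
        gene = _gene(tss=10_000, strand="+", length=4_000)
        assert classify_site_region(_site(start, end), gene) == expected

    def test_different_chromosome_is_distal(self):
        gene = _gene(tss=10_000)
        assert classify_site_region(_site(10_000, 10_100, chrom="chr2"), gene) == "distal"

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_site_region(_site(0, 10), _gene(), window=0)

    def test_matches_per_base_oracle_on_random_sites(self, rng):
        gene = _gene(tss=50_000, strand="+", length=5_000)
        for _ in range(1000):
            start = int(rng.integers(44_000, 60_000))
            width = int(rng.integers(1, 500))
            site = _site(start, start + width)
            assert classify_site_region(site, gene) == brute_force_region(site, gene)

    def test_strand_mirror_invariance(self, rng):
        """Reflecting the whole locus and flipping strand preserves labels."""
        mirror = 200_000
        plus = _gene(tss=50_000, strand="+", length=4_000)
        minus = GeneModel(
            "G1",
            plus.biotype,
            GenomicInterval(
                "chr1", mirror - plus.body.end, mirror - plus.body.start, "-"
            ),
            tuple(
                GenomicInterval("chr1", mirror - iv.end, mirror - iv.start, "-")
                for iv in plus.exons
            ),
            tuple(
                GenomicInterval("chr1", mirror - iv.end, mirror - iv.start, "-")
                for iv in plus.cds
            ),
            tuple(
                GenomicInterval("chr1", mirror - iv.end, mirror - iv.start, "-")
                for iv in plus.utr3
            ),
        )
        assert minus.tss == mirror - plus.tss - 1
        for _ in range(300):
            start = int(rng.integers(44_000, 58_000))
            width = int(rng.integers(1, 400))
            site = _site(start, start + width)
            mirrored = _site(mirror - (start + width), mirror - start)
            assert classify_site_region(site, plus) == classify_site_region(
                mirrored, minus
            )

    def test_promoter_bins_partition_the_window(self):
        gene = _gene(tss=10_000, strand="+", length=4_000)
        for base in range(10_000 - 3_000, 10_000 + 3_000):
            label = classify_site_region(_site(base, base + 1), gene)
            assert label.startswith("promoter_")
        for base in (10_000 - 3_001, 10_000 + 3_000):
            label = classify_site_region(_site(base, base + 1), gene)
            assert not label.startswith("promoter_")
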