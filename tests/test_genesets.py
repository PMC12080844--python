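"""Gene windows, panel harmonization, LD estimation, and pruning."""

import numpy as np
import pandas as pd
import pytest

from genewas.genesets import (
    GeneAnnotation,
    GeneSnpSet,
    ReferencePanel,
    ZeroVarianceError,
    assign_to_gene,
    build_gene_sets,
    harmonize_to_panel,
    ld_matrix,
    prune_perfect_ld,
    read_gene_annotation,
    read_panel_tsv,
    write_panel_tsv,
)
from genewas.sumstats import VariantSummary


def variant(pos, rsid="rs1", chrom="1", ea="G", oa="A", z=1.0):
    return VariantSummary(
        chrom=chrom, pos=pos, rsid=rsid, effect_allele=ea, other_allele=oa,
        odds_ratio=1.1, se=0.05, pvalue=0.5, info=0.95, z=z,
    )


GENE = GeneAnnotation(gene_id="G1", symbol="G1", chrom="1", tx_start=10_000, tx_end=20_000)


class TestAssignToGene:
    def test_flank_boundary_inclusive(self):
        inside = variant(pos=GENE.tx_start - 1000)
        outside = variant(pos=GENE.tx_start - 1001, rsid="rs2")
        end_inside = variant(pos=GENE.tx_end + 1000, rsid="rs3")
        got = assign_to_gene([inside, outside, end_inside], GENE, flank=1000)
        assert [v.rsid for v in got] == ["rs1", "rs3"]

    def test_other_chromosome_excluded(self):
        assert assign_to_gene([variant(pos=15_000, chrom="2")], GENE) == []

    def test_monotone_in_flank(self):
        rng = np.random.default_rng(0)
        variants = [variant(pos=int(p), rsid=f"rs{i}") for i, p in
                    enumerate(rng.integers(5_000, 25_000, size=50))]
        small = set(v.rsid for v in assign_to_gene(variants, GENE, flank=0))
        large = set(v.rsid for v in assign_to_gene(variants, GENE, flank=1000))
        assert small <= large


def panel_record(ref="A", alt="G"):
    return pd.Series({"ref": ref, "alt": alt})


class TestHarmonize:
    def test_matching_order_keeps_z(self):
        assert harmonize_to_panel(variant(1, ea="G", oa="A", z=1.7), panel_record()) == 1.7

    def test_swapped_order_negates_z(self):
        assert harmonize_to_panel(variant(1, ea="A", oa="G", z=1.7), panel_record()) == -1.7

    def test_irreconcilable_alleles_dropped(self):
        assert harmonize_to_panel(variant(1, ea="A", oa="G", z=1.7),
                                  panel_record(ref="T", alt="C")) is None

    def test_idempotent_once_aligned(self):
        z1 = harmonize_to_panel(variant(1, ea="A", oa="G", z=1.7), panel_record())
        again = harmonize_to_panel(variant(1, ea="G", oa="A", z=z1), panel_record())
        assert again == z1


def make_panel(dosages, rsids=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    rsids = rsids or [f"rs{i}" for i in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(100, 100 + m),
            "rsid": rsids,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return ReferencePanel(variants=meta, dosages=dosages)


class TestLdMatrix:
    def test_unit_diagonal(self):
        panel = make_panel([[0, 1], [1, 0], [2, 1], [1, 2]])
        R = ld_matrix(panel, ["rs0", "rs1"])
        assert np.allclose(np.diag(R), 1.0)

    def test_perfect_anticorrelation(self):
        panel = make_panel(np.array([[0, 2], [1, 1], [2, 0], [1, 1]]))
        R = ld_matrix(panel, ["rs0", "rs1"])
        assert R[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_covariance_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 1.0])
        y = np.array([0.0, 1.0, 2.0, 2.0])

        def two_pass_corr(a, b):
            am, bm = a.mean(), b.mean()
            cov = np.sum((a - am) * (b - bm))
            return cov / np.sqrt(np.sum((a - am) ** 2) * np.sum((b - bm) ** 2))

        panel = make_panel(np.column_stack([x, y]))
        R = ld_matrix(panel, ["rs0", "rs1"])
        assert R[0, 1] == pytest.approx(two_pass_corr(x, y), abs=1e-12)

    def test_zero_variance_names_variant(self):
        panel = make_panel([[1, 0], [1, 1], [1, 2]])
        with pytest.raises(ZeroVarianceError, match="rs0"):
            ld_matrix(panel, ["rs0", "rs1"])


def snp_set(R, rsids=None, positions=None):
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    rsids = rsids or [f"rs{i}" for i in range(m)]
    return GeneSnpSet(
        gene=GENE, rsids=rsids, z=np.ones(m), R=R,
        positions=positions or list(range(100, 100 + m)),
    )


class TestPrunePerfectLd:
    def test_duplicate_pair_keeps_earlier_position(self):
        R = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        pruned = prune_perfect_ld(snp_set(R))
        assert pruned.rsids == ["rs0", "rs2"]
        assert pruned.R.shape == (2, 2)

    def test_three_mutually_perfect_leave_one_survivor(self):
        R = np.ones((3, 3))
        gs = snp_set(R)
        # brute force: whatever removal order is used, one variant survives
        assert prune_perfect_ld(gs) is None  # m falls to 1 -> gene dropped
        R4 = np.eye(4)
        R4[:3, :3] = 1.0
        pruned = prune_perfect_ld(snp_set(R4))
        assert pruned.rsids == ["rs0", "rs3"]

    def test_negative_perfect_correlation_is_retained(self):
        R = np.array([[1.0, -1.0], [-1.0, 1.0]])
        pruned = prune_perfect_ld(snp_set(R))
        assert pruned.rsids == ["rs0", "rs1"]

    def test_no_offending_pair_unchanged(self):
        R = np.array([[1.0, 0.8], [0.8, 1.0]])
        assert prune_perfect_ld(snp_set(R)).rsids == ["rs0", "rs1"]

    def test_output_has_no_perfect_pairs(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 4))
        X = np.column_stack([X, X[:, 0], X[:, 2]])  # plant duplicates
        R = np.corrcoef(X, rowvar=False)
        pruned = prune_perfect_ld(snp_set(R))
        off = pruned.R[~np.eye(pruned.m, dtype=bool)]
        assert (off < 1.0 - 1e-8).all()


class TestBuildGeneSets:
    def test_assembles_harmonized_sets_and_drops_small_genes(self):
        dosages = np.array([[0, 0, 2], [1, 1, 1], [2, 2, 0], [1, 0, 1], [0, 1, 2]], float)
        meta = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "pos": [10_100, 10_200, 10_300],
                "rsid": ["rs0", "rs1", "rs2"],
                "ref": ["A", "A", "A"],
                "alt": ["G", "G", "G"],
            }
        )
        panel = ReferencePanel(variants=meta, dosages=dosages)
        variants = [
            variant(10_100, rsid="rs0", ea="G", oa="A", z=1.0),
            variant(10_200, rsid="rs1", ea="A", oa="G", z=1.0),  # swapped -> -1
            variant(10_300, rsid="rs2", ea="C", oa="T", z=1.0),  # irreconcilable
        ]
        lonely_gene = GeneAnnotation(gene_id="G2", symbol="G2", chrom="1",
                                     tx_start=10_300, tx_end=10_300)
        sets, log = build_gene_sets(variants, panel, [GENE, lonely_gene], flank=0)
        assert len(sets) == 1
        gs = sets[0]
        assert gs.rsids == ["rs0", "rs1"]
        assert gs.z.tolist() == [1.0, -1.0]
        assert "alleles_irreconcilable" in set(log["reason"])
        assert "fewer_than_min_snps" in set(log["reason"])

    def test_rsid_position_mismatch_dropped(self):
        dosages = np.array([[0, 1], [1, 0], [2, 2], [0, 1]], float)
        meta = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [10_100, 10_200],
                "rsid": ["rs0", "rs1"],
                "ref": ["A", "A"],
                "alt": ["G", "G"],
            }
        )
        panel = ReferencePanel(variants=meta, dosages=dosages)
        variants = [
            variant(10_100, rsid="rs0", ea="G", oa="A"),
            variant(19_999, rsid="rs1", ea="G", oa="A"),  # position disagrees
        ]
        sets, log = build_gene_sets(variants, panel, [GENE])
        assert sets == []
        assert "not_in_panel_or_position_mismatch" in set(log["reason"])


class TestIO:
    def test_panel_tsv_round_trip(self, tmp_path, small_panel):
        panel, _ = small_panel
        sub = ReferencePanel(variants=panel.variants.iloc[:5].copy(),
                             dosages=panel.dosages[:20, :5])
        path = tmp_path / "panel.tsv"
        write_panel_tsv(sub, path)
        back = read_panel_tsv(path)
        assert np.allclose(back.dosages, sub.dosages)
        assert list(back.variants["rsid"]) == list(sub.variants["rsid"])

    def test_gene_annotation_reader(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "gene_id\tsymbol\tchrom\ttx_start\ttx_end\tstrand\n"
            "G1\tSYM1\t8\t100\t900\t+\n"
        )
        genes = read_gene_annotation(path)
        assert genes[0].chrom == "8" and genes[0].tx_start == 100

    def test_gene_set_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        gs = snp_set(np.corrcoef(X, rowvar=False))
        from genewas.genesets import read_gene_set, write_gene_sets

        write_gene_sets([gs], tmp_path)
        back = read_gene_set(gs.gene, tmp_path)
        assert back.rsids == gs.rsids
        assert np.allclose(back.z, gs.z)
        assert np.allclose(back.R, gs.R)

    def test_vcf_panel_reader(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\trs0\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t0/1\t0/0\n"
        )
        from genewas.genesets import read_panel_vcf

        panel = read_panel_vcf(vcf)
        assert panel.dosages.shape == (3, 2)
        assert panel.dosages[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert list(panel.variants["rsid"]) == ["rs0", "rs1"]
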