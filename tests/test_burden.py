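import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from netburden import (
    BurdenMatrix,
    EffectOrienter,
    FilterCriteria,
    build_burden,
    filter_variants,
    orient_effects,
)

EXEMPT = FilterCriteria(frameshift_cadd_exempt=True)


class TestFilterVariants:
    def test_high_maf_excluded(self):
        df = pd.DataFrame(
            [["v", "G", "missense", 0.02, 35.0]],
            columns=["variant_id", "gene", "consequence", "maf", "cadd_phred"],
        )
        assert len(filter_variants(df)) == 0

    def test_cadd_threshold_is_strict(self):
        df = pd.DataFrame(
            [["v", "G", "missense", 0.001, 20.0]],
            columns=["variant_id", "gene", "consequence", "maf", "cadd_phred"],
        )
        assert len(filter_variants(df)) == 0  # exactly 20 fails the strict >

    def test_six_record_branch_enumeration(self, toy_variants, caplog):
        # hand-derived: v3 passes all filters; v4 is a CADD-exempt frameshift;
        # v1 fails MAF, v2 fails strict CADD, v5 fails consequence,
        # v6 lacks a required CADD annotation and is excluded with a warning
        with caplog.at_level("WARNING"):
            kept = filter_variants(toy_variants, EXEMPT)
        assert list(kept["variant_id"]) == ["v3", "v4"]
        assert "missing annotations" in caplog.text

    def test_frameshift_needs_cadd_without_exemption(self, toy_variants):
        kept = filter_variants(toy_variants, FilterCriteria())
        assert list(kept["variant_id"]) == ["v3"]

    def test_lof_set_excludes_missense(self, toy_variants):
        from netburden.burden import LOF_CONSEQUENCES

        crit = FilterCriteria(
            consequences=LOF_CONSEQUENCES, frameshift_cadd_exempt=True
        )
        kept = filter_variants(toy_variants, crit)
        assert list(kept["variant_id"]) == ["v4"]

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            FilterCriteria(maf_max=0.0)
        with pytest.raises(ValueError):
            FilterCriteria(cadd_min=-1.0)


def toy_panel():
    """Filtered variants mapped to genes + 4x5 genotype presence matrix."""
    variants = pd.DataFrame(
        {
            "variant_id": ["va1", "va2", "va3", "va4", "va5"],
            "gene": ["G1", "G1", "G2", "G3", "G2"],
        }
    )
    genotypes = pd.DataFrame(
        [
            [1, 1, 0, 1, 1],
            [0, 0, 0, 0, 0],
            [0, 1, 1, 0, 1],
            [0, 0, 0, 1, 0],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["va1", "va2", "va3", "va4", "va5"],
    )
    return variants, genotypes


class TestBuildBurden:
    def test_hand_tallied_counts_with_network_alignment(self):
        variants, genotypes = toy_panel()
        genes = np.array(["G1", "G2", "G4"], dtype=object)  # G3 not in network
        counts = build_burden(variants, genotypes, encoding="burden", genes=genes)
        expected = np.array(
            [[2, 1, 0], [0, 0, 0], [1, 2, 0], [0, 0, 0]], dtype=float
        )
        assert np.array_equal(counts.values.toarray(), expected)
        status = build_burden(variants, genotypes, encoding="status", genes=genes)
        assert np.array_equal(status.values.toarray(), (expected > 0).astype(float))

    def test_status_equals_indicator_of_counts(self):
        rng = np.random.default_rng(0)
        variants = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(30)],
                "gene": rng.choice(["A", "B", "C", "D"], 30),
            }
        )
        genotypes = pd.DataFrame(
            rng.integers(0, 2, size=(15, 30)),
            index=[f"s{i}" for i in range(15)],
            columns=variants["variant_id"],
        )
        counts = build_burden(variants, genotypes, encoding="burden")
        status = build_burden(variants, genotypes, encoding="status")
        assert np.array_equal(
            status.values.toarray(), (counts.values.toarray() > 0).astype(float)
        )

    def test_column_sums_match_per_subject_scan(self):
        variants, genotypes = toy_panel()
        status = build_burden(variants, genotypes, encoding="status")
        by_gene = variants.groupby("gene")["variant_id"].apply(list)
        for j, gene in enumerate(status.genes):
            carriers = sum(
                genotypes.loc[s, by_gene[gene]].sum() > 0 for s in genotypes.index
            )
            assert status.values.toarray()[:, j].sum() == carriers

    def test_missing_variant_errors(self):
        variants, genotypes = toy_panel()
        variants.loc[len(variants)] = ["vmissing", "G9"]
        with pytest.raises(ValueError, match="vmissing"):
            build_burden(variants, genotypes)

    def test_encoding_validation(self):
        with pytest.raises(ValueError, match="status"):
            BurdenMatrix(
                np.array(["s1"], dtype=object),
                np.array(["G"], dtype=object),
                sp.csr_matrix(np.array([[2.0]])),
                encoding="status",
            )


class TestOrientEffects:
    def build(self, values, encoding="status"):
        values = np.asarray(values, dtype=float)
        s, m = values.shape
        return BurdenMatrix(
            np.array([f"s{i}" for i in range(s)], dtype=object),
            np.array([f"G{j}" for j in range(m)], dtype=object),
            sp.csr_matrix(values),
            encoding=encoding,
        )

    def risk_cohort(self):
        # 8/50 case carriers, 2/50 control carriers: OR = (8*48)/(2*42) ~ 4.57
        carriers = np.zeros(100)
        carriers[:8] = 1  # cases 0..49
        carriers[50:52] = 1  # controls 50..99
        phenotype = np.r_[np.ones(50), np.zeros(50)]
        return carriers, phenotype

    def test_risk_gene_unchanged_under_signed(self):
        carriers, phenotype = self.risk_cohort()
        burden = self.build(carriers[:, None])
        oriented, meta = orient_effects(burden, phenotype, mode="signed")
        assert meta.loc[0, "odds_ratio"] == pytest.approx(8 * 48 / (2 * 42))
        assert meta.loc[0, "direction"] == "risk"
        assert np.array_equal(
            oriented.values.toarray(), burden.values.toarray()
        )

    def test_protective_gene_negated_under_signed(self):
        carriers, phenotype = self.risk_cohort()
        burden = self.build(carriers[:, None])
        oriented, meta = orient_effects(burden, 1 - phenotype, mode="signed")
        assert meta.loc[0, "direction"] == "protective"
        assert meta.loc[0, "odds_ratio"] == pytest.approx(2 * 42 / (8 * 48))
        assert np.array_equal(
            oriented.values.toarray(), -burden.values.toarray()
        )
        assert oriented.encoding == "signed_status"

    def test_mode_none_is_identity(self):
        carriers, phenotype = self.risk_cohort()
        burden = self.build(carriers[:, None])
        oriented, _ = orient_effects(burden, phenotype, mode="none")
        assert np.array_equal(oriented.values.toarray(), burden.values.toarray())

    def test_zero_protective_mode(self):
        carriers, phenotype = self.risk_cohort()
        burden = self.build(carriers[:, None])
        oriented, _ = orient_effects(burden, 1 - phenotype, mode="zero_protective")
        assert oriented.values.nnz == 0

    def test_direction_metadata_idempotent_and_magnitude_preserved(self):
        rng = np.random.default_rng(1)
        values = (rng.random((60, 5)) < 0.3).astype(float)
        phenotype = np.r_[np.ones(30), np.zeros(30)]
        burden = self.build(values)
        once, meta1 = orient_effects(burden, phenotype, mode="signed")
        orienter = EffectOrienter(mode="signed").fit(np.abs(once.values.toarray()), phenotype)
        assert list(orienter.direction_) == list(meta1["direction"])
        assert np.array_equal(
            np.abs(once.values.toarray()), values
        )

    def test_degenerate_columns_flagged_undetermined(self):
        values = np.c_[np.ones(40), np.zeros(40)]
        phenotype = np.r_[np.ones(20), np.zeros(20)]
        burden = self.build(values)
        oriented, meta = orient_effects(burden, phenotype, mode="signed")
        assert list(meta["direction"]) == ["undetermined", "undetermined"]
        assert np.array_equal(oriented.values.toarray(), values)

    def test_orientation_uses_phenotyped_subset_only(self):
        carriers, phenotype = self.risk_cohort()
        # append unphenotyped carriers; direction must not change
        values = np.r_[carriers, np.ones(10)][:, None]
        pheno = np.r_[phenotype, np.full(10, np.nan)]
        burden = self.build(values)
        oriented, meta = orient_effects(burden, pheno, mode="signed")
        assert meta.loc[0, "direction"] == "risk"
        assert oriented.values.toarray().shape[0] == 110

    def test_requires_status_encoding(self):
        burden = self.build(np.array([[2.0], [0.0]]) , encoding="burden")
        with pytest.raises(ValueError, match="status"):
            orient_effects(burden, np.array([1.0, 0.0]))


class TestVCFGenotypes:
    VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1
1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
"""

    def test_presence_extraction(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from netburden.burden import read_vcf_genotypes

        vcf = tmp_path / "toy.vcf"
        vcf.write_text(self.VCF_TEXT)
        geno = read_vcf_genotypes(vcf)
        assert list(geno.index) == ["s1", "s2", "s3"]
        assert list(geno["v1"]) == [1, 0, 1]  # het and hom-alt both carry
        assert list(geno["v2"]) == [0, 1, 0]
        assert list(geno["1:300:G:A"]) == [0, 0, 1]  # fallback key

    def test_variant_subset(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from netburden.burden import read_vcf_genotypes

        vcf = tmp_path / "toy.vcf"
        vcf.write_text(self.VCF_TEXT)
        geno = read_vcf_genotypes(vcf, variant_ids=["v1"])
        assert list(geno.columns) == ["v1"]
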