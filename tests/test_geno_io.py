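"""Genotype/phenotype/annotation readers and the QC filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import pathassoc as pa
from pathassoc.geno_io import FormatError, _orient_to_minor


TSV_3x2 = "sample_id\tsnpA\tsnpB\nS1\t0\t2\nS2\t1\tNA\nS3\t2\t1\n"

VCF_BODY = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tT\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1
"""


class TestReaders:
    def test_tsv_matrix_roundtrip(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(TSV_3x2)
        gm = pa.read_genotypes(p)
        assert gm.sample_ids == ["S1", "S2", "S3"]
        assert gm.snp_ids == ["snpA", "snpB"]
        assert np.isnan(gm.calls[1, 1])
        # snpA f=0.5, tie kept as coded; snpB f=0.75 flipped to minor counts
        np.testing.assert_array_equal(gm.calls[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(gm.calls[[0, 2], 1], [0, 1])

    def test_tsv_invalid_entry_named(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tsnpA\nS1\t3\n")
        with pytest.raises(FormatError, match="snpA"):
            pa.read_genotypes(p)

    def test_tsv_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tsnpA\nS1\t0\nS1\t1\n")
        with pytest.raises(FormatError, match="duplicate"):
            pa.read_genotypes(p)

    def test_vcf_alt_counts_and_minor_orientation(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_BODY)
        gm = pa.read_genotypes(p)
        # rs1: ALT G is minor (freq 3/6 tie -> lexicographic G > A flips? G vs A:
        # tie at 0.5 broken lexicographically, minor = smaller symbol A)
        np.testing.assert_array_equal(gm.calls[:, 0], [2, 1, 0])
        assert gm.allele_labels["rs1"] == ("A", "G")
        # rs2: ALT C freq 5/6 -> minor is REF T, counts flipped
        np.testing.assert_array_equal(gm.calls[:, 1], [0, 0, 1])
        assert gm.allele_labels["rs2"] == ("T", "C")

    def test_orientation_flips_high_frequency_columns(self):
        gm = pa.GenotypeMatrix(["a", "b", "c"], ["s1"], np.array([[2.0], [2.0], [1.0]]))
        out = _orient_to_minor(gm)
        np.testing.assert_array_equal(out.calls[:, 0], [0, 0, 1])

    def test_samples_schema_and_validation(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_id\tstatus\tage\tinstitution\tethnicity\nA\t1\t60\tx\tCaucasian\n")
        st = pa.read_samples(p)
        assert st.status.tolist() == [1.0]
        p.write_text("sample_id\tstatus\tage\tinstitution\tethnicity\nA\t2\t60\tx\tCaucasian\n")
        with pytest.raises(FormatError, match="status"):
            pa.read_samples(p)
        p.write_text("sample_id\tstatus\n")
        with pytest.raises(FormatError):
            pa.read_samples(p)

    def test_annotation_rejects_unknown_subpathway(self):
        df = pa.packaged_annotation().table.copy()
        df.loc[0, "subpathway"] = "mystery pathway"
        with pytest.raises(FormatError, match="mystery"):
            pa.SnpAnnotation(df)


class TestPackagedCatalog:
    def test_catalog_counts_match_design(self):
        ann = pa.packaged_annotation()
        h = pa.PathwayHierarchy.from_annotation(ann)
        assert len(h.pathway) == 320
        assert len(h.genes) == 46
        assert len(ann.aim_ids) == 39
        sizes = {k: len(v) for k, v in h.subpathways.items()}
        assert sizes == {
            "cytokine signaling": 179,
            "eicosanoid signaling": 9,
            "extracellular pattern recognition": 56,
            "intracellular antiviral molecules": 40,
            "NFKB signaling": 27,
            "selenoproteins": 9,
        }

    def test_gene_sets_partition_subpathways(self):
        h = pa.packaged_hierarchy()
        for sub, ids in h.subpathways.items():
            genes_in = [g for g, s in h.gene_subpathway.items() if s == sub]
            from_genes = sorted(s for g in genes_in for s in h.genes[g])
            assert from_genes == sorted(ids)


class TestMaf:
    @pytest.mark.parametrize("calls,expected", [
        ([0, 1, 2, 2], 0.375),
        ([0, 0, 0, 0], 0.0),
        ([0, 1, np.nan], 0.25),
        ([2, 2, 2], 0.0),       # fixed allele: minor side is zero
    ])
    def test_values(self, calls, expected):
        assert pa.compute_maf(calls) == pytest.approx(expected)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            pa.compute_maf([np.nan, np.nan])

    def test_invariant_under_allele_swap(self, rng):
        calls = rng.integers(0, 3, 50).astype(float)
        assert pa.compute_maf(calls) == pytest.approx(pa.compute_maf(2 - calls))
        assert pa.compute_maf(calls) <= 0.5


class TestHwe:
    def test_perfect_proportions(self):
        stat, p = pa.hwe_chisq(25, 50, 25)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_total_het_deficit(self):
        stat, p = pa.hwe_chisq(50, 0, 50)
        assert stat == pytest.approx(100.0)
        assert p == pytest.approx(chi2.sf(100.0, 1))

    def test_against_hand_computed_expected_counts(self):
        # counts (90, 40, 10), n=140: p = 220/280, expected (86.4286, 47.1429, 6.4286)
        n = 140
        p_freq = (2 * 90 + 40) / (2 * n)
        exp = n * np.array([p_freq ** 2, 2 * p_freq * (1 - p_freq), (1 - p_freq) ** 2])
        oracle = float(np.sum((np.array([90, 40, 10]) - exp) ** 2 / exp))
        stat, p = pa.hwe_chisq(90, 40, 10)
        assert stat == pytest.approx(oracle)
        assert p == pytest.approx(chi2.sf(oracle, 1))

    def test_monomorphic_is_safe(self):
        assert pa.hwe_chisq(100, 0, 0) == (0.0, 1.0)


class TestQc:
    def _gm(self, calls, snps=None):
        calls = np.asarray(calls, float)
        snps = snps or [f"snp{j}" for j in range(calls.shape[1])]
        return pa.GenotypeMatrix([f"S{i}" for i in range(calls.shape[0])], snps, calls)

    def _samples(self, n, eth):
        return pa.SampleTable(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": np.tile([0, 1], n)[:n],
            "age": 65.0, "institution": "site_A", "ethnicity": eth,
        }))

    def test_sample_call_rate_boundary(self):
        calls = np.ones((3, 10))
        calls[0, 0] = np.nan                      # 90% exactly -> kept
        calls[1, :2] = np.nan                     # 80% -> removed
        gm = self._gm(calls)
        kept, log = pa.qc_samples(gm)
        assert kept.sample_ids == ["S0", "S2"]
        assert log["id"].tolist() == ["S1"]

    def test_snp_maf_rule_requires_both_groups(self, rng):
        n = 400
        eth = np.array(["A"] * 200 + ["B"] * 200)
        # snp0: rare in A only; snp1: rare in both
        calls = rng.binomial(2, 0.3, (n, 2)).astype(float)
        calls[:200, 0] = 0.0
        calls[rng.choice(200), 0] = 1.0           # MAF 1/400 in A
        calls[:, 1] = 0.0
        calls[[5, 305], 1] = 1.0                  # rare in both
        gm = self._gm(calls)
        kept, log = pa.qc_snps(gm, self._samples(n, eth))
        assert "snp0" in kept.snp_ids
        assert dict(zip(log["id"], log["reason"])) == {"snp1": "maf<0.01_both_groups"}

    def test_snp_call_rate_strict(self, rng):
        n = 100
        calls = rng.binomial(2, 0.4, (n, 2)).astype(float)
        calls[:11, 0] = np.nan                    # 89% -> removed
        calls[:10, 1] = np.nan                    # 90% -> kept
        gm = self._gm(calls)
        kept, log = pa.qc_snps(gm, self._samples(n, np.repeat(["A", "B"], 50)))
        assert kept.snp_ids == ["snp1"]
        assert log["reason"].iloc[0].startswith("call_rate")

    def test_idempotent_and_counts_conserved(self):
        gm, samples, _ = pa.simulate_qc_fixture(seed=5)
        kept1, log1 = pa.qc_snps(gm, samples)
        kept2, log2 = pa.qc_snps(kept1, samples)
        assert kept2.snp_ids == kept1.snp_ids
        assert len(log2) == 0
        assert len(log1) + kept1.n_snps == gm.n_snps

    def test_planted_fixture_330_to_320(self):
        gm, samples, expected = pa.simulate_qc_fixture(seed=11)
        assert gm.n_snps == 330
        kept, log = pa.qc_snps(gm, samples)
        assert kept.n_snps == 320
        assert dict(zip(log["id"], log["reason"])) == expected
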