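"""Variant frequency spectra: VAF arithmetic, filtering, germline removal,
tabular/VCF round trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vfsage as v
from conftest import make_vfs


class TestVafArithmetic:
    @pytest.mark.parametrize(
        "mutant, nonmutant, expected",
        [(100, 200, 1 / 6), (0, 250, 0.0), (300, 0, 0.5)],
    )
    def test_cell_counts(self, mutant, nonmutant, expected):
        assert v.vaf_from_cell_counts(mutant, nonmutant) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "alt, ref, expected", [(15, 85, 0.15), (0, 30, 0.0), (30, 0, 1.0)]
    )
    def test_read_counts(self, alt, ref, expected):
        assert v.vaf_from_read_counts(alt, ref) == pytest.approx(expected)

    def test_zero_total_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            v.vaf_from_cell_counts(0, 0)
        with pytest.raises(ZeroDivisionError):
            v.vaf_from_read_counts(0, 0)

    @given(m=st.integers(0, 10_000), u=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=100)
    def test_cell_vaf_bounded_by_half(self, m, u):
        if m + u == 0:
            return
        assert 0.0 <= v.vaf_from_cell_counts(m, u) <= 0.5


class TestRescaleCountsToDepth:
    def test_printed_worked_example(self):
        # 300 total reads at target 30: divisor 10, nonmutant = 30 - 10.
        assert v.rescale_counts_to_depth(100, 300, 30) == (10.0, 20.0)

    @pytest.mark.parametrize(
        "mutant, total, target, expected",
        [(0, 300, 30, (0.0, 30.0)), (30, 30, 30, (30.0, 0.0))],
    )
    def test_edge_cases(self, mutant, total, target, expected):
        assert v.rescale_counts_to_depth(mutant, total, target) == expected

    def test_upscaling_rejected(self):
        with pytest.raises(ValueError, match="upscal"):
            v.rescale_counts_to_depth(5, 20, 30)

    def test_integer_mode_rounds_half_away_from_zero(self):
        scaled, rest = v.rescale_counts_to_depth(45, 300, 30, integer=True)
        assert scaled == 5.0 and rest == 25.0  # 4.5 -> 5

    @given(
        total=st.integers(30, 5000),
        frac=st.floats(0, 1),
        target=st.integers(1, 30),
    )
    @settings(derandomize=True, max_examples=100)
    def test_vaf_preserved_exactly(self, total, frac, target):
        mutant = int(frac * total)
        scaled, rest = v.rescale_counts_to_depth(mutant, total, target)
        assert scaled / target == pytest.approx(mutant / total, abs=1e-12)
        assert scaled + rest == pytest.approx(target)


class TestTipVariantFilter:
    def test_boundary_inclusive(self):
        vfs = make_vfs([0.005, 0.010, 0.20])
        out = v.filter_tip_variants(vfs, 0.01)
        assert list(out.vaf) == [0.010, 0.20]
        assert out.vaf_threshold_applied == 0.01

    def test_empty_and_all_below(self):
        assert len(v.filter_tip_variants(make_vfs([]), 0.01)) == 0
        out = v.filter_tip_variants(make_vfs([0.002, 0.004]), 0.01)
        assert len(out) == 0 and out.vaf_threshold_applied == 0.01

    @given(
        vafs=st.lists(st.floats(0, 1), max_size=30),
        t1=st.floats(0.001, 0.5),
        t2=st.floats(0.001, 0.5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_idempotent_and_composable(self, vafs, t1, t2):
        vfs = make_vfs(vafs, depth=10_000)
        lo, hi = sorted([t1, t2])
        once = v.filter_tip_variants(vfs, hi)
        twice = v.filter_tip_variants(v.filter_tip_variants(vfs, lo), hi)
        assert list(twice.variant_ids) == list(once.variant_ids)
        again = v.filter_tip_variants(once, hi)
        assert list(again.variant_ids) == list(once.variant_ids)


class TestCohortGermlineFilter:
    def test_recurrence_rule(self):
        target = make_vfs([0.1, 0.2, 0.3], sample_id="t")
        cohort = [make_vfs([0.1], sample_id=f"o{i}") for i in range(5)]
        # v0 present in 2 of 5 other samples -> removed at min_other_samples=2
        cohort = cohort[:2] + [c.subset(np.zeros(1, bool)) for c in cohort[2:]]
        res = v.cohort_germline_filter(target, cohort, min_other_samples=2)
        assert "v0" in res.removed
        assert set(res.vfs.variant_ids) == {"v1", "v2"}

    def test_known_germline_removed_regardless(self):
        target = make_vfs([0.1, 0.2], sample_id="t")
        res = v.cohort_germline_filter(target, [], known_germline_sites={"v1"})
        assert res.removed == {"v1": "known_germline_site"}
        assert set(res.vfs.variant_ids) == {"v0"}

    def test_private_variant_retained(self):
        target = make_vfs([0.1], sample_id="t")
        res = v.cohort_germline_filter(target, [make_vfs([], sample_id="o")])
        assert list(res.vfs.variant_ids) == ["v0"] and not res.removed

    @given(min_other=st.integers(1, 5))
    @settings(derandomize=True, max_examples=20)
    def test_monotone_in_min_other_samples(self, min_other):
        rng = np.random.default_rng(7)
        target = make_vfs(rng.uniform(0.05, 0.4, 10), sample_id="t")
        cohort = []
        for i in range(6):
            o = make_vfs(rng.uniform(0.05, 0.4, 10), sample_id=f"o{i}")
            cohort.append(o.subset(rng.random(10) < 0.5))
        strict = v.cohort_germline_filter(target, cohort, min_other_samples=min_other)
        lax = v.cohort_germline_filter(target, cohort, min_other_samples=min_other + 1)
        assert set(strict.removed) >= set(lax.removed)


class TestTabularIO:
    def test_round_trip(self, tmp_path):
        vfs = make_vfs([0.1, 0.25, 0.0035], sample_id="ind1", source="colony_cells")
        path = tmp_path / "ind1.tsv"
        v.write_vfs(vfs, path)
        back = v.read_vfs(path)
        assert back.sample_id == "ind1"
        assert list(back.variant_ids) == list(vfs.variant_ids)
        np.testing.assert_allclose(back.vaf, vfs.vaf)
        np.testing.assert_allclose(back.mutant, vfs.mutant)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample_id\tvariant_id\tref_count\talt_count\tvaf\tsource\n"
            "s\tv1\t90\t10\t0.1\tbulk_reads\n"
            "s\tv2\t90\toops\t0.1\tbulk_reads\n"
        )
        with pytest.raises(ValueError, match=":3"):
            v.read_vfs(path)

    def test_inconsistent_vaf_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample_id\tvariant_id\tref_count\talt_count\tvaf\tsource\n"
            "s\tv1\t90\t10\t0.5\tbulk_reads\n"
        )
        with pytest.raises(ValueError, match="disagrees"):
            v.read_vfs(path)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


class TestVcfIO:
    def test_read_allele_depths(self, tmp_path):
        path = tmp_path / "in.vcf"
        path.write_text(
            VCF_HEADER
            + "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD\t0/1:85,15\n"
            + "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT:AD\t0/1:60,40\n"
        )
        vfs = v.read_vfs(path, format="vcf")
        assert len(vfs) == 2
        np.testing.assert_allclose(vfs.vaf, [0.15, 0.4])
        assert list(vfs.pos) == [100, 200]  # 1-based

    def test_missing_ad_errors_with_record(self, tmp_path):
        header = VCF_HEADER.replace(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n',
            "",
        )
        path = tmp_path / "noad.vcf"
        path.write_text(header + "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="chr1:100"):
            v.read_vfs(path, format="vcf")

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            VCF_HEADER + "chr1\t100\t.\tA\tT,G\t.\tPASS\t.\tGT:AD\t1/2:50,25,25\n"
        )
        with pytest.raises(ValueError, match="multi-allelic"):
            v.read_vfs(path, format="vcf")


class TestGenotypeMatrix:
    def test_single_carrier_vaf(self):
        import pandas as pd

        matrix = pd.DataFrame(
            {"m1": [1] + [0] * 199}, index=[f"L{i}" for i in range(200)]
        )
        vfs = v.genotype_matrix_to_vfs(matrix)
        assert vfs.vaf[0] == pytest.approx(0.0025)
        assert vfs.source[0] == "colony_cells"

    def test_matrix_round_trip(self, tmp_path, rng):
        import pandas as pd

        matrix = pd.DataFrame(
            rng.integers(0, 2, size=(6, 4)).astype(float),
            index=[f"L{i}" for i in range(6)],
            columns=[f"m{i}" for i in range(4)],
        )
        matrix.iloc[0, 0] = np.nan
        matrix.index.name = "lineage"
        path = tmp_path / "mat.tsv"
        v.write_genotype_matrix(matrix, path)
        back = v.read_genotype_matrix(path)
        pd.testing.assert_frame_equal(back, matrix)
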