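"""Index formulas, category bands and the whole-panel report."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bioload import (
    BackgroundTable,
    CFCategory,
    ConcentrationPanel,
    DCCategory,
    DomainError,
    PLICategory,
    bioconcentration_factor,
    build_index_report,
    classify_cf,
    classify_cf_two_way,
    classify_dc,
    classify_pli,
    contamination_factor,
    degree_of_contamination,
    pollution_load_index,
    site_ratio,
)

cf_values = st.floats(min_value=0, max_value=1e6, allow_nan=False)


class TestContaminationFactor:
    @pytest.mark.parametrize(
        "metal, background, expected",
        [(2.0, 2.0, 1.0), (6.0, 2.0, 3.0), (883.5467, 1.0, 883.5467), (0.0, 5.0, 0.0)],
    )
    def test_ratio(self, metal, background, expected):
        assert contamination_factor(metal, background) == pytest.approx(expected)

    @pytest.mark.parametrize("background", [0.0, -1.0])
    def test_nonpositive_background_is_domain_error(self, background):
        with pytest.raises(DomainError):
            contamination_factor(1.0, background)

    @pytest.mark.parametrize(
        "cf, category",
        [
            (0.0, CFCategory.LOW),
            (0.999, CFCategory.LOW),
            (1.0, CFCategory.MODERATE),
            (2.6501, CFCategory.MODERATE),
            (3.0, CFCategory.CONSIDERABLE),
            (5.999, CFCategory.CONSIDERABLE),
            (6.0, CFCategory.VERY_HIGH),
            (66530.3, CFCategory.VERY_HIGH),
        ],
    )
    def test_category_bands(self, cf, category):
        assert classify_cf(cf) is category

    def test_two_way_split(self):
        assert classify_cf_two_way(2.9) == "moderate"
        assert classify_cf_two_way(3.0) == "high"

    @given(st.tuples(cf_values, cf_values))
    def test_classification_monotone(self, pair):
        lo, hi = sorted(pair)
        order = list(CFCategory)
        assert order.index(classify_cf(lo)) <= order.index(classify_cf(hi))

    def test_negative_cf_rejected(self):
        with pytest.raises(DomainError):
            classify_cf(-0.1)


class TestPollutionLoadIndex:
    @pytest.mark.parametrize(
        "cfs, expected",
        [([1.0] * 16, 1.0), ([4.0, 1.0], 2.0), ([0.0, 5.0, 9.0], 0.0), ([7.0], 7.0)],
    )
    def test_examples(self, cfs, expected):
        assert pollution_load_index(cfs) == pytest.approx(expected)

    def test_matches_log_space_oracle(self, rng):
        cfs = rng.uniform(1e-6, 10.0, size=16)
        oracle = math.exp(np.mean(np.log(cfs)))
        assert pollution_load_index(cfs) == pytest.approx(oracle, rel=1e-12)

    def test_empty_is_domain_error(self):
        with pytest.raises(DomainError):
            pollution_load_index([])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=20))
    def test_bounded_by_min_and_max(self, cfs):
        pli = pollution_load_index(cfs)
        assert min(cfs) * (1 - 1e-9) <= pli <= max(cfs) * (1 + 1e-9)

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1, max_size=10),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_equivariant(self, cfs, k):
        assert pollution_load_index([k * c for c in cfs]) == pytest.approx(
            k * pollution_load_index(cfs), rel=1e-9
        )

    @pytest.mark.parametrize(
        "pli, category",
        [
            (0.0, PLICategory.PERFECTION),
            (0.5, PLICategory.BASELINE),
            (1.0, PLICategory.BASELINE),
            (1.0001, PLICategory.DETERIORATED),
            (2.6525, PLICategory.DETERIORATED),
        ],
    )
    def test_classify(self, pli, category):
        assert classify_pli(pli) is category


class TestDegreeOfContamination:
    @pytest.mark.parametrize(
        "cfs, dc, category",
        [
            ([0.5] * 16, 8.0, DCCategory.LOW),
            ([3.0] * 16, 48.0, DCCategory.CONSIDERABLE),
            ([1, 2, 3, 10], 16.0, DCCategory.VERY_HIGH),
            ([1.0], 1.0, DCCategory.MODERATE),  # dc == n sits on the moderate band edge
        ],
    )
    def test_examples(self, cfs, dc, category):
        got_dc, got_cat = degree_of_contamination(cfs)
        assert got_dc == pytest.approx(dc)
        assert got_cat is category

    @given(
        st.lists(cf_values, min_size=1, max_size=8),
        st.lists(cf_values, min_size=1, max_size=8),
    )
    def test_additive_over_disjoint_element_sets(self, a, b):
        assert degree_of_contamination(a + b)[0] == pytest.approx(
            degree_of_contamination(a)[0] + degree_of_contamination(b)[0]
        )

    @given(st.floats(min_value=0, max_value=1e4), st.integers(min_value=1, max_value=32))
    def test_bands_scale_linearly_in_n(self, dc, n):
        assert classify_dc(dc, n) is classify_dc(2 * dc, 2 * n)

    def test_empty_is_domain_error(self):
        with pytest.raises(DomainError):
            degree_of_contamination([])


class TestBCFAndRatio:
    def test_pb_site_i_reproduces_printed_bcf(self):
        bcf, accumulating = bioconcentration_factor(3.0707, 0.1553)
        assert bcf == pytest.approx(19.774, abs=2e-3)
        assert accumulating

    @pytest.mark.parametrize(
        "biota, soil, bcf, flag",
        [(1.0, 1.0, 1.0, True), (0.0, 5.0, 0.0, False), (0.5, 1.0, 0.5, False)],
    )
    def test_boundary_inclusive(self, biota, soil, bcf, flag):
        assert bioconcentration_factor(biota, soil) == (pytest.approx(bcf), flag)

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_reciprocal_identity(self, c, b):
        assert bioconcentration_factor(c, b)[0] * bioconcentration_factor(b, c)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "c1, c2, expected",
        [(42.7720, 23.2357, 1.8408), (2009.0593, 1656.1273, 1.2131), (3.0, 3.0, 1.0)],
    )
    def test_site_ratio(self, c1, c2, expected):
        assert site_ratio(c1, c2) == pytest.approx(expected, abs=5e-4)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bioconcentration_factor(1.0, 0.0)
        with pytest.raises(DomainError):
            site_ratio(1.0, 0.0)


class TestIndexReport:
    def test_single_element_at_background(self):
        panel = ConcentrationPanel(
            [("A", "soil", "Pb", 1, 2.0), ("A", "biota", "Pb", 1, 2.0)]
        )
        report = build_index_report(panel, BackgroundTable({"Pb": 2.0}))
        assert report.cf["cf"].tolist() == [pytest.approx(1.0)]
        assert report.cf["cf_category"].tolist() == ["moderate"]
        row = report.site_summary.iloc[0]
        assert row.pli == pytest.approx(1.0)
        assert row.pli_category == "baseline"
        assert row.dc == pytest.approx(1.0)

    def test_report_equals_scalar_operations(self, rng):
        """The whole-panel report is element-by-element scalar arithmetic."""
        from bioload import SyntheticConfig, generate_panel

        cfg = SyntheticConfig(
            elements=("Pb", "Zn", "Cu", "Cd"),
            soil_median={"Pb": 1.0, "Zn": 50.0, "Cu": 3.0, "Cd": 0.1},
            enrichment={"Pb": 20.0, "Zn": 2.0, "Cu": 10.0, "Cd": 2.5},
            site_effect={"A": 1.0, "B": 2.0},
            dispersion=0.4,
            n_replicates=4,
            seed=11,
        )
        panel = generate_panel(cfg)
        bg = BackgroundTable({"Pb": 0.5, "Zn": 40.0, "Cu": 2.0, "Cd": 0.05})
        report = build_index_report(panel, bg)
        means = panel.means().set_index(["site", "compartment", "element"])["mean"]
        for site in panel.sites:
            cfs = []
            for elem in panel.elements:
                cf = contamination_factor(means[(site, "soil", elem)], bg[elem])
                cfs.append(cf)
                got = report.cf.query("site == @site and element == @elem")["cf"].item()
                assert got == pytest.approx(cf, rel=1e-12)
                got_bcf = report.bcf.query("site == @site and element == @elem")["bcf"].item()
                assert got_bcf == pytest.approx(
                    bioconcentration_factor(
                        means[(site, "biota", elem)], means[(site, "soil", elem)]
                    )[0],
                    rel=1e-12,
                )
            row = report.site_summary.query("site == @site").iloc[0]
            assert row.pli == pytest.approx(pollution_load_index(cfs), rel=1e-12)
            assert row.dc == pytest.approx(degree_of_contamination(cfs)[0], rel=1e-12)
        for elem in panel.elements:
            got = report.ratio.query("element == @elem")["ratio"].item()
            assert got == pytest.approx(
                site_ratio(means[("A", "biota", elem)], means[("B", "biota", elem)]),
                rel=1e-12,
            )

    def test_missing_background_is_warning_not_fatal(self, table2_panel):
        bg = BackgroundTable({"Pb": 1.0, "Zn": 1.0})
        report = build_index_report(table2_panel, bg)
        assert any("background" in w for w in report.warnings)
        assert set(report.cf["element"]) == {"Pb", "Zn"}
        assert (report.site_summary["n_elements"] == 2).all()
        # BCF does not need backgrounds: full panel present
        assert len(report.bcf) == 32

    def test_table2_report_ratio_matches_consistent_printed_cells(
        self, table2_panel, unit_background
    ):
        from bioload.fixtures import CONSISTENT_RATIO_ELEMENTS, table4_bcf_ratio

        report = build_index_report(
            table2_panel, unit_background, ratio_pair=("Site I", "Site II")
        )
        printed = table4_bcf_ratio()["ratio_site1_site2"]
        got = report.ratio.set_index("element")["ratio"]
        for elem in CONSISTENT_RATIO_ELEMENTS:
            assert abs(got[elem] - printed[elem]) <= 5e-4
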