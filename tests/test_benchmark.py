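"""Threshold filters, chaining, top-fraction curves, grids, ClinVar strata."""

import math

import numpy as np
import pandas as pd
import pytest

import capsbench as cb
from capsbench import benchmark as bm
from capsbench.caps import CapsEstimate, ReferenceModel, compute_caps
from capsbench.errors import ConfigurationError, EmptyGroupError
from capsbench.tools import HIGHER, LOWER, ToolMeta


def make_table(scores_by_tool, model=None):
    """A toy scored table; every row is a singleton in context ACA>G."""
    n = len(next(iter(scores_by_tool.values())))
    df = pd.DataFrame(
        {
            "context_label": ["ACA>G"] * n,
            "is_singleton": [True] * n,
        }
    )
    for tool, vals in scores_by_tool.items():
        df[f"score_{tool}"] = vals
    return df


TOY_MODEL = ReferenceModel.from_counts({"ACA>G": (100, 40)})

REGISTRY = {
    "SIFT": ToolMeta("SIFT", LOWER, (0.0, 1.0), "Damaging", 0.05),
    "PolyPhen": ToolMeta("PolyPhen", HIGHER, (0.0, 1.0), "Possibly damaging", 0.8),
    "CADD": ToolMeta("CADD", HIGHER, (0.0, 99.0), "", 20.0),
}


class TestApplyFilters:
    specs = [
        bm.FilterSpec("SIFT", "<", 0.05),
        bm.FilterSpec("PolyPhen", ">", 0.8),
        bm.FilterSpec("CADD", ">", 20.0),
    ]

    def table(self):
        return make_table(
            {
                "SIFT": [0.01, 0.01, 0.5, 0.01, np.nan],
                "PolyPhen": [0.9, 0.5, 0.95, 0.99, 0.99],
                "CADD": [25.0, 30.0, 28.0, 10.0, 33.0],
            }
        )

    def test_conjunction(self):
        out = bm.apply_filters(self.table(), self.specs, REGISTRY)
        assert out.index.tolist() == [0]

    def test_empty_spec_list_is_identity(self):
        t = self.table()
        pd.testing.assert_frame_equal(bm.apply_filters(t, []), t)

    def test_missing_score_fails_the_filter(self):
        out = bm.apply_filters(self.table(), [bm.FilterSpec("SIFT", "<", 0.05)])
        assert 4 not in out.index

    def test_orientation_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="benign side"):
            bm.apply_filters(self.table(), [bm.FilterSpec("SIFT", ">", 0.05)], REGISTRY)


class TestChain:
    def test_single_step_equals_compute_caps(self):
        t = make_table({"CADD": [25.0, 10.0, 30.0, 15.0]})
        spec = bm.FilterSpec("CADD", ">", 20.0)
        chain = bm.chain_filters(t, [spec], TOY_MODEL)
        direct = compute_caps(bm.apply_filters(t, [spec]), TOY_MODEL)
        assert len(chain) == 1
        assert chain[0].caps == direct.caps

    def test_counts_non_increasing(self, cohort):
        specs = bm.established_filters()
        chain = bm.chain_filters(cohort["study"], specs, cohort["model"], cohort["registry"])
        counts = [e.n_variants for e in chain]
        assert counts == sorted(counts, reverse=True)

    def test_truncates_on_empty_step(self):
        t = make_table({"CADD": [25.0, 30.0]})
        specs = [bm.FilterSpec("CADD", ">", 20.0), bm.FilterSpec("CADD", ">", 98.0)]
        chain = bm.chain_filters(t, specs, TOY_MODEL)
        assert len(chain) == 1


class TestTopFraction:
    def test_higher_orientation_top_two(self):
        t = make_table({"CADD": [float(i) for i in range(1, 11)]})
        scheme = cb.TopFractionScheme(fractions=(20.0,), na_policy="per_tool")
        (est,) = bm.top_fraction_curve(t, "CADD", scheme, TOY_MODEL, REGISTRY)
        assert est.n_variants == 2  # scores 10 and 9

    def test_lower_orientation_selects_smallest(self):
        scores = [round(0.01 * i, 2) for i in range(1, 11)]
        t = make_table({"SIFT": scores})
        scheme = cb.TopFractionScheme(fractions=(20.0,), na_policy="per_tool")
        (est,) = bm.top_fraction_curve(t, "SIFT", scheme, TOY_MODEL, REGISTRY)
        sel = t.nsmallest(2, "score_SIFT")
        assert est.n_variants == 2
        assert sel["score_SIFT"].tolist() == [0.01, 0.02]

    def test_full_fraction_equals_complete_case_estimate(self, cohort):
        scheme = cb.TopFractionScheme(fractions=(100.0,))
        (est,) = bm.top_fraction_curve(
            cohort["study"], "REVEL", scheme, cohort["model"], cohort["registry"]
        )
        cc = bm.complete_case(cohort["study"])
        direct = compute_caps(cc, cohort["model"])
        assert est.n_variants == len(cc)
        assert est.caps == direct.caps

    def test_counts_follow_ceiling_rule(self, cohort):
        scheme = cb.TopFractionScheme()
        curve = bm.top_fraction_curve(
            cohort["study"], "CADD", scheme, cohort["model"], cohort["registry"]
        )
        N = len(bm.complete_case(cohort["study"]))
        for est, f in zip(curve, scheme.fractions):
            assert est.n_variants == math.ceil(f * N / 100.0)

    def test_fractions_must_decrease(self):
        with pytest.raises(ConfigurationError):
            cb.TopFractionScheme(fractions=(50.0, 50.0))


class TestGrid:
    def grid(self, cohort):
        specs = [
            bm.FilterSpec("REVEL", ">", 0.75),
            bm.FilterSpec("CADD", ">", 20.0),
            bm.FilterSpec("SIFT", "<", 0.05),
        ]
        return specs, bm.pairwise_filter_grid(
            cohort["study"], specs, cohort["model"], cohort["registry"]
        )

    def test_combinatorics_and_symmetry(self, cohort):
        specs, grid = self.grid(cohort)
        assert len(grid.singles) == 3
        assert len(grid.pairs) == 3
        a, b = specs[0].label, specs[1].label
        assert grid.pair(a, b) is grid.pair(b, a)

    def test_pair_counts_bounded_by_singles(self, cohort):
        specs, grid = self.grid(cohort)
        for key, est in grid.pairs.items():
            a, b = sorted(key)
            assert est.n_variants <= min(
                grid.singles[a].n_variants, grid.singles[b].n_variants
            )

    def test_matrix_diagonal_equals_singles(self, cohort):
        specs, grid = self.grid(cohort)
        m = grid.matrix()
        for lab, est in grid.singles.items():
            assert m.loc[lab, lab] == est.caps
        assert (m.to_numpy() == m.to_numpy().T).all()

    def test_empty_cell_marked_not_raised(self):
        t = make_table({"CADD": [25.0, 30.0], "SIFT": [0.9, 0.95]})
        specs = [bm.FilterSpec("CADD", ">", 20.0), bm.FilterSpec("SIFT", "<", 0.05)]
        grid = bm.pairwise_filter_grid(t, specs, TOY_MODEL)
        assert grid.singles["SIFT < 0.05"] is None
        assert grid.pair("CADD > 20", "SIFT < 0.05") is None


class TestKeyAnnotation:
    @staticmethod
    def est(label, caps, half=0.02):
        return CapsEstimate(label, 100, 50, 40, caps, 0.01, caps - half, caps + half)

    def test_dominating_filter_found(self):
        grid = bm.GridResult(
            singles={"R": self.est("R", 0.40), "X": self.est("X", 0.25)},
            pairs={frozenset(("R", "X")): self.est("R & X", 0.41)},
            labels=["R", "X"],
        )
        assert bm.find_key_annotation(grid) == "R"

    def test_synergy_defeats_single_key(self):
        grid = bm.GridResult(
            singles={"A": self.est("A", 0.30), "B": self.est("B", 0.28)},
            pairs={frozenset(("A", "B")): self.est("A & B", 0.45)},
            labels=["A", "B"],
        )
        assert bm.find_key_annotation(grid) is None

    def test_single_filter_is_vacuously_key(self):
        grid = bm.GridResult(singles={"R": self.est("R", 0.4)}, pairs={}, labels=["R"])
        assert bm.find_key_annotation(grid) == "R"


class TestClinvarStrata:
    def toy(self):
        return pd.DataFrame(
            {
                "context_label": ["ACA>G"] * 4,
                "is_singleton": [True, False, True, False],
                "clinvar_significance": ["benign", "likely_benign", "uncertain", "absent"],
                "clinvar_stars": [2, 2, 1, 0],
            }
        )

    def test_merge_likely(self):
        strata = bm.clinvar_strata(self.toy(), TOY_MODEL, merge_likely=True)
        labels = {e.group_label: e.n_variants for e in strata}
        assert labels == {"benign|2*": 2, "uncertain|1*": 1}

    def test_no_merge(self):
        strata = bm.clinvar_strata(self.toy(), TOY_MODEL, merge_likely=False)
        assert {e.group_label for e in strata} == {
            "benign|2*", "likely_benign|2*", "uncertain|1*",
        }

    def test_partition_recomposes(self, cohort):
        study = cohort["study"]
        labelled = study[study["clinvar_significance"] != "absent"]
        whole = compute_caps(labelled, cohort["model"])
        strata = bm.clinvar_strata(study, cohort["model"], merge_likely=True)
        total_n = sum(e.n_variants for e in strata)
        recomposed = sum(e.caps * e.n_variants for e in strata) / total_n
        assert total_n == len(labelled)
        assert recomposed == pytest.approx(whole.caps, abs=1e-12)

    def test_requires_labels(self):
        t = make_table({"CADD": [25.0]})
        t["clinvar_significance"] = "absent"
        with pytest.raises(EmptyGroupError):
            bm.clinvar_strata(t, TOY_MODEL)


class TestLabelCalibration:
    def test_threshold_passed_by_all_matches_cohort_average(self, cohort):
        study = cohort["study"]
        registry = {"CADD": ToolMeta("CADD", HIGHER, (0.0, 99.0), "Disease causing", -1.0)}
        # threshold below the score range: every scored variant passes
        (est,) = bm.label_calibration(study, registry, cohort["model"])
        scored = study[study["score_CADD"].notna()]
        assert est.n_variants == len(scored)
        assert est.caps == compute_caps(scored, cohort["model"]).caps

    def test_unpassed_threshold_omitted(self, cohort):
        registry = {"CADD": ToolMeta("CADD", HIGHER, (0.0, 99.0), "", 98.9)}
        assert bm.label_calibration(cohort["study"], registry, cohort["model"]) == []

    def test_identical_tools_get_identical_estimates(self, cohort):
        study = cohort["study"].copy()
        study["score_clone"] = study["score_REVEL"]
        registry = {
            "REVEL": ToolMeta("REVEL", HIGHER, (0.0, 1.0), "", 0.75),
            "clone": ToolMeta("clone", HIGHER, (0.0, 1.0), "", 0.75),
        }
        a, b = bm.label_calibration(study, registry, cohort["model"])
        assert a.caps == b.caps
        assert a.n_variants == b.n_variants

    def test_tool_without_threshold_skipped(self, cohort):
        registry = {"REVEL": ToolMeta("REVEL", HIGHER, (0.0, 1.0), "", None)}
        assert bm.label_calibration(cohort["study"], registry, cohort["model"]) == []
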