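"""Contrast indices, feature evaluation, proposal heuristics, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoplast.expression_io import PhenoplastError
from phenoplast.features import (
    FeatureSpec,
    contrast_index,
    evaluate_features,
    preset_specs,
    propose_features,
    validate_features,
)
from phenoplast.pca import PCAModel

from conftest import make_feature_table, make_table

positive = st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False)


class TestContrastIndex:
    def test_balance_and_forced_values(self):
        assert contrast_index(2, 2) == 0.0
        assert contrast_index(3, 1) == 0.5
        assert contrast_index(1, 0) == 1.0
        assert contrast_index(0, 1) == -1.0

    def test_zero_total_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(contrast_index(0, 0))

    @settings(max_examples=200, derandomize=True)
    @given(a=positive, b=positive)
    def test_antisymmetry_and_bounds(self, a, b):
        v = contrast_index(a, b)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(-contrast_index(b, a), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(a=positive, b=positive, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, b, c):
        assert contrast_index(c * a, c * b) == pytest.approx(
            contrast_index(a, b), abs=1e-9
        )


CAT_PROTEINS = ["Synapsin", "GluN1", "GluN2A", "GluN2B", "GluA2", "GABAAa1", "GABAAa3"]


class TestEvaluateFeatures:
    def test_sum_of_units(self):
        table = make_table([[1.0] * 4], ["GluN1", "GluN2A", "GluN2B", "GluA2"])
        spec = FeatureSpec(name="GlutR Sum", kind="sum",
                           numerator=("GluN1", "GluN2A", "GluN2B", "GluA2"))
        out = evaluate_features(table, [spec])
        assert out.data["GlutR Sum"].iloc[0] == 4.0

    def test_multi_protein_index_contrasts_sums(self):
        table = make_table([[2.0, 2.0, 2.0, 1.0, 1.0]],
                           ["GluN1", "GluN2A", "GluN2B", "GABAAa1", "GABAAa3"])
        spec = FeatureSpec(
            name="GlutR:GABAAR", kind="index",
            numerator=("GluN1", "GluN2A", "GluN2B"),
            denominator=("GABAAa1", "GABAAa3"),
        )
        out = evaluate_features(table, [spec])
        assert out.data["GlutR:GABAAR"].iloc[0] == pytest.approx((6 - 2) / 8)

    def test_nine_panel_features_match_hand_computation(self, rng):
        values = rng.uniform(0.5, 3.0, size=(4, 7))
        table = make_table(values, CAT_PROTEINS,
                           {"case_id": [f"c{i}" for i in range(4)]})
        out = evaluate_features(table, preset_specs("cat9"))
        cols = {p: values[:, j] for j, p in enumerate(CAT_PROTEINS)}
        glut = cols["GluN1"] + cols["GluN2A"] + cols["GluN2B"] + cols["GluA2"]
        gaba = cols["GABAAa1"] + cols["GABAAa3"]
        expected = {
            "Protein Sum": values.sum(axis=1),
            "GlutR Sum": glut,
            "GABAAR Sum": gaba,
            "GlutR:GABAAR": (glut - gaba) / (glut + gaba),
            "GluN2A:GluN2B": (cols["GluN2A"] - cols["GluN2B"])
            / (cols["GluN2A"] + cols["GluN2B"]),
            "GluN2B:GluA2": (cols["GluN2B"] - cols["GluA2"])
            / (cols["GluN2B"] + cols["GluA2"]),
            "GABAAa1:GABAAa3": (cols["GABAAa1"] - cols["GABAAa3"])
            / (cols["GABAAa1"] + cols["GABAAa3"]),
            "GABAAa1:GluN2A": (cols["GABAAa1"] - cols["GluN2A"])
            / (cols["GABAAa1"] + cols["GluN2A"]),
            "GluN2A:GluA2": (cols["GluN2A"] - cols["GluA2"])
            / (cols["GluN2A"] + cols["GluA2"]),
        }
        for name, vals in expected.items():
            np.testing.assert_allclose(out.data[name], vals, atol=1e-12,
                                       err_msg=name)

    def test_missing_protein_makes_feature_missing(self):
        table = make_table([[1.0, np.nan]], ["A", "B"])
        spec = FeatureSpec(name="S", kind="sum", numerator=("A", "B"))
        out = evaluate_features(table, [spec])
        assert np.isnan(out.data["S"].iloc[0])

    def test_unknown_protein_fails_at_spec_time(self):
        table = make_table([[1.0]], ["A"])
        spec = FeatureSpec(name="S", kind="sum", numerator=("Nope",))
        with pytest.raises(PhenoplastError, match="Nope"):
            evaluate_features(table, [spec])

    def test_panel_rescaling_scales_sums_fixes_indices(self, rng):
        values = rng.uniform(0.5, 3.0, size=(5, 7))
        t1 = make_table(values, CAT_PROTEINS)
        t2 = make_table(values * 3.7, CAT_PROTEINS)
        specs = preset_specs("cat9")
        f1 = evaluate_features(t1, specs)
        f2 = evaluate_features(t2, specs)
        for spec in specs:
            if spec.kind == "sum":
                np.testing.assert_allclose(
                    f2.data[spec.name], 3.7 * f1.data[spec.name], rtol=1e-12
                )
            else:
                np.testing.assert_allclose(
                    f2.data[spec.name], f1.data[spec.name], atol=1e-12
                )


def toy_model(var_coords, proteins):
    """Assemble a PCAModel with prescribed variable coordinates."""
    var_coords = np.asarray(var_coords, dtype=float)
    p, d = var_coords.shape
    full = np.zeros((p, p))
    full[:, :d] = var_coords
    row_ss = (full**2).sum(axis=1)
    cos2 = np.where(row_ss[:, None] > 0, full**2 / np.maximum(row_ss, 1e-300)[:, None], 0.0)
    return PCAModel(
        eigenvalues=np.ones(p), pct_variance=np.full(p, 100.0 / p),
        cum_pct_variance=np.linspace(100.0 / p, 100.0, p),
        scores=np.zeros((2, p)), loadings=np.eye(p),
        var_coords=full, cos2=cos2, protein_names=list(proteins),
    )


class TestProposeFeatures:
    def test_all_positive_loadings_yield_only_sums(self):
        model = toy_model([[0.9], [0.8], [0.85], [0.7]], ["A", "B", "C", "D"])
        specs = propose_features(
            model, 1, apriori_pairs=[],
            protein_classes={"Glut": ["A", "B"], "GABA": ["C", "D"]},
            amplitude_quantile=0.5,
        )
        kinds = {s.kind for s in specs}
        assert kinds == {"sum"}
        names = {s.name for s in specs}
        assert {"Protein Sum", "Glut Sum", "GABA Sum"} <= names

    def test_opposite_large_amplitudes_become_novel_pair(self):
        model = toy_model([[0.1, 0.9], [0.1, -0.9], [0.9, 0.0]], ["A", "B", "C"])
        specs = propose_features(model, 2, amplitude_quantile=0.5)
        pairs = [s for s in specs if s.provenance == "novel_pair"]
        assert len(pairs) == 1
        assert pairs[0].numerator == ("A",)
        assert pairs[0].denominator == ("B",)

    def test_apriori_pairs_kept_and_deduplicated(self):
        model = toy_model([[0.9, 0.8], [0.8, -0.8]], ["A", "B"])
        specs = propose_features(model, 2, apriori_pairs=[("A", "B")],
                                 amplitude_quantile=0.0)
        indices = [s for s in specs if s.kind == "index"]
        # the novel A/B opposition duplicates the a-priori pair: kept once
        assert len(indices) == 1
        assert indices[0].provenance == "a_priori"

    def test_subunit_sign_oppositions_found_in_cat_like_structure(self):
        # dimension signs arranged as in the seven-protein worked example:
        # dim1 all positive; dim2 GluN2A vs (GluN2B, GluA2, GABAAa1) opposed;
        # dim3 GABAAa1 vs GABAAa3 opposed.
        coords = np.array([
            # dim1  dim2   dim3
            [0.40, 0.05, 0.05],   # Synapsin
            [0.80, 0.10, 0.10],   # GluN1
            [0.75, 0.60, 0.10],   # GluN2A
            [0.85, -0.45, 0.05],  # GluN2B
            [0.80, -0.50, 0.10],  # GluA2
            [0.45, -0.65, 0.55],  # GABAAa1
            [0.50, 0.10, -0.60],  # GABAAa3
        ])
        model = toy_model(coords, CAT_PROTEINS)
        specs = propose_features(model, 3, amplitude_quantile=0.6)
        # oracle: enumerate all pairs against the rule directly
        thresholds = np.quantile(np.abs(coords), 0.6, axis=0)
        expected = set()
        for i in range(7):
            for j in range(i + 1, 7):
                for d in range(3):
                    if (abs(coords[i, d]) >= thresholds[d]
                            and abs(coords[j, d]) >= thresholds[d]
                            and coords[i, d] * coords[j, d] < 0):
                        expected.add(frozenset({CAT_PROTEINS[i], CAT_PROTEINS[j]}))
        got = {
            frozenset(s.numerator) | frozenset(s.denominator)
            for s in specs if s.kind == "index"
        }
        assert got == expected
        assert frozenset({"GluN2A", "GABAAa1"}) in got
        assert frozenset({"GluN2A", "GluA2"}) in got


class TestValidateFeatures:
    def test_feature_identical_to_score_is_significant(self, rng):
        scores = rng.normal(size=(30, 3))
        features = make_feature_table(scores[:, [0]], ["F"])
        out = validate_features(features, scores, ndims=3)
        assert out.r.loc["Dim1", "F"] == pytest.approx(1.0)
        assert bool(out.significant.loc["Dim1", "F"])
        assert out.validated_features() == ["F"]

    def test_bonferroni_multiplies_by_test_count(self, rng):
        scores = rng.normal(size=(40, 3))
        values = rng.normal(size=(40, 9))
        features = make_feature_table(values, [f"F{j}" for j in range(9)])
        out = validate_features(features, scores, ndims=3, method="bonferroni")
        from scipy import stats
        for d in range(3):
            for j in range(9):
                raw = stats.pearsonr(scores[:, d], values[:, j]).pvalue
                assert out.p_adjusted.iloc[d, j] == pytest.approx(
                    min(1.0, 27 * raw), rel=1e-9
                )

    def test_constant_feature_not_significant_with_warning(self, rng):
        scores = rng.normal(size=(20, 2))
        features = make_feature_table(np.ones((20, 1)), ["Const"])
        with pytest.warns(UserWarning, match="constant"):
            out = validate_features(features, scores, ndims=2)
        assert not out.significant.to_numpy().any()

    def test_fdr_no_stricter_than_bonferroni(self, rng):
        scores = rng.normal(size=(25, 3))
        values = np.column_stack([scores[:, 0] + rng.normal(0, 0.5, 25),
                                  rng.normal(size=25)])
        features = make_feature_table(values, ["F0", "F1"])
        bf = validate_features(features, scores, ndims=3, method="bonferroni")
        fdr = validate_features(features, scores, ndims=3, method="fdr")
        assert (fdr.p_adjusted.to_numpy() <= bf.p_adjusted.to_numpy() + 1e-12).all()
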