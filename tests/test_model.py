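"""Network model: aggregation rules, invariants, and recovery."""

import numpy as np
import pandas as pd
import pytest

from ssrinet import MGMConfig, MixedGraphicalModel, default_nodes, estimate_network
from ssrinet.model import SIGN_UNDEFINED, NodeSpec, combine_nodewise
from ssrinet.solver import NodewiseFit


def _fit(node, predictors, coefs):
    return NodewiseFit(node=node, family="gaussian", predictors=predictors,
                       intercept=0.0, coefficients=np.asarray(coefs, float), lam=0.1)


class TestCombineRules:
    names = ["a", "b"]

    def _pair(self, ab, ba):
        return {"a": _fit("a", ["b"], [ab]), "b": _fit("b", ["a"], [ba])}

    def test_and_rule_average_and_sign(self):
        w, s = combine_nodewise(self._pair(-0.2, -0.1), self.names, "AND")
        assert w[0, 1] == pytest.approx(-0.15)
        assert s[0, 1] == -1

    def test_and_rule_zeroes_one_sided(self):
        w, s = combine_nodewise(self._pair(0.2, 0.0), self.names, "AND")
        assert w[0, 1] == 0 and s[0, 1] == 0
        w, s = combine_nodewise(self._pair(0.2, 0.0), self.names, "OR")
        assert w[0, 1] == pytest.approx(0.1)
        assert s[0, 1] == 1

    def test_disagreeing_signs_undefined(self):
        with pytest.warns(UserWarning, match="disagreeing"):
            w, s = combine_nodewise(self._pair(0.2, -0.3), self.names, "AND")
        assert abs(w[0, 1]) == pytest.approx(0.25)
        assert s[0, 1] == SIGN_UNDEFINED

    def test_missing_fit_errors(self):
        with pytest.raises(ValueError, match="missing nodewise fit"):
            combine_nodewise({"a": _fit("a", ["b"], [0.1])}, self.names, "AND")


class TestModelValidation:
    def test_exactly_one_treatment_node(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        nodes = [NodeSpec(n, "continuous", "symptom") for n in small_latent_ds.item_names]
        with pytest.raises(ValueError, match="treatment"):
            MixedGraphicalModel(wk, nodes)

    def test_missing_values_rejected(self, small_ordinal_ds):
        wk = small_ordinal_ds.frame[small_ordinal_ds.frame.week == 6]
        nodes = default_nodes(small_ordinal_ds.item_names)
        if not wk[small_ordinal_ds.item_names].isna().any().any():
            wk = wk.copy()
            wk.iloc[0, wk.columns.get_loc("guilt")] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            MixedGraphicalModel(wk, nodes)

    def test_needs_more_rows_than_nodes(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6].head(10)
        with pytest.raises(ValueError, match="rows"):
            MixedGraphicalModel(wk, default_nodes(small_latent_ds.item_names))


class TestEstimation:
    def test_weights_symmetric_zero_diagonal(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        res = estimate_network(wk, default_nodes(small_latent_ds.item_names), seed=1)
        assert np.array_equal(res.weights, res.weights.T)
        assert np.all(np.diag(res.weights) == 0)
        # sign matrix consistent with weights
        assert np.all((res.signs == 0) == (res.weights == 0))

    def test_and_rule_requires_both_coefficients(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        res = estimate_network(wk, default_nodes(small_latent_ds.item_names), seed=1)
        for i, a in enumerate(res.node_names):
            for j, b in enumerate(res.node_names):
                if i < j and res.weights[i, j] != 0:
                    assert res.fits[a].coef(b) != 0
                    assert res.fits[b].coef(a) != 0

    def test_same_seed_identical_network(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        nodes = default_nodes(small_latent_ds.item_names)
        r1 = estimate_network(wk, nodes, seed=5)
        r2 = estimate_network(wk, nodes, seed=5)
        assert np.array_equal(r1.weights, r2.weights)
        assert r1.lambdas() == r2.lambdas()

    def test_paper_like_week6_mood_edge_negative(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        res = estimate_network(wk, default_nodes(small_latent_ds.item_names), seed=2)
        assert res.weight("arm", "depressed_mood") < 0

    def test_duplicated_rows_similar_network(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        nodes = default_nodes(small_latent_ds.item_names)
        r1 = estimate_network(wk, nodes, seed=3)
        dup = pd.concat([wk, wk], ignore_index=True)
        r2 = estimate_network(dup, nodes, seed=3)
        # CV folds differ with n, so equality is up to fold noise
        strong = np.abs(r1.weights) > 0.1
        assert np.all(r2.weights[strong] != 0)
        assert np.corrcoef(r1.weights.ravel(), r2.weights.ravel())[0, 1] > 0.95

    def test_kkt_certificates_recorded(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        res = estimate_network(wk, default_nodes(small_latent_ds.item_names), seed=1)
        for fit in res.fits.values():
            assert fit.kkt_violation < 1e-6

    def test_null_data_no_strong_treatment_edges(self, null_gt):
        from ssrinet import simulate_trial
        ds = simulate_trial(null_gt, 2000, weeks=(0, 6), seed=42, latent_only=True)
        wk = ds.frame[ds.frame.week == 6]
        res = estimate_network(wk, default_nodes(ds.item_names), seed=0)
        assert (res.treatment_row().abs() <= 0.05).all()


class TestResultsSurface:
    def test_summary_and_edge_list(self, small_latent_ds):
        wk = small_latent_ds.frame[small_latent_ds.frame.week == 6]
        res = estimate_network(wk, default_nodes(small_latent_ds.item_names), seed=1)
        text = res.summary()
        assert "AND rule" in text and f"n = {len(wk)}" in text
        el = res.edge_list()
        assert set(el.columns) == {"node_a", "node_b", "weight", "sign", "rule"}
        assert el.weight.abs().is_monotonic_decreasing

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MGMConfig(rule="XOR")
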