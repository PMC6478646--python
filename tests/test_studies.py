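"""Study pipelines: initialization schemes, manifests, summaries."""

import numpy as np
import pandas as pd
import pytest

from spreadnet import (
    Network,
    build_manifest,
    difference_scores,
    execute_manifest,
    init_neighbors,
    init_prime,
    init_target,
    make_semantic_testbed,
    make_two_hop_testbed,
    priming_contrast,
    run_clustering_study,
    run_priming_study,
    standardized_ols,
)
from spreadnet.metrics import TwoHopNetwork


@pytest.fixture
def tb_deg3():
    return make_two_hop_testbed(3, 0.0, 1, seed=0)


class TestInitSchemes:
    def test_target_scheme_puts_budget_on_target(self, tb_deg3):
        init = init_target(tb_deg3, 100.0)
        assert init == [(tb_deg3.target, 100.0)]

    def test_neighbor_scheme_splits_budget_exactly(self, tb_deg3):
        init = init_neighbors(tb_deg3, 100.0)
        labels = {n for n, _ in init}
        assert labels == set(tb_deg3.one_hop)
        per_node = [a for _, a in init]
        assert per_node == pytest.approx([100.0 / 3] * 3)
        assert sum(per_node) == pytest.approx(100.0)
        assert tb_deg3.target not in labels

    def test_neighbor_scheme_even_degree(self):
        tb = make_two_hop_testbed(4, 0.0, 1, seed=0)
        init = init_neighbors(tb, 100.0)
        assert [a for _, a in init] == pytest.approx([25.0] * 4)

    def test_neighbor_scheme_rejects_degree_zero(self):
        net = Network.from_edges([], nodes=["t"])
        orphan = TwoHopNetwork(net, "t", frozenset(), frozenset())
        with pytest.raises(ValueError):
            init_neighbors(orphan, 100.0)

    def test_prime_scheme(self):
        st = make_semantic_testbed(200, 5, seed=1)
        target, related, unrelated = st.triples[0]
        assert init_prime(st, related, 100.0) == [(related, 100.0)]
        with pytest.raises(KeyError):
            init_prime(st, "no-such-word", 100.0)


class TestManifest:
    def test_study1_factorial_count(self):
        units = [{"network_id": f"net{i}", "target": "t"} for i in range(24)]
        grid = [round(0.1 * i, 1) for i in range(1, 10)]
        manifest = build_manifest(units, grid, "target")
        assert len(manifest) == 216

    def test_priming_factorial_count(self):
        units = [
            {"network_id": "sem", "target": f"t{i}", "prime": f"p{i}{pt[0]}",
             "prime_type": pt}
            for i in range(100)
            for pt in ("related", "unrelated")
        ]
        manifest = build_manifest(units, [0.2, 0.4, 0.6, 0.8], "prime")
        assert len(manifest) == 800

    def test_single_cell(self):
        manifest = build_manifest([{"network_id": "x", "target": "t"}], [0.5], "target")
        assert len(manifest) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_manifest([{"network_id": "x"}], [], "target")
        with pytest.raises(ValueError):
            build_manifest([], [0.5], "target")


class TestExecuteManifest:
    def test_edge_readout(self):
        net = Network.from_edges([("A", "B")])
        tb = TwoHopNetwork(net, "A", frozenset({"B"}), frozenset())
        manifest = build_manifest(
            [{"network_id": "edge", "target": "A"}], [0.5], "target", time_steps=10
        )
        res = execute_manifest(manifest, {"edge": tb})
        assert res.loc[0, "final_activation"] == pytest.approx(50.0)

    def test_execution_is_deterministic(self, tb_deg3):
        manifest = build_manifest(
            [{"network_id": "tb", "target": tb_deg3.target}], [0.3, 0.7], "neighbors"
        )
        a = execute_manifest(manifest, {"tb": tb_deg3})
        b = execute_manifest(manifest, {"tb": tb_deg3})
        pd.testing.assert_frame_equal(a, b)

    def test_low_clustering_target_beats_high(self):
        """Matched pair, same degree: low-C readout exceeds high-C."""
        low = make_two_hop_testbed(6, 0.1, 2, seed=1)
        high = make_two_hop_testbed(6, 0.7, 2, seed=2)
        manifest = build_manifest(
            [
                {"network_id": "low", "target": low.target},
                {"network_id": "high", "target": high.target},
            ],
            [0.5],
            "target",
        )
        res = execute_manifest(manifest, {"low": low, "high": high}).set_index(
            "network_id"
        )
        assert (
            res.loc["low", "final_activation"] > res.loc["high", "final_activation"]
        )


class TestStandardizedOls:
    def test_noise_free_single_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "y": 3.0 * x + 1.0})
        fit = standardized_ols(df, "y", ["x"], standardize_outcome=True)
        assert fit.coefficients.loc["x", "beta"] == pytest.approx(1.0)
        assert fit.adj_r_squared == pytest.approx(1.0)
        raw = standardized_ols(df, "y", ["x"], standardize_outcome=False)
        # raw-outcome beta = slope * sd(x)
        assert raw.coefficients.loc["x", "beta"] == pytest.approx(3.0 * x.std(ddof=1))

    def test_null_simulation_gives_small_t_and_r2(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(
            {"x1": rng.normal(size=1000), "x2": rng.normal(size=1000),
             "y": rng.normal(size=1000)}
        )
        fit = standardized_ols(df, "y", ["x1", "x2"])
        assert (fit.coefficients["t"].abs() < 3).all()
        assert abs(fit.adj_r_squared) < 0.02

    def test_rank_deficiency_rejected(self):
        df = pd.DataFrame({"x1": [1.0, 2, 3, 4, 5, 6], "y": [1.0, 2, 1, 2, 1, 2]})
        df["x2"] = df["x1"]
        with pytest.raises(ValueError):
            standardized_ols(df, "y", ["x1", "x2"])

    def test_zero_variance_outcome_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0] * 5})
        with pytest.raises(ValueError):
            standardized_ols(df, "y", ["x"])


class TestDifferenceScores:
    @staticmethod
    def _results(diff_map):
        rows = []
        for (k, r), (lo, hi) in diff_map.items():
            rows.append({"degree": k, "retention": r, "c_level": "low",
                         "final_activation": lo})
            rows.append({"degree": k, "retention": r, "c_level": "high",
                         "final_activation": hi})
        return pd.DataFrame(rows)

    def test_identical_pairs_give_zero(self):
        res = self._results({(3, 0.5): (10.0, 10.0), (4, 0.5): (20.0, 20.0)})
        cells, by_degree = difference_scores(res)
        assert cells["difference"].to_numpy() == pytest.approx(np.zeros(2))
        assert by_degree["mean"].to_numpy() == pytest.approx(np.zeros(2))

    def test_antisymmetry_under_label_swap(self):
        res = self._results({(3, 0.5): (12.0, 8.0), (4, 0.5): (30.0, 20.0)})
        swapped = res.copy()
        swapped["c_level"] = swapped["c_level"].map({"low": "high", "high": "low"})
        cells, _ = difference_scores(res)
        cells_sw, _ = difference_scores(swapped)
        assert cells_sw["difference"].to_numpy() == pytest.approx(
            -cells["difference"].to_numpy()
        )

    def test_orphan_cells_rejected(self):
        res = self._results({(3, 0.5): (12.0, 8.0)})
        res = res[res["c_level"] == "low"]
        with pytest.raises(ValueError, match="unmatched"):
            difference_scores(res)


class TestPrimingContrast:
    def test_identical_prime_gives_zero_contrast(self):
        rows = []
        for t in range(10):
            for r in (0.2, 0.4):
                for pt in ("related", "unrelated"):
                    rows.append({"target": f"t{t}", "retention": r,
                                 "prime_type": pt, "final_activation": 5.0 + t})
        contrast = priming_contrast(pd.DataFrame(rows), seed=0)
        assert contrast["mean_difference"].to_numpy() == pytest.approx(np.zeros(2))

    def test_unpaired_rejected(self):
        rows = [{"target": "t0", "retention": 0.2, "prime_type": "related",
                 "final_activation": 1.0}]
        with pytest.raises(ValueError, match="unpaired"):
            priming_contrast(pd.DataFrame(rows), seed=0)

    def test_contrast_scales_linearly_with_budget(self):
        """Dynamics are linear in the initial vector: doubling the prime
        budget doubles every readout, hence the contrast."""
        st = make_semantic_testbed(200, 8, seed=5)
        from spreadnet import SimParams, simulate, state_at

        target, related, unrelated = st.triples[0]
        params = SimParams(0.4, time_steps=10)
        outs = []
        for budget in (100.0, 200.0):
            vals = []
            for prime in (related, unrelated):
                h = simulate(st.network, [(prime, budget)], params)
                vals.append(state_at(h, 10).activation[target])
            outs.append(vals[0] - vals[1])
        assert outs[1] == pytest.approx(2 * outs[0])


class TestStudyDrivers:
    def test_clustering_study_shapes_and_signs(self):
        out = run_clustering_study("target", degrees=range(3, 9), seed=3)
        assert len(out["results"]) == 2 * 6 * 9
        coef = out["ols"].coefficients
        assert coef.loc["retention", "beta"] > 0
        assert coef.loc["clustering", "beta"] < 0

    def test_priming_study_contrast_positive(self):
        out = run_priming_study(n_words=200, n_pairs=10, seed=3)
        assert len(out["results"]) == 10 * 2 * 4
        assert (out["contrast"]["mean_difference"] > 0).all()
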