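import numpy as np
import pandas as pd
import pytest

from interdep import ExperimentConfig
from interdep.experiments import (grid_fixation, make_fixtures,
                                  rare_mutant_robustness, sweep_cost,
                                  sweep_heterogeneity)

from conftest import dense_absorption_oracle

M_TEST = 100_000  # sample size for experiment tests (maps are threshold-based)


class TestConfig:
    def test_json_round_trip(self, tmp_path):
        cfg = ExperimentConfig("grid_fixation", grid={"s0_points": 9, "t0_points": 9},
                               n=30, c=0.05, m=1000, seed=3, initial=(10, 10, 10))
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert ExperimentConfig.from_json(path) == cfg

    def test_grid_and_fixed_parameters_must_be_disjoint(self):
        with pytest.raises(ValueError):
            ExperimentConfig("sweep_cost", grid={"c": [0.1]})


@pytest.fixture(scope="module")
def het():
    cfg = ExperimentConfig("sweep_heterogeneity", grid={"deltas": [0.1, 2.0]},
                           m=M_TEST, seed=1)
    return sweep_heterogeneity(cfg)


@pytest.fixture(scope="module")
def small_map():
    cfg = ExperimentConfig("grid_fixation",
                           grid={"s0_points": 9, "t0_points": 9},
                           m=M_TEST, seed=1)
    return grid_fixation(cfg)


class TestSweeps:
    def test_rows_carry_full_parameter_set(self, het):
        needed = {"S0", "T0", "delta", "c", "beta", "N", "X0", "Y0", "Z0",
                  "agent_kind", "phi_A", "phi_C", "phi_D", "P_c", "seed", "m"}
        assert needed <= set(het.columns)

    def test_low_heterogeneity_pd_disfavours_costly_inference(self, het):
        row = het[(het.ecology == "PD") & (het.delta == 0.1) & (het.agent_kind == "doc")]
        assert float(row.phi_A.iloc[0]) < 1 / 3

    def test_fixation_rises_with_heterogeneity_in_pd_and_ch(self, het):
        for eco in ("PD", "CH"):
            for kind in ("doc", "tog"):
                sub = het[(het.ecology == eco) & (het.agent_kind == kind)]
                lo = float(sub[sub.delta == 0.1].phi_A.iloc[0])
                hi = float(sub[sub.delta == 2.0].phi_A.iloc[0])
                assert hi > lo

    def test_cost_sweep_is_monotone(self):
        cfg = ExperimentConfig("sweep_cost", grid={"costs": [0.0, 0.1, 0.2, 0.3]},
                               m=M_TEST, seed=1)
        df = sweep_cost(cfg)
        for (eco, kind), sub in df.groupby(["ecology", "agent_kind"]):
            phis = sub.sort_values("c").phi_A.to_numpy()
            assert np.all(np.diff(phis) <= 1e-12)

    def test_costfree_inference_dominates_in_heterogeneous_ch(self):
        cfg = ExperimentConfig("sweep_cost", grid={"costs": [0.0]}, m=M_TEST, seed=1)
        df = sweep_cost(cfg)
        row = df[(df.ecology == "CH") & (df.agent_kind == "doc")]
        assert float(row.phi_A.iloc[0]) > 1 / 3


class TestGridMaps:
    def test_probabilities_conserved_on_grid(self, small_map):
        total = small_map[["phi_A", "phi_C", "phi_D"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_doc_favored_region_wider_than_tog(self, small_map):
        frac = small_map.groupby("agent_kind")["favored"].mean()
        assert frac["doc"] > frac["tog"]

    def test_sh_quadrant_cooperation_signs(self, small_map):
        sub = small_map[(small_map.S0 == -0.5) & (small_map.T0 == 0.5)]
        inc = sub.set_index("agent_kind")["coop_increase"]
        assert inc["doc"] > 0
        assert inc["tog"] < 0

    def test_rare_mutant_map_schema_and_neutral_reference(self):
        cfg = ExperimentConfig("rare", grid={"s0_points": 3, "t0_points": 3},
                               beta=0.0, m=10_000, seed=1)
        df = rare_mutant_robustness(cfg)
        assert set(df.columns) == set(grid_fixation(
            ExperimentConfig("g", grid={"s0_points": 2, "t0_points": 2},
                             m=10_000, seed=1)).columns)
        # neutral drift: phi_A equals the rare initial frequency 2/N,
        # which is also the "favored" reference for this map
        np.testing.assert_allclose(df.phi_A, 2 / 60, atol=1e-8)
        assert df.attrs["neutral"] == pytest.approx(2 / 60)


class TestFixtures:
    def test_fixture_files_are_deterministic(self, tmp_path):
        p1 = make_fixtures(seed=5, outdir=tmp_path / "a")
        p2 = make_fixtures(seed=5, outdir=tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_chain_reference_matches_dense_oracle(self, tmp_path):
        from interdep import Ecology, compute_stats, payoff_matrix

        paths = make_fixtures(seed=5, outdir=tmp_path)
        ref = pd.read_csv(paths["chain"])
        for _, row in ref.iterrows():
            stats = compute_stats(Ecology(-0.5, 1.5, 2.0, m=10_000, seed=5),
                                  agent_kind=row.agent_kind)
            M = payoff_matrix(stats, 0.1, row.agent_kind)
            scale = stats.payoff_span
            B, index = dense_absorption_oracle(M, 6, 1.0, scale=scale)
            phi = B[index[(2, 2, 2)]]
            np.testing.assert_allclose(
                [row.phi_A, row.phi_C, row.phi_D], phi, atol=1e-10)

    def test_ecology_fixture_round_trip(self, tmp_path):
        from interdep import degree_of_correspondence

        paths = make_fixtures(seed=5, outdir=tmp_path)
        df = pd.read_csv(paths["ecology"])
        np.testing.assert_allclose(
            df["doc"],
            degree_of_correspondence(S=df["S"].to_numpy(), T=df["T"].to_numpy()),
            atol=1e-12)
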