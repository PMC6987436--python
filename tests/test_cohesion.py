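"""Cohesion, M-C ratio, coupling, group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micronet.cohesion import (
    CohesionProfile,
    cohesion,
    connectedness,
    coupling,
    group_summary,
    mc_ratio,
)
from micronet.network import SignedNetwork

from conftest import random_signed_network


def worked_network():
    # w12 = +0.8, w13 = -0.5, w23 = 0
    w = np.array([[0.0, 0.8, -0.5], [0.8, 0.0, 0.0], [-0.5, 0.0, 0.0]])
    return SignedNetwork(["x", "y", "z"], w)


def rel_frame(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns, index=["x", "y", "z"])


class TestConnectedness:
    def test_isolated_node_and_mean(self):
        net = worked_network()
        c_plus, c_minus = connectedness(net)
        assert c_plus.tolist() == pytest.approx([0.8, 0.8, 0.0])
        assert c_minus.tolist() == pytest.approx([-0.5, 0.0, -0.5])

    def test_mean_of_mixed_positive_weights(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[0, 2] = w[2, 0] = 0.4
        net = SignedNetwork(list("abc"), w)
        c_plus, _ = connectedness(net)
        assert c_plus[0] == pytest.approx(0.6)

    def test_matches_brute_force_row_scan(self, random_network):
        c_plus, c_minus = connectedness(random_network)
        w = random_network.weights
        for i in range(random_network.n_nodes):
            pos = [w[i, j] for j in range(w.shape[0]) if w[i, j] > 0]
            neg = [w[i, j] for j in range(w.shape[0]) if w[i, j] < 0]
            assert c_plus[i] == pytest.approx(np.mean(pos) if pos else 0.0)
            assert c_minus[i] == pytest.approx(np.mean(neg) if neg else 0.0)

    def test_sum_mode(self, random_network):
        c_plus, c_minus = connectedness(random_network, mode="sum")
        w = random_network.weights
        assert np.allclose(c_plus, np.where(w > 0, w, 0).sum(axis=1))
        assert np.allclose(c_minus, np.where(w < 0, w, 0).sum(axis=1))


class TestCohesion:
    def test_worked_example(self):
        rel = rel_frame({"s1": [0.5, 0.3, 0.2]})
        profile = cohesion(rel, worked_network())
        assert profile.data.loc["s1", "c_plus"] == pytest.approx(0.64)
        assert profile.data.loc["s1", "c_minus"] == pytest.approx(-0.35)
        assert profile.data.loc["s1", "mc_ratio"] == pytest.approx(0.64 / 0.35)

    def test_empty_network_gives_zero_cohesion(self):
        net = SignedNetwork(["x", "y", "z"], np.zeros((3, 3)))
        rel = rel_frame({"s1": [0.2, 0.3, 0.5], "s2": [0.6, 0.2, 0.2]})
        profile = cohesion(rel, net)
        assert (profile.data[["c_plus", "c_minus"]] == 0).all().all()

    def test_constant_connectedness_recovers_constant(self):
        w = np.array([[0.0, 0.6, 0.6], [0.6, 0.0, 0.6], [0.6, 0.6, 0.0]])
        net = SignedNetwork(["x", "y", "z"], w)
        rel = rel_frame({"s1": [0.1, 0.4, 0.5]})  # sums to 1 over net taxa
        profile = cohesion(rel, net)
        assert profile.data.loc["s1", "c_plus"] == pytest.approx(0.6)

    def test_missing_taxa_listed(self):
        rel = pd.DataFrame({"s1": [0.5]}, index=["x"])
        with pytest.raises(KeyError, match="y"):
            cohesion(rel, worked_network())

    def test_linear_in_abundances(self, random_network):
        rng = np.random.default_rng(0)
        taxa = random_network.taxon_ids
        a = rng.dirichlet(np.ones(len(taxa)))
        b = rng.dirichlet(np.ones(len(taxa)))
        lam = 0.3
        rel = pd.DataFrame(
            {"a": a, "b": b, "mix": lam * a + (1 - lam) * b}, index=taxa
        )
        profile = cohesion(rel, random_network).data
        for col in ("c_plus", "c_minus"):
            mixed = lam * profile.loc["a", col] + (1 - lam) * profile.loc["b", col]
            assert profile.loc["mix", col] == pytest.approx(mixed, abs=1e-12)

    def test_sign_contract(self, random_network):
        rng = np.random.default_rng(1)
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(random_network.n_nodes), size=10).T,
            index=random_network.taxon_ids,
            columns=[f"s{j}" for j in range(10)],
        )
        profile = cohesion(rel, random_network).data
        assert (profile["c_plus"] >= 0).all()
        assert (profile["c_minus"] <= 0).all()


class TestMcRatio:
    def test_edge_cases(self):
        c_plus = pd.Series([0.64, 0.5, 0.0, 0.3])
        c_minus = pd.Series([-0.35, -0.5, -0.2, 0.0])
        ratio = mc_ratio(c_plus, c_minus)
        assert ratio.iloc[0] == pytest.approx(1.829, abs=1e-3)
        assert ratio.iloc[1] == pytest.approx(1.0)
        assert ratio.iloc[2] == 0.0
        assert np.isnan(ratio.iloc[3])


def profile_from(c_plus, c_minus, group="g"):
    df = pd.DataFrame(
        {
            "group": group,
            "c_plus": c_plus,
            "c_minus": c_minus,
        },
        index=[f"s{i}" for i in range(len(c_plus))],
    )
    df["mc_ratio"] = mc_ratio(df["c_plus"], df["c_minus"])
    return CohesionProfile(df)


class TestCoupling:
    def test_exact_linear_relation_gives_r2_one(self):
        c_plus = np.linspace(0.1, 0.9, 12)
        profile = profile_from(c_plus, -2.0 * c_plus)
        assert coupling(profile, "g").r_squared == pytest.approx(1.0)

    def test_zero_variance_flagged_undefined(self):
        profile = profile_from(np.full(6, 0.4), -np.linspace(0.1, 0.6, 6))
        assert coupling(profile, "g").undefined

    def test_independent_components_rarely_couple(self):
        weak = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            profile = profile_from(
                rng.uniform(0.1, 0.9, size=200), -rng.uniform(0.1, 0.9, size=200)
            )
            weak += coupling(profile, "g").r_squared < 0.05
        assert weak >= 90

    def test_planted_coupling_recovered(self):
        # C- built as an affine function of C+ plus noise at R^2 ~ 0.5
        r2s = []
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            c_plus = rng.normal(0.5, 0.1, size=45)
            noise = rng.normal(0, 0.1, size=45)  # equal variance -> R^2 = 0.5
            profile = profile_from(c_plus, -(0.2 + c_plus + noise))
            r2s.append(coupling(profile, "g").r_squared)
        assert np.mean(r2s) == pytest.approx(0.5, abs=0.15)


class TestGroupSummary:
    @staticmethod
    def _two_group_profile(shift=0.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for group, offset in (("A", 0.0), ("B", shift)):
            df = pd.DataFrame(
                {
                    "group": group,
                    "c_plus": rng.normal(0.5 + offset, 0.05, size=n),
                    "c_minus": -rng.uniform(0.2, 0.4, size=n),
                },
                index=[f"{group}{i}" for i in range(n)],
            )
            df["mc_ratio"] = mc_ratio(df["c_plus"], df["c_minus"])
            frames.append(df)
        return CohesionProfile(pd.concat(frames))

    def test_identical_groups_not_rejected(self):
        summary = group_summary(self._two_group_profile(shift=0.0))
        assert (summary["p_adjusted"] > 0.05).all()

    def test_large_shift_detected(self):
        summary = group_summary(self._two_group_profile(shift=0.15))
        assert summary.loc["c_plus", "p_adjusted"] < 0.001

    def test_single_sample_group_rejected(self):
        df = pd.DataFrame(
            {"group": ["A", "A", "A", "B"], "c_plus": [1, 2, 3, 4.0],
             "c_minus": [-1, -1, -1, -1.0], "mc_ratio": [1, 2, 3, 4.0]},
            index=list("wxyz"),
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            group_summary(CohesionProfile(df))
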