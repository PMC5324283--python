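"""RIF1/RIF2 differential-connectivity scores and their standardisation."""

import numpy as np
import pandas as pd
import pytest

import pifrif as p
from pifrif.rif import RIFInputs
from tests.conftest import make_expression


def naive_rif(inputs: RIFInputs):
    """Independent double-loop oracle for both metrics."""
    R, T = len(inputs.regulators), len(inputs.targets)
    rif1 = np.zeros(R)
    rif2 = np.zeros(R)
    for r in range(R):
        s1 = 0.0
        s2 = 0.0
        for j in range(T):
            dc = inputs.r_hfe[r, j] - inputs.r_lfe[r, j]
            s1 += inputs.x[j] * inputs.d[j] * dc**2
            s2 += (inputs.x_hfe[j] * inputs.r_hfe[r, j]) ** 2 - (
                inputs.x_lfe[j] * inputs.r_lfe[r, j]
            ) ** 2
        rif1[r] = s1 / T
        rif2[r] = s2 / T
    return rif1, rif2


def random_inputs(rng):
    R = int(rng.integers(1, 6))
    T = int(rng.integers(1, 11))
    return RIFInputs(
        regulators=[f"r{i}" for i in range(R)],
        targets=[f"t{j}" for j in range(T)],
        x=rng.uniform(0, 12, T),
        d=rng.normal(0, 1, T),
        x_hfe=rng.uniform(0, 12, T),
        x_lfe=rng.uniform(0, 12, T),
        r_hfe=rng.uniform(-1, 1, (R, T)),
        r_lfe=rng.uniform(-1, 1, (R, T)),
    )


class TestConditionCorrelations:
    def test_identical_and_negated_vectors(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 6)
        vals = np.vstack([np.tile(v, 2), np.tile(v, 2), np.tile(-v, 2)])
        em = make_expression(vals, ["HFE"] * 6 + ["LFE"] * 6)
        r_h, r_l = p.condition_correlations(em, ["g0"], ["g1", "g2"])
        assert r_h[0, 0] == pytest.approx(1.0)
        assert r_l[0, 0] == pytest.approx(1.0)
        assert r_h[0, 1] == pytest.approx(-1.0)
        assert r_l[0, 1] == pytest.approx(-1.0)

    def test_six_sample_pair_matches_hand_computation(self):
        reg = np.array([2.0, 4.0, 3.0, 7.0, 5.0, 6.0])
        tgt = np.array([1.0, 3.0, 2.0, 8.0, 4.0, 9.0])
        # hand oracle: covariance over product of SDs, population form
        cov = np.mean((reg - reg.mean()) * (tgt - tgt.mean()))
        want = cov / (reg.std() * tgt.std())
        vals = np.vstack([np.concatenate([reg, reg]), np.concatenate([tgt, tgt])])
        em = make_expression(vals, ["HFE"] * 6 + ["LFE"] * 6)
        r_h, _ = p.condition_correlations(em, ["g0"], ["g1"])
        assert r_h[0, 0] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_vector_gives_r_zero(self, caplog):
        vals = np.vstack(
            [np.ones(12), np.concatenate([np.arange(6.0), np.arange(6.0)])]
        )
        em = make_expression(vals, ["HFE"] * 6 + ["LFE"] * 6)
        with caplog.at_level("WARNING"):
            r_h, r_l = p.condition_correlations(em, ["g0"], ["g1"])
        assert r_h[0, 0] == 0.0 and r_l[0, 0] == 0.0
        assert "zero-variance" in caplog.text

    def test_absent_ids_error(self, small_expression):
        with pytest.raises(p.ValidationError, match="absent"):
            p.condition_correlations(small_expression, ["nope"], ["alsonope"])


class TestRIF1:
    def test_null_wiring_gives_zero(self):
        rng = np.random.default_rng(1)
        inp = random_inputs(rng)
        inp.r_lfe = inp.r_hfe.copy()
        assert np.allclose(p.compute_rif1(inp), 0.0)

    def test_single_target_substitution(self):
        inp = RIFInputs(
            regulators=["r0"],
            targets=["t0"],
            x=np.array([5.0]),
            d=np.array([2.0]),
            x_hfe=np.array([6.0]),
            x_lfe=np.array([4.0]),
            r_hfe=np.array([[0.5]]),
            r_lfe=np.array([[-0.5]]),
        )
        assert p.compute_rif1(inp)[0] == pytest.approx(5 * 2 * 1.0**2)

    def test_homogeneous_of_degree_two_in_dc(self):
        rng = np.random.default_rng(2)
        inp = random_inputs(rng)
        base = p.compute_rif1(inp)
        mid = (inp.r_hfe + inp.r_lfe) / 2
        half = (inp.r_hfe - inp.r_lfe) / 2
        doubled = RIFInputs(
            regulators=inp.regulators,
            targets=inp.targets,
            x=inp.x,
            d=inp.d,
            x_hfe=inp.x_hfe,
            x_lfe=inp.x_lfe,
            r_hfe=np.clip(mid + 2 * half, -1, 1),
            r_lfe=np.clip(mid - 2 * half, -1, 1),
        )
        ok = np.abs(doubled.dc - 2 * inp.dc).max() < 1e-12  # no clipping bound hit
        if ok:
            assert np.allclose(p.compute_rif1(doubled), 4 * base)


class TestRIF2:
    def test_symmetric_groups_give_zero(self):
        rng = np.random.default_rng(3)
        inp = random_inputs(rng)
        inp.x_lfe = inp.x_hfe.copy()
        inp.r_lfe = inp.r_hfe.copy()
        assert np.allclose(p.compute_rif2(inp), 0.0)

    def test_single_target_substitution(self):
        inp = RIFInputs(
            regulators=["r0"],
            targets=["t0"],
            x=np.array([3.0]),
            d=np.array([2.0]),
            x_hfe=np.array([4.0]),
            x_lfe=np.array([2.0]),
            r_hfe=np.array([[0.5]]),
            r_lfe=np.array([[0.5]]),
        )
        assert p.compute_rif2(inp)[0] == pytest.approx((4 * 0.5) ** 2 - (2 * 0.5) ** 2)

    def test_even_in_correlations(self):
        rng = np.random.default_rng(4)
        inp = random_inputs(rng)
        negated = RIFInputs(
            regulators=inp.regulators,
            targets=inp.targets,
            x=inp.x,
            d=inp.d,
            x_hfe=inp.x_hfe,
            x_lfe=inp.x_lfe,
            r_hfe=-inp.r_hfe,
            r_lfe=-inp.r_lfe,
        )
        assert np.allclose(p.compute_rif2(negated), p.compute_rif2(inp))


def test_both_metrics_match_naive_oracle_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(25):
        inp = random_inputs(rng)
        w1, w2 = naive_rif(inp)
        assert np.abs(p.compute_rif1(inp) - w1).max() < 1e-10
        assert np.abs(p.compute_rif2(inp) - w2).max() < 1e-10


class TestStandardizeAndFlag:
    def test_z_scores_match_independent_computation(self):
        rng = np.random.default_rng(6)
        raw1 = rng.normal(3, 2, 40)
        raw2 = rng.normal(-1, 5, 40)
        table = p.standardize_and_flag([f"r{i}" for i in range(40)], raw1, raw2)
        assert np.abs(
            table["rif1_z"] - (raw1 - raw1.mean()) / raw1.std()
        ).max() < 1e-12
        assert abs(table["rif1_z"].mean()) < 1e-9
        assert abs(table["rif1_z"].std(ddof=0) - 1) < 1e-9
        assert abs(table["rif2_z"].std(ddof=0) - 1) < 1e-9

    def test_constant_scores_flag_nothing(self, caplog):
        with caplog.at_level("WARNING"):
            table = p.standardize_and_flag(["a", "b", "c"], np.ones(3), np.ones(3))
        assert not table["outlier"].any()
        assert "zero spread" in caplog.text

    def test_extreme_regulator_is_flagged(self):
        raw = np.zeros(50)
        raw[:49] = np.random.default_rng(7).normal(0, 1, 49)
        raw[49] = raw[:49].mean() + 10 * raw[:49].std()
        table = p.standardize_and_flag(
            [f"r{i}" for i in range(50)], raw, np.zeros(50)
        )
        assert table.loc["r49", "outlier"]

    def test_needs_two_regulators(self):
        with pytest.raises(p.ValidationError):
            p.standardize_and_flag(["only"], np.array([1.0]), np.array([2.0]))


def test_self_pair_contributes_zero_dc(small_expression, small_de):
    """A regulator that is also a target has r = 1 to itself in both groups,
    hence DC = 0; excluding self-pairs removes it from the target list."""
    gene = small_de.index[0]
    inputs = p.build_rif_inputs(
        small_expression, small_de, [gene], [gene, small_de.index[1]]
    )
    j = inputs.targets.index(gene)
    assert inputs.r_hfe[0, j] == pytest.approx(1.0)
    assert inputs.dc[0, j] == pytest.approx(0.0)
    excl = p.build_rif_inputs(
        small_expression,
        small_de,
        [gene],
        [gene, small_de.index[1]],
        exclude_self_pairs=True,
    )
    assert gene not in excl.targets
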