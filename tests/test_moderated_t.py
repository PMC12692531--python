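"""Empirical-Bayes moderated t, BH adjustment and the two validation designs.

The reference for the moderated statistics is an independently coded scalar
oracle implementing the same closed forms (log-variance moments, trigamma
inversion by bisection, posterior variance shrinkage).
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from carpoligo.normalize import (
    EBayesParams,
    bh_adjust,
    call_significant,
    dye_balance_contrast,
    fit_moderated_t,
    isolation_contrast,
)


# ---------------------------------------------------------------------------
# independent oracle (scalar, bisection-based)


def _oracle_trigamma_inverse(y):
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def oracle_moderated_t(a_rows, b_rows):
    """Two-group moderated t computed feature by feature with plain floats."""
    k = len(a_rows)
    na, nb = len(a_rows[0]), len(b_rows[0])
    df = na + nb - 2
    logfc, s2 = [], []
    for ai, bi in zip(a_rows, b_rows):
        ma = sum(ai) / na
        mb = sum(bi) / nb
        logfc.append(ma - mb)
        ss = sum((x - ma) ** 2 for x in ai) + sum((x - mb) ** 2 for x in bi)
        s2.append(ss / df)
    e = [math.log(v) - special.digamma(df / 2) + math.log(df / 2) for v in s2]
    emean = sum(e) / k
    evar = sum((x - emean) ** 2 for x in e) / (k - 1)
    excess = evar - special.polygamma(1, df / 2)
    if excess > 0:
        d0 = 2.0 * _oracle_trigamma_inverse(excess)
        s0 = math.exp(emean + special.digamma(d0 / 2) - math.log(d0 / 2))
        df_total = d0 + df
        post = [(d0 * s0 + df * v) / (d0 + df) for v in s2]
    else:
        d0 = math.inf
        s0 = math.exp(emean)
        df_total = math.inf
        post = [s0] * k
    scale = 1 / na + 1 / nb
    t = [f / math.sqrt(p * scale) for f, p in zip(logfc, post)]
    if math.isinf(df_total):
        p = [2 * stats.norm.sf(abs(x)) for x in t]
    else:
        p = [2 * stats.t.sf(abs(x), df_total) for x in t]
    return np.array(t), np.array(p), d0, s0


class TestOracleEquivalence:
    def test_five_feature_fixture_matches_oracle_to_1e10(self, rng):
        a = rng.normal(8, 1, size=(5, 3))
        b = rng.normal(8, 1, size=(5, 3))
        res = fit_moderated_t(pd.DataFrame(a), pd.DataFrame(b))
        t_o, p_o, d0_o, s0_o = oracle_moderated_t(a.tolist(), b.tolist())
        assert np.allclose(res.table["t"].to_numpy(), t_o, atol=1e-10)
        assert np.allclose(res.table["p_value"].to_numpy(), p_o, atol=1e-10)
        assert res.prior.d0 == pytest.approx(d0_o, rel=1e-8)
        assert res.prior.s0_sq == pytest.approx(s0_o, rel=1e-8)

    def test_larger_fixture_matches_oracle(self, rng):
        a = rng.normal(0, 1, size=(40, 4)) + rng.normal(0, 1, size=(40, 1))
        b = rng.normal(0, 1, size=(40, 5))
        res = fit_moderated_t(pd.DataFrame(a), pd.DataFrame(b))
        t_o, p_o, _, _ = oracle_moderated_t(a.tolist(), b.tolist())
        assert np.allclose(res.table["t"].to_numpy(), t_o, atol=1e-10)
        assert np.allclose(res.table["p_value"].to_numpy(), p_o, atol=1e-10)


class TestModeratedTLimits:
    def test_infinite_prior_df_limit(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, size=(10, 3)))
        b = pd.DataFrame(rng.normal(0, 1, size=(10, 3)))
        prior = EBayesParams(math.inf, 0.25)
        res = fit_moderated_t(a, b, prior=prior)
        scale = 1 / 3 + 1 / 3
        expected = res.table["logFC"].to_numpy() / math.sqrt(0.25 * scale)
        assert np.allclose(res.table["t"].to_numpy(), expected)

    def test_shrinkage_fixed_point_equals_ordinary_t(self, rng):
        a = rng.normal(0, 1, size=(8, 4))
        b = rng.normal(0, 1, size=(8, 4))
        na = nb = 4
        s2 = np.array(
            [
                (np.sum((r - r.mean()) ** 2) + np.sum((q - q.mean()) ** 2)) / (na + nb - 2)
                for r, q in zip(a, b)
            ]
        )
        # fix the prior at one feature's own variance: its moderated t is its
        # ordinary two-sample t regardless of d0
        prior = EBayesParams(4.0, float(s2[0]))
        res = fit_moderated_t(pd.DataFrame(a), pd.DataFrame(b), prior=prior)
        t_ord = stats.ttest_ind(a[0], b[0]).statistic
        assert res.table["t"].iloc[0] == pytest.approx(t_ord, rel=1e-12)

    def test_identical_groups_have_zero_logfc(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, size=(6, 4)))
        res = fit_moderated_t(a, a.copy())
        assert np.allclose(res.table["logFC"].to_numpy(), 0.0)

    def test_label_swap_antisymmetry(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, size=(20, 4)))
        b = pd.DataFrame(rng.normal(0.5, 1, size=(20, 4)))
        ab = fit_moderated_t(a, b)
        ba = fit_moderated_t(b, a)
        assert np.allclose(ab.table["logFC"].to_numpy(), -ba.table["logFC"].to_numpy())
        assert np.allclose(ab.table["p_value"].to_numpy(), ba.table["p_value"].to_numpy())

    def test_zero_residual_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_moderated_t(pd.DataFrame([[1.0]]), pd.DataFrame([[2.0]]))


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_properties(self, ps):
        q = bh_adjust(ps)
        assert (q <= 1).all()
        assert (q >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallSignificant:
    def _result(self, logfc, p, q):
        table = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(len(logfc))],
                "logFC": logfc,
                "t": 0.0,
                "df_total": 10.0,
                "p_value": p,
                "q_value": q,
                "significant": False,
            }
        ).set_index("feature_id", drop=False)
        from carpoligo.normalize import ContrastResult

        return ContrastResult(table)

    def test_gates(self):
        res = self._result([1.5, 0.5, 2.0], [0.001, 0.0005, 0.20], [0.01, 0.001, 0.30])
        out = call_significant(res, criterion="bh_q")
        assert out.table["significant"].tolist() == [True, False, False]
        out = call_significant(self._result([2.0], [0.20], [0.30]), criterion="raw_p")
        assert out.table["significant"].tolist() == [False]

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            call_significant(self._result([1.0], [0.01], [0.01]), criterion="magic")


class TestDesigns:
    def test_zero_noise_self_self_has_no_significant_features(self):
        m = pd.DataFrame(np.zeros((50, 3)), index=[f"p{i}" for i in range(50)])
        res, sig = dye_balance_contrast(m, {f"p{i}": "biological" for i in range(50)})
        assert len(sig) == 0

    def test_null_self_self_false_positive_fraction(self, rng):
        n = 5000
        m = pd.DataFrame(
            rng.normal(0, 0.1, size=(n, 3)), index=[f"p{i}" for i in range(n)]
        )
        classes = {f"p{i}": "biological" for i in range(n)}
        res, _ = dye_balance_contrast(m, classes, criterion="raw_p")
        frac = (res.table["p_value"] < 0.05).mean()
        assert frac <= 2 * 0.05

    def test_spikein_only_offsets_confine_significance_to_controls(self, rng):
        n = 2000
        idx = [f"p{i}" for i in range(n)]
        classes = {p: ("spikein" if i < 40 else "biological") for i, p in enumerate(idx)}
        m = pd.DataFrame(rng.normal(0, 0.05, size=(n, 4)), index=idx)
        m.iloc[:40] += 1.5  # dye offsets injected only into spike-ins
        res, sig = dye_balance_contrast(m, classes, criterion="raw_p")
        assert len(sig) > 0
        assert set(sig["feature_class"]) == {"spikein"}
        assert not sig["dye_bias_warning"].any()

    def test_isolation_contrast_label_swap(self, rng):
        a = pd.DataFrame(rng.normal(8, 0.2, size=(100, 4)))
        b = pd.DataFrame(rng.normal(8, 0.2, size=(100, 4)))
        ab = isolation_contrast(a, b)
        ba = isolation_contrast(b, a)
        assert np.allclose(ab.table["logFC"].to_numpy(), -ba.table["logFC"].to_numpy())
        assert np.allclose(ab.table["p_value"].to_numpy(), ba.table["p_value"].to_numpy())

    def test_too_few_self_self_arrays_rejected(self):
        with pytest.raises(ValueError):
            dye_balance_contrast(pd.DataFrame(np.zeros((10, 1))), {})
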