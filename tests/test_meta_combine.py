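"""Stouffer and Hartung p-value combination."""

import math
from statistics import NormalDist

import numpy as np
import pytest
from scipy.stats import combine_pvalues, norm

from consentree import TipResult, combine_tree, hartung, stouffer, z_from_p
from consentree.fixtures import FixtureSpec, make_pvalues, make_tree


def _phi_upper(z: float) -> float:
    # independent normal upper-tail via the complementary error function
    return 0.5 * math.erfc(z / math.sqrt(2.0))


class TestZFromP:
    def test_median(self):
        assert z_from_p(0.5) == 0.0

    def test_quantile_example(self):
        assert z_from_p(0.975) == pytest.approx(-1.959964, abs=1e-5)

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.2, 0.7, 0.999])
    def test_antisymmetry(self, p):
        assert z_from_p(p) == pytest.approx(-z_from_p(1 - p), abs=1e-10)

    def test_extremes_clamped_finite(self):
        assert math.isfinite(z_from_p(0.0))
        assert math.isfinite(z_from_p(1.0))
        assert z_from_p(0.0) > 0 > z_from_p(1.0)

    def test_domain(self):
        with pytest.raises(ValueError):
            z_from_p(-0.2)


class TestStouffer:
    @pytest.mark.parametrize("p", [0.01, 0.3, 0.5, 0.97])
    def test_single_p_identity(self, p):
        assert stouffer([p]).combined_p == pytest.approx(p, abs=1e-12)

    def test_all_null(self):
        assert stouffer([0.5, 0.5, 0.5]).combined_p == pytest.approx(0.5, abs=1e-12)

    def test_two_small_against_closed_form(self):
        """[0.01, 0.01] -> 1 - Phi(2*Phi^{-1}(0.99)/sqrt(2)), via erfc."""
        expect = _phi_upper(2 * NormalDist().inv_cdf(0.99) / math.sqrt(2))
        assert expect == pytest.approx(5.0e-4, rel=0.01)
        assert stouffer([0.01, 0.01]).combined_p == pytest.approx(expect, rel=1e-9)

    def test_matches_scipy_combiner(self, rng):
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, size=rng.integers(2, 9))
            ours = stouffer(p)
            theirs = combine_pvalues(p, method="stouffer")
            assert ours.combined_p == pytest.approx(theirs.pvalue, rel=1e-10)
            assert ours.z_stat == pytest.approx(theirs.statistic, rel=1e-10)

    def test_consensus_power_increases_with_k(self):
        last = 1.0
        for k in range(1, 8):
            p = stouffer([0.2] * k).combined_p
            assert p < last
            last = p

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no p-values"):
            stouffer([])


def _hartung_oracle(ps, kappa=0.2):
    """Line-by-line re-evaluation with the stdlib normal quantile."""
    nd = NormalDist()
    z = [nd.inv_cdf(1 - p) for p in ps]
    k = len(z)
    mean = sum(z) / k
    var = sum((v - mean) ** 2 for v in z) / (k - 1)
    rho_star = max(-1.0 / (k - 1), 1.0 - var)
    denom = k + (k * k - k) * (rho_star + kappa * math.sqrt(2 / (k + 1)) * (1 - rho_star))
    return _phi_upper(sum(z) / math.sqrt(denom))


class TestHartung:
    def test_zero_variance_returns_common_p(self):
        assert hartung([0.1, 0.1, 0.1]).combined_p == pytest.approx(0.1, abs=1e-12)

    def test_antisymmetric_input_is_half(self):
        assert hartung([0.2, 0.8]).combined_p == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "ps", [[0.01, 0.02, 0.03], [0.4, 0.6, 0.9, 0.2], [0.001, 0.5, 0.999]]
    )
    def test_against_formula_oracle(self, ps):
        assert hartung(ps).combined_p == pytest.approx(_hartung_oracle(ps), rel=1e-8)

    def test_rho_star_floor(self):
        res = hartung([0.001, 0.999])  # huge variance -> rho_hat << floor
        assert res.rho_star == pytest.approx(-1.0 / (res.k - 1))
        assert res.rho_hat < res.rho_star

    def test_k1_falls_back_to_identity(self):
        res = hartung([0.03])
        assert res.combined_p == pytest.approx(0.03, abs=1e-12)
        assert res.method == "hartung"

    def test_variants_agree_at_zero_variance(self):
        a = hartung([0.2, 0.2, 0.2], variant="published").combined_p
        b = hartung([0.2, 0.2, 0.2], variant="sqrt-pooled").combined_p
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("k, shift", [(2, 0.4), (3, -0.3), (5, 0.8)])
    def test_equals_stouffer_when_dependence_term_vanishes(self, k, shift):
        """If rho* + kappa*sqrt(2/(k+1))*(1-rho*) == 0 the denominator
        collapses to k and Hartung coincides with Stouffer.

        Solve for the rho* that zeroes the bracket, build z-values with
        exactly the implied sample variance (an equispaced set around a
        nonzero mean), and compare the two combiners on the induced
        p-values."""
        kappa, c = 0.2, math.sqrt(2 / (k + 1))
        rho_star = -kappa * c / (1 - kappa * c)
        assert rho_star > -1 / (k - 1) or k == 2  # not floored away
        target_var = 1.0 - rho_star
        base = np.arange(k) - (k - 1) / 2  # mean-zero, equispaced
        z = shift + base * math.sqrt(target_var / np.var(base, ddof=1))
        p = [_phi_upper(v) for v in z]
        res = hartung(p)
        assert res.rho_star == pytest.approx(rho_star, abs=1e-9)
        assert res.combined_p == pytest.approx(stouffer(p).combined_p, abs=1e-10)


class TestDirectionalSymmetry:
    @pytest.mark.parametrize("method", [stouffer, hartung])
    def test_flip_all_flips_combined(self, method, rng):
        for _ in range(50):
            p = rng.uniform(0.01, 0.99, size=rng.integers(2, 10))
            a = method(list(p)).combined_p
            b = method(list(1.0 - p)).combined_p
            assert b == pytest.approx(1.0 - a, abs=1e-10)

    @pytest.mark.parametrize("method", [stouffer, hartung])
    def test_order_invariance(self, method, rng):
        p = list(rng.uniform(0.01, 0.99, size=6))
        shuffled = list(p)
        rng.shuffle(shuffled)
        assert method(shuffled).combined_p == pytest.approx(
            method(p).combined_p, abs=1e-12
        )


class TestCombineTree:
    def test_star_null(self):
        from consentree import parse_tree
        tree = parse_tree("(A,B);")
        res = combine_tree(tree, [TipResult("A", 0.5), TipResult("B", 0.5)])
        assert res[tree.root].combined_p == pytest.approx(0.5, abs=1e-12)

    def test_opposing_tip_dilutes_root(self):
        from consentree import parse_tree
        tree = parse_tree("((A,B),C);")
        tips = [TipResult("A", 0.01), TipResult("B", 0.01), TipResult("C", 0.99)]
        res = combine_tree(tree, tips)
        ab = next(n for n in res if not tree.is_tip(n) and n != tree.root)
        assert res[ab].combined_p < res[tree.root].combined_p

    def test_missing_tip_reduces_k_and_skips_small_nodes(self):
        from consentree import parse_tree
        tree = parse_tree("((A,B),(C,D));")
        tips = [TipResult("A", 0.01), TipResult("C", 0.2)]
        res = combine_tree(tree, tips)
        internal = [n for n in res if not tree.is_tip(n)]
        # only the root has k >= 2; the two cherries have k = 1 each
        assert internal == [tree.root]
        assert res[tree.root].k == 2

    def test_no_overlap_rejected(self, three_tip_tree):
        with pytest.raises(ValueError, match="no overlap"):
            combine_tree(three_tip_tree, [TipResult("Z", 0.1)])

    @pytest.mark.parametrize("method", ["stouffer", "hartung"])
    def test_compositional_oracle(self, method):
        """Per-node results equal combining each node's member p-values directly."""
        combiner = {"stouffer": stouffer, "hartung": hartung}[method]
        from consentree import branch_table
        for seed in range(20):
            spec = FixtureSpec(n_tips=4 + seed % 8, topology="random", seed=seed)
            tree = make_tree(spec)
            tips = make_pvalues(tree, spec)
            by_tip = {t.tip: t.p1 for t in tips}
            res = combine_tree(tree, tips, method=method)
            for entry in branch_table(tree, set(by_tip)):
                if tree.is_tip(entry.node):
                    assert res[entry.node].combined_p == by_tip[entry.tips[0]]
                else:
                    expect = combiner([by_tip[t] for t in entry.tips]).combined_p
                    assert res[entry.node].combined_p == pytest.approx(
                        expect, abs=1e-12
                    )
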