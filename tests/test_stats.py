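import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from astromorph.stats import (
    bky_fdr,
    describe,
    kruskal_wallis,
    targeted_posthoc,
)


def bky_literal_oracle(pvals, alpha):
    """Independent, literal two-stage step-up: sorted-loop implementation."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])

    def step_up(level):
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i * level / m:
                k = i
        return k

    a1 = alpha / (1 + alpha)
    r1 = step_up(a1)
    if r1 == 0:
        return [False] * m
    if r1 == m:
        return [True] * m
    r2 = step_up(a1 * m / (m - r1))
    reject = [False] * m
    for idx in order[:r2]:
        reject[idx] = True
    return reject


class TestKruskalWallis:
    def test_worked_example_h(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                              method="asymptotic")
        assert h == pytest.approx(7.2)

    def test_all_tied(self):
        h, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert h == 0.0 and p == 1.0

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(25):
            groups = [rng.normal(size=rng.integers(5, 12)) for _ in range(3)]
            h, p = kruskal_wallis(groups, method="asymptotic")
            ref = scipy.stats.kruskal(*groups)
            assert h == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_ties_match_scipy(self):
        groups = [[1, 1, 2, 3], [2, 2, 3], [3, 3, 1]]
        h, p = kruskal_wallis(groups, method="asymptotic")
        ref = scipy.stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)

    def test_exact_two_groups_vs_brute_force(self):
        """Exact p equals exhaustive label-permutation enumeration with the
        scipy statistic as the independent route."""
        a, b = [1.2, 3.4, 5.1, 0.3], [2.2, 6.7, 7.1, 8.0]
        h_obs, p_exact = kruskal_wallis([a, b], method="exact")
        pooled = np.array(a + b)
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(8) if i not in idx]]
            h = scipy.stats.kruskal(ga, gb).statistic
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
        assert p_exact == pytest.approx(count / total)

    def test_exact_three_groups_vs_brute_force(self):
        groups = [[3.0, 1.0, 4.0], [1.5, 5.0], [9.0, 2.6, 5.3]]
        h_obs, p_exact = kruskal_wallis(groups, method="exact")
        pooled = np.concatenate(groups)
        count = total = 0
        for idx_a in itertools.combinations(range(8), 3):
            rest = [i for i in range(8) if i not in idx_a]
            for idx_b in itertools.combinations(rest, 2):
                idx_c = [i for i in rest if i not in idx_b]
                h = scipy.stats.kruskal(pooled[list(idx_a)], pooled[list(idx_b)],
                                        pooled[idx_c]).statistic
                total += 1
                if h >= h_obs - 1e-12:
                    count += 1
        assert p_exact == pytest.approx(count / total)

    def test_auto_uses_exact_at_small_n(self):
        _, p_auto = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        _, p_exact = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                                    method="exact")
        assert p_auto == p_exact

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=8).tolist() for _ in range(3)]
        h1, p1 = kruskal_wallis(groups, method="asymptotic")
        transformed = [[np.exp(v) for v in g] for g in groups]
        h2, p2 = kruskal_wallis(transformed, method="asymptotic")
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])
        with pytest.raises(ValueError):
            kruskal_wallis([[1], [2]])


class TestBkyFdr:
    def test_all_large_p_no_rejections(self):
        reject, _ = bky_fdr([0.9] * 6, alpha=0.05)
        assert not reject.any()

    def test_all_tiny_p_all_rejected(self):
        reject, adjusted = bky_fdr([0.0001] * 5, alpha=0.05)
        assert reject.all()
        assert (adjusted <= 0.05).all()

    def test_empty_input(self):
        reject, adjusted = bky_fdr([])
        assert reject.size == 0 and adjusted.size == 0

    def test_decisions_match_literal_oracle(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 21))
            p = rng.uniform(size=m)
            if rng.random() < 0.5:  # mix in some genuine signals
                k = int(rng.integers(0, m + 1))
                p[:k] = rng.uniform(0, 0.01, size=k)
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            reject, _ = bky_fdr(p, alpha=alpha)
            assert reject.tolist() == bky_literal_oracle(p, alpha)

    def test_adjusted_reproduces_decisions(self, rng):
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 15)))
            reject, adjusted = bky_fdr(p, alpha=0.05)
            assert ((adjusted <= 0.05) == reject).all()

    def test_monotonicity(self, rng):
        """Decreasing any single p-value never loses a rejection."""
        for _ in range(150):
            m = int(rng.integers(2, 15))
            p = rng.uniform(size=m)
            reject, _ = bky_fdr(p, alpha=0.05)
            i = int(rng.integers(m))
            p2 = p.copy()
            p2[i] /= 2
            reject2, _ = bky_fdr(p2, alpha=0.05)
            assert not (reject & ~reject2).any()  # old rejections survive

    def test_rejects_superset_of_bh_with_signal(self, rng):
        """Adaptive two-stage is at least as powerful as plain BH whenever
        some nulls are false."""
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            m = int(rng.integers(4, 16))
            p = np.concatenate([rng.uniform(0, 0.004, size=m // 2),
                                rng.uniform(size=m - m // 2)])
            rng.shuffle(p)
            reject, _ = bky_fdr(p, alpha=0.05)
            bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert (reject | ~bh).all()  # bh => reject

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bky_fdr([1.5])
        with pytest.raises(ValueError):
            bky_fdr([0.5], alpha=0)


class TestTargetedPosthoc:
    def test_reference_is_closest_to_global_median(self):
        samples = {1: [9, 10, 11], 2: [32, 33, 34], 3: [59, 60, 61]}
        comp = targeted_posthoc("x", samples, alpha=0.05)
        assert comp.reference == "2"
        assert len(comp.posthoc) == 2
        assert {tuple(e["pair"])[0] for e in comp.posthoc} == {1, 3}

    def test_tie_goes_to_lower_profile_id(self):
        samples = {1: [10.0], 2: [30.0], 3: [20.0]}  # global median 20 -> ref 3
        comp = targeted_posthoc("x", samples)
        assert comp.reference == "3"
        samples = {1: [10.0, 10.0], 4: [20.0, 20.0]}  # equidistant from 15
        comp = targeted_posthoc("x", samples)
        assert comp.reference == "1"
        assert comp.reference_tie

    def test_identical_samples_never_rejected(self):
        samples = {p: [5.0, 5.0, 5.0] for p in range(1, 5)}
        comp = targeted_posthoc("x", samples, alpha=0.5)
        assert comp.H == 0.0 and comp.p == 1.0
        assert all(not e["reject"] for e in comp.posthoc)

    def test_detects_shifted_profile(self, rng):
        samples = {1: rng.normal(0, 1, 12).tolist(),
                   2: rng.normal(0, 1, 12).tolist(),
                   3: rng.normal(8, 1, 12).tolist()}
        comp = targeted_posthoc("x", samples, alpha=0.05)
        shifted = [e for e in comp.posthoc if e["pair"][0] == 3]
        assert shifted and shifted[0]["reject"]

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            targeted_posthoc("x", {1: [1.0, 2.0]})


class TestDescribe:
    def test_nine_values(self):
        med, iqr = describe(range(1, 10))
        assert med == 5.0
        assert iqr == (3.0, 7.0)

    def test_single_value(self):
        med, iqr = describe([4.2])
        assert med == 4.2 and iqr == (4.2, 4.2)

    def test_plausibility_fixture(self):
        med, _ = describe([22.86, 33.0, 36.78])
        assert med == 33.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            describe([])


class TestNullCalibration:
    def test_kw_type_i_error_rate(self):
        """Rejection rate under the null within [0.035, 0.065] at alpha=0.05
        (3 groups of 10, 2000 replicates)."""
        rng = np.random.default_rng(20240901)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            groups = rng.normal(size=(3, 10))
            _, p = kruskal_wallis(groups, method="asymptotic")
            if p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065
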