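"""Fisher information, CRLB precision, and waveform-combination ranking."""

from itertools import combinations

import numpy as np
import pytest

import ogsekit as ok
from ogsekit.crlb import _jacobian, compute_crlb, rank_combinations
from ogsekit.karger import PARAM_NAMES


def richardson_jacobian(operator, theta, free_idx, h0=1e-3):
    """Higher-order differentiation oracle: Richardson-extrapolated central
    differences, O(h^4)."""
    cols = []
    for i in free_idx:
        h = h0 * max(abs(theta[i]), 1e-8)

        def d(step):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += step
            tm[i] -= step
            return (operator.predict(tp) - operator.predict(tm)) / (2 * step)

        cols.append((4 * d(h / 2) - d(h)) / 3)
    return np.stack(cols, axis=1)


class TestCRLB:
    def test_doubling_sigma_doubles_every_cv(self, operator, gm_median):
        r1 = compute_crlb(operator, gm_median, sigma=0.02)
        r2 = compute_crlb(operator, gm_median, sigma=0.04)
        assert r2.cv == pytest.approx(2 * r1.cv, rel=1e-12)

    def test_fisher_symmetric_positive_semidefinite(self, operator, wm_median):
        rep = compute_crlb(operator, wm_median)
        assert rep.fisher == pytest.approx(rep.fisher.T)
        assert np.all(np.linalg.eigvalsh(rep.fisher) >= -1e-6 * np.abs(rep.fisher).max())

    def test_jacobian_matches_higher_order_oracle(self, operator, gm_median):
        theta = gm_median.as_array()
        free_idx = [PARAM_NAMES.index(n) for n in ("t_ex", "f_ic", "alpha_d", "alpha_c")]
        j_fd = _jacobian(operator, theta, free_idx)
        j_hi = richardson_jacobian(operator, theta, free_idx)
        scale = np.abs(j_hi).max(axis=0)
        assert np.all(np.abs(j_fd - j_hi) / scale < 1e-4)

    def test_too_few_waveforms_raise(self, protocol, gm_median):
        sub = protocol.subset(["30Hz-N1", "40Hz-N1", "50Hz-N1"])
        with pytest.raises(ValueError, match="cannot bound"):
            compute_crlb(sub, gm_median)

    def test_singular_fisher_names_collinear_pair(self, protocol, gm_median):
        """Four copies of the same waveform carry rank-one information."""
        sub = ok.Protocol(spectra=tuple([protocol["30Hz-N1"]] * 4), b_target=2.0)
        with pytest.raises(ValueError, match="collinear"):
            compute_crlb(sub, gm_median)


@pytest.fixture(scope="module")
def truths(gm_median, wm_median):
    rng = np.random.default_rng(42)
    out = []
    for base in (wm_median, gm_median):
        arr = base.as_array()
        for _ in range(4):
            t = np.clip(
                arr * (1 + 0.1 * rng.standard_normal(5)),
                [1, 0.01, 1, 0.01, 0.01],
                [200, 0.99, 10, 20, 1],
            )
            out.append(ok.TissueParams.from_array(t))
    return out


@pytest.fixture(scope="module")
def ranking(protocol, truths):
    return rank_combinations(protocol, truths, k=4, sigma=0.02)


class TestRanking:
    def test_all_subsets_enumerated(self, ranking):
        assert len(ranking.combinations) == 15  # C(6, 4)

    def test_full_protocol_never_worse_than_any_subset(self, protocol, truths):
        """Information monotonicity: the six-waveform cv lower-bounds every
        four-waveform subset for every parameter and ROI."""
        full_op = ok.ForwardOperator(protocol)
        for truth in truths[:4]:
            full = compute_crlb(full_op, truth, sigma=0.02).cv
            for c in combinations(protocol.labels, 4):
                sub = compute_crlb(protocol.subset(list(c)), truth, sigma=0.02).cv
                assert np.all(full <= sub * (1 + 1e-9))

    def test_ranking_invariant_to_sigma(self, protocol, truths, ranking):
        other = rank_combinations(protocol, truths, k=4, sigma=0.1)
        assert other.scores == ranking.scores

    def test_scores_bounded_per_roi(self, ranking, truths):
        max_total = len(truths) * sum(range(1, 11))  # 55 points per ROI
        for param, sc in ranking.scores.items():
            assert all(v >= 0 for v in sc.values())
            assert sum(sc.values()) <= max_total

    def test_single_roi_ranking_matches_independent_sort(self, protocol, gm_median):
        rk = rank_combinations(protocol, [gm_median], k=4, sigma=0.02)
        cv = rk.cv_table
        for param in rk.free_params:
            sub = cv[cv.parameter == param].sort_values(["cv", "combination"])
            expected_best = tuple(sub.iloc[0]["combination"])
            assert rk.best(param) == expected_best

    def test_exchange_time_favours_single_oscillation_waveforms(self, ranking):
        """Score-weighted count of N=1 waveforms is at least as high for the
        exchange time as for the neurite fraction (the short-time regime
        carries the exchange information)."""

        def weighted_n1(param):
            sc = ranking.scores[param]
            total = sum(sc.values())
            return sum(
                s * sum(1 for lab in c if lab.endswith("N1")) for c, s in sc.items()
            ) / total

        assert weighted_n1("t_ex") >= weighted_n1("f_ic")

    def test_subset_size_below_parameter_count_raises(self, protocol, gm_median):
        with pytest.raises(ValueError, match="degenerate"):
            rank_combinations(protocol, [gm_median], k=3)
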