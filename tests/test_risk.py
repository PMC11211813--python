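import math

import numpy as np
import pytest

from oracles import (
    bce_loop,
    multilabel_risk_loop,
    ranking_risk_loop,
    risk_components_loop,
)

from pufun.ontology import PriorVector
from pufun.risk import (
    RiskConfig,
    bce_loss,
    nnpu_class_risk,
    pugo_loss,
    ranking_unlabeled_risk,
    risk_components,
)

LN2 = math.log(2.0)


def random_batch(rng, n=12, k=5, p=0.4):
    logits = rng.normal(0, 2, size=(n, k))
    labels = (rng.random((n, k)) < p).astype(np.int8)
    return logits, labels


class TestRiskComponents:
    def test_zero_logits_give_ln2_everywhere(self):
        labels = np.array([1, 1, 0, 0, 0])
        rpp, rpm, rum = risk_components(np.zeros(5), labels)
        for v in (rpp, rpm, rum):
            assert v == pytest.approx(LN2, abs=1e-12)

    def test_saturated_logits(self):
        logits = np.array([20.0, 20.0, -20.0, -20.0])
        labels = np.array([1, 1, 0, 0])
        rpp, rpm, rum = risk_components(logits, labels)
        assert rpp == pytest.approx(0.0, abs=1e-8)
        assert rum == pytest.approx(0.0, abs=1e-8)
        assert rpm == pytest.approx(20.0, abs=1e-8)

    def test_empty_sides_return_skip_sentinel(self):
        rpp, rpm, rum = risk_components(np.zeros(3), np.ones(3))
        assert rum is None and rpp is not None
        rpp2, _, rum2 = risk_components(np.zeros(3), np.zeros(3))
        assert rpp2 is None and rum2 is not None

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            logits = rng.normal(0, 3, size=15)
            labels = rng.random(15) < 0.5
            if labels.all() or not labels.any():
                continue
            got = risk_components(logits, labels)
            want = risk_components_loop(list(logits), list(labels))
            for g, w in zip(got, want):
                assert g == pytest.approx(w, abs=1e-10)


class TestRankingRisk:
    def test_equal_logits_give_ln2(self):
        labels = np.array([1, 0, 0, 1, 0])
        assert ranking_unlabeled_risk(np.full(5, 3.7), labels) == pytest.approx(LN2, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(0, 2, 9)
        labels = rng.random(9) < 0.4
        labels[0], labels[1] = True, False
        base = ranking_unlabeled_risk(logits, labels)
        shifted = ranking_unlabeled_risk(logits + 7.0, labels)
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_sigmoid_unlabeled_risk_not_translation_invariant(self):
        logits = np.array([1.0, -1.0, 0.5, -0.5])
        labels = np.array([1, 0, 1, 0])
        _, _, base = risk_components(logits, labels)
        _, _, shifted = risk_components(logits + 7.0, labels)
        assert abs(base - shifted) > 0.1

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(0, 2, 7)
        labels = np.array([1, 1, 1, 0, 0, 0, 0])
        got = ranking_unlabeled_risk(logits, labels)
        assert got == pytest.approx(ranking_risk_loop(list(logits), list(labels)), abs=1e-10)

    def test_decreasing_unlabeled_logit_never_increases_risk(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(0, 1, 8)
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        base = ranking_unlabeled_risk(logits, labels)
        for j in range(2, 8):
            lowered = logits.copy()
            lowered[j] -= 1.5
            assert ranking_unlabeled_risk(lowered, labels) <= base + 1e-12


class TestNnpuClassRisk:
    def test_worked_sigmoid_value(self):
        # zero logits, pi=0.2, beta=0: 0.2*ln2 + max(0, ln2 - 0.2*ln2) = ln2
        v, clamped = nnpu_class_risk(LN2, LN2, LN2, pi=0.2, beta=0.0)
        assert v == pytest.approx(0.693147, abs=1e-6)
        assert not clamped

    def test_worked_ranking_value_with_margin(self):
        # zero logits, pi=0.2, gamma=0.1 -> beta=0.02, ranking RU- = ln2:
        # 0.2*ln2 + max(0, ln2 - 0.2*ln2 + 0.02) = ln2 + 0.02
        v, _ = nnpu_class_risk(LN2, LN2, LN2, pi=0.2, beta=0.02)
        assert v == pytest.approx(0.713147, abs=1e-6)

    def test_clamp_engages_on_separated_logits(self):
        logits = np.concatenate([np.full(3, 20.0), np.full(5, -20.0)])
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        rpp, rpm, rum = risk_components(logits, labels)
        v, clamped = nnpu_class_risk(rpp, rpm, rum, pi=0.3, beta=0.0)
        assert clamped
        assert v == pytest.approx(0.3 * rpp, abs=1e-12)
        assert v >= 0.0

    def test_clamp_off_reproduces_upu(self):
        rpp, rpm, rum = 0.5, 1.2, 0.4
        v, _ = nnpu_class_risk(rpp, rpm, rum, pi=0.3, beta=0.02, clamp=False)
        assert v == pytest.approx(0.3 * 0.5 - 0.3 * 1.2 + 0.4)

    def test_invalid_pi_or_beta_rejected(self):
        with pytest.raises(ValueError):
            nnpu_class_risk(1, 1, 1, pi=1.5, beta=0.0)
        with pytest.raises(ValueError):
            nnpu_class_risk(1, 1, 1, pi=0.2, beta=0.3)


class TestPugoLoss:
    def test_additivity_on_zero_logits(self):
        logits = np.zeros((6, 2))
        labels = np.array([[1, 1], [1, 1], [0, 0], [0, 0], [0, 0], [0, 0]])
        cfg = RiskConfig(variant="pu_basic", pi_o=0.2, gamma=0.0)
        report = pugo_loss(logits, labels, None, cfg)
        assert report.total == pytest.approx(2 * LN2, abs=1e-10)

    def test_all_positive_class_skipped_and_flagged(self):
        logits = np.zeros((4, 2))
        labels = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
        cfg = RiskConfig(variant="pu_basic", pi_o=0.2, gamma=0.0)
        report = pugo_loss(logits, labels, None, cfg)
        assert report.n_skipped == 1
        assert report.per_class[0].skipped

    def test_fully_degenerate_batch_raises(self):
        cfg = RiskConfig(variant="pu_basic", pi_o=0.2)
        with pytest.raises(ValueError):
            pugo_loss(np.zeros((3, 2)), np.ones((3, 2)), None, cfg)

    @pytest.mark.parametrize("variant", ["pu_basic", "pu_ranking", "pu_go"])
    def test_matches_per_class_oracle(self, variant):
        rng = np.random.default_rng(4)
        logits, labels = random_batch(rng, n=8, k=5)
        pi_o, gamma = 0.3, 0.1
        priors = PriorVector(pi_o * np.linspace(0.4, 1.0, 5), pi_o=pi_o, gamma=gamma)
        cfg = RiskConfig(variant=variant, pi_o=pi_o, gamma=gamma)
        report = pugo_loss(logits, labels, priors, cfg)
        if variant == "pu_go":
            pi, beta = priors.pi, priors.beta
        else:
            pi = np.full(5, pi_o)
            beta = gamma * pi
        want, contributing = multilabel_risk_loop(
            logits, labels, pi, beta, ranking=cfg.uses_ranking
        )
        assert report.total == pytest.approx(want, abs=1e-8)
        assert report.n_contributing == contributing

    @pytest.mark.parametrize("variant", ["pu_basic", "pu_ranking", "pu_go", "pn_bce"])
    def test_gradient_matches_finite_difference(self, variant):
        rng = np.random.default_rng(5)
        logits, labels = random_batch(rng, n=8, k=4)
        priors = PriorVector(0.3 * np.linspace(0.5, 1.0, 4), pi_o=0.3, gamma=0.1)
        cfg = RiskConfig(variant=variant, pi_o=0.3, gamma=0.1)
        report, grad = pugo_loss(logits, labels, priors, cfg, with_grad=True)
        eps = 1e-6
        num = np.zeros_like(grad)
        for i in range(logits.shape[0]):
            for j in range(logits.shape[1]):
                up, down = logits.copy(), logits.copy()
                up[i, j] += eps
                down[i, j] -= eps
                num[i, j] = (
                    pugo_loss(up, labels, priors, cfg).total
                    - pugo_loss(down, labels, priors, cfg).total
                ) / (2 * eps)
        assert np.abs(num - grad).max() < 1e-4

    def test_clamped_risk_non_negative_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for variant in ("pu_basic", "pu_ranking", "pu_go"):
            cfg = RiskConfig(variant=variant, pi_o=0.4, gamma=0.2)
            priors = PriorVector(0.4 * np.linspace(0.2, 1.0, 6), pi_o=0.4, gamma=0.2)
            for _ in range(30):
                logits, labels = random_batch(rng, n=10, k=6, p=0.35)
                try:
                    report = pugo_loss(logits, labels, priors, cfg)
                except ValueError:
                    continue
                assert report.total >= 0.0
                for c in report.per_class:
                    if not c.skipped:
                        assert c.risk >= 0.0


class TestBceLoss:
    def test_zero_logits_give_ln2(self):
        assert bce_loss(np.zeros((3, 4)), np.zeros((3, 4))) == pytest.approx(LN2)

    def test_perfect_saturated_logits_near_zero(self):
        labels = np.array([[1, 0], [0, 1]])
        logits = np.where(labels, 20.0, -20.0)
        assert bce_loss(logits, labels) == pytest.approx(0.0, abs=1e-8)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(7)
        logits, labels = random_batch(rng, n=6, k=3)
        assert bce_loss(logits, labels) == pytest.approx(
            bce_loop(logits, labels), abs=1e-10
        )


class TestUpuUnbiasedness:
    def test_mean_difference_matches_true_negative_risk(self):
        """uPU identity: E[RU- - pi* RP-] = (1-pi*) RN- under SCAR sampling.

        A fixed finite population with known true labels and a fixed random
        linear scorer; each resample redraws the sample and the SCAR mask.
        """
        rng = np.random.default_rng(11)
        n_pop, d = 4000, 10
        X = rng.standard_normal((n_pop, d))
        w_true = rng.standard_normal(d)
        y = (X @ w_true + 0.3 * rng.standard_normal(n_pop)) > 0.4
        pi_star = y.mean()
        w_g = rng.standard_normal(d)  # fixed arbitrary classifier
        c = 0.35
        diffs = []
        for _ in range(200):
            # unlabeled block: a marginal draw; positive block: SCAR-observed
            # positives from an independent draw of the same size
            u_idx = rng.integers(0, n_pop, size=500)
            p_pool = rng.integers(0, n_pop, size=500)
            observed = p_pool[y[p_pool] & (rng.random(500) < c)]
            if observed.size == 0:
                continue
            logits = np.concatenate([X[observed] @ w_g, X[u_idx] @ w_g])
            labels = np.concatenate([np.ones(observed.size), np.zeros(500)])
            _, rp_minus, ru = risk_components(logits, labels)
            rn = np.logaddexp(0, X[u_idx][~y[u_idx]] @ w_g).mean()  # hidden negatives
            diffs.append((ru - pi_star * rp_minus) - (1 - pi_star) * rn)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se
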