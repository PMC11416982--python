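"""Connection saliency, top-q masks, aggregation, and the mask protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsefl import (
    ParamVector,
    SaliencyScores,
    aggregate_scores,
    build_model,
    connection_saliency,
    flatten,
    iterative_mask,
    keep_count,
    make_prune_schedule,
    set_model_params,
    topq_mask,
)
from sparsefl.model_core import layout_of
from sparsefl.nn import Dense, Sequential
from sparsefl.saliency import PruneSchedule, global_mask_protocol
from sparsefl.synthetic import make_tabular


def _single_weight_model(w):
    """Linear model with one 1x2 weight matrix; class-0 logit is w*x."""
    rng = np.random.default_rng(0)
    model = Sequential([Dense(1, 2, rng)], (1,))
    model.layers[0].params["W"] = np.array([[w, 0.0]])
    model.layers[0].params["b"] = np.zeros(2)
    return model


class TestConnectionSaliency:
    def test_score_is_param_times_gradient(self, tiny_model, tiny_batch):
        X, y = tiny_batch
        pv = flatten(tiny_model)
        scores = connection_saliency(tiny_model, pv, [(X, y)])
        # independent recomputation: |theta_i * g_i| on prunable positions
        from sparsefl.model_core import flat_gradients

        set_model_params(tiny_model, pv)
        tiny_model.loss_and_backward(X, y)
        g = flat_gradients(tiny_model, pv.layout)
        pm = pv.layout.prunable_mask
        assert np.array_equal(scores.values, np.abs(pv.values[pm] * g[pm]))
        assert (scores.values >= 0).all()
        assert scores.n_samples_used == len(X)

    def test_zero_parameter_gives_zero_score(self, tiny_model, tiny_batch):
        X, y = tiny_batch
        pv = flatten(tiny_model)
        pv.values[0] = 0.0
        scores = connection_saliency(tiny_model, pv, [(X, y)])
        assert scores.values[0] == 0.0

    def test_matches_finite_difference_sensitivity(self):
        # d L(theta . c) / d c_i at c=1 equals theta_i * g_i; check |.| against
        # a per-coordinate central difference on a <=500-parameter model
        model = build_model("tiny-mlp", 8, 2, seed=7, hidden=8)
        pv = flatten(model)
        X, y = make_tabular(16, 8, seed=11)
        scores = connection_saliency(model, pv, [(X, y)])
        layout = pv.layout
        pidx = np.flatnonzero(layout.prunable_mask)
        eps = 1e-5
        fd = np.empty(pidx.size)
        for j, i in enumerate(pidx):
            for sign, out in ((1, "lp"), (-1, "lm")):
                v = pv.values.copy()
                v[i] *= 1 + sign * eps  # c_i = 1 +/- eps scales theta_i
                set_model_params(model, ParamVector(v, layout))
                loss = model.loss_and_backward(X, y)
                if sign == 1:
                    lp = loss
                else:
                    lm = loss
            fd[j] = (lp - lm) / (2 * eps)
        rel = np.abs(np.abs(fd) - scores.values) / np.maximum(scores.values, 1e-6)
        assert np.max(rel) < 1e-3

    def test_closed_form_single_weight(self):
        # L = mean CE of 2-logit model on x=1, y=1 (other logit fixed 0):
        # score for w=2: |w * dL/dw| with dL/dw = (softmax_0 - 0) * x
        model = _single_weight_model(2.0)
        pv = flatten(model)
        X = np.array([[1.0]])
        y = np.array([1])
        scores = connection_saliency(model, pv, [(X, y)])
        p0 = np.exp(2.0) / (np.exp(2.0) + 1.0)
        assert scores.values[0] == pytest.approx(2.0 * p0, rel=1e-12)

    def test_multi_batch_accumulation_is_sum(self, tiny_model, tiny_batch):
        X, y = tiny_batch
        pv = flatten(tiny_model)
        both = connection_saliency(tiny_model, pv, [(X[:8], y[:8]), (X[8:], y[8:])])
        from sparsefl.model_core import flat_gradients

        g = np.zeros(pv.layout.size)
        for Xb, yb in [(X[:8], y[:8]), (X[8:], y[8:])]:
            set_model_params(tiny_model, pv)
            tiny_model.loss_and_backward(Xb, yb)
            g += flat_gradients(tiny_model, pv.layout)
        pm = pv.layout.prunable_mask
        assert np.allclose(both.values, np.abs(pv.values[pm] * g[pm]), rtol=1e-12)

    def test_empty_batch_set_rejected(self, tiny_model, tiny_params):
        with pytest.raises(ValueError, match="at least one batch"):
            connection_saliency(tiny_model, tiny_params, [])

    def test_scale_property(self, tiny_model, tiny_batch):
        # multiplying the loss by a constant scales scores, not the mask
        X, y = tiny_batch
        pv = flatten(tiny_model)
        s1 = connection_saliency(tiny_model, pv, [(X, y)])
        s3 = SaliencyScores(3.0 * s1.values)
        layout = pv.layout
        m1 = topq_mask(s1, 0.8, layout)
        m3 = topq_mask(s3, 0.8, layout)
        assert np.array_equal(m1.bits, m3.bits)


class TestTopQMask:
    def test_simple_sort(self, tiny_params):
        layout = tiny_params.layout
        n_p = layout.n_prunable
        scores = np.zeros(n_p)
        scores[:5] = [5, 1, 4, 2, 3]
        # keep 2 of 5 nonzero: positions 0 and 2
        sparsity = 1 - 2 / n_p
        m = topq_mask(scores, sparsity, layout)
        bits_p = m.bits[layout.prunable_mask]
        assert list(bits_p[:5]) == [1, 0, 1, 0, 0]
        assert bits_p.sum() == 2

    def test_sparsity_zero_is_dense(self, tiny_params, rng):
        layout = tiny_params.layout
        m = topq_mask(rng.random(layout.n_prunable), 0.0, layout)
        assert m.bits.all()

    def test_tie_break_lowest_index(self, tiny_params):
        layout = tiny_params.layout
        n_p = layout.n_prunable
        scores = np.zeros(n_p)
        scores[:3] = [1, 4, 4]
        m = topq_mask(scores, 1 - 1 / n_p, layout)
        bits_p = m.bits[layout.prunable_mask]
        assert list(bits_p[:3]) == [0, 1, 0]
        # exhaustive check against all 1-subsets: index 1 is the unique
        # lexicographically-first maximiser of the score sum
        best = max(range(n_p), key=lambda i: (scores[i], -i))
        assert bits_p[best] == 1

    def test_sparsity_one_rejected(self, tiny_params, rng):
        with pytest.raises(ValueError):
            topq_mask(rng.random(tiny_params.layout.n_prunable), 1.0, tiny_params.layout)

    @given(st.integers(min_value=1, max_value=400), st.integers(min_value=0, max_value=6))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_brute_force_sort(self, n_scores, seed):
        """top-q mask equals the brute-force full-sort selection, exactly."""
        model = build_model("tiny-mlp", 8, 2, seed=0, hidden=8)
        layout = layout_of(model)
        n_p = layout.n_prunable
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n_p), 2)  # rounding forces ties
        sparsity = rng.uniform(0, 0.99)
        m = topq_mask(scores, sparsity, layout)
        k = keep_count(sparsity, n_p)
        order = sorted(range(n_p), key=lambda i: (-scores[i], i))
        brute = np.zeros(n_p, dtype=np.uint8)
        brute[order[:k]] = 1
        assert np.array_equal(m.bits[layout.prunable_mask], brute)

    def test_permutation_equivariance(self, tiny_params, rng):
        layout = tiny_params.layout
        n_p = layout.n_prunable
        scores = rng.random(n_p)
        perm = rng.permutation(n_p)
        m = topq_mask(scores, 0.7, layout)
        mp = topq_mask(scores[perm], 0.7, layout)
        # ties are absent w.p. 1, so the permuted mask is the permuted bits
        assert np.array_equal(
            mp.bits[layout.prunable_mask], m.bits[layout.prunable_mask][perm]
        )


class TestAggregation:
    def test_unweighted_sum(self):
        a = SaliencyScores(np.array([1.0, 0.0, 3.0]))
        b = SaliencyScores(np.array([0.0, 4.0, 1.0]))
        assert np.array_equal(aggregate_scores([a, b]), [1.0, 4.0, 4.0])

    def test_single_client_identity(self):
        a = SaliencyScores(np.array([2.0, 5.0]))
        assert np.array_equal(aggregate_scores([a]), a.values)

    def test_weighted_mean(self):
        a = SaliencyScores(np.array([2.0, 0.0]))
        b = SaliencyScores(np.array([0.0, 4.0]))
        out = aggregate_scores([a, b], weights=[1, 3])
        assert np.allclose(out, [0.5, 3.0])

    def test_commutative_in_client_order(self, rng):
        ss = [SaliencyScores(rng.random(10)) for _ in range(4)]
        assert np.allclose(aggregate_scores(ss), aggregate_scores(ss[::-1]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            aggregate_scores([SaliencyScores(np.ones(3)), SaliencyScores(np.ones(4))])


class TestIterativeMask:
    def test_one_step_recovers_single_shot(self, tiny_model, tiny_batch):
        X, y = tiny_batch
        pv = flatten(tiny_model)
        layout = pv.layout
        sparsity = 0.9
        k = keep_count(sparsity, layout.n_prunable)
        snip = topq_mask(connection_saliency(tiny_model, pv, [(X, y)]), sparsity, layout)
        iter1 = iterative_mask(tiny_model, pv, [(X, y)], sparsity, PruneSchedule((k,)))
        assert np.array_equal(snip.bits, iter1.bits)

    def test_scheduled_popcounts_exact_and_nested(self, tiny_model, tiny_batch):
        X, y = tiny_batch
        pv = flatten(tiny_model)
        layout = pv.layout
        n_p = layout.n_prunable
        sparsity = 0.9
        k = keep_count(sparsity, n_p)
        schedule = make_prune_schedule(n_p, k, 4)
        # re-run the loop step by step to check the per-step contract
        prev_support = set(np.flatnonzero(layout.prunable_mask))
        supports = []
        bits_prev = None
        for t in range(1, len(schedule.steps) + 1):
            sub = PruneSchedule(schedule.steps[:t], schedule.kind)
            m = iterative_mask(tiny_model, pv, [(X, y)], 1 - sub.steps[-1] / n_p, sub)
            bits_p = m.bits[layout.prunable_mask]
            assert bits_p.sum() == schedule.steps[t - 1]
            if bits_prev is not None:
                assert np.all(bits_p <= bits_prev)  # supp(c_{t+1}) subset supp(c_t)
            bits_prev = bits_p
        final = iterative_mask(tiny_model, pv, [(X, y)], sparsity, schedule)
        assert final.bits[layout.prunable_mask].sum() == k

    def test_non_decreasing_schedule_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            PruneSchedule((10, 10, 5))

    def test_schedule_generator_ends_at_target(self):
        s = make_prune_schedule(1000, 10, 5, "exponential")
        assert s.steps[-1] == 10
        assert all(a > b for a, b in zip(s.steps, s.steps[1:]))
        lin = make_prune_schedule(1000, 10, 5, "linear")
        assert lin.steps[-1] == 10


class TestGlobalMaskProtocol:
    def _clients(self, n_clients, per_class=False, seed=0):
        model = build_model("tiny-mlp", 8, 2, seed=seed, hidden=8)
        pv = flatten(model)
        clients = []
        for c in range(n_clients):
            X, y = make_tabular(12, 8, separation=3.0, seed=100 + c)
            if per_class:  # disjoint single-class data
                keep = y == (c % 2)
                X, y = X[keep], y[keep]
            clients.append((model, [(X, y)]))
        return model, pv, clients

    @pytest.mark.parametrize("mode", ["sum", "weighted", "random"])
    def test_shared_modes_identical_masks(self, mode):
        _, pv, clients = self._clients(3)
        masks = global_mask_protocol(clients, pv, 0.8, mode=mode, seed=5)
        assert len(masks) == 3
        for m in masks[1:]:
            assert np.array_equal(m.bits, masks[0].bits)

    def test_individual_masks_differ_on_disjoint_data(self):
        _, pv, clients = self._clients(2, per_class=True)
        masks = global_mask_protocol(clients, pv, 0.9, mode="individual")
        assert np.any(masks[0].bits != masks[1].bits)

    def test_random_mode_reproducible_with_popcount(self, tiny_params):
        model = build_model("tiny-mlp", 8, 2, seed=7, hidden=8)
        pv = flatten(model)
        clients = [(model, [])] * 2  # random mode never touches data
        m1 = global_mask_protocol(clients, pv, 0.75, mode="random", seed=3)
        m2 = global_mask_protocol(clients, pv, 0.75, mode="random", seed=3)
        assert np.array_equal(m1[0].bits, m2[0].bits)
        layout = pv.layout
        assert m1[0].bits[layout.prunable_mask].sum() == keep_count(0.75, layout.n_prunable)

    def test_heterogeneous_layouts_rejected(self):
        m1 = build_model("tiny-mlp", 8, 2, seed=0, hidden=8)
        m2 = build_model("tiny-mlp", 8, 2, seed=0, hidden=4)
        pv = flatten(m1)
        X, y = make_tabular(8, 8, seed=0)
        with pytest.raises(ValueError, match="heterogeneous"):
            global_mask_protocol([(m1, [(X, y)]), (m2, [(X, y)])], pv, 0.5)

    def test_one_time_costs_logged_exactly_once(self):
        from sparsefl.comms import TrafficLedger

        _, pv, clients = self._clients(3)
        ledger = TrafficLedger()
        global_mask_protocol(clients, pv, 0.8, mode="sum", ledger=ledger)
        kinds = [e.kind for e in ledger.entries]
        assert kinds.count("mask") == 1
        assert kinds.count("scores") == 1
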