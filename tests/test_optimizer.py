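"""Cut/merge heuristics: normalized cut, candidate rules, the full loop."""

import itertools

import numpy as np
import pytest
from scipy import sparse

from sensopt.macrostates import MacrostateConfig, macro_transitions, random_config
from sensopt.microstates import TransitionModel
from sensopt.objective import ObjectiveParams, evaluate
from sensopt.optimizer import (
    OptimizerSettings,
    _spectral_bipartition,
    build_candidates,
    cut_state,
    merge_states,
    optimize,
    projection_similarity,
    step,
)

from conftest import random_model


def brute_force_ncut(W: np.ndarray):
    """Exhaustive minimum-Ncut bipartition over all 2^(m-1) splits."""
    m = W.shape[0]
    d = W.sum(axis=1)
    best_val, best_mask = np.inf, None
    for bits in itertools.product([0, 1], repeat=m - 1):
        mask = np.array((1,) + bits, dtype=bool)
        if mask.all() or not mask.any():
            continue
        cut = W[np.ix_(mask, ~mask)].sum()
        a1, a2 = d[mask].sum(), d[~mask].sum()
        if a1 == 0 or a2 == 0:
            continue
        val = cut / a1 + cut / a2
        if val < best_val:
            best_val, best_mask = val, mask
    return best_val, best_mask


def block_cyclic_model(n_blocks: int = 4, block: int = 3) -> TransitionModel:
    """Deterministic block-cyclic tensor: block i maps onto block i+1."""
    M = n_blocks * block
    mats = []
    for k in range(2):
        dense = np.zeros((M, M))
        shift = 1 if k == 0 else n_blocks - 1
        for b in range(n_blocks):
            src = slice(b * block, (b + 1) * block)
            tgt = ((b + shift) % n_blocks) * block
            dense[src, tgt : tgt + block] = 1.0 / block
        mats.append(sparse.csr_matrix(dense))
    return TransitionModel(tm=mats, visit_counts=np.full((M, 2), 9))


class TestNormalizedCut:
    def test_two_blocks_recovered_exactly(self):
        # block-structured similarity: exact cluster recovery
        W = np.ones((6, 6)) * 0.01
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        mask = _spectral_bipartition(W)
        group = set(np.flatnonzero(mask))
        assert group in ({0, 1, 2}, {3, 4, 5})

    @pytest.mark.parametrize("m,seed", [(6, 0), (8, 1), (10, 2)])
    def test_matches_exhaustive_search(self, m, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((m, m))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        mask = _spectral_bipartition(W)
        d = W.sum(axis=1)
        cut = W[np.ix_(mask, ~mask)].sum()
        got = cut / d[mask].sum() + cut / d[~mask].sum()
        want, _ = brute_force_ncut(W)
        # the spectral relaxation with full split scan matches the
        # exhaustive optimum on these small dense graphs
        assert got == pytest.approx(want, rel=1e-9)

    def test_disconnected_graph_splits_components(self):
        W = np.zeros((5, 5))
        W[:2, :2] = 1.0
        W[2:, 2:] = 1.0
        mask = _spectral_bipartition(W)
        assert set(np.flatnonzero(mask)) in ({0, 1}, {2, 3, 4})


class TestProjectionSimilarity:
    def test_self_similarity_is_one(self, rng):
        model = random_model(10, 2, rng)
        cfg = random_config(10, 3, rng)
        assert projection_similarity(model, cfg, 4, 4) == 1.0

    def test_disjoint_projections_orthogonal(self):
        # microstate 0 maps into macrostate A, microstate 1 into B
        dense = np.zeros((4, 4))
        dense[0, 2] = 1.0
        dense[1, 3] = 1.0
        dense[2, 2] = 1.0
        dense[3, 3] = 1.0
        model = TransitionModel(
            tm=[sparse.csr_matrix(dense)], visit_counts=np.full((4, 1), 5)
        )
        cfg = MacrostateConfig(labels=np.array([0, 1, 0, 1]))
        assert projection_similarity(model, cfg, 0, 1) == pytest.approx(0.0)

    def test_hand_computed_toy(self):
        # 3 microstates, 1 action, 2 macrostates {0,1} and {2}
        dense = np.array(
            [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]]
        )
        model = TransitionModel(
            tm=[sparse.csr_matrix(dense)], visit_counts=np.full((3, 1), 5)
        )
        cfg = MacrostateConfig(labels=np.array([0, 0, 1]))
        # projections onto (A, B): row0 -> (1, 0); row1 -> (0.5, 0.5)
        want = 0.5 / (1.0 * np.sqrt(0.5))
        assert projection_similarity(model, cfg, 0, 1) == pytest.approx(want)


class TestCutAndMerge:
    def test_cut_recovers_planted_blocks(self):
        model = block_cyclic_model(4, 3)
        # one macrostate holding blocks 0 and 1; others split per block
        labels = np.array([0] * 6 + [1] * 3 + [2] * 3)
        cfg = MacrostateConfig(labels=labels)
        new = cut_state(cfg, model, 0)
        assert new.n_macro == 4
        # the two halves are exactly the planted blocks
        parts = {frozenset(np.flatnonzero(new.labels == lab)) for lab in (0, 3)}
        assert parts == {frozenset(range(3)), frozenset(range(3, 6))}

    def test_cut_singleton_rejected(self, rng):
        model = random_model(6, 2, rng)
        cfg = MacrostateConfig(labels=np.array([0, 1, 1, 1, 1, 1]))
        with pytest.raises(ValueError):
            cut_state(cfg, model, 0)

    def test_merge_reduces_count_by_one(self, rng):
        cfg = random_config(20, 6, rng)
        assert merge_states(cfg, 1, 4).n_macro == 5

    def test_merge_self_rejected(self, rng):
        cfg = random_config(10, 3, rng)
        with pytest.raises(ValueError):
            merge_states(cfg, 2, 2)

    def test_merging_everything_gives_global_state(self, rng):
        cfg = random_config(12, 5, rng)
        while cfg.n_macro > 1:
            cfg = merge_states(cfg, 0, 1)
        assert cfg.n_macro == 1
        assert (cfg.labels == 0).all()


class TestBuildCandidates:
    def test_greedy_disjoint_pairs(self, rng):
        model = random_model(30, 2, rng)
        cfg = random_config(30, 8, rng)
        TM = macro_transitions(cfg, model)
        report = evaluate(TM)
        cand = build_candidates(report, TM, sizes=cfg.sizes())
        seen = [s for pair in cand.merge_pairs for s in pair]
        assert len(seen) == len(set(seen))  # one modification per state

    def test_pairs_accepted_in_ascending_decorrelation(self, rng):
        # most correlated pairs first (some may be skipped by the
        # merged-self-connection veto, so order, not optimality)
        model = random_model(24, 2, rng)
        cfg = random_config(24, 6, rng)
        TM = macro_transitions(cfg, model)
        report = evaluate(TM)
        cand = build_candidates(report, TM, sizes=cfg.sizes())
        vals = [report.decorr_pair[a, b] for a, b in cand.merge_pairs]
        assert vals == sorted(vals)
        assert all(v < 1 for v in vals)  # orthogonal pairs never merge

    def test_cut_list_is_below_median_cut_score(self, rng):
        # score is predictability discounted by self-connectivity, which
        # coincides with plain predictability when self-connectivity ~ 0
        model = random_model(30, 3, rng)
        cfg = random_config(30, 7, rng)
        TM = macro_transitions(cfg, model)
        report = evaluate(TM)
        cand = build_candidates(report, TM)
        diag = np.column_stack([t.diagonal() for t in TM.TM])
        score = report.pred * (1 - diag.mean(axis=1))
        med = np.median(score)
        assert set(cand.cut_states) == set(np.flatnonzero(score < med))


class TestStepAndOptimize:
    def test_branch_rule_merge_when_correlated(self, rng):
        # near-identical rows for all states: decorr ~ 0 << pred -> merge
        row = np.array([0.6, 0.4, 0.0, 0.0])
        dense = np.tile(row, (4, 1)) + rng.random((4, 4)) * 0.01
        dense /= dense.sum(axis=1, keepdims=True)
        model = TransitionModel(
            tm=[sparse.csr_matrix(dense)], visit_counts=np.full((4, 1), 5)
        )
        cfg = MacrostateConfig(labels=np.arange(4))
        new, rec = step(cfg, model, OptimizerSettings(), 0)
        assert rec.operation in ("merge", "forced_merge", "none")

    def test_boundary_blocks_cuts(self, rng):
        model = random_model(40, 2, rng)
        cfg = random_config(40, 20, rng)
        settings = OptimizerSettings(boundary_schedule=(10,), boundary_period=20)
        new, rec = step(cfg, model, settings, 0)
        # 20 states over a boundary of 10: cuts must not fire
        assert rec.operation != "cut"

    def test_count_bookkeeping(self, rng):
        model = random_model(40, 3, rng)
        cfg = random_config(40, 10, rng)
        new, rec = step(cfg, model, OptimizerSettings(), 0)
        if rec.operation in ("merge", "forced_merge"):
            assert new.n_macro == cfg.n_macro - rec.n_ops
        elif rec.operation == "cut":
            assert new.n_macro == cfg.n_macro + rec.n_ops
        new.validate()

    def test_partition_stays_valid_throughout(self, rng):
        model = random_model(50, 2, rng)
        trace = optimize(
            model,
            OptimizerSettings(max_iters=30, init_n_range=(5, 15)),
            rng=rng,
        )
        trace.best_config.validate()
        assert len(trace.records) == 30

    def test_optimizer_improves_on_block_structure(self):
        # perfectly predictable planted blocks: the optimizer should find
        # configurations with much higher Psi than the random start
        model = block_cyclic_model(5, 4)
        rng = np.random.default_rng(1)
        trace = optimize(
            model,
            OptimizerSettings(max_iters=60, init_n_range=(4, 8)),
            rng=rng,
        )
        assert trace.best_psi > trace.records[0].mean_psi
        rep = evaluate(macro_transitions(trace.best_config, model))
        assert rep.pred.max() == pytest.approx(1.0, abs=1e-9)

    def test_best_psi_tracks_maximum(self, rng):
        model = random_model(40, 2, rng)
        trace = optimize(
            model, OptimizerSettings(max_iters=25, init_n_range=(5, 20)), rng=rng
        )
        assert trace.best_psi == pytest.approx(
            max(r.mean_psi for r in trace.records)
        )
        assert trace.best_iter == int(
            np.argmax([r.mean_psi for r in trace.records])
        )

    def test_fixed_seed_reproducible(self, rng):
        model = random_model(30, 2, rng)
        t1 = optimize(model, OptimizerSettings(max_iters=15), np.random.default_rng(5))
        t2 = optimize(model, OptimizerSettings(max_iters=15), np.random.default_rng(5))
        np.testing.assert_array_equal(t1.best_config.labels, t2.best_config.labels)
        assert [r.mean_psi for r in t1.records] == [r.mean_psi for r in t2.records]

    def test_boundary_schedule_cycles(self):
        s = OptimizerSettings()
        assert s.boundary_at(0) == 1000
        assert s.boundary_at(19) == 1000
        assert s.boundary_at(20) == 500
        assert s.boundary_at(40) == 10
        assert s.boundary_at(60) == 1000

    def test_reselect_recovers_default_beta_choice(self, rng):
        model = random_model(40, 2, rng)
        trace = optimize(
            model, OptimizerSettings(max_iters=20, init_n_range=(5, 20)), rng=rng
        )
        it, rec = trace.reselect(0.8)
        assert it == trace.best_iter
        assert rec.mean_psi == pytest.approx(trace.best_psi)
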