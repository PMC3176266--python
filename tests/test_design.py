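import math

import numpy as np
import pytest

from rnaforge.design import (
    AnnealConfig,
    DesignGoals,
    Evaluator,
    Metrics,
    ObjectiveWeights,
    adaptive_walk,
    anneal,
    design,
    init_sequence,
    objective_fn,
    sample_neighbor,
    tie_ends,
)
from rnaforge.structures import bp_distance, compatible, parse_dotbracket


def goals_for(db: str, dg=-5.0, eta=0.8) -> DesignGoals:
    return DesignGoals(parse_dotbracket(db), desired_dG=dg, desired_neutrality=eta)


class TestObjective:
    def test_vanishes_when_all_goals_met(self):
        g = goals_for("(((...)))", dg=-7.0, eta=0.9)
        m = Metrics(neutrality=0.9, dG=-7.0, shape_distance=0.0, bp_dist=0)
        assert objective_fn(m, g, ObjectiveWeights()) == 0.0

    def test_zero_weights_ignore_metrics(self):
        g = goals_for("(((...)))")
        m = Metrics(neutrality=0.1, dG=3.0, shape_distance=9.0, bp_dist=7)
        assert objective_fn(m, g, ObjectiveWeights(0, 0, 0, 0)) == 0.0

    def test_linear_form_arithmetic(self):
        g = goals_for("(((...)))", dg=-10.0, eta=0.90)
        w = ObjectiveWeights(neutrality=500, dG=2, shape=50, bp=1)
        m = Metrics(neutrality=0.89, dG=-8.5, shape_distance=2.0, bp_dist=4)
        # 500*0.01 + 2*1.5 + 50*2 + 1*4
        assert objective_fn(m, g, w) == pytest.approx(112.0)

    def test_desired_neutrality_validated(self):
        with pytest.raises(ValueError):
            goals_for("(((...)))", eta=1.5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveWeights(neutrality=-1)


class TestInitSequence:
    def test_compatible_with_target(self, rng):
        g = goals_for("((.((...)).((...)).))")
        for _ in range(20):
            assert compatible(init_sequence(g, rng), g.target_structure)

    def test_distinct_across_seeds(self):
        g = goals_for("(((...)))")
        seqs = {
            init_sequence(g, np.random.default_rng(s)) for s in range(100)
        }
        assert len(seqs) >= 99

    def test_unpaired_target_any_sequence(self, rng):
        s = init_sequence(goals_for("..."), rng)
        assert len(s) == 3 and set(s) <= set("ACGU")


class TestSampleNeighbor:
    @staticmethod
    def hamming(a, b):
        return sum(x != y for x, y in zip(a, b))

    def test_lookahead_one_gives_distance_one(self, rng):
        seq = "GGGAAACCC"
        for _ in range(50):
            assert self.hamming(seq, sample_neighbor(seq, 1, rng)) == 1

    def test_distances_uniform_over_lookahead(self, rng):
        seq = "GGGGAAAACCCC"
        n = 10_000
        counts = np.zeros(5)
        for _ in range(n):
            counts[self.hamming(seq, sample_neighbor(seq, 4, rng))] += 1
        assert counts[0] == 0
        sigma = math.sqrt(n * 0.25 * 0.75)
        for d in (1, 2, 3, 4):
            assert abs(counts[d] - n / 4) < 3 * sigma

    def test_lookahead_beyond_length_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_neighbor("ACG", 4, rng)


class TestTieEnds:
    def test_already_tied_unchanged(self, rng):
        g = goals_for("((...))")
        assert tie_ends("GGAAACC", g, rng) == "GGAAACC"

    def test_untied_ends_get_resampled_to_complement(self, rng):
        g = goals_for("((...))")
        seq = "AGAAACC"  # ends A...C cannot pair
        for _ in range(20):
            out = tie_ends(seq, g, rng)
            assert sum(a != b for a, b in zip(seq, out)) == 1
            assert (out[0], out[6]) in {
                ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                ("G", "U"), ("U", "G"),
            }

    def test_open_target_is_noop(self, rng):
        assert tie_ends("ACGUA", goals_for("....."), rng) == "ACGUA"


class TestAdaptiveWalk:
    def test_start_at_target_unchanged(self, toy_backend):
        g = goals_for("((((....))))")
        seq = "GGGGAAAACCCC"
        res = adaptive_walk(seq, g, toy_backend)
        assert res.sequence == seq and res.moves == ()

    def test_reaches_target_from_random_starts(self, toy_backend):
        g = goals_for("((((....))))")
        wins = 0
        for s in range(100):
            start = init_sequence(g, np.random.default_rng(s))
            walked = adaptive_walk(start, g, toy_backend).sequence
            if bp_distance(toy_backend.fold(walked).structure,
                           g.target_structure) == 0:
                wins += 1
        assert wins >= 90

    def test_never_increases_distance(self, toy_backend, rng):
        g = goals_for("((.((...)).((...)).))")
        start = init_sequence(g, rng)
        d0 = bp_distance(toy_backend.fold(start).structure, g.target_structure)
        walked = adaptive_walk(start, g, toy_backend).sequence
        d1 = bp_distance(toy_backend.fold(walked).structure, g.target_structure)
        assert d1 <= d0


class TestAnneal:
    def test_perfect_start_returned_unchanged(self, toy_backend):
        seq = "GGGGAAAACCCC"
        fr = toy_backend.fold(seq)
        from rnaforge.robustness import neutrality

        g = DesignGoals(
            fr.structure,
            desired_dG=fr.dG,
            desired_neutrality=neutrality(seq, toy_backend).value,
        )
        out = anneal(seq, g, cfg=AnnealConfig(steps=30, seed=5),
                     backend=toy_backend)
        assert out.result.sequence == seq
        assert out.result.objective == 0.0

    def test_best_objective_non_increasing(self, toy_backend):
        g = goals_for("((((....))))", dg=-9.0, eta=0.77)
        ev = Evaluator(g, ObjectiveWeights(), toy_backend)
        start = init_sequence(g, np.random.default_rng(3))
        out = anneal(start, g, cfg=AnnealConfig(steps=60, seed=3),
                     backend=toy_backend, evaluator=ev)
        objs = [ev.evaluate(s)[1] for s in (start,) + out.accepted]
        best_so_far = np.minimum.accumulate(objs)
        assert list(best_so_far) == sorted(best_so_far, reverse=True)
        assert out.result.objective == best_so_far[-1]

    def test_zero_temperature_reduces_to_adaptive_walk(self, toy_backend):
        g = goals_for("(((....)))", dg=-6.0, eta=0.8)
        w = ObjectiveWeights()
        start = init_sequence(g, np.random.default_rng(9))
        walk = adaptive_walk(start, g, toy_backend, weights=w)
        cfg = AnnealConfig(steps=40, T0=0.0, exhaustive=True,
                           exact_objective=True, seed=9)
        annealed = anneal(start, g, w, cfg, toy_backend)
        assert annealed.accepted == walk.moves
        assert annealed.result.sequence == walk.sequence


class TestDesign:
    def test_single_run_returns_singleton(self, toy_backend):
        g = goals_for("((((....))))", dg=-9.0, eta=0.77)
        res = design(g, 1, cfg=AnnealConfig(steps=40, seed=2), backend=toy_backend)
        assert len(res) == 1

    def test_deterministic_and_sorted(self, toy_backend):
        g = goals_for("((((....))))", dg=-9.0, eta=0.77)
        cfg = AnnealConfig(steps=40, seed=11)
        a = design(g, 3, cfg=cfg, backend=toy_backend)
        b = design(g, 3, cfg=cfg, backend=toy_backend)
        assert a == b
        scores = [r.rank_score for r in a]
        assert scores == sorted(scores)

    def test_result_objective_recomputable(self, toy_backend):
        g = goals_for("((((....))))", dg=-9.0, eta=0.77)
        w = ObjectiveWeights()
        res = design(g, 2, w, AnnealConfig(steps=40, seed=4), toy_backend)
        for r in res:
            m = Metrics(r.neutrality.value, r.predicted.dG,
                        r.shape_distance, r.bp_dist)
            assert objective_fn(m, g, w) == pytest.approx(r.objective)
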