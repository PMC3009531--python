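import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmactive import (
    GeneratorParams,
    NodeLabelStats,
    RunConfig,
    SelectionState,
    generate_dataset,
    node_entropy,
    run_active_learning,
    select_confusion,
    select_next,
    select_node_coverage,
    select_random,
)
from tmactive.pipeline import prepare_study

from conftest import make_prepared


class TestNodeEntropy:
    @pytest.mark.parametrize(
        "n_tm,n_nontm,expected",
        [
            (5, 5, 1.0),
            (7, 0, 0.0),
            (0, 7, 0.0),
            (0, 0, 0.0),
            (1, 3, 0.8112781244591328),  # -0.25 log2 0.25 - 0.75 log2 0.75
        ],
    )
    def test_values(self, n_tm, n_nontm, expected):
        assert node_entropy(n_tm, n_nontm) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            node_entropy(-1, 2)

    @given(a=st.integers(0, 1000), b=st.integers(0, 1000))
    def test_symmetry_and_bounds(self, a, b):
        e = node_entropy(a, b)
        assert e == node_entropy(b, a)
        assert 0.0 <= e <= 1.0

    @given(k=st.integers(1, 49))
    def test_increases_toward_even_split(self, k):
        """Entropy is strictly increasing in min(p0, p1)."""
        assert node_entropy(k, 100 - k) < node_entropy(k + 1, 99 - k) or k + 1 > 50

    def test_stats_p0_p1_sum_to_one(self):
        stats = NodeLabelStats(4)
        stats.add_protein(np.array([0, 0, 1, 2]), np.array([1, -1, 1, 0]))
        total = stats.tm_counts + stats.nontm_counts
        seen = total > 0
        assert np.allclose((stats.p0 + stats.p1)[seen], 1.0)
        # node 2 saw only a mixed window -> unlabeled under the pure-class rule
        assert total[2] == 0


def _state(proteins, **kw):
    return SelectionState(pool={p.id: p for p in proteins}, n_nodes=50, **kw)


class TestSelectRandom:
    def test_pool_of_one(self):
        state = _state([make_prepared("only", [0, 1])])
        assert select_random(state, np.random.default_rng(0)) == "only"

    def test_deterministic_sequence(self):
        proteins = [make_prepared(f"p{i}", [i]) for i in range(6)]
        picks1 = [select_random(_state(proteins), np.random.default_rng(5)) for _ in range(4)]
        picks2 = [select_random(_state(proteins), np.random.default_rng(5)) for _ in range(4)]
        assert picks1 == picks2

    def test_uniform_frequency(self):
        proteins = [make_prepared(f"p{i}", [i]) for i in range(4)]
        state = _state(proteins)
        rng = np.random.default_rng(123)
        counts = {f"p{i}": 0 for i in range(4)}
        for _ in range(10_000):
            counts[select_random(state, rng)] += 1
        for c in counts.values():
            assert abs(c / 10_000 - 0.25) < 0.02

    def test_empty_pool_errors(self):
        state = _state([make_prepared("a", [0])])
        state.labeled = ["a"]
        with pytest.raises(ValueError, match="empty"):
            select_random(state, np.random.default_rng(0))


class TestSelectNodeCoverage:
    def test_strict_dominance(self):
        state = _state([make_prepared("A", [1, 2, 3]), make_prepared("B", [1, 2])])
        assert select_node_coverage(state) == "A"

    def test_counts_only_new_nodes(self):
        state = _state([make_prepared("A", [1, 2, 3]), make_prepared("B", [4, 5])])
        state.covered = {1, 2, 3}
        assert select_node_coverage(state) == "B"

    def test_absolute_mode_ignores_covered(self):
        state = _state(
            [make_prepared("A", [1, 2, 3]), make_prepared("B", [4, 5])],
            coverage_mode="absolute",
        )
        state.covered = {1, 2, 3}
        assert select_node_coverage(state) == "A"

    def test_tie_breaks_by_window_count_then_id(self):
        # same new-node count; B has more windows
        state = _state(
            [make_prepared("A", [1, 2]), make_prepared("B", [1, 1, 2])]
        )
        assert select_node_coverage(state) == "B"
        state = _state([make_prepared("B", [1, 2]), make_prepared("A", [1, 2])])
        assert select_node_coverage(state) == "A"


class TestSelectConfusion:
    def test_only_contributor_wins(self):
        a = make_prepared("A", [9, 9, 9] + [0] * 7)
        b = make_prepared("B", [0] * 10)
        state = _state([a, b, make_prepared("seed", [9], classes=[0])])
        state.labeled = ["seed"]
        state.node_stats.tm_counts[9] = 5
        state.node_stats.nontm_counts[9] = 5  # node 9: entropy 1, rest 0
        assert select_confusion(state) == "A"

    def test_identical_assignments_tie_break(self):
        state = _state([make_prepared("B", [3, 4]), make_prepared("A", [3, 4]),
                        make_prepared("seed", [3])])
        state.labeled = ["seed"]
        state.node_stats.tm_counts[3] = 1
        state.node_stats.nontm_counts[3] = 1
        assert select_confusion(state) == "A"

    def test_requires_labeled_data(self):
        state = _state([make_prepared("A", [1])])
        with pytest.raises(ValueError, match="labeled"):
            select_confusion(state)


class TestAlternating:
    def test_strategy_sequence(self):
        """Four alternating iterations dispatch [coverage, confusion,
        coverage, confusion], and the first pick equals coverage's."""
        proteins = [
            make_prepared("A", [1, 2, 3, 4], classes=[1, -1, 1, -1]),
            make_prepared("B", [1, 2], classes=[1, -1]),
            make_prepared("C", [5, 6, 7], classes=[1, 1, -1]),
            make_prepared("D", [5, 6], classes=[-1, -1]),
            make_prepared("E", [8], classes=[1]),
        ]
        state = _state(proteins, strategy="alternating")
        rng = np.random.default_rng(0)
        cov_first = select_node_coverage(state)
        picks = []
        for _ in range(4):
            expected = (
                select_node_coverage(state)
                if state.iteration % 2 == 1
                else select_confusion(state)
            )
            pick = select_next(state, rng)
            assert pick == expected
            state.reveal(pick)
            picks.append(pick)
        assert picks[0] == cov_first
        assert len(set(picks)) == 4


def _coverage_oracle(state):
    """Exhaustive re-scoring: new-node count, then window count; iterating
    ids in ascending order with a strict improvement test leaves the
    lexicographically smallest id on full ties."""
    best_key, best_pid = None, None
    for pid in sorted(state.pool):
        if pid in state.labeled:
            continue
        prot = state.pool[pid]
        key = (
            len({int(n) for n in prot.nodes} - state.covered),
            prot.features.n_windows,
        )
        if best_key is None or key > best_key:
            best_key, best_pid = key, pid
    return best_pid


def _confusion_oracle(state):
    ent = {
        node: node_entropy(int(t), int(n))
        for node, (t, n) in enumerate(
            zip(state.node_stats.tm_counts, state.node_stats.nontm_counts)
        )
    }
    best_key, best_pid = None, None
    for pid in sorted(state.pool):
        if pid in state.labeled:
            continue
        prot = state.pool[pid]
        score = sum(ent[int(n)] for n in prot.nodes) / len(prot.nodes)
        key = (score, prot.features.n_windows)
        if best_key is None or key > best_key:
            best_key, best_pid = key, pid
    return best_pid


@pytest.mark.parametrize("seed", [0, 1])
def test_selectors_agree_with_bruteforce_on_synthetic_pool(seed):
    """Both greedy selectors equal exhaustive argmax scoring at every
    iteration of a 20-protein synthetic pool."""
    cfg = RunConfig(synthetic_pool=20, synthetic_test=2)
    records = [rec for rec, _ in generate_dataset(GeneratorParams(20, seed=seed))]
    test = [rec for rec, _ in generate_dataset(GeneratorParams(2, seed=seed + 900))]
    pool, _, _, som = prepare_study(records, test, cfg, seed)
    state = SelectionState(pool={p.id: p for p in pool}, n_nodes=som.n_nodes)
    for _ in range(10):
        assert select_node_coverage(state) == _coverage_oracle(state)
        if state.labeled:
            assert select_confusion(state) == _confusion_oracle(state)
        state.reveal(select_node_coverage(state))


def test_run_active_learning_never_repeats_and_is_reproducible():
    cfg = RunConfig(synthetic_pool=8, synthetic_test=3)
    records = [rec for rec, _ in generate_dataset(GeneratorParams(8, seed=3))]
    test = [rec for rec, _ in generate_dataset(GeneratorParams(3, seed=901))]
    pool, tst, _, som = prepare_study(records, test, cfg, 3)
    curves = [
        run_active_learning(
            pool, tst, strategy="random", n_iterations=8, n_nodes=som.n_nodes, seed=5
        )
        for _ in range(2)
    ]
    assert len(set(curves[0].selected_ids)) == 8  # pool exhausted, no repeats
    assert curves[0].selected_ids == curves[1].selected_ids
    assert [r.fscore for r in curves[0].reports] == [r.fscore for r in curves[1].reports]


def test_iterations_beyond_pool_error():
    pool = [make_prepared(f"p{i}", [i], classes=[1]) for i in range(3)]
    with pytest.raises(ValueError, match="exceeds pool"):
        run_active_learning(pool, pool, strategy="random", n_iterations=4, n_nodes=50)
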