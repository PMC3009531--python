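"""Pool-based active selection of proteins for labeling.

Four strategies decide, one protein per iteration, whose structure to
"reveal" next:

* **random** — the passive baseline, uniform over the unlabeled pool;
* **coverage** — density-style: the protein whose windows occupy the most
  SOM nodes not yet covered by the labeled set (greedy set cover; raw node
  counting available via ``coverage_mode="absolute"``);
* **confusion** — uncertainty-style: after a random first pick, the protein
  whose windows sit in the nodes with the highest TM/non-TM label entropy
  E = -p0 log2 p0 - p1 log2 p1, where p0 and p1 are the fractions of a
  node's labeled windows carrying the TM and non-TM class;
* **alternating** — coverage on odd iterations, confusion on even ones
  (hence its first pick equals coverage's).

After every selection the classifier is retrained from scratch on all
labeled pure-class windows and scored on the held-out test set, yielding a
learning curve of benchmark metrics versus training-set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .property_features import FeatureSet
from .segment_eval import (
    DEFAULT_MIN_OVERLAP,
    EvalReport,
    ProteinPrediction,
    evaluate,
)
from .sequence_io import ProteinRecord, labels_to_segments
from .tm_classifier import NNModel, predict_segments, train_nn


def node_entropy(n_tm: int, n_nontm: int) -> float:
    """Label confusion of a node in bits, with the 0*log0 = 0 convention.

    Symmetric in its arguments, 0 for a pure or empty node, maximal (1 bit)
    at a 50/50 split.
    """
    if n_tm < 0 or n_nontm < 0:
        raise ValueError("counts must be non-negative")
    total = n_tm + n_nontm
    if total == 0:
        return 0.0
    e = 0.0
    for count in (n_tm, n_nontm):
        p = count / total
        if p > 0.0:
            e -= p * np.log2(p)
    return float(e)


@dataclass
class NodeLabelStats:
    """Per-node labeled-window counts and derived entropies.

    Only pure-class windows contribute (class +1 counts as TM, -1 as
    non-TM); mixed windows are excluded, mirroring the classifier's training
    set.  Nodes with no labeled windows get entropy 0 by default ("no
    observed confusion"); ``unseen="max"`` treats them as maximally
    uncertain instead.
    """

    n_nodes: int
    tm_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    nontm_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    unseen: Literal["zero", "max"] = "zero"

    def __post_init__(self) -> None:
        if self.tm_counts is None:
            self.tm_counts = np.zeros(self.n_nodes, dtype=np.int64)
        if self.nontm_counts is None:
            self.nontm_counts = np.zeros(self.n_nodes, dtype=np.int64)

    def add_protein(self, nodes: np.ndarray, classes: np.ndarray) -> None:
        """Accumulate one labeled protein's pure windows into the counts."""
        nodes = np.asarray(nodes)
        classes = np.asarray(classes)
        self.tm_counts += np.bincount(nodes[classes == 1], minlength=self.n_nodes)
        self.nontm_counts += np.bincount(nodes[classes == -1], minlength=self.n_nodes)

    @property
    def p0(self) -> np.ndarray:
        """Fraction of each node's labeled windows that are TM (nan if none)."""
        total = self.tm_counts + self.nontm_counts
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, self.tm_counts / np.maximum(total, 1), np.nan)

    @property
    def p1(self) -> np.ndarray:
        total = self.tm_counts + self.nontm_counts
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, self.nontm_counts / np.maximum(total, 1), np.nan)

    @property
    def entropy(self) -> np.ndarray:
        """Per-node entropy in bits, unseen nodes per the ``unseen`` policy."""
        e = np.array(
            [
                node_entropy(int(t), int(n))
                for t, n in zip(self.tm_counts, self.nontm_counts)
            ]
        )
        if self.unseen == "max":
            e[(self.tm_counts + self.nontm_counts) == 0] = 1.0
        return e


@dataclass
class PreparedProtein:
    """A pool/test protein with everything the loop needs precomputed."""

    record: ProteinRecord
    features: FeatureSet  # projected
    nodes: np.ndarray | None  # SOM node per window
    classes: np.ndarray  # window classes from gold labels (revealed on pick)

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def observed_segments(self) -> list[tuple[int, int]]:
        return labels_to_segments(self.record.labels)


@dataclass
class SelectionState:
    """Bookkeeping of one active-learning run."""

    pool: dict[str, PreparedProtein]
    n_nodes: int
    strategy: str = "coverage"
    coverage_mode: Literal["new", "absolute"] = "new"
    score_mode: Literal["mean", "sum", "max"] = "mean"
    unseen_entropy: Literal["zero", "max"] = "zero"
    labeled: list[str] = field(default_factory=list)
    covered: set[int] = field(default_factory=set)
    node_stats: NodeLabelStats = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.node_stats is None:
            self.node_stats = NodeLabelStats(self.n_nodes, unseen=self.unseen_entropy)

    @property
    def unlabeled(self) -> list[str]:
        lab = set(self.labeled)
        return sorted(pid for pid in self.pool if pid not in lab)

    @property
    def iteration(self) -> int:
        """1-based index of the *next* selection."""
        return len(self.labeled) + 1

    def reveal(self, protein_id: str) -> None:
        """Move a protein to the labeled set and update coverage/entropy."""
        if protein_id in self.labeled:
            raise ValueError(f"{protein_id!r} already labeled")
        prot = self.pool[protein_id]
        self.labeled.append(protein_id)
        self.covered.update(int(n) for n in prot.nodes)
        self.node_stats.add_protein(prot.nodes, prot.classes)


def _best(
    candidates: Sequence[tuple[float, int, str]],
) -> str:
    """Argmax by (score, window count, lexicographically smallest id)."""
    return min(candidates, key=lambda t: (-t[0], -t[1], t[2]))[2]


def select_random(state: SelectionState, rng: np.random.Generator) -> str:
    """Uniform pick from the unlabeled pool (sorted ids, so seed-stable)."""
    pool = state.unlabeled
    if not pool:
        raise ValueError("empty unlabeled pool")
    return pool[int(rng.integers(len(pool)))]


def select_node_coverage(state: SelectionState) -> str:
    """Unlabeled protein whose windows hit the most not-yet-covered nodes.

    Ties break toward the protein with more windows, then the
    lexicographically smallest id.  ``coverage_mode="absolute"`` ranks by
    raw node counts instead of new ones.
    """
    pool = state.unlabeled
    if not pool:
        raise ValueError("empty unlabeled pool")
    cands = []
    for pid in pool:
        prot = state.pool[pid]
        nodes = set(int(n) for n in prot.nodes)
        if state.coverage_mode == "new":
            score = len(nodes - state.covered)
        else:
            score = len(nodes)
        cands.append((float(score), prot.features.n_windows, pid))
    return _best(cands)


def select_confusion(state: SelectionState) -> str:
    """Unlabeled protein whose windows sit in the most confused nodes.

    Score is the mean (or sum/max, per ``score_mode``) entropy of the nodes
    its windows are assigned to; requires at least one labeled protein.
    """
    pool = state.unlabeled
    if not pool:
        raise ValueError("empty unlabeled pool")
    if not state.labeled:
        raise ValueError("confusion-rated selection needs labeled data; pick randomly first")
    entropy = state.node_stats.entropy
    reducer = {"mean": np.mean, "sum": np.sum, "max": np.max}[state.score_mode]
    cands = []
    for pid in pool:
        prot = state.pool[pid]
        score = float(reducer(entropy[prot.nodes]))
        cands.append((score, prot.features.n_windows, pid))
    return _best(cands)


def select_next(
    state: SelectionState, rng: np.random.Generator
) -> str:
    """Dispatch one selection according to the state's strategy.

    ``confusion`` starts with a random pick (no labels exist yet);
    ``alternating`` uses coverage on odd iterations and confusion on even.
    """
    strategy = state.strategy
    if strategy == "alternating":
        strategy = "coverage" if state.iteration % 2 == 1 else "confusion"
    if strategy == "random":
        return select_random(state, rng)
    if strategy == "coverage":
        return select_node_coverage(state)
    if strategy == "confusion":
        if not state.labeled:
            return select_random(state, rng)
        return select_confusion(state)
    raise ValueError(f"unknown strategy {state.strategy!r}")


@dataclass
class LearningCurve:
    """Per-iteration evaluation of one active-learning run."""

    strategy: str
    seed: int | None
    selected_ids: list[str] = field(default_factory=list)
    reports: list[EvalReport] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (pid, rep) in enumerate(zip(self.selected_ids, self.reports), 1):
            rows.append(
                {
                    "iteration": i,
                    "strategy": self.strategy,
                    "selected_id": pid,
                    "qok": rep.qok,
                    "recall": rep.recall,
                    "precision": rep.precision,
                    "fscore": rep.fscore,
                    "q2": rep.q2,
                }
            )
        return pd.DataFrame(rows)


def evaluate_model(
    model: NNModel,
    test: Sequence[PreparedProtein],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = 1,
) -> EvalReport:
    """Score a trained classifier on prepared held-out proteins."""
    dataset = [
        ProteinPrediction(
            protein_id=prot.id,
            length=len(prot.record),
            observed=prot.observed_segments,
            predicted=predict_segments(prot.features, model, min_len=min_len),
        )
        for prot in test
    ]
    return evaluate(dataset, min_overlap=min_overlap)


def _derived_seed(seed: int | None, *path: int) -> int:
    """A reproducible 31-bit child seed for a sub-computation."""
    entropy = [0 if seed is None else int(seed), *path]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def run_active_learning(
    pool: Sequence[PreparedProtein],
    test: Sequence[PreparedProtein],
    strategy: str,
    n_iterations: int,
    n_nodes: int,
    seed: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = 1,
    coverage_mode: Literal["new", "absolute"] = "new",
    score_mode: Literal["mean", "sum", "max"] = "mean",
    unseen_entropy: Literal["zero", "max"] = "zero",
    nn_params: dict | None = None,
) -> LearningCurve:
    """The full loop: select, reveal, retrain from scratch, evaluate.

    One protein is added per iteration; the network is reinitialised (fresh
    weights from a seed derived from ``seed`` and the iteration number) and
    retrained on all labeled pure-class windows each time, then scored on
    ``test``.  Selected ids are unique by construction.
    """
    if n_iterations > len(pool):
        raise ValueError(
            f"n_iterations={n_iterations} exceeds pool size {len(pool)}"
        )
    nn_params = nn_params or {}
    state = SelectionState(
        pool={p.id: p for p in pool},
        n_nodes=n_nodes,
        strategy=strategy,
        coverage_mode=coverage_mode,
        score_mode=score_mode,
        unseen_entropy=unseen_entropy,
    )
    rng = np.random.default_rng(seed)
    curve = LearningCurve(strategy=strategy, seed=seed)
    for it in range(1, n_iterations + 1):
        pid = select_next(state, rng)
        state.reveal(pid)
        X = np.concatenate(
            [state.pool[q].features.projected for q in state.labeled]
        )
        classes = np.concatenate([state.pool[q].classes for q in state.labeled])
        model = train_nn(X, classes, seed=_derived_seed(seed, it), **nn_params)
        report = evaluate_model(model, test, min_overlap=min_overlap, min_len=min_len)
        curve.selected_ids.append(pid)
        curve.reports.append(report)
    return curve
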