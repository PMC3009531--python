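"""Segment-level benchmark metrics for TM helix prediction.

The metrics follow the TMH-benchmark conventions: observed and predicted
segments are put into a one-to-one correspondence (greedy, by descending
overlap, a pair counting only if it shares at least ``min_overlap``
residues), and from the pooled match counts we report

* ``Q_ok`` — percentage of proteins with *all* segments correct (every
  observed segment matched, no unmatched prediction),
* segment recall ``Q_obs_htm`` — % observed segments that are predicted,
* segment precision ``Q_pred_htm`` — % predicted segments that are correct,
* ``F`` — the geometric mean sqrt(recall * precision), the point where the
  two measures would be equal,
* residue accuracy ``Q2`` — % residues labeled correctly.

Aggregation is a micro-average over pooled segment counts; a per-protein
macro-average is available via ``macro=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_OVERLAP = 3

SegmentTuple = tuple[int, int]


def _check_sorted(segments: Sequence[SegmentTuple], name: str) -> None:
    prev_end = 0
    for s, e in segments:
        if s > e:
            raise ValueError(f"{name}: segment ({s},{e}) has start > end")
        if s <= prev_end:
            raise ValueError(f"{name}: segments unsorted or overlapping at ({s},{e})")
        prev_end = e


def segment_overlap(a: SegmentTuple, b: SegmentTuple) -> int:
    """Number of residues shared by two 1-based inclusive segments."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def match_segments(
    observed: Sequence[SegmentTuple],
    predicted: Sequence[SegmentTuple],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of observed to predicted segments.

    Candidate pairs overlapping by at least ``min_overlap`` residues are
    taken in order of descending overlap (ties: earlier observed segment
    first, then earlier predicted); each segment participates in at most one
    match.  Returns ``(observed_index, predicted_index)`` pairs.
    """
    _check_sorted(observed, "observed")
    _check_sorted(predicted, "predicted")
    candidates = []
    for i, obs in enumerate(observed):
        for j, pred in enumerate(predicted):
            ov = segment_overlap(obs, pred)
            if ov >= min_overlap:
                candidates.append((-ov, i, j))
    candidates.sort()
    matched_obs: set[int] = set()
    matched_pred: set[int] = set()
    matches = []
    for _negov, i, j in candidates:
        if i in matched_obs or j in matched_pred:
            continue
        matched_obs.add(i)
        matched_pred.add(j)
        matches.append((i, j))
    return matches


def protein_ok(
    observed: Sequence[SegmentTuple],
    predicted: Sequence[SegmentTuple],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> bool:
    """True iff every observed segment is matched and nothing extra predicted."""
    m = match_segments(observed, predicted, min_overlap)
    return len(m) == len(observed) == len(predicted)


@dataclass
class ProteinPrediction:
    """Observed vs predicted segments for one protein of known length."""

    protein_id: str
    length: int
    observed: list[SegmentTuple]
    predicted: list[SegmentTuple]

    def labels(self, segments: Sequence[SegmentTuple]) -> np.ndarray:
        lab = np.zeros(self.length, dtype=np.int8)
        for s, e in segments:
            if e > self.length:
                raise ValueError(
                    f"{self.protein_id}: segment ({s},{e}) exceeds length {self.length}"
                )
            lab[s - 1 : e] = 1
        return lab


@dataclass
class EvalReport:
    """The five benchmark metrics (percent) plus a per-protein breakdown."""

    qok: float
    recall: float
    precision: float
    fscore: float
    q2: float
    n_proteins: int
    n_observed: int
    n_predicted: int
    n_matched: int
    per_protein: pd.DataFrame | None = None

    def rounded(self) -> dict[str, int]:
        """Integer-percent view, the form benchmark tables are printed in."""
        return {
            "qok": round(self.qok),
            "fscore": round(self.fscore),
            "recall": round(self.recall),
            "precision": round(self.precision),
            "q2": round(self.q2),
        }

    def to_dict(self) -> dict:
        return {
            "qok": self.qok,
            "recall": self.recall,
            "precision": self.precision,
            "fscore": self.fscore,
            "q2": self.q2,
            "n_proteins": self.n_proteins,
            "n_observed": self.n_observed,
            "n_predicted": self.n_predicted,
            "n_matched": self.n_matched,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def __str__(self) -> str:
        return (
            f"Qok={self.qok:.1f}% F={self.fscore:.1f}% "
            f"recall={self.recall:.1f}% precision={self.precision:.1f}% "
            f"Q2={self.q2:.1f}% (n={self.n_proteins})"
        )


def fscore(recall: float, precision: float) -> float:
    """Geometric mean of segment recall and precision (percent scale)."""
    return float(np.sqrt(recall * precision))


def _rate(num: int, den: int, other_total: int) -> float:
    # empty-denominator convention: perfect when the other side is empty too
    if den > 0:
        return 100.0 * num / den
    return 100.0 if other_total == 0 else 0.0


def evaluate(
    dataset: Sequence[ProteinPrediction],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    macro: bool = False,
) -> EvalReport:
    """Score a dataset of per-protein predictions.

    Micro-average (default): recall and precision are computed from segment
    totals pooled over proteins.  ``macro=True`` instead averages per-protein
    rates.  Metrics are invariant under protein reordering.
    """
    if len(dataset) == 0:
        raise ValueError("evaluate: empty dataset")
    rows = []
    tot_obs = tot_pred = tot_match = 0
    n_ok = 0
    correct_residues = 0
    total_residues = 0
    for item in dataset:
        matches = match_segments(item.observed, item.predicted, min_overlap)
        ok = len(matches) == len(item.observed) == len(item.predicted)
        obs_lab = item.labels(item.observed)
        pred_lab = item.labels(item.predicted)
        correct = int((obs_lab == pred_lab).sum())
        rows.append(
            {
                "protein_id": item.protein_id,
                "n_observed": len(item.observed),
                "n_predicted": len(item.predicted),
                "n_matched": len(matches),
                "ok": ok,
                "recall": _rate(len(matches), len(item.observed), len(item.predicted)),
                "precision": _rate(len(matches), len(item.predicted), len(item.observed)),
                "q2": 100.0 * correct / item.length,
            }
        )
        tot_obs += len(item.observed)
        tot_pred += len(item.predicted)
        tot_match += len(matches)
        n_ok += ok
        correct_residues += correct
        total_residues += item.length
    per_protein = pd.DataFrame(rows)
    if macro:
        recall = float(per_protein["recall"].mean())
        precision = float(per_protein["precision"].mean())
    else:
        recall = _rate(tot_match, tot_obs, tot_pred)
        precision = _rate(tot_match, tot_pred, tot_obs)
    return EvalReport(
        qok=100.0 * n_ok / len(dataset),
        recall=recall,
        precision=precision,
        fscore=fscore(recall, precision),
        q2=100.0 * correct_residues / total_residues,
        n_proteins=len(dataset),
        n_observed=tot_obs,
        n_predicted=tot_pred,
        n_matched=tot_match,
        per_protein=per_protein,
    )
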