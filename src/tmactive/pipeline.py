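"""End-to-end orchestration: features -> SVD -> SOM -> active loop -> report.

``RunConfig`` captures every dial of a run; ``pipeline_run`` executes the
whole study and writes a tidy learning-curve CSV, the fitted models and a
manifest, all deterministically — re-running the same config reproduces the
outputs byte for byte.  Repeats are implemented as seed offsets
(``seed + 0 .. seed + repeats - 1``), each repeat regenerating its pool and
rerunning every requested strategy, and the reported curve is per-repeat
plus the mean.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .active_selection import LearningCurve, PreparedProtein, run_active_learning
from .property_features import (
    DEFAULT_RANK,
    DEFAULT_WINDOW_LENGTH,
    PropertyTable,
    SVDModel,
    fit_svd,
    project,
    window_features,
)
from .segment_eval import DEFAULT_MIN_OVERLAP
from .sequence_io import (
    ProteinRecord,
    Segment,
    read_fasta,
    read_segments,
    segments_to_labels,
)
from .som_cluster import (
    DEFAULT_COLS,
    DEFAULT_N_SAMPLES,
    DEFAULT_ROWS,
    SOMModel,
    assign,
    train_som,
)
from .synthetic_data import GeneratorParams, generate_dataset
from .tm_classifier import DEFAULT_SPAN, DEFAULT_THETA, window_classes

STRATEGIES = ("random", "coverage", "confusion", "alternating")


@dataclass
class RunConfig:
    """Fully serialisable description of one study."""

    # inputs: either files ...
    fasta: str | None = None
    segments: str | None = None
    test_fasta: str | None = None
    test_segments: str | None = None
    # ... or synthetic pools
    synthetic_pool: int = 160
    synthetic_test: int = 40
    # features
    window_length: int = DEFAULT_WINDOW_LENGTH
    svd_rank: int = DEFAULT_RANK
    property_table: str | None = None
    # SOM
    som_rows: int = DEFAULT_ROWS
    som_cols: int = DEFAULT_COLS
    som_samples: int = DEFAULT_N_SAMPLES
    # active learning
    strategies: tuple[str, ...] = STRATEGIES
    iterations: int = 10
    repeats: int = 10
    coverage_mode: str = "new"
    score_mode: str = "mean"
    unseen_entropy: str = "zero"
    # classifier / decoding
    theta: float = DEFAULT_THETA
    span: int = DEFAULT_SPAN
    min_len: int = 1
    min_overlap: int = DEFAULT_MIN_OVERLAP
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        if "strategies" in payload:
            payload["strategies"] = tuple(payload["strategies"])
        return cls(**payload)


def load_labeled_proteins(
    fasta: str | Path, segment_table: str | Path
) -> list[ProteinRecord]:
    """Read FASTA + segment table and attach per-residue gold labels."""
    records = read_fasta(fasta)
    segs = read_segments(segment_table)
    by_protein: dict[str, list[Segment]] = {}
    for s in segs:
        by_protein.setdefault(s.protein_id, []).append(s)
    out = []
    for rec in records:
        labels = segments_to_labels(rec, by_protein.get(rec.id, []))
        out.append(ProteinRecord(id=rec.id, sequence=rec.sequence, labels=labels))
    return out


def prepare_proteins(
    records: Sequence[ProteinRecord],
    table: PropertyTable,
    svd: SVDModel,
    som: SOMModel | None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> list[PreparedProtein]:
    """Project every protein's windows and assign them to SOM nodes."""
    prepared = []
    for rec in records:
        fs = project(window_features(rec, table, window_length), svd)
        nodes = assign(fs.projected, som) if som is not None else None
        classes = window_classes(rec.labels, window_length)
        prepared.append(
            PreparedProtein(record=rec, features=fs, nodes=nodes, classes=classes)
        )
    return prepared


def prepare_study(
    pool_records: Sequence[ProteinRecord],
    test_records: Sequence[ProteinRecord],
    config: RunConfig,
    seed: int,
) -> tuple[list[PreparedProtein], list[PreparedProtein], SVDModel, SOMModel]:
    """Fit SVD + SOM on the pool and prepare pool and test proteins."""
    table = (
        PropertyTable.from_file(config.property_table)
        if config.property_table
        else PropertyTable.default()
    )
    pool_feats = [
        window_features(rec, table, config.window_length) for rec in pool_records
    ]
    svd = fit_svd(pool_feats, k=config.svd_rank)
    for fs in pool_feats:
        project(fs, svd)
    som = train_som(
        np.concatenate([fs.projected for fs in pool_feats]),
        rows=config.som_rows,
        cols=config.som_cols,
        n_samples=config.som_samples,
        seed=seed,
    )
    pool = prepare_proteins(pool_records, table, svd, som, config.window_length)
    test = prepare_proteins(test_records, table, svd, som, config.window_length)
    return pool, test, svd, som


def _records_for_repeat(
    config: RunConfig, seed: int
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    if config.fasta:
        pool = load_labeled_proteins(config.fasta, config.segments)
        if config.test_fasta:
            test = load_labeled_proteins(config.test_fasta, config.test_segments)
        else:
            raise ValueError("file-based runs need test_fasta/test_segments")
        return pool, test
    pool_ds = generate_dataset(
        GeneratorParams(n_proteins=config.synthetic_pool, seed=seed)
    )
    test_ds = generate_dataset(
        GeneratorParams(n_proteins=config.synthetic_test, seed=seed + 500_000)
    )
    return [rec for rec, _ in pool_ds], [rec for rec, _ in test_ds]


def run_repeat(
    config: RunConfig, seed: int, strategies: Sequence[str] | None = None
) -> dict[str, LearningCurve]:
    """One repeat: build the study at ``seed`` and run each strategy on it."""
    strategies = tuple(strategies or config.strategies)
    pool_records, test_records = _records_for_repeat(config, seed)
    pool, test, _svd, som = prepare_study(pool_records, test_records, config, seed)
    nn_params = {"theta": config.theta, "span": config.span}
    return {
        strat: run_active_learning(
            pool,
            test,
            strategy=strat,
            n_iterations=config.iterations,
            n_nodes=som.n_nodes,
            seed=seed,
            min_overlap=config.min_overlap,
            min_len=config.min_len,
            coverage_mode=config.coverage_mode,  # type: ignore[arg-type]
            score_mode=config.score_mode,  # type: ignore[arg-type]
            unseen_entropy=config.unseen_entropy,  # type: ignore[arg-type]
            nn_params=nn_params,
        )
        for strat in strategies
    }


def pipeline_run(config: RunConfig, workdir: str | Path) -> pd.DataFrame:
    """Execute the full study and write curve.csv, mean_curve.csv, manifest.

    Returns the tidy per-repeat learning-curve DataFrame with columns
    (iteration, repeat, strategy, qok, recall, precision, fscore, q2,
    selected_id).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for rep in range(config.repeats):
        seed = config.seed + rep
        curves = run_repeat(config, seed)
        for strat, curve in curves.items():
            df = curve.to_dataframe()
            df.insert(1, "repeat", rep)
            frames.append(df)
    tidy = pd.concat(frames, ignore_index=True)
    tidy.to_csv(workdir / "curve.csv", index=False, float_format="%.6f")
    mean = (
        tidy.groupby(["strategy", "iteration"], as_index=False)[
            ["qok", "recall", "precision", "fscore", "q2"]
        ]
        .mean()
        .sort_values(["strategy", "iteration"])
    )
    mean.to_csv(workdir / "mean_curve.csv", index=False, float_format="%.6f")
    manifest = {
        "config": json.loads(config.to_json()),
        "version": __version__,
        "seeds": [config.seed + r for r in range(config.repeats)],
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return tidy
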