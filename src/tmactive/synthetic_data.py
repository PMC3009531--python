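"""Synthetic alpha-helical membrane proteins with gold TM annotations.

Generated proteins alternate polar-enriched loops with hydrophobic-enriched
transmembrane stretches — the two classical signals of TM helices: a helix
long enough (~20 residues) to cross the ~30 A bilayer, and strongly
hydrophobic composition.  Every protein starts and ends with a loop, so the
architecture is loop-(TM-loop) x n.  Residues are drawn i.i.d. from
per-region categorical distributions; there is no homology between proteins
and no attempt to match real membrane-protein statistics beyond the
hydrophobic/polar contrast, which is what makes windows fully inside TM vs
fully inside loops nearly linearly separable in the latent feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .sequence_io import ProteinRecord, Segment, write_fasta, write_segments

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: hydrophobic residues dominating TM helices
TM_ENRICHED = tuple("AILVFMGWC")
#: polar/charged/turn-forming residues dominating loops
LOOP_ENRICHED = tuple("DEKRNQSTPHGY")


def _composition(enriched: tuple[str, ...], mass: float) -> dict[str, float]:
    other = tuple(a for a in AMINO_ACIDS if a not in enriched)
    comp = {a: mass / len(enriched) for a in enriched}
    comp.update({a: (1.0 - mass) / len(other) for a in other})
    return comp


@dataclass
class GeneratorParams:
    """Dials of the generator; defaults define the standard study conditions.

    ``tm_count``, ``tm_length`` and ``loop_length`` are inclusive integer
    ranges sampled uniformly.  Compositions are categorical distributions
    over the 20 amino acids (normalised at construction).  ``label_noise``
    flips each residue label independently — the segment table always stays
    the true architecture, so with noise > 0 labels are deliberately
    inconsistent with segments (annotation-error simulation).
    """

    n_proteins: int = 160
    tm_count: tuple[int, int] = (1, 7)
    tm_length: tuple[int, int] = (17, 25)
    loop_length: tuple[int, int] = (8, 60)
    tm_composition: dict[str, float] = field(
        default_factory=lambda: _composition(TM_ENRICHED, 0.9)
    )
    loop_composition: dict[str, float] = field(
        default_factory=lambda: _composition(LOOP_ENRICHED, 0.9)
    )
    label_noise: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("tm_count", "tm_length", "loop_length"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: need 0 < lo <= hi, got ({lo},{hi})")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0,1]")
        for name in ("tm_composition", "loop_composition"):
            comp = dict(getattr(self, name))
            if set(comp) - set(AMINO_ACIDS):
                raise ValueError(f"{name}: unknown residues {set(comp) - set(AMINO_ACIDS)}")
            total = sum(comp.values())
            if total <= 0:
                raise ValueError(f"{name}: non-positive total mass")
            setattr(self, name, {a: comp[a] / total for a in sorted(comp)})

    def hard(self) -> "GeneratorParams":
        """Stress-test variant with a much weaker TM/loop contrast."""
        return GeneratorParams(
            n_proteins=self.n_proteins,
            tm_count=self.tm_count,
            tm_length=self.tm_length,
            loop_length=self.loop_length,
            tm_composition=_composition(TM_ENRICHED, 0.6),
            loop_composition=_composition(LOOP_ENRICHED, 0.6),
            label_noise=self.label_noise,
            seed=self.seed,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _sample_region(comp: dict[str, float], length: int, rng: np.random.Generator) -> str:
    letters = list(comp)
    probs = np.array([comp[a] for a in letters])
    return "".join(rng.choice(letters, size=length, p=probs))


def generate_protein(
    params: GeneratorParams, rng: np.random.Generator, protein_id: str = "syn0001"
) -> tuple[ProteinRecord, list[Segment]]:
    """One protein: loop-(TM-loop) x n architecture with gold labels.

    Segments mark exactly the TM spans; labels agree with segments unless
    ``label_noise`` > 0.
    """
    n_tm = int(rng.integers(params.tm_count[0], params.tm_count[1] + 1))
    parts: list[str] = []
    labels: list[np.ndarray] = []
    segments: list[Segment] = []
    pos = 0
    for i in range(n_tm + 1):
        loop_len = int(rng.integers(params.loop_length[0], params.loop_length[1] + 1))
        parts.append(_sample_region(params.loop_composition, loop_len, rng))
        labels.append(np.zeros(loop_len, dtype=np.int8))
        pos += loop_len
        if i < n_tm:
            tm_len = int(rng.integers(params.tm_length[0], params.tm_length[1] + 1))
            parts.append(_sample_region(params.tm_composition, tm_len, rng))
            labels.append(np.ones(tm_len, dtype=np.int8))
            segments.append(Segment(protein_id, pos + 1, pos + tm_len))
            pos += tm_len
    label_vec = np.concatenate(labels)
    if params.label_noise > 0:
        flip = rng.random(len(label_vec)) < params.label_noise
        label_vec = np.where(flip, 1 - label_vec, label_vec).astype(np.int8)
    record = ProteinRecord(id=protein_id, sequence="".join(parts), labels=label_vec)
    return record, segments


def generate_dataset(
    params: GeneratorParams,
) -> list[tuple[ProteinRecord, list[Segment]]]:
    """``n_proteins`` independent proteins, ids ``syn0001``..., seeded."""
    rng = np.random.default_rng(params.seed)
    return [
        generate_protein(params, rng, protein_id=f"syn{i + 1:04d}")
        for i in range(params.n_proteins)
    ]


def write_dataset(
    dataset: list[tuple[ProteinRecord, list[Segment]]],
    out_dir: str | Path,
    params: GeneratorParams | None = None,
    prefix: str = "synthetic",
) -> dict[str, Path]:
    """Write FASTA + segment table (+ params manifest) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{prefix}.fasta"
    table = out_dir / f"{prefix}.segments.tsv"
    write_fasta([rec for rec, _ in dataset], fasta)
    write_segments([s for _, segs in dataset for s in segs], table)
    paths = {"fasta": fasta, "segments": table}
    if params is not None:
        manifest = out_dir / f"{prefix}.params.json"
        manifest.write_text(params.to_json())
        paths["params"] = manifest
    return paths
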