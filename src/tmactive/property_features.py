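"""Amino-acid property window features and their SVD latent space.

Each residue is described by five categorical physicochemical properties
(charge, polarity, aromaticity, electronic property, size).  A sliding window
of length ``l`` (default 16) over the sequence yields, at every position, a
16-dimensional count vector: the number of residues in the window taking each
property value.  The 16 coordinates partition into 5 groups (3 charge +
2 polarity + 3 aromaticity + 5 electronic + 3 size values), so each group sums
to ``l`` exactly — the central invariant of the representation.

All window vectors of a protein pool are stacked into one matrix and factored
by singular value decomposition; window vectors (of pooled and of new
proteins alike) are then projected onto the top ``k`` (default 4) left
singular directions, which concentrate most of the variance ("energy") of the
counts.  The projection is a fixed linear map — the SVD is never refitted per
protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .sequence_io import ProteinRecord

DEFAULT_WINDOW_LENGTH = 16
DEFAULT_RANK = 4

#: The five properties and the fixed order of their values.  Flattened, this
#: enumerates the 16 feature coordinates: charge-positive, charge-negative,
#: charge-neutral, polarity-polar, polarity-nonpolar, aromaticity-aromatic,
#: aromaticity-aliphatic, aromaticity-neither, electronic strong-acceptor,
#: strong-donor, acceptor, donor, neutral, size-medium, size-small, size-big.
PROPERTY_VALUES: dict[str, tuple[str, ...]] = {
    "charge": ("positive", "negative", "neutral"),
    "polarity": ("polar", "nonpolar"),
    "aromaticity": ("aromatic", "aliphatic", "neither"),
    "electronic": ("strong-acceptor", "strong-donor", "acceptor", "donor", "neutral"),
    "size": ("medium", "small", "big"),
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{prop}-{val}" for prop, vals in PROPERTY_VALUES.items() for val in vals
)
N_FEATURES = len(FEATURE_NAMES)  # 16

#: slice of the 16 coordinates belonging to each property group
GROUP_SLICES: dict[str, slice] = {}
_off = 0
for _prop, _vals in PROPERTY_VALUES.items():
    GROUP_SLICES[_prop] = slice(_off, _off + len(_vals))
    _off += len(_vals)
del _off, _prop, _vals


class PropertyTable:
    """Total assignment of one value per property to each amino acid.

    The table is data, not code: it is loaded from a 6-column TSV (residue +
    five property values), so an alternative published assignment can be
    dropped in without touching the feature computation.
    """

    def __init__(self, assignment: Mapping[str, Mapping[str, str]]):
        self._indicator: dict[str, np.ndarray] = {}
        for aa, props in assignment.items():
            vec = np.zeros(N_FEATURES, dtype=np.int64)
            if set(props) != set(PROPERTY_VALUES):
                raise ValueError(f"{aa}: must assign exactly the properties {list(PROPERTY_VALUES)}")
            for prop, vals in PROPERTY_VALUES.items():
                val = props[prop]
                if val not in vals:
                    raise ValueError(f"{aa}: unknown {prop} value {val!r}")
                vec[GROUP_SLICES[prop].start + vals.index(val)] = 1
            self._indicator[aa.upper()] = vec

    @classmethod
    def from_file(cls, path: str | Path) -> "PropertyTable":
        assignment: dict[str, dict[str, str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns")
                aa, charge, polarity, aromaticity, electronic, size = parts
                assignment[aa] = {
                    "charge": charge,
                    "polarity": polarity,
                    "aromaticity": aromaticity,
                    "electronic": electronic,
                    "size": size,
                }
        return cls(assignment)

    @classmethod
    def default(cls) -> "PropertyTable":
        """The table shipped with the package (data/properties.tsv)."""
        ref = resources.files("tmactive").joinpath("data/properties.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def __contains__(self, aa: str) -> bool:
        return aa.upper() in self._indicator

    def indicator(self, aa: str) -> np.ndarray:
        """16-dim 0/1 vector with one 1 per property group."""
        try:
            return self._indicator[aa.upper()]
        except KeyError:
            raise KeyError(f"residue {aa!r} absent from property table") from None

    def encode(self, sequence: str) -> np.ndarray:
        """Per-residue indicator matrix of shape (L, 16)."""
        return np.stack([self.indicator(aa) for aa in sequence])


@dataclass
class FeatureSet:
    """Window features of one protein.

    ``raw`` holds one 16-dim count row per window position (window moved one
    residue at a time); ``projected`` is filled in by :func:`project`.
    ``window_starts`` are 0-based sequence positions of each window's first
    residue; sequence length is recoverable as ``window_starts[-1] +
    window_length``.
    """

    protein_id: str
    window_length: int
    raw: np.ndarray
    window_starts: np.ndarray
    projected: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.raw.shape[0]

    @property
    def sequence_length(self) -> int:
        return int(self.window_starts[-1]) + self.window_length


def window_features(
    protein: ProteinRecord,
    table: PropertyTable | None = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> FeatureSet:
    """Compute the 16-dim property-value counts for every window.

    Raises if the protein is shorter than the window.
    """
    table = table or PropertyTable.default()
    L, l = len(protein), window_length
    if L < l:
        raise ValueError(
            f"protein {protein.id!r} (length {L}) shorter than window length {l}"
        )
    onehot = table.encode(protein.sequence)  # (L, 16)
    csum = np.concatenate([np.zeros((1, N_FEATURES), dtype=np.int64), np.cumsum(onehot, axis=0)])
    raw = csum[l:] - csum[:-l]  # (L - l + 1, 16), exact integer counts
    return FeatureSet(
        protein_id=protein.id,
        window_length=l,
        raw=raw,
        window_starts=np.arange(L - l + 1),
    )


@dataclass
class SVDModel:
    """Fitted latent space of the pooled window-count matrix.

    ``U`` (16x16) are the left singular vectors of the pooled matrix with
    windows as columns; projecting a window row ``R`` is ``U[:, :k].T @ R``.
    The sign of each column of ``U`` is fixed so its largest-magnitude entry
    is positive, making projections reproducible across runs.
    """

    U: np.ndarray
    singular_values: np.ndarray
    k: int = DEFAULT_RANK

    @property
    def energy_fractions(self) -> np.ndarray:
        """Per-dimension fraction of total energy, S_j^2 / sum(S^2)."""
        s2 = self.singular_values**2
        return s2 / s2.sum()

    def energy_retained(self, k: int | None = None) -> float:
        """Cumulative energy fraction carried by the top-k dimensions."""
        k = self.k if k is None else k
        return float(self.energy_fractions[:k].sum())

    def save(self, path: str | Path) -> None:
        payload = {
            "U": self.U.tolist(),
            "singular_values": self.singular_values.tolist(),
            "k": self.k,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SVDModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            U=np.asarray(payload["U"], dtype=float),
            singular_values=np.asarray(payload["singular_values"], dtype=float),
            k=int(payload["k"]),
        )


def fit_svd(feature_sets: Iterable[FeatureSet], k: int = DEFAULT_RANK) -> SVDModel:
    """Factor the stacked raw window counts of a protein pool.

    Counts are used as-is — no centering or scaling.  ``k`` defaults to 4;
    the retained-energy report (:meth:`SVDModel.energy_retained`) lets users
    check how much variance the chosen rank carries on their pool.
    """
    mats = [fs.raw for fs in feature_sets]
    if not mats:
        raise ValueError("fit_svd: empty input")
    A = np.concatenate(mats, axis=0).astype(float)  # windows as rows
    # rows-as-windows SVD: A_rows = W diag(s) Vt, so the paper-orientation
    # left factor (windows as columns) is U = Vt.T
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    U = Vt.T
    # sign convention: largest-magnitude entry of each column of U positive
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    return SVDModel(U=U, singular_values=s, k=k)


def project(features: FeatureSet, model: SVDModel) -> FeatureSet:
    """Project raw window counts onto the top-k latent dimensions (in place).

    The projection of row ``R_i`` is the first ``k`` entries of ``U^T R_i``;
    the same fixed map applies to pooled and new proteins alike.
    """
    if features.raw.shape[1] != model.U.shape[0]:
        raise ValueError(
            f"dimension mismatch: features have {features.raw.shape[1]} dims, "
            f"model expects {model.U.shape[0]}"
        )
    features.projected = features.raw.astype(float) @ model.U[:, : model.k]
    return features
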