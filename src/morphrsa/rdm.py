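"""Representational dissimilarity matrices, Kendall tau-a, and noise ceilings.

Dissimilarity between condition patterns is 1 − Pearson correlation. RDMs are
rank-rescaled to [0, 1] with ties kept tied (average ranks, affine map).
Model–brain agreement is Kendall's tau-a — (concordant − discordant) over all
pairs, ties counting to neither — evaluated on a configurable cell set,
by default the 48 neutral × partial cross-condition cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.stats import rankdata

from .design import IDENTITIES, PRIOR_MORPH_COMBOS

__all__ = [
    "RDM",
    "NeuralPatterns",
    "rsa_condition_labels",
    "neutral_by_partial_cells",
    "rank01",
    "correlation_distance_matrix",
    "neural_rdm",
    "average_hemispheres",
    "kendall_tau_a",
    "noise_ceiling",
]


def rsa_condition_labels(identities: tuple[str, ...] = IDENTITIES) -> list[str]:
    """The 16 RSA condition labels: 4 neutral faces then the 12 prior×morph cells."""
    labels = [f"neutral:{i}" for i in identities]
    labels += [f"partial:{prior}:{pair}" for prior, pair in PRIOR_MORPH_COMBOS]
    return labels


def neutral_by_partial_cells(labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the neutral × partial block of a labeled RDM."""
    neutral = [i for i, l in enumerate(labels) if l.startswith("neutral:")]
    partial = [i for i, l in enumerate(labels) if l.startswith("partial:")]
    rows, cols = zip(*[(i, j) for i in neutral for j in partial])
    return np.asarray(rows), np.asarray(cols)


def lower_triangle_cells(labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    n = len(labels)
    rows, cols = np.tril_indices(n, k=-1)
    return rows, cols


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix with condition labels."""

    labels: list[str]
    matrix: np.ndarray
    scaling: str = "raw"  # 'raw' or 'rank01'
    source: str = "neural"  # 'neural' or 'hypothesis_{PE,sharpening,input}'
    layer_tag: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("RDM matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = m

    def rank_rescaled(self) -> "RDM":
        """Return a copy rescaled to [0, 1] via average ranks (ties stay tied)."""
        if self.scaling == "rank01":
            return self
        return RDM(self.labels, rank01(self.matrix), "rank01", self.source,
                   self.layer_tag)

    def cells(self, cell_idx: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        rows, cols = cell_idx
        return self.matrix[rows, cols]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            matrix=self.matrix,
            labels=np.asarray(self.labels, dtype=object),
            meta=np.asarray(
                json.dumps({"scaling": self.scaling, "source": self.source,
                            "layer_tag": self.layer_tag})
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RDM":
        with np.load(path, allow_pickle=True) as fh:
            meta = json.loads(str(fh["meta"]))
            return cls(list(fh["labels"]), fh["matrix"], **meta)


def rank01(matrix: np.ndarray) -> np.ndarray:
    """Rank-rescale off-diagonal dissimilarities to [0, 1], preserving ties."""
    m = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    # round at 1e-12 so floating-point fuzz does not break genuine ties
    vals = np.round(m[iu], 12)
    ranks = rankdata(vals, method="average")
    span = ranks.max() - ranks.min()
    scaled = np.full_like(ranks, 0.5) if span == 0 else (ranks - ranks.min()) / span
    out = np.zeros_like(m)
    out[iu] = scaled
    return out + out.T


def correlation_distance_matrix(patterns: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between the rows of a condition × feature matrix."""
    p = np.asarray(patterns, dtype=float)
    sd = p.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant pattern row at index {bad}: correlation undefined")
    d = 1.0 - np.corrcoef(p)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


@dataclass
class NeuralPatterns:
    """Condition × voxel response statistics (T-statistic semantics) for one region."""

    subject_id: str
    region_id: str
    hemisphere: str  # 'left' | 'right' | 'bilateral'
    matrix: np.ndarray
    condition_labels: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("pattern matrix must be conditions × voxels")
        if m.shape[0] != len(self.condition_labels):
            raise ValueError("condition label count does not match matrix rows")
        # voxels with any missing value are dropped listwise within the region
        keep = ~np.isnan(m).any(axis=0)
        m = m[:, keep]
        if m.shape[1] < 2:
            raise ValueError("need at least 2 usable voxels after masking")
        self.matrix = m


def neural_rdm(patterns: NeuralPatterns, rescale: bool = True) -> RDM:
    """Correlation-distance RDM of a region's condition patterns."""
    try:
        d = correlation_distance_matrix(patterns.matrix)
    except ValueError as err:
        idx = int(str(err).split("index ")[1].split(":")[0]) if "index" in str(err) else -1
        label = patterns.condition_labels[idx] if idx >= 0 else "?"
        raise ValueError(f"constant pattern for condition {label!r}") from err
    out = RDM(list(patterns.condition_labels), d, "raw", "neural")
    return out.rank_rescaled() if rescale else out


def average_hemispheres(rdm_left: RDM, rdm_right: RDM) -> RDM:
    """Cellwise mean of two hemispheric RDMs, rank-rescaled once afterwards.

    Averaging is intended to run on raw distances; rank-rescaling is applied
    to the mean (ranks of averaged ranks would be ill-defined).
    """
    if rdm_left.labels != rdm_right.labels:
        raise ValueError("hemispheric RDMs have different condition labels")
    if rdm_left.scaling != rdm_right.scaling:
        raise ValueError("hemispheric RDMs have different scaling states")
    mean = (rdm_left.matrix + rdm_right.matrix) / 2.0
    out = RDM(list(rdm_left.labels), mean, "raw", rdm_left.source,
              rdm_left.layer_tag)
    return out.rank_rescaled()


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-a: (concordant − discordant) / (m(m−1)/2).

    Tied pairs in either vector count to neither concordant nor discordant but
    remain in the denominator, making tau-a the appropriate rank correlation
    for dissimilarity vectors with tied ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 observations")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(m, k=1)
    cd = float(np.sum(sx[iu] * sy[iu]))
    return cd / (m * (m - 1) / 2.0)


def noise_ceiling(
    subject_rdms: list[RDM],
    comparison_cells: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """Lower/upper bounds on attainable model–brain tau-a given subject noise.

    Upper bound: mean over subjects of tau-a between each subject's RDM and
    the grand-mean RDM (the subject is included in the mean, optimistically).
    Lower bound: the same with a leave-one-out mean (the subject excluded).
    Both are evaluated on ``comparison_cells`` only (default: the full
    neutral × partial block).
    """
    if len(subject_rdms) < 2:
        raise ValueError("noise ceiling requires at least 2 subjects")
    labels = subject_rdms[0].labels
    if comparison_cells is None:
        comparison_cells = neutral_by_partial_cells(labels)
    vecs = np.stack([r.cells(comparison_cells) for r in subject_rdms])
    n = vecs.shape[0]
    grand = vecs.mean(axis=0)
    upper = float(np.mean([kendall_tau_a(v, grand) for v in vecs]))
    lower = float(
        np.mean(
            [
                kendall_tau_a(vecs[i], (grand * n - vecs[i]) / (n - 1))
                for i in range(n)
            ]
        )
    )
    return lower, upper
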