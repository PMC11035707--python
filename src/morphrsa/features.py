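"""Layer-activation feature banks for the four face identities and six morphs.

A :class:`FeatureBank` stands in for pooled convolutional-layer activations
(e.g. a pool4/pool5-style readout of a face-trained network): one vector per
clear identity and one per 50/50 morph. Synthetic banks are generated as
rectified Gaussians with a shared baseline; morph vectors are convex mixtures
of the parent identities, rectified. Real network activations can be imported
from an NPZ/HDF5 export and are used as-is (no rectification, may be signed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .design import IDENTITIES, MORPH_PAIRS

__all__ = [
    "FeatureBank",
    "make_identity_features",
    "morph_features",
    "make_feature_bank",
    "load_activation_export",
    "save_activation_export",
]


@dataclass
class FeatureBank:
    """Per-identity and per-morph activation vectors for one layer."""

    layer_tag: str
    identity_features: dict[str, np.ndarray]
    morph_features: dict[str, np.ndarray] = field(default_factory=dict)
    #: True for synthetic banks whose vectors are rectified (nonnegative).
    rectified: bool = True

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.identity_features.values()}
        dims |= {v.shape for v in self.morph_features.values()}
        if len(dims) > 1:
            raise ValueError(f"feature vectors have mismatched shapes: {dims}")
        for pair in self.morph_features:
            a, b = pair.split("+")
            if a not in self.identity_features or b not in self.identity_features:
                raise ValueError(f"morph {pair!r} references unknown identities")

    @property
    def dim(self) -> int:
        return next(iter(self.identity_features.values())).shape[0]

    @property
    def identities(self) -> tuple[str, ...]:
        return tuple(sorted(self.identity_features))

    def identity(self, ident: str) -> np.ndarray:
        try:
            return self.identity_features[ident]
        except KeyError:
            raise KeyError(f"unknown identity {ident!r}") from None

    def morph(self, pair: str) -> np.ndarray:
        key = "+".join(sorted(pair.split("+")))
        try:
            return self.morph_features[key]
        except KeyError:
            raise KeyError(f"unknown morph pair {key!r}") from None


def make_identity_features(
    n_identities: int = 4,
    dim: int = 128,
    distinctness: float = 1.0,
    seed: int = 0,
    layer_tag: str = "high",
) -> FeatureBank:
    """Synthesize rectified identity activation vectors.

    Each identity vector is ``relu(baseline + distinctness * idiosyncratic)``
    with a shared nonnegative baseline, so all identities are roughly equally
    distinct from each other (the coefficient of variation of the pairwise
    correlation distances is small for the defaults), mimicking a stimulus set
    of equally distinguishable faces.
    """
    if n_identities < 2:
        raise ValueError("need at least 2 identities")
    if dim < n_identities:
        raise ValueError("dim must be >= n_identities to guarantee distinctness")
    if not 0.0 < distinctness <= 1.0:
        raise ValueError("distinctness must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    def sparse_uniform() -> np.ndarray:
        # sparse nonnegative code with bounded dynamic range, emulating
        # contrast-normalized pooled post-ReLU activations
        return rng.binomial(1, 0.2, size=dim) * rng.uniform(0.5, 1.0, size=dim)

    common = sparse_uniform()
    names = [IDENTITIES[i] if i < len(IDENTITIES) else f"I{i}" for i in range(n_identities)]
    feats = {
        name: np.maximum(
            (1.0 - distinctness) * common + distinctness * sparse_uniform(), 0.0
        )
        for name in names
    }
    return FeatureBank(layer_tag=layer_tag, identity_features=feats)


def morph_features(bank: FeatureBank, pair: str, alpha: float = 0.5) -> np.ndarray:
    """Feature-level stand-in for a morph image's activations.

    Convex mixture ``alpha * F_A + (1 - alpha) * F_B`` of the parents
    (A = first identity of the sorted pair), rectified for rectified banks.
    ``alpha=1`` returns A's vector, ``alpha=0`` B's.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    a, b = sorted(pair.split("+"))
    vec = alpha * bank.identity(a) + (1.0 - alpha) * bank.identity(b)
    return np.maximum(vec, 0.0) if bank.rectified else vec


def make_feature_bank(
    n_identities: int = 4,
    dim: int = 128,
    distinctness: float = 1.0,
    seed: int = 0,
    layer_tag: str = "high",
) -> FeatureBank:
    """Synthetic bank with all identity vectors and all 50/50 morphs filled in."""
    bank = make_identity_features(n_identities, dim, distinctness, seed, layer_tag)
    import itertools

    for a, b in itertools.combinations(bank.identities, 2):
        pair = f"{a}+{b}"
        bank.morph_features[pair] = morph_features(bank, pair, 0.5)
    return bank


def save_activation_export(bank: FeatureBank, path: str | Path) -> None:
    """Write a bank to an HDF5 store (one group per layer tag)."""
    with h5py.File(path, "a") as fh:
        grp = fh.require_group(bank.layer_tag)
        grp.attrs["rectified"] = bank.rectified
        for name, vec in bank.identity_features.items():
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=vec)
        for name, vec in bank.morph_features.items():
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=vec)


def load_activation_export(
    path: str | Path,
    layer_tag: str,
    identities: tuple[str, ...] = IDENTITIES,
    pairs: tuple[str, ...] = MORPH_PAIRS,
) -> FeatureBank:
    """Load externally exported activations (HDF5, one group per layer).

    Imported vectors are taken verbatim — they may be signed, and no
    rectification is applied. Raises ``KeyError`` naming the first missing
    dataset, ``ValueError`` on length mismatches.
    """
    with h5py.File(path, "r") as fh:
        if layer_tag not in fh:
            raise KeyError(f"layer {layer_tag!r} not present in {path}")
        grp = fh[layer_tag]
        ident_feats, morph_feats = {}, {}
        for name in identities:
            if name not in grp:
                raise KeyError(f"missing identity dataset {layer_tag}/{name}")
            ident_feats[name] = np.asarray(grp[name])
        for pair in pairs:
            if pair not in grp:
                raise KeyError(f"missing morph dataset {layer_tag}/{pair}")
            morph_feats[pair] = np.asarray(grp[pair])
        rectified = bool(grp.attrs.get("rectified", False))
    return FeatureBank(
        layer_tag=layer_tag,
        identity_features=ident_feats,
        morph_features=morph_feats,
        rectified=rectified,
    )
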