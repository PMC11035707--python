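"""Prediction-Error, Sharpening, and Sensory-Input hypothesis representations.

Each hypothesis model states how a prior face representation combines with the
activation of an ambiguous 50/50 morph:

* Prediction Error: ``PE = morph − prior · precision`` — the precision-weighted
  prior is subtracted, leaving the unexpected residual.
* Sharpening: prior-congruent features of the input are multiplicatively
  enhanced, ``morph · (1 + prior · precision)``, with sign rules for signed
  activations and a compressive log transform.
* Sensory Input: the morph activation unchanged — no prior influence.

A hypothesis RDM covers 16 conditions (4 neutral faces with pure identity
vectors + 12 prior×morph partial conditions with model-combined vectors),
with 1 − Pearson correlation distances, rank-rescaled to [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np

from .design import PRIOR_MORPH_COMBOS, PrecisionTable
from .features import FeatureBank
from .rdm import RDM, correlation_distance_matrix, rsa_condition_labels

__all__ = [
    "MODELS",
    "combine_pe",
    "combine_sharpening",
    "sensory_input_vector",
    "build_hypothesis_rdm",
]

MODELS = ("PE", "sharpening", "input")


def _check_pair(morph: np.ndarray, prior: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    morph = np.asarray(morph, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if morph.shape != prior.shape:
        raise ValueError(
            f"morph and prior have different lengths ({morph.shape} vs {prior.shape})"
        )
    return morph, prior


def combine_pe(morph: np.ndarray, prior: np.ndarray, precision: float) -> np.ndarray:
    """Prediction-error representation: elementwise ``morph − prior·precision``."""
    morph, prior = _check_pair(morph, prior)
    return morph - prior * precision


def signed_log1p(x: np.ndarray) -> np.ndarray:
    """Sign-preserving compressive transform ``sign(x)·log(1+|x|)``.

    Monotone, zero-preserving stand-in for the plain log used to tame large
    products of activations; defined at 0 where log is not.
    """
    return np.sign(x) * np.log1p(np.abs(x))


def combine_sharpening(
    morph: np.ndarray,
    prior: np.ndarray,
    precision: float,
    log_mode: str = "signed_log1p",
    log_eps: float = 1e-6,
) -> np.ndarray:
    """Sharpening representation with sign rules for signed activations.

    The prior is first rescaled by its maximum absolute entry (so the
    dampening factor below cannot go negative). Where input and prior share a
    sign (or either is zero) the input is sharpened — multiplied by
    ``1 + |prior_i|·precision``, preserving its sign, so a positive precision
    enhances congruent features and a negative (contrastive) precision dampens
    them. Where the signs are opposite the input is dampened by
    ``1 − |prior_i·precision|``. Finally a compressive log transform is
    applied: sign-preserving log1p by default, or ``log(|y|+eps)`` on
    magnitudes (``log_mode='log_eps'``).
    """
    morph, prior = _check_pair(morph, prior)
    if not -1.0 <= precision <= 1.0:
        raise ValueError("precision must lie in [-1, 1]")
    pmax = np.max(np.abs(prior))
    p = prior / pmax if pmax > 0 else prior  # all-zero prior: q = 0
    congruent = (np.sign(morph) == np.sign(p)) | (morph == 0) | (p == 0)
    mult = np.where(
        congruent,
        1.0 + np.abs(p) * precision,
        1.0 - np.abs(p * precision),
    )
    y = morph * mult
    if log_mode == "signed_log1p":
        return signed_log1p(y)
    if log_mode == "log_eps":
        return np.sign(y) * np.log(np.abs(y) + log_eps)
    raise ValueError(f"unknown log_mode {log_mode!r}")


def sensory_input_vector(morph: np.ndarray) -> np.ndarray:
    """Sensory-Input representation: the morph activation, prior-free."""
    return np.asarray(morph, dtype=float).copy()


def _model_vector(
    model: str,
    morph_vec: np.ndarray,
    prior_vec: np.ndarray,
    precision: float,
    log_mode: str,
) -> np.ndarray:
    if model == "PE":
        return combine_pe(morph_vec, prior_vec, precision)
    if model == "sharpening":
        return combine_sharpening(morph_vec, prior_vec, precision, log_mode)
    if model == "input":
        return sensory_input_vector(morph_vec)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def build_hypothesis_rdm(
    bank: FeatureBank,
    precisions: PrecisionTable,
    model: str,
    layer_tag: str | None = None,
    log_mode: str = "signed_log1p",
    rescale: bool = True,
) -> RDM:
    """Assemble a 16-condition hypothesis RDM for one model and layer.

    Neutral conditions carry the pure identity activation vectors; each of the
    12 partial conditions carries the model's combination of the morph and the
    (behaviorally precision-weighted) prior identity vector. Distances are
    1 − Pearson correlation, rank-rescaled to [0, 1]. Conditions whose
    precision is missing are dropped with a warning.
    """
    labels = rsa_condition_labels(tuple(bank.identities[:4]))
    vectors: list[np.ndarray] = []
    kept: list[str] = []
    for label in labels:
        if label.startswith("neutral:"):
            vec = bank.identity(label.split(":")[1])
        else:
            _, prior, pair = label.split(":")
            precision = precisions.get(prior, pair)
            if np.isnan(precision):
                warnings.warn(
                    f"missing precision for prior={prior} pair={pair}; "
                    "condition dropped from hypothesis RDM"
                )
                continue
            vec = _model_vector(model, bank.morph(pair), bank.identity(prior),
                                precision, log_mode)
        if np.std(vec) == 0:
            raise ValueError(f"condition {label!r} has a constant vector; "
                             "correlation distance undefined")
        vectors.append(vec)
        kept.append(label)
    matrix = correlation_distance_matrix(np.stack(vectors))
    out = RDM(kept, matrix, "raw", f"hypothesis_{model}",
              layer_tag or bank.layer_tag)
    return out.rank_rescaled() if rescale else out
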