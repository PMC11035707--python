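"""Synthetic cohorts with a known generative mechanism.

Behavior: on each partial (morph) trial the expected identity is reported with
probability (1 + w)/2, where w in [-1, 1] is the subject's prior-use weight,
so the expected value of the behavioral precision estimator equals w exactly.
Reaction times are log-normal with condition-specific means.

Patterns: condition × voxel responses are a linear voxel encoding of the
mechanism's feature-space representation plus iid Gaussian noise,
``pattern(c) = W · center(f_mechanism(c)) + eps``. By default W is a random
isometry whose columns are orthogonal to the constant vector, which preserves
pattern Pearson correlations exactly — in the noiseless limit the neural RDM
equals the matching hypothesis RDM. ``noise_sd`` is dimensionless
(noise-to-signal norm ratio). Neutral conditions always carry the pure
identity vectors; partial conditions carry the mechanism's combination at the
subject's true precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import (
    DesignConfig,
    PrecisionTable,
    TrialTable,
    compute_precision,
    generate_block_design,
)
from .features import (
    FeatureBank,
    make_feature_bank,
    morph_features,
    save_activation_export,
    load_activation_export,
)
from .hypotheses import MODELS, _model_vector
from .rdm import NeuralPatterns, rsa_condition_labels

__all__ = [
    "SimulationConfig",
    "RTParams",
    "simulate_behavior",
    "encoding_matrix",
    "simulate_patterns",
    "simulate_cohort",
    "simulate_searchlight_volume",
    "Cohort",
    "SubjectData",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class RTParams:
    """Log-normal RT means/SDs (ms) per condition, matching the study's scale."""

    match_mean: float = 591.0
    mismatch_mean: float = 727.0
    neutral_mean: float = 600.0
    partial_confirm_mean: float = 670.0
    partial_contrast_mean: float = 784.0
    catch_mean: float = 700.0
    sd: float = 100.0


@dataclass(frozen=True)
class SimulationConfig:
    """Fully determines a synthetic cohort given the master seed."""

    mechanism: str = "PE"
    n_subjects: int = 20
    n_voxels: int = 200
    noise_sd: float = 2.8
    prior_use_mean: float = 0.35
    prior_use_sd: float = 0.2
    feature_dim: int = 128
    distinctness: float = 1.0
    n_blocks: int = 4
    seed: int = 0
    layer_tag: str = "high"
    regions: tuple[str, ...] = ("region1",)
    hemispheres: tuple[str, ...] = ("bilateral",)
    invalid_rate: float = 0.04
    lapse_rate: float = 0.02
    share_design: bool = True
    #: Idiosyncratic deviation of each subject's neural feature tuning from
    #: the shared stimulus feature bank (0 = all subjects encode the shared
    #: bank exactly). This between-subject representational variability is
    #: what bounds the noise ceiling in real multi-subject RSA.
    subject_jitter: float = 0.4
    #: SD of each subject's perceptual 50/50 morph point around 0.5. Morph
    #: stimuli are calibrated per subject, so the physical mixture a subject
    #: sees deviates from the canonical 50/50 morph the hypothesis models use.
    morph_alpha_sd: float = 0.12
    #: Fraction of stimulus feature dimensions each subject's region actually
    #: encodes (subject-specific random subset). Idiosyncratic feature
    #: sampling decorrelates subjects' RDMs — and thereby lowers the noise
    #: ceiling — without adding within-subject measurement noise.
    feature_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in MODELS:
            raise ValueError(f"mechanism must be one of {MODELS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    mu = np.log(mean**2 / np.sqrt(sd**2 + mean**2))
    sigma = np.sqrt(np.log(1 + sd**2 / mean**2))
    return rng.lognormal(mu, sigma, size=size)


def simulate_behavior(
    w: float,
    design: TrialTable,
    seed: int = 0,
    rt_params: RTParams = RTParams(),
    invalid_rate: float = 0.04,
    lapse_rate: float = 0.02,
    response_model: str = "linear",
) -> TrialTable:
    """Fill in responses and RTs for a designed trial sequence.

    Partial trials: the expected identity is reported with probability
    (1 + w)/2 (``response_model='linear'``) or a logistic link on w
    (``'logistic'``); with probability ``invalid_rate`` the response instead
    names an identity outside the morph (excluded from precision counts).
    Match/mismatch/catch responses are correct up to ``lapse_rate``.
    """
    if not -1.0 <= w <= 1.0:
        raise ValueError("w must lie in [-1, 1]")
    if response_model == "linear":
        p_expected = np.clip(0.5 + 0.5 * w, 0.0, 1.0)
    elif response_model == "logistic":
        p_expected = 1.0 / (1.0 + np.exp(-2.5 * w))
    else:
        raise ValueError(f"unknown response_model {response_model!r}")
    rng = np.random.default_rng(seed)
    df = design.data.copy()
    idents = set("ABCD")
    responses, rts, valids = [], [], []
    for cond, prior, stim in zip(df["condition"], df["prior"], df["stimulus"]):
        resp, rt, valid = "none", np.nan, False
        if cond == "partial":
            a, b = stim.split("+")
            other = b if prior == a else a
            if rng.random() < invalid_rate:
                resp = rng.choice(sorted(idents - {a, b}))
            elif rng.random() < p_expected:
                resp = prior
            else:
                resp = other
            mean = (rt_params.partial_confirm_mean if resp == prior
                    else rt_params.partial_contrast_mean)
            rt, valid = float(_lognormal(rng, mean, rt_params.sd)), True
        elif cond in ("match", "mismatch"):
            shown = stim
            resp = shown if rng.random() > lapse_rate else rng.choice(
                sorted(idents - {shown}))
            mean = rt_params.match_mean if cond == "match" else rt_params.mismatch_mean
            rt, valid = float(_lognormal(rng, mean, rt_params.sd)), True
        elif cond == "neutral":
            resp = "any"
            rt, valid = float(_lognormal(rng, rt_params.neutral_mean, rt_params.sd)), True
        elif cond == "catch":
            resp = prior
            rt, valid = float(_lognormal(rng, rt_params.catch_mean, rt_params.sd)), True
        elif cond == "neutral_catch":
            resp = "all"
            rt, valid = float(_lognormal(rng, rt_params.catch_mean, rt_params.sd)), True
        responses.append(resp)
        rts.append(rt)
        valids.append(valid)
    df["response"] = responses
    df["rt_ms"] = rts
    df["valid"] = valids
    return TrialTable(df)


def calibrate_morphs(bank: FeatureBank, alpha_sd: float, seed: int) -> FeatureBank:
    """A subject's individually calibrated morph stimuli.

    Each morph pair's physical mixing weight is drawn around the canonical
    0.5 (clipped to [0.2, 0.8]), emulating the per-subject psychophysical
    calibration of the perceptual 50/50 point. Identity vectors are shared.
    """
    if alpha_sd == 0:
        return bank
    rng = np.random.default_rng(seed)
    out = FeatureBank(bank.layer_tag, dict(bank.identity_features),
                      rectified=bank.rectified)
    for pair in bank.morph_features:
        alpha = float(np.clip(rng.normal(0.5, alpha_sd), 0.2, 0.8))
        out.morph_features[pair] = morph_features(out, pair, alpha)
    return out


def jitter_bank(bank: FeatureBank, jitter: float, seed: int) -> FeatureBank:
    """A subject's idiosyncratic version of a shared feature bank.

    Each identity vector is perturbed by rectified Gaussian noise scaled to
    ``jitter`` times the feature standard deviation; morph vectors are
    re-derived as 50/50 mixtures of the perturbed identities. ``jitter=0``
    returns the bank unchanged.
    """
    if jitter == 0:
        return bank
    rng = np.random.default_rng(seed)
    feats = {}
    for name, vec in bank.identity_features.items():
        sd = float(vec.std())
        feats[name] = np.maximum(vec + jitter * sd * rng.normal(size=vec.shape), 0.0)
    out = FeatureBank(bank.layer_tag, feats, rectified=bank.rectified)
    for pair in bank.morph_features:
        a, b = pair.split("+")
        out.morph_features[pair] = 0.5 * feats[a] + 0.5 * feats[b]
    return out


def encoding_matrix(dim: int, n_voxels: int, rng: np.random.Generator) -> np.ndarray:
    """Random linear voxel encoding W (n_voxels × dim).

    When n_voxels >= dim + 2, W is an isometry with zero column sums (QR of a
    column-centered Gaussian), so voxel-pattern Pearson correlations of
    centered feature vectors equal their feature-space correlations exactly.
    Otherwise a plain Gaussian W/sqrt(dim) is used and correlations are only
    approximately preserved.
    """
    g = rng.normal(size=(n_voxels, dim))
    if n_voxels >= dim + 2:
        g -= g.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(g)
        return q
    return g / np.sqrt(dim)


def _mechanism_vectors(
    bank: FeatureBank,
    mechanism: str,
    precisions: PrecisionTable,
) -> np.ndarray:
    labels = rsa_condition_labels(tuple(bank.identities[:4]))
    vecs = []
    for label in labels:
        if label.startswith("neutral:"):
            vecs.append(bank.identity(label.split(":")[1]))
        else:
            _, prior, pair = label.split(":")
            prec = precisions.get(prior, pair)
            vecs.append(_model_vector(mechanism, bank.morph(pair),
                                      bank.identity(prior), prec, "signed_log1p"))
    return np.stack(vecs)


def simulate_patterns(
    bank: FeatureBank,
    mechanism: str,
    true_precision: PrecisionTable,
    n_voxels: int = 200,
    noise_sd: float = 3.0,
    seed: int = 0,
    subject_id: str = "sub-01",
    region_id: str = "region1",
    hemisphere: str = "bilateral",
    feature_frac: float = 1.0,
) -> NeuralPatterns:
    """Simulate condition × voxel T-patterns under one generative mechanism.

    ``feature_frac`` < 1 restricts the region's encoding to a random subset
    of the feature dimensions (at least 8), modeling idiosyncratic neural
    sampling of the stimulus feature space.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 < feature_frac <= 1:
        raise ValueError("feature_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    vecs = _mechanism_vectors(bank, mechanism, true_precision)
    if feature_frac < 1.0:
        n_keep = max(8, int(round(feature_frac * vecs.shape[1])))
        keep = rng.choice(vecs.shape[1], size=n_keep, replace=False)
        vecs = vecs[:, keep]
    centered = vecs - vecs.mean(axis=1, keepdims=True)
    w_mat = encoding_matrix(centered.shape[1], n_voxels, rng)
    signal = centered @ w_mat.T
    scale = float(np.mean(np.linalg.norm(centered, axis=1)))
    noise = rng.normal(scale=noise_sd * scale / np.sqrt(n_voxels),
                       size=signal.shape) if noise_sd > 0 else 0.0
    return NeuralPatterns(
        subject_id=subject_id,
        region_id=region_id,
        hemisphere=hemisphere,
        matrix=signal + noise,
        condition_labels=rsa_condition_labels(tuple(bank.identities[:4])),
    )


@dataclass
class SubjectData:
    subject_id: str
    w_true: float
    trials: TrialTable
    precision_true: PrecisionTable
    precision_est: PrecisionTable
    patterns: dict[str, dict[str, NeuralPatterns]]  # region -> hemisphere -> patterns


@dataclass
class Cohort:
    config: SimulationConfig
    bank: FeatureBank
    subjects: list[SubjectData]
    ground_truth: dict


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a full cohort: behavior, precision, and multivoxel patterns.

    Per subject: draw the prior-use weight w from a clipped normal
    distribution, simulate behavior, derive the estimated (behavioral) and
    true precision tables, then simulate patterns per region and hemisphere
    with subject-specific encoding matrices. Bit-reproducible for a fixed
    config; seed substreams are spawned per subject and region so the cohort
    is reproducible under any execution order.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    bank_seed, design_seed, *subject_seeds = ss.spawn(2 + cfg.n_subjects)
    bank = make_feature_bank(4, cfg.feature_dim, cfg.distinctness,
                             seed=bank_seed.generate_state(1)[0] % (2**31),
                             layer_tag=cfg.layer_tag)
    design_cfg = DesignConfig()
    shared_blocks = None
    if cfg.share_design:
        dseeds = design_seed.generate_state(cfg.n_blocks) % (2**31)
        shared_blocks = [
            generate_block_design(design_cfg, seed=int(s), block=b)
            for b, s in enumerate(dseeds)
        ]
    subjects = []
    for si, sub_ss in enumerate(subject_seeds):
        rng = np.random.default_rng(sub_ss)
        w = float(np.clip(rng.normal(cfg.prior_use_mean, cfg.prior_use_sd), -1, 1))
        if shared_blocks is not None:
            blocks = shared_blocks
        else:
            dseeds = rng.integers(0, 2**31, size=cfg.n_blocks)
            blocks = [generate_block_design(design_cfg, seed=int(s), block=b)
                      for b, s in enumerate(dseeds)]
        behav_seed = int(rng.integers(0, 2**31))
        trials = TrialTable.concat(
            [simulate_behavior(w, blk, seed=behav_seed + b,
                               invalid_rate=cfg.invalid_rate,
                               lapse_rate=cfg.lapse_rate)
             for b, blk in enumerate(blocks)]
        )
        prec_true = PrecisionTable.constant(w)
        prec_est = compute_precision(trials, mode="pooled",
                                     response_window_ms=design_cfg.response_window_ms)
        sub_bank = jitter_bank(bank, cfg.subject_jitter,
                               seed=int(rng.integers(0, 2**31)))
        sub_bank = calibrate_morphs(sub_bank, cfg.morph_alpha_sd,
                                    seed=int(rng.integers(0, 2**31)))
        patterns: dict[str, dict[str, NeuralPatterns]] = {}
        for region in cfg.regions:
            patterns[region] = {}
            for hemi in cfg.hemispheres:
                pseed = int(rng.integers(0, 2**31))
                patterns[region][hemi] = simulate_patterns(
                    sub_bank, cfg.mechanism, prec_true,
                    n_voxels=cfg.n_voxels, noise_sd=cfg.noise_sd, seed=pseed,
                    subject_id=f"sub-{si + 1:02d}", region_id=region,
                    hemisphere=hemi, feature_frac=cfg.feature_frac,
                )
        subjects.append(SubjectData(
            subject_id=f"sub-{si + 1:02d}", w_true=w, trials=trials,
            precision_true=prec_true, precision_est=prec_est,
            patterns=patterns,
        ))
    ground_truth = {
        "mechanism": cfg.mechanism,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "w_true": {s.subject_id: s.w_true for s in subjects},
    }
    return Cohort(config=cfg, bank=bank, subjects=subjects,
                  ground_truth=ground_truth)


def simulate_searchlight_volume(
    bank: FeatureBank,
    mechanism: str,
    precision: float,
    shape: tuple[int, int, int] = (10, 10, 10),
    planted: tuple[slice, slice, slice] = (slice(3, 6), slice(3, 6), slice(3, 6)),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """A condition × volume array with one mechanism-encoding planted region.

    Voxels inside ``planted`` carry the mechanism's signal plus noise; all
    other voxels are pure noise of the same amplitude. Returns an array of
    shape (16, *shape).
    """
    rng = np.random.default_rng(seed)
    labels = rsa_condition_labels(tuple(bank.identities[:4]))
    vol = np.zeros((len(labels),) + tuple(shape))
    planted_mask = np.zeros(shape, dtype=bool)
    planted_mask[planted] = True
    n_planted = int(planted_mask.sum())
    prec = PrecisionTable.constant(precision)
    vecs = _mechanism_vectors(bank, mechanism, prec)
    centered = vecs - vecs.mean(axis=1, keepdims=True)
    w_mat = encoding_matrix(bank.dim, n_planted, rng)
    signal = centered @ w_mat.T
    scale = float(np.mean(np.linalg.norm(centered, axis=1)))
    sd = noise_sd * scale / np.sqrt(n_planted)
    vol[:, planted_mask] = signal
    vol += rng.normal(scale=sd, size=vol.shape)
    return vol


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort in the analysis modules' on-disk layout.

    ``bank.h5`` (activations), per-subject ``behavior.tsv`` and
    ``patterns.h5`` (region/hemisphere groups with a condition-label
    attribute), and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_activation_export(cohort.bank, out / "bank.h5")
    (out / "config.json").write_text(json.dumps(asdict(cohort.config), indent=2))
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=2))
    for sub in cohort.subjects:
        sdir = out / sub.subject_id
        sdir.mkdir(exist_ok=True)
        sub.trials.to_tsv(sdir / "behavior.tsv")
        with h5py.File(sdir / "patterns.h5", "w") as fh:
            for region, hemis in sub.patterns.items():
                for hemi, pat in hemis.items():
                    ds = fh.create_dataset(f"{region}/{hemi}", data=pat.matrix)
                    ds.attrs["condition_labels"] = json.dumps(pat.condition_labels)


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    cfg = SimulationConfig(**json.loads((src / "config.json").read_text()))
    # json round-trips tuples as lists
    cfg = SimulationConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in json.loads((src / "config.json").read_text()).items()
    })
    ground_truth = json.loads((src / "ground_truth.json").read_text())
    bank = load_activation_export(src / "bank.h5", cfg.layer_tag)
    subjects = []
    for sdir in sorted(src.glob("sub-*")):
        trials = TrialTable.from_tsv(sdir / "behavior.tsv")
        w = float(ground_truth["w_true"][sdir.name])
        patterns: dict[str, dict[str, NeuralPatterns]] = {}
        with h5py.File(sdir / "patterns.h5", "r") as fh:
            for region in fh:
                patterns[region] = {}
                for hemi in fh[region]:
                    ds = fh[region][hemi]
                    patterns[region][hemi] = NeuralPatterns(
                        subject_id=sdir.name, region_id=region, hemisphere=hemi,
                        matrix=np.asarray(ds),
                        condition_labels=json.loads(ds.attrs["condition_labels"]),
                    )
        subjects.append(SubjectData(
            subject_id=sdir.name, w_true=w, trials=trials,
            precision_true=PrecisionTable.constant(w),
            precision_est=compute_precision(trials),
            patterns=patterns,
        ))
    return Cohort(config=cfg, bank=bank, subjects=subjects,
                  ground_truth=ground_truth)
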