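"""Trial design generation and behavioral quantities.

The experiment pairs predictive scene cues with face images. Each block mixes
seven trial types:

* ``match`` — cued face shown,
* ``partial`` — a 50/50 two-identity morph that always contains the cued face,
* ``mismatch`` — a different face than cued,
* ``catch`` — a question mark; subjects report the cued identity,
* ``neutral`` — non-predictive cue followed by any face,
* ``neutral_catch`` — question mark after the neutral cue,
* ``null`` — fixation only.

From the responses on partial trials this module derives the behavioral
quantities that parameterize the hypothesis models: the per-morph *prior
precision* (n_prior − n_otherpart)/n in [−1, 1], the assimilation index
(percent of morph responses naming the expected identity), and the reaction
time split between prior-confirming and contrastive responses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IDENTITIES",
    "MORPH_PAIRS",
    "DesignConfig",
    "DesignError",
    "TrialTable",
    "PrecisionTable",
    "generate_block_design",
    "compute_precision",
    "assimilation_index",
    "split_partial_rts",
]

IDENTITIES: tuple[str, ...] = ("A", "B", "C", "D")

QUESTION_MARK = "question_mark"
NEUTRAL = "neutral"
NONE = "none"

#: Canonical sorted encoding of the six unordered 50/50 morph pairs.
MORPH_PAIRS: tuple[str, ...] = tuple(
    "+".join(p) for p in itertools.combinations(IDENTITIES, 2)
)

#: The 12 valid (prior, morph) combinations: the morph always contains the prior.
PRIOR_MORPH_COMBOS: tuple[tuple[str, str], ...] = tuple(
    (ident, pair)
    for ident in IDENTITIES
    for pair in MORPH_PAIRS
    if ident in pair.split("+")
)

TRIAL_COLUMNS = [
    "trial_index",
    "block",
    "condition",
    "prior",
    "stimulus",
    "response",
    "rt_ms",
    "valid",
]


class DesignError(RuntimeError):
    """Raised when a block satisfying the randomization constraints cannot be built."""


@dataclass(frozen=True)
class DesignConfig:
    """Per-block condition counts and randomization constraints.

    Defaults reproduce the study design: 107 experimental trials
    (16 match / 48 partial / 12 mismatch / 12 catch / 16 neutral /
    3 neutral catch) plus 36 null events per block, with no face identity
    present on more than 4 consecutive trials and at most 2 consecutive
    null trials.
    """

    n_match: int = 16
    n_partial: int = 48
    n_mismatch: int = 12
    n_catch: int = 12
    n_neutral: int = 16
    n_neutral_catch: int = 3
    n_null: int = 36
    max_identity_run: int = 4
    max_null_run: int = 2
    response_window_ms: float = 1500.0
    max_attempts: int = 10_000
    identities: tuple[str, ...] = IDENTITIES

    @property
    def n_experimental(self) -> int:
        return (
            self.n_match
            + self.n_partial
            + self.n_mismatch
            + self.n_catch
            + self.n_neutral
            + self.n_neutral_catch
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "identities" in kwargs:
            kwargs["identities"] = tuple(kwargs["identities"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["identities"] = list(self.identities)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class TrialTable:
    """Per-trial records for one subject (one or more blocks)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"TrialTable missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def experimental(self) -> pd.DataFrame:
        return self.data[self.data["condition"] != "null"]

    @property
    def partial(self) -> pd.DataFrame:
        return self.data[self.data["condition"] == "partial"]

    def condition_counts(self, block: int | None = None) -> dict[str, int]:
        df = self.data if block is None else self.data[self.data["block"] == block]
        return df["condition"].value_counts().to_dict()

    @staticmethod
    def concat(tables: list["TrialTable"]) -> "TrialTable":
        return TrialTable(pd.concat([t.data for t in tables], ignore_index=True))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrialTable":
        # 'null'/'none' are real condition values, not missing data
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
        df["valid"] = df["valid"].astype(str).str.lower().isin(("true", "1"))
        return cls(df)


def _stimulus_identities(stimulus: str) -> tuple[str, ...]:
    """Identities visually present in a stimulus ('' entries carry no face)."""
    if stimulus in (QUESTION_MARK, NONE) or not isinstance(stimulus, str):
        return ()
    if "+" in stimulus:
        return tuple(stimulus.split("+"))
    return (stimulus,)


def _check_runs(seq: list[tuple[str, str]], cfg: DesignConfig) -> str | None:
    """Return a description of the first violated run constraint, or None.

    ``seq`` holds (condition, stimulus) tuples in presentation order.
    """
    run_counts: dict[str, int] = {i: 0 for i in cfg.identities}
    null_run = 0
    for cond, stim in seq:
        if cond == "null":
            null_run += 1
            if null_run > cfg.max_null_run:
                return f"more than {cfg.max_null_run} consecutive null trials"
        else:
            null_run = 0
        present = set(_stimulus_identities(stim))
        for ident in cfg.identities:
            if ident in present:
                run_counts[ident] += 1
                if run_counts[ident] > cfg.max_identity_run:
                    return (
                        f"identity {ident} present on more than "
                        f"{cfg.max_identity_run} consecutive trials"
                    )
            else:
                run_counts[ident] = 0
    return None


def _cycle_assign(items: list, n: int, rng: np.random.Generator) -> list:
    """Assign n slots over items as evenly as possible, random remainder."""
    if n == 0:
        return []
    if not items:
        raise ValueError("no stimuli available for a nonzero condition count")
    reps, rem = divmod(n, len(items))
    out = list(items) * reps
    if rem:
        picked = rng.choice(len(items), size=min(rem, len(items)), replace=False)
        out += [items[int(i)] for i in picked]
    return out


def generate_block_design(
    config: DesignConfig | None = None,
    seed: int = 0,
    block: int = 0,
) -> TrialTable:
    """Generate one pseudo-randomized block of trials.

    Trials are composed per the configured condition counts and then the full
    block order is rejection-resampled until no face identity (clear face or
    within-morph) appears on more than ``max_identity_run`` consecutive trials
    and at most ``max_null_run`` null trials are consecutive. Deterministic for
    a fixed seed.

    Raises
    ------
    DesignError
        If no valid ordering is found within ``config.max_attempts`` attempts.
    """
    cfg = config or DesignConfig()
    for n in (cfg.n_match, cfg.n_partial, cfg.n_mismatch, cfg.n_catch,
              cfg.n_neutral, cfg.n_neutral_catch, cfg.n_null):
        if n < 0:
            raise ValueError("condition counts must be nonnegative")
    rng = np.random.default_rng(seed)
    idents = list(cfg.identities)
    combos = [
        (i, p) for i, p in
        ((i, "+".join(sorted(pr))) for i in idents
         for pr in itertools.combinations(idents, 2) if i in pr)
    ]

    trials: list[tuple[str, str, str]] = []  # (condition, prior, stimulus)
    for ident in _cycle_assign(idents, cfg.n_match, rng):
        trials.append(("match", ident, ident))
    for prior, pair in _cycle_assign(combos, cfg.n_partial, rng):
        trials.append(("partial", prior, pair))
    mismatch_pairs = [(a, b) for a in idents for b in idents if a != b]
    for prior, stim in _cycle_assign(mismatch_pairs, cfg.n_mismatch, rng):
        trials.append(("mismatch", prior, stim))
    for prior in _cycle_assign(idents, cfg.n_catch, rng):
        trials.append(("catch", prior, QUESTION_MARK))
    for ident in _cycle_assign(idents, cfg.n_neutral, rng):
        trials.append(("neutral", NEUTRAL, ident))
    for _ in range(cfg.n_neutral_catch):
        trials.append(("neutral_catch", NEUTRAL, QUESTION_MARK))
    for _ in range(cfg.n_null):
        trials.append(("null", NONE, NONE))

    order = np.arange(len(trials))
    violation = "no attempt made"
    for _ in range(cfg.max_attempts):
        rng.shuffle(order)
        seq = [trials[i] for i in order]
        violation = _check_runs([(c, s) for c, _, s in seq], cfg)
        if violation is None:
            df = pd.DataFrame(seq, columns=["condition", "prior", "stimulus"])
            df.insert(0, "block", block)
            df.insert(0, "trial_index", np.arange(len(df)))
            df["response"] = NONE
            df["rt_ms"] = np.nan
            df["valid"] = False
            return TrialTable(df[TRIAL_COLUMNS + []])
    raise DesignError(
        f"no valid block ordering in {cfg.max_attempts} attempts; "
        f"last violated constraint: {violation}"
    )


# ---------------------------------------------------------------------------
# Behavioral quantities
# ---------------------------------------------------------------------------

@dataclass
class PrecisionTable:
    """Behavioral prior-precision weights per morph (or per prior-by-morph).

    Each entry holds ``precision = (n_prior − n_otherpart) / n`` where
    ``n = n_prior + n_otherpart`` counts only valid responses naming one of
    the two identities in the morph. Values lie in [−1, 1]; a key with n = 0
    is reported as missing (NaN).
    """

    data: pd.DataFrame  # columns: prior, pair, n_prior, n_otherpart, n, precision
    mode: str = "pooled"  # 'pooled' (per morph pair) or 'keyed' (per prior, pair)

    def get(self, prior: str, pair: str) -> float:
        if self.mode == "pooled":
            rows = self.data[self.data["pair"] == pair]
        else:
            rows = self.data[(self.data["pair"] == pair) & (self.data["prior"] == prior)]
        if rows.empty:
            return float("nan")
        return float(rows["precision"].iloc[0])

    @classmethod
    def constant(cls, value: float, n: int = 0, mode: str = "pooled") -> "PrecisionTable":
        """A table assigning one precision to every morph pair (simulation truth)."""
        rows = [
            {"prior": "*", "pair": pair, "n_prior": n, "n_otherpart": 0,
             "n": n, "precision": float(value)}
            for pair in MORPH_PAIRS
        ]
        return cls(pd.DataFrame(rows), mode=mode)


def _valid_partial_mask(df: pd.DataFrame, response_window_ms: float) -> pd.Series:
    in_morph = np.asarray(
        [resp in _stimulus_identities(stim)
         for resp, stim in zip(df["response"], df["stimulus"])],
        dtype=bool,
    )
    fast = df["rt_ms"].to_numpy(dtype=float) <= response_window_ms
    valid = df["valid"].to_numpy(dtype=bool)
    return pd.Series(in_morph & fast & valid, index=df.index)


def compute_precision(
    trials: TrialTable,
    mode: str = "pooled",
    response_window_ms: float = 1500.0,
) -> PrecisionTable:
    """Estimate prior precision from the partial-trial responses.

    Responses naming an identity not contained in the morph, responses slower
    than the response window, and trials flagged invalid are excluded from n.
    ``mode='pooled'`` pools counts across the two prior directions of each
    morph pair; ``mode='keyed'`` keeps one entry per (prior, pair).
    """
    if mode not in ("pooled", "keyed"):
        raise ValueError("mode must be 'pooled' or 'keyed'")
    designed = trials.partial
    ok = _valid_partial_mask(designed, response_window_ms) if len(designed) else []
    df = designed[ok] if len(designed) else designed
    rows = []
    # keys cover every combination present in the design, so combinations
    # whose responses were all excluded still appear (as missing, with n = 0)
    if mode == "pooled":
        keys = sorted(designed["stimulus"].unique())
        groups = [("*", pair, df[df["stimulus"] == pair]) for pair in keys]
    else:
        keys = sorted(set(zip(designed["prior"], designed["stimulus"])))
        groups = [
            (prior, pair, df[(df["prior"] == prior) & (df["stimulus"] == pair)])
            for prior, pair in keys
        ]
    for prior, pair, g in groups:
        n_prior = int((g["response"] == g["prior"]).sum())
        n_other = len(g) - n_prior
        n = n_prior + n_other
        if n == 0:
            warnings.warn(
                f"no valid responses for prior={prior} pair={pair}; "
                "precision reported as missing"
            )
            prec = np.nan
        else:
            prec = (n_prior - n_other) / n
        rows.append({"prior": prior, "pair": pair, "n_prior": n_prior,
                     "n_otherpart": n_other, "n": n, "precision": prec})
    return PrecisionTable(pd.DataFrame(rows), mode=mode)


def assimilation_index(
    trials: TrialTable,
    response_window_ms: float = 1500.0,
) -> float:
    """Percent of morph responses naming the expected identity, in [0, 100].

    A percent-expected score is computed for each (prior scene, morph)
    combination and the scores are averaged; 50 indicates no prior influence,
    above 50 an assimilative bias, below 50 a contrastive bias. Invariant to
    trial order and to null trials.
    """
    df = trials.partial
    if df.empty:
        raise ValueError("no valid partial trials; assimilation index undefined")
    ok = _valid_partial_mask(df, response_window_ms)
    df = df[ok]
    if df.empty:
        raise ValueError("no valid partial trials; assimilation index undefined")
    scores = []
    for (_, _), g in df.groupby(["prior", "stimulus"]):
        scores.append(100.0 * (g["response"] == g["prior"]).mean())
    return float(np.mean(scores))


def split_partial_rts(
    trials: TrialTable,
    response_window_ms: float = 1500.0,
) -> tuple[float, float]:
    """Mean RT of prior-confirming vs contrastive morph responses (ms).

    Returns (mean_confirming, mean_contrastive). Raises if either subset is
    empty; callers exclude such subjects with a warning.
    """
    df = trials.partial
    ok = _valid_partial_mask(df, response_window_ms)
    df = df[ok]
    confirming = df[df["response"] == df["prior"]]
    contrastive = df[df["response"] != df["prior"]]
    if confirming.empty or contrastive.empty:
        raise ValueError(
            "empty response subset (confirming and contrastive RTs both required)"
        )
    return float(confirming["rt_ms"].mean()), float(contrastive["rt_ms"].mean())
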