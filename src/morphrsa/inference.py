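"""Nonparametric group statistics for model–brain correlations.

Per-model tau-a distributions are tested against zero with one-sided Wilcoxon
signed-rank tests (Bonferroni-corrected over the tests per region); models are
compared pairwise with two-sided paired Wilcoxon tests (Benjamini–Hochberg FDR
over the declared comparison family). Effect sizes are Wilcoxon's
r = |Z|/sqrt(N); RT condition effects use a Friedman omnibus with Kendall's W
and a rank-based Tukey–Kramer (Nemenyi) post hoc.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "GroupResult",
    "test_vs_zero",
    "compare_models_paired",
    "wilcoxon_effect_size_r",
    "friedman_omnibus",
]


@dataclass
class TestResult:
    """One group-level test (vs zero or paired model comparison)."""

    label: str
    test: str
    n: int
    statistic: float
    z: float
    p_raw: float
    p_corrected: float
    correction: str
    effect_size_r: float


@dataclass
class GroupResult:
    """Per-region group inference: tau-a samples, tests, and noise ceiling."""

    region_id: str = ""
    layer_tag: str = ""
    taus: dict[str, np.ndarray] = field(default_factory=dict)
    vs_zero: list[TestResult] = field(default_factory=list)
    comparisons: list[TestResult] = field(default_factory=list)
    noise_ceiling: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(t) for t in self.vs_zero + self.comparisons]
        df = pd.DataFrame(rows)
        if not df.empty:
            df.insert(0, "region", self.region_id)
            df.insert(1, "layer", self.layer_tag)
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "region": self.region_id,
            "layer": self.layer_tag,
            "taus": {k: list(map(float, v)) for k, v in self.taus.items()},
            "tests": [asdict(t) for t in self.vs_zero + self.comparisons],
            "noise_ceiling": self.noise_ceiling,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def wilcoxon_effect_size_r(z: float, n: int) -> float:
    """Wilcoxon's r effect size, |Z| / sqrt(N)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return abs(z) / np.sqrt(n)


def _wilcoxon(values: np.ndarray, alternative: str, method: str = "auto"):
    """Wilcoxon signed-rank test returning (statistic, z, p).

    Normal approximation with tie/continuity correction for N >= 20, exact
    null distribution otherwise (``method`` overrides). The Z statistic is
    always taken from the normal approximation so Wilcoxon's r is defined in
    both modes. Zero differences are dropped (Wilcoxon convention).
    """
    values = np.asarray(values, dtype=float)
    nonzero = values[values != 0]
    if nonzero.size == 0:
        raise ValueError("all differences are zero: Wilcoxon test undefined")
    if method == "auto":
        method = "approx" if nonzero.size >= 20 else "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        approx = stats.wilcoxon(nonzero, alternative=alternative,
                                method="approx", correction=True)
        z = float(approx.zstatistic)
        if method == "exact" and np.unique(np.abs(nonzero)).size == nonzero.size:
            res = stats.wilcoxon(nonzero, alternative=alternative, method="exact")
        else:
            res = approx
    return float(res.statistic), z, float(res.pvalue)


def test_vs_zero(
    taus: np.ndarray,
    n_tests: int = 1,
    label: str = "",
    method: str = "auto",
) -> TestResult:
    """One-sided (greater) Wilcoxon signed-rank test of tau-a values vs zero.

    The raw p is Bonferroni-multiplied by ``n_tests`` (the number of tests per
    region), capped at 1.
    """
    taus = np.asarray(taus, dtype=float)
    stat, z, p = _wilcoxon(taus, "greater", method)
    return TestResult(
        label=label,
        test="wilcoxon_one_sided_vs_zero",
        n=taus.size,
        statistic=stat,
        z=z,
        p_raw=p,
        p_corrected=min(1.0, p * n_tests),
        correction="bonferroni",
        effect_size_r=wilcoxon_effect_size_r(z, taus.size),
    )


def compare_models_paired(
    tau_samples: dict[str, np.ndarray],
    family: list[tuple[str, str]] | None = None,
    method: str = "auto",
) -> list[TestResult]:
    """Two-sided paired Wilcoxon tests between models, BH-FDR over the family.

    ``family`` lists the (model_a, model_b) comparisons forming one FDR
    family (default: all unordered pairs). Degenerate comparisons with all
    differences zero are reported as p = 1 with a warning.
    """
    models = list(tau_samples)
    if family is None:
        family = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    results = []
    pvals = []
    for a, b in family:
        xa, xb = np.asarray(tau_samples[a], float), np.asarray(tau_samples[b], float)
        if xa.shape != xb.shape:
            raise ValueError(f"unequal sample sizes for comparison {a} vs {b}")
        diff = xa - xb
        if np.all(diff == 0):
            warnings.warn(f"all paired differences zero for {a} vs {b}; p = 1")
            stat, z, p = 0.0, 0.0, 1.0
        else:
            stat, z, p = _wilcoxon(diff, "two-sided", method)
        pvals.append(p)
        results.append(
            TestResult(
                label=f"{a} vs {b}",
                test="wilcoxon_paired_two_sided",
                n=xa.size,
                statistic=stat,
                z=z,
                p_raw=p,
                p_corrected=np.nan,
                correction="bh_fdr",
                effect_size_r=wilcoxon_effect_size_r(z, xa.size),
            )
        )
    if results:
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for r, p in zip(results, p_adj):
            r.p_corrected = float(p)
    return results


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    kendall_w: float
    mean_ranks: dict[str, float]
    posthoc: pd.DataFrame  # columns: a, b, rank_diff, q, p


def friedman_omnibus(
    condition_values: pd.DataFrame,
) -> FriedmanResult:
    """Friedman test over subjects × conditions with Kendall's W effect size.

    Post-hoc pairwise comparisons use the rank-based Tukey–Kramer (Nemenyi)
    procedure: the difference of average within-subject ranks is referred to
    the studentized range distribution with infinite degrees of freedom.
    """
    df = pd.DataFrame(condition_values)
    n, k = df.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 conditions")
    if n < 5:
        raise ValueError("Friedman test needs at least 5 subjects")
    cols = [df[c].to_numpy(float) for c in df.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.friedmanchisquare(*cols)
    if np.isnan(stat):  # fully tied data: no evidence of any difference
        stat, p = 0.0, 1.0
    w = float(stat) / (n * (k - 1))
    ranks = df.rank(axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    rows = []
    names = list(df.columns)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = float(mean_ranks[a] - mean_ranks[b])
            q = abs(diff) / se
            p_pair = float(stats.studentized_range.sf(q, k, np.inf))
            rows.append({"a": a, "b": b, "rank_diff": diff, "q": q, "p": p_pair})
    return FriedmanResult(
        statistic=float(stat),
        p_value=float(p),
        kendall_w=w,
        mean_ranks={c: float(mean_ranks[c]) for c in names},
        posthoc=pd.DataFrame(rows),
    )
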