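"""Model/Results interface for the ROI model-comparison RSA.

:class:`PriorRSA` is constructed from per-subject neural and hypothesis RDMs
(or directly from a simulated cohort) and its :meth:`PriorRSA.fit` returns a
:class:`PriorRSAResults` carrying the per-subject tau-a estimates, the
vs-zero and pairwise model tests with their corrections, effect sizes, the
noise ceiling, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PrecisionTable
from .hypotheses import MODELS, build_hypothesis_rdm
from .inference import GroupResult, _wilcoxon, compare_models_paired, test_vs_zero
from .rdm import (
    RDM,
    average_hemispheres,
    kendall_tau_a,
    neural_rdm,
    neutral_by_partial_cells,
    noise_ceiling,
)

__all__ = ["PriorRSA", "PriorRSAResults"]


class PriorRSA:
    """Group-level model-comparison RSA for one region and layer.

    Parameters
    ----------
    neural_rdms
        One (hemisphere-averaged, rank-rescaled) neural RDM per subject.
    hypothesis_rdms
        Per subject, a mapping from model name to that subject's hypothesis
        RDM (they differ across subjects through the behavioral precision
        weights).
    comparison_cells
        Index pair selecting the dissimilarities entering tau-a; defaults to
        the 48 neutral × partial cells.
    """

    def __init__(
        self,
        neural_rdms: list[RDM],
        hypothesis_rdms: list[dict[str, RDM]],
        comparison_cells: tuple[np.ndarray, np.ndarray] | None = None,
        region_id: str = "",
        layer_tag: str = "",
    ) -> None:
        if len(neural_rdms) != len(hypothesis_rdms):
            raise ValueError("need one hypothesis RDM set per subject")
        if not neural_rdms:
            raise ValueError("no subjects")
        self.neural_rdms = neural_rdms
        self.hypothesis_rdms = hypothesis_rdms
        self.models = list(hypothesis_rdms[0])
        self.comparison_cells = (
            comparison_cells
            if comparison_cells is not None
            else neutral_by_partial_cells(neural_rdms[0].labels)
        )
        self.region_id = region_id
        self.layer_tag = layer_tag

    @classmethod
    def from_cohort(
        cls,
        cohort,
        region: str | None = None,
        models: tuple[str, ...] = MODELS,
        precision_source: str = "behavioral",
        log_mode: str = "signed_log1p",
    ) -> "PriorRSA":
        """Build the model from a simulated cohort's patterns and behavior.

        Hemispheric RDMs are computed on raw correlation distances, averaged
        cellwise, then rank-rescaled once. ``precision_source`` selects the
        behaviorally estimated precision table (default) or the generator's
        ground truth (``'truth'``).
        """
        region = region or cohort.config.regions[0]
        neural, hypotheses = [], []
        for sub in cohort.subjects:
            hemis = list(sub.patterns[region].values())
            raws = [neural_rdm(p, rescale=False) for p in hemis]
            if len(raws) == 2:
                nr = average_hemispheres(raws[0], raws[1])
            elif len(raws) == 1:
                nr = raws[0].rank_rescaled()
            else:
                mean = np.mean([r.matrix for r in raws], axis=0)
                nr = RDM(raws[0].labels, mean, "raw", "neural").rank_rescaled()
            neural.append(nr)
            prec: PrecisionTable = (
                sub.precision_est if precision_source == "behavioral"
                else sub.precision_true
            )
            hypotheses.append({
                m: build_hypothesis_rdm(cohort.bank, prec, m, log_mode=log_mode)
                for m in models
            })
        return cls(neural, hypotheses, region_id=region,
                   layer_tag=cohort.bank.layer_tag)

    def fit(
        self,
        n_tests: int | None = None,
        alpha: float = 0.05,
    ) -> "PriorRSAResults":
        """Compute tau-a per subject and model, then the group statistics.

        ``n_tests`` is the Bonferroni family size for the vs-zero tests
        (default: the number of models). With fewer than 5 subjects the taus
        and noise ceiling are reported but the tests are skipped.
        """
        cells = self.comparison_cells
        taus = {m: np.empty(len(self.neural_rdms)) for m in self.models}
        for i, (nr, hyps) in enumerate(zip(self.neural_rdms, self.hypothesis_rdms)):
            nv = nr.cells(cells)
            for m in self.models:
                taus[m][i] = kendall_tau_a(nv, hyps[m].cells(cells))
        n_sub = len(self.neural_rdms)
        group = GroupResult(region_id=self.region_id, layer_tag=self.layer_tag,
                            taus=taus)
        if n_sub >= 2:
            group.noise_ceiling = noise_ceiling(self.neural_rdms, cells)
        if n_sub >= 5:
            k = n_tests if n_tests is not None else len(self.models)
            group.vs_zero = [test_vs_zero(taus[m], n_tests=k, label=m)
                             for m in self.models]
            group.comparisons = compare_models_paired(taus)
        return PriorRSAResults(model=self, group=group, alpha=alpha)


@dataclass
class PriorRSAResults:
    """Fitted group RSA: estimates, tests, noise ceiling, and summaries."""

    model: PriorRSA
    group: GroupResult
    alpha: float = 0.05

    @property
    def taus(self) -> pd.DataFrame:
        return pd.DataFrame(self.group.taus)

    @property
    def mean_taus(self) -> pd.Series:
        return self.taus.mean()

    def winning_model(self) -> str | None:
        """The model the data support, or None if no model meets the bar.

        Criterion: largest group-mean tau-a, significant vs zero after
        Bonferroni correction, and significantly *greater* than the runner-up
        model (one-sided paired Wilcoxon signed-rank test, the directional
        complement of the two-sided comparison table).
        """
        if not self.group.vs_zero:
            return None
        means = self.mean_taus.sort_values(ascending=False)
        best, runner_up = means.index[0], means.index[1]
        vs_zero = {t.label: t for t in self.group.vs_zero}
        if vs_zero[best].p_corrected >= self.alpha:
            return None
        diff = self.group.taus[best] - self.group.taus[runner_up]
        if np.all(diff == 0):
            return None
        _, _, p_greater = _wilcoxon(diff, "greater")
        return best if p_greater < self.alpha else None

    def summary(self) -> str:
        lines = [
            f"Model-comparison RSA — region: {self.group.region_id or '-'} "
            f"layer: {self.group.layer_tag or '-'}",
            f"Subjects: {len(self.model.neural_rdms)}   "
            f"comparison cells: {len(self.model.comparison_cells[0])}",
            "",
            f"{'model':<12}{'mean tau-a':>12}{'p (corr.)':>12}{'r':>8}",
        ]
        vs_zero = {t.label: t for t in self.group.vs_zero}
        for m in self.model.models:
            t = vs_zero.get(m)
            p = f"{t.p_corrected:.4f}" if t else "-"
            r = f"{t.effect_size_r:.2f}" if t else "-"
            lines.append(f"{m:<12}{self.mean_taus[m]:>12.4f}{p:>12}{r:>8}")
        if self.group.comparisons:
            lines.append("")
            lines.append(f"{'comparison':<24}{'p (FDR)':>10}")
            for t in self.group.comparisons:
                lines.append(f"{t.label:<24}{t.p_corrected:>10.4f}")
        if self.group.noise_ceiling is not None:
            lo, hi = self.group.noise_ceiling
            lines.append("")
            lines.append(f"Noise ceiling: [{lo:.4f}, {hi:.4f}]")
        win = self.winning_model()
        lines.append(f"Winning model: {win or 'none'}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of group-mean tau-a per model with the noise-ceiling band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = self.mean_taus
        sems = self.taus.sem()
        ax.bar(means.index, means.to_numpy(), yerr=sems.to_numpy(), capsize=3)
        if self.group.noise_ceiling is not None:
            lo, hi = self.group.noise_ceiling
            ax.axhspan(lo, hi, color="0.85", zorder=0)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("Kendall tau-a (model vs brain)")
        ax.set_title(f"{self.group.region_id} {self.group.layer_tag}".strip())
        return ax
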