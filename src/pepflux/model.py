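"""Model/Results front end for proteolysis-activity inference.

`ProteolysisModel` bundles a pruned cleavage graph with its observed
amounts; `fit` runs the multi-start Levenberg-Marquardt estimation and
returns a `ProteolysisResults` carrying the fitted rates, the normalised
(compositional) peptidase activities, fit diagnostics, a permutation
significance test and a summary table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import infer, stats
from .graph import CleavageGraph, in_silico_digest
from .infer import FitResult, ModelParameters
from .msmatch import MatchConfig, RTModel, fill_graph, match_peaks
from .profiles import FrequencyMatrix
from .stats import ActivityProfile, PermutationResult

__all__ = ["ProteolysisModel", "ProteolysisResults"]


class ProteolysisModel:
    """First-order proteolytic degradation network fitted to LC-MS amounts.

    Parameters
    ----------
    graph
        A pruned cleavage graph (sources and leaves disjoint).
    observed
        Observed amount per peptide node.  Defaults to the positive
        amounts stored on the graph's nodes.
    """

    def __init__(self, graph: CleavageGraph, observed: Mapping[str, float] | None = None):
        self.graph = graph
        self.observed = dict(graph.observed() if observed is None else observed)
        self._compiled = infer._CompiledGraph(graph)

    # -- constructors --------------------------------------------------

    @classmethod
    def from_peaks(
        cls,
        precursors: Sequence[str],
        matrices: Sequence[FrequencyMatrix],
        peaks,
        rtm: RTModel,
        threshold: float,
        gamma: float = 1.0,
        match_config: MatchConfig | None = None,
    ) -> "ProteolysisModel":
        """Digest precursors, match a peak list, fill and prune the graph."""
        graph = in_silico_digest(precursors, matrices, threshold, gamma)
        amounts = match_peaks(sorted(graph.nodes), peaks, rtm, match_config or MatchConfig())
        return cls(fill_graph(graph, amounts))

    @classmethod
    def from_amounts(
        cls,
        graph: CleavageGraph,
        amounts: Mapping[str, float],
    ) -> "ProteolysisModel":
        """Fill an existing digestion graph with amounts, prune, wrap."""
        return cls(fill_graph(graph, amounts))

    # -- dimensions ----------------------------------------------------

    @property
    def nobs(self) -> int:
        """m, the number of observed peptide nodes."""
        return len(self.observed)

    @property
    def n_params(self) -> int:
        """n = |S| + |L| + |P|."""
        return self._compiled.n_params

    @property
    def peptidases(self) -> list[str]:
        return list(self._compiled.pep_order)

    def expected_amounts(self, z: ModelParameters) -> dict[str, float]:
        return infer.expected_amounts(self.graph, z)

    def fit(self, n_starts: int = 7, max_iter: int = 200, seed: int = 0) -> "ProteolysisResults":
        """Estimate creation/degradation rates and peptidase activities."""
        result = infer.fit(self.graph, self.observed, n_starts=n_starts,
                           max_iter=max_iter, seed=seed)
        return ProteolysisResults(self, result)


class ProteolysisResults:
    """Fitted parameters, diagnostics and compositional activities."""

    def __init__(self, model: ProteolysisModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self.activity_profile, self.params = stats.normalize_activities(fit_result.z_hat)

    # -- estimates -----------------------------------------------------

    @property
    def rse(self) -> float:
        """Relative squared error of the best start."""
        return self.fit_result.rse

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def fittedvalues(self) -> dict[str, float]:
        """Expected amounts at the optimum, over the observed nodes."""
        return dict(self.fit_result.y_hat)

    @property
    def resid(self) -> dict[str, float]:
        return {k: self.fit_result.y_hat[k] - self.model.observed[k]
                for k in self.fit_result.y_hat}

    @property
    def activities(self) -> dict[str, float]:
        """Normalised (simplex) peptidase activities."""
        return dict(zip(self.activity_profile.peptidase_ids,
                        self.activity_profile.normalized.tolist()))

    @property
    def clr_activities(self) -> dict[str, float]:
        return dict(zip(self.activity_profile.peptidase_ids,
                        self.activity_profile.clr_values.tolist()))

    # -- inference -----------------------------------------------------

    def permutation_test(self, n_perm: int = 1000, seed: int = 0,
                         **fit_options) -> PermutationResult:
        """Permutation-null p-value for the achieved rse."""
        return stats.permutation_pvalue(self.model.graph, self.model.observed,
                                        n_perm=n_perm, fit_options=fit_options,
                                        seed=seed)

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of the fit."""
        fr = self.fit_result
        lines = [
            "Proteolysis activity model",
            "=" * 58,
            f"observed nodes (m):        {self.model.nobs}",
            f"parameters (n):            {self.model.n_params}"
            f"  (S={len(fr.z_hat.creation)}, L={len(fr.z_hat.degradation)},"
            f" P={len(fr.z_hat.activities)})",
            f"relative squared error:    {fr.rse:.6g}",
            f"starts / best / converged: {fr.n_starts} / {fr.best_start_index} /"
            f" {fr.converged}",
            f"seed:                      {fr.seed}",
            "",
            "Peptidase activities (identified up to scale)",
            "-" * 58,
            f"{'peptidase':<20}{'normalized':>14}{'clr':>14}",
        ]
        for pid, norm, c in zip(self.activity_profile.peptidase_ids,
                                self.activity_profile.normalized,
                                self.activity_profile.clr_values):
            lines.append(f"{pid:<20}{norm:>14.6f}{c:>14.4f}")
        lines.append("-" * 58)
        return "\n".join(lines)

    def plot_activities(self, ax=None):
        """Bar plot of clr-transformed activities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ids = self.activity_profile.peptidase_ids
        ax.bar(range(len(ids)), self.activity_profile.clr_values)
        ax.set_xticks(range(len(ids)), ids, rotation=45, ha="right")
        ax.set_ylabel("clr activity")
        ax.axhline(0.0, color="k", lw=0.5)
        return ax
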