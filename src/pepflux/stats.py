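"""Permutation significance of fits and compositional post-processing.

Because the activity gauge fixes peptidase activities only up to a global
scale, fitted activities are reported as a composition: normalised to the
unit simplex and mapped to Euclidean space by the centred log-ratio (clr)
transform.  Fit quality is judged against an empirical null in which the
observed amounts are randomly re-assigned over the observed nodes while
the graph topology stays fixed; the p-value is the fraction of permuted
datasets whose refitted relative squared error is at most the observed
one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import CleavageGraph
from .infer import ModelParameters, expected_amounts, fit

__all__ = [
    "PermutationResult",
    "ActivityProfile",
    "permutation_pvalue",
    "normalize_activities",
    "clr",
    "activity_matrix",
]

_SEED_CAP = 2**31 - 1


def clr(x: Sequence[float]) -> np.ndarray:
    """Centred log-ratio: ln(x_i / geometric mean); output sums to zero."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("clr expects a non-empty vector")
    if np.any(arr <= 0):
        raise ValueError("clr requires strictly positive entries")
    logs = np.log(arr)
    return logs - logs.mean()


@dataclass
class ActivityProfile:
    """A sample's peptidase activities as a composition."""

    peptidase_ids: list[str]
    normalized: np.ndarray
    clr_values: np.ndarray

    def __post_init__(self) -> None:
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.clr_values = np.asarray(self.clr_values, dtype=float)
        if not (len(self.peptidase_ids) == self.normalized.size == self.clr_values.size):
            raise ValueError("profile fields must share one length")
        if np.any(self.normalized <= 0):
            raise ValueError("normalized activities must be strictly positive")
        if abs(self.normalized.sum() - 1.0) > 1e-12:
            raise ValueError("normalized activities must sum to 1")
        if abs(self.clr_values.sum()) > 1e-9:
            raise ValueError("clr values must sum to 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.clr_values, index=self.peptidase_ids)


def normalize_activities(z: ModelParameters) -> tuple[ActivityProfile, ModelParameters]:
    """Project activities onto the simplex, preserving every expected amount.

    Returns the activity composition (with its clr image) and the jointly
    rescaled parameter vector: dividing creation, degradation and
    activities by the same constant leaves Phi unchanged, so the rescaled
    parameters reproduce exactly the same expected amounts.
    """
    ids = sorted(z.activities)
    lam = np.array([z.activities[p] for p in ids], dtype=float)
    total = float(lam.sum())
    normalized = lam / total
    profile = ActivityProfile(ids, normalized, clr(normalized))
    return profile, z.scaled(1.0 / total)


@dataclass
class PermutationResult:
    """Observed rse against its permutation null distribution."""

    observed_rse: float
    null_rses: list[float]
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.null_rses) != self.n_perm:
            raise ValueError("null distribution length must equal n_perm")
        expected = sum(r <= self.observed_rse for r in self.null_rses) / self.n_perm
        if abs(self.p_value - expected) > 1e-12:
            raise ValueError("p_value inconsistent with the null distribution")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "observed_rse": self.observed_rse,
            "null_rses": self.null_rses,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PermutationResult":
        p = json.loads(Path(path).read_text())
        return cls(p["observed_rse"], p["null_rses"], p["p_value"], p["n_perm"], p["seed"])


def count_pvalue(observed_rse: float, null_rses: Sequence[float]) -> float:
    """Literal empirical p-value: |{i : null_i <= observed}| / n."""
    if not null_rses:
        raise ValueError("empty null distribution")
    return sum(r <= observed_rse for r in null_rses) / len(null_rses)


def permutation_pvalue(
    graph: CleavageGraph,
    observed: Mapping[str, float],
    n_perm: int = 1000,
    fit_options: Mapping | None = None,
    seed: int = 0,
    baseline_rse: float | None = None,
) -> PermutationResult:
    """Permutation-null significance of the fit to ``observed``.

    The multiset of observed amounts is randomly re-assigned over the
    observed nodes (graph topology unchanged), the model is refitted to
    each permuted dataset, and the p-value is the fraction of null rse
    values at or below the observed one.  When ``baseline_rse`` is not
    supplied, the baseline fit is run here with the same ``fit_options``
    and the same per-fit seeding scheme as the permutation refits, which
    keeps the observed dataset exchangeable with its permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    keys = sorted(observed)
    if len(keys) < 2:
        raise ValueError("nothing to permute: need at least two observed nodes")
    options = dict(fit_options or {})
    options.pop("seed", None)
    rng = np.random.default_rng(seed)

    def _refit(amounts: Mapping[str, float]) -> float:
        fit_seed = int(rng.integers(_SEED_CAP))
        return fit(graph, amounts, seed=fit_seed, **options).rse

    if baseline_rse is None:
        baseline_rse = _refit(observed)
    values = np.array([observed[k] for k in keys], dtype=float)
    null_rses: list[float] = []
    for _ in range(n_perm):
        permuted = dict(zip(keys, values[rng.permutation(len(keys))].tolist()))
        null_rses.append(_refit(permuted))
    return PermutationResult(
        observed_rse=float(baseline_rse),
        null_rses=null_rses,
        p_value=count_pvalue(baseline_rse, null_rses),
        n_perm=n_perm,
        seed=seed,
    )


def activity_matrix(
    profiles: Sequence[tuple[str, ActivityProfile]],
    union: bool = False,
) -> pd.DataFrame:
    """Samples x peptidases matrix of clr activities for downstream analysis.

    By default only peptidases present in every sample are kept (each
    sample's composition is restricted, renormalised and re-transformed).
    With ``union=True`` every peptidase seen anywhere is kept and a
    sample's absent activities are imputed by its minimum observed
    normalised activity before renormalisation and clr.
    """
    if not profiles:
        raise ValueError("no activity profiles given")
    sets = [set(p.peptidase_ids) for _, p in profiles]
    universe = sorted(set.union(*sets) if union else set.intersection(*sets))
    if not universe:
        raise ValueError("no common peptidases across samples")
    rows = {}
    for sample_id, profile in profiles:
        lookup = dict(zip(profile.peptidase_ids, profile.normalized))
        floor = min(profile.normalized)
        raw = np.array([lookup.get(p, floor) for p in universe])
        comp = raw / raw.sum()
        rows[sample_id] = clr(comp)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=universe)
    frame.index.name = "sample"
    return frame


def write_activity_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")


def read_activity_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
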