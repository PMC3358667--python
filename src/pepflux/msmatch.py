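"""Assigning LC-MS peak intensities to peptide nodes.

Peptides are located in the (m/z, retention time) plane: the monoisotopic
mass fixes the m/z at each charge state 1-8, and the retention time is
predicted from amino-acid composition by a linear regression trained on
the precursor peptides' known retention times.  Each expected coordinate
is matched to the nearest observed monoisotopic peak of the same charge
under a tolerance-scaled Euclidean distance, with a single dimensionless
cut-off; matched intensities are summed over charge states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .graph import CleavageGraph, prune
from .profiles import AMINO_ACIDS

logger = logging.getLogger(__name__)

#: Mass of a proton in Da.
PROTON_MASS = 1.007276466

MIN_CHARGE, MAX_CHARGE = 1, 8


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic peptide mass in Da (residue masses plus water)."""
    for ch in sequence:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"unknown residue symbol {ch!r}")
    return float(_ptmass.fast_mass(sequence))


def mz_for_charge(mass_da: float, z: int) -> float:
    """m/z in Th of a peptide of the given mass carrying ``z`` protons."""
    if not MIN_CHARGE <= z <= MAX_CHARGE:
        raise ValueError(f"charge must be in {MIN_CHARGE}..{MAX_CHARGE}, got {z}")
    return (mass_da + z * PROTON_MASS) / z


@dataclass(frozen=True)
class Peak:
    """One monoisotopic LC-MS feature."""

    mz: float
    rt: float
    charge: int
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if not MIN_CHARGE <= self.charge <= MAX_CHARGE:
            raise ValueError(f"charge must be in {MIN_CHARGE}..{MAX_CHARGE}")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances of the nearest-neighbour peak assignment.

    ``mz_tolerance`` (ppm) and ``rt_tolerance`` (minutes) scale the two
    axes; ``max_distance`` is the dimensionless cut-off on the scaled
    Euclidean distance (1.0 means "within one combined tolerance").
    """

    mz_tolerance: float = 10.0
    rt_tolerance: float = 2.0
    max_distance: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mz_tolerance, self.rt_tolerance, self.max_distance) <= 0:
            raise ValueError("all matching tolerances must be strictly positive")


class RTModel:
    """Composition-only linear retention-time predictor.

    rt = intercept + sum_a coefficients[a] * count_a(sequence); permuting
    a sequence's residues cannot change its prediction.
    """

    def __init__(self, intercept: float, coefficients: Mapping[str, float]):
        if set(coefficients) != set(AMINO_ACIDS):
            raise ValueError("need exactly one coefficient per amino acid")
        self.intercept = float(intercept)
        self.coefficients = {a: float(coefficients[a]) for a in AMINO_ACIDS}

    def predict(self, sequence: str) -> float:
        return self.intercept + sum(
            self.coefficients[a] * sequence.count(a) for a in AMINO_ACIDS
        )


def _composition_design(sequences: Sequence[str]) -> np.ndarray:
    x = np.zeros((len(sequences), len(AMINO_ACIDS) + 1))
    for i, seq in enumerate(sequences):
        for j, a in enumerate(AMINO_ACIDS):
            x[i, j] = seq.count(a)
    x[:, -1] = 1.0
    return x


def train_rt_model(training: Sequence[tuple[str, float]]) -> RTModel:
    """Ordinary least squares of retention time on residue counts."""
    if len(training) < len(AMINO_ACIDS) + 1:
        raise ValueError(
            f"need at least {len(AMINO_ACIDS) + 1} training peptides, got {len(training)}"
        )
    sequences = [s for s, _ in training]
    rts = np.array([t for _, t in training], dtype=float)
    design = _composition_design(sequences)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"insufficient compositional diversity: design rank {rank} < {design.shape[1]}"
        )
    coef, *_ = np.linalg.lstsq(design, rts, rcond=None)
    return RTModel(coef[-1], dict(zip(AMINO_ACIDS, coef[:-1])))


def match_peaks(
    candidates: Sequence[str],
    peaks: Sequence[Peak],
    rtm: RTModel,
    cfg: MatchConfig,
) -> dict[str, float]:
    """Greedy one-to-one nearest-neighbour assignment of peaks to peptides.

    For every candidate and every charge state the expected coordinate is
    compared with same-charge peaks; candidate-charge slots claim peaks in
    ascending order of scaled distance (ties broken towards the lower-m/z
    peak) so no feature is counted twice.  A candidate's amount is the sum
    of its matched intensities over charges; unmatched candidates get 0.
    """
    amounts = {seq: 0.0 for seq in candidates}
    if not peaks:
        return amounts
    by_charge: dict[int, list[int]] = {}
    for i, p in enumerate(peaks):
        by_charge.setdefault(p.charge, []).append(i)
    pairs: list[tuple[float, float, int, str, int]] = []
    for seq in candidates:
        mass_da = monoisotopic_mass(seq)
        rt_pred = rtm.predict(seq)
        for z in range(MIN_CHARGE, MAX_CHARGE + 1):
            exp_mz = mz_for_charge(mass_da, z)
            for i in by_charge.get(z, ()):  # only same-charge peaks compete
                p = peaks[i]
                d = math.hypot(
                    (p.mz - exp_mz) / (exp_mz * cfg.mz_tolerance * 1e-6),
                    (p.rt - rt_pred) / cfg.rt_tolerance,
                )
                if d <= cfg.max_distance:
                    pairs.append((d, p.mz, i, seq, z))
    used_peaks: set[int] = set()
    used_slots: set[tuple[str, int]] = set()
    for d, _mz, i, seq, z in sorted(pairs):
        if i in used_peaks or (seq, z) in used_slots:
            if i in used_peaks and (seq, z) not in used_slots:
                logger.debug("peak %d contested by %s/+%d at distance %.3g", i, seq, z, d)
            continue
        used_peaks.add(i)
        used_slots.add((seq, z))
        amounts[seq] += peaks[i].intensity
    return amounts


def fill_graph(graph: CleavageGraph, amounts: Mapping[str, float]) -> CleavageGraph:
    """Write matched amounts onto peptide nodes, then prune.

    Returns the pruned graph; the observed set O (nodes with positive
    amount) is available from ``graph.observed()``.
    """
    g = graph.copy()
    for seq, amount in amounts.items():
        if seq in g.nodes:
            g.nodes[seq].y = float(amount)
    return prune(g)


# -- peak-list TSV ----------------------------------------------------

_PEAK_COLUMNS = ["mz", "rt", "charge", "intensity"]


def write_peaklist(peaks: Sequence[Peak], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(p.mz, p.rt, p.charge, p.intensity) for p in peaks], columns=_PEAK_COLUMNS
    )
    frame.to_csv(path, sep="\t", index=False)


def read_peaklist(path: str | Path) -> list[Peak]:
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != _PEAK_COLUMNS:
        raise ValueError(f"{path}: expected columns {_PEAK_COLUMNS}")
    return [
        Peak(float(r.mz), float(r.rt), int(r.charge), float(r.intensity))
        for r in frame.itertuples()
    ]
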