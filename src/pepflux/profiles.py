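"""Peptidase cleavage-specificity profiles and affinity scoring.

An endopeptidase's sequence preference is summarised by a *frequency
matrix*: for each of the eight loci flanking the scissile bond
(P4 P3 P2 P1 | P1' P2' P3' P4', cut between P1 and P1') it stores the
empirical distribution of amino acids observed at that locus across known
cleavage events of the enzyme (MEROPS-style specificity profiles).

A candidate cleavage site inside a peptide is scored against a profile by
the affinity coefficient

    rho = gamma * (prod_{j in J'} f[a_j, j]) ** (8 / (k + l))

where J' is the set of loci actually present in the substrate (windows are
truncated near the termini: k residues on the non-prime side, l on the
prime side, 1 <= k, l <= 4), a_j is the residue at locus j and gamma is a
global scale constant.  The 8/(k+l) exponent is a geometric-mean
normalisation that makes truncated windows commensurate with full 8-locus
windows; with gamma = 1 the score always lies in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Gap symbol used in specificity records whose context window runs past a
#: substrate terminus.  Always the last row of a frequency matrix.
GAP = "-"

#: Full 21-symbol alphabet (amino acids then the gap symbol).
ALPHABET = AMINO_ACIDS + GAP

#: The eight loci flanking the scissile bond, non-prime side first.
LOCI = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}
_LOCUS_INDEX = {locus: j for j, locus in enumerate(LOCI)}

_COLUMN_SUM_TOL = 1e-9


def _check_residues(seq: str, *, allow_gap: bool = False) -> None:
    allowed = ALPHABET if allow_gap else AMINO_ACIDS
    for ch in seq:
        if ch not in allowed:
            raise ValueError(f"unknown residue symbol {ch!r}")


@dataclass(frozen=True)
class CleavageContext:
    """Residues flanking a single cleavage site.

    ``left`` holds the k residues at loci P_k..P1 (so ``left[-1]`` is P1),
    ``right`` the l residues at P1'..P_l' (``right[0]`` is P1').  Loci that
    fall outside the substrate are simply absent, not gap-filled.
    """

    left: str
    right: str

    def __post_init__(self) -> None:
        if not (1 <= len(self.left) <= 4 and 1 <= len(self.right) <= 4):
            raise ValueError("context must hold 1-4 residues on each side")
        _check_residues(self.left)
        _check_residues(self.right)

    @property
    def k(self) -> int:
        return len(self.left)

    @property
    def l(self) -> int:
        return len(self.right)

    def loci(self) -> list[tuple[str, str]]:
        """Pairs ``(locus, residue)`` for the present loci J'."""
        out = []
        for offset, residue in enumerate(reversed(self.left)):
            out.append((LOCI[3 - offset], residue))
        for offset, residue in enumerate(self.right):
            out.append((LOCI[4 + offset], residue))
        return out


@dataclass(frozen=True)
class DetectedCleavage:
    """A scored cleavage of ``substrate`` after residue ``cut_position``.

    ``cut_position`` is the 1-based prefix length: the prefix is
    ``substrate[:cut_position]`` and the suffix ``substrate[cut_position:]``,
    both non-empty.
    """

    substrate: str
    cut_position: int
    peptidase_id: str
    rho: float

    def __post_init__(self) -> None:
        if not 1 <= self.cut_position <= len(self.substrate) - 1:
            raise ValueError("cut position must leave non-empty products")
        if self.rho < 0:
            raise ValueError("affinity coefficient must be non-negative")

    @property
    def prefix(self) -> str:
        return self.substrate[: self.cut_position]

    @property
    def suffix(self) -> str:
        return self.substrate[self.cut_position :]


class FrequencyMatrix:
    """Per-peptidase amino-acid frequencies over the 8 cleavage-site loci.

    Rows follow :data:`ALPHABET` (gap last), columns follow :data:`LOCI`.
    Every column is a probability distribution (sums to 1).
    """

    def __init__(self, peptidase_id: str, f: np.ndarray, n_events: int | None = None):
        f = np.asarray(f, dtype=float)
        if f.shape != (len(ALPHABET), len(LOCI)):
            raise ValueError(f"frequency matrix must be {len(ALPHABET)}x{len(LOCI)}, got {f.shape}")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        colsums = f.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COLUMN_SUM_TOL):
            bad = LOCI[int(np.argmax(np.abs(colsums - 1.0)))]
            raise ValueError(f"column {bad} does not sum to 1 (got {colsums.max():.12g})")
        self.peptidase_id = peptidase_id
        self.f = f
        self.n_events = n_events

    def freq(self, symbol: str, locus: str) -> float:
        """Frequency of ``symbol`` at ``locus``."""
        return float(self.f[_SYMBOL_INDEX[symbol], _LOCUS_INDEX[locus]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f, index=list(ALPHABET), columns=list(LOCI))

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "symbol"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyMatrix":
        """Read a matrix from TSV; the filename stem is the peptidase id."""
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if list(frame.columns) != list(LOCI):
            raise ValueError(f"{path}: expected locus columns {LOCI}")
        if list(frame.index) != list(ALPHABET):
            raise ValueError(f"{path}: expected 21 symbol rows with '-' last")
        return cls(path.stem, frame.to_numpy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"FrequencyMatrix({self.peptidase_id!r}, n_events={self.n_events})"


def build_frequency_matrix(
    peptidase_id: str,
    observed_contexts: Iterable[tuple[str, str]],
    ) -> FrequencyMatrix:
    """Tally cleavage records into a frequency matrix.

    Each record is a ``(left, right)`` pair of flanking residues; sides
    shorter than four residues (cleavages near a terminus in the source
    records) contribute the gap symbol at their missing outer loci.
    """
    counts = np.zeros((len(ALPHABET), len(LOCI)))
    n = 0
    for left, right in observed_contexts:
        left = left.rjust(4, GAP)
        right = right.ljust(4, GAP)
        for j, symbol in enumerate(left + right):
            if symbol not in _SYMBOL_INDEX:
                raise ValueError(f"unknown residue symbol {symbol!r}")
            counts[_SYMBOL_INDEX[symbol], j] += 1
        n += 1
    if n == 0:
        raise ValueError("no cleavage records")
    return FrequencyMatrix(peptidase_id, counts / n, n_events=n)


def extract_context(sequence: str, cut_position: int) -> CleavageContext:
    """Flanking residues of the cut after ``cut_position`` residues.

    At most four residues are taken on each side; loci beyond the termini
    are left absent (the scoring window shrinks, it is not gap-padded).
    """
    if not 1 <= cut_position <= len(sequence) - 1:
        raise ValueError("empty cleavage product")
    left = sequence[max(0, cut_position - 4) : cut_position]
    right = sequence[cut_position : cut_position + 4]
    return CleavageContext(left, right)


def affinity_coefficient(context: CleavageContext, fm: FrequencyMatrix, gamma: float = 1.0) -> float:
    """Affinity score coupling a cleavage site to a specificity profile.

    Geometric-mean-normalised product of the matched frequencies raised to
    the power 8/(k+l), scaled by ``gamma``; zero as soon as any matched
    frequency is zero.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    prod = 1.0
    for locus, residue in context.loci():
        freq = fm.freq(residue, locus)
        if freq == 0.0:
            return 0.0
        prod *= freq
    return gamma * prod ** (8.0 / (context.k + context.l))


def detect_cleavages(
    sequence: str,
    fm: FrequencyMatrix,
    threshold: float,
    gamma: float = 1.0,
) -> list[DetectedCleavage]:
    """All cut positions of ``sequence`` scoring at least ``threshold``.

    Detection is thresholding of the affinity coefficient itself, so the
    detected set is monotone in the threshold.  Sequences shorter than two
    residues have no internal bond and yield an empty list.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out: list[DetectedCleavage] = []
    if len(sequence) < 2:
        return out
    _check_residues(sequence)
    for c in range(1, len(sequence)):
        rho = affinity_coefficient(extract_context(sequence, c), fm, gamma)
        if rho >= threshold:
            out.append(DetectedCleavage(sequence, c, fm.peptidase_id, rho))
    return out


def read_frequency_matrices(directory: str | Path) -> list[FrequencyMatrix]:
    """Load every ``*.tsv`` specificity profile in a directory."""
    paths = sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no frequency-matrix TSV files in {directory}")
    return [FrequencyMatrix.from_tsv(p) for p in paths]
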