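"""Synthetic inputs for the whole pipeline, plus a stochastic oracle.

Everything the pipeline consumes can be generated here with a seed:
peptidase specificity matrices (column-stochastic, one designated
dominant P1 residue per enzyme, near-uniform flanking loci), random
precursor pools, ground-truth degradation parameters, model-consistent
noisy amounts, composition-based retention-time models and synthetic
monoisotopic peak lists.

The noise model follows the validation design of the underlying method:
observed amounts are drawn per node from a normal distribution centred on
the stationary expectation with standard deviation sigma relative to that
expectation (sigma in {0.1, 0.01, 0.001} spans weak/moderate/good
agreement with the model), redrawing until positive.

A Gillespie stochastic-simulation algorithm over the reaction network
(creation at sources, per-particle cleavage, per-particle complete
degradation at leaves) serves as an independent oracle: the network is
first order, so its stationary mean particle counts satisfy the same
balance equations as the deterministic expectations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .graph import CleavageGraph, in_silico_digest
from .infer import ModelParameters, activity_constraint_matrix, expected_amounts
from .msmatch import (
    MAX_CHARGE,
    MIN_CHARGE,
    Peak,
    RTModel,
    monoisotopic_mass,
    mz_for_charge,
    write_peaklist,
)
from .profiles import ALPHABET, AMINO_ACIDS, GAP, LOCI, FrequencyMatrix

_SEED_CAP = 2**31 - 1


@dataclass
class SynthConfig:
    """Conditions of the synthetic study.

    ``specificity_sharpness`` s controls how concentrated the generated
    profiles are: the dominant P1 residue carries weight 1 - 1/s and the
    flanking columns are Dirichlet-distributed around uniform with
    concentration 2.5*s per residue.  ``gamma`` rescales all affinity
    coefficients (pure gauge: absorbed by the activities); the default
    puts full-window matching sites at order unity.  The detection
    threshold sits between the scores of sites that do and do not carry a
    dominant P1 residue, with a wide margin on both sides.
    """

    n_peptidases: int = 4
    n_precursors: int = 3
    precursor_length_range: tuple[int, int] = (10, 14)
    specificity_sharpness: float = 200.0
    noise_sigma: float = 0.01
    seed: int = 0
    gamma: float = 5e10
    detection_threshold: float = 0.15
    scan_range: tuple[float, float] = (100.0, 2000.0)

    def __post_init__(self) -> None:
        lo, hi = self.precursor_length_range
        if lo < 2 or hi < lo:
            raise ValueError("precursor lengths must be >= 2 and ordered")
        if min(self.n_peptidases, self.n_precursors) < 1:
            raise ValueError("need at least one peptidase and one precursor")
        if self.specificity_sharpness < 1:
            raise ValueError("specificity_sharpness must be >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """A generated graph with its true parameters and expectations."""

    z_true: ModelParameters
    graph: CleavageGraph
    phi_true: dict[str, float]


@dataclass
class Benchmark:
    """Ground truth plus noisy datasets at the three study noise levels."""

    config: SynthConfig
    matrices: list[FrequencyMatrix]
    precursors: list[str]
    truth: GroundTruth
    datasets: dict[float, dict[str, float]]


def _rng_for(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.default_rng([cfg_seed, stream]).integers(_SEED_CAP))


def generate_frequency_matrices(cfg: SynthConfig) -> list[FrequencyMatrix]:
    """Distinct specificity profiles, one dominant P1 residue per enzyme."""
    rng = _rng_for(cfg.seed, 1)
    n_aa = len(AMINO_ACIDS)
    dominant = rng.choice(n_aa, size=min(cfg.n_peptidases, n_aa), replace=False)
    if cfg.n_peptidases > n_aa:  # more enzymes than residues: reuse with jitter
        extra = rng.choice(n_aa, size=cfg.n_peptidases - n_aa, replace=True)
        dominant = np.concatenate([dominant, extra])
    s = cfg.specificity_sharpness
    w = 1.0 - 1.0 / s
    matrices = []
    p1 = LOCI.index("P1")
    for k in range(cfg.n_peptidases):
        f = np.zeros((len(ALPHABET), len(LOCI)))
        for j in range(len(LOCI)):
            if j == p1:
                col = np.full(n_aa, (1.0 - w) / (n_aa - 1))
                col[dominant[k]] = w
            else:
                col = rng.dirichlet(np.full(n_aa, 2.5 * s))
            f[:n_aa, j] = col / col.sum()
        matrices.append(FrequencyMatrix(f"pep{k:02d}", f))
    return matrices


def generate_precursors(cfg: SynthConfig, stream: int = 2) -> list[str]:
    """Uniform-random precursor sequences within the configured length range."""
    rng = _rng_for(cfg.seed, stream)
    lo, hi = cfg.precursor_length_range
    out = []
    for _ in range(cfg.n_precursors):
        length = int(rng.integers(lo, hi + 1))
        out.append("".join(rng.choice(list(AMINO_ACIDS), size=length)))
    return out


def generate_rt_model(seed: int = 0) -> RTModel:
    """A random but fixed composition-based retention-time law.

    Coefficients span roughly -0.5..2.5 min per residue around a 10 min
    intercept — the scale of reversed-phase gradients.
    """
    rng = np.random.default_rng(seed)
    coefs = {a: float(rng.uniform(-0.5, 2.5)) for a in AMINO_ACIDS}
    return RTModel(10.0, coefs)


def generate_rt_training(
    rtm: RTModel, n: int = 30, seed: int = 0, noise_sd: float = 0.0
) -> list[tuple[str, float]]:
    """Training pairs drawn exactly (or noisily) from an RT law."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        length = int(rng.integers(6, 16))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        rt = rtm.predict(seq) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        pairs.append((seq, rt))
    return pairs


def simulate_amounts(
    gt: GroundTruth, sigma: float, seed: int, absolute: bool = False
) -> dict[str, float]:
    """Noisy observed amounts around the stationary expectations.

    Per node: normal with mean phi_true and standard deviation
    sigma * phi_true (relative noise; amounts are in arbitrary intensity
    units, so a dimensionless sigma is read as a fraction of the mean),
    redrawn until strictly positive.  ``absolute=True`` uses sigma as an
    absolute standard deviation instead.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    amounts = {}
    for seq in sorted(gt.phi_true):
        mean = gt.phi_true[seq]
        sd = sigma if absolute else sigma * mean
        draw = rng.normal(mean, sd)
        while draw <= 0:
            draw = rng.normal(mean, sd)
        amounts[seq] = float(draw)
    return amounts


def simulate_peaklist(
    amounts: Mapping[str, float],
    rtm: RTModel,
    coordinate_noise: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    scan_range: tuple[float, float] = (100.0, 2000.0),
) -> list[Peak]:
    """One monoisotopic peak per peptide, intensity equal to its amount.

    The charge is the heaviest state in 1..8 whose m/z stays inside the
    scan range; coordinates are jittered by ``coordinate_noise``
    (ppm on m/z, minutes on RT).  Peptides with no feasible charge are
    silently absent from the list.
    """
    mz_ppm, rt_sd = coordinate_noise
    rng = np.random.default_rng(seed)
    lo, hi = scan_range
    peaks = []
    for seq in sorted(amounts):
        if amounts[seq] <= 0:
            continue
        mass_da = monoisotopic_mass(seq)
        charge = None
        for z in range(MAX_CHARGE, MIN_CHARGE - 1, -1):
            if lo <= mz_for_charge(mass_da, z) <= hi:
                charge = z
                break
        if charge is None:
            continue
        mz = mz_for_charge(mass_da, charge)
        if mz_ppm:
            mz *= 1.0 + rng.normal(0.0, mz_ppm) * 1e-6
        rt = rtm.predict(seq)
        if rt_sd:
            rt += rng.normal(0.0, rt_sd)
        peaks.append(Peak(mz, rt, charge, float(amounts[seq])))
    return peaks


def gillespie_stationary_means(
    graph: CleavageGraph,
    z: ModelParameters,
    horizon: float,
    burn_in: float,
    seed: int = 0,
    n_batches: int = 20,
) -> dict[str, tuple[float, float]]:
    """Time-averaged stationary particle counts by exact stochastic simulation.

    Reactions: creation of one particle at each source at constant rate
    phi*, cleavage of each substrate particle by each event at
    per-particle rate rho*lambda (consuming the substrate, producing one
    prefix and one suffix particle), and complete degradation of each
    leaf particle at per-particle rate phi-bot.  Returns per node the
    time-weighted mean count over (burn_in, horizon] and its batch-means
    standard error over ``n_batches`` equal spans.
    """
    if horizon <= burn_in:
        raise ValueError("horizon must exceed burn_in")
    order = sorted(graph.nodes)
    index = {s: i for i, s in enumerate(order)}
    n = len(order)
    # reaction table: (rate-constant, substrate-or-None, delta vector)
    const_rates = []
    for seq, rate in z.creation.items():
        delta = np.zeros(n)
        delta[index[seq]] = 1
        const_rates.append((rate, None, delta))
    for e in graph.events:
        delta = np.zeros(n)
        delta[index[e.substrate]] -= 1
        delta[index[e.prefix]] += 1
        delta[index[e.suffix]] += 1
        const_rates.append((e.rho * z.activities[e.peptidase_id], index[e.substrate], delta))
    for seq, rate in z.degradation.items():
        delta = np.zeros(n)
        delta[index[seq]] = -1
        const_rates.append((rate, index[seq], delta))
    k = np.array([c for c, _, _ in const_rates])
    subs = [s for _, s, _ in const_rates]
    deltas = np.array([d for _, _, d in const_rates])

    rng = np.random.default_rng(seed)
    state = np.zeros(n)
    t = 0.0
    edges = np.linspace(burn_in, horizon, n_batches + 1)
    batch_sums = np.zeros((n_batches, n))
    batch_len = edges[1] - edges[0]

    def accumulate(t0: float, t1: float, counts: np.ndarray) -> None:
        # spread the dwell interval [t0, t1) over the batch grid
        lo_b = max(0, int(np.searchsorted(edges, t0, side="right")) - 1)
        for b in range(lo_b, n_batches):
            a, bnd = edges[b], edges[b + 1]
            overlap = min(t1, bnd) - max(t0, a)
            if overlap > 0:
                batch_sums[b] += overlap * counts
            if bnd >= t1:
                break

    while t < horizon:
        rates = np.array([k[i] if subs[i] is None else k[i] * state[subs[i]]
                          for i in range(len(k))])
        total = rates.sum()
        if total <= 0:  # empty network: dwell forever in the current state
            if t < horizon:
                accumulate(max(t, burn_in), horizon, state)
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        if t_next > burn_in:
            accumulate(max(t, burn_in), min(t_next, horizon), state)
        if t_next >= horizon:
            break
        reaction = rng.choice(len(k), p=rates / total)
        state = state + deltas[reaction]
        t = t_next

    batch_means = batch_sums / batch_len
    means = batch_means.mean(axis=0)
    ses = batch_means.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return {seq: (float(means[i]), float(ses[i])) for seq, i in index.items()}


_BENCHMARK_SIGMAS = (0.1, 0.01, 0.001)


def _draw_parameters(graph: CleavageGraph, rng: np.random.Generator) -> ModelParameters:
    creation = {s: float(rng.uniform(5.0, 20.0)) for s in sorted(graph.sources())}
    degradation = {s: float(rng.uniform(0.5, 2.0)) for s in sorted(graph.leaves())}
    activities = {p: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                  for p in sorted(graph.peptidases())}
    return ModelParameters(creation, degradation, activities)


def make_ground_truth(cfg: SynthConfig) -> tuple[list[FrequencyMatrix], list[str], GroundTruth]:
    """Matrices, precursors and a fully observed, well-posed ground truth.

    Precursor pools are resampled (deterministically) until the digestion
    graph is well posed: every precursor is cleaved at least once and is
    a true source, every peptidase drives at least one event, no node is
    simultaneously source and leaf, and the fully observed node count m
    is at least the parameter count n.
    """
    matrices = generate_frequency_matrices(cfg)
    param_rng = _rng_for(cfg.seed, 3)
    for attempt in range(100):
        precursors = generate_precursors(cfg, stream=100 + attempt)
        if len(set(precursors)) < len(precursors):
            continue
        graph = in_silico_digest(precursors, matrices, cfg.detection_threshold, cfg.gamma)
        sources, leaves = graph.sources(), graph.leaves()
        if sources & leaves:
            continue
        if set(precursors) != sources:
            continue
        if {fm.peptidase_id for fm in matrices} != graph.peptidases():
            continue
        m = len(graph.nodes)
        n = len(sources) + len(leaves) + len(graph.peptidases())
        if m < n:
            continue
        z_true = _draw_parameters(graph, param_rng)
        phi_true = expected_amounts(graph, z_true)
        # all activities must be identifiable up to the scale gauge, and
        # not just barely: require a well-conditioned constraint matrix
        constraints, peps = activity_constraint_matrix(graph, phi_true)
        svals = np.linalg.svd(constraints, compute_uv=False)
        if len(svals) < len(peps) - 1 or svals[len(peps) - 2] < 1e-4 * svals[0]:
            continue
        return matrices, precursors, GroundTruth(z_true, graph, phi_true)
    raise RuntimeError("could not generate a well-posed benchmark graph; "
                       "relax the configuration")


def make_benchmark(cfg: SynthConfig) -> Benchmark:
    """Ground truth plus noisy datasets at sigma in {0.1, 0.01, 0.001}."""
    matrices, precursors, truth = make_ground_truth(cfg)
    noise_rng = _rng_for(cfg.seed, 4)
    datasets = {
        sigma: simulate_amounts(truth, sigma, int(noise_rng.integers(_SEED_CAP)))
        for sigma in _BENCHMARK_SIGMAS
    }
    return Benchmark(cfg, matrices, precursors, truth, datasets)


def write_benchmark(bench: Benchmark, directory: str | Path) -> None:
    """Write a benchmark as plain-text artifacts (TSV/FASTA/JSON)."""
    directory = Path(directory)
    (directory / "matrices").mkdir(parents=True, exist_ok=True)
    for fm in bench.matrices:
        fm.to_tsv(directory / "matrices" / f"{fm.peptidase_id}.tsv")
    with open(directory / "precursors.fasta", "w") as fh:
        for i, seq in enumerate(bench.precursors):
            fh.write(f">precursor_{i}\n{seq}\n")
    bench.truth.graph.to_json(directory / "graph.json")
    (directory / "truth.json").write_text(json.dumps({
        "z_true": bench.truth.z_true.to_dict(),
        "phi_true": bench.truth.phi_true,
    }, indent=1))
    for sigma, amounts in bench.datasets.items():
        name = f"amounts_sigma{sigma}.tsv"
        with open(directory / name, "w") as fh:
            fh.write("sequence\tamount\n")
            for seq in sorted(amounts):
                fh.write(f"{seq}\t{amounts[seq]!r}\n")
    rtm = generate_rt_model(bench.config.seed)
    peaks = simulate_peaklist(bench.datasets[0.001], rtm, seed=bench.config.seed,
                              scan_range=bench.config.scan_range)
    write_peaklist(peaks, directory / "peaks.tsv")
    (directory / "config.json").write_text(json.dumps(bench.config.to_dict(), indent=1))
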