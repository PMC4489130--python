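"""Zipf-Mandelbrot simulation of clonal frequency distributions.

Immune repertoires empirically follow power-law (Zipf-like) clonal
frequency distributions: log clone frequency is approximately linear in
log clonal rank.  The generator here draws sequencing reads from a
Zipf-Mandelbrot population whose type density is

    g(p) = C * p^(-a-1)   for 0 <= p <= B,   0 otherwise,

with shape ``a`` (``zipf_alpha``) in (0, 1), top-clone probability ``B``
(``zipf_B``) in (0, 1), and normalizing constant ``C``.  ``B`` is the
probability of the most frequent clone and thus sets the degree of
clonal expansion: small ``B`` gives a polyclonal (even) repertoire,
large ``B`` an oligoclonal (expanded) one.

Integrating the density gives the number of clone types with probability
at least ``p``, ``G(p) = (C/a) * (p^-a - B^-a)``; inverting the count law
at integer ranks yields the clone probabilities

    pi_k = (a*(k-1)/C + B^-a)^(-1/a),   k = 1, 2, ...

so that ``pi_1 = B`` exactly and ``pi_k`` decreases in ``k``.  ``C`` is
fixed by requiring ``sum_k pi_k = 1`` (numeric root-finding on the
Hurwitz-zeta closed form of the series).  Reads are then drawn
multinomially from ``pi`` truncated to a finite support carrying all but
a negligible tail mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import zeta

from .repertoire import ClonalFrequencyDistribution

__all__ = [
    "ZipfModel",
    "SimulatedRepertoire",
    "zipf_clone_probabilities",
    "simulate_repertoire",
    "simulate_cohort",
    "subsample_reads",
    "frequency_matrix",
]

_TAIL_MASS = 1e-9
_MAX_RANK_CAP = 10**7


def _series_total(C: float, a: float, B: float, k_from: int = 0) -> float:
    """sum_{k > k_from} pi_k for unnormalized pi, via the Hurwitz zeta."""
    s = 1.0 / a
    q = C * B ** (-a) / a
    return (C / a) ** s * zeta(s, q + k_from)


@dataclass(frozen=True)
class ZipfModel:
    """Zipf-Mandelbrot clone-probability model.

    Use :meth:`from_params` to construct; it solves for the normalizing
    constant ``C`` and the truncation rank.
    """

    zipf_alpha: float
    zipf_B: float
    C: float
    max_rank: int

    @classmethod
    def from_params(
        cls,
        zipf_alpha: float,
        zipf_B: float,
        tail_mass: float = _TAIL_MASS,
        max_rank_cap: int = _MAX_RANK_CAP,
    ) -> "ZipfModel":
        if not (0.0 < zipf_alpha < 1.0):
            raise ValueError(f"zipf_alpha must be in (0, 1), got {zipf_alpha}")
        if not (0.0 < zipf_B < 1.0):
            raise ValueError(f"zipf_B must be in (0, 1), got {zipf_B}")
        a, B = float(zipf_alpha), float(zipf_B)

        def total_minus_one(log_C: float) -> float:
            return _series_total(np.exp(log_C), a, B) - 1.0

        lo, hi = -50.0, 50.0
        # the series total is strictly increasing in C
        while total_minus_one(lo) > 0 and lo > -700:
            lo -= 50.0
        while total_minus_one(hi) < 0 and hi < 700:
            hi += 50.0
        C = float(np.exp(brentq(total_minus_one, lo, hi, xtol=1e-14, rtol=1e-15)))

        # smallest K whose tail carries less than tail_mass
        k_lo, k_hi = 1, 1
        while _series_total(C, a, B, k_hi) > tail_mass and k_hi < max_rank_cap:
            k_hi *= 2
        k_hi = min(k_hi, max_rank_cap)
        while k_lo < k_hi:
            mid = (k_lo + k_hi) // 2
            if _series_total(C, a, B, mid) > tail_mass:
                k_lo = mid + 1
            else:
                k_hi = mid
        return cls(zipf_alpha=a, zipf_B=B, C=C, max_rank=int(k_lo))


def zipf_clone_probabilities(model: ZipfModel) -> np.ndarray:
    """Clone probabilities ``pi_k`` up to the model's truncation rank.

    The residual tail mass beyond ``max_rank`` is renormalized away, so
    the returned vector sums to 1 exactly.
    """
    a, B, C = model.zipf_alpha, model.zipf_B, model.C
    k = np.arange(model.max_rank, dtype=float)
    pi = (a * k / C + B ** (-a)) ** (-1.0 / a)
    return pi / pi.sum()


@dataclass(frozen=True)
class SimulatedRepertoire:
    """A multinomial read sample from a Zipf-Mandelbrot clone population."""

    distribution: ClonalFrequencyDistribution
    model: ZipfModel
    n_reads: int
    seed: int


def _counts_to_distribution(counts: np.ndarray, sample_id: str) -> ClonalFrequencyDistribution:
    observed = np.nonzero(counts)[0]
    obs_counts = counts[observed]
    ids = [f"c{r + 1:07d}" for r in observed]  # rank-indexed clone labels
    total = int(obs_counts.sum())
    return ClonalFrequencyDistribution(
        ids, obs_counts / total, total_reads=total, counts=obs_counts, sample_id=sample_id
    )


def simulate_repertoire(
    model: ZipfModel, n_reads: int, seed: int, sample_id: str | None = None
) -> SimulatedRepertoire:
    """Draw ``n_reads`` i.i.d. reads from the model's clone probabilities."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    pi = zipf_clone_probabilities(model)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, pi)
    sid = sample_id if sample_id is not None else f"zm_a{model.zipf_alpha}_B{model.zipf_B}_s{seed}"
    return SimulatedRepertoire(
        distribution=_counts_to_distribution(counts, sid),
        model=model,
        n_reads=int(n_reads),
        seed=int(seed),
    )


def _spaced_b_values(n: int, b_range, spacing: str, rng) -> np.ndarray:
    b_min, b_max = float(b_range[0]), float(b_range[1])
    if not (0 < b_min <= b_max < 1):
        raise ValueError(f"invalid zipf_B range {b_range}")
    if spacing == "log":
        return np.geomspace(b_min, b_max, n)
    if spacing == "linear":
        return np.linspace(b_min, b_max, n)
    if spacing == "uniform-random":
        return np.sort(rng.uniform(b_min, b_max, n))
    raise ValueError(f"unknown spacing {spacing!r}")


def simulate_cohort(
    n_repertoires: int = 1000,
    zipf_alpha: float = 0.1,
    zipf_B_range=(0.001, 0.1),
    n_reads: int = 10**6,
    seed: int = 0,
    spacing: str = "log",
    equal_composition: bool = True,
) -> list[SimulatedRepertoire]:
    """Simulate a cohort spanning a range of clonal-expansion states.

    ``zipf_B`` values are spread across ``zipf_B_range`` (logarithmically
    by default, since B spans decades of expansion states).  With
    ``equal_composition`` the clones are indexed by population rank, so
    every repertoire lives on one shared clone index and the cohort can
    be assembled into a common frequency matrix for clustering (see
    :func:`frequency_matrix`); this padding never enters diversity
    computations, which only ever see the observed positive frequencies.
    """
    if n_repertoires < 2:
        raise ValueError("n_repertoires must be >= 2")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    b_values = _spaced_b_values(n_repertoires, zipf_B_range, spacing, rng)
    child_seeds = ss.generate_state(n_repertoires, dtype=np.uint32) % (2**31)
    reps = []
    for i, (b, s) in enumerate(zip(b_values, child_seeds)):
        model = ZipfModel.from_params(zipf_alpha, float(b))
        reps.append(simulate_repertoire(model, n_reads, int(s), sample_id=f"sim{i:04d}"))
    return reps


def frequency_matrix(reps) -> tuple[np.ndarray, list[str]]:
    """Stack cohort distributions on the union (rank) clone index.

    Returns an ``(n_repertoires, n_clones)`` frequency matrix with zeros
    for clones absent from a repertoire, and the sample ids.  Intended
    only for clustering/comparison of equal-composition cohorts.
    """
    dists = [r.distribution if isinstance(r, SimulatedRepertoire) else r for r in reps]
    max_rank = 0
    for d in dists:
        ranks = [int(c[1:]) for c in d.clone_ids]
        max_rank = max(max_rank, max(ranks))
    X = np.zeros((len(dists), max_rank))
    for i, d in enumerate(dists):
        idx = np.array([int(c[1:]) - 1 for c in d.clone_ids])
        X[i, idx] = d.frequencies
    return X, [d.sample_id for d in dists]


def subsample_reads(
    rep: SimulatedRepertoire | ClonalFrequencyDistribution,
    fraction: float,
    seed: int,
) -> ClonalFrequencyDistribution:
    """Downsample the read pool without replacement to a depth fraction.

    Draws ``round(fraction * total_reads)`` reads from the observed read
    multiset (multivariate hypergeometric); clones with zero sampled
    reads are dropped.  ``fraction=1`` returns the distribution unchanged.
    """
    dist = rep.distribution if isinstance(rep, SimulatedRepertoire) else rep
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if dist.counts is None:
        raise ValueError("distribution carries no read counts; cannot subsample")
    if fraction == 1.0:
        return dist
    total = int(dist.counts.sum())
    m = int(round(fraction * total))
    if m < 1:
        raise ValueError(f"fraction {fraction} leaves no reads at depth {total}")
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(dist.counts, m)
    keep = np.nonzero(sub)[0]
    kept_counts = sub[keep]
    return ClonalFrequencyDistribution(
        [dist.clone_ids[i] for i in keep],
        kept_counts / m,
        total_reads=m,
        counts=kept_counts,
        sample_id=dist.sample_id,
    )
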