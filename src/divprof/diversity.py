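"""Hill-number Diversity and Evenness profiles.

The order-``alpha`` Hill diversity of a clonal frequency distribution
``f`` is

    D_alpha(f) = (sum_i f_i^alpha)^(1/(1-alpha)),   alpha >= 0,

the *effective number* of equally abundant clones: a repertoire with
``D_alpha = k`` has the same order-``alpha`` diversity as one of ``k``
equally frequent clones.  Special orders recover the classical indices:
``alpha=0`` the species richness SR (number of clones), ``alpha=1`` the
exponential Shannon entropy (the L'Hopital limit of the closed form),
``alpha=2`` the inverse Simpson index, and ``alpha -> inf`` the inverse
Berger-Parker index ``1/max_i f_i``.  As ``alpha`` grows, abundant clones
are weighted more, so the profile ``alpha -> D_alpha`` is non-increasing
and scans the repertoire from its rare tail to its dominant clones.

Evenness divides out the richness, ``E_alpha = D_alpha / SR``, isolating
the *shape* of the distribution (extent of clonal expansion) from its
size; ``E_alpha`` lies in (0, 1] and equals 1 for a uniform repertoire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repertoire import ClonalFrequencyDistribution

__all__ = [
    "default_alpha_grid",
    "validate_alpha_grid",
    "hill_diversity",
    "renyi_entropy",
    "DiversityProfile",
    "EvennessProfile",
    "diversity_profile",
    "evenness_profile",
    "profiles_to_frame",
    "write_profiles_csv",
    "read_profiles_csv",
]

# compensated summation kicks in for very large repertoires
_FSUM_THRESHOLD = 100_000


def default_alpha_grid() -> np.ndarray:
    """The default alpha grid: 0 to 10 in steps of 0.2 (51 values)."""
    return np.round(np.arange(51) * 0.2, 10)


def validate_alpha_grid(alphas) -> np.ndarray:
    grid = np.asarray(alphas, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("alpha grid must be a non-empty 1-D array")
    if np.any(grid < 0):
        raise ValueError("alpha values must be >= 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("alpha grid must be strictly increasing")
    return grid


def _power_sum(f: np.ndarray, alpha: float) -> float:
    p = f**alpha
    if f.size > _FSUM_THRESHOLD:
        return math.fsum(p.tolist())
    return float(np.sum(p))


def hill_diversity(f: ClonalFrequencyDistribution | np.ndarray, alpha: float) -> float:
    """Order-``alpha`` Hill diversity of a frequency distribution.

    ``alpha`` may be any finite value >= 0 or ``numpy.inf`` (the inverse
    Berger-Parker limit ``1/max f_i``).
    """
    freqs = f.frequencies if isinstance(f, ClonalFrequencyDistribution) else np.asarray(f, float)
    if np.isnan(alpha) or (not np.isinf(alpha) and alpha < 0):
        raise ValueError(f"alpha must be >= 0 or inf, got {alpha}")
    if np.isinf(alpha):
        return 1.0 / float(np.max(freqs))
    if alpha == 0:
        return float(freqs.size)
    if alpha == 1:
        # L'Hopital limit of the closed form: exp(Shannon entropy)
        logs = freqs * np.log(freqs)
        if freqs.size > _FSUM_THRESHOLD:
            return math.exp(-math.fsum(logs.tolist()))
        return float(np.exp(-np.sum(logs)))
    s = _power_sum(freqs, alpha)
    return float(s ** (1.0 / (1.0 - alpha)))


def renyi_entropy(f: ClonalFrequencyDistribution | np.ndarray, alpha: float) -> float:
    """Order-``alpha`` Renyi entropy, ``log`` of the Hill diversity."""
    return math.log(hill_diversity(f, alpha))


@dataclass(frozen=True)
class DiversityProfile:
    """Diversity values over an alpha grid for one repertoire."""

    alphas: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", validate_alpha_grid(self.alphas))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.alphas.size != self.values.size:
            raise ValueError("alphas and values must have equal length")


@dataclass(frozen=True)
class EvennessProfile:
    """Evenness values (diversity / species richness) over an alpha grid."""

    alphas: np.ndarray
    values: np.ndarray
    species_richness: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", validate_alpha_grid(self.alphas))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.alphas.size != self.values.size:
            raise ValueError("alphas and values must have equal length")


def diversity_profile(
    f: ClonalFrequencyDistribution, alphas=None, sample_id: str | None = None
) -> DiversityProfile:
    """Evaluate the Hill diversity on a grid of alpha values."""
    grid = default_alpha_grid() if alphas is None else validate_alpha_grid(alphas)
    values = np.array([hill_diversity(f, a) for a in grid])
    sid = sample_id if sample_id is not None else getattr(f, "sample_id", "")
    return DiversityProfile(grid, values, sample_id=sid)


def evenness_profile(
    f: ClonalFrequencyDistribution, alphas=None, sample_id: str | None = None
) -> EvennessProfile:
    """Evaluate the evenness ``E_alpha = D_alpha / SR`` on an alpha grid."""
    prof = diversity_profile(f, alphas, sample_id=sample_id)
    sr = int(hill_diversity(f, 0.0))
    return EvennessProfile(prof.alphas, prof.values / sr, species_richness=sr, sample_id=prof.sample_id)


def profiles_to_frame(profiles: list[DiversityProfile | EvennessProfile]) -> pd.DataFrame:
    """Long-format table with columns sample_id, alpha, diversity, evenness.

    Accepts diversity profiles, evenness profiles, or a mixture; missing
    columns are filled with NaN.
    """
    rows = []
    for p in profiles:
        kind = "evenness" if isinstance(p, EvennessProfile) else "diversity"
        for a, v in zip(p.alphas, p.values):
            rows.append({"sample_id": p.sample_id, "alpha": a, kind: v})
    df = pd.DataFrame(rows)
    for col in ("diversity", "evenness"):
        if col not in df.columns:
            df[col] = np.nan
    return (
        df.groupby(["sample_id", "alpha"], as_index=False)[["diversity", "evenness"]]
        .first()
        .sort_values(["sample_id", "alpha"], kind="stable")
        .reset_index(drop=True)
    )


def write_profiles_csv(path, profiles: list[DiversityProfile | EvennessProfile]) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles_csv(path) -> tuple[list[DiversityProfile], list[EvennessProfile]]:
    """Inverse of :func:`write_profiles_csv`."""
    df = pd.read_csv(path)
    div, eve = [], []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("alpha", kind="stable")
        alphas = grp["alpha"].to_numpy()
        if "diversity" in grp and grp["diversity"].notna().all():
            div.append(DiversityProfile(alphas, grp["diversity"].to_numpy(), sample_id=str(sid)))
        if "evenness" in grp and grp["evenness"].notna().all():
            vals = grp["evenness"].to_numpy()
            sr = int(round(1.0 / vals[0])) if vals[0] > 0 else 0
            # SR is recoverable when a diversity column is present
            if "diversity" in grp and grp["diversity"].notna().all():
                sr = int(round(grp["diversity"].to_numpy()[0]))
            eve.append(EvennessProfile(alphas, vals, species_richness=sr, sample_id=str(sid)))
    return div, eve
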