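"""Clonotype table ingestion and clonal frequency distributions.

A *clone* (clonotype) is the set of sequencing reads sharing a clonal
identifier, typically the exact CDR3 amino-acid sequence.  The object all
downstream computations consume is the :class:`ClonalFrequencyDistribution`:
the vector ``f`` of per-clone read proportions, ``f_i > 0``, ``sum f_i = 1``.

Two table dialects are read:

``simple``
    two tab-separated columns ``clone_id`` and ``count`` with a header row;
``airr``
    an AIRR Rearrangement-style TSV where ``junction_aa`` carries the clone
    identifier, ``duplicate_count`` the read count (1 if the column is
    absent) and ``productive`` the functionality flag.

Preprocessing mirrors standard repertoire-sequencing practice: keep
productive rearrangements, require a minimal CDR3 length of four amino
acids, aggregate reads by exact (100 % identity) amino-acid sequence, and
require a minimum aggregated abundance of two reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClonotypeRecord",
    "ClonalFrequencyDistribution",
    "SampleMetadata",
    "FormatError",
    "EmptyInputError",
    "EmptyRepertoireError",
    "read_clonotype_table",
    "read_metadata_table",
    "apply_preprocessing_filters",
    "aggregate_by_clone",
    "to_frequency_distribution",
]

_FREQ_SUM_TOL = 1e-9


class FormatError(ValueError):
    """A required column is missing or a table cannot be interpreted."""


class EmptyInputError(ValueError):
    """An input file or record list contains no usable rows."""


class EmptyRepertoireError(ValueError):
    """Preprocessing removed every clonotype of a sample."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype row: identifier, read count and functionality flag."""

    clone_id: str
    count: int
    productive: bool = True
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.clone_id:
            raise ValueError("clone_id must be non-empty")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class SampleMetadata:
    """Maps a sample to its immunological-status label (plus covariates)."""

    sample_id: str
    status_label: str
    covariates: dict[str, str] = field(default_factory=dict)


class ClonalFrequencyDistribution:
    """Normalized clonal frequency vector with clone identifiers.

    Parameters
    ----------
    clone_ids
        Unique clone identifiers, one per frequency.
    frequencies
        Per-clone read proportions; all positive, summing to 1 within 1e-9.
    total_reads
        Number of sequencing reads the frequencies were derived from.
    counts
        Optional integer read counts per clone (kept when the distribution
        was built from counts; required for read subsampling).
    sample_id
        Optional sample identifier carried through profiles.
    """

    __slots__ = ("clone_ids", "frequencies", "total_reads", "counts", "sample_id")

    def __init__(
        self,
        clone_ids,
        frequencies,
        total_reads: int | None = None,
        counts=None,
        sample_id: str = "",
    ) -> None:
        ids = tuple(str(c) for c in clone_ids)
        f = np.asarray(frequencies, dtype=float)
        if f.ndim != 1 or len(ids) != f.size:
            raise ValueError("clone_ids and frequencies must be 1-D and equal length")
        if f.size == 0:
            raise EmptyRepertoireError("empty frequency distribution")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be > 0")
        if abs(f.sum() - 1.0) > _FREQ_SUM_TOL:
            raise ValueError(f"frequencies must sum to 1 (got {f.sum()!r})")
        if len(set(ids)) != len(ids):
            raise ValueError("clone_ids must be unique")
        self.clone_ids = ids
        self.frequencies = f
        self.counts = None if counts is None else np.asarray(counts, dtype=np.int64)
        if self.counts is not None and self.counts.size != f.size:
            raise ValueError("counts must match frequencies in length")
        self.total_reads = int(total_reads) if total_reads is not None else None
        self.sample_id = sample_id

    @property
    def n(self) -> int:
        """Number of unique clones (species richness)."""
        return self.frequencies.size

    @classmethod
    def from_counts(cls, counts: dict[str, int] | "pd.Series", sample_id: str = ""):
        """Build a distribution from a clone -> read-count mapping."""
        if isinstance(counts, pd.Series):
            counts = counts.to_dict()
        ids = list(counts)
        c = np.array([counts[k] for k in ids], dtype=np.int64)
        if c.size == 0:
            raise EmptyRepertoireError("no clones")
        if np.any(c < 1):
            raise ValueError("counts must be >= 1")
        total = int(c.sum())
        if total == 0:
            raise ValueError("zero total read count")
        return cls(ids, c / total, total_reads=total, counts=c, sample_id=sample_id)

    @classmethod
    def from_frequencies(cls, frequencies, clone_ids=None, sample_id: str = ""):
        """Build a distribution from frequencies printed to finite precision."""
        f = np.asarray(frequencies, dtype=float)
        if clone_ids is None:
            clone_ids = [f"clone_{i + 1}" for i in range(f.size)]
        return cls(clone_ids, f, sample_id=sample_id)

    def sorted_descending(self) -> "ClonalFrequencyDistribution":
        """Return a copy with clones rank-ordered by decreasing frequency."""
        order = np.argsort(-self.frequencies, kind="stable")
        return ClonalFrequencyDistribution(
            [self.clone_ids[i] for i in order],
            self.frequencies[order],
            total_reads=self.total_reads,
            counts=None if self.counts is None else self.counts[order],
            sample_id=self.sample_id,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ClonalFrequencyDistribution(n={self.n}, "
            f"total_reads={self.total_reads}, sample_id={self.sample_id!r})"
        )


def _parse_productive(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().upper() in {"T", "TRUE", "YES", "Y", "1", "PRODUCTIVE"}


def read_clonotype_table(path, dialect: str = "simple", sample_id: str = "") -> list[ClonotypeRecord]:
    """Read a clonotype table into :class:`ClonotypeRecord` rows.

    Rows lacking a clone identifier or a parseable count are reported via
    :mod:`logging` and dropped.
    """
    if dialect not in {"simple", "airr"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if dialect == "simple":
        id_col, count_col, prod_col = "clone_id", "count", None
    else:
        id_col, count_col, prod_col = "junction_aa", "duplicate_count", "productive"
    if id_col not in df.columns:
        raise FormatError(f"{path}: missing required column {id_col!r}")
    if dialect == "simple" and count_col not in df.columns:
        raise FormatError(f"{path}: missing required column {count_col!r}")
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")

    records: list[ClonotypeRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        clone = row.get(id_col)
        if clone is None or pd.isna(clone) or str(clone).strip() == "":
            n_dropped += 1
            continue
        raw_count = row.get(count_col)
        if raw_count is None or pd.isna(raw_count):
            if dialect == "airr" and count_col not in df.columns:
                count = 1
            else:
                n_dropped += 1
                continue
        else:
            try:
                count = int(float(raw_count))
            except (TypeError, ValueError):
                n_dropped += 1
                continue
        if count < 1:
            n_dropped += 1
            continue
        productive = True
        if prod_col is not None and prod_col in df.columns:
            productive = _parse_productive(row.get(prod_col))
        records.append(
            ClonotypeRecord(str(clone).strip(), count, productive=productive, sample_id=sample_id)
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing/invalid clone_id or count", path, n_dropped)
    return records


def read_metadata_table(path) -> list[SampleMetadata]:
    """Read a sample-metadata TSV with ``sample_id`` and ``status_label`` columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "status_label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in ("sample_id", "status_label")]
    out = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = str(d["sample_id"])
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        out.append(
            SampleMetadata(sid, str(d["status_label"]), {k: str(d[k]) for k in extra})
        )
    return out


def aggregate_by_clone(records: list[ClonotypeRecord]) -> list[ClonotypeRecord]:
    """Sum read counts of records sharing the exact same clone_id."""
    agg: dict[tuple[str, str], int] = {}
    prod: dict[tuple[str, str], bool] = {}
    for r in records:
        key = (r.sample_id, r.clone_id)
        agg[key] = agg.get(key, 0) + r.count
        # a clone is productive if any of its reads were flagged productive
        prod[key] = prod.get(key, False) or r.productive
    return [
        ClonotypeRecord(clone, count, productive=prod[(sid, clone)], sample_id=sid)
        for (sid, clone), count in agg.items()
    ]


def apply_preprocessing_filters(
    records: list[ClonotypeRecord],
    min_cdr3_aa_len: int = 4,
    min_abundance: int = 2,
    require_productive: bool = True,
) -> list[ClonotypeRecord]:
    """Apply the standard repertoire preprocessing filters.

    Order: productive flag, then CDR3 amino-acid length, then aggregation by
    exact clone identity, then the minimum aggregated abundance.  The
    operation is idempotent.
    """
    if not records:
        raise EmptyInputError("no records to filter")
    kept = records
    if require_productive:
        kept = [r for r in kept if r.productive]
    kept = [r for r in kept if len(r.clone_id) >= min_cdr3_aa_len]
    kept = aggregate_by_clone(kept)
    kept = [r for r in kept if r.count >= min_abundance]
    if not kept:
        raise EmptyRepertoireError("all clonotypes removed by preprocessing filters")
    return sorted(kept, key=lambda r: (r.sample_id, -r.count, r.clone_id))


def to_frequency_distribution(
    records: list[ClonotypeRecord], sample_id: str | None = None
) -> ClonalFrequencyDistribution:
    """Turn clonotype records (one sample) into a frequency distribution.

    Records are aggregated by exact clone identity; ``f_i = count_i / total``.
    """
    if not records:
        raise EmptyInputError("no records")
    sids = {r.sample_id for r in records}
    if len(sids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(sids)}")
    agg = aggregate_by_clone(records)
    agg.sort(key=lambda r: (-r.count, r.clone_id))
    counts = {r.clone_id: r.count for r in agg}
    return ClonalFrequencyDistribution.from_counts(
        counts, sample_id=sample_id if sample_id is not None else next(iter(sids))
    )
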