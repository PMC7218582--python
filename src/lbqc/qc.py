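"""Per-sample QC statistics and technical-repeat reproducibility.

These are the quantities the exclusion criteria are derived from: read
count, Shannon diversity, observed and spurious OTU counts, biomass/age
correlations, and the pairwise R² of repeat sequencing profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountTable, ProportionTable, Role, SampleRecord, to_proportions

__all__ = [
    "QCRecord",
    "ReproducibilityRecord",
    "shannon_index",
    "pairwise_r2",
    "group_reproducibility",
    "spurious_otu_stats",
    "compute_qc",
    "qc_correlations",
    "biomass_gate",
]


@dataclass(frozen=True)
class QCRecord:
    sample_id: str
    read_count: int
    shannon: float
    otu_count: int
    spurious_count: int
    copies_per_ul: float
    age_days: float


@dataclass(frozen=True)
class ReproducibilityRecord:
    """Squared Pearson correlation of two repeat profiles over the union of
    their OTUs (equal to the OLS-with-intercept coefficient of
    determination). ``undefined`` marks zero-variance inputs."""

    repeat_group: str
    pair: tuple[str, str]
    r_squared: float
    same_run: bool
    undefined: bool = False


def shannon_index(p: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H = −Σ p_i ln p_i (natural log), zero terms skipped.

    Accepts a proportion vector or a raw count vector (closed internally).
    """
    v = np.asarray(p, dtype=float)
    if (v < 0).any():
        raise ValueError("negative entries in abundance vector")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector has no diversity")
    q = v / total
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def _r2_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), True
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r), False


def pairwise_r2(
    group: ProportionTable,
    repeat_group: str = "",
    same_run: Mapping[str, str] | None = None,
) -> list[ReproducibilityRecord]:
    """All unordered-pair R² records for one repeat group.

    ``same_run`` maps sample_id -> run_id; when given, each record notes
    whether the two repeats came from the same sequencing run. A group of
    size k yields k(k−1)/2 records.
    """
    ids = group.sample_ids
    if len(ids) < 2:
        raise ValueError("a repeat group needs at least two samples")
    out = []
    mat = group.data.to_numpy(dtype=float)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            r2, undef = _r2_pair(mat[:, a], mat[:, b])
            within = (
                same_run is not None and same_run[ids[a]] == same_run[ids[b]]
            )
            out.append(
                ReproducibilityRecord(
                    repeat_group, (ids[a], ids[b]), r2, within, undef
                )
            )
    return out


def group_reproducibility(
    p: ProportionTable, records: Sequence[SampleRecord]
) -> list[ReproducibilityRecord]:
    """Pairwise R² for every repeat group of size >= 2 in the metadata."""
    by_group: dict[str, list[SampleRecord]] = {}
    for r in records:
        if r.role == Role.SPECIMEN and r.repeat_group and r.sample_id in p.sample_ids:
            by_group.setdefault(r.repeat_group, []).append(r)
    runs = {r.sample_id: r.run_id for r in records}
    out: list[ReproducibilityRecord] = []
    for group, members in sorted(by_group.items()):
        if len(members) < 2:
            continue
        sub = p.select_samples([m.sample_id for m in members])
        out.extend(pairwise_r2(sub, group, same_run=runs))
    return out


def spurious_otu_stats(
    t: CountTable,
    min_total: int = 5,
    roles: Mapping[str, Role] | None = None,
) -> tuple[list[str], pd.Series, dict[str, float]]:
    """Identify spurious OTUs and summarize their per-sample occurrence.

    An OTU is spurious iff its total count across ALL samples (specimens and
    controls together) is below ``min_total``. Returns the spurious OTU ids,
    the per-sample count of spurious OTUs present, and — when ``roles`` is
    given — the per-role frequency (total spurious occurrences / number of
    samples of that role).
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = t.data.sum(axis=1)
    spurious = list(totals.index[totals < min_total])
    present = (t.data.loc[spurious] > 0).sum(axis=0) if spurious else pd.Series(
        0, index=t.sample_ids
    )
    per_sample = present.astype(int)
    freq: dict[str, float] = {}
    if roles is not None:
        by_role: dict[str, list[str]] = {}
        for sid in t.sample_ids:
            role = roles.get(sid)
            if role is not None:
                by_role.setdefault(role.value, []).append(sid)
        for role, sids in by_role.items():
            freq[role] = float(per_sample[sids].sum() / len(sids))
    return spurious, per_sample, freq


def compute_qc(
    t: CountTable,
    records: Sequence[SampleRecord],
    min_total: int = 5,
) -> list[QCRecord]:
    """Assemble per-sample QC records from a count table and metadata."""
    _, spurious_per_sample, _ = spurious_otu_stats(t, min_total)
    by_id = {r.sample_id: r for r in records}
    out = []
    for sid in t.sample_ids:
        col = t.data[sid].to_numpy()
        nreads = int(col.sum())
        n_otu = int((col > 0).sum())
        shannon = shannon_index(col) if nreads > 0 else 0.0
        meta = by_id.get(sid)
        out.append(
            QCRecord(
                sample_id=sid,
                read_count=nreads,
                shannon=shannon,
                otu_count=n_otu,
                spurious_count=int(spurious_per_sample[sid]),
                copies_per_ul=meta.copies_per_ul if meta else float("nan"),
                age_days=meta.age_days if meta else float("nan"),
            )
        )
    return out


def _log_biomass(x: np.ndarray) -> np.ndarray:
    return np.log(x + 1.0)


def qc_correlations(
    records: Sequence[QCRecord], method: str = "pearson"
) -> dict[str, float | None]:
    """Correlations of biomass with age, read count and Shannon diversity.

    Biomass enters on the natural-log scale, ln(copies/μl + 1); incomplete
    records are dropped pairwise. A ``None`` value marks an undefined
    correlation (fewer than 3 complete pairs or zero variance).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    biomass = np.array([r.copies_per_ul for r in records], dtype=float)
    pairs = {
        "r_age_biomass": np.array([r.age_days for r in records], dtype=float),
        "r_biomass_reads": np.array([r.read_count for r in records], dtype=float),
        "r_biomass_shannon": np.array([r.shannon for r in records], dtype=float),
    }
    out: dict[str, float | None] = {}
    lb = np.where(np.isnan(biomass), np.nan, _log_biomass(biomass))
    for name, other in pairs.items():
        mask = ~(np.isnan(lb) | np.isnan(other))
        x, y = lb[mask], other[mask]
        if mask.sum() < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[name] = None
            continue
        if method == "spearman":
            from scipy.stats import spearmanr

            out[name] = float(spearmanr(x, y).statistic)
        else:
            out[name] = float(np.corrcoef(x, y)[0, 1])
    return out


def biomass_gate(
    records: Sequence[SampleRecord], cutoff: float = 500.0
) -> tuple[list[str], list[str], list[str]]:
    """Partition specimens at the biomass cut-off.

    Returns (retained, excluded, missing): specimens are retained iff
    copies_per_ul is strictly greater than ``cutoff``; ones without a
    measurement are listed separately. NTCs (and mocks) are never gated and
    appear in none of the three lists.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    retained, excluded, missing = [], [], []
    for r in records:
        if r.role != Role.SPECIMEN:
            continue
        if not r.has_biomass:
            missing.append(r.sample_id)
        elif r.copies_per_ul > cutoff:
            retained.append(r.sample_id)
        else:
            excluded.append(r.sample_id)
    return retained, excluded, missing
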