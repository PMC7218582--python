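"""Dataset denoising: spurious-OTU removal and the low-biomass specimen gate.

The documented order matters: spurious totals are computed over the FULL
pre-gate dataset (specimens of every biomass plus controls), and only then
are low-biomass specimens excluded. ``denoise_and_gate`` enforces this
order.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .io import CountTable, Role, SampleRecord
from .qc import biomass_gate

__all__ = ["remove_spurious_otus", "exclude_low_biomass", "denoise_and_gate"]


def remove_spurious_otus(
    t: CountTable, min_total: int = 5
) -> tuple[CountTable, list[str]]:
    """Drop OTUs whose grand total across all samples is below ``min_total``.

    The sample set is unchanged and surviving cells are untouched.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = t.data.sum(axis=1)
    removed = list(totals.index[totals < min_total])
    return t.drop_otus(removed), removed


def exclude_low_biomass(
    t: CountTable,
    records: Sequence[SampleRecord],
    cutoff: float = 500.0,
) -> tuple[CountTable, list[str]]:
    """Drop specimen columns not strictly above the biomass cut-off.

    NTC (and mock) columns are always retained as controls; the OTU axis is
    unchanged, so all-zero rows may remain. Specimens lacking metadata are a
    hard error.
    """
    by_id = {r.sample_id: r for r in records}
    missing_meta = [sid for sid in t.sample_ids if sid not in by_id]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta}")
    specimen_ids = {
        sid for sid in t.sample_ids if by_id[sid].role == Role.SPECIMEN
    }
    retained, excluded, missing = biomass_gate(
        [by_id[sid] for sid in t.sample_ids], cutoff
    )
    drop = set(excluded) | set(missing)
    keep = [sid for sid in t.sample_ids if sid not in specimen_ids or sid not in drop]
    return t.select_samples(keep), sorted(drop, key=t.sample_ids.index)


def denoise_and_gate(
    t: CountTable,
    records: Sequence[SampleRecord],
    min_total: int = 5,
    cutoff: float = 500.0,
) -> tuple[CountTable, dict]:
    """Spurious removal first, biomass gate second (the documented order)."""
    denoised, removed_otus = remove_spurious_otus(t, min_total)
    gated, excluded_samples = exclude_low_biomass(denoised, records, cutoff)
    manifest = {
        "min_total": min_total,
        "biomass_cutoff": cutoff,
        "removed_otus": removed_otus,
        "n_removed_otus": len(removed_otus),
        "excluded_samples": excluded_samples,
        "n_excluded_samples": len(excluded_samples),
        "n_otus_before": len(t.otu_ids),
        "n_otus_after": len(gated.otu_ids),
        "n_samples_before": len(t.sample_ids),
        "n_samples_after": len(gated.sample_ids),
    }
    return gated, manifest
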