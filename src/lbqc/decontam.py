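"""In-silico contaminant identification and removal.

Two identification routes are provided:

* ``ntconly`` — an OTU is a potential contaminant iff it is detected in at
  least one no-template control AND at least one specimen;
* a statistical classifier combining two kinds of evidence:

  - **frequency**: a genuine contaminant contributes a roughly fixed number
    of reads regardless of specimen biomass, so its relative frequency f
    scales inversely with the total DNA concentration c. In (ln c, ln f)
    space two one-parameter models are fit by least squares — the
    contaminant-free model ln f = β0 and the contaminant model
    ln f = −ln c + β0′ (fixed slope −1) — and the evidence is the F-ratio
    tail p = Pr(F_{n−1,n−1} ≥ SSR_null/SSR_cont);
  - **prevalence**: a one-sided Fisher exact test for presence being
    enriched in NTCs relative to specimens;
  - the two p-values are pooled by Fisher's method (χ² with 4 df), with
    pass-through when only one kind of evidence exists.

Removal is by max-proportion subtraction: for every flagged OTU its maximum
proportion across NTCs is subtracted from each specimen, clipping at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ContaminantReport,
    CountTable,
    ProportionTable,
    Role,
    SampleRecord,
    TaxonomyMap,
)

__all__ = [
    "identify_ntconly",
    "frequency_pvalue",
    "prevalence_pvalue",
    "combined_pvalue",
    "classify_contaminants",
    "call_contaminants",
    "subtract_contaminants",
    "ShiftRecord",
    "shift_report",
]

MIN_FREQ_SAMPLES = 4


def _split_roles(
    sample_ids: Sequence[str], records: Sequence[SampleRecord]
) -> tuple[list[str], list[str]]:
    by_id = {r.sample_id: r for r in records}
    ntc = [s for s in sample_ids if s in by_id and by_id[s].role == Role.NTC]
    spec = [s for s in sample_ids if s in by_id and by_id[s].role == Role.SPECIMEN]
    return ntc, spec


def _max_ntc_proportion(p: ProportionTable, ntc_ids: Sequence[str]) -> pd.Series:
    return p.data[list(ntc_ids)].max(axis=1)


def identify_ntconly(
    p: ProportionTable, records: Sequence[SampleRecord], threshold: float = 0.1
) -> ContaminantReport:
    """Flag OTUs present in >= 1 NTC and >= 1 specimen.

    ``max_ntc_proportion`` is the OTU's maximum proportion over NTC columns
    (zero for OTUs absent from every NTC). The ``threshold`` is carried for
    bookkeeping only; the presence rule alone decides the flag.
    """
    ntc_ids, spec_ids = _split_roles(p.sample_ids, records)
    if not ntc_ids:
        raise ValueError("NTConly identification requires at least one NTC")
    if not spec_ids:
        raise ValueError("NTConly identification requires at least one specimen")
    in_ntc = (p.data[ntc_ids] > 0).any(axis=1)
    in_spec = (p.data[spec_ids] > 0).any(axis=1)
    table = pd.DataFrame(
        {
            "max_ntc_proportion": _max_ntc_proportion(p, ntc_ids),
            "p_freq": np.nan,
            "p_prev": np.nan,
            "p_comb": np.nan,
            "is_contaminant": in_ntc & in_spec,
        },
        index=p.otu_ids,
    )
    return ContaminantReport("ntconly", table, threshold)


def frequency_pvalue(
    freqs: Sequence[float] | np.ndarray, concs: Sequence[float] | np.ndarray
) -> float:
    """Frequency-based contaminant evidence for one OTU.

    Only samples with positive frequency AND positive concentration enter;
    fewer than ``MIN_FREQ_SAMPLES`` such samples yields NaN (no frequency
    evidence). Small p favors the contaminant (inverse-proportionality)
    model.
    """
    f = np.asarray(freqs, dtype=float)
    c = np.asarray(concs, dtype=float)
    if f.shape != c.shape:
        raise ValueError("freqs and concs must have equal length")
    mask = (f > 0) & (c > 0)
    n = int(mask.sum())
    if n < MIN_FREQ_SAMPLES:
        return float("nan")
    lf = np.log(f[mask])
    lc = np.log(c[mask])
    ssr_null = float(((lf - lf.mean()) ** 2).sum())
    resid_cont = lf + lc
    ssr_cont = float(((resid_cont - resid_cont.mean()) ** 2).sum())
    # a numerically-perfect contaminant fit is the p -> 0 limit
    if ssr_cont <= 1e-12 * max(ssr_null, 1e-30):
        return 0.0
    ratio = ssr_null / ssr_cont
    return float(stats.f.sf(ratio, n - 1, n - 1))


def prevalence_pvalue(k_ntc: int, n_ntc: int, k_spec: int, n_spec: int) -> float:
    """One-sided Fisher exact (hypergeometric tail) for NTC enrichment."""
    if not (0 <= k_ntc <= n_ntc and 0 <= k_spec <= n_spec):
        raise ValueError("presence counts must satisfy 0 <= k <= n")
    if n_ntc < 1 or n_spec < 1:
        raise ValueError("both arms need at least one sample")
    table = [[k_ntc, n_ntc - k_ntc], [k_spec, n_spec - k_spec]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def combined_pvalue(p_freq: float, p_prev: float) -> float:
    """Fisher's method: X = −2(ln p_freq + ln p_prev), p = Pr(χ²_4 >= X).

    A missing (NaN) input passes the other through; both missing gives NaN.
    """
    f_missing = p_freq is None or math.isnan(p_freq)
    p_missing = p_prev is None or math.isnan(p_prev)
    if f_missing and p_missing:
        return float("nan")
    if f_missing:
        return float(p_prev)
    if p_missing:
        return float(p_freq)
    if not (0 < p_freq <= 1 and 0 < p_prev <= 1):
        # p of exactly 0 (perfect inverse proportionality) dominates
        return 0.0
    x = -2.0 * (math.log(p_freq) + math.log(p_prev))
    return float(stats.chi2.sf(x, 4))


def classify_contaminants(
    counts: CountTable,
    p: ProportionTable,
    records: Sequence[SampleRecord],
    method: str = "combined",
    threshold: float = 0.1,
) -> ContaminantReport:
    """Score every OTU and call contaminants with the requested method.

    ``counts`` provides presence/absence for the prevalence test; ``p``
    provides frequencies for the frequency test (specimen columns with a
    positive biomass measurement) and the max NTC proportions used later for
    subtraction. The two tables must share axes.
    """
    if method == "ntconly":
        return identify_ntconly(p, records, threshold)
    if method not in {"frequency", "prevalence", "combined"}:
        raise ValueError(f"unknown method {method!r}")
    if list(counts.otu_ids) != list(p.otu_ids) or list(counts.sample_ids) != list(
        p.sample_ids
    ):
        raise ValueError("count and proportion tables must share axes")
    ntc_ids, spec_ids = _split_roles(p.sample_ids, records)
    if not ntc_ids:
        raise ValueError("contaminant classification requires at least one NTC")
    if not spec_ids:
        raise ValueError("contaminant classification requires specimens")
    by_id = {r.sample_id: r for r in records}
    conc = np.array([by_id[s].copies_per_ul for s in spec_ids], dtype=float)

    spec_props = p.data[spec_ids].to_numpy(dtype=float)
    spec_counts = counts.data[spec_ids].to_numpy()
    ntc_counts = counts.data[ntc_ids].to_numpy()
    n_ntc, n_spec = len(ntc_ids), len(spec_ids)

    p_freq = np.full(len(p.otu_ids), np.nan)
    p_prev = np.full(len(p.otu_ids), np.nan)
    for i in range(len(p.otu_ids)):
        if method in ("frequency", "combined"):
            p_freq[i] = frequency_pvalue(spec_props[i], conc)
        if method in ("prevalence", "combined"):
            p_prev[i] = prevalence_pvalue(
                int((ntc_counts[i] > 0).sum()),
                n_ntc,
                int((spec_counts[i] > 0).sum()),
                n_spec,
            )
    if method == "frequency":
        score = p_freq
    elif method == "prevalence":
        score = p_prev
    else:
        score = np.array(
            [combined_pvalue(pf, pp) for pf, pp in zip(p_freq, p_prev)]
        )
    table = pd.DataFrame(
        {
            "max_ntc_proportion": _max_ntc_proportion(p, ntc_ids),
            "p_freq": p_freq,
            "p_prev": p_prev,
            "p_comb": score,
            "is_contaminant": False,
        },
        index=p.otu_ids,
    )
    report = ContaminantReport(method, table, threshold)
    return call_contaminants(report, threshold)


def call_contaminants(
    report: ContaminantReport, threshold: float = 0.1
) -> ContaminantReport:
    """Apply the decision rule p < threshold (strict) for statistical
    methods; the NTConly presence rule is left untouched."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    table = report.table.copy()
    if report.method != "ntconly":
        col = {"frequency": "p_freq", "prevalence": "p_prev", "combined": "p_comb"}[
            report.method
        ]
        score = table[col].to_numpy(dtype=float)
        table["is_contaminant"] = ~np.isnan(score) & (score < threshold)
    return ContaminantReport(report.method, table, threshold)


def subtract_contaminants(
    p: ProportionTable,
    report: ContaminantReport,
    records: Sequence[SampleRecord] | None = None,
    renormalize: bool = True,
) -> ProportionTable:
    """Max-proportion subtraction of flagged OTUs from specimen columns.

    q_ij = max(0, p_ij − m_j) with m_j the OTU's maximum NTC proportion;
    unflagged OTUs are untouched before re-closure. With ``renormalize``
    each specimen column is re-closed to sum 1 (preserving ratios among
    surviving values); columns emptied by the subtraction are flagged
    degenerate and left all-zero. When ``records`` is given only specimen
    columns are modified; otherwise every column is treated as a specimen.
    """
    if list(report.table.index) != list(p.otu_ids):
        raise ValueError("report and table OTU axes differ")
    targets = set(p.sample_ids)
    if records is not None:
        by_id = {r.sample_id: r for r in records}
        targets = {
            s
            for s in p.sample_ids
            if s in by_id and by_id[s].role == Role.SPECIMEN
        }
    m = report.table["max_ntc_proportion"].to_numpy(dtype=float)
    flagged = report.table["is_contaminant"].to_numpy(dtype=bool)
    sub = np.where(flagged, m, 0.0)
    out = p.data.copy()
    degenerate = set(p.degenerate)
    for sid in p.sample_ids:
        if sid not in targets:
            continue
        col = out[sid].to_numpy(dtype=float)
        q = np.maximum(col - sub, 0.0)
        # only flagged OTUs change
        q = np.where(flagged, q, col)
        total = q.sum()
        if total <= 0:
            degenerate.add(sid)
            out[sid] = 0.0
        elif renormalize:
            out[sid] = q / total
        else:
            out[sid] = q
    return ProportionTable(out, frozenset(degenerate), closed=renormalize)


@dataclass(frozen=True)
class ShiftRecord:
    """Pre/post decontamination summary for one taxon at one level."""

    level: str  # "otu" | "genus"
    taxon: str
    n_positive: int
    mean_before: float
    mean_after: dict[str, float]
    fraction_completely_removed: dict[str, float]


def _genus_table(p: ProportionTable, taxonomy: TaxonomyMap) -> pd.DataFrame:
    missing = [o for o in p.otu_ids if o not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy does not map OTUs: {missing[:5]}")
    genus = pd.Series({o: taxonomy[o][0] for o in p.otu_ids})
    return p.data.groupby(genus).sum()


def shift_report(
    before: ProportionTable,
    after_by_method: Mapping[str, ProportionTable],
    taxonomy: TaxonomyMap,
    level: str = "genus",
    positives_only: bool = True,
) -> list[ShiftRecord]:
    """Per-taxon shifts in specimen proportions caused by decontamination.

    For each taxon (genus-level proportions are sums of member OTUs) the
    fraction of initially-positive specimens whose post-method proportion is
    exactly zero is the "complete removal" rate. Taxa absent everywhere are
    omitted.
    """
    if level not in ("otu", "genus"):
        raise ValueError("level must be 'otu' or 'genus'")
    if level == "genus":
        b = _genus_table(before, taxonomy)
        afters = {m: _genus_table(t, taxonomy) for m, t in after_by_method.items()}
    else:
        b = before.data
        afters = {m: t.data for m, t in after_by_method.items()}
    for m, t in afters.items():
        if list(t.columns) != list(b.columns):
            raise ValueError(f"method {m!r} table has different samples")
    out: list[ShiftRecord] = []
    for taxon in b.index:
        row = b.loc[taxon].to_numpy(dtype=float)
        pos = row > 0
        n_pos = int(pos.sum())
        if n_pos == 0:
            continue
        sel = pos if positives_only else np.ones_like(pos, dtype=bool)
        mean_after = {}
        frac_removed = {}
        for m, t in afters.items():
            a = t.loc[taxon].to_numpy(dtype=float) if taxon in t.index else np.zeros_like(row)
            mean_after[m] = float(a[sel].mean())
            frac_removed[m] = float((a[pos] == 0).sum() / n_pos)
        out.append(
            ShiftRecord(
                level=level,
                taxon=str(taxon),
                n_positive=n_pos,
                mean_before=float(row[sel].mean()),
                mean_after=mean_after,
                fraction_completely_removed=frac_removed,
            )
        )
    return out
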