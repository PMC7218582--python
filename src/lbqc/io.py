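"""Domain types and tab-separated readers/writers.

Count tables are OTUs x samples (rows x columns), the common orientation of
amplicon pipeline exports. All identifiers are case-sensitive and only
line-end whitespace is stripped. Missing metadata values are encoded as
empty fields; a ``copies_per_ul`` of exactly 0 is legal and distinct from
missing.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Buffer",
    "Kit",
    "CountTable",
    "ProportionTable",
    "SampleRecord",
    "MockReference",
    "TaxonomyMap",
    "ContaminantReport",
    "read_count_table",
    "write_count_table",
    "to_proportions",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_mock_reference",
    "write_mock_reference",
    "write_contaminant_report",
    "write_run_summary",
]

_MISSING = float("nan")


class Role(str, enum.Enum):
    """What a sample column is: a biological specimen, a no-template control
    (a blank buffer processed like a specimen) or a mock community control."""

    SPECIMEN = "specimen"
    NTC = "ntc"
    MOCK = "mock"


class Buffer(str, enum.Enum):
    PRIMESTORE = "primestore"
    STGG = "stgg"
    NONE = "none"


class Kit(str, enum.Enum):
    KIT_QS = "kit_qs"
    KIT_ZB = "kit_zb"
    NONE = "none"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class CountTable:
    """Integer read counts, OTUs x samples.

    ``data`` is a pandas DataFrame with OTU ids as the index and sample ids
    as columns; both axes are unique and order is meaningful.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "OTU")
        _check_unique(list(self.data.columns), "sample")
        vals = self.data.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be integers")
        if vals.size and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(ids)])

    def drop_otus(self, ids: Iterable[str]) -> "CountTable":
        return CountTable(self.data.drop(index=list(ids)))


@dataclass(frozen=True)
class ProportionTable:
    """Per-sample relative abundances on the same axes as a CountTable.

    Columns sum to 1 except those listed in ``degenerate`` (all-zero source
    columns, which are left all-zero). ``closed=False`` marks a table whose
    columns were deliberately left un-renormalized (sums <= 1), e.g. raw
    max-proportion subtraction output.
    """

    data: pd.DataFrame
    degenerate: frozenset[str] = frozenset()
    closed: bool = True

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "OTU")
        _check_unique(list(self.data.columns), "sample")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and ((vals < -1e-12).any() or (vals > 1 + 1e-9).any()):
            raise ValueError("proportions must lie in [0, 1]")
        if not self.closed:
            return
        sums = vals.sum(axis=0) if vals.size else np.array([])
        for j, s in enumerate(sums):
            sid = self.data.columns[j]
            if sid in self.degenerate:
                continue
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"column {sid!r} sums to {s!r}, expected 1 "
                    "(flag it degenerate if its source was all-zero)"
                )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def column(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def select_samples(self, ids: Sequence[str]) -> "ProportionTable":
        ids = list(ids)
        return ProportionTable(
            self.data.loc[:, ids],
            frozenset(s for s in self.degenerate if s in ids),
            self.closed,
        )


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata.

    ``copies_per_ul`` is the qPCR 16S rRNA gene copy number per microlitre
    of template (the biomass proxy); NaN means not measured. ``repeat_group``
    is shared by all technical repeats of one underlying specimen and must be
    absent for NTCs.
    """

    sample_id: str
    role: Role
    copies_per_ul: float = _MISSING
    age_days: float = _MISSING
    run_id: str = ""
    well: str = ""
    repeat_group: str | None = None
    buffer: Buffer = Buffer.NONE
    kit: Kit = Kit.NONE

    def __post_init__(self) -> None:
        if self.role == Role.NTC and self.repeat_group is not None:
            raise ValueError(
                f"NTC {self.sample_id!r} must not carry a repeat_group"
            )
        if not math.isnan(self.copies_per_ul) and self.copies_per_ul < 0:
            raise ValueError(f"negative copies_per_ul for {self.sample_id!r}")

    @property
    def has_biomass(self) -> bool:
        return not math.isnan(self.copies_per_ul)


@dataclass(frozen=True)
class MockReference:
    """Theoretical 16S composition of a named mock community standard."""

    name: str
    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mock reference {self.name!r} proportions sum to {total}, not 1"
            )
        for taxon, p in self.composition.items():
            if p <= 0:
                raise ValueError(f"non-positive proportion for {taxon!r}")


# otu_id -> (genus, species); species may be "unclassified"
TaxonomyMap = dict[str, tuple[str, str]]


@dataclass
class ContaminantReport:
    """Per-OTU contaminant calls for one identification method.

    ``table`` columns: max_ntc_proportion, p_freq, p_prev, p_comb,
    is_contaminant (NaN p-values mean the evidence type was unavailable).
    """

    method: str  # ntconly | frequency | prevalence | combined
    table: pd.DataFrame
    threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in {"ntconly", "frequency", "prevalence", "combined"}:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def contaminants(self) -> list[str]:
        return list(self.table.index[self.table["is_contaminant"]])

    def max_ntc_proportion(self, otu_id: str) -> float:
        return float(self.table.at[otu_id, "max_ntc_proportion"])


# ---------------------------------------------------------------------------
# Count tables


def read_count_table(path: str | Path, transpose: bool = False) -> CountTable:
    """Read a TSV count table (first column OTU ids, header sample ids).

    ``transpose=True`` accepts the samples-as-rows orientation.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        col_ids = header[1:]
        _check_unique(col_ids, "sample" if not transpose else "OTU")
        row_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    f"expected {len(header)}"
                )
            rid = parts[0]
            vals = []
            for j, cell in enumerate(parts[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer count {cell!r} at row {rid!r}, "
                        f"column {col_ids[j]!r}"
                    ) from None
                if v < 0:
                    raise ValueError(
                        f"{path}: negative count {v} at row {rid!r}, "
                        f"column {col_ids[j]!r}"
                    )
                vals.append(v)
            row_ids.append(rid)
            rows.append(vals)
    _check_unique(row_ids, "OTU" if not transpose else "sample")
    df = pd.DataFrame(
        np.array(rows, dtype=np.int64).reshape(len(row_ids), len(col_ids)),
        index=row_ids,
        columns=col_ids,
    )
    if transpose:
        df = df.T
    return CountTable(df)


def write_count_table(t: CountTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("otu_id\t" + "\t".join(t.sample_ids) + "\n")
        for otu, row in zip(t.otu_ids, t.counts):
            fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def to_proportions(t: CountTable) -> ProportionTable:
    """Close each sample column to sum 1; all-zero columns are flagged
    degenerate and left all-zero."""
    counts = t.counts.astype(float)
    sums = counts.sum(axis=0)
    degenerate = [sid for sid, s in zip(t.sample_ids, sums) if s == 0]
    safe = np.where(sums > 0, sums, 1.0)
    props = counts / safe
    return ProportionTable(
        pd.DataFrame(props, index=t.otu_ids, columns=t.sample_ids),
        frozenset(degenerate),
    )


def write_proportion_table(p: ProportionTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("otu_id\t" + "\t".join(p.sample_ids) + "\n")
        for otu in p.otu_ids:
            row = p.data.loc[otu]
            fh.write(otu + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# Metadata

_META_COLUMNS = [
    "sample_id",
    "role",
    "copies_per_ul",
    "age_days",
    "run_id",
    "well",
    "repeat_group",
    "buffer",
    "kit",
]


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the fixed-column sample metadata TSV."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != _META_COLUMNS:
            raise ValueError(
                f"{path}: metadata header must be {_META_COLUMNS}, got {header}"
            )
        records: list[SampleRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}: line {lineno} has wrong field count")
            d = dict(zip(header, parts))
            records.append(
                SampleRecord(
                    sample_id=d["sample_id"],
                    role=Role(d["role"]),
                    copies_per_ul=float(d["copies_per_ul"])
                    if d["copies_per_ul"] != ""
                    else _MISSING,
                    age_days=float(d["age_days"]) if d["age_days"] != "" else _MISSING,
                    run_id=d["run_id"],
                    well=d["well"],
                    repeat_group=d["repeat_group"] or None,
                    buffer=Buffer(d["buffer"]) if d["buffer"] else Buffer.NONE,
                    kit=Kit(d["kit"]) if d["kit"] else Kit.NONE,
                )
            )
    _check_unique([r.sample_id for r in records], "sample")
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    path = Path(path)

    def fmt(v: float) -> str:
        return "" if math.isnan(v) else format(v, ".10g")

    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.role.value,
                        fmt(r.copies_per_ul),
                        fmt(r.age_days),
                        r.run_id,
                        r.well,
                        r.repeat_group or "",
                        r.buffer.value,
                        r.kit.value,
                    ]
                )
                + "\n"
            )


def records_by_id(records: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


# ---------------------------------------------------------------------------
# Taxonomy and mock references


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    path = Path(path)
    tax: TaxonomyMap = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != ["otu_id", "genus", "species"]:
            raise ValueError(f"{path}: taxonomy header must be otu_id/genus/species")
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            otu, genus, species = line.split("\t")
            if otu in tax:
                raise ValueError(f"{path}: duplicate taxonomy entry for {otu!r}")
            tax[otu] = (genus, species)
    return tax


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("otu_id\tgenus\tspecies\n")
        for otu, (genus, species) in tax.items():
            fh.write(f"{otu}\t{genus}\t{species}\n")


def read_mock_reference(path: str | Path, name: str | None = None) -> MockReference:
    path = Path(path)
    comp: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != ["taxon", "proportion"]:
            raise ValueError(f"{path}: mock reference header must be taxon/proportion")
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            taxon, prop = line.split("\t")
            comp[taxon] = float(prop)
    return MockReference(name or path.stem, comp)


def write_mock_reference(ref: MockReference, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("taxon\tproportion\n")
        for taxon, p in ref.composition.items():
            fh.write(f"{taxon}\t{format(p, '.10g')}\n")


# ---------------------------------------------------------------------------
# Reports


def write_contaminant_report(report: ContaminantReport, path: str | Path) -> None:
    df = report.table.copy()
    df.insert(0, "otu_id", df.index)
    df.to_csv(path, sep="\t", index=False)


def write_run_summary(summary: Mapping, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, enum.Enum):
            return o.value
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
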