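"""Mock-community evaluation: expected-vs-observed composition and
quantification of background (unexpected) OTUs.

OTUs are matched to mock reference taxa at genus+species level through the
taxonomy map; a reference entry like ``"Staphylococcus aureus/epidermidis"``
matches any of its slash-separated species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MockReference, ProportionTable, TaxonomyMap

__all__ = ["background_proportion", "composition_agreement", "TaxonAgreement"]


def _expected_lookup(ref: MockReference) -> dict[tuple[str, str], str]:
    """(genus, species) -> reference taxon name, expanding grouped species."""
    out: dict[tuple[str, str], str] = {}
    for taxon in ref.composition:
        parts = taxon.split(" ", 1)
        genus = parts[0]
        species_field = parts[1] if len(parts) > 1 else ""
        for sp in species_field.split("/") if species_field else [""]:
            out[(genus, sp)] = taxon
    return out


def _match(tax_entry: tuple[str, str], lookup: dict[tuple[str, str], str]) -> str | None:
    genus, species = tax_entry
    return lookup.get((genus, species)) or lookup.get((genus, ""))


def background_proportion(
    p: ProportionTable, sample_id: str, ref: MockReference, tax: TaxonomyMap
) -> float:
    """Summed proportion of OTUs whose taxon is not in the mock reference."""
    col = p.column(sample_id)
    detected = [o for o in p.otu_ids if col[o] > 0]
    unmapped = [o for o in detected if o not in tax]
    if unmapped:
        raise ValueError(f"taxonomy does not map detected OTUs: {unmapped[:5]}")
    lookup = _expected_lookup(ref)
    return float(
        sum(col[o] for o in detected if _match(tax[o], lookup) is None)
    )


@dataclass(frozen=True)
class TaxonAgreement:
    taxon: str
    expected: float
    observed: float
    log2_ratio: float  # log2(observed/expected); -inf when undetected


def composition_agreement(
    p: ProportionTable, sample_id: str, ref: MockReference, tax: TaxonomyMap
) -> tuple[list[TaxonAgreement], pd.Series]:
    """Observed vs theoretical proportion per expected mock taxon.

    Observed values sum member-OTU proportions; expected-but-undetected taxa
    are reported with observed 0 (not an error). The second return value
    lists unexpected (background) taxa with their summed proportions.
    """
    col = p.column(sample_id)
    detected = [o for o in p.otu_ids if col[o] > 0]
    unmapped = [o for o in detected if o not in tax]
    if unmapped:
        raise ValueError(f"taxonomy does not map detected OTUs: {unmapped[:5]}")
    lookup = _expected_lookup(ref)
    observed: dict[str, float] = {t: 0.0 for t in ref.composition}
    unexpected: dict[str, float] = {}
    for o in detected:
        taxon = _match(tax[o], lookup)
        if taxon is not None:
            observed[taxon] += float(col[o])
        else:
            genus, species = tax[o]
            label = f"{genus} {species}".strip()
            unexpected[label] = unexpected.get(label, 0.0) + float(col[o])
    out = []
    for taxon, expected in ref.composition.items():
        obs = observed[taxon]
        ratio = math.log2(obs / expected) if obs > 0 else -math.inf
        out.append(TaxonAgreement(taxon, expected, obs, ratio))
    return out, pd.Series(unexpected, dtype=float).sort_values(ascending=False)
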