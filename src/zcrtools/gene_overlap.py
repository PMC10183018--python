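"""Flagging genes whose exons overlap ZCRs, per sample and combined.

A gene is flagged when at least one base of at least one exon of its
canonical transcript intersects a ZCR. Per-sample flags are OR-ed into a
combined list, and percentages are summarised per user-supplied gene set
(e.g. an MHC list, an NLR list, or the whole annotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import _intervals
from .io_formats import GeneModel
from .zcr import ZCRSet

COMBINED = "Comb."


@dataclass
class GeneFlagTable:
    """Per-sample and combined ZCR-overlap flags over one gene universe."""

    per_sample: dict[str, dict[str, bool]]
    combined: dict[str, bool]

    @property
    def samples(self) -> list[str]:
        return list(self.per_sample)

    def flagged_genes(self, sample: str | None = None) -> set[str]:
        flags = self.combined if sample is None else self.per_sample[sample]
        return {g for g, hit in flags.items() if hit}


def flag_genes_by_zcr(
    zcrs: ZCRSet, genes: list[GeneModel], *, use_cds: bool = False
) -> dict[str, bool]:
    """Flag each gene whose exons share >=1 base with a ZCR interval."""
    flags: dict[str, bool] = {}
    for gene in genes:
        intervals = gene.cds if use_cds else gene.exons
        flags[gene.gene_id] = _intervals.overlaps_any(
            intervals, zcrs.chrom_intervals(gene.chrom)
        )
    return flags


def combine_flags(per_sample: dict[str, dict[str, bool]]) -> GeneFlagTable:
    """OR per-sample flags into a combined table; universes must agree."""
    if not per_sample:
        raise ValueError("need flags for at least one sample")
    samples = list(per_sample)
    universe = set(per_sample[samples[0]])
    for sample in samples[1:]:
        if set(per_sample[sample]) != universe:
            raise ValueError(f"gene universe of {sample} differs")
    combined = {
        gene: any(per_sample[s][gene] for s in samples) for gene in universe
    }
    return GeneFlagTable(per_sample=per_sample, combined=combined)


def geneset_zcr_summary(
    flags: GeneFlagTable, catalog: dict[str, set[str]]
) -> pd.DataFrame:
    """Per gene set and per sample (plus combined), the flagged percentage.

    Returns rows (set, sample, n_flagged, n_total, percent) with percent
    reported to one decimal.
    """
    universe = set(flags.combined)
    rows = []
    columns = [(s, flags.per_sample[s]) for s in flags.samples]
    columns.append((COMBINED, flags.combined))
    for set_name, genes in catalog.items():
        if not genes:
            raise ValueError(f"gene set {set_name!r} is empty")
        missing = genes - universe
        if missing:
            raise ValueError(
                f"gene set {set_name!r} has genes outside the universe: "
                f"{sorted(missing)[:5]}"
            )
        for col_name, col_flags in columns:
            n_flagged = sum(1 for g in genes if col_flags[g])
            rows.append(
                {
                    "set": set_name,
                    "sample": col_name,
                    "n_flagged": n_flagged,
                    "n_total": len(genes),
                    "percent": round(100.0 * n_flagged / len(genes), 1),
                }
            )
    return pd.DataFrame(rows)
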