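"""Sequence context around poly(A) sites and polymerase occupancy ratios.

Nucleotide composition is tallied on the sense strand around each gene's
max-isoform endpoint, per gene category.  Signed positions have no zero:
-1 is the last genomically encoded nucleotide of the isoform (the base at
the endpoint offset itself), -2 one nt upstream, +1 the first genomic base
past the cleavage site (not part of the mRNA).  Frequencies are reported in
the RNA alphabet (U for T) by default.

The processivity ratio compares promoter/ORF polymerase occupancy between
two conditions: (promoter/ORF in condition 2) / (promoter/ORF in
condition 1); values > 1 mean disproportionate promoter accumulation in
condition 2, a signature of slower elongation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

RNA_BASES = ("A", "C", "G", "U")
DNA_BASES = ("A", "C", "G", "T")


def composition_around_max(
    max_positions: Mapping[str, int],
    bundle,
    categories: Mapping[str, Iterable[str]],
    window: int = 10,
    alphabet: str = "rna",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-category nucleotide percentages around max-isoform endpoints.

    `max_positions` maps gene -> max-isoform offset; `categories` maps a
    category label to its gene set.  Returns (tables, exclusion log).  Each
    table is indexed by signed position (-window..-1, +1..+window) with one
    column per base; percentages divide by the category's gene count, so
    columns sum to 100 only at positions where no gene was skipped.  Genes
    whose window runs off the sequence are skipped at the missing positions
    and logged.
    """
    bases = RNA_BASES if alphabet == "rna" else DNA_BASES
    positions = [*range(-window, 0), *range(1, window + 1)]
    tables: dict[str, pd.DataFrame] = {}
    excluded = []
    for label, genes in categories.items():
        genes = [g for g in genes if g in max_positions]
        tally = pd.DataFrame(0.0, index=positions, columns=list(bases))
        for gene in genes:
            offset = max_positions[gene]
            for pos in positions:
                b = bundle.sense_flank(gene, offset, pos)
                if b is None:
                    excluded.append({"category": label, "gene": gene, "position": pos})
                    continue
                if alphabet == "rna":
                    b = "U" if b == "T" else b
                tally.at[pos, b] += 1
        n = len(genes)
        tables[label] = 100.0 * tally / n if n else tally
        tables[label].attrs["n_genes"] = n
        tables[label].index.name = "position"
    return tables, pd.DataFrame(excluded, columns=["category", "gene", "position"])


@dataclass(frozen=True)
class OccupancyRecord:
    """Background-subtracted ChIP occupancy at one gene in one condition."""

    gene: str
    condition: str
    promoter: float
    orf: float

    def ratio(self) -> float:
        if self.promoter <= 0 or self.orf <= 0:
            raise ValueError(f"non-positive occupancy for {self.gene}/{self.condition}")
        return self.promoter / self.orf


def processivity_ratio(baseline: OccupancyRecord, perturbed: OccupancyRecord) -> float:
    """(promoter/ORF in the perturbed condition) / (promoter/ORF at baseline)."""
    return perturbed.ratio() / baseline.ratio()


def read_occupancy_table(path) -> list[OccupancyRecord]:
    """TSV with columns gene, condition, promoter, orf."""
    df = pd.read_csv(path, sep="\t")
    return [
        OccupancyRecord(r.gene, r.condition, float(r.promoter), float(r.orf))
        for r in df.itertuples(index=False)
    ]


def shift_vs_processivity(
    ratios: Mapping[str, float], net_shifts: Mapping[str, float]
) -> tuple[float, pd.DataFrame]:
    """Pearson R between per-gene processivity ratios and end-zone net shifts.

    Returns (R, scatter table).  R is NaN with fewer than three paired genes
    or when either quantity is constant.
    """
    genes = sorted(set(ratios) & set(net_shifts))
    table = pd.DataFrame(
        {
            "gene": genes,
            "processivity_ratio": [ratios[g] for g in genes],
            "net_shift": [net_shifts[g] for g in genes],
        }
    )
    if len(genes) < 3:
        return float("nan"), table
    x, y = table["processivity_ratio"], table["net_shift"]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), table
    return float(pearsonr(x, y).statistic), table
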