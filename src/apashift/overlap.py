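"""Conservation of poly(A) endpoints between conditions.

If polyadenylation could occur at any of N eligible non-A positions, and
two conditions independently used alpha and beta major-isoform positions,
the chance that they share at least c positions is the hypergeometric upper
tail

    P(q) = sum_{i=c}^{min(alpha, beta)} C(beta, i) C(N-beta, alpha-i) / C(N, alpha),

symmetric in (alpha, beta).  The eligible universe N is either the non-A
position count of the gene's combined major end zone (the union of its
major end zones across all conditions) or, in the permissive variant, of
the whole 400-nt 3'UTR.  A small P(q) means the positional overlap between
conditions is far larger than chance, i.e. shifts re-balance a conserved
repertoire of sites rather than creating new ones.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .endzone import EndZoneProfile


def overlap_probability(N: int, alpha: int, beta: int, c: int) -> float:
    """Upper-tail hypergeometric probability of sharing >= c of the positions.

    Evaluated in log space by scipy's survival function; algebraically equal
    to both printed branch formulas (terms past min(alpha, beta) vanish).
    """
    if not (0 <= c <= min(alpha, beta)):
        raise ValueError(f"need 0 <= c <= min(alpha, beta); got c={c}")
    if alpha > N or beta > N:
        raise ValueError("alpha and beta cannot exceed N")
    if alpha + beta - c > N:
        raise ValueError(
            f"impossible configuration: alpha+beta-c = {alpha + beta - c} > N = {N}"
        )
    # P(X >= c) with X ~ Hypergeom(N, beta, alpha)
    return float(hypergeom.sf(c - 1, N, beta, alpha))


def combined_major_end_zone(
    profiles: Mapping[str, EndZoneProfile], bundle, gene: str
) -> tuple[int, int, int]:
    """Union of a gene's major end zones across conditions.

    `profiles` maps condition -> that gene's profile.  Returns (5' boundary,
    3' boundary, non-A position count inside the window).
    """
    zones = [p for p in profiles.values() if p is not None]
    if not zones:
        raise ValueError(f"gene {gene} has no major isoforms in any condition")
    lo = min(p.zone5 for p in zones)
    hi = max(p.zone3 for p in zones)
    return lo, hi, bundle.count_non_a(gene, lo, hi)


def full_utr_non_a(bundle, gene: str, utr_len: int = 400) -> int:
    """Non-A position count over the whole 3'UTR window (permissive universe)."""
    return bundle.count_non_a(gene, 1, utr_len)


def genewise_overlap_summary(
    profiles_a: Mapping[str, EndZoneProfile],
    profiles_b: Mapping[str, EndZoneProfile],
    all_profiles: Mapping[str, Mapping[str, EndZoneProfile]],
    bundle,
    genes: Iterable[str] | None = None,
    utr_len: int = 400,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene overlap probabilities between two conditions, plus medians.

    `all_profiles` maps every condition to its per-gene profiles and defines
    the combined major end zones.  Genes need at least one major isoform in
    both compared conditions (alpha, beta >= 1).  Returns the per-gene table
    (gene, N_combined, N_full, alpha, beta, c, p_combined, p_full) and the
    medians of both probability columns.
    """
    if genes is None:
        genes = sorted(set(profiles_a) & set(profiles_b))
    rows = []
    for gene in genes:
        pa, pb = profiles_a.get(gene), profiles_b.get(gene)
        if pa is None or pb is None:
            continue
        sa = set(int(o) for o in pa.major_offsets)
        sb = set(int(o) for o in pb.major_offsets)
        per_cond = {c: profs[gene] for c, profs in all_profiles.items() if gene in profs}
        lo, hi, n_combined = combined_major_end_zone(per_cond, bundle, gene)
        n_full = full_utr_non_a(bundle, gene, utr_len)
        alpha, beta, c = len(sa), len(sb), len(sa & sb)
        rows.append(
            {
                "gene": gene,
                "zone5": lo,
                "zone3": hi,
                "N_combined": n_combined,
                "N_full": n_full,
                "alpha": alpha,
                "beta": beta,
                "c": c,
                "p_combined": overlap_probability(n_combined, alpha, beta, c),
                "p_full": overlap_probability(n_full, alpha, beta, c),
            }
        )
    table = pd.DataFrame(rows)
    medians = {
        "p_combined": float(table["p_combined"].median()) if len(table) else float("nan"),
        "p_full": float(table["p_full"].median()) if len(table) else float("nan"),
    }
    return table, medians
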