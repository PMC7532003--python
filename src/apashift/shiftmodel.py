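"""Replicate-calibrated percentile shift statistic and gene classification.

For a comparison of a test condition against a reference (each with two
biological replicates), every gene contributes, at each of the five
percentile coordinates q in {10, 25, 50, 75, 90}:

* raw shift  = round( ((T1-R1) + (T2-R2)) / 2 )   (test - reference, so
  negative values are upstream shifts),
* percentile error = round( |((T1-T2) + (R1-R2)) / 2| )   (the averaged
  within-condition replicate discrepancy),
* net shift  k = sign(raw) * max(0, |raw| - error).

Rounding is half-away-from-zero throughout.  The error magnitudes across
the analyzed gene set (G genes) form an empirical null per percentile: the
frequency f(i) of magnitude i, with non-zero frequencies halved because an
error of magnitude i could have been observed in either direction, and the
cumulative tail probability

    P(x) = sum_{i=x}^{Max} f(i) / G.

A net shift beyond the largest observed error magnitude receives the floor
probability 1/G.  The per-gene probability that the five observed net
shifts arise from replicate noise is

    P(g) = min(1, 5 * prod_q P(|k_q|)),

the factor 5 correcting for the five percentile tests.  A gene is called
"upshifted" when sum(k) < 0, the net number of shifted positions
(sum of sign(k_q)) is < 0, and P(g) < 0.01; "downshifted" with all three
reversed; otherwise "other".  Combined across strains: "Upstream" = up in
both slow-polymerase strains, "Downstream" = down in both fast strains
(each ignoring the other pair), "Neutral" = other in all four, the
remainder "Other"; genes meeting both the Upstream and Downstream criteria
form the "Both" subcategory.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .endzone import PERCENTILES, percentile_coords_by_replicate

UPSHIFTED = "upshifted"
DOWNSHIFTED = "downshifted"
OTHER = "other"

DEFAULT_ALPHA = 0.01


def raw_shift(test_pair: Sequence[float], ref_pair: Sequence[float]) -> int:
    """Rounded mean of the per-replicate (test - reference) coordinate differences."""
    (t1, t2), (r1, r2) = test_pair, ref_pair
    return round_half_away(((t1 - r1) + (t2 - r2)) / 2.0)


def percentile_error(test_pair: Sequence[float], ref_pair: Sequence[float]) -> int:
    """Rounded |mean| of the within-condition replicate coordinate differences."""
    (t1, t2), (r1, r2) = test_pair, ref_pair
    return abs(round_half_away(((t1 - t2) + (r1 - r2)) / 2.0))


def net_shift(raw: int, error: int) -> int:
    """Error-subtracted shift: k = sign(raw) * max(0, |raw| - error)."""
    if error >= abs(raw):
        return 0
    mag = abs(raw) - error
    return mag if raw > 0 else -mag


@dataclass
class ErrorModel:
    """Empirical per-percentile null of coordinate-measurement error.

    ``freqs[q]`` maps an integer error magnitude to its (possibly halved)
    frequency across the G analyzed genes; ``max_mag[q]`` is the largest
    observed magnitude; the floor probability is 1/G.
    """

    comparison: str
    G: int
    freqs: dict[int, dict[int, float]]
    max_mag: dict[int, int]

    @property
    def floor(self) -> float:
        return 1.0 / self.G

    def tail_prob(self, q: int, x: int) -> float:
        """P(x) = cumulative frequency of magnitudes >= x, over G; floor beyond Max."""
        if x < 0:
            raise ValueError("error magnitude must be >= 0")
        if x > self.max_mag[q]:
            return self.floor
        f = self.freqs[q]
        return sum(v for i, v in f.items() if i >= x) / self.G


def build_error_model(
    errors: Mapping[int, Sequence[int]], comparison: str = ""
) -> ErrorModel:
    """Tabulate per-percentile error magnitudes into an :class:`ErrorModel`.

    `errors` maps each percentile q to the per-gene error magnitudes (one
    per analyzed gene; all percentiles must cover the same G genes).
    Non-zero magnitudes are tabulated at half weight (one-sided
    symmetrization of a sign-less magnitude distribution).
    """
    sizes = {q: len(v) for q, v in errors.items()}
    G = next(iter(sizes.values()), 0)
    if G == 0:
        raise ValueError("cannot build an error model from zero genes")
    if len(set(sizes.values())) != 1:
        raise ValueError(f"inconsistent gene counts across percentiles: {sizes}")
    freqs: dict[int, dict[int, float]] = {}
    max_mag: dict[int, int] = {}
    for q, mags in errors.items():
        table: dict[int, float] = {}
        for m in mags:
            m = int(m)
            if m < 0:
                raise ValueError("error magnitudes must be non-negative")
            table[m] = table.get(m, 0.0) + (1.0 if m == 0 else 0.5)
        freqs[q] = table
        max_mag[q] = max(table)
    return ErrorModel(comparison=comparison, G=G, freqs=freqs, max_mag=max_mag)


def gene_probability(ks: Mapping[int, int], model: ErrorModel) -> float:
    """P(g): product of the five per-percentile tail probabilities, x5, capped at 1."""
    prob = 1.0
    for q, k in ks.items():
        prob *= model.tail_prob(q, abs(int(k)))
    return min(1.0, 5.0 * prob)


def classify_strain(
    sum_k: float, net_positions: int, p_g: float, alpha: float = DEFAULT_ALPHA
) -> str:
    """Direction call for one comparison (conjunctive three-part rule)."""
    if sum_k < 0 and net_positions < 0 and p_g < alpha:
        return UPSHIFTED
    if sum_k > 0 and net_positions > 0 and p_g < alpha:
        return DOWNSHIFTED
    return OTHER


@dataclass
class CombinedClass:
    gene: str
    cls: str              # Upstream / Downstream / Neutral / Other
    is_upstream: bool     # upshifted in both slow strains
    is_downstream: bool   # downshifted in both fast strains
    both_flag: bool       # in the intersection of the two criteria sets


def classify_combined(
    calls: Mapping[str, str],
    slow: Sequence[str],
    fast: Sequence[str],
    gene: str = "",
) -> CombinedClass:
    """Combine per-strain calls into the four-way multi-strain class.

    The Upstream and Downstream criteria sets are not disjoint; a gene in
    both is labelled Upstream with ``both_flag`` set, and the two boolean
    fields preserve the full (overlapping) category membership.
    """
    for strain in (*slow, *fast):
        if strain not in calls:
            raise KeyError(f"missing call for strain {strain}")
    up = all(calls[s] == UPSHIFTED for s in slow)
    down = all(calls[s] == DOWNSHIFTED for s in fast)
    neutral = all(calls[s] == OTHER for s in (*slow, *fast))
    if up:
        cls = "Upstream"
    elif down:
        cls = "Downstream"
    elif neutral:
        cls = "Neutral"
    else:
        cls = "Other"
    return CombinedClass(gene, cls, up, down, up and down)


def assess_genes(
    coords: pd.DataFrame,
    ref_condition: str,
    test_condition: str,
    alpha: float = DEFAULT_ALPHA,
    qs: Sequence[int] = PERCENTILES,
) -> tuple[pd.DataFrame, ErrorModel]:
    """Per-gene shift assessment for one test-vs-reference comparison.

    `coords` is the long (condition, replicate, gene, q, coord) table from
    :func:`apashift.endzone.percentile_coords_by_replicate` and must hold
    exactly two replicates per condition.  Genes missing a replicate in
    either condition are excluded.  Returns the assessment table (gene,
    raw/error/k per q, sum_k, net_positions, p_g, call) plus the fitted
    error model.
    """
    wide = {}
    for cond, label in ((ref_condition, "R"), (test_condition, "T")):
        sub = coords[coords["condition"] == cond]
        reps = sorted(sub["replicate"].unique())
        if len(reps) != 2:
            raise ValueError(f"condition {cond!r} needs exactly 2 replicates, has {reps}")
        for rep, tag in zip(reps, ("1", "2")):
            piv = sub[sub["replicate"] == rep].pivot(index="gene", columns="q", values="coord")
            wide[label + tag] = piv
    genes = sorted(
        set.intersection(*(set(piv.dropna().index) for piv in wide.values()))
    )
    comparison = f"{test_condition}_vs_{ref_condition}"

    raws: dict[int, list[int]] = {q: [] for q in qs}
    errs: dict[int, list[int]] = {q: [] for q in qs}
    for gene in genes:
        for q in qs:
            t = (wide["T1"].at[gene, q], wide["T2"].at[gene, q])
            r = (wide["R1"].at[gene, q], wide["R2"].at[gene, q])
            raws[q].append(raw_shift(t, r))
            errs[q].append(percentile_error(t, r))
    model = build_error_model(errs, comparison=comparison)

    rows = []
    for gi, gene in enumerate(genes):
        ks = {q: net_shift(raws[q][gi], errs[q][gi]) for q in qs}
        sum_k = sum(ks.values())
        net_pos = int(sum(np.sign(k) for k in ks.values()))
        p_g = gene_probability(ks, model)
        call = classify_strain(sum_k, net_pos, p_g, alpha=alpha)
        row = {"gene": gene, "comparison": comparison}
        for q in qs:
            row[f"raw{q}"] = raws[q][gi]
            row[f"err{q}"] = errs[q][gi]
            row[f"k{q}"] = ks[q]
        row.update(sum_k=sum_k, net_positions=net_pos, p_g=p_g, call=call)
        rows.append(row)
    return pd.DataFrame(rows), model


def run_shift_analysis(
    counts: pd.DataFrame,
    ref_condition: str,
    test_conditions: Sequence[str],
    genes: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, tuple[pd.DataFrame, ErrorModel]]:
    """Shift assessment of several test conditions against one reference."""
    conds = [ref_condition, *test_conditions]
    coords = percentile_coords_by_replicate(
        counts[counts["condition"].isin(conds)], genes
    )
    return {
        test: assess_genes(coords, ref_condition, test, alpha=alpha)
        for test in test_conditions
    }


def weighted_average_net_shift(
    test_was: Sequence[float], ref_was: Sequence[float]
) -> float:
    """Error-diminished shift in the weighted-average endpoint (nt).

    s = mean replicate shift (test - reference); e = |mean within-condition
    replicate difference|; the net shift is sign(s) * (|s| - e), set to zero
    when |s| < e.
    """
    (t1, t2), (r1, r2) = test_was, ref_was
    s = ((t1 - r1) + (t2 - r2)) / 2.0
    e = abs(((t1 - t2) + (r1 - r2)) / 2.0)
    if abs(s) < e:
        return 0.0
    return float(np.sign(s) * (abs(s) - e))


def net_overall_end_zone_shift(ks: Mapping[int, int] | Sequence[float]) -> float:
    """Mean of the five percentile net shifts (nt); the scatter-plot quantity.

    Pass the per-percentile k values of one comparison, or the per-strain
    values themselves to average two same-speed strains.
    """
    vals = list(ks.values()) if isinstance(ks, Mapping) else list(ks)
    return float(np.mean(vals))
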