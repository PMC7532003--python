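"""End-zone profiles, landmarks, percentile coordinates and replicate QC.

An "end zone" is the stretch of a gene's 3'UTR over which poly(A) endpoints
are observed.  A gene's end-zone profile scales every isoform to the
maximally expressed isoform (max isoform = 100%); "major isoforms" are those
at >= 5% of the max, and the "major end zone" runs from the 5'-most to the
3'-most major isoform.  The weighted average endpoint is the read-weighted
mean offset.  Percentile coordinates locate the offsets at which 10/25/50/
75/90% of a gene's reads have accumulated (inclusive); they are the raw
material for the distribution-shift statistic in :mod:`apashift.shiftmodel`.

Count tables are long-format DataFrames with columns condition, replicate,
gene, offset, count (the ``sample`` column is optional and ignored here).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_MIN_COMBINED = 1000
MAJOR_FRACTION = 5.0      # percent of the max isoform
PERCENTILES = (10, 25, 50, 75, 90)
LANDMARKS = ("max_position", "zone5", "zone3", "span", "weighted_average")


@dataclass
class EndZoneProfile:
    gene: str
    condition: str
    scaled: pd.Series            # offset -> percent of max isoform
    max_position: int
    major_offsets: np.ndarray
    zone5: int
    zone3: int
    span: int
    weighted_average: float
    total: float


def filter_genes(
    counts: pd.DataFrame, min_combined: float = DEFAULT_MIN_COMBINED
) -> list[str]:
    """Genes whose replicate-combined total is >= min_combined in EVERY condition."""
    totals = counts.groupby(["condition", "gene"], sort=False)["count"].sum().unstack("condition")
    totals = totals.fillna(0.0)
    keep = totals.index[(totals >= min_combined).all(axis=1)]
    return sorted(keep)


def build_profile(
    counts: Mapping[int, float] | pd.Series, gene: str = "", condition: str = ""
) -> EndZoneProfile | None:
    """End-zone profile and landmarks for one gene in one condition.

    `counts` maps offsets to (replicate-combined) read counts.  Returns None
    for an all-zero gene (unprofiled).  Ties for the max isoform go to the
    most ORF-proximal offset.  The profile is invariant to positive scaling
    of the counts.
    """
    s = pd.Series(dict(counts), dtype=float) if not isinstance(counts, pd.Series) else counts.astype(float)
    s = s[s > 0].sort_index()
    total = float(s.sum())
    if total <= 0:
        return None
    peak = float(s.max())
    scaled = 100.0 * s / peak
    max_position = int(s.index[s.values >= peak][0])  # proximal tie-break
    major = scaled.index[scaled.values >= MAJOR_FRACTION].to_numpy()
    zone5, zone3 = int(major.min()), int(major.max())
    wa = float(np.dot(s.index.to_numpy(dtype=float), s.to_numpy()) / total)
    return EndZoneProfile(
        gene=gene,
        condition=condition,
        scaled=scaled,
        max_position=max_position,
        major_offsets=major,
        zone5=zone5,
        zone3=zone3,
        span=zone3 - zone5,
        weighted_average=wa,
        total=total,
    )


def condition_profiles(
    counts: pd.DataFrame, genes: Iterable[str], condition: str
) -> dict[str, EndZoneProfile]:
    """Profiles for a gene set in one condition, replicates summed before scaling."""
    sub = counts[counts["condition"] == condition]
    pooled = sub.groupby(["gene", "offset"], sort=False)["count"].sum()
    present = set(pooled.index.get_level_values(0))
    out: dict[str, EndZoneProfile] = {}
    for gene in genes:
        if gene not in present:
            continue
        prof = build_profile(pooled.loc[gene], gene=gene, condition=condition)
        if prof is not None:
            out[gene] = prof
    return out


def percentile_coords(
    counts: Mapping[int, float] | pd.Series, qs: Sequence[int] = PERCENTILES
) -> dict[int, int]:
    """Smallest offset at which the cumulative count reaches q% (inclusive)."""
    s = pd.Series(dict(counts), dtype=float) if not isinstance(counts, pd.Series) else counts.astype(float)
    s = s[s > 0].sort_index()
    total = float(s.sum())
    if total <= 0:
        raise ValueError("percentile coordinates of an empty profile")
    cum = 100.0 * s.cumsum() / total
    offsets = s.index.to_numpy()
    out: dict[int, int] = {}
    for q in qs:
        idx = int(np.searchsorted(cum.to_numpy(), q, side="left"))
        # weak inequality: the coordinate where cumulative first reaches q%
        while cum.iloc[idx] < q:  # guard float slop at exact thresholds
            idx += 1
        out[q] = int(offsets[idx])
    return out


def percentile_coords_by_replicate(
    counts: pd.DataFrame, genes: Iterable[str], qs: Sequence[int] = PERCENTILES
) -> pd.DataFrame:
    """Long table (condition, replicate, gene, q, coord) for a gene set."""
    genes = set(genes)
    grouped = counts[counts["gene"].isin(genes)].groupby(
        ["condition", "replicate", "gene"], sort=False
    )
    rows = []
    for (cond, rep, gene), sub in grouped:
        coords = percentile_coords(
            pd.Series(sub["count"].to_numpy(), index=sub["offset"].to_numpy()), qs
        )
        for q, coord in coords.items():
            rows.append((cond, rep, gene, q, coord))
    return pd.DataFrame(rows, columns=["condition", "replicate", "gene", "q", "coord"])


def metagene_and_landmark_table(
    profiles_by_condition: Mapping[str, Mapping[str, EndZoneProfile]],
    comparisons: Sequence[tuple[str, str]] = (),
    utr_len: int = 400,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genome-wide landmark medians, meta-gene profiles and shift tests.

    Returns (landmark table, metagene table, test table).  The landmark
    table has one row per condition with the median across genes of each
    landmark.  The metagene table holds the mean scaled-percentage profile
    over offsets 1..utr_len per condition.  For each (reference, test)
    comparison a paired two-sided Wilcoxon signed-rank test across genes is
    run per landmark and flagged at p < alpha.
    """
    land_rows, meta = {}, {}
    for cond, profs in profiles_by_condition.items():
        frame = _landmark_frame(profs)
        land_rows[cond] = frame.median()
        land_rows[cond]["n_genes"] = len(frame)
        grid = np.zeros(utr_len)
        for p in profs.values():
            idx = p.scaled.index.to_numpy() - 1
            grid[idx] += p.scaled.to_numpy()
        meta[cond] = grid / max(len(profs), 1)
    landmark_table = pd.DataFrame(land_rows).T
    metagene = pd.DataFrame(meta, index=pd.RangeIndex(1, utr_len + 1, name="offset"))

    test_rows = []
    for ref, test in comparisons:
        fa = _landmark_frame(profiles_by_condition[ref])
        fb = _landmark_frame(profiles_by_condition[test])
        common = fa.index.intersection(fb.index)
        for lm in LANDMARKS:
            x, y = fa.loc[common, lm], fb.loc[common, lm]
            if len(common) < 2 or np.allclose(x, y):
                p = 1.0
            else:
                p = float(sps.wilcoxon(x, y).pvalue)
            test_rows.append(
                {
                    "reference": ref,
                    "test": test,
                    "landmark": lm,
                    "median_difference": float((y - x).median()),
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    tests = pd.DataFrame(test_rows)
    return landmark_table, metagene, tests


def _landmark_frame(profiles: Mapping[str, EndZoneProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            gene: (p.max_position, p.zone5, p.zone3, p.span, p.weighted_average)
            for gene, p in profiles.items()
        },
        index=LANDMARKS,
    ).T


def percent_coordinate_usage(
    counts: pd.DataFrame,
    bundle,
    genes: Iterable[str],
    condition: str | None = None,
    utr_len: int = 400,
) -> pd.Series:
    """Per offset: 100 x (#genes with reads there) / (#genes with a non-A base there).

    Offsets where no gene has a non-A base are reported as NaN.
    """
    genes = sorted(set(genes))
    sub = counts if condition is None else counts[counts["condition"] == condition]
    sub = sub[sub["gene"].isin(genes)]
    pooled = sub.groupby(["gene", "offset"], sort=False)["count"].sum()
    covered = np.zeros(utr_len)
    for gene, offset in pooled.index[pooled.to_numpy() > 0]:
        covered[offset - 1] += 1
    eligible = np.zeros(utr_len)
    for gene in genes:
        win = bundle.sense_window(gene)
        for i, b in enumerate(win[:utr_len]):
            if b != "A":
                eligible[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(eligible > 0, 100.0 * covered / eligible, np.nan)
    return pd.Series(pct, index=pd.RangeIndex(1, utr_len + 1, name="offset"))


def replicate_correlations(
    counts: pd.DataFrame,
    genes: Iterable[str] | None = None,
    condition: str | None = None,
    min_isoform_reads: float = 10,
    utr_len: int = 400,
) -> dict[str, object]:
    """Three levels of replicate reproducibility (Pearson R).

    (i) per-gene totals; (ii) individual isoforms genome-wide, omitting
    isoforms with fewer than `min_isoform_reads` reads in both replicates;
    (iii) per-gene scaled profiles over the full 400-offset vector (requires
    a gene set, e.g. the >=1000-read genes).  Exactly two replicates.
    """
    sub = counts if condition is None else counts[counts["condition"] == condition]
    reps = sorted(sub["replicate"].unique())
    if len(reps) != 2:
        raise ValueError(f"expected exactly two replicates, found {reps}")
    a = sub[sub["replicate"] == reps[0]]
    b = sub[sub["replicate"] == reps[1]]

    ta = a.groupby("gene")["count"].sum()
    tb = b.groupby("gene")["count"].sum()
    totals = pd.concat([ta, tb], axis=1, keys=["a", "b"]).fillna(0.0)
    r_totals = _pearson(totals["a"], totals["b"])

    ia = a.groupby(["gene", "offset"])["count"].sum()
    ib = b.groupby(["gene", "offset"])["count"].sum()
    iso = pd.concat([ia, ib], axis=1, keys=["a", "b"]).fillna(0.0)
    iso = iso[(iso["a"] >= min_isoform_reads) | (iso["b"] >= min_isoform_reads)]
    r_isoforms = _pearson(iso["a"], iso["b"])

    r_profiles: dict[str, float] = {}
    if genes is not None:
        for gene in sorted(set(genes)):
            va = _scaled_vector(ia, gene, utr_len)
            vb = _scaled_vector(ib, gene, utr_len)
            if va is None or vb is None:
                continue
            r_profiles[gene] = _pearson(pd.Series(va), pd.Series(vb))
    return {"totals": r_totals, "isoforms": r_isoforms, "profiles": pd.Series(r_profiles)}


def _scaled_vector(iso: pd.Series, gene: str, utr_len: int) -> np.ndarray | None:
    if gene not in iso.index.get_level_values(0):
        return None
    s = iso.loc[gene]
    peak = float(s.max())
    if peak <= 0:
        return None
    v = np.zeros(utr_len)
    v[s.index.to_numpy() - 1] = 100.0 * s.to_numpy() / peak
    return v


def _pearson(x: pd.Series, y: pd.Series) -> float:
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)
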