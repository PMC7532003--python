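"""Synthetic 3'-end sequencing data with a known ground truth.

The generator emulates the study design that the analysis modules consume:
a mini-genome of non-overlapping genes with strand-aware 400-nt 3'UTR
windows, per-gene poly(A)-site architectures placed at non-A sense-strand
positions, condition-dependent re-weighting of site usage for a configurable
"sensitive" gene fraction, multinomial replicate sampling at configurable
depth, and optionally raw reads carrying the leading-T / genomic-A-run
structure that the read filters act on.

The condition effect is an exponential positional tilt: with tilt parameter
tau, the effective weight of a site at offset p becomes

    w'_i  ∝  w_i * exp(-tau * p_i / 100)

renormalized per gene.  tau > 0 favours ORF-proximal sites (upstream shift),
tau < 0 favours distal sites, and tau = 0 leaves usage unchanged.  The tilt
re-balances existing sites without creating new ones.  Non-sensitive genes
always use tau = 0.

Every output is a pure function of the spec (which carries the seed); the
truth ledger records, per gene, the site positions, the baseline and
per-condition effective weights, the sensitivity flag, and the analytic
weighted-mean endpoint per condition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import CORE_LEN, GeneRecord, GenomeBundle, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class GenerationError(ValueError):
    """Raised when a spec cannot be realized (e.g. too many sites per UTR)."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset; identical spec => identical bytes."""

    n_genes: int = 100
    utr_len: int = 400
    sites_per_gene: tuple[int, int] = (4, 8)
    minor_sites_per_gene: tuple[int, int] = (8, 16)
    minor_usage: float = 0.10
    zone_width: int = 150
    min_site_offset: int = 20
    depth_per_replicate: int = 2000
    n_replicates_per_condition: int = 2
    conditions: tuple[tuple[str, float], ...] = (("ref", 0.0), ("test", 1.0))
    sensitive_fraction: float = 0.2
    weight_concentration: float = 3.0
    purine_enrichment: float | None = None
    replicate_jitter: float | None = None
    t_run_range: tuple[int, int] = (4, 12)
    decoy_fraction: float = 0.0
    orf_pad: int = 60
    spacer: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitive_fraction <= 1.0:
            raise ValueError("sensitive_fraction must lie in [0, 1]")
        if self.depth_per_replicate <= 0:
            raise ValueError("depth_per_replicate must be positive")
        if self.utr_len < 1:
            raise ValueError("utr_len must be >= 1")
        lo, hi = self.sites_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("sites_per_gene must be an increasing range >= 1")
        tlo, thi = self.t_run_range
        if not 1 <= tlo <= thi:
            raise ValueError("t_run_range must be an increasing range >= 1")
        if len({label for label, _ in self.conditions}) != len(self.conditions):
            raise ValueError("condition labels must be unique")

    @property
    def condition_labels(self) -> list[str]:
        return [label for label, _ in self.conditions]

    def tau(self, condition: str) -> float:
        for label, tau in self.conditions:
            if label == condition:
                return tau
        raise KeyError(condition)

    # seeds for the independent generation stages, all < 2**31
    def _stage_seed(self, stage: int) -> int:
        ss = np.random.SeedSequence([int(self.seed), stage])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("sites_per_gene", "t_run_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "conditions" in raw:
            raw["conditions"] = tuple((str(c[0]), float(c[1])) for c in raw["conditions"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            **{k: v for k, v in self.__dict__.items()},
            "sites_per_gene": list(self.sites_per_gene),
            "t_run_range": list(self.t_run_range),
            "conditions": [[label, tau] for label, tau in self.conditions],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GeneTruth:
    gene_id: str
    sites: np.ndarray                       # sorted offsets, non-A positions
    baseline_weights: np.ndarray            # sum to 1
    condition_weights: dict[str, np.ndarray]
    sensitive: bool

    def analytic_mean(self, condition: str) -> float:
        w = self.condition_weights[condition]
        return float(np.dot(self.sites, w))


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: per-gene architecture and effective usage."""

    genes: dict[str, GeneTruth]
    conditions: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            for i, p in enumerate(g.sites):
                row = {
                    "gene": g.gene_id,
                    "site": int(p),
                    "baseline_weight": g.baseline_weights[i],
                    "sensitive": g.sensitive,
                }
                for cond in self.conditions:
                    row[f"weight_{cond}"] = g.condition_weights[cond][i]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def analytic_means(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g.gene_id,
                "sensitive": g.sensitive,
                **{cond: g.analytic_mean(cond) for cond in self.conditions},
            }
            for g in self.genes.values()
        ]
        return pd.DataFrame(rows).set_index("gene")


def tilt_weights(weights: np.ndarray, sites: np.ndarray, tau: float) -> np.ndarray:
    """Re-weight site usage by the exponential positional tilt (see module doc).

    Evaluated in log space so extreme tilts saturate (all weight on the most
    proximal or distal site) instead of underflowing.
    """
    w = np.asarray(weights, dtype=float)
    p = np.asarray(sites, dtype=float)
    if np.all(w <= 0):
        raise ValueError("tilt requires at least one positive weight")
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
    logw = logw - tau * p / 100.0
    logw -= logw.max()
    out = np.exp(logw)
    return out / out.sum()


def build_genome(spec: SyntheticSpec) -> GenomeBundle:
    """Random mini-genome: one chromosome, non-overlapping genes, 400-nt UTRs.

    Each gene occupies a private block [ORF pad | UTR window] (mirrored for
    minus-strand genes) separated by spacers, so UTR windows never overlap.
    Fails when the UTR cannot host the requested number of non-A sites.
    """
    _, hi_sites = spec.sites_per_gene
    if hi_sites > spec.utr_len:
        raise GenerationError(
            f"cannot place up to {hi_sites} sites in a {spec.utr_len}-nt UTR"
        )
    rng = np.random.default_rng(spec._stage_seed(0))
    block = spec.orf_pad + spec.utr_len
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    length = spec.spacer + spec.n_genes * (block + spec.spacer)
    seq = rng.choice(_BASES, size=length)
    chrom = "synth_1"
    genes = []
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        start = spec.spacer + i * (block + spec.spacer) + 1  # 1-based block start
        gene_id = f"g{i + 1:0{width}d}"
        if strands[i] == "+":
            orf_start, orf_end = start, start + spec.orf_pad - 1
        else:
            # UTR occupies the left part of the block, ORF the right
            orf_start = start + spec.utr_len
            orf_end = start + block - 1
        genes.append(
            GeneRecord(gene_id, chrom, str(strands[i]), orf_start, orf_end, spec.utr_len)
        )
    bundle = GenomeBundle({chrom: "".join(seq)}, genes)
    for g in genes:
        n_non_a = bundle.count_non_a(g.gene_id)
        if n_non_a < hi_sites:
            raise GenerationError(
                f"gene {g.gene_id} has only {n_non_a} non-A positions "
                f"(< {hi_sites} requested sites)"
            )
    return bundle


def _eligible_offsets(spec: SyntheticSpec, bundle: GenomeBundle, gene: GeneRecord,
                      lo: int, hi: int) -> list[int]:
    """Site-eligible offsets in [lo, hi]: non-A base, short downstream A-run,
    globally unique 17-mer core, full core sequence available."""
    t_min = spec.t_run_range[0]
    out = []
    win = bundle.sense_window(gene.gene_id)
    for o in range(lo, hi + 1):
        if win[o - 1] == "A":
            continue
        p = gene.offset_to_genomic(o)
        if bundle.downstream_a_run(gene.chrom, gene.strand, p) >= t_min:
            continue
        seg = _forward_core(bundle, gene, o)
        if seg is None or not bundle.core_is_unique(seg):
            continue
        out.append(o)
    return out


def _spread_sites(
    rng: np.random.Generator, eligible: list[int], n_sites: int, lo: int, hi: int
) -> np.ndarray:
    """Draw one eligible offset per equal sub-segment of the zone (jittered grid).

    Spreading sites across the zone keeps the positional spread — and hence
    the tilt response — comparable across genes, mirroring the multi-site end
    zones seen in real data rather than tight random clusters.  Segments with
    no free eligible offset fall back to a uniform draw from the remainder.
    """
    edges = np.linspace(lo, hi + 1, n_sites + 1)
    chosen: list[int] = []
    pool = set(eligible)
    for i in range(n_sites):
        seg = sorted(o for o in pool if edges[i] <= o < edges[i + 1])
        if seg:
            pick = int(seg[int(rng.integers(len(seg)))])
        else:
            rest = sorted(pool)
            pick = int(rest[int(rng.integers(len(rest)))])
        chosen.append(pick)
        pool.discard(pick)
    return np.sort(np.array(chosen))


def _forward_core(bundle: GenomeBundle, gene: GeneRecord, offset: int) -> str | None:
    """Forward-strand 17-mer covering the read core ending at `offset`."""
    p = gene.offset_to_genomic(offset)
    seq = bundle.seqs[gene.chrom]
    if gene.strand == "+":
        if p - CORE_LEN < 0:
            return None
        return seq[p - CORE_LEN : p]
    if p + CORE_LEN - 1 > len(seq):
        return None
    return seq[p - 1 : p + CORE_LEN - 1]


def assign_site_weights(spec: SyntheticSpec, bundle: GenomeBundle) -> SyntheticTruth:
    """Draw per-gene site architectures and per-condition usage weights.

    Sites are drawn from eligible non-A offsets inside a random end-zone of
    ``zone_width`` nt; baseline weights are Dirichlet; condition weights are
    the exponential tilt of the baseline (tau = 0 for non-sensitive genes).
    An exact count round(n_genes * sensitive_fraction) of genes is sensitive.
    """
    rng = np.random.default_rng(spec._stage_seed(1))
    lo_sites, hi_sites = spec.sites_per_gene
    n_sens = int(round(spec.n_genes * spec.sensitive_fraction))
    order = rng.permutation(spec.n_genes)
    sensitive = np.zeros(spec.n_genes, dtype=bool)
    sensitive[order[:n_sens]] = True

    genes: dict[str, GeneTruth] = {}
    for gi, gene in enumerate(bundle.genes):
        n_sites = int(rng.integers(lo_sites, hi_sites + 1))
        zone_lo = spec.min_site_offset
        zone_hi = min(spec.utr_len, zone_lo + spec.zone_width - 1)
        if zone_hi < spec.utr_len:
            shift_max = spec.utr_len - zone_hi
            dz = int(rng.integers(0, shift_max + 1))
            zone_lo, zone_hi = zone_lo + dz, zone_hi + dz
        eligible = _eligible_offsets(spec, bundle, gene, zone_lo, zone_hi)
        if len(eligible) < n_sites:  # fall back to the whole window
            eligible = _eligible_offsets(spec, bundle, gene, 1, spec.utr_len)
            zone_lo, zone_hi = 1, spec.utr_len
        if len(eligible) < n_sites:
            raise GenerationError(
                f"gene {gene.gene_id}: only {len(eligible)} eligible sites "
                f"for {n_sites} requested"
            )
        sites = _spread_sites(rng, eligible, n_sites, zone_lo, zone_hi)
        w0 = rng.dirichlet(np.full(n_sites, spec.weight_concentration))
        # minor-isoform background: real end zones carry low-level reads at
        # many additional non-A positions beyond the handful of major sites
        remaining = sorted(set(eligible) - set(int(s) for s in sites))
        lo_m, hi_m = spec.minor_sites_per_gene
        n_minor = min(int(rng.integers(lo_m, hi_m + 1)), len(remaining))
        if n_minor > 0 and spec.minor_usage > 0:
            minor_sites = np.sort(rng.choice(remaining, size=n_minor, replace=False))
            w_minor = rng.dirichlet(np.ones(n_minor)) * spec.minor_usage
            sites = np.concatenate([sites, minor_sites])
            w0 = np.concatenate([w0 * (1.0 - spec.minor_usage), w_minor])
            order_idx = np.argsort(sites)
            sites, w0 = sites[order_idx], w0[order_idx]
        cond_w = {}
        for label, tau in spec.conditions:
            eff_tau = tau if sensitive[gi] else 0.0
            cond_w[label] = tilt_weights(w0, sites, eff_tau)
        genes[gene.gene_id] = GeneTruth(
            gene.gene_id, sites, w0, cond_w, bool(sensitive[gi])
        )

    truth = SyntheticTruth(genes, conditions=spec.condition_labels)
    if spec.purine_enrichment:
        _enrich_purines(spec, bundle, truth, rng)
    return truth


def _enrich_purines(spec: SyntheticSpec, bundle: GenomeBundle,
                    truth: SyntheticTruth, rng: np.random.Generator) -> None:
    """Bias A/G content in the +/-10 nt flanks of sensitive genes' sites.

    Mutates the bundle's sequences in place.  Site offsets themselves are
    left untouched (they must stay non-A with unique cores); flank edits can
    break 17-mer core uniqueness, so raw-read round-trips are only exact
    when purine_enrichment is disabled.
    """
    seqs = {k: list(v) for k, v in bundle.seqs.items()}
    for g in truth.genes.values():
        if not g.sensitive:
            continue
        rec = bundle.genes_by_id[g.gene_id]
        site_set = set(int(s) for s in g.sites)
        for site in g.sites:
            for d in range(-10, 11):
                o = int(site) + d
                if d == 0 or o in site_set or not 1 <= o <= rec.utr_len:
                    continue
                if rng.random() < spec.purine_enrichment:
                    base = str(rng.choice(["A", "G"]))
                    p = rec.offset_to_genomic(o)
                    fwd = base if rec.strand == "+" else revcomp(base)
                    seqs[rec.chrom][p - 1] = fwd
    bundle.seqs = {k: "".join(v) for k, v in seqs.items()}
    bundle.__dict__.pop("kmer_index", None)  # invalidate cache


def sample_counts(truth: SyntheticTruth, spec: SyntheticSpec) -> pd.DataFrame:
    """Multinomial endpoint counts per gene x condition x replicate.

    Returns a long table with columns condition, replicate, sample, gene,
    offset, count; per gene and replicate the counts sum to the configured
    depth.  With ``replicate_jitter`` set, each replicate draws its own
    weights from Dirichlet(jitter * w'), adding biological over-dispersion.
    """
    rng = np.random.default_rng(spec._stage_seed(2))
    rows: list[tuple[str, int, str, str, int, int]] = []
    for cond in spec.condition_labels:
        for rep in range(1, spec.n_replicates_per_condition + 1):
            sample = f"{cond}_rep{rep}"
            for g in truth.genes.values():
                w = g.condition_weights[cond]
                if spec.replicate_jitter:
                    w = rng.dirichlet(np.maximum(spec.replicate_jitter * w, 1e-9))
                counts = rng.multinomial(spec.depth_per_replicate, w)
                for p, c in zip(g.sites, counts):
                    if c:
                        rows.append((cond, rep, sample, g.gene_id, int(p), int(c)))
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "sample", "gene", "offset", "count"]
    )


def emit_reads(
    counts: pd.DataFrame,
    truth: SyntheticTruth,
    bundle: GenomeBundle,
    spec: SyntheticSpec,
    path: str | Path,
    seed: int | None = None,
) -> dict[str, int]:
    """Write raw 3'-end reads for one sample's counts as FASTQ.

    Each sampled endpoint at offset p yields one read: k leading Ts (k drawn
    uniformly from ``t_run_range``) followed by the reverse complement of the
    17 genomic nt ending at p on the sense strand.  With ``decoy_fraction``
    > 0, additional internal-priming decoys are emitted at positions just
    upstream of genomic A-runs, with leading-T count <= the run length, so a
    sound priming filter removes all of them.  Returns emission statistics.
    """
    rng = np.random.default_rng(
        spec._stage_seed(3) if seed is None else int(seed) % (2**31)
    )
    t_lo, t_hi = spec.t_run_range
    stats = {"reads": 0, "decoys": 0, "skipped": 0}
    with open(path, "w") as fh:
        for row in counts.itertuples(index=False):
            gene, offset, n = row.gene, int(row.offset), int(row.count)
            core_sense = bundle.sense_upstream(gene, offset, CORE_LEN)
            if core_sense is None:
                logger.warning(
                    "skipping %d reads at %s:%d (core runs off the sequence)",
                    n, gene, offset,
                )
                stats["skipped"] += n
                continue
            core = revcomp(core_sense)
            ts = rng.integers(t_lo, t_hi + 1, size=n)
            for j in range(n):
                seq = "T" * int(ts[j]) + core
                fh.write(f"@{gene}:{offset}:{stats['reads']}\n{seq}\n+\n{'I' * len(seq)}\n")
                stats["reads"] += 1
        if spec.decoy_fraction > 0:
            n_decoys = int(round(spec.decoy_fraction * max(stats["reads"], 1)))
            decoy_pool = _decoy_positions(bundle)
            for j in range(n_decoys):
                if not decoy_pool:
                    break
                gene, offset, run = decoy_pool[int(rng.integers(len(decoy_pool)))]
                core_sense = bundle.sense_upstream(gene, offset, CORE_LEN)
                if core_sense is None:
                    continue
                t = int(rng.integers(1, run + 1))
                seq = "T" * t + revcomp(core_sense)
                fh.write(f"@decoy:{gene}:{offset}:{j}\n{seq}\n+\n{'I' * len(seq)}\n")
                stats["decoys"] += 1
    return stats


def _decoy_positions(bundle: GenomeBundle) -> list[tuple[str, int, int]]:
    """(gene, offset, A-run) for non-A offsets immediately upstream of A-runs."""
    out = []
    for g in bundle.genes:
        win = bundle.sense_window(g.gene_id)
        for o in range(CORE_LEN, len(win)):
            if win[o - 1] == "A":
                continue
            p = g.offset_to_genomic(o)
            run = bundle.downstream_a_run(g.chrom, g.strand, p)
            if run >= 1:
                out.append((g.gene_id, o, run))
    return out


def simulate(spec: SyntheticSpec) -> tuple[GenomeBundle, SyntheticTruth, pd.DataFrame]:
    """Convenience wrapper: genome + truth + counts from one spec."""
    bundle = build_genome(spec)
    truth = assign_site_weights(spec, bundle)
    counts = sample_counts(truth, spec)
    return bundle, truth, counts
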