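"""Read-level processing of 3'-end sequencing data.

Reads from a poly(A)-selected 3'-end protocol begin with a run of Ts that is
the reverse complement of the poly(A) tail; the first templated base follows
that run.  Processing steps:

1. parse: reject reads with ambiguous bases or not starting with T; strip
   the maximal leading-T run and keep the first 17 nt of the remainder.
2. place: exact-match the 17-mer core (and its reverse complement) over the
   genome; zero or multiple matches are rejected.  The inferred mRNA
   endpoint is the sense-strand position adjacent to the leading-T run.
3. internal-priming filter: keep a read only when the leading-T count
   strictly exceeds the length of the genomic A-run immediately downstream
   of the endpoint (otherwise the Ts may be templated, i.e. oligo-dT primed
   internally rather than on a real tail).
4. assign: endpoints inside a gene's 400-nt 3'UTR window (strand-consistent)
   are tabulated per (gene, offset); endpoints in two overlapping windows
   are counted for both genes.
5. normalize: scale each sample's counts to a common total (25 million by
   default), allowing fractional counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .genome import CORE_LEN, GenomeBundle, revcomp

logger = logging.getLogger(__name__)

DEFAULT_TARGET_DEPTH = 25_000_000

_VALID = frozenset("ACGT")


class ParsedRead(NamedTuple):
    t_count: int
    core17: str


class Rejection(NamedTuple):
    reason: str


class Locus(NamedTuple):
    chrom: str
    strand: str
    endpoint: int  # 1-based genomic position of the last templated base


@dataclass
class ProcessingStats:
    total: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    filtered_internal_priming: int = 0
    unassigned: int = 0
    kept: int = 0

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1


def parse_read(read: str) -> ParsedRead | Rejection:
    """Strip the maximal leading-T run and return (t_count, 17-nt core).

    Rejects reads containing non-ACGT symbols, reads not starting with T,
    and reads whose post-T remainder is shorter than 17 nt.
    """
    if not read or read[0] != "T":
        return Rejection("no_leading_t")
    if not _VALID.issuperset(read):
        return Rejection("ambiguous_base")
    t_count = len(read) - len(read.lstrip("T"))
    remainder = read[t_count:]
    if len(remainder) < CORE_LEN:
        return Rejection("too_short")
    return ParsedRead(t_count, remainder[:CORE_LEN])


def place_core(core17: str, bundle: GenomeBundle) -> Locus | Rejection:
    """Unique exact placement of the core over both strands of the genome.

    A forward-strand match of the core itself corresponds to a minus-strand
    endpoint at the match start; a forward-strand match of its reverse
    complement corresponds to a plus-strand endpoint at the match end.
    """
    if len(core17) != CORE_LEN:
        raise ValueError(f"core must be {CORE_LEN} nt")
    idx = bundle.kmer_index
    hits: list[Locus] = []
    for chrom, start in idx.get(core17, ()):
        hits.append(Locus(chrom, "-", start))
    for chrom, start in idx.get(revcomp(core17), ()):
        hits.append(Locus(chrom, "+", start + CORE_LEN - 1))
    if not hits:
        return Rejection("unmapped")
    if len(hits) > 1:
        return Rejection("multimapped")
    return hits[0]


def internal_priming_filter(t_count: int, locus: Locus, bundle: GenomeBundle) -> bool:
    """True (keep) iff the leading-T count exceeds the downstream genomic A-run."""
    run = bundle.downstream_a_run(locus.chrom, locus.strand, locus.endpoint)
    return t_count > run


def assign_and_tabulate(
    endpoints: Iterable[Locus],
    bundle: GenomeBundle,
    sample: str = "sample",
    stats: ProcessingStats | None = None,
) -> pd.DataFrame:
    """Tabulate endpoints into per-(gene, offset) counts.

    Endpoints inside two genes' windows increment both genes (logged).  The
    placement convention guarantees endpoints sit at non-A sense positions
    (a templated A would have been stripped with the leading-T run); this is
    asserted defensively.
    """
    stats = stats if stats is not None else ProcessingStats()
    gene_map = bundle.endpoint_gene_map()
    counts: dict[tuple[str, int], float] = {}
    for locus in endpoints:
        targets = gene_map.get((locus.chrom, locus.strand, locus.endpoint))
        if not targets:
            stats.unassigned += 1
            continue
        if len(targets) > 1:
            logger.info("endpoint %s falls in %d gene windows", locus, len(targets))
        for gene_id, offset in targets:
            base = bundle.sense_base(gene_id, offset)
            if base == "A":
                raise AssertionError(
                    f"endpoint at sense-strand A position: {gene_id}:{offset}"
                )
            counts[(gene_id, offset)] = counts.get((gene_id, offset), 0) + 1
        stats.kept += 1
    df = pd.DataFrame(
        [(sample, g, o, c) for (g, o), c in sorted(counts.items())],
        columns=["sample", "gene", "offset", "count"],
    )
    return df


def normalize_depth(
    table: pd.DataFrame,
    target: float = DEFAULT_TARGET_DEPTH,
    total: float | None = None,
) -> pd.DataFrame:
    """Scale counts so the sample total equals `target` (fractional allowed).

    `total` defaults to the table's own sum; pass the sample's full mapped-
    read total when the table covers only a subset of mapped reads.
    Relative proportions are preserved exactly.
    """
    if table.empty:
        raise ValueError("cannot normalize an empty table")
    observed = float(table["count"].sum()) if total is None else float(total)
    if observed <= 0:
        raise ValueError("cannot normalize a table with zero total")
    out = table.copy()
    out["count"] = out["count"] * (target / observed)
    return out


def process_fastq(
    path: str | Path,
    bundle: GenomeBundle,
    sample: str = "sample",
    target_depth: float | None = None,
) -> tuple[pd.DataFrame, ProcessingStats]:
    """Full read pipeline: FASTQ -> filtered, tabulated EndpointTable.

    With `target_depth` set, the table is depth-normalized using the number
    of reads that survive all filters as the mapped total.
    """
    import pysam

    stats = ProcessingStats()
    endpoints: list[Locus] = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            stats.total += 1
            parsed = parse_read(entry.sequence.upper())
            if isinstance(parsed, Rejection):
                stats.reject(parsed.reason)
                continue
            locus = place_core(parsed.core17, bundle)
            if isinstance(locus, Rejection):
                stats.reject(locus.reason)
                continue
            if not internal_priming_filter(parsed.t_count, locus, bundle):
                stats.filtered_internal_priming += 1
                continue
            endpoints.append(locus)
    table = assign_and_tabulate(endpoints, bundle, sample=sample, stats=stats)
    if target_depth is not None and not table.empty:
        table = normalize_depth(table, target=target_depth, total=stats.kept)
    return table, stats


def read_endpoint_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV endpoint table (sample, gene, offset, count [+ extras])."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "offset", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
    return df


def write_endpoint_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
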