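"""Reference sequences plus strand-aware 3'UTR windows.

The central container is :class:`GenomeBundle`: named chromosome sequences
together with gene records, each carrying a fixed-length 3'UTR window that
starts at the first nucleotide after the stop codon.  Offsets are 1-based in
transcript orientation: offset 100 is the position 100 nt downstream of the
ORF end on the sense strand.  Endpoint counts are only ever tabulated at
offsets whose sense-strand base is not A, because an adenosine at the mRNA
3' end is indistinguishable from the first residue of the poly(A) tail.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CORE_LEN = 17  # length of the mapped read core


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One gene: genomic ORF span plus a downstream 3'UTR window.

    ``orf_start``/``orf_end`` are 1-based inclusive genomic coordinates with
    ``orf_start <= orf_end`` regardless of strand.  For a ``+`` gene the UTR
    window is ``[orf_end+1, orf_end+utr_len]``; for a ``-`` gene it is
    ``[orf_start-utr_len, orf_start-1]`` read right-to-left.
    """

    gene_id: str
    chrom: str
    strand: str
    orf_start: int
    orf_end: int
    utr_len: int = 400

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.orf_start > self.orf_end:
            raise ValueError("orf_start must be <= orf_end")

    def offset_to_genomic(self, offset: int) -> int:
        """Genomic coordinate of 3'UTR offset (1..utr_len)."""
        if not 1 <= offset <= self.utr_len:
            raise ValueError(f"offset {offset} outside [1, {self.utr_len}]")
        if self.strand == "+":
            return self.orf_end + offset
        return self.orf_start - offset

    def genomic_to_offset(self, pos: int) -> int | None:
        """Inverse of :meth:`offset_to_genomic`; None when outside the window."""
        if self.strand == "+":
            offset = pos - self.orf_end
        else:
            offset = self.orf_start - pos
        return offset if 1 <= offset <= self.utr_len else None

    @property
    def utr_span(self) -> tuple[int, int]:
        """Genomic (start, end) of the UTR window, start <= end."""
        if self.strand == "+":
            return self.orf_end + 1, self.orf_end + self.utr_len
        return self.orf_start - self.utr_len, self.orf_start - 1


class GenomeBundle:
    """Chromosome sequences + gene records with offset/base lookups."""

    def __init__(self, seqs: Mapping[str, str], genes: Iterable[GeneRecord]):
        self.seqs: dict[str, str] = {k: v.upper() for k, v in seqs.items()}
        self.genes: list[GeneRecord] = list(genes)
        self.genes_by_id: dict[str, GeneRecord] = {g.gene_id: g for g in self.genes}
        if len(self.genes_by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")
        for g in self.genes:
            if g.chrom not in self.seqs:
                raise ValueError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            lo, hi = g.utr_span
            if lo < 1 or hi > len(self.seqs[g.chrom]):
                raise ValueError(f"UTR window of {g.gene_id} runs off {g.chrom}")

    # ---- base lookups -------------------------------------------------
    def base(self, chrom: str, pos: int) -> str:
        """Forward-strand base at 1-based position."""
        return self.seqs[chrom][pos - 1]

    def sense_base(self, gene_id: str, offset: int) -> str:
        g = self.genes_by_id[gene_id]
        b = self.base(g.chrom, g.offset_to_genomic(offset))
        return b if g.strand == "+" else b.translate(_COMPLEMENT)

    def sense_window(self, gene_id: str) -> str:
        """The UTR window sequence in transcript orientation (offsets 1..L)."""
        g = self.genes_by_id[gene_id]
        lo, hi = g.utr_span
        seq = self.seqs[g.chrom][lo - 1 : hi]
        return seq if g.strand == "+" else revcomp(seq)

    def non_a_offsets(self, gene_id: str) -> list[int]:
        win = self.sense_window(gene_id)
        return [i + 1 for i, b in enumerate(win) if b != "A"]

    def count_non_a(self, gene_id: str, lo: int = 1, hi: int | None = None) -> int:
        """Number of non-A sense positions at offsets lo..hi (inclusive)."""
        win = self.sense_window(gene_id)
        hi = len(win) if hi is None else hi
        return sum(1 for b in win[lo - 1 : hi] if b != "A")

    def sense_upstream(self, gene_id: str, offset: int, length: int) -> str | None:
        """Sense-strand sequence of `length` nt ending at `offset` (inclusive).

        May extend upstream of the UTR window into the ORF.  Returns None when
        the slice would run off the chromosome.
        """
        g = self.genes_by_id[gene_id]
        p = g.offset_to_genomic(offset)
        seq = self.seqs[g.chrom]
        if g.strand == "+":
            if p - length < 0:
                return None
            return seq[p - length : p]
        if p + length - 1 > len(seq):
            return None
        return revcomp(seq[p - 1 : p + length - 1])

    def sense_flank(self, gene_id: str, offset: int, position: int) -> str | None:
        """Base at a signed position relative to a cleavage site at `offset`.

        Position -1 is the last genomically encoded nucleotide, i.e. the base
        at `offset` itself; -2 is one nt upstream; +1 is the first genomic
        base past the cleavage site.  There is no position 0.  Returns None
        when the base falls outside the chromosome.
        """
        if position == 0:
            raise ValueError("position 0 does not exist")
        g = self.genes_by_id[gene_id]
        delta = position + 1 if position < 0 else position
        p = g.offset_to_genomic(offset)
        p = p + delta if g.strand == "+" else p - delta
        seq = self.seqs[g.chrom]
        if not 1 <= p <= len(seq):
            return None
        b = seq[p - 1]
        return b if g.strand == "+" else b.translate(_COMPLEMENT)

    def downstream_a_run(self, chrom: str, strand: str, pos: int) -> int:
        """Length of the sense-strand A-run immediately downstream of `pos`."""
        seq = self.seqs[chrom]
        run = 0
        if strand == "+":
            i = pos  # 0-based index of pos+1
            while i < len(seq) and seq[i] == "A":
                run += 1
                i += 1
        else:
            i = pos - 2  # 0-based index of pos-1; sense A = forward T
            while i >= 0 and seq[i] == "T":
                run += 1
                i -= 1
        return run

    # ---- k-mer index for exact placement ------------------------------
    @cached_property
    def kmer_index(self) -> dict[str, list[tuple[str, int]]]:
        """Forward-strand 17-mer -> list of (chrom, 1-based start)."""
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.seqs.items():
            for i in range(len(seq) - CORE_LEN + 1):
                index.setdefault(seq[i : i + CORE_LEN], []).append((chrom, i + 1))
        return index

    def core_is_unique(self, forward_seg: str) -> bool:
        """True when the 17-mer occurs exactly once over both strands."""
        idx = self.kmer_index
        n = len(idx.get(forward_seg, ())) + len(idx.get(revcomp(forward_seg), ()))
        return n == 1

    def endpoint_gene_map(self) -> dict[tuple[str, str, int], list[tuple[str, int]]]:
        """(chrom, strand, genomic pos) -> [(gene_id, offset)] over all windows."""
        cached = self.__dict__.get("_endpoint_gene_map")
        if cached is not None:
            return cached
        out: dict[tuple[str, str, int], list[tuple[str, int]]] = {}
        for g in self.genes:
            for o in range(1, g.utr_len + 1):
                key = (g.chrom, g.strand, g.offset_to_genomic(o))
                out.setdefault(key, []).append((g.gene_id, o))
        self.__dict__["_endpoint_gene_map"] = out
        return out

    # ---- serialization -------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\tapashift\tgene\t{g.orf_start}\t{g.orf_end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                lo, hi = g.utr_span
                fh.write(
                    f"{g.chrom}\tapashift\tthree_prime_UTR\t{lo}\t{hi}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}:utr3;Parent={g.gene_id}\n"
                )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path, utr_len: int = 400) -> "GenomeBundle":
        import gffutils

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        db = gffutils.create_db(
            str(gff3), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene"):
            genes.append(
                GeneRecord(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    orf_start=feat.start,
                    orf_end=feat.end,
                    utr_len=utr_len,
                )
            )
        return cls(seqs, genes)
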