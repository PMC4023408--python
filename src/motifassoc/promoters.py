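"""Promoter extraction and k-let-preserving sequence shuffling.

Promoters are fixed-flank windows around a gene's transcription start
site (TSS). Genes with several annotated transcripts use the TSS of the
shortest one. Coordinates are 0-based half-open internally; BED files are
read and written natively in that convention.

The shuffle implemented here preserves the exact multiset of length-k
substrings (k=3 preserves trinucleotide frequencies), which is the
standard control for motif-enrichment statistics in genomic sequence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .motifs import reverse_complement


@dataclass(frozen=True)
class TssRecord:
    """Strand-aware TSS annotation for one transcript of a gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    transcript_length: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.transcript_length <= 0:
            raise ValueError(f"{self.gene_id}: transcript_length must be > 0")


@dataclass
class PromoterSet:
    """gene_id -> promoter sequence, read 5'->3' relative to the gene."""

    sequences: dict[str, str]
    flank: int
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=gid, description="")
            for gid, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, flank: int) -> "PromoterSet":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences=seqs, flank=flank, provenance=f"fasta:{path}")


def read_tss_bed(path) -> list[TssRecord]:
    """BED6: chrom, start, end(=start+1), name=gene_id, score=transcript_length, strand."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            records.append(
                TssRecord(
                    gene_id=f[3],
                    chrom=f[0],
                    strand=f[5],
                    tss=int(f[1]),
                    transcript_length=int(float(f[4])),
                )
            )
    return records


def write_tss_bed(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.tss}\t{r.tss + 1}\t{r.gene_id}\t"
                f"{r.transcript_length}\t{r.strand}\n"
            )


def select_tss(records) -> dict[str, TssRecord]:
    """One TSS per gene: the shortest transcript, ties to the smallest coordinate."""
    best: dict[str, TssRecord] = {}
    for r in records:
        cur = best.get(r.gene_id)
        if cur is None or (r.transcript_length, r.tss) < (
            cur.transcript_length,
            cur.tss,
        ):
            best[r.gene_id] = r
    return best


def extract_promoters(genome_fasta, tss_by_gene, flank: int = 1000) -> PromoterSet:
    """Extract the promoter window of each gene from a genome FASTA.

    The window is ``[tss - flank, tss + flank)`` for '+' strand genes and
    ``[tss - flank + 1, tss + flank + 1)`` reverse-complemented for '-'
    strand genes, so the TSS occupies the same relative offset in every
    promoter. Windows are truncated at chromosome ends.
    """
    if isinstance(tss_by_gene, list):
        tss_by_gene = select_tss(tss_by_gene)
    fa = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=False)
    missing = sorted(
        {r.gene_id for r in tss_by_gene.values() if r.chrom not in fa}
    )
    if missing:
        raise KeyError(
            f"chromosomes missing from {genome_fasta} for genes: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    seqs: dict[str, str] = {}
    for gid, r in tss_by_gene.items():
        size = len(fa[r.chrom])
        if r.strand == "+":
            start, end = r.tss - flank, r.tss + flank
        else:
            start, end = r.tss - flank + 1, r.tss + flank + 1
        start, end = max(0, start), min(size, end)
        seq = str(fa[r.chrom][start:end])
        if r.strand == "-":
            seq = reverse_complement(seq)
        seqs[gid] = seq
    return PromoterSet(
        sequences=seqs, flank=flank, provenance=f"genome:{genome_fasta}"
    )


# ---------------------------------------------------------------------------
# k-let shuffle


def klet_shuffle(seq: str, k: int = 3, seed: int | None = None, rng=None) -> str:
    """Uniform random shuffle preserving the exact k-mer multiset.

    Implements the Eulerian-path method: the sequence is a walk on the
    de Bruijn multigraph whose vertices are (k-1)-mers and whose edges are
    the k-mers in order. A uniform random Eulerian walk with the same start
    and end vertices is sampled by (a) choosing a uniform random in-bound
    arborescence toward the final vertex (rejection sampling over per-vertex
    last-edge choices), and (b) uniformly permuting each vertex's remaining
    out-edges. By the BEST theorem this yields a uniform draw from all
    sequences with the same k-mer composition, unlike naive swapping
    heuristics which are both biased and not exactly k-let preserving.

    Sequences of length <= k are returned unchanged. Deterministic given
    ``seed`` (or an explicit ``random.Random`` via ``rng``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(seq)
    if n == 0:
        raise ValueError("cannot shuffle an empty sequence")
    if n <= k:
        return seq
    if rng is None:
        rng = random.Random(seed)
    if k == 1:
        chars = list(seq)
        rng.shuffle(chars)
        return "".join(chars)

    # vertices are (k-1)-mers; edge i goes v_i -> v_{i+1} emitting seq[i+k-1]
    km1 = k - 1
    verts = [seq[i : i + km1] for i in range(n - km1 + 1)]
    out_edges: dict[str, list[str]] = {}
    for i in range(len(verts) - 1):
        out_edges.setdefault(verts[i], []).append(verts[i + 1])
    start, end = verts[0], verts[-1]

    vkeys = [v for v in out_edges if v != end]
    for _ in range(10000):
        last = {v: rng.randrange(len(out_edges[v])) for v in vkeys}
        # arborescence check: following chosen last edges must reach `end`
        # from every vertex without hitting a cycle
        ok = True
        state: dict[str, int] = {end: 1}  # 1 = reaches end, 0 = on current path
        for v in vkeys:
            path = []
            u = v
            while u not in state:
                state[u] = 0
                path.append(u)
                u = out_edges[u][last[u]]
            if state[u] == 0:  # walked onto the current path: a cycle
                ok = False
                break
            for p in path:
                state[p] = 1
        if ok:
            break
    else:  # pragma: no cover - rejection virtually always succeeds quickly
        raise RuntimeError("could not sample an Eulerian shuffle (graph too rigid)")

    # permute non-last edges; append the chosen last edge at the end
    shuffled: dict[str, list[str]] = {}
    for v, edges in out_edges.items():
        if v in last:
            rest = edges[: last[v]] + edges[last[v] + 1 :]
            rng.shuffle(rest)
            rest.append(edges[last[v]])
        else:
            rest = edges[:]
            rng.shuffle(rest)
        shuffled[v] = rest

    # walk the Eulerian path
    out = [start]
    ptr = {v: 0 for v in shuffled}
    u = start
    for _ in range(len(verts) - 1):
        nxt = shuffled[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt[-1])
        u = nxt
    return "".join(out)


def kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Multiset of length-k substrings, as a dict."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts
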