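"""Position-weight-matrix models of transcription-factor binding specificity.

This module covers the motif side of the pipeline: parsing motif files
(MEME minimal text and a 4-column tabular PFM), turning frequency matrices
into log-odds scoring matrices, scanning sequences for the best-scoring
site, computing the exact null distribution of per-window scores by dynamic
programming (so that a site can be called at a score *p*-value threshold
such as 1e-5), and comparing/clustering motifs by Pearson correlation of
their aligned frequency columns with UPGMA.

Alphabet order is A, C, G, T throughout; scores are log2-odds ("bits").
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

ALPHABET = "ACGT"
#: integer codes: A=0 C=1 G=2 T=3, anything else (N, gaps) = 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_LOWER = np.zeros(256, dtype=bool)
for _c in range(ord("a"), ord("z") + 1):
    _LOWER[_c] = True

#: default score-bin width for discretized score distributions, in bits.
#: Fine enough that tail probabilities near 1e-5 are stable to well under
#: 5% relative error (checked against exhaustive enumeration in the tests).
DEFAULT_GRANULARITY = 1e-3

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0..T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def softmask(seq: str) -> np.ndarray:
    """Boolean array marking lowercase (soft-masked) positions."""
    return _LOWER[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]


class MotifParseError(ValueError):
    """Raised when a motif file does not parse under the named dialect."""


@dataclass
class MotifMatrix:
    """A position frequency matrix over A,C,G,T.

    ``counts`` may hold raw counts or probabilities; rows are normalized on
    demand via :attr:`probabilities`. ``source`` records where the motif
    came from (a SELEX compendium, ChIP-derived discovery, or synthesis).
    """

    id: str
    counts: np.ndarray
    gene_label: str | None = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"motif {self.id}: counts must be L x 4")
        if self.counts.shape[0] < 1:
            raise ValueError(f"motif {self.id}: length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.id}: negative frequencies")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError(f"motif {self.id}: a position row sums to 0")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalized L x 4 matrix (each row sums to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.probabilities.argmax(axis=1))

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(
            id=self.id + "_rc",
            counts=self.counts[::-1, ::-1].copy(),
            gene_label=self.gene_label,
            source=self.source,
        )


@dataclass
class ScoringMatrix:
    """Log2-odds scoring form of a motif against a 0-order background."""

    motif_id: str
    scores: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        """Minimum achievable window score (may be -inf at pseudocount 0)."""
        return float(self.scores.min(axis=1).sum())

    @property
    def sentinel_score(self) -> float:
        """Score reported for sequences with no scorable window.

        One granularity step below the minimum achievable score, so that
        unscorable promoters rank strictly last in downstream rank-sum
        tests instead of being dropped silently.
        """
        lo = self.min_score
        if not np.isfinite(lo):
            return -np.inf
        return lo - DEFAULT_GRANULARITY


def make_scoring_matrix(
    motif: MotifMatrix,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> ScoringMatrix:
    """Build the log-odds matrix for ``motif``.

    score[i][b] = log2( (counts[i][b] + pc*bg[b]) / (rowsum_i + pc) / bg[b] )

    The pseudocount is distributed proportionally to the background. With
    ``pseudocount=0`` and a zero count the corresponding entry is -inf;
    that is permitted but flagged with a warning.
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 positive probabilities")
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = motif.counts
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        scores = np.log2(
            (counts + pseudocount * background) / (rowsum + pseudocount) / background
        )
    if not np.all(np.isfinite(scores)):
        warnings.warn(
            f"motif {motif.id}: zero counts with pseudocount=0 give "
            "-inf log-odds entries",
            RuntimeWarning,
            stacklevel=2,
        )
    return ScoringMatrix(
        motif_id=motif.id,
        scores=scores,
        background=background,
        pseudocount=float(pseudocount),
    )


def estimate_background(seqs) -> np.ndarray:
    """0-order background from observed A/C/G/T counts in ``seqs``."""
    counts = np.zeros(4)
    for s in seqs:
        codes = encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BACKGROUND.copy()
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# scanning


def window_scores(
    sm: ScoringMatrix, codes: np.ndarray, masked: np.ndarray | None = None
) -> np.ndarray:
    """Score every window of an encoded sequence on the given strand.

    Windows containing an ambiguous base (code 4) or a masked position
    are assigned -inf. Returns an empty array if the sequence is shorter
    than the motif.
    """
    L = sm.length
    n = codes.shape[0]
    if n < L:
        return np.empty(0)
    invalid = codes >= 4
    if masked is not None:
        invalid = invalid | masked
    # pad scores with a column for code 4 so fancy indexing never fails
    padded = np.hstack([sm.scores, np.zeros((sm.length, 1))])
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    vals = padded[np.arange(L)[None, :], win.astype(np.intp)].sum(axis=1)
    bad = np.convolve(invalid.astype(np.intp), np.ones(L, dtype=np.intp), "valid") > 0
    vals[bad] = -np.inf
    return vals


def best_site_score(
    sm: ScoringMatrix,
    seq: str,
    both_strands: bool = True,
    respect_softmask: bool = False,
) -> tuple[float, int, str]:
    """Best windowed log-odds score over a sequence.

    Returns ``(score, offset, strand)`` where ``offset`` is the 0-based
    start of the best window on the input sequence. Ties are broken by
    smallest offset, '+' strand first. Sequences with no valid window
    (too short, all-N, fully masked) return the sentinel score with
    offset -1.
    """
    if len(seq) == 0:
        warnings.warn("empty sequence: returning sentinel score", stacklevel=2)
        return sm.sentinel_score, -1, "+"
    codes = encode(seq)
    masked = softmask(seq) if respect_softmask else None
    fwd = window_scores(sm, codes, masked)
    best = -np.inf
    best_off, best_strand = -1, "+"
    if fwd.size and np.max(fwd) > -np.inf:
        i = int(np.argmax(fwd))
        best, best_off = float(fwd[i]), i
    if both_strands:
        # a site on the '-' strand is a forward-strand window matching the
        # reverse-complemented motif
        rc = ScoringMatrix(sm.motif_id, sm.scores[::-1, ::-1], sm.background,
                           sm.pseudocount)
        rev = window_scores(rc, codes, masked)
        if rev.size and np.max(rev) > best:
            i = int(np.argmax(rev))
            best, best_off, best_strand = float(rev[i]), i, "-"
    if best == -np.inf:
        return sm.sentinel_score, -1, "+"
    return best, best_off, best_strand


# ---------------------------------------------------------------------------
# exact score distribution


@dataclass
class ScoreDistribution:
    """Exact distribution of the per-window score under the background.

    ``tail[i]`` is P(score >= (min_bin + i) * granularity) for a random
    background word of the motif's length, computed by dynamic programming
    over positions with scores discretized to ``granularity``-width bins.
    """

    motif_id: str
    granularity: float
    min_bin: int
    tail: np.ndarray = field(repr=False)

    def pvalue_of_score(self, score: float) -> float:
        """P(window score >= ``score``) under the background model."""
        if not np.isfinite(score):
            return 1.0 if score < 0 else float(self.tail[-1])
        b = int(np.rint(score / self.granularity)) - self.min_bin
        if b <= 0:
            # every word with a finite score qualifies; -inf words do not
            return float(self.tail[0])
        if b >= self.tail.shape[0]:
            return 0.0
        return float(self.tail[b])

    def score_at_pvalue(self, p: float) -> float:
        """Smallest score whose tail probability is <= ``p``."""
        if not 0 < p <= 1:
            raise ValueError("p-value threshold must be in (0, 1]")
        idx = int(np.searchsorted(-self.tail, -p, side="left"))
        if idx >= self.tail.shape[0]:
            idx = self.tail.shape[0] - 1
        return (self.min_bin + idx) * self.granularity


def score_distribution(
    sm: ScoringMatrix, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact DP over positions for the null window-score distribution.

    Each position contributes its discretized score with the background
    probability of the corresponding base; the full distribution is the
    convolution across positions. -inf entries (possible at pseudocount 0)
    carry their probability mass to the bottom of the distribution: it is
    included in the tail at the minimum bin (which is therefore 1) but in
    no finite-score tail.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    finite = np.isfinite(sm.scores)
    bins = np.zeros_like(sm.scores, dtype=np.int64)
    bins[finite] = np.rint(sm.scores[finite] / granularity).astype(np.int64)
    # run the convolution in a shifting frame: track the current min bin
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(sm.length):
        row_bins = bins[i][finite[i]]
        row_p = sm.background[finite[i]]
        nlo = cur_lo + int(row_bins.min())
        nhi = cur_lo + cur.shape[0] - 1 + int(row_bins.max())
        nxt = np.zeros(nhi - nlo + 1)
        for b, p in zip(row_bins, row_p):
            off = cur_lo + int(b) - nlo
            nxt[off : off + cur.shape[0]] += p * cur
        cur, cur_lo = nxt, nlo
    # words hitting a -inf entry score -infinity: their mass sits strictly
    # below every finite bin, so it never enters a finite-score tail (the
    # tail at -inf itself is 1 by definition, handled in pvalue_of_score)
    neginf_mass = max(1.0 - cur.sum(), 0.0)
    tail = np.minimum(np.cumsum(cur[::-1])[::-1], 1.0).copy()
    if neginf_mass <= 1e-12:
        tail[0] = 1.0  # tail at the minimum achievable score is exactly 1
    # coarse granularity merges *distinct* per-position scores into one
    # bin; when that moves a sizeable share of score mass the tail
    # probabilities are no longer trustworthy
    merged_mass = 0.0
    for i in range(sm.length):
        row_bins = bins[i][finite[i]]
        row_scores = sm.scores[i][finite[i]]
        for b in np.unique(row_bins):
            sel = row_bins == b
            if sel.sum() > 1 and np.ptp(row_scores[sel]) > 0:
                merged_mass = max(merged_mass, float(sm.background[finite[i]][sel].sum()))
    if merged_mass > 0.05:
        warnings.warn(
            f"motif {sm.motif_id}: granularity {granularity} merges distinct "
            f"position scores carrying {merged_mass:.1%} probability mass",
            RuntimeWarning,
            stacklevel=2,
        )
    return ScoreDistribution(
        motif_id=sm.motif_id, granularity=granularity, min_bin=cur_lo, tail=tail
    )


# ---------------------------------------------------------------------------
# parsing / writing


def _normalize_rows(rows, motif_id, lineno):
    arr = np.asarray(rows, dtype=float)
    if np.any(arr.sum(axis=1) <= 0):
        raise MotifParseError(
            f"line {lineno}: motif {motif_id} has a position row summing to 0"
        )
    return arr


def parse_motifs(path, fmt: str = "meme_minimal") -> list[MotifMatrix]:
    """Parse a motif file. ``fmt`` is 'meme_minimal' or 'tabular_pfm'."""
    if fmt == "meme_minimal":
        return parse_meme_minimal(path)
    if fmt == "tabular_pfm":
        return parse_tabular_pfm(path)
    raise ValueError(f"unknown motif format: {fmt}")


def parse_meme_minimal(path) -> list[MotifMatrix]:
    """Read MEME minimal motif text (letter-probability blocks)."""
    motifs: list[MotifMatrix] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)
    seen: set[str] = set()
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"line {i+1}: MOTIF line without an id")
            mid = parts[1]
            gene = parts[2] if len(parts) > 2 else None
            if mid in seen:
                raise MotifParseError(f"line {i+1}: duplicate motif id {mid!r}")
            seen.add(mid)
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifParseError(
                        f"line {i+1}: motif {mid} has no letter-probability matrix"
                    )
                i += 1
            if i >= n:
                raise MotifParseError(f"motif {mid}: missing letter-probability block")
            header = lines[i].strip()
            width = None
            for tok in ("w=",):
                if tok in header:
                    try:
                        width = int(header.split(tok)[1].split()[0])
                    except (ValueError, IndexError):
                        raise MotifParseError(
                            f"line {i+1}: cannot parse width from {header!r}"
                        ) from None
            i += 1
            rows = []
            start_line = i + 1
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise MotifParseError(
                        f"line {i+1}: expected 4 probabilities, got {len(vals)}"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    raise MotifParseError(f"line {i+1}: non-numeric entry") from None
                i += 1
            if not rows:
                raise MotifParseError(f"line {start_line}: motif {mid} has no rows")
            if width is not None and len(rows) != width:
                raise MotifParseError(
                    f"motif {mid}: header says w={width} but block has {len(rows)} rows"
                )
            arr = _normalize_rows(rows, mid, start_line)
            motifs.append(
                MotifMatrix(id=mid, counts=arr / arr.sum(axis=1, keepdims=True),
                            gene_label=gene, source="chip_meme")
            )
        else:
            i += 1
    return motifs


def write_meme_minimal(motifs, path, background=None) -> None:
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{b} {p:.5f}" for b, p in zip(ALPHABET, bg)) + "\n\n")
    for m in motifs:
        header = f"MOTIF {m.id}"
        if m.gene_label:
            header += f" {m.gene_label}"
        buf.write(header + "\n")
        prob = m.probabilities
        buf.write(
            f"letter-probability matrix: alength= 4 w= {m.length} "
            f"nsites= 20 E= 0\n"
        )
        for row in prob:
            buf.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def parse_tabular_pfm(path) -> list[MotifMatrix]:
    """Read a simple tabular PFM file.

    Format: ``>id [gene_label]`` header lines followed by one row per
    position with 4 whitespace-separated numbers (A C G T).
    """
    motifs: list[MotifMatrix] = []
    seen: set[str] = set()
    cur_id, cur_gene, rows, start = None, None, [], 0

    def flush(lineno):
        if cur_id is None:
            return
        if not rows:
            raise MotifParseError(f"line {lineno}: motif {cur_id} has no rows")
        arr = _normalize_rows(rows, cur_id, start)
        motifs.append(
            MotifMatrix(id=cur_id, counts=arr / arr.sum(axis=1, keepdims=True),
                        gene_label=cur_gene, source="selex_compendium")
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split()
                if not parts:
                    raise MotifParseError(f"line {lineno}: empty motif header")
                cur_id = parts[0]
                if cur_id in seen:
                    raise MotifParseError(
                        f"line {lineno}: duplicate motif id {cur_id!r}"
                    )
                seen.add(cur_id)
                cur_gene = parts[1] if len(parts) > 1 else None
                rows, start = [], lineno + 1
            else:
                if cur_id is None:
                    raise MotifParseError(f"line {lineno}: data before any header")
                vals = line.split()
                if len(vals) != 4:
                    raise MotifParseError(
                        f"line {lineno}: expected 4 columns, got {len(vals)}"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    raise MotifParseError(f"line {lineno}: non-numeric entry") from None
        flush(lineno if "lineno" in locals() else 0)
    return motifs


def write_tabular_pfm(motifs, path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            header = f">{m.id}"
            if m.gene_label:
                header += f" {m.gene_label}"
            fh.write(header + "\n")
            for row in m.probabilities:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# similarity and clustering


def motif_similarity(a: MotifMatrix, b: MotifMatrix, min_overlap: int = 4) -> float:
    """Best Pearson correlation between aligned frequency columns.

    Maximized over ungapped offsets with at least ``min_overlap``
    overlapping columns and over both orientations of ``b``. Columns are
    flattened into a single vector before correlating, matching the common
    PFM-comparison convention.
    """
    pa = a.probabilities
    best = -np.inf
    for pb in (b.probabilities, b.reverse_complement().probabilities):
        la, lb = pa.shape[0], pb.shape[0]
        found = False
        for off in range(-(lb - min_overlap), la - min_overlap + 1):
            s_a, e_a = max(0, off), min(la, off + lb)
            if e_a - s_a < min_overlap:
                continue
            found = True
            xa = pa[s_a:e_a].ravel()
            xb = pb[s_a - off : e_a - off].ravel()
            da, db = xa - xa.mean(), xb - xb.mean()
            denom = np.sqrt((da * da).sum() * (db * db).sum())
            if denom == 0:
                continue
            best = max(best, float((da * db).sum() / denom))
        if not found:
            raise ValueError(
                f"motifs {a.id}/{b.id}: no offset achieves overlap >= {min_overlap}"
            )
    if best == -np.inf:
        raise ValueError(
            f"motifs {a.id}/{b.id}: all alignments degenerate (zero variance)"
        )
    return min(1.0, max(-1.0, best))


def similarity_matrix(motifs, min_overlap: int = 4) -> np.ndarray:
    n = len(motifs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = motif_similarity(
                motifs[i], motifs[j], min_overlap=min_overlap
            )
    return sim


@dataclass
class _TreeNode:
    height: float
    label: str | None = None
    children: tuple = ()

    def to_newick(self) -> str:
        return self._newick(self.height) + ";"

    def _newick(self, parent_height: float) -> str:
        bl = parent_height - self.height
        if not self.children:
            return f"{self.label}:{bl:.6g}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{bl:.6g}"


def upgma_cluster(dist: np.ndarray, labels=None) -> _TreeNode:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Returns the root of an ultrametric tree; node heights are half the
    linkage distances, leaves sit at height 0. Serialize with
    ``root.to_newick()``.
    """
    dist = np.asarray(dist, dtype=float)
    if np.any(np.isnan(dist)):
        raise ValueError("distance matrix contains NaN")
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(dist < 0) or np.any(np.diag(dist) != 0):
        raise ValueError("distances must be >= 0 with zero diagonal")
    n = dist.shape[0]
    if labels is None:
        labels = [f"L{i}" for i in range(n)]
    if n == 1:
        return _TreeNode(height=0.0, label=labels[0])
    Z = linkage(squareform(dist, checks=False), method="average")
    nodes = [_TreeNode(height=0.0, label=lab) for lab in labels]
    for a, b, d, _ in Z:
        nodes.append(
            _TreeNode(height=float(d) / 2.0, children=(nodes[int(a)], nodes[int(b)]))
        )
    return nodes[-1]
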