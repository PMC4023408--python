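"""The Motif Association Score (MAS).

For a motif M and a knockout target partition, every gene's proximal
promoter is scanned with M and the best log-odds score is kept. Two
one-sided Wilcoxon rank-sum tests then ask whether those best scores are
stochastically greater in the activated genes than in the non-target
genes (``p_act``) and likewise for the repressed genes (``p_rep``). The
two p-values are combined into a single signed score,

    MAS = -log10(min(p_act, p_rep)),  signed + if p_act <= p_rep else -,

so a large positive MAS marks a motif enriched in promoters of genes that
lose expression when the factor is knocked out (candidate activation) and
a large negative MAS marks enrichment on the repressed side. Because
neither p-value is adjusted for the number of motifs tested, MAS is a
ranking score, not a calibrated confidence measure; results carry the
motif count so users can apply their own correction.

The model/results split follows the usual statsmodels convention:
:class:`MotifAssociation` holds the data (a promoter score table and a
target classification); ``fit()`` returns :class:`MASResults` with the
per-motif table, ranks and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import (
    ScoringMatrix,
    encode,
    estimate_background,
    make_scoring_matrix,
    softmask,
)

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # clamp to avoid infinite MAS from approximation underflow


@dataclass
class PromoterScoreTable:
    """Best promoter score per (motif, gene), plus scan metadata.

    ``scores`` is a genes x motifs DataFrame (index gene_id, columns
    motif_id). Genes whose promoter had no scorable window hold the
    motif's sentinel score — one granularity step below the minimum
    achievable score — so they rank strictly last.
    """

    scores: pd.DataFrame
    flank: int
    background: np.ndarray
    pseudocount: float
    both_strands: bool = True
    sentinels: dict[str, float] = field(default_factory=dict)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, flank: int = 1000, background=None,
                 pseudocount: float = 0.1) -> "PromoterScoreTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        df.index = df.index.astype(str)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(scores=df, flank=flank, background=bg, pseudocount=pseudocount)


def _batched_best_scores(
    matrices: list[ScoringMatrix],
    seqs: list[str],
    both_strands: bool,
    respect_softmask: bool,
    batch_size: int = 256,
) -> np.ndarray:
    """Best score per (sequence, motif), vectorized.

    One-hot encodes sequence batches and reduces all motifs of equal
    length with a single matrix product per batch; this is what makes
    compendium-scale scans (hundreds of motifs x 10^4 promoters)
    practical. Must agree exactly with `motifs.best_site_score` — tested.
    """
    n, m = len(seqs), len(matrices)
    out = np.full((n, m), np.nan)
    # kernels grouped by motif length; '-' strand scored as the
    # reverse-complemented kernel on the forward sequence
    by_len: dict[int, list[tuple[int, np.ndarray]]] = {}
    for j, sm in enumerate(matrices):
        ker = [sm.scores]
        if both_strands:
            ker.append(sm.scores[::-1, ::-1])
        for K in ker:
            by_len.setdefault(sm.length, []).append((j, np.asarray(K)))

    maxlen = max(len(s) for s in seqs) if seqs else 0
    for lo in range(0, n, batch_size):
        chunk = seqs[lo : lo + batch_size]
        B = len(chunk)
        codes = np.full((B, maxlen), 4, dtype=np.int8)
        for i, s in enumerate(chunk):
            codes[i, : len(s)] = encode(s)
            if respect_softmask:
                codes[i, : len(s)][softmask(s)] = 4
        onehot = (codes[..., None] == np.arange(4, dtype=np.int8)).astype(np.float32)
        invalid = (codes >= 4).astype(np.float32)
        for L, kernels in by_len.items():
            if maxlen < L:
                continue
            W = maxlen - L + 1
            sw = np.lib.stride_tricks.sliding_window_view(onehot, L, axis=1)
            # sw: (B, W, 4, L) -> (B*W, 4L); kernel (L,4) flattens as (a,l)->a*L+l
            X = np.ascontiguousarray(sw).reshape(B * W, 4 * L)
            Kmat = np.stack(
                [K.T.astype(np.float32).reshape(-1) for _, K in kernels], axis=1
            )
            vals = (X @ Kmat).reshape(B, W, len(kernels))
            # windows touching an N/masked base are invalid
            bad = (
                np.lib.stride_tricks.sliding_window_view(invalid, L, axis=1).sum(
                    axis=2
                )
                > 0
            )
            vals[bad] = -np.inf
            best = vals.max(axis=1)  # (B, n_kernels)
            for c, (j, _) in enumerate(kernels):
                col = best[:, c].astype(float)
                cur = out[lo : lo + B, j]
                out[lo : lo + B, j] = np.where(
                    np.isnan(cur), col, np.maximum(cur, col)
                )
    # sequences with no valid window anywhere -> sentinel
    for j, sm in enumerate(matrices):
        col = out[:, j]
        col[~np.isfinite(col)] = sm.sentinel_score
        out[:, j] = col
    return out


def scan_promoters(
    motifs,
    promoters,
    background="promoters",
    pseudocount: float = 0.1,
    both_strands: bool = True,
    respect_softmask: bool = False,
) -> PromoterScoreTable:
    """Scan every promoter with every motif, keeping the best site score.

    ``motifs`` may be MotifMatrix or ScoringMatrix objects. ``background``
    is either the string ``'promoters'`` (0-order model estimated from the
    scanned sequences, the default), ``'uniform'``, or an explicit
    4-vector. The result feeds :class:`MotifAssociation`.
    """
    seq_map = promoters.sequences if hasattr(promoters, "sequences") else promoters
    gene_ids = list(seq_map.keys())
    seqs = [seq_map[g] for g in gene_ids]
    if not seqs:
        raise ValueError("no promoter sequences to scan")
    if isinstance(background, str):
        if background == "uniform":
            bg = np.full(4, 0.25)
        elif background == "promoters":
            bg = estimate_background(seqs)
        else:
            raise ValueError(f"unknown background option: {background!r}")
    else:
        bg = np.asarray(background, dtype=float)
    matrices = [
        m if isinstance(m, ScoringMatrix) else make_scoring_matrix(m, bg, pseudocount)
        for m in motifs
    ]
    vals = _batched_best_scores(matrices, seqs, both_strands, respect_softmask)
    df = pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[sm.motif_id for sm in matrices])
    flank = getattr(promoters, "flank", max(len(s) for s in seqs) // 2)
    return PromoterScoreTable(
        scores=df,
        flank=flank,
        background=bg,
        pseudocount=pseudocount,
        both_strands=both_strands,
        sentinels={sm.motif_id: sm.sentinel_score for sm in matrices},
    )


def rank_sum_test(x, y, alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum p-value that ``x`` is stochastically greater.

    Uses the exact distribution when the pooled sample is small (<= 20)
    and tie-free, otherwise the normal approximation with tie correction
    and a 0.5 continuity correction. The p-value is clamped to
    [1e-300, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # fully tied samples carry no ordering evidence; the one-sided
        # mid-p is 1/2 (the normal approximation's sd degenerates to 0)
        return 0.5
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(np.clip(res.pvalue, P_FLOOR, 1.0))


def compute_mas(p_act: float, p_rep: float) -> float:
    """Signed MAS from the two enrichment p-values.

    Magnitude -log10(min(p_act, p_rep)); positive iff p_act <= p_rep
    (ties go to the activated side).
    """
    if not (0 < p_act <= 1) or not (0 < p_rep <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    s = -np.log10(min(p_act, p_rep))
    return float(s if p_act <= p_rep else -s)


@dataclass
class MasResult:
    """Per-motif outcome: the two enrichment p-values and the signed MAS."""

    motif_id: str
    gene_label: str | None
    p_act: float
    p_rep: float
    mas: float
    n_act: int
    n_rep: int
    n_non: int
    flag: str = "ok"


class MotifAssociation:
    """Rank-sum association between promoter motif scores and KO targets.

    Parameters
    ----------
    score_table : PromoterScoreTable
        Best promoter score per (motif, gene).
    classification : TargetClassification or CommonTargets
        Activated / repressed / non-target gene partition. Its universe
        must be contained in the score table's gene set. For the
        two-knockout analysis pass the intersection partition from
        :func:`motifassoc.expression.intersect_classifications`; the
        computation is identical.
    include_unscored : bool
        Keep genes whose promoter produced only the sentinel score (they
        rank last). Set False to drop them from the tests.
    gene_labels : mapping motif_id -> gene symbol, optional.
    """

    def __init__(self, score_table, classification, include_unscored: bool = True,
                 gene_labels=None):
        self.score_table = score_table
        self.classification = classification
        self.include_unscored = include_unscored
        self.gene_labels = dict(gene_labels or {})
        universe = classification.universe
        missing = universe - set(score_table.gene_ids)
        if missing:
            raise ValueError(
                f"{len(missing)} classified genes lack promoter scores, e.g. "
                + ", ".join(sorted(missing)[:5])
            )

    @classmethod
    def from_promoters(cls, motifs, promoters, classification, **scan_kwargs):
        """Scan promoters and build the model in one step."""
        table = scan_promoters(motifs, promoters, **scan_kwargs)
        labels = {
            m.id: m.gene_label for m in motifs if getattr(m, "gene_label", None)
        }
        return cls(table, classification, gene_labels=labels)

    def fit(self) -> "MASResults":
        cls = self.classification
        act = sorted(cls.activated)
        rep = sorted(cls.repressed)
        non = sorted(cls.non_target)
        results = []
        for motif_id in self.score_table.motif_ids:
            col = self.score_table.scores[motif_id]
            sa = col.loc[act].to_numpy(dtype=float)
            sr = col.loc[rep].to_numpy(dtype=float)
            sn = col.loc[non].to_numpy(dtype=float)
            if not self.include_unscored:
                sentinel = self.score_table.sentinels.get(motif_id, -np.inf)
                sa = sa[sa > sentinel]
                sr = sr[sr > sentinel]
                sn = sn[sn > sentinel]
            flag = "ok"
            if sa.size and sn.size:
                p_act = rank_sum_test(sa, sn)
            else:
                p_act, flag = 1.0, "empty_activated"
            if sr.size and sn.size:
                p_rep = rank_sum_test(sr, sn)
            else:
                p_rep = 1.0
                flag = "empty_repressed" if flag == "ok" else flag + "+empty_repressed"
            pooled = np.concatenate([sa, sr, sn])
            if pooled.size and np.ptp(pooled) == 0:
                flag = "constant_scores"
            results.append(
                MasResult(
                    motif_id=motif_id,
                    gene_label=self.gene_labels.get(motif_id),
                    p_act=p_act,
                    p_rep=p_rep,
                    mas=compute_mas(p_act, p_rep),
                    n_act=int(sa.size),
                    n_rep=int(sr.size),
                    n_non=int(sn.size),
                    flag=flag,
                )
            )
        results.sort(key=lambda r: (-r.mas, r.motif_id))
        return MASResults(self, results)


class MASResults:
    """Fitted MAS table, ranked by descending score."""

    def __init__(self, model: MotifAssociation, results: list[MasResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.results) + 1),
                "motif_id": [r.motif_id for r in self.results],
                "gene_label": [r.gene_label for r in self.results],
                "p_act": [r.p_act for r in self.results],
                "p_rep": [r.p_rep for r in self.results],
                "mas": [r.mas for r in self.results],
                "n_act": [r.n_act for r in self.results],
                "n_rep": [r.n_rep for r in self.results],
                "n_non": [r.n_non for r in self.results],
                "flag": [r.flag for r in self.results],
            }
        )
        return df

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def motif(self, motif_id: str) -> MasResult:
        for r in self.results:
            if r.motif_id == motif_id:
                return r
        raise KeyError(motif_id)

    def top(self, k: int = 10) -> list[dict]:
        return self.frame.head(k).to_dict(orient="records")

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        df = self.frame
        lines = [
            "Motif Association Score results",
            "=" * 64,
            f"motifs tested: {len(df)}   (p-values unadjusted; apply your own "
            "multiple-testing correction across this count)",
            f"gene sets: activated={df['n_act'].iloc[0] if len(df) else 0}, "
            f"repressed={df['n_rep'].iloc[0] if len(df) else 0}, "
            f"non-target={df['n_non'].iloc[0] if len(df) else 0}",
            "-" * 64,
        ]
        show = df.head(20)[["rank", "motif_id", "gene_label", "p_act", "p_rep", "mas"]]
        lines.append(show.to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))
        if len(df) > 20:
            lines.append(f"... ({len(df) - 20} more)")
        return "\n".join(lines)

    def plot_histogram(self, ax=None, highlight=(), bins=40):
        """Histogram of the MAS values, optionally marking named motifs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.frame["mas"].to_numpy()
        ax.hist(vals, bins=bins, color="0.6")
        for mid in highlight:
            ax.axvline(self.motif(mid).mas, color="tab:red", lw=1)
            ax.annotate(mid, (self.motif(mid).mas, ax.get_ylim()[1] * 0.9),
                        rotation=90, fontsize=8, ha="right")
        ax.set_xlabel("MAS")
        ax.set_ylabel("motifs")
        return ax
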