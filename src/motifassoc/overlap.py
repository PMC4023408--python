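"""Hypergeometric overlap between two knockouts' target sets.

If two gene sets A and B are drawn independently and without replacement
from a universe C, the size z of their intersection is hypergeometric
with parameters m=|A|, n=|C|-|A|, k=|B|. The enrichment p-value is the
upper tail P(Z >= z); the expected overlap is m*k/(n+m) and the fold
enrichment is z over that expectation. The universe used here is the set
of genes with expression data in *both* studies — the expectation and
fold depend directly on |C|, so it is carried in the result and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Observed/expected overlap of two gene sets with the tail p-value."""

    m: int  # |A|
    k: int  # |B|
    n: int  # |C| - |A|
    z: int  # observed |A & B|
    expected: float
    fold: float
    p_tail: float
    label: str = ""

    @property
    def universe_size(self) -> int:
        return self.n + self.m

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self) | {"universe_size": self.universe_size},
                       indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def summary(self) -> str:
        return (
            f"Overlap {self.label or '(A,B)'}: |A|={self.m}, |B|={self.k}, "
            f"|C|={self.universe_size}\n"
            f"  observed overlap  {self.z}\n"
            f"  expected overlap  {self.expected:.1f}\n"
            f"  fold enrichment   {self.fold:.1f}\n"
            f"  P(Z >= z)         {self.p_tail:.3g}"
        )


def hypergeom_overlap(set_a, set_b, universe, label: str = "") -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    The survival function is evaluated through log-gamma based binomial
    coefficients (scipy's hypergeometric distribution), so universes of
    10^4 genes do not underflow.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    stray = (set_a | set_b) - universe
    if stray:
        raise ValueError(
            "sets are not subsets of the universe; offenders include "
            + ", ".join(sorted(stray)[:10])
        )
    m, k, C = len(set_a), len(set_b), len(universe)
    n = C - m
    z = len(set_a & set_b)
    expected = m * k / (n + m) if (n + m) > 0 else 0.0
    fold = z / expected if expected > 0 else float("inf") if z else 1.0
    # P(Z >= z); sf(z-1) under Hypergeometric(M=C, n=m, N=k)
    p_tail = float(stats.hypergeom.sf(z - 1, C, m, k)) if C > 0 else 1.0
    p_tail = min(max(p_tail, 5e-324), 1.0)
    result = OverlapResult(
        m=m, k=k, n=n, z=z, expected=expected, fold=fold, p_tail=p_tail,
        label=label,
    )
    logger.info("hypergeom_overlap %s: |C|=%d z=%d expected=%.2f fold=%.2f p=%.3g",
                label, C, z, expected, fold, p_tail)
    return result


def concordance(shared_log2fc: pd.DataFrame | np.ndarray):
    """Sign agreement and Pearson correlation of paired log2 fold changes.

    ``shared_log2fc`` holds one row per shared gene with the two studies'
    log2fc values in the first two columns. Pairs where either value is
    exactly 0 are excluded from the sign counts (and reported). Returns
    ``(n_same_sign, n_opposite, pearson_r, n_zero)``; r is NaN (flagged
    via logging) with fewer than 2 pairs.
    """
    arr = np.asarray(shared_log2fc, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("expected pairs of log2 fold changes")
    a, b = arr[:, 0], arr[:, 1]
    nonzero = (a != 0) & (b != 0)
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("concordance: excluded %d pairs with a zero log2fc", n_zero)
    same = int(np.sum(np.sign(a[nonzero]) == np.sign(b[nonzero])))
    opposite = int(nonzero.sum()) - same
    if arr.shape[0] >= 2:
        r = float(np.corrcoef(a, b)[0, 1])
    else:
        logger.warning("concordance: fewer than 2 pairs, r undefined")
        r = float("nan")
    return same, opposite, r, n_zero


def shared_target_table(
    a_records: pd.DataFrame, b_records: pd.DataFrame, genes
) -> pd.DataFrame:
    """Two-column log2fc table for a set of shared target genes."""
    a = a_records.set_index("gene_id")["log2fc"]
    b = b_records.set_index("gene_id")["log2fc"]
    genes = sorted(genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc_a": a.reindex(genes).to_numpy(dtype=float),
            "log2fc_b": b.reindex(genes).to_numpy(dtype=float),
        }
    )
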