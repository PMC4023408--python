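"""Knockout differential-expression tables and target classification.

The primary ingestion path is a per-probe TSV with columns
``probe_id, gene_id, log2fc, p`` (optionally ``q``), where ``log2fc`` is
log2(KO/WT). Probes are collapsed to one record per gene (the most
significant probe), p-values are Benjamini-Hochberg adjusted, and genes
are partitioned into three disjoint sets:

* activated   -- KO/WT <= 0.5 (log2fc <= -1) and q <= 0.05
* repressed   -- KO/WT >= 2   (log2fc >= +1) and q <= 0.05
* non-target  -- every other gene with expression data

"Activated"/"repressed" name the inferred effect of the knocked-out
factor, so genes *down* in the KO are the factor-*activated* set. For
synthetic replicate matrices a pooled-variance t-test stands in for the
microarray model fit; real studies supply precomputed (log2fc, p) tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["probe_id", "gene_id", "log2fc", "p"]


@dataclass
class TargetClassification:
    """Disjoint activated/repressed/non-target partition for one knockout."""

    ko_label: str
    activated: set[str]
    repressed: set[str]
    non_target: set[str]
    fc_threshold: float = 2.0
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if (
            self.activated & self.repressed
            or self.activated & self.non_target
            or self.repressed & self.non_target
        ):
            raise ValueError("target sets must be pairwise disjoint")

    @property
    def universe(self) -> set[str]:
        return self.activated | self.repressed | self.non_target

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "activated") for g in sorted(self.activated)]
        rows += [(g, "repressed") for g in sorted(self.repressed)]
        rows += [(g, "non_target") for g in sorted(self.non_target)]
        return pd.DataFrame(rows, columns=["gene_id", "set"])


@dataclass
class CommonTargets:
    """Intersection of two knockouts' classifications on the shared universe."""

    label: str
    activated: set[str]
    repressed: set[str]
    non_target: set[str]

    @property
    def universe(self) -> set[str]:
        return self.activated | self.repressed | self.non_target


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def two_group_diff(
    log2_matrix: pd.DataFrame,
    groups,
    probe_genes: pd.Series | None = None,
    variance: str = "per_probe",
) -> pd.DataFrame:
    """Per-probe differential expression between two sample groups.

    ``log2_matrix`` is probes x samples of log2 intensities; ``groups`` is
    a label per sample with exactly two levels, the first-appearing level
    taken as KO (so log2fc = mean(KO) - mean(WT) = log2(KO/WT) when the
    second level is WT). With ``variance='per_probe'`` p-values come from
    the classic two-sided pooled-variance t-test within each probe.

    ``variance='common'`` instead estimates a single residual variance
    shared by all probes (the average within-group variance across the
    whole matrix) and refers the statistic to the normal distribution.
    This is the appropriate test when replicate noise is homoscedastic
    across probes — true by construction for the synthetic studies in
    :mod:`motifassoc.simulate` — and stands in for the variance-moderated
    fits used on real arrays, which borrow strength across probes in the
    same spirit. With 3-vs-3 designs the per-probe test has only 4
    degrees of freedom and essentially no power after FDR control at
    10^4 genes.

    Probes with zero variance in both groups get p = 1 and
    ``flag='degenerate'``.
    """
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    a = log2_matrix.loc[:, groups == levels[0]].to_numpy(dtype=float)
    b = log2_matrix.loc[:, groups == levels[1]].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if variance == "per_probe":
        import warnings as _warnings

        with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
            # degenerate zero-variance probes are flagged below, not warned
            _warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    elif variance == "common":
        pooled = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / (
            na + nb - 2
        )
        s2 = pooled.mean()
        if s2 <= 0:
            p = np.ones_like(log2fc)
        else:
            z = log2fc / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
            p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown variance mode: {variance!r}")
    p = np.where(degenerate, 1.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.nextafter(0, 1), 1.0)
    out = pd.DataFrame(
        {
            "probe_id": log2_matrix.index.astype(str),
            "gene_id": (
                probe_genes.reindex(log2_matrix.index).astype(str).to_numpy()
                if probe_genes is not None
                else log2_matrix.index.astype(str)
            ),
            "log2fc": log2fc,
            "p": p,
            "flag": np.where(degenerate, "degenerate", "ok"),
        }
    )
    return out.reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def collapse_probes(records: pd.DataFrame) -> pd.DataFrame:
    """Keep the most significant probe per gene.

    Order of precedence: smallest p, then largest |log2fc|, then
    lexicographically smallest probe_id.
    """
    df = records.copy()
    df["_abs_fc"] = -df["log2fc"].abs()
    df = df.sort_values(["gene_id", "p", "_abs_fc", "probe_id"], kind="mergesort")
    out = df.groupby("gene_id", sort=True).head(1).drop(columns="_abs_fc")
    return out.reset_index(drop=True)


def classify_targets(
    gene_records: pd.DataFrame,
    ko_label: str = "KO",
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> TargetClassification:
    """Partition gene-level records into activated/repressed/non-target.

    Thresholds are inclusive ("at least" ``fc_threshold``-fold change):
    activated iff log2fc <= -log2(fc_threshold) and q <= q_threshold,
    repressed iff log2fc >= +log2(fc_threshold) and q <= q_threshold.
    ``gene_records`` must be collapsed to one row per gene; a ``q`` column
    is filled via :func:`bh_adjust` if absent.
    """
    df = gene_records.copy()
    if df["gene_id"].duplicated().any():
        raise ValueError("records must be collapsed to one row per gene")
    if "q" not in df.columns:
        df["q"] = bh_adjust(df["p"].to_numpy())
    lfc_cut = np.log2(fc_threshold)
    sig = df["q"] <= q_threshold
    act = set(df.loc[sig & (df["log2fc"] <= -lfc_cut), "gene_id"])
    rep = set(df.loc[sig & (df["log2fc"] >= lfc_cut), "gene_id"])
    non = set(df["gene_id"]) - act - rep
    return TargetClassification(
        ko_label=ko_label,
        activated=act,
        repressed=rep,
        non_target=non,
        fc_threshold=fc_threshold,
        q_threshold=q_threshold,
    )


def intersect_classifications(
    a: TargetClassification, b: TargetClassification
) -> CommonTargets:
    """Common activated / repressed / non-target sets of two knockouts.

    All sets are restricted to genes with expression data in both studies;
    the common non-target set is the intersection of the two non-target
    sets. The intersection universe size is logged because downstream
    overlap statistics depend on it.
    """
    shared = a.universe & b.universe
    if not shared:
        raise ValueError("classifications have disjoint gene universes")
    common = CommonTargets(
        label=f"{a.ko_label}&{b.ko_label}",
        activated=a.activated & b.activated & shared,
        repressed=a.repressed & b.repressed & shared,
        non_target=a.non_target & b.non_target & shared,
    )
    logger.info(
        "common targets %s: |universe|=%d, activated=%d, repressed=%d, "
        "common non-target=%d",
        common.label,
        len(shared),
        len(common.activated),
        len(common.repressed),
        len(common.non_target),
    )
    return common


def rank_genes_max_fc(
    a_records: pd.DataFrame, b_records: pd.DataFrame
) -> pd.DataFrame:
    """Rank genes by likeliness of being down-regulated in both knockouts.

    The sorting key is the *maximum* of the two fold changes on the ratio
    scale (KO/WT = 2**log2fc), ascending, so a gene strongly down in both
    studies sorts first. Genes missing from either table are excluded and
    logged; ties are broken by gene id for a stable output. The single
    ordered gene column is directly usable as a ranked-list input to GO
    enrichment tools.
    """
    a = a_records.set_index("gene_id")["log2fc"].dropna()
    b = b_records.set_index("gene_id")["log2fc"].dropna()
    shared = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(shared)
    if dropped:
        logger.info("rank_genes_max_fc: excluded %d genes missing from one table",
                    dropped)
    key = np.maximum(
        np.power(2.0, a.loc[shared].to_numpy(dtype=float)),
        np.power(2.0, b.loc[shared].to_numpy(dtype=float)),
    )
    out = pd.DataFrame({"gene_id": shared.astype(str), "max_fc": key})
    out = out.sort_values(["max_fc", "gene_id"], kind="mergesort")
    return out.reset_index(drop=True)
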