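"""Expression integration and binary motif-presence clustering.

Expression comes in as gene x sample RPKM matrices with tumor/normal group
labels.  Fold change is log2 of the ratio of group means; transcription
factors behind enriched motifs are filtered by a BH-corrected two-sample
test with a required direction of change (loss of expression for TFs whose
motifs are enriched in hypermethylated enhancers, gain for hypomethylated
ones).  Motif presence/absence across DMRs is clustered column-wise with
complete-linkage hierarchical clustering on Euclidean distances and the tree
cut at a configured height; groups with more than one TF are clusters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeResult:
    gene: str
    mean_tumor: float
    mean_normal: float
    log2_fold_change: Optional[float]  # None when undefined (zero/missing mean)


def _group_columns(expr: pd.DataFrame, groups: Mapping[str, str]) -> Tuple[List[str], List[str]]:
    tumor = [s for s in expr.columns if groups.get(s) == "tumor"]
    normal = [s for s in expr.columns if groups.get(s) == "normal"]
    if not tumor or not normal:
        raise ValueError("both tumor and normal sample groups must be present")
    return tumor, normal


def fold_change(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    genes: Sequence[str],
) -> Tuple[List[FoldChangeResult], List[str]]:
    """Per-gene log2(mean tumor RPKM / mean normal RPKM).

    Returns (results, genes with no expression data).  Zero or missing
    denominators yield an undefined (None) fold change, reported as such.
    """
    tumor, normal = _group_columns(expr, groups)
    out: List[FoldChangeResult] = []
    missing: List[str] = []
    for g in genes:
        if g not in expr.index:
            missing.append(g)
            continue
        mt = float(expr.loc[g, tumor].mean())
        mn = float(expr.loc[g, normal].mean())
        fc = math.log2(mt / mn) if mt > 0 and mn > 0 else None
        out.append(FoldChangeResult(g, mt, mn, fc))
    if missing:
        logger.info("%d genes without expression data", len(missing))
    return out, missing


def normalize_tf_expression(
    expr: pd.DataFrame,
    tf_list: Sequence[str],
    min_rpkm: float = 1.0,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per TF: drop samples with RPKM <= min_rpkm, log2, z-score the rest.

    Genes with fewer than two retained samples or zero variance are skipped
    (z-score undefined).  Returns a TF x sample frame with NaN where a sample
    was dropped.
    """
    rows = {}
    for g in tf_list:
        if g not in expr.index:
            logger.info("TF %s has no expression rows; skipped", g)
            continue
        vals = expr.loc[g].astype(float)
        kept = vals[vals > min_rpkm]
        if len(kept) < 2:
            logger.info("TF %s: <2 samples above %.3g RPKM; skipped", g, min_rpkm)
            continue
        logged = np.log2(kept)
        sd = logged.std(ddof=ddof)
        if sd == 0:
            logger.info("TF %s: constant expression; skipped", g)
            continue
        z = (logged - logged.mean()) / sd
        rows[g] = z.reindex(expr.columns)
    return pd.DataFrame(rows).T.reindex(columns=expr.columns)


def bh_retain(p_values: Sequence[float], alpha: float = 0.05) -> List[bool]:
    """Benjamini-Hochberg step-up retention at level alpha."""
    return list(multipletests(p_values, alpha=alpha, method="fdr_bh")[0])


def tf_expression_filter(
    tf_to_motifs: Mapping[str, Sequence[str]],
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    direction: str,
    alpha: float = 0.05,
    equal_var: bool = False,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Retain TFs whose expression changes significantly in the required
    direction (loss: tumor < normal; gain: tumor > normal).

    Two-sample t-test (Welch by default) per TF, BH adjustment across all
    tested TFs, retained iff adjusted p <= alpha and the group-mean
    difference has the required sign.
    """
    if direction not in ("loss", "gain"):
        raise ValueError("direction must be 'loss' or 'gain'")
    tumor, normal = _group_columns(expr, groups)
    rows = []
    for tf in sorted(tf_to_motifs):
        if tf not in expr.index:
            logger.info("TF %s without expression rows; dropped", tf)
            continue
        t_vals = expr.loc[tf, tumor].to_numpy(dtype=float)
        n_vals = expr.loc[tf, normal].to_numpy(dtype=float)
        if log_transform:
            t_vals, n_vals = np.log2(t_vals + 1), np.log2(n_vals + 1)
        res = sps.ttest_ind(t_vals, n_vals, equal_var=equal_var)
        rows.append(
            {
                "tf": tf,
                "motifs": ",".join(tf_to_motifs[tf]),
                "mean_tumor": float(np.mean(t_vals)),
                "mean_normal": float(np.mean(n_vals)),
                "p": float(res.pvalue) if not math.isnan(res.pvalue) else 1.0,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[], retained=[])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    diff = df["mean_tumor"] - df["mean_normal"]
    sign_ok = diff < 0 if direction == "loss" else diff > 0
    df["retained"] = (df["q"] <= alpha) & sign_ok
    return df


def filter_enriched_motifs(
    motifs: pd.DataFrame,
    q_max: float = 0.05,
    min_fraction: float = 0.0,
) -> pd.DataFrame:
    """Keep motif rows with q <= q_max and target fraction >= min_fraction
    (both boundaries inclusive).  Expects columns 'motif', 'q', 'fraction'."""
    for thr in (q_max, min_fraction):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    needed = {"motif", "q", "fraction"}
    if motifs.empty:
        return motifs
    if not needed <= set(motifs.columns):
        raise ValueError(f"motif table needs columns {sorted(needed)}")
    return motifs[(motifs["q"] <= q_max) & (motifs["fraction"] >= min_fraction)].copy()


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    cut_height: float
    clusters: Dict[int, List[str]]        # cluster id -> TF list (>1 TF only)
    cluster_dmrs: Dict[int, List[str]]    # cluster id -> DMRs with >= 1 member hit
    singletons: List[str]


def cluster_motif_matrix(matrix: pd.DataFrame, cut_height: float) -> ClusterResult:
    """Complete-linkage clustering of TF columns of a binary DMR x TF matrix.

    Euclidean distance between binary column vectors; the dendrogram is cut
    at ``cut_height`` (clusters = groups whose internal merge heights are all
    <= cut_height); groups with > 1 TF are reported as clusters, each with
    the DMR rows carrying >= 1 hit for any member TF.
    """
    if cut_height <= 0:
        raise ValueError("cut height must be positive")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two TF columns")
    vals = matrix.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("motif hit matrix must be binary")
    z = linkage(vals.T, method="complete", metric="euclidean")
    labels = fcluster(z, t=cut_height, criterion="distance")
    clusters: Dict[int, List[str]] = {}
    for tf, lab in zip(matrix.columns, labels):
        clusters.setdefault(int(lab), []).append(str(tf))
    multi = {cid: tfs for cid, tfs in clusters.items() if len(tfs) > 1}
    singles = [tfs[0] for tfs in clusters.values() if len(tfs) == 1]
    cluster_dmrs = {
        cid: list(matrix.index[(matrix[tfs].sum(axis=1) > 0)].astype(str))
        for cid, tfs in multi.items()
    }
    return ClusterResult(
        linkage_matrix=z,
        cut_height=cut_height,
        clusters=multi,
        cluster_dmrs=cluster_dmrs,
        singletons=singles,
    )
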