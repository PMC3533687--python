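"""Expression time-course analysis.

Covers transcriptome-complexity banding, time-course clustering of
standardized per-gene profiles (average linkage on correlation distance),
repeat-consensus expression fractions, and methylation–expression
association during the de novo remethylation phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .errors import ConfigurationError


@dataclass
class ProfileCluster:
    """A set of genes sharing an expression profile across the stage order."""

    cluster_id: int
    members: tuple[str, ...]
    mean_profile: pd.Series
    dispersion: pd.Series

    @property
    def size(self) -> int:
        return len(self.members)

    def peak_stage(self) -> str:
        """Stage (sample key) of the profile maximum; ties take the earliest."""
        return str(self.mean_profile.idxmax())


def complexity_profile(matrix: pd.DataFrame, band_edges=(0.0, 1.0, 2.0)) -> pd.DataFrame:
    """Counts of genes per log10-expression band, per sample.

    Bands over log10(expression) for expressed genes: (−inf, e0], (e0, e1],
    …, (e_last, inf); zero-expression genes go to a separate "silent" band.
    """
    edges = np.asarray(list(band_edges), dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ConfigurationError("band edges must be strictly increasing")
    labels = (
        ["silent"]
        + [f"<= {edges[0]:g}"]
        + [f"({edges[i]:g}, {edges[i+1]:g}]" for i in range(len(edges) - 1)]
        + [f"> {edges[-1]:g}"]
    )
    out = {}
    for sid in matrix.columns:
        vals = matrix[sid].to_numpy(dtype=float)
        silent = vals == 0
        logs = np.log10(vals[~silent])
        idx = np.searchsorted(edges, logs, side="left")
        band_counts = np.bincount(idx, minlength=len(edges) + 1)
        out[sid] = np.concatenate([[silent.sum()], band_counts])
    return pd.DataFrame(out, index=pd.Index(labels, name="band"))


def standardize_profiles(matrix: pd.DataFrame):
    """Per-gene zero-mean, unit-variance profiles; constant genes excluded.

    Returns (standardized DataFrame, excluded gene index).
    """
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    z = (vals[~constant] - mean[~constant]) / sd[~constant]
    return (
        pd.DataFrame(z, index=matrix.index[~constant], columns=matrix.columns),
        matrix.index[constant],
    )


def cluster_profiles(
    matrix: pd.DataFrame,
    min_cluster_size: int = 2,
    similarity_threshold: float = 0.8,
) -> tuple[list[ProfileCluster], pd.Index]:
    """Average-linkage clustering of standardized profiles.

    Correlation distance (1 − r) between per-gene standardized profiles,
    average linkage, tree cut at distance 1 − ``similarity_threshold``;
    clusters smaller than ``min_cluster_size`` are discarded.  Genes are
    sorted by id before clustering so the outcome is independent of input
    order (ties break toward the lowest gene id).  Returns (clusters,
    excluded constant genes).
    """
    if matrix.shape[1] < 2:
        raise ConfigurationError("need at least two stages to cluster")
    z, excluded = standardize_profiles(matrix.sort_index())
    clusters: list[ProfileCluster] = []
    if len(z) >= 2:
        dist = pdist(z.to_numpy(), metric="correlation")
        tree = linkage(dist, method="average")
        assignment = fcluster(tree, t=1.0 - similarity_threshold, criterion="distance")
        for cid in np.unique(assignment):
            members = z.index[assignment == cid]
            if len(members) < min_cluster_size:
                continue
            sub = matrix.loc[members]
            clusters.append(
                ProfileCluster(
                    cluster_id=int(cid),
                    members=tuple(members),
                    mean_profile=sub.mean(axis=0),
                    dispersion=sub.std(axis=0, ddof=0),
                )
            )
    clusters.sort(key=lambda c: (-c.size, c.members[0]))
    for rank, c in enumerate(clusters, start=1):
        c.cluster_id = rank
    return clusters, excluded


def cluster_trajectory_summary(cluster: ProfileCluster, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-stage mean ± standard deviation of member profiles, with peak stage."""
    if cluster.size == 0:
        raise ConfigurationError("cluster has no members")
    sub = matrix.loc[list(cluster.members)]
    out = pd.DataFrame(
        {"mean": sub.mean(axis=0), "sd": sub.std(axis=0, ddof=0)}
    )
    out.attrs["peak_stage"] = str(out["mean"].idxmax())
    return out


def repeat_expression_fraction(
    read_counts: pd.DataFrame,
    totals: pd.Series,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Percentage of all reads mapping to each consensus target, per sample.

    ``read_counts`` is targets × samples; ``totals`` the total read count
    per sample.  Comparator single-copy genes ride along as extra rows.
    """
    totals = totals.reindex(read_counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ConfigurationError("every sample needs a positive total read count")
    if targets is not None:
        missing = set(targets) - set(read_counts.index)
        if missing:
            raise ConfigurationError(f"unknown targets: {sorted(missing)}")
        read_counts = read_counts.loc[list(targets)]
    return 100.0 * read_counts.div(totals, axis=1)


def methylation_expression_correlation(methylation, expression) -> dict:
    """Spearman rank correlation of gene-body methylation vs expression.

    Returns rho, its sign, and a defined flag (False on zero variance).
    """
    m = np.asarray(methylation, dtype=float)
    e = np.asarray(expression, dtype=float)
    if m.shape != e.shape or m.ndim != 1:
        raise ConfigurationError("methylation and expression must be equal-length vectors")
    if m.size < 3:
        raise ConfigurationError("need at least 3 paired genes")
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        return {"rho": float("nan"), "sign": 0, "defined": False, "n": m.size}
    rho, p = spearmanr(m, e)
    return {
        "rho": float(rho),
        "sign": int(np.sign(rho)),
        "defined": True,
        "p_value": float(p),
        "n": int(m.size),
    }


def denovo_vs_expression_change(
    promoter_meth_before,
    promoter_meth_after,
    expression_before,
    expression_after,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare promoter de novo methylation gain between up- and down-genes.

    Genes are split by the sign of their expression change between the two
    stages (zero-change genes are dropped); the group difference of mean
    promoter methylation gain is tested against a permutation null
    (two-sided, label shuffles).  An empty group is reported, not tested.
    """
    gain = np.asarray(promoter_meth_after, float) - np.asarray(promoter_meth_before, float)
    delta = np.asarray(expression_after, float) - np.asarray(expression_before, float)
    if gain.shape != delta.shape:
        raise ConfigurationError("methylation and expression vectors differ in length")
    up, down = delta > 0, delta < 0
    result = {
        "n_up": int(up.sum()),
        "n_down": int(down.sum()),
        "mean_gain_up": float(gain[up].mean()) if up.any() else float("nan"),
        "mean_gain_down": float(gain[down].mean()) if down.any() else float("nan"),
    }
    if not up.any() or not down.any():
        result.update({"difference": float("nan"), "p_value": float("nan"),
                       "tested": False, "empty_group": "down" if up.any() else "up"})
        return result
    observed = result["mean_gain_up"] - result["mean_gain_down"]
    rng = np.random.default_rng(seed)
    pool = gain[up | down]
    n_up = int(up.sum())
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(pool)
        null[i] = perm[:n_up].mean() - perm[n_up:].mean()
    p = (np.sum(np.abs(null) >= abs(observed)) + 1) / (n_permutations + 1)
    result.update({"difference": float(observed), "p_value": float(p), "tested": True})
    return result
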