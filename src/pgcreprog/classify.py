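"""Demethylation-resistance classification.

Selection rules follow the germline reprogramming phenotypes: late
demethylaters retain more than 25% methylation at every stage before
gonadal entry (E6.5–E11.5); resistant elements keep >25% at E13.5 in male
or female PGCs; CGIs within 2 kb of an IAP copy are treated as
IAP-context-protected; variably erased CGIs (VECs) are resistant outside
IAP context.  Thresholds are strict (">" and "<").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError
from .stages import stage_key


@dataclass(frozen=True)
class SelectionRule:
    """Methylation threshold applied at a set of stages (strict greater-than)."""

    threshold: float = 25.0
    stages: tuple[str, ...] = ("E6.5", "E9.5", "E10.5", "E11.5")
    sex: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 100.0:
            raise ConfigurationError("threshold outside [0, 100]")
        if len(self.stages) == 0:
            raise ConfigurationError("stage set is empty")


@dataclass
class SelectionResult:
    selected: frozenset
    excluded_missing: frozenset


def _resolve_column(matrix: pd.DataFrame, stage: str, sex: str | None):
    """Find the stage-median column for a stage (and optional sex)."""
    candidates = []
    if sex is not None:
        candidates.append(stage_key(stage, sex))
    candidates.append(stage)
    for cand in candidates:
        if cand in matrix.columns:
            return cand
    raise ConfigurationError(f"stage {stage!r} absent from matrix columns")


def select_late_demethylaters(
    matrix: pd.DataFrame, rule: SelectionRule = SelectionRule()
) -> SelectionResult:
    """Features exceeding the threshold at every rule stage.

    ``matrix`` holds stage-median percentages (features × stage columns).
    Features missing at any rule stage are excluded and reported separately.
    """
    cols = [_resolve_column(matrix, s, rule.sex) for s in rule.stages]
    sub = matrix[cols]
    missing = sub.isna().any(axis=1)
    passing = (sub > rule.threshold).all(axis=1) & ~missing
    return SelectionResult(
        frozenset(matrix.index[passing]), frozenset(matrix.index[missing])
    )


def select_resistant(
    matrix: pd.DataFrame,
    sex: str,
    stage: str = "E13.5",
    threshold: float = 25.0,
) -> SelectionResult:
    """Features strictly above the threshold at one (sexed) stage."""
    return select_late_demethylaters(
        matrix, SelectionRule(threshold=threshold, stages=(stage,), sex=sex)
    )


def annotate_iap_proximity(
    features: pd.DataFrame, iaps: pd.DataFrame, cutoff_bp: int = 2000
) -> pd.DataFrame:
    """Edge-to-edge distance from each feature to its nearest IAP.

    Distance is 0 for overlap; with no IAPs at all every distance is the
    infinite sentinel and nothing is proximal.  Proximal iff distance <
    cutoff (strict).
    """
    out = pd.DataFrame(
        {"distance": np.inf, "proximal": False},
        index=pd.Index(features["feature_id"], name="feature_id"),
    )
    if iaps is None or len(iaps) == 0:
        return out
    for chrom, sub in features.groupby("chrom"):
        isub = iaps[iaps["chrom"] == chrom].sort_values("start")
        if isub.empty:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        istart, iend = isub["start"].to_numpy(), isub["end"].to_numpy()
        idx = np.searchsorted(istart, s, side="right")
        dist = np.full(s.shape, np.inf)
        left_ok = idx - 1 >= 0
        dist[left_ok] = np.maximum(s[left_ok] - iend[idx[left_ok] - 1], 0)
        right_ok = idx < istart.size
        dist[right_ok] = np.minimum(
            dist[right_ok], np.maximum(istart[idx[right_ok]] - e[right_ok], 0)
        )
        out.loc[sub["feature_id"], "distance"] = dist
    out["proximal"] = out["distance"] < cutoff_bp
    return out


def resistance_vs_distance(
    matrix: pd.DataFrame,
    proximity: pd.DataFrame,
    bin_edges,
    sex: str,
    stage: str = "E13.5",
    threshold: float = 25.0,
) -> pd.DataFrame:
    """Fraction of features resistant at E13.5 per IAP-distance bin.

    Bins follow ``bin_edges`` ([e0, e1), [e1, e2), …, plus a final open
    bin); bins containing no features are omitted.
    """
    resistant = select_resistant(matrix, sex=sex, stage=stage, threshold=threshold)
    ids = proximity.index.intersection(matrix.index)
    dist = proximity.loc[ids, "distance"].to_numpy(dtype=float)
    edges = np.asarray(list(bin_edges), dtype=float)
    bin_idx = np.searchsorted(edges, dist, side="right") - 1
    is_res = np.array([fid in resistant.selected for fid in ids])
    rows = []
    for b in range(len(edges)):
        mask = bin_idx == b
        if not mask.any():
            continue
        hi = edges[b + 1] if b + 1 < len(edges) else np.inf
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": hi,
                "n_features": int(mask.sum()),
                "resistant_fraction": float(is_res[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def identify_vecs(
    resistant_male: frozenset | set,
    resistant_female: frozenset | set,
    proximity: pd.DataFrame,
    matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Variably erased CGIs: resistant in at least one sex, not IAP-proximal.

    Returns a per-VEC table with the methylation range across stage columns
    (a continuous variability summary — there is no principled numeric
    cutoff for "variable") and the sex-bias sign: +1 male-only, −1
    female-only, 0 resistant in both.
    """
    resistant_any = set(resistant_male) | set(resistant_female)
    proximal = set(proximity.index[proximity["proximal"]])
    vec_ids = sorted(resistant_any - proximal)
    rows = []
    for fid in vec_ids:
        vals = matrix.loc[fid].dropna() if fid in matrix.index else pd.Series(dtype=float)
        in_m, in_f = fid in resistant_male, fid in resistant_female
        rows.append(
            {
                "feature_id": fid,
                "resistant_male": in_m,
                "resistant_female": in_f,
                "sex_bias": (1 if in_m and not in_f else -1 if in_f and not in_m else 0),
                "methylation_range": float(vals.max() - vals.min()) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["feature_id", "resistant_male", "resistant_female", "sex_bias", "methylation_range"]
    ).set_index("feature_id") if rows else pd.DataFrame(
        columns=["resistant_male", "resistant_female", "sex_bias", "methylation_range"],
        index=pd.Index([], name="feature_id"),
    )


def male_bias_tally(vecs: pd.DataFrame) -> dict:
    """Counts of male-biased / female-biased / shared VECs."""
    return {
        "male_biased": int((vecs["sex_bias"] == 1).sum()),
        "female_biased": int((vecs["sex_bias"] == -1).sum()),
        "both_sexes": int((vecs["sex_bias"] == 0).sum()),
    }


def core_vs_flank_profile(
    calls: dict[str, pd.DataFrame],
    cgi: tuple[str, int, int],
    flank_bp: int = 2000,
    chrom_length: int | None = None,
    min_total_count: int = 10,
) -> pd.DataFrame:
    """Weighted methylation of a CGI core vs its pooled flanks, per sample.

    Flanks of ``flank_bp`` each side are clipped at chromosome ends; a
    flank with no informative CpGs is reported missing.  The difference is
    core − flank.
    """
    if flank_bp <= 0:
        raise ConfigurationError("flank_bp must be > 0")
    chrom, start, end = cgi
    f_lo = max(0, start - flank_bp)
    f_hi = end + flank_bp
    if chrom_length is not None:
        f_hi = min(f_hi, chrom_length)
    rows = {}
    for sid, df in calls.items():
        sub = df[(df["context"] == "CG") & (df["chrom"] == chrom)]
        pos = sub["pos"].to_numpy()
        meth = sub["count_methylated"].to_numpy()
        tot = meth + sub["count_unmethylated"].to_numpy()

        def pct(mask):
            m, t = meth[mask].sum(), tot[mask].sum()
            return 100.0 * m / t if t >= min_total_count else np.nan

        core_mask = (pos >= start) & (pos < end)
        flank_mask = ((pos >= f_lo) & (pos < start)) | ((pos >= end) & (pos < f_hi))
        core, flank = pct(core_mask), pct(flank_mask)
        rows[sid] = {
            "core_percent": core,
            "flank_percent": flank,
            "difference": core - flank,
        }
    return pd.DataFrame(rows).T


@dataclass
class EnrichmentResult:
    ratio: float
    defined: bool
    p_value: float
    n_selected: int
    n_background: int
    hits_selected: int
    hits_background: int


def overlap_enrichment(
    selected, background, site_bearing
) -> EnrichmentResult:
    """Enrichment of binding-site-bearing features inside a selected set.

    Ratio = (hit fraction in selected) / (hit fraction in background); the
    tail probability is the hypergeometric P(X >= observed hits) for drawing
    |selected| features from the background.  A background hit fraction of
    0 yields an undefined ratio flag, not an exception.
    """
    selected, background, sites = set(selected), set(background), set(site_bearing)
    if not selected <= background:
        raise ConfigurationError("selected set is not a subset of background")
    if not background:
        raise ConfigurationError("background is empty")
    K = len(background & sites)
    n = len(selected)
    k = len(selected & sites)
    N = len(background)
    if K == 0:
        return EnrichmentResult(np.nan, False, 1.0, n, N, k, K)
    ratio = (k / n) / (K / N) if n else np.nan
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(float(ratio), n > 0, p, n, N, k, K)
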