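"""Methylation quantification over tiling probes and features.

Percentage methylation within a probe or feature is read-count weighted:
100 · Σ methylated / (Σ methylated + Σ unmethylated) over contained
cytosines.  Probes below a minimum informative count are flagged missing
(NaN), never reported as 0.  Sample-level global values are unweighted
means of non-missing probe percentages; stage summaries are replicate
medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSet, assign_to_intervals
from .stages import parse_sample_id, stage_key

CALL_COLUMNS = (
    "chrom",
    "pos",
    "strand",
    "context",
    "count_methylated",
    "count_unmethylated",
)


@dataclass
class MethylationMatrix:
    """Probe-or-feature × sample percentage methylation with coverage.

    ``percent`` holds values in [0, 100] with NaN for cells below the
    coverage minimum; ``counts`` the total informative count per cell;
    ``samples`` per-sample stage/sex/replicate metadata.
    """

    percent: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        vals = self.percent.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if finite.any() and ((vals[finite] < 0) | (vals[finite] > 100)).any():
            raise ValueError("percentages outside [0, 100]")

    def stage_medians(self) -> pd.DataFrame:
        """Collapse replicates to per-stage(/sex) medians.

        Columns are keyed ``stage`` for mixed-sex pools and
        ``stage_sex`` otherwise.
        """
        groups: dict[str, list[str]] = {}
        for sid, row in self.samples.iterrows():
            key = stage_key(row["stage"], row["sex"])
            groups.setdefault(key, []).append(sid)
        med = {key: self.percent[cols].median(axis=1) for key, cols in groups.items()}
        return pd.DataFrame(med)


def sample_metadata(sample_ids) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        stage, sex, rep = parse_sample_id(sid)
        rows.append({"stage": stage, "sex": sex, "replicate": rep})
    return pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"))


def tile_genome(chrom_lengths: dict[str, int], window_bp: int) -> pd.DataFrame:
    """Non-overlapping abutting windows covering each chromosome.

    The last partial window is kept, so probe spans partition the genome.
    """
    if window_bp < 1:
        raise ValueError("window must be >= 1 bp")
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            rows.append((chrom, start, end, f"{chrom}:{start}-{end}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id"])


def _aggregate_counts(calls: pd.DataFrame, intervals: pd.DataFrame, context: str):
    """Sum (methylated, total) calls per interval; intervals must be
    non-overlapping within each chromosome."""
    meth = np.zeros(len(intervals), dtype=np.int64)
    total = np.zeros(len(intervals), dtype=np.int64)
    sub = calls[calls["context"] == context]
    iv_by_chrom = {
        chrom: g.sort_values("start") for chrom, g in intervals.groupby("chrom")
    }
    for chrom, cg in sub.groupby("chrom"):
        iv = iv_by_chrom.get(chrom)
        if iv is None:
            continue
        idx = assign_to_intervals(
            cg["pos"].to_numpy(),
            iv["start"].to_numpy(),
            iv["end"].to_numpy(),
        )
        hit = idx >= 0
        rows = iv.index.to_numpy()[idx[hit]]
        np.add.at(meth, rows, cg["count_methylated"].to_numpy()[hit])
        np.add.at(
            total,
            rows,
            cg["count_methylated"].to_numpy()[hit]
            + cg["count_unmethylated"].to_numpy()[hit],
        )
    return meth, total


def _counts_to_matrix(per_sample, ids, min_total) -> MethylationMatrix:
    percent, counts = {}, {}
    for sid, (meth, total) in per_sample.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * meth / total
        pct = np.where(total >= min_total, pct, np.nan)
        percent[sid] = pct
        counts[sid] = total
    index = pd.Index(ids, name="id")
    return MethylationMatrix(
        pd.DataFrame(percent, index=index),
        pd.DataFrame(counts, index=index),
        sample_metadata(list(per_sample)),
    )


def probe_methylation(
    calls: dict[str, pd.DataFrame],
    probes: pd.DataFrame,
    min_total_count: int = 10,
) -> MethylationMatrix:
    """Weighted CG methylation percentage per probe per sample."""
    if probes is None or len(probes) == 0:
        raise ValueError("probe set is empty")
    probes = probes.reset_index(drop=True)
    per_sample = {
        sid: _aggregate_counts(df, probes, "CG") for sid, df in calls.items()
    }
    return _counts_to_matrix(per_sample, probes["probe_id"], min_total_count)


def feature_methylation(
    calls: dict[str, pd.DataFrame],
    annotation: FeatureSet,
    min_total_count: int = 10,
    classes: list[str] | None = None,
) -> MethylationMatrix:
    """Weighted CG methylation percentage per annotated feature.

    Both strands of a dyad count toward the containing feature (bottom-strand
    calls sit at position + 1 and fall inside the same interval).  Classes
    are aggregated separately so nested features of different classes each
    receive their own calls.
    """
    df = annotation.features
    if classes is not None:
        df = df[df["feature_class"].isin(classes)]
    if df.empty:
        raise ValueError("no features to quantify")
    ids = []
    per_sample = {sid: [np.empty(0, np.int64), np.empty(0, np.int64)] for sid in calls}
    for cls, sub in df.groupby("feature_class", sort=True):
        sub = sub.reset_index(drop=True)
        ids.extend(sub["feature_id"])
        for sid, table in calls.items():
            meth, total = _aggregate_counts(table, sub, "CG")
            per_sample[sid][0] = np.concatenate([per_sample[sid][0], meth])
            per_sample[sid][1] = np.concatenate([per_sample[sid][1], total])
    per_sample = {sid: tuple(v) for sid, v in per_sample.items()}
    return _counts_to_matrix(per_sample, ids, min_total_count)


def global_summary(matrix: MethylationMatrix):
    """Per-sample global methylation level and per-stage replicate median.

    The global value is the unweighted mean of non-missing probe
    percentages (use ``statistic="median"`` for the median variant).
    """
    per_sample = {}
    for sid in matrix.percent.columns:
        col = matrix.percent[sid]
        if col.notna().sum() == 0:
            raise ValueError(f"all probes missing for sample {sid!r}")
        per_sample[sid] = float(col.mean())
    per_sample = pd.Series(per_sample, name="global_percent")
    groups: dict[str, list[float]] = {}
    for sid, row in matrix.samples.iterrows():
        groups.setdefault(stage_key(row["stage"], row["sex"]), []).append(
            per_sample[sid]
        )
    per_stage = pd.Series(
        {k: float(np.median(v)) for k, v in groups.items()}, name="stage_median"
    )
    return per_sample, per_stage


def methylation_distribution(
    matrix: MethylationMatrix, percentiles=(5, 10, 25, 50, 75, 90, 95)
) -> pd.DataFrame:
    """Percentiles of non-missing probe percentages per sample."""
    out = {}
    for sid in matrix.percent.columns:
        vals = matrix.percent[sid].dropna().to_numpy()
        out[sid] = (
            np.percentile(vals, percentiles)
            if vals.size
            else np.full(len(percentiles), np.nan)
        )
    return pd.DataFrame(out, index=pd.Index(percentiles, name="percentile"))


def conversion_efficiency(
    chh_calls: dict[str, pd.DataFrame],
    probes: pd.DataFrame,
    min_total_count: int = 20,
):
    """Fraction of qualifying probes showing 100% bisulfite conversion.

    A probe counts as fully converted iff its summed methylated CHH count is
    exactly 0 with at least ``min_total_count`` CHH observations.  Returns
    (per-sample fraction Series, per-probe long table).
    """
    if probes is None or len(probes) == 0:
        raise ValueError("probe set is empty")
    probes = probes.reset_index(drop=True)
    fractions = {}
    tables = []
    for sid, df in chh_calls.items():
        meth, total = _aggregate_counts(df, probes, "CHH")
        qualifying = total >= min_total_count
        if not qualifying.any():
            raise ValueError(f"no qualifying CHH probes for sample {sid!r}")
        converted = qualifying & (meth == 0)
        fractions[sid] = converted.sum() / qualifying.sum()
        tables.append(
            pd.DataFrame(
                {
                    "sample": sid,
                    "probe_id": probes["probe_id"],
                    "chh_methylated": meth,
                    "chh_total": total,
                    "qualifying": qualifying,
                    "fully_converted": converted,
                }
            )
        )
    return (
        pd.Series(fractions, name="fraction_fully_converted"),
        pd.concat(tables, ignore_index=True),
    )


def cg_density_correlation(
    matrix: MethylationMatrix, cpg_counts: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of per-probe CpG count vs methylation, per sample.

    Zero variance in either variable yields an undefined flag (NaN r),
    not an exception.
    """
    rows = {}
    for sid in matrix.percent.columns:
        col = matrix.percent[sid]
        mask = col.notna() & cpg_counts.reindex(col.index).notna()
        x = cpg_counts.reindex(col.index)[mask].to_numpy(dtype=float)
        y = col[mask].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"fewer than 3 probes with both values for {sid!r}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[sid] = {"r": np.nan, "defined": False, "n": x.size}
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            rows[sid] = {"r": r, "defined": True, "n": x.size}
    return pd.DataFrame(rows).T


def merge_probe_counts(meth_a, total_a, meth_b, total_b):
    """Count-weighted combination of two probes' percentages (consistency helper)."""
    meth, total = meth_a + meth_b, total_a + total_b
    return 100.0 * meth / total if total else float("nan")
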