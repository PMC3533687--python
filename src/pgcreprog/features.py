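"""Genomic feature annotations (CGIs, DMRs, promoters, repeats, gene parts).

Coordinates are 0-based, half-open throughout.  CpG dyads are indexed by the
position of the C on the top strand.  Features of one class never overlap
each other; classes may nest (a CGI inside a promoter is legal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

FEATURE_CLASSES = (
    "CGI",
    "CGI_X",
    "DMR_mat",
    "DMR_pat",
    "germline_CGI",
    "promoter",
    "IAP",
    "LINE1",
    "exon",
    "intron",
)

#: classes that are CpG-island-like (dense CpG spacing in the simulator)
CGI_LIKE_CLASSES = ("CGI", "CGI_X", "DMR_mat", "DMR_pat", "germline_CGI")

FEATURE_COLUMNS = ("chrom", "start", "end", "feature_id", "feature_class", "strand")


@dataclass
class FeatureSet:
    """Interval annotations plus the CpG/CHH site maps of the genome.

    ``features`` has columns chrom, start, end, feature_id, feature_class,
    strand.  ``cpgs`` maps chromosome -> sorted array of top-strand C
    positions of CpG dyads; ``chh_sites`` likewise for CHH cytosines (used
    for bisulfite conversion control).
    """

    features: pd.DataFrame
    chrom_lengths: dict[str, int]
    cpgs: dict[str, np.ndarray] = field(default_factory=dict)
    chh_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.features = self.features.reset_index(drop=True)
        for col in FEATURE_COLUMNS:
            if col not in self.features.columns:
                raise ConfigurationError(f"feature table missing column {col!r}")

    def validate(self) -> None:
        """Check class membership, chromosome bounds, and same-class overlap."""
        df = self.features
        bad = set(df["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ConfigurationError(f"unknown feature classes: {sorted(bad)}")
        for chrom, sub in df.groupby("chrom"):
            if chrom not in self.chrom_lengths:
                raise ConfigurationError(f"feature on unknown chromosome {chrom!r}")
            length = self.chrom_lengths[chrom]
            if (sub["start"] < 0).any() or (sub["end"] > length).any():
                raise ConfigurationError(
                    f"feature outside chromosome bounds on {chrom}"
                )
        if (df["start"] >= df["end"]).any():
            raise ConfigurationError("feature with start >= end")
        for (chrom, cls), sub in df.groupby(["chrom", "feature_class"]):
            sub = sub.sort_values("start")
            overlap = sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]
            if overlap.any():
                i = int(np.argmax(overlap))
                a = sub.iloc[i]["feature_id"]
                b = sub.iloc[i + 1]["feature_id"]
                raise ConfigurationError(
                    f"overlapping {cls} features on {chrom}: {a!r} and {b!r}"
                )

    def by_class(self, feature_class: str) -> pd.DataFrame:
        return self.features[self.features["feature_class"] == feature_class]

    def classes(self) -> list[str]:
        return sorted(set(self.features["feature_class"]))

    def x_chromosomes(self) -> list[str]:
        """Chromosomes flagged as X (name ends in 'X')."""
        return [c for c in self.chrom_lengths if str(c).endswith("X")]

    def feature_cpgs(self, feature_id: str) -> np.ndarray:
        """CpG dyad positions (top-strand C) contained in one feature."""
        row = self.features[self.features["feature_id"] == feature_id]
        if row.empty:
            raise KeyError(feature_id)
        chrom, start, end = row.iloc[0][["chrom", "start", "end"]]
        sites = self.cpgs.get(chrom, np.empty(0, dtype=np.int64))
        lo, hi = np.searchsorted(sites, [start, end])
        return sites[lo:hi]

    def n_features(self) -> int:
        return len(self.features)


def make_feature_table(records) -> pd.DataFrame:
    """Build a feature table from (chrom, start, end, id, class, strand) rows."""
    return pd.DataFrame(records, columns=list(FEATURE_COLUMNS))


def assign_to_intervals(
    positions: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Map positions into sorted non-overlapping [start, end) intervals.

    Returns the interval index per position, or -1 where uncovered.
    ``starts``/``ends`` must be sorted by start and non-overlapping.
    """
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    ok[ok] &= positions[ok] < ends[idx[ok]]
    out = np.where(ok, idx, -1)
    return out
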