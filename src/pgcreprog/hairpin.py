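"""Hairpin bisulfite dyad analysis.

Hairpin bisulfite sequencing ligates the two strands of a DNA molecule so
both strands of each CpG dyad are read together, distinguishing full
methylation (both strands), hemimethylation (one strand), and no
methylation.  The joint distribution of methylated CGs across top and
bottom strands within hemimethylated molecules separates passive
demethylation (all meCs on the parental template strand, so one strand of
every molecule is clean) from strand-independent active removal (meCs
scattered over both strands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DYAD_STATES = ("M", "T", "B", "U", ".")  # both / top-only / bottom-only / neither / missing


@dataclass(frozen=True)
class HairpinRead:
    """One hairpin molecule: ordered dyad states over L positions."""

    read_id: str
    states: str

    def __post_init__(self):
        if len(self.states) < 1:
            raise ConfigurationError("hairpin read needs >= 1 position")
        bad = set(self.states) - set(DYAD_STATES)
        if bad:
            raise ConfigurationError(
                f"read {self.read_id}: invalid dyad states {sorted(bad)}"
            )

    def __len__(self):
        return len(self.states)


@dataclass
class DyadJoint:
    """(k_top, k_bottom) meC count matrix over hemimethylated dyads per read."""

    counts: np.ndarray  # (L+1, L+1), counts[k_top, k_bottom]
    n_reads: int

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0] - 1

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ConfigurationError("empty dyad joint")
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        lab = list(range(self.counts.shape[0]))
        return pd.DataFrame(self.counts, index=lab, columns=lab).rename_axis(
            index="k_top", columns="k_bottom"
        )


def _state_matrix(reads) -> np.ndarray:
    if not reads:
        raise ConfigurationError("no reads given")
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ConfigurationError("reads have differing numbers of dyad positions")
    return np.array([list(r.states) for r in reads])


def classify_dyads(reads: list[HairpinRead]):
    """Fractions of fully/hemi/unmethylated dyads, per position and pooled.

    Missing ('.') positions are dropped per read, never imputed.  Returns
    (per_position DataFrame, pooled dict); fractions sum to 1.
    """
    mat = _state_matrix(reads)
    informative = mat != "."
    if not informative.any():
        raise ConfigurationError("all dyad positions missing")
    full = (mat == "M") & informative
    hemi = ((mat == "T") | (mat == "B")) & informative
    un = (mat == "U") & informative
    n = informative.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_pos = pd.DataFrame(
            {
                "n_informative": informative.sum(axis=0),
                "full": full.sum(axis=0) / n,
                "hemi": hemi.sum(axis=0) / n,
                "unmethylated": un.sum(axis=0) / n,
            },
            index=pd.RangeIndex(mat.shape[1], name="position"),
        )
    total = informative.sum()
    pooled = {
        "full": full.sum() / total,
        "hemi": hemi.sum() / total,
        "unmethylated": un.sum() / total,
        "n_informative": int(total),
    }
    return per_pos, pooled


def strand_joint(reads: list[HairpinRead]) -> DyadJoint:
    """Tally the per-read (k_top, k_bottom) hemimethylated meC counts.

    Only T and B states contribute; a read with no hemimethylated dyads
    lands in cell (0, 0).
    """
    mat = _state_matrix(reads)
    k_top = (mat == "T").sum(axis=1)
    k_bot = (mat == "B").sum(axis=1)
    L = mat.shape[1]
    counts = np.zeros((L + 1, L + 1), dtype=np.int64)
    np.add.at(counts, (k_top, k_bot), 1)
    return DyadJoint(counts, n_reads=len(reads))


def strand_bias_stat(joint: DyadJoint) -> dict:
    """Fraction of hemi-bearing reads with all meCs confined to one strand.

    Reads with k_top = k_bottom = 0 are excluded from the denominator.
    Returns confined_fraction, off_axis_mass, and n_hemi_reads; the
    fractions are undefined (NaN, defined=False) when no read carries a
    hemimethylated dyad.
    """
    counts = joint.counts
    if counts.sum() == 0:
        raise ConfigurationError("empty dyad joint")
    hemi_mask = np.ones_like(counts, dtype=bool)
    hemi_mask[0, 0] = False
    n_hemi = counts[hemi_mask].sum()
    if n_hemi == 0:
        return {
            "confined_fraction": float("nan"),
            "off_axis_mass": float("nan"),
            "defined": False,
            "n_hemi_reads": 0,
        }
    on_axis = counts[0, 1:].sum() + counts[1:, 0].sum()
    confined = on_axis / n_hemi
    return {
        "confined_fraction": float(confined),
        "off_axis_mass": float(1.0 - confined),
        "defined": True,
        "n_hemi_reads": int(n_hemi),
    }


def compare_to_nulls(
    observed: DyadJoint, passive: DyadJoint, active: DyadJoint
) -> dict:
    """Total-variation distance of the observed joint to each null.

    The verdict names the closer null; exact ties are "indeterminate".
    """
    if not (
        observed.n_positions == passive.n_positions == active.n_positions
    ):
        raise ConfigurationError("joints are over different numbers of positions")
    p_obs = observed.normalized()
    d_passive = 0.5 * np.abs(p_obs - passive.normalized()).sum()
    d_active = 0.5 * np.abs(p_obs - active.normalized()).sum()
    if d_passive < d_active:
        verdict = "passive"
    elif d_active < d_passive:
        verdict = "active"
    else:
        verdict = "indeterminate"
    return {
        "distance_passive": float(d_passive),
        "distance_active": float(d_active),
        "verdict": verdict,
    }
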