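"""Synthetic methylome, hairpin, and expression generators.

This module emulates the statistical structure of the mouse PGC
reprogramming time course so that every downstream analysis stage is
testable without sequencing data:

* a small annotated genome (CGIs, imprinted DMRs, germline-gene promoter
  CGIs, X-linked CGIs, IAP and LINE1 copies, promoters, exons/introns);
* per-stage bisulfite call tables in which unprotected methylation halves
  with every cell division (passive dilution with maintenance off) while
  protected classes — imprinted DMRs at 50%, X-linked CGIs in the female
  lineage, germline promoter CGIs — hold their level until gonadal entry,
  IAPs resist throughout, and E16.5 male PGCs regain methylation de novo;
* hairpin bisulfite reads under passive, active, or mixed demethylation
  nulls;
* a gene-by-sample expression matrix with planted pluripotency-like and
  meiosis-like clusters.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizingError
from .features import (
    CGI_LIKE_CLASSES,
    FeatureSet,
    assign_to_intervals,
    make_feature_table,
)
from .hairpin import HairpinRead
from .stages import STAGE_ORDER, StageSpec, default_stage_series, stage_index

# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenomeConfig:
    """Sizes and feature counts of the synthetic genome.

    Chromosomes whose name ends in "X" are treated as the X chromosome;
    X-linked CGIs (class ``CGI_X``) are placed only there, every other
    class only on autosomes.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 3_000_000,
            "chr2": 3_000_000,
            "chr3": 3_000_000,
            "chrX": 1_000_000,
        }
    )
    n_cgi: int = 150
    n_cgi_x: int = 30
    n_dmr_mat: int = 15
    n_dmr_pat: int = 10
    n_germline_cgi: int = 25
    n_promoter: int = 100
    n_promoter_near_iap: int = 25
    n_iap: int = 60
    n_line1: int = 120
    n_exon: int = 150
    n_intron: int = 150
    cgi_length_range: tuple[int, int] = (500, 2000)
    promoter_length: int = 1000
    iap_length: int = 5000
    line1_length: int = 6000
    gene_part_length: int = 2000
    promoter_iap_gap_range: tuple[int, int] = (0, 4000)
    background_cpg_spacing: float = 100.0
    cgi_cpg_spacing: float = 10.0
    chh_spacing: float = 100.0
    seed: int = 0

    def validate(self):
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ConfigurationError("chromosome lengths must be > 0")
        lo, hi = self.cgi_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid CGI length range")
        if self.n_promoter_near_iap > self.n_promoter:
            raise ConfigurationError(
                "n_promoter_near_iap exceeds n_promoter"
            )
        if not [c for c in self.chrom_lengths if str(c).endswith("X")]:
            if self.n_cgi_x > 0:
                raise ConfigurationError("X-linked CGIs requested but no X chromosome")


@dataclass
class ClassPolicy:
    """Methylation trajectory policy for one feature class.

    ``initial`` is the E6.5 methylation fraction.  A class with an
    ``erasure_stage`` is protected: it holds ``initial`` at stages strictly
    before that stage and drops to 0 from it (erasure upon gonadal entry).
    ``resistant`` classes hold their level at every stage (IAPs).
    ``denovo_exempt`` classes are skipped by E16.5 male de novo methylation.
    ``protect_window`` optionally records the stage range of active
    maintenance; its end may not come after the erasure stage.
    """

    initial: float
    erasure_stage: str | None = None
    resistant: bool = False
    denovo_exempt: bool = False
    protect_window: tuple[str, str] | None = None

    def validate(self, name: str = "?"):
        if not 0.0 <= self.initial <= 1.0:
            raise ConfigurationError(f"{name}: initial fraction outside [0,1]")
        if self.erasure_stage is not None:
            stage_index(self.erasure_stage)
        if self.protect_window is not None:
            w0, w1 = self.protect_window
            if stage_index(w0) > stage_index(w1):
                raise ConfigurationError(f"{name}: protection window reversed")
            if self.erasure_stage is not None and stage_index(
                self.erasure_stage
            ) < stage_index(w1):
                raise ConfigurationError(
                    f"{name}: erasure stage earlier than protection window end"
                )


def default_class_policies() -> dict[str, ClassPolicy]:
    return {
        # bulk sequence: epiblast-like 71% methylation, passively diluted
        "background": ClassPolicy(0.71),
        "exon": ClassPolicy(0.71),
        "intron": ClassPolicy(0.71),
        "promoter": ClassPolicy(0.60),
        "LINE1": ClassPolicy(0.80),
        # ordinary CGIs are largely unmethylated already in the epiblast
        "CGI": ClassPolicy(0.15),
        # long-term epigenetic memory: held until gonadal entry
        "DMR_mat": ClassPolicy(0.5, erasure_stage="E13.5", denovo_exempt=True),
        "DMR_pat": ClassPolicy(0.5, erasure_stage="E13.5", denovo_exempt=True),
        "germline_CGI": ClassPolicy(0.75, erasure_stage="E13.5", denovo_exempt=True),
        # X-linked CGIs: 50% in an all-female pool (random X inactivation);
        # the simulator scales by the sample's sex composition
        "CGI_X": ClassPolicy(0.5, erasure_stage="E13.5", denovo_exempt=True),
        # young LTR retrotransposons resist erasure throughout
        "IAP": ClassPolicy(0.90, resistant=True, denovo_exempt=True),
    }


@dataclass
class DynamicsProfile:
    """Global dynamics of the two-phase demethylation time course."""

    class_policies: dict[str, ClassPolicy] = field(
        default_factory=default_class_policies
    )
    bulk_maintenance: bool = False
    denovo_target: float = 0.5
    conversion_failure_rate: float = 0.002
    iap_protection_radius_bp: int = 2000

    def validate(self):
        for name, pol in self.class_policies.items():
            pol.validate(name)
        if not 0.0 <= self.denovo_target <= 1.0:
            raise ConfigurationError("denovo_target outside [0,1]")
        if not 0.0 <= self.conversion_failure_rate <= 1.0:
            raise ConfigurationError("conversion_failure_rate outside [0,1]")
        if self.iap_protection_radius_bp < 0:
            raise ConfigurationError("iap_protection_radius_bp must be >= 0")


# ---------------------------------------------------------------------------
# annotation generator
# ---------------------------------------------------------------------------


def _place_intervals(rng, occupied, chrom_len, n, length_lo, length_hi, cls):
    """Sample n non-overlapping intervals avoiding already-occupied ones."""
    placed = []
    max_tries = 200 * max(n, 1)
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise SizingError(
                f"chromosome too short to host {n} features of class {cls}"
            )
        length = int(rng.integers(length_lo, length_hi + 1))
        if length >= chrom_len:
            raise SizingError(
                f"chromosome too short to host class {cls} (length {length})"
            )
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        placed.append((start, end))
    return placed


def _sites_by_spacing(rng, start, end, spacing):
    """CpG positions with geometric spacing of the given mean within [start, end)."""
    n_expect = int((end - start) / spacing * 1.5) + 5
    gaps = rng.geometric(1.0 / spacing, size=n_expect)
    pos = start + np.cumsum(gaps) - 1
    return pos[pos < end - 1]  # leave room for the G of the dyad


def generate_annotation(config: SyntheticGenomeConfig) -> FeatureSet:
    """Generate the synthetic genome annotation.

    Features of one class never overlap (placement is globally
    non-overlapping, which is stricter); CpG-island-like classes get dense
    CpG spacing, the rest of the genome background spacing.  A configured
    subset of promoters is placed within ``promoter_iap_gap_range`` of an
    IAP copy to emulate IAP-context protection.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    x_chroms = [c for c in config.chrom_lengths if str(c).endswith("X")]
    autosomes = [c for c in config.chrom_lengths if c not in x_chroms]
    if not autosomes:
        raise ConfigurationError("at least one autosome is required")

    occupied = {c: [] for c in config.chrom_lengths}
    records = []
    counters = {}

    def add(chrom, start, end, cls):
        counters[cls] = counters.get(cls, 0) + 1
        fid = f"{cls}_{counters[cls]:04d}"
        records.append((chrom, int(start), int(end), fid, cls, "+"))
        return fid

    def spread(n):
        """Split a class count across autosomes, weighted by length."""
        lengths = np.array([config.chrom_lengths[c] for c in autosomes], float)
        alloc = np.floor(lengths / lengths.sum() * n).astype(int)
        for i in range(n - alloc.sum()):
            alloc[i % len(alloc)] += 1
        return dict(zip(autosomes, alloc))

    lo, hi = config.cgi_length_range

    # paired promoter/IAP placements first (they constrain each other)
    n_paired = config.n_promoter_near_iap
    paired_alloc = spread(n_paired)
    gap_lo, gap_hi = config.promoter_iap_gap_range
    for chrom, n in paired_alloc.items():
        for _ in range(n):
            for _ in range(200):
                gap = int(rng.integers(gap_lo, gap_hi + 1))
                span = config.iap_length + gap + config.promoter_length
                if span >= config.chrom_lengths[chrom]:
                    raise SizingError(
                        "chromosome too short to host class promoter near IAP"
                    )
                start = int(rng.integers(0, config.chrom_lengths[chrom] - span))
                iap_iv = (start, start + config.iap_length)
                prom_iv = (iap_iv[1] + gap, iap_iv[1] + gap + config.promoter_length)
                if any(
                    a < e and s < b
                    for (a, b) in (iap_iv, prom_iv)
                    for (s, e) in occupied[chrom]
                ):
                    continue
                occupied[chrom].extend([iap_iv, prom_iv])
                add(chrom, *iap_iv, "IAP")
                add(chrom, *prom_iv, "promoter")
                break
            else:
                raise SizingError(
                    "chromosome too short to host class promoter near IAP"
                )

    class_plan = [
        ("IAP", config.n_iap - n_paired, config.iap_length, config.iap_length),
        (
            "promoter",
            config.n_promoter - n_paired,
            config.promoter_length,
            config.promoter_length,
        ),
        ("CGI", config.n_cgi, lo, hi),
        ("DMR_mat", config.n_dmr_mat, lo, hi),
        ("DMR_pat", config.n_dmr_pat, lo, hi),
        ("germline_CGI", config.n_germline_cgi, lo, hi),
        ("LINE1", config.n_line1, config.line1_length, config.line1_length),
        ("exon", config.n_exon, config.gene_part_length, config.gene_part_length),
        ("intron", config.n_intron, config.gene_part_length, config.gene_part_length),
    ]
    for cls, total, llo, lhi in class_plan:
        if total < 0:
            raise ConfigurationError(f"negative count for class {cls}")
        for chrom, n in spread(total).items():
            for start, end in _place_intervals(
                rng, occupied[chrom], config.chrom_lengths[chrom], n, llo, lhi, cls
            ):
                add(chrom, start, end, cls)
    for chrom in x_chroms:
        for start, end in _place_intervals(
            rng, occupied[chrom], config.chrom_lengths[chrom], config.n_cgi_x, lo, hi, "CGI_X"
        ):
            add(chrom, start, end, "CGI_X")

    table = make_feature_table(records)
    table = table.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )

    # CpG site map: background spacing everywhere, dense inside CGI-like
    # features (each guaranteed at least one dyad)
    cpgs, chh = {}, {}
    for chrom, length in config.chrom_lengths.items():
        sites = [_sites_by_spacing(rng, 0, length, config.background_cpg_spacing)]
        sub = table[
            (table["chrom"] == chrom)
            & table["feature_class"].isin(CGI_LIKE_CLASSES)
        ]
        for _, row in sub.iterrows():
            dense = _sites_by_spacing(
                rng, row["start"], row["end"], config.cgi_cpg_spacing
            )
            if dense.size == 0:
                dense = np.array([(row["start"] + row["end"]) // 2])
            sites.append(dense)
        merged = np.unique(np.concatenate(sites)).astype(np.int64)
        # drop adjacent positions that would overlap as dyads
        keep = np.ones(merged.size, dtype=bool)
        keep[1:] = np.diff(merged) > 1
        cpgs[chrom] = merged[keep]
        chh[chrom] = np.unique(
            _sites_by_spacing(rng, 0, length, config.chh_spacing)
        ).astype(np.int64)

    fs = FeatureSet(table, dict(config.chrom_lengths), cpgs, chh)
    fs.validate()
    return fs


# ---------------------------------------------------------------------------
# methylome simulator
# ---------------------------------------------------------------------------


def class_level(
    profile: DynamicsProfile, feature_class: str, spec: StageSpec
) -> float:
    """Deterministic true methylation fraction of a class in one sample.

    Unprotected classes halve per division (maintenance off); protected
    classes hold their initial level until their erasure stage; resistant
    classes hold throughout; E16.5 male samples gain de novo methylation
    toward ``denovo_target`` except at exempt classes.  X-linked CGIs are
    scaled by the sample's sex composition (female pools carry one
    methylated, inactive X; male pools none; mixed pools half of each).
    """
    pol = profile.class_policies.get(
        feature_class, profile.class_policies["background"]
    )
    level = pol.initial
    if pol.resistant:
        pass
    elif pol.erasure_stage is not None:
        if stage_index(spec.stage) >= stage_index(pol.erasure_stage):
            level = 0.0
    elif not profile.bulk_maintenance:
        level = pol.initial * 0.5 ** spec.divisions
    if feature_class == "CGI_X":
        level *= {"female": 1.0, "male": 0.0, "mixed": 0.5}[spec.sex]
    if (
        spec.stage == "E16.5"
        and spec.sex == "male"
        and not pol.denovo_exempt
        and not pol.resistant
    ):
        level = max(level, profile.denovo_target)
    return level


def _iap_distance(starts, ends, iap_starts, iap_ends):
    """Edge-to-edge distance from each interval to the nearest IAP (same chrom)."""
    if iap_starts.size == 0:
        return np.full(starts.shape, np.inf)
    order = np.argsort(iap_starts)
    iap_starts, iap_ends = iap_starts[order], iap_ends[order]
    idx = np.searchsorted(iap_starts, starts, side="right")
    dist = np.full(starts.shape, np.inf)
    left = idx - 1
    ok = left >= 0
    dist[ok] = np.maximum(starts[ok] - iap_ends[left[ok]], 0)
    ok = idx < iap_starts.size
    dist[ok] = np.minimum(dist[ok], np.maximum(iap_starts[idx[ok]] - ends[ok], 0))
    return dist


def ground_truth_levels(
    annotation: FeatureSet, profile: DynamicsProfile, spec: StageSpec
) -> pd.DataFrame:
    """Per-feature true methylation fraction for one sample.

    Applies the class policy plus IAP-context protection: promoters and
    ordinary CGIs within the protection radius of an IAP are pulled toward
    the IAP level in proportion to 1 − d/radius (edge-to-edge distance d).
    """
    df = annotation.features
    levels = np.array(
        [class_level(profile, c, spec) for c in df["feature_class"]], dtype=float
    )
    radius = profile.iap_protection_radius_bp
    if radius > 0:
        iap_level = class_level(profile, "IAP", spec)
        iaps = annotation.by_class("IAP")
        shielded = df["feature_class"].isin(["promoter", "CGI"]).to_numpy()
        for chrom in df.loc[shielded, "chrom"].unique():
            mask = shielded & (df["chrom"] == chrom).to_numpy()
            sub = df[mask]
            isub = iaps[iaps["chrom"] == chrom]
            d = _iap_distance(
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                isub["start"].to_numpy(),
                isub["end"].to_numpy(),
            )
            w = np.clip(1.0 - d / radius, 0.0, 1.0)
            levels[mask] = levels[mask] + w * (iap_level - levels[mask])
    return pd.DataFrame(
        {
            "feature_id": df["feature_id"],
            "feature_class": df["feature_class"],
            "true_fraction": levels,
        }
    ).set_index("feature_id")


def _per_cpg_levels(annotation, profile, spec):
    """True fraction for every CpG dyad, honouring feature and IAP context."""
    truth = ground_truth_levels(annotation, profile, spec)
    bulk = class_level(profile, "background", spec)
    out = {}
    df = annotation.features
    for chrom, sites in annotation.cpgs.items():
        level = np.full(sites.shape, bulk)
        sub = df[df["chrom"] == chrom]
        # later (nested / CGI-like) classes override earlier generic ones
        order = [
            "exon",
            "intron",
            "LINE1",
            "promoter",
            "CGI",
            "DMR_mat",
            "DMR_pat",
            "germline_CGI",
            "CGI_X",
            "IAP",
        ]
        for cls in order:
            csub = sub[sub["feature_class"] == cls].sort_values("start")
            if csub.empty:
                continue
            idx = assign_to_intervals(
                sites, csub["start"].to_numpy(), csub["end"].to_numpy()
            )
            hit = idx >= 0
            if hit.any():
                vals = truth.loc[csub["feature_id"].to_numpy()[idx[hit]]][
                    "true_fraction"
                ].to_numpy()
                level[hit] = vals
        out[chrom] = level
    return out


def simulate_methylome(
    annotation: FeatureSet,
    stages: list[StageSpec] | None = None,
    profile: DynamicsProfile | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate per-sample cytosine call tables (CG and CHH contexts).

    Returns a mapping sample_id -> call table with columns chrom, pos,
    strand, context, count_methylated, count_unmethylated.  Each CpG dyad
    yields one row per strand (top at the C position, bottom at position+1);
    coverage per strand is Poisson with half the sample's mean.  Bisulfite
    conversion failure inflates the apparent methylation of a site with true
    fraction m to m + (1−m)·ε and is the sole source of CHH methylation.
    """
    if stages is None:
        stages = default_stage_series(replicates=2)
    if profile is None:
        profile = DynamicsProfile()
    profile.validate()
    order = [stage_index(s.stage) for s in stages]
    if order != sorted(order):
        raise ConfigurationError("stages must be ordered by development")
    divs = [s.divisions for s in stages]
    if any(
        b < a
        for (ia, a), (ib, b) in zip(zip(order, divs), zip(order[1:], divs[1:]))
        if ib > ia
    ):
        raise ConfigurationError("divisions must be non-decreasing along stages")

    eps = profile.conversion_failure_rate
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(stages))
    out = {}
    for spec, child in zip(stages, children):
        rng = np.random.default_rng(child)
        levels = _per_cpg_levels(annotation, profile, spec)
        frames = []
        for chrom, sites in annotation.cpgs.items():
            m_obs = levels[chrom] + (1.0 - levels[chrom]) * eps
            for strand, offset in (("+", 0), ("-", 1)):
                cov = rng.poisson(spec.mean_coverage / 2.0, size=sites.size)
                meth = rng.binomial(cov, m_obs)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": sites + offset,
                            "strand": strand,
                            "context": "CG",
                            "count_methylated": meth,
                            "count_unmethylated": cov - meth,
                        }
                    )
                )
            chh = annotation.chh_sites.get(chrom, np.empty(0, dtype=np.int64))
            if chh.size:
                cov = rng.poisson(spec.mean_coverage, size=chh.size)
                meth = rng.binomial(cov, eps)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": chh,
                            "strand": "+",
                            "context": "CHH",
                            "count_methylated": meth,
                            "count_unmethylated": cov - meth,
                        }
                    )
                )
        out[spec.sample_id] = pd.concat(frames, ignore_index=True)
    return out


def simulate_female_epiblast_x_pool(
    annotation: FeatureSet, n_cells: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Pool of exclusively female epiblast cells under random X inactivation.

    Each cell independently inactivates one of its two X chromosomes with
    probability 1/2; X-linked CGIs are fully methylated on the inactive copy
    and unmethylated on the active one.  Every cell contributes one read per
    CpG drawn from a random allele, so the pooled expectation is 50%.
    Returns a CG call table restricted to X-linked CGI CpGs.
    """
    if n_cells <= 0:
        raise ConfigurationError("n_cells must be > 0")
    rng = np.random.default_rng(seed)
    x_cgis = annotation.by_class("CGI_X").sort_values(["chrom", "start"])
    frames = []
    inactive = rng.integers(0, 2, size=n_cells)  # which allele is inactive
    for chrom in x_cgis["chrom"].unique():
        sub = x_cgis[x_cgis["chrom"] == chrom]
        sites = annotation.cpgs[chrom]
        idx = assign_to_intervals(
            sites, sub["start"].to_numpy(), sub["end"].to_numpy()
        )
        sites = sites[idx >= 0]
        # sampled allele per cell per CpG; methylated iff it is the inactive X
        meth = np.empty(sites.size, dtype=np.int64)
        block = max(1, int(2e7) // max(n_cells, 1))
        for lo in range(0, sites.size, block):
            hi = min(lo + block, sites.size)
            picks = rng.integers(0, 2, size=(n_cells, hi - lo))
            meth[lo:hi] = (picks == inactive[:, None]).sum(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sites,
                    "strand": "+",
                    "context": "CG",
                    "count_methylated": meth,
                    "count_unmethylated": n_cells - meth,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom",
                "pos",
                "strand",
                "context",
                "count_methylated",
                "count_unmethylated",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# hairpin read simulator
# ---------------------------------------------------------------------------


@dataclass
class HairpinSimParams:
    """Dyad-state mixture and strand-switching for hairpin simulation.

    ``p_full``/``p_hemi``/``p_un`` give the per-dyad probabilities of fully
    methylated, hemimethylated, and unmethylated states (they must sum to 1).
    ``switch_prob`` only matters for the ``mixed`` mechanism: with that
    per-dyad probability the methylated strand of a hemimethylated dyad is
    redrawn uniformly instead of following the read's template strand
    (0 → passive, 1 → active).  ``missing_rate`` blanks states to '.'.
    """

    p_full: float = 0.10
    p_hemi: float = 0.50
    p_un: float = 0.40
    switch_prob: float = 0.5
    missing_rate: float = 0.0

    def validate(self):
        probs = (self.p_full, self.p_hemi, self.p_un)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("dyad-state probabilities outside [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("dyad-state probabilities must sum to 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ConfigurationError("switch_prob outside [0,1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate outside [0,1]")


def simulate_hairpin_reads(
    n_reads: int,
    n_positions: int = 5,
    mechanism: str = "passive",
    params: HairpinSimParams | None = None,
    seed: int = 0,
) -> list[HairpinRead]:
    """Simulate hairpin bisulfite reads over CpG dyads.

    passive: one template strand per read (top/bottom, equal probability);
    every hemimethylated dyad keeps its meC on that strand — replication
    without maintenance leaves the parental strand methylated.
    active: each hemimethylated dyad assigns its meC to top or bottom
    independently with probability 1/2 (strand-independent removal).
    mixed: interpolates via ``params.switch_prob``.
    """
    if n_reads <= 0:
        raise ConfigurationError("n_reads must be > 0")
    if n_positions < 1:
        raise ConfigurationError("n_positions must be >= 1")
    if mechanism not in ("passive", "active", "mixed"):
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    params = params or HairpinSimParams()
    params.validate()
    rng = np.random.default_rng(seed)
    cats = rng.choice(
        3, size=(n_reads, n_positions), p=[params.p_full, params.p_hemi, params.p_un]
    )
    template_top = rng.integers(0, 2, size=n_reads).astype(bool)
    if mechanism == "passive":
        hemi_top = np.broadcast_to(template_top[:, None], cats.shape)
    elif mechanism == "active":
        hemi_top = rng.integers(0, 2, size=cats.shape).astype(bool)
    else:
        switched = rng.random(cats.shape) < params.switch_prob
        coin = rng.integers(0, 2, size=cats.shape).astype(bool)
        hemi_top = np.where(switched, coin, template_top[:, None])
    states = np.where(cats == 0, "M", np.where(cats == 2, "U", ""))
    states = np.where(
        (cats == 1), np.where(hemi_top, "T", "B"), states
    )
    if params.missing_rate > 0:
        states = np.where(rng.random(cats.shape) < params.missing_rate, ".", states)
    return [
        HairpinRead(f"read_{i:06d}", "".join(row)) for i, row in enumerate(states)
    ]


# ---------------------------------------------------------------------------
# expression simulator
# ---------------------------------------------------------------------------


@dataclass
class ExpressionClusterSpec:
    """One planted co-expression cluster: per-sample mean trajectory + noise."""

    name: str
    n_genes: int
    trajectory: tuple[float, ...]
    noise_sd: float = 0.5


def default_cluster_specs(sample_keys: list[str]) -> list[ExpressionClusterSpec]:
    """Pluripotency-like and meiosis-like clusters over the default roster."""
    traj = {
        # fully expressed at E11.5, steep decline toward E16.5
        "pluripotency": {
            "E6.5": 2.0,
            "E9.5": 6.0,
            "E10.5": 8.0,
            "E11.5": 10.0,
            "E13.5_male": 4.0,
            "E13.5_female": 4.0,
            "E16.5_male": 0.5,
            "E16.5_female": 0.5,
        },
        # rises from E13.5, highest in female gonadal PGCs
        "meiosis": {
            "E6.5": 0.2,
            "E9.5": 0.2,
            "E10.5": 0.3,
            "E11.5": 0.5,
            "E13.5_male": 2.0,
            "E13.5_female": 8.0,
            "E16.5_male": 1.0,
            "E16.5_female": 9.0,
        },
    }
    return [
        ExpressionClusterSpec(
            name, 30, tuple(t[k] for k in sample_keys), noise_sd=0.5
        )
        for name, t in traj.items()
    ]


def simulate_expression(
    stages: list[StageSpec] | None = None,
    cluster_specs: list[ExpressionClusterSpec] | None = None,
    n_background: int = 940,
    background_mean_log: float = 1.0,
    background_noise_sd: float = 0.15,
    seed: int = 0,
):
    """Gene-by-sample expression matrix with known cluster labels.

    In-cluster genes follow their cluster's per-sample mean trajectory plus
    additive Gaussian noise (clipped at 0); background genes get a per-gene
    constant lognormal baseline with independent noise, so transcriptome
    complexity is held constant across samples.  Returns (matrix, labels).
    """
    if stages is None:
        stages = default_stage_series(replicates=1)
    sample_keys = [s.stage_key for s in stages]
    if cluster_specs is None:
        cluster_specs = default_cluster_specs(sample_keys)
    for cs in cluster_specs:
        if len(cs.trajectory) != len(sample_keys):
            raise ConfigurationError(
                f"cluster {cs.name!r}: trajectory length {len(cs.trajectory)} "
                f"does not match {len(sample_keys)} samples"
            )
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for cs in cluster_specs:
        base = np.asarray(cs.trajectory, dtype=float)
        noise = rng.normal(0.0, cs.noise_sd, size=(cs.n_genes, base.size))
        vals = np.clip(base[None, :] + noise, 0.0, None)
        if cs.noise_sd == 0:
            vals = np.tile(base, (cs.n_genes, 1))
        rows.append(vals)
        labels.extend([cs.name] * cs.n_genes)
        index.extend(f"{cs.name}_{i:04d}" for i in range(cs.n_genes))
    if n_background > 0:
        base = rng.lognormal(background_mean_log, 0.8, size=n_background)
        noise = rng.normal(
            0.0, background_noise_sd, size=(n_background, len(sample_keys))
        )
        vals = np.clip(base[:, None] * (1.0 + noise), 0.0, None)
        rows.append(vals)
        labels.extend(["background"] * n_background)
        index.extend(f"bg_{i:04d}" for i in range(n_background))
    matrix = pd.DataFrame(
        np.vstack(rows), index=pd.Index(index, name="gene"), columns=sample_keys
    )
    return matrix, pd.Series(labels, index=matrix.index, name="cluster")


def simulate_repeat_counts(
    stages: list[StageSpec] | None = None,
    total_reads: int = 1_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-target RNA-Seq read tallies with a female-E16.5 LINE1 burst.

    Targets are the LINE1Tf and LINE1A consensus sequences plus two
    constantly expressed single-copy comparator genes.  Returns
    (counts target×sample, total reads per sample).
    """
    if stages is None:
        stages = default_stage_series(replicates=1)
    rng = np.random.default_rng(seed)
    keys = [s.stage_key for s in stages]
    base = {
        "LINE1Tf": 0.001,
        "LINE1A": 0.0008,
        "Cnpy3": 0.0004,
        "Pdia5": 0.0003,
    }
    counts = {}
    for key, spec in zip(keys, stages):
        burst = 10.0 if (spec.stage == "E16.5" and spec.sex == "female") else 1.0
        counts[key] = [
            rng.poisson(total_reads * frac * (burst if t.startswith("LINE1") else 1.0))
            for t, frac in base.items()
        ]
    df = pd.DataFrame(counts, index=list(base))
    totals = pd.Series(total_reads, index=keys, name="total_reads")
    return df, totals
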