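"""End-to-end pipeline driver: simulate → quantify → classify → hairpin →
dilution fit → expression, with a hashed output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, dilution, expression, hairpin, io, quant
from . import synthetic
from .errors import ConfigurationError, PipelineStageError
from .stages import default_stage_series

log = logging.getLogger("pgcreprog")


@dataclass
class PipelineConfig:
    """Everything the demo pipeline needs: sizes, thresholds, seeds, paths."""

    chrom_lengths: dict = field(
        default_factory=lambda: {
            "chr1": 3_000_000,
            "chr2": 3_000_000,
            "chr3": 3_000_000,
            "chrX": 1_000_000,
        }
    )
    genome_overrides: dict = field(default_factory=dict)
    replicates: int = 1
    mean_coverage: float = 20.0
    divisions_per_interval: int = 2
    probe_window_bp: int = 5000
    conversion_probe_window_bp: int = 1000
    min_probe_count: int = 10
    min_chh_count: int = 20
    resistance_threshold: float = 25.0
    iap_cutoff_bp: int = 2000
    hairpin_reads: int = 2000
    hairpin_null_reads: int = 5000
    dilution_dyads: int = 10_000
    dilution_truth: dict = field(
        default_factory=lambda: {"p_maintenance": 0.1, "p_denovo": 0.0, "p_active": 0.05}
    )
    fit_grid_step: float = 0.02
    seed: int = 0
    output_dir: str = "pgcreprog_out"

    def validate(self):
        if not 0 <= self.resistance_threshold <= 100:
            raise ConfigurationError("resistance_threshold outside [0, 100]")
        if self.iap_cutoff_bp < 0 or self.min_probe_count < 0:
            raise ConfigurationError("negative threshold")
        if self.seed is None:
            raise ConfigurationError("an explicit seed is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded, so
        the same analysis in a different directory hashes identically)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, quiet: bool = False) -> dict:
    """Run every stage, writing outputs and a manifest under the output dir.

    Any stage failure aborts with the stage name; outputs of earlier stages
    are preserved.  Reruns with identical config and seed are byte-identical.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "config": config.config_hash()}
    manifest = {
        "tool": f"pgcreprog/{__version__}",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
        "outputs": {},
    }
    state: dict = {}

    def record(name: str, *paths):
        manifest["stages"].append(name)
        for p in paths:
            manifest["outputs"][str(Path(p).relative_to(outdir))] = _sha256(Path(p))

    def run_stage(name, fn):
        t0 = time.monotonic()
        if not quiet:
            log.info("stage %s ...", name)
        try:
            fn()
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        if not quiet:
            log.info("stage %s done in %.1fs", name, time.monotonic() - t0)

    # -- simulate ----------------------------------------------------------
    def stage_simulate():
        cfg = synthetic.SyntheticGenomeConfig(
            chrom_lengths=dict(config.chrom_lengths),
            seed=config.seed,
            **config.genome_overrides,
        )
        annotation = synthetic.generate_annotation(cfg)
        stages = default_stage_series(
            replicates=config.replicates,
            mean_coverage=config.mean_coverage,
            divisions_per_interval=config.divisions_per_interval,
        )
        profile = synthetic.DynamicsProfile()
        calls = synthetic.simulate_methylome(
            annotation, stages, profile, seed=config.seed
        )
        bed = outdir / "annotation.bed"
        io.write_features_bed(annotation, bed, **prov)
        paths = [bed]
        for sid, table in calls.items():
            p = outdir / "calls" / f"{sid}.tsv"
            io.write_cytosine_calls(table, p, **prov)
            paths.append(p)
        state.update(annotation=annotation, stages=stages, profile=profile, calls=calls)
        record("simulate", *paths)

    # -- quantify ----------------------------------------------------------
    def stage_quantify():
        annotation = state["annotation"]
        calls = state["calls"]
        probes = quant.tile_genome(annotation.chrom_lengths, config.probe_window_bp)
        probe_mat = quant.probe_methylation(calls, probes, config.min_probe_count)
        per_sample, per_stage = quant.global_summary(probe_mat)
        probes_1kb = quant.tile_genome(
            annotation.chrom_lengths, config.conversion_probe_window_bp
        )
        conv, _ = quant.conversion_efficiency(calls, probes_1kb, config.min_chh_count)
        feat_mat = quant.feature_methylation(calls, annotation, config.min_probe_count)
        p1 = outdir / "probe_matrix.tsv"
        p2 = outdir / "feature_matrix.tsv"
        p3 = outdir / "global_summary.tsv"
        io.write_methylation_matrix(probe_mat, p1, **prov)
        io.write_methylation_matrix(feat_mat, p2, **prov)
        io.write_table(per_stage.to_frame(), outdir / "stage_medians.tsv", **prov)
        io.write_table(
            per_sample.to_frame().join(conv.rename("fraction_converted")), p3, **prov
        )
        state.update(probe_mat=probe_mat, feat_mat=feat_mat)
        record(
            "quantify",
            p1,
            str(p1) + ".counts",
            p2,
            str(p2) + ".counts",
            p3,
            outdir / "stage_medians.tsv",
        )

    # -- classify ----------------------------------------------------------
    def stage_classify():
        annotation = state["annotation"]
        med = state["feat_mat"].stage_medians()
        late = classify.select_late_demethylaters(
            med, classify.SelectionRule(threshold=config.resistance_threshold)
        )
        res_m = classify.select_resistant(med, "male", threshold=config.resistance_threshold)
        res_f = classify.select_resistant(med, "female", threshold=config.resistance_threshold)
        prox = classify.annotate_iap_proximity(
            annotation.features, annotation.by_class("IAP"), config.iap_cutoff_bp
        )
        vecs = classify.identify_vecs(res_m.selected, res_f.selected, prox, med)
        p1 = outdir / "late_demethylaters.txt"
        p2 = outdir / "resistant_male.txt"
        p3 = outdir / "resistant_female.txt"
        p4 = outdir / "iap_proximity.tsv"
        p5 = outdir / "vecs.tsv"
        io.write_id_list(late.selected, p1, **prov)
        io.write_id_list(res_m.selected, p2, **prov)
        io.write_id_list(res_f.selected, p3, **prov)
        prox_out = prox.copy()
        prox_out["distance"] = prox_out["distance"].replace(np.inf, -1)
        io.write_table(prox_out, p4, **prov)
        io.write_table(vecs, p5, **prov)
        record("classify", p1, p2, p3, p4, p5)

    # -- hairpin -----------------------------------------------------------
    def stage_hairpin():
        rng_seed = config.seed
        observed = synthetic.simulate_hairpin_reads(
            config.hairpin_reads, mechanism="passive", seed=rng_seed + 1
        )
        passive = synthetic.simulate_hairpin_reads(
            config.hairpin_null_reads, mechanism="passive", seed=rng_seed + 2
        )
        active = synthetic.simulate_hairpin_reads(
            config.hairpin_null_reads, mechanism="active", seed=rng_seed + 3
        )
        j_obs = hairpin.strand_joint(observed)
        verdict = hairpin.compare_to_nulls(
            j_obs, hairpin.strand_joint(passive), hairpin.strand_joint(active)
        )
        verdict["strand_bias"] = hairpin.strand_bias_stat(j_obs)
        p1 = outdir / "hairpin_reads.tsv"
        p2 = outdir / "hairpin_joint.tsv"
        p3 = outdir / "hairpin_verdict.json"
        io.write_hairpin_reads(observed, p1, **prov)
        io.write_table(j_obs.to_frame(), p2, **prov)
        p3.write_text(json.dumps(verdict, indent=2, sort_keys=True) + "\n")
        record("hairpin", p1, p2, p3)

    # -- dilution fit ------------------------------------------------------
    def stage_dilution():
        truth = dilution.DyadDynamicsParams(**config.dilution_truth)
        rng = np.random.default_rng(config.seed + 11)
        divisions = [2, 2, 2]
        traj = dilution.trajectory((1.0, 0.0, 0.0), truth, sum(divisions))
        idx = np.cumsum([0] + divisions)
        counts = np.array(
            [rng.multinomial(config.dilution_dyads, traj[i]) for i in idx]
        )
        result = dilution.fit(counts, divisions, grid_step=config.fit_grid_step)
        payload = {
            "true_params": asdict(truth),
            "fitted_params": asdict(result.params),
            "log_likelihood": result.log_likelihood,
            "counts": counts.tolist(),
            "divisions": divisions,
        }
        p1 = outdir / "dilution_fit.json"
        p1.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        p2 = outdir / "dilution_pm_profile.tsv"
        io.write_table(result.pm_profile, p2, index=False, **prov)
        record("dilution_fit", p1, p2)

    # -- expression --------------------------------------------------------
    def stage_expression():
        matrix, labels = synthetic.simulate_expression(seed=config.seed + 21)
        clusters, _ = expression.cluster_profiles(matrix)
        counts, totals = synthetic.simulate_repeat_counts(seed=config.seed + 22)
        frac = expression.repeat_expression_fraction(counts, totals)
        p1 = outdir / "expression.tsv"
        p2 = outdir / "clusters.tsv"
        p3 = outdir / "repeat_fractions.tsv"
        io.write_expression(matrix, p1, **prov)
        rows = [
            {"cluster_id": c.cluster_id, "size": c.size,
             "peak_stage": c.peak_stage(), "members": ",".join(c.members)}
            for c in clusters
        ]
        io.write_table(pd.DataFrame(rows), p2, index=False, **prov)
        io.write_table(frac, p3, **prov)
        record("expression", p1, p2, p3)

    for name, fn in [
        ("simulate", stage_simulate),
        ("quantify", stage_quantify),
        ("classify", stage_classify),
        ("hairpin", stage_hairpin),
        ("dilution_fit", stage_dilution),
        ("expression", stage_expression),
    ]:
        run_stage(name, fn)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
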