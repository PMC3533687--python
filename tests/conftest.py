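import numpy as np
import pandas as pd
import pytest

from pgcreprog import synthetic
from pgcreprog.stages import StageSpec


@pytest.fixture(scope="session")
def small_genome_config():
    return synthetic.SyntheticGenomeConfig(
        chrom_lengths={"chr1": 500_000, "chrX": 300_000},
        n_cgi=20,
        n_cgi_x=10,
        n_dmr_mat=5,
        n_dmr_pat=3,
        n_germline_cgi=5,
        n_promoter=15,
        n_promoter_near_iap=5,
        n_iap=8,
        n_line1=10,
        n_exon=10,
        n_intron=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def annotation(small_genome_config):
    return synthetic.generate_annotation(small_genome_config)


@pytest.fixture(scope="session")
def default_stages():
    from pgcreprog.stages import default_stage_series

    return default_stage_series(replicates=2, mean_coverage=30)


@pytest.fixture(scope="session")
def calls(annotation, default_stages):
    return synthetic.simulate_methylome(annotation, default_stages, seed=7)


def make_calls(rows):
    """Build a call table from (chrom, pos, strand, context, meth, unmeth) rows."""
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "strand",
            "context",
            "count_methylated",
            "count_unmethylated",
        ],
    )
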