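"""Developmental stage roster and sample identity conventions.

The analysis covers the mouse germline time course from E6.5 epiblast through
E16.5 primordial germ cells (PGCs).  Samples before E13.5 are mixed-sex pools;
E13.5 and E16.5 gonadal PGCs are sexed.  A sample is identified by
``{stage}_{sex}_r{replicate}`` and stage-level summaries are keyed by
``{stage}`` for mixed pools or ``{stage}_{sex}`` for sexed ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

STAGE_ORDER = ("E6.5", "E9.5", "E10.5", "E11.5", "E13.5", "E16.5")
SEXES = ("male", "female", "mixed")


def stage_index(stage: str) -> int:
    try:
        return STAGE_ORDER.index(stage)
    except ValueError:
        raise ConfigurationError(
            f"unknown stage {stage!r}; expected one of {STAGE_ORDER}"
        ) from None


@dataclass(frozen=True)
class StageSpec:
    """One sequenced sample: stage, sex, replicate, divisions, coverage.

    ``divisions`` is the cumulative number of cell divisions since E6.5 and
    drives passive dilution of methylation; ``mean_coverage`` is the mean
    sequencing depth per CpG (reads, both strands pooled).
    """

    stage: str
    sex: str
    replicate: int = 1
    divisions: int = 0
    mean_coverage: float = 20.0

    def __post_init__(self):
        stage_index(self.stage)
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.divisions < 0:
            raise ConfigurationError("divisions must be >= 0")
        if self.mean_coverage <= 0:
            raise ConfigurationError("mean coverage must be > 0")

    @property
    def sample_id(self) -> str:
        return f"{self.stage}_{self.sex}_r{self.replicate}"

    @property
    def stage_key(self) -> str:
        return stage_key(self.stage, self.sex)


def stage_key(stage: str, sex: str = "mixed") -> str:
    """Column key for stage-level summaries."""
    return stage if sex == "mixed" else f"{stage}_{sex}"


def parse_sample_id(sample_id: str):
    """Split ``{stage}_{sex}_r{replicate}`` back into its parts.

    Returns (stage, sex, replicate) or (None, None, None) when the id does
    not follow the convention (hand-made fixtures are allowed to deviate).
    """
    parts = sample_id.rsplit("_", 2)
    if len(parts) == 3 and parts[0] in STAGE_ORDER and parts[1] in SEXES:
        rep = parts[2]
        if rep.startswith("r") and rep[1:].isdigit():
            return parts[0], parts[1], int(rep[1:])
    return None, None, None


def default_stage_series(
    replicates: int = 1,
    mean_coverage: float = 20.0,
    divisions_per_interval: int = 2,
) -> list[StageSpec]:
    """The default eight-sample roster of the time course.

    E6.5 epiblast and migrating E9.5–E11.5 PGCs are mixed-sex pools; E13.5
    and E16.5 PGCs are sexed.  Cumulative divisions grow by
    ``divisions_per_interval`` per stage interval (the germline literature
    gives no exact cell-cycle counts, so this is configuration, not fact).
    """
    d = divisions_per_interval
    roster = [
        ("E6.5", "mixed", 0),
        ("E9.5", "mixed", d),
        ("E10.5", "mixed", 2 * d),
        ("E11.5", "mixed", 3 * d),
        ("E13.5", "male", 4 * d),
        ("E13.5", "female", 4 * d),
        ("E16.5", "male", 5 * d),
        ("E16.5", "female", 5 * d),
    ]
    return [
        StageSpec(stage, sex, rep, div, mean_coverage)
        for stage, sex, div in roster
        for rep in range(1, replicates + 1)
    ]
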