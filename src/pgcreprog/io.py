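"""Readers and writers for the package's text dialects.

Formats: per-cytosine call tables (TSV: chrom, pos, strand, context,
count_methylated, count_unmethylated), BED6 feature annotations with the
class token in the name field, hairpin dyad-state strings, expression and
methylation matrices.  All writers emit '#'-prefixed provenance comment
lines (tool version, seed, config hash) that every reader skips; none of
them write wall-clock timestamps, so outputs are byte-identical across
reruns.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError
from .features import FEATURE_CLASSES, FeatureSet
from .hairpin import DYAD_STATES, HairpinRead
from .quant import CALL_COLUMNS, MethylationMatrix, sample_metadata

_CONTEXTS = ("CG", "CHH")


def provenance_lines(**fields) -> list[str]:
    parts = [f"tool=pgcreprog/{__version__}"] + [
        f"{k}={v}" for k, v in fields.items() if v is not None
    ]
    return ["# " + " ".join(parts)]


def _write_lines(path, header_lines, body: str):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        fh.write(body)


# -- cytosine calls ---------------------------------------------------------


def write_cytosine_calls(calls: pd.DataFrame, path, **provenance):
    body = calls[list(CALL_COLUMNS)].to_csv(sep="\t", header=False, index=False)
    _write_lines(path, provenance_lines(**provenance), body)


def read_cytosine_calls(path) -> pd.DataFrame:
    """Parse a cytosine call table, validating every row.

    Malformed rows raise :class:`ParseError` carrying the line number; an
    empty file yields an empty table with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=list(CALL_COLUMNS),
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
            },
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(CALL_COLUMNS))
    except Exception as exc:  # malformed structure: locate the line
        raise _locate_call_error(path) or ParseError(str(exc)) from exc
    if df.empty:
        warnings.warn(f"empty cytosine call file: {path}")
        return df
    ok_context = df["context"].isin(_CONTEXTS)
    numeric = df[["pos", "count_methylated", "count_unmethylated"]].apply(
        pd.to_numeric, errors="coerce"
    )
    ok_counts = (
        numeric.notna().all(axis=1)
        & (numeric["count_methylated"] >= 0)
        & (numeric["count_unmethylated"] >= 0)
        & (numeric % 1 == 0).all(axis=1)
    )
    ok_strand = df["strand"].isin(["+", "-"])
    bad = ~(ok_context & ok_counts & ok_strand)
    if bad.any():
        raise _locate_call_error(path)
    df[["pos", "count_methylated", "count_unmethylated"]] = numeric.astype(np.int64)
    return df


def _locate_call_error(path):
    """Slow scan to report the first malformed call line."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                return ParseError(f"expected 6 columns, got {len(fields)}", lineno)
            if fields[3] not in _CONTEXTS:
                return ParseError(
                    f"unknown context token {fields[3]!r} (expected CG or CHH)",
                    lineno,
                )
            if fields[2] not in ("+", "-"):
                return ParseError(f"bad strand {fields[2]!r}", lineno)
            for col in (1, 4, 5):
                try:
                    v = int(fields[col])
                except ValueError:
                    return ParseError(f"non-integer field {fields[col]!r}", lineno)
                if col != 1 and v < 0:
                    return ParseError(f"negative count {v}", lineno)
    return None


# -- BED6 features ----------------------------------------------------------


def write_features_bed(annotation: FeatureSet, path, **provenance):
    df = annotation.features
    body_df = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["feature_class"] + ":" + df["feature_id"],
            "score": 0,
            "strand": df["strand"],
        }
    )
    header = provenance_lines(**provenance) + [
        "# chrom_lengths " + ",".join(f"{c}:{l}" for c, l in annotation.chrom_lengths.items())
    ]
    _write_lines(path, header, body_df.to_csv(sep="\t", header=False, index=False))


def read_features_bed(path) -> FeatureSet:
    """Parse BED6 features with the class token in the name field."""
    path = Path(path)
    chrom_lengths: dict[str, int] = {}
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# chrom_lengths "):
                    for tok in line[len("# chrom_lengths "):].split(","):
                        c, l = tok.split(":")
                        chrom_lengths[c] = int(l)
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"expected 6 BED columns, got {len(fields)}", lineno)
            chrom, start, end, name, _score, strand = fields
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer coordinates", lineno) from None
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", lineno)
            if ":" in name:
                cls, fid = name.split(":", 1)
            else:
                cls, fid = name, f"{name}_{lineno}"
            if cls not in FEATURE_CLASSES:
                raise ParseError(
                    f"unknown class token {cls!r}; allowed: {', '.join(FEATURE_CLASSES)}",
                    lineno,
                )
            records.append((chrom, start, end, fid, cls, strand))
    df = pd.DataFrame(
        records,
        columns=["chrom", "start", "end", "feature_id", "feature_class", "strand"],
    )
    if not chrom_lengths:
        chrom_lengths = {
            c: int(g["end"].max()) for c, g in df.groupby("chrom")
        }
    fs = FeatureSet(df, chrom_lengths)
    fs.validate()
    return fs


# -- hairpin reads ----------------------------------------------------------


def write_hairpin_reads(reads: list[HairpinRead], path, **provenance):
    body = "".join(f"{r.read_id}\t{r.states}\n" for r in reads)
    _write_lines(path, provenance_lines(**provenance), body)


def read_hairpin_reads(path) -> list[HairpinRead]:
    reads = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", lineno)
            rid, states = fields
            bad = set(states) - set(DYAD_STATES)
            if bad:
                raise ParseError(f"invalid dyad states {sorted(bad)}", lineno)
            reads.append(HairpinRead(rid, states))
    return reads


# -- matrices ---------------------------------------------------------------


def write_expression(matrix: pd.DataFrame, path, **provenance):
    body = matrix.to_csv(sep="\t", index_label="gene")
    _write_lines(path, provenance_lines(**provenance), body)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene")


def write_methylation_matrix(matrix: MethylationMatrix, path, **provenance):
    """Percent matrix as TSV with sample metadata in a sidecar comment header."""
    header = provenance_lines(**provenance)
    for sid, row in matrix.samples.iterrows():
        header.append(
            f"# sample={sid} stage={row['stage']} sex={row['sex']} replicate={row['replicate']}"
        )
    body = matrix.percent.to_csv(sep="\t", index_label="id", na_rep="NA")
    _write_lines(path, header, body)
    counts_path = Path(str(path) + ".counts")
    _write_lines(
        counts_path,
        provenance_lines(**provenance),
        matrix.counts.to_csv(sep="\t", index_label="id"),
    )


def read_methylation_matrix(path) -> MethylationMatrix:
    percent = pd.read_csv(path, sep="\t", comment="#", index_col="id", na_values="NA")
    counts_path = Path(str(path) + ".counts")
    if counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col="id")
    else:
        counts = pd.DataFrame(np.nan, index=percent.index, columns=percent.columns)
    meta_rows = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# sample="):
                kv = dict(tok.split("=", 1) for tok in line[2:].split())
                rep = kv.get("replicate")
                meta_rows[kv["sample"]] = {
                    "stage": kv.get("stage"),
                    "sex": kv.get("sex"),
                    "replicate": int(rep) if rep not in (None, "None") else None,
                }
    if meta_rows:
        samples = pd.DataFrame(meta_rows).T.reindex(percent.columns)
        samples.index.name = "sample"
    else:
        samples = sample_metadata(percent.columns)
    return MethylationMatrix(percent, counts, samples)


def write_id_list(ids, path, **provenance):
    body = "".join(f"{fid}\n" for fid in sorted(ids))
    _write_lines(path, provenance_lines(**provenance), body)


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [l.strip() for l in fh if l.strip() and not l.startswith("#")]


def write_table(df: pd.DataFrame, path, index=True, **provenance):
    _write_lines(
        path, provenance_lines(**provenance), df.to_csv(sep="\t", index=index)
    )
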