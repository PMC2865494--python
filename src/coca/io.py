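"""Readers and writers for the plain-text formats the tool consumes.

Expression matrices come as tab- or comma-delimited tables (first column the
gene id, header row the sample ids) or as GCT 1.2 (two header lines, a
Description column that is ignored).  Gene sets are one-id-per-line lists or
GMT records (name, description, ids...).  All matching is by exact string id.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .bagging import ParticipationResult
from .data import ExpressionMatrix

__all__ = [
    "load_expression",
    "write_expression",
    "load_geneset",
    "load_gmt",
    "write_ranking",
    "load_ranking",
    "write_manifest",
]

RANKING_COLUMNS = [
    "rank",
    "gene_id",
    "participation_bagged",
    "abs_participation",
    "participation_sd",
    "method",
]


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        return "gct"
    if path.suffix.lower() == ".csv":
        return "csv"
    if "\t" in first:
        return "tsv"
    return "csv" if "," in first else "tsv"


def load_expression(path, dialect: str | None = None) -> ExpressionMatrix:
    """Read an expression table (TSV/CSV/GCT 1.2) into an ExpressionMatrix."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"expression file not found: {path}")
    dialect = dialect or _sniff_dialect(path)
    try:
        if dialect == "gct":
            df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0,
                             float_precision="round_trip")
            drop = [c for c in df.columns[:1] if c.lower() == "description"]
            df = df.drop(columns=drop)
        elif dialect in ("tsv", "csv"):
            df = pd.read_csv(path, sep="\t" if dialect == "tsv" else ",",
                             index_col=0, float_precision="round_trip")
        else:
            raise InputError(f"unknown dialect {dialect!r}")
    except pd.errors.ParserError as exc:  # ragged rows etc.; pandas names the line
        raise InputError(f"malformed expression file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene ids in {path}: {dups[:10]}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise InputError(f"missing values in {path} for genes {bad[:10]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InputError(f"non-numeric expression values in {path}: {exc}") from exc
    return ExpressionMatrix(values, df.index.to_numpy(), df.columns.to_numpy())


_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_expression(x: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    path = Path(path)
    df = x.to_dataframe()
    if dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{x.n_genes}\t{x.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format=_FLOAT_FMT)
    elif dialect in ("tsv", "csv"):
        df.to_csv(path, sep="\t" if dialect == "tsv" else ",",
                  index_label="gene_id", float_format=_FLOAT_FMT)
    else:
        raise InputError(f"unknown dialect {dialect!r}")


def _parse_gmt_line(line: str, lineno: int) -> tuple[str, set]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise InputError(f"GMT line {lineno}: need name, description and >= 1 gene id")
    genes = {g for g in parts[2:] if g}
    return parts[0], genes


def load_gmt(path) -> dict[str, set]:
    """All records of a GMT file as {set name: gene-id set}."""
    path = Path(path)
    sets: dict[str, set] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            name, genes = _parse_gmt_line(line, i)
            sets[name] = genes
    if not sets:
        raise InputError(f"no gene sets found in {path}")
    return sets


def load_geneset(path, name: str | None = None) -> set:
    """A gene-id set from a plain list (one id per line, '#' comments allowed)
    or a GMT file (first record unless ``name`` picks one)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene set file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    if path.suffix.lower() == ".gmt" or first.count("\t") >= 2:
        sets = load_gmt(path)
        if name is None:
            return next(iter(sets.values()))
        if name not in sets:
            raise InputError(f"gene set {name!r} not in {path} (has {sorted(sets)})")
        return sets[name]
    genes: set = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    if not genes:
        raise InputError(f"no gene ids found in {path}")
    return genes


def write_ranking(result, path, method: str = "coca") -> None:
    """Write a ranking table (TSV) from a ParticipationResult or DataFrame."""
    if isinstance(result, ParticipationResult):
        df = result.to_frame(method=method)
    elif isinstance(result, pd.DataFrame):
        df = result
    else:
        raise InputError(f"cannot write ranking from {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_ranking(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"ranking file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    missing = [c for c in ("gene_id",) if c not in df.columns]
    if missing:
        raise InputError(f"ranking file {path} lacks columns {missing}")
    return df


def write_manifest(path, seed=None, config: dict | None = None, **extra) -> dict:
    """Reproducibility manifest (seed, config hash, versions) written as JSON."""
    import coca

    config = config or {}
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "coca": coca.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
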