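"""Reading and writing the on-disk formats, TPM normalization, and the
expressed-gene filter that defines the analysis universe.

Formats
-------
* expression matrix: TSV, first column ``gene_id``, header = sample ids
* sample sheet: TSV with columns ``sample_id, tissue, ct, replicate, condition``
* gene sets: GMT (name <tab> description <tab> members...)
* annotation: BED6 plus a seventh ``biotype`` column
* run manifest: JSON (parameters, seed, versions)
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .experiment import ExpressionExperiment, GeneSetCollection, validate_annotation

__all__ = [
    "read_experiment",
    "write_experiment",
    "counts_to_tpm",
    "filter_expressed",
    "read_gmt",
    "write_gmt",
    "read_annotation_bed",
    "write_annotation_bed",
    "write_manifest",
]


def read_experiment(matrix_path, samples_path, unit: str = "counts") -> ExpressionExperiment:
    """Read a matrix TSV and its sample sheet into an experiment.

    Matrix columns are aligned to sample-sheet rows by sample id; a mismatch
    between the two id sets is fatal and lists the offending ids.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in matrix {matrix_path}: {exc}") from exc
    sheet = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet must have a sample_id column")
    sheet = sheet.set_index("sample_id")
    mat.columns = mat.columns.astype(str)
    return ExpressionExperiment(mat, sheet, unit=unit)


def write_experiment(exp: ExpressionExperiment, matrix_path, samples_path) -> None:
    exp.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    exp.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")


def counts_to_tpm(exp: ExpressionExperiment, lengths) -> ExpressionExperiment:
    """Length-normalize counts to transcripts per million.

    Per sample, ``tpm_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j)`` with L in
    base pairs. Column sums are exactly 1e6 (up to float error).
    """
    lengths = pd.Series(lengths).reindex(exp.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for genes {missing[:10]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = exp.values.div(lengths, axis=0)
    total = rate.sum(axis=0)
    if (total <= 0).any():
        bad = total.index[total <= 0].tolist()
        raise ValueError(f"zero total expression rate in samples {bad}")
    tpm = rate.div(total, axis=1) * 1e6
    return ExpressionExperiment(tpm, exp.samples.copy(), unit="TPM")


def filter_expressed(exp: ExpressionExperiment, min_tpm: float = 0.0) -> ExpressionExperiment:
    """Keep genes expressed above ``min_tpm`` in *every* sample.

    The default (strictly greater than 0 everywhere) defines the background
    universe for all downstream enrichment. Idempotent.
    """
    if exp.unit != "TPM":
        raise ValueError("filter_expressed expects a TPM experiment")
    keep = (exp.values > min_tpm).all(axis=1)
    if not keep.any():
        raise ValueError("no gene passes the expressed filter; degenerate analysis")
    return ExpressionExperiment(exp.values.loc[keep].copy(), exp.samples.copy(), unit="TPM")


# -- gene sets (GMT) ----------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, description, *members = parts
        members = frozenset(m for m in members if m)
        if not members:
            raise ValueError(f"gene set {name!r} has no members")
        sets[name] = members
        desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# -- annotation (BED6 + biotype) ----------------------------------------------

_BED_COLS = ["chrom", "start", "end", "gene_id", "score", "strand", "biotype"]


def read_annotation_bed(path) -> pd.DataFrame:
    """Read a BED6+1 annotation (7th column = biotype); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS)
    return validate_annotation(df)


def write_annotation_bed(annot: pd.DataFrame, path) -> None:
    out = annot.copy()
    if "score" not in out.columns:
        out["score"] = 0
    out[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


# -- run manifest -------------------------------------------------------------


def write_manifest(path, params: Mapping, seed: int | None = None) -> None:
    """Write a JSON manifest of run parameters and library versions."""
    import scipy
    manifest = {
        "params": dict(params),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
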