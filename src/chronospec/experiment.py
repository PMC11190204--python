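"""Core in-memory containers for multi-tissue circadian expression data.

The universal input to every stage is an :class:`ExpressionExperiment`: a
gene x sample matrix (counts or TPM) together with a sample sheet recording,
for every sample, the tissue of origin, the circadian time (CT, hours in
[0, 24)), the replicate number and the experimental condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("tissue", "ct", "replicate", "condition")

BIOTYPES = frozenset({"coding", "lncRNA", "antisense", "bidirectional"})


@dataclass
class ExpressionExperiment:
    """A gene x sample expression matrix with its sample sheet.

    Parameters
    ----------
    values
        DataFrame, rows indexed by unique gene ids, columns by sample ids.
        All entries non-negative.
    samples
        DataFrame indexed by sample id with columns ``tissue``, ``ct``
        (circadian time, hours in [0, 24)), ``replicate`` (positive int)
        and ``condition``. Row order defines the column order of ``values``.
    unit
        ``"counts"`` or ``"TPM"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:10]}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        mat_ids = list(self.values.columns)
        sheet_ids = list(self.samples.index)
        if set(mat_ids) != set(sheet_ids):
            only_mat = sorted(set(mat_ids) - set(sheet_ids))
            only_sheet = sorted(set(sheet_ids) - set(mat_ids))
            raise ValueError(
                "sample ids of matrix and sheet disagree; "
                f"matrix-only={only_mat[:10]}, sheet-only={only_sheet[:10]}"
            )
        # sheet order is authoritative
        self.values = self.values.loc[:, sheet_ids]
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric entries")
        if np.any(vals < 0):
            raise ValueError("expression matrix contains negative entries")
        ct = self.samples["ct"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ct)) or np.any(ct < 0) or np.any(ct >= 24):
            raise ValueError("circadian times must be finite and in [0, 24)")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique circadian times (the sampling grid)."""
        return np.unique(self.samples["ct"].to_numpy(dtype=float))

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique().tolist())

    def subset(
        self,
        tissue: str | None = None,
        condition: str | None = None,
        genes: Iterable[str] | None = None,
    ) -> "ExpressionExperiment":
        """Restrict to a tissue and/or condition and/or gene list."""
        mask = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if not mask.any():
            raise ValueError(f"no samples match tissue={tissue!r} condition={condition!r}")
        sheet = self.samples.loc[mask]
        vals = self.values.loc[:, sheet.index]
        if genes is not None:
            genes = list(genes)
            missing = [g for g in genes if g not in self.values.index]
            if missing:
                raise KeyError(f"genes absent from experiment: {missing[:10]}")
            vals = vals.loc[genes]
        return ExpressionExperiment(vals.copy(), sheet.copy(), unit=self.unit)

    def tissue_timepoint_means(self, condition: str | None = None) -> pd.DataFrame:
        """Replicate-averaged expression, columns MultiIndex (tissue, ct)."""
        sheet = self.samples
        if condition is not None:
            sheet = sheet[sheet["condition"] == condition]
        key = pd.MultiIndex.from_frame(sheet[["tissue", "ct"]])
        grouped = self.values.loc[:, sheet.index].T.groupby(key).mean().T
        grouped.columns = pd.MultiIndex.from_tuples(grouped.columns, names=["tissue", "ct"])
        return grouped.sort_index(axis=1)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        sets = {}
        for name, members in d.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = members
        return cls(sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def union(self, names: Iterable[str] | None = None) -> frozenset[str]:
        names = list(self.sets) if names is None else list(names)
        out: frozenset[str] = frozenset()
        for n in names:
            out |= self.sets[n]
        return out

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a background universe; drop emptied sets."""
        uni = frozenset(universe)
        kept = {n: s & uni for n, s in self.sets.items() if s & uni}
        return GeneSetCollection(kept, dict(self.descriptions))


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-annotation table.

    Expected columns: ``gene_id``, ``chrom``, ``start``, ``end`` (0-based,
    half-open), ``strand`` (+/-), ``biotype`` (coding, lncRNA, antisense,
    bidirectional). Returns the table indexed by gene_id.
    """
    req = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
    missing = [c for c in req if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (annot["start"] >= annot["end"]).any():
        bad = annot.loc[annot["start"] >= annot["end"], "gene_id"].tolist()
        raise ValueError(f"start >= end for genes {bad[:10]}")
    bad_bt = set(annot["biotype"]) - BIOTYPES
    if bad_bt:
        raise ValueError(f"unknown biotypes: {sorted(bad_bt)}")
    out = annot.set_index("gene_id", drop=False)
    if not out.index.is_unique:
        raise ValueError("duplicate gene_id in annotation")
    return out
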