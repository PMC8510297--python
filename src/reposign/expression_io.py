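"""Reading, validation and harmonization of per-cohort expression matrices.

A cohort is a genes x samples matrix of log2-scale expression values plus a
two-class phenotype label per sample (``case`` vs ``control``).  Matrices
arrive as tab-separated text with the first column holding the feature
(probe or gene symbol) and the header row holding sample ids; labels arrive
as a two-column TSV mapping sample id to class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_TOKENS = ("case", "control")

#: 99th-percentile cutoff above which a matrix is assumed to be on a linear
#: (unlogged) intensity scale and is log2(x+1)-transformed.
LINEAR_SCALE_THRESHOLD = 50.0


class ExpressionFormatError(ValueError):
    """Malformed expression matrix or labels file."""


class ValidationError(ValueError):
    """Input violates a dataset invariant (e.g. a class is empty)."""


@dataclass
class ExpressionDataset:
    """One cohort: expression matrix, labels and minimal provenance.

    Parameters
    ----------
    dataset_id:
        Short identifier for the cohort (e.g. a repository accession).
    expr:
        Genes x samples matrix; rows indexed by unique gene symbols,
        columns by sample ids.  Missing entries are NaN.
    labels:
        Per-sample class, one of ``case`` / ``control``, indexed like the
        matrix columns.
    """

    dataset_id: str
    expr: pd.DataFrame
    labels: pd.Series
    platform: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.expr.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValidationError(
                f"{self.dataset_id}: samples without a label: {missing}"
            )
        bad = set(self.labels.unique()) - set(CLASS_TOKENS)
        if bad:
            raise ValidationError(
                f"{self.dataset_id}: unknown class tokens {sorted(bad)}; "
                f"expected {CLASS_TOKENS}"
            )
        counts = self.labels.value_counts()
        if counts.get("case", 0) < 1 or counts.get("control", 0) < 1:
            raise ValidationError(
                f"{self.dataset_id}: need at least one case and one control "
                f"(got {counts.to_dict()})"
            )
        if self.expr.index.has_duplicates:
            dups = self.expr.index[self.expr.index.duplicated()].unique()
            raise ValidationError(
                f"{self.dataset_id}: duplicate gene symbols, e.g. {list(dups[:5])}"
            )
        all_missing = self.expr.columns[self.expr.isna().all(axis=0)]
        if len(all_missing):
            raise ValidationError(
                f"{self.dataset_id}: entirely missing sample columns: "
                f"{list(all_missing)}"
            )

    # -- convenience accessors -------------------------------------------

    @property
    def n_case(self) -> int:
        return int((self.labels == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == "control").sum())

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    def case_matrix(self) -> pd.DataFrame:
        return self.expr.loc[:, self.labels == "case"]

    def control_matrix(self) -> pd.DataFrame:
        return self.expr.loc[:, self.labels == "control"]

    def swap_labels(self) -> "ExpressionDataset":
        """Return a copy with case/control labels exchanged."""
        swapped = self.labels.map({"case": "control", "control": "case"})
        return ExpressionDataset(
            self.dataset_id, self.expr.copy(), swapped, self.platform, dict(self.meta)
        )


def read_expression_table(
    matrix_path, labels_path, dataset_id: str, platform: str = ""
) -> ExpressionDataset:
    """Read a TSV expression matrix and its labels file into a dataset.

    Samples present in the matrix but absent from the labels file are
    dropped with a warning; a label class outside {case, control} raises
    :class:`ValidationError`.
    """
    try:
        expr = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExpressionFormatError(f"cannot parse matrix {matrix_path}: {exc}")
    if expr.shape[1] == 0:
        raise ExpressionFormatError(f"{matrix_path}: no sample columns in header")
    non_numeric = [c for c in expr.columns if not np.issubdtype(expr[c].dtype, np.number)]
    if non_numeric:
        raise ExpressionFormatError(
            f"{matrix_path}: non-numeric columns {non_numeric}"
        )
    labels_df = pd.read_csv(labels_path, sep="\t", header=0)
    if labels_df.shape[1] < 2:
        raise ExpressionFormatError(f"{labels_path}: expected two columns")
    labels = pd.Series(
        labels_df.iloc[:, 1].astype(str).values,
        index=labels_df.iloc[:, 0].astype(str).values,
    )
    expr.columns = expr.columns.astype(str)
    unlabeled = [s for s in expr.columns if s not in labels.index]
    if unlabeled:
        logger.warning(
            "%s: dropping %d unlabeled sample(s): %s",
            dataset_id, len(unlabeled), unlabeled,
        )
        expr = expr.drop(columns=unlabeled)
    labels = labels.reindex(expr.columns)
    return ExpressionDataset(dataset_id, expr, labels, platform=platform)


def write_expression_dataset(ds: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write a dataset back to the TSV formats ``read_expression_table`` reads."""
    out = ds.expr.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t", na_rep="NA")
    lab = ds.labels.rename("class").rename_axis("sample").reset_index()
    lab.to_csv(labels_path, sep="\t", index=False)


def collapse_probes(expr: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe x sample matrix to gene x sample by per-sample mean.

    Multiple probes mapping to one gene are summarized by the arithmetic
    mean; probes absent from the mapping are dropped.
    """
    if not probe_to_gene:
        raise ValidationError("probe-to-gene mapping is empty")
    mapped = expr.index.intersection(list(probe_to_gene))
    if len(mapped) == 0:
        raise ValidationError("no probe in the matrix is covered by the mapping")
    sub = expr.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes).mean()
    return collapsed


def ensure_log_scale(
    ds: ExpressionDataset, threshold: float = LINEAR_SCALE_THRESHOLD
) -> ExpressionDataset:
    """Log2-transform a dataset that looks linear-scale; otherwise return as is.

    The heuristic: if the 99th percentile of the values exceeds ``threshold``
    the matrix is treated as linear intensities and transformed by
    log2(x + 1).  The decision is recorded in ``meta['log_transformed']``,
    which makes the operation idempotent.
    """
    vals = ds.expr.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    p99 = float(np.percentile(finite, 99)) if finite.size else 0.0
    if p99 <= threshold:
        meta = dict(ds.meta)
        meta.setdefault("log_transformed", False)
        return ExpressionDataset(ds.dataset_id, ds.expr, ds.labels, ds.platform, meta)
    if np.nanmin(vals) < 0:
        raise ValidationError(
            f"{ds.dataset_id}: looks linear-scale (p99={p99:.1f}) but has "
            "negative values; cannot log-transform"
        )
    logger.info("%s: p99=%.1f > %.0f, applying log2(x+1)", ds.dataset_id, p99, threshold)
    meta = dict(ds.meta)
    meta["log_transformed"] = True
    return ExpressionDataset(
        ds.dataset_id, np.log2(ds.expr + 1.0), ds.labels, ds.platform, meta
    )


def shared_gene_universe(
    datasets: Sequence[ExpressionDataset], min_fraction: float = 1.0
) -> list[str]:
    """Genes measured in at least ceil(min_fraction * n_datasets) cohorts.

    Returned sorted lexicographically.  With ``min_fraction=1`` this is the
    plain intersection; an empty result is valid, not an error.
    """
    if len(datasets) < 2:
        raise ValidationError("need at least 2 datasets to form a gene universe")
    if not (0 < min_fraction <= 1):
        raise ValidationError("min_fraction must be in (0, 1]")
    need = int(np.ceil(min_fraction * len(datasets)))
    counts: dict[str, int] = {}
    for ds in datasets:
        for g in ds.genes:
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= need)
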