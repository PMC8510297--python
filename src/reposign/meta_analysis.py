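"""Per-gene multi-cohort effect-size meta-analysis and signature selection.

For every gene measured across cohorts the pipeline computes a Hedges'
adjusted g (standardized mean difference with small-sample correction) per
cohort, pools the per-cohort effects by inverse-variance weighting (fixed
effect or DerSimonian–Laird random effects), combines one-sided p-values by
Fisher's method per direction, corrects the pooled-effect p-values by
Benjamini–Hochberg, and applies a leave-one-dataset-out (LODO) robustness
filter before selecting the signed disease gene signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionDataset, shared_gene_universe

logger = logging.getLogger(__name__)

PoolingModel = Literal["fixed", "random_dl"]

#: smallest p-value accepted by Fisher's combination; exact zeros are clamped
P_CLAMP = 1e-300


class DegenerateGeneError(ValueError):
    """Zero pooled standard deviation: the effect size is undefined."""


class MetaAnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-study effect sizes
# ---------------------------------------------------------------------------

def hedges_g(case_vals, ctrl_vals) -> tuple[float, float]:
    """Hedges' adjusted g and its variance for one gene in one cohort.

    g = J * (mean_case - mean_ctrl) / s_pooled with the pooled SD on
    n1 + n2 - 2 degrees of freedom and the small-sample correction
    J = 1 - 3 / (4*df - 1);
    var(g) = (n1 + n2) / (n1 * n2) + g**2 / (2 * (n1 + n2)).
    """
    case = np.asarray(case_vals, dtype=float)
    ctrl = np.asarray(ctrl_vals, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise MetaAnalysisError("need >=2 values per group")
    if not (np.isfinite(case).all() and np.isfinite(ctrl).all()):
        raise MetaAnalysisError("non-finite values in input")
    n1, n2 = case.size, ctrl.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * ctrl.var(ddof=1)) / df
    if sp2 <= 0:
        raise DegenerateGeneError("zero pooled standard deviation")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (case.mean() - ctrl.mean()) / np.sqrt(sp2)
    var_g = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return float(g), float(var_g)


def _study_stats(
    ds: ExpressionDataset, universe: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene (g, var_g, t, df) for one cohort over a universe.

    Genes absent from the cohort, with missing values, or with zero pooled
    SD come back NaN and are treated as unusable in that study.
    """
    idx = pd.Index(universe)
    expr = ds.expr.reindex(idx)
    case = expr.loc[:, ds.labels == "case"].to_numpy(dtype=float)
    ctrl = expr.loc[:, ds.labels == "control"].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    df = n1 + n2 - 2

    with np.errstate(invalid="ignore", divide="ignore"):
        m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
        v1 = case.var(axis=1, ddof=1)
        v2 = ctrl.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        sp = np.sqrt(sp2)
        d = (m1 - m2) / sp
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = j * d
        var_g = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
        t = (m1 - m2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))

    bad = ~np.isfinite(g) | (sp2 <= 0)
    g[bad] = np.nan
    var_g[bad] = np.nan
    t[bad] = np.nan
    return g, var_g, t, np.full(len(idx), df, dtype=float)


def study_effect_matrices(
    datasets: Sequence[ExpressionDataset], universe: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-study statistics into (k x n_genes) matrices G, V, T, DF."""
    rows = [_study_stats(ds, universe) for ds in datasets]
    G = np.vstack([r[0] for r in rows])
    V = np.vstack([r[1] for r in rows])
    T = np.vstack([r[2] for r in rows])
    DF = np.vstack([r[3] for r in rows])
    return G, V, T, DF


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

class PooledEffect(NamedTuple):
    summary_es: float
    summary_se: float
    z: float
    p_two_sided: float
    tau2: float
    cochran_q: float


def _pool_matrix(
    G: np.ndarray, V: np.ndarray, model: PoolingModel
) -> dict[str, np.ndarray]:
    """Inverse-variance pooling per gene (columns) with NaN-aware study masks."""
    ok = np.isfinite(G) & np.isfinite(V) & (V > 0)
    k = ok.sum(axis=0).astype(float)
    w = np.where(ok, 1.0 / np.where(ok, V, 1.0), 0.0)
    sw = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        es_fixed = np.where(sw > 0, (w * np.where(ok, G, 0.0)).sum(axis=0) / sw, np.nan)
        q = (w * np.where(ok, (G - es_fixed) ** 2, 0.0)).sum(axis=0)
        if model == "fixed":
            tau2 = np.zeros_like(q)
            w_star, sw_star, es = w, sw, es_fixed
        elif model == "random_dl":
            c = sw - (w ** 2).sum(axis=0) / np.where(sw > 0, sw, 1.0)
            tau2 = np.where(c > 0, np.maximum(0.0, (q - (k - 1.0)) / c), 0.0)
            w_star = np.where(ok, 1.0 / (V + tau2[None, :]), 0.0)
            sw_star = w_star.sum(axis=0)
            es = np.where(
                sw_star > 0,
                (w_star * np.where(ok, G, 0.0)).sum(axis=0) / sw_star,
                np.nan,
            )
        else:
            raise MetaAnalysisError(f"unknown pooling model {model!r}")
        se = np.where(sw_star > 0, np.sqrt(1.0 / sw_star), np.nan)
        z = es / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {
        "summary_es": es, "summary_se": se, "z": z, "p_es": p,
        "tau2": tau2, "cochran_q": q, "n_studies": k,
    }


def pool_effects(
    g_list: Iterable[float], var_list: Iterable[float], model: PoolingModel = "random_dl"
) -> PooledEffect:
    """Pool per-study effect sizes into a summary effect.

    ``fixed``: weights 1/v_i.  ``random_dl``: DerSimonian–Laird — Cochran's Q
    on the fixed-effect weights, tau2 = max(0, (Q - (k-1)) / C) with
    C = sum(w) - sum(w^2)/sum(w), then re-pool with weights 1/(v_i + tau2).
    """
    g = np.asarray(list(g_list), dtype=float)
    v = np.asarray(list(var_list), dtype=float)
    if g.shape != v.shape or g.size < 2:
        raise MetaAnalysisError("need k >= 2 studies with matching variances")
    if (v <= 0).any() or not (np.isfinite(g).all() and np.isfinite(v).all()):
        raise MetaAnalysisError("variances must be finite and positive")
    res = _pool_matrix(g[:, None], v[:, None], model)
    return PooledEffect(
        float(res["summary_es"][0]), float(res["summary_se"][0]),
        float(res["z"][0]), float(res["p_es"][0]),
        float(res["tau2"][0]), float(res["cochran_q"][0]),
    )


# ---------------------------------------------------------------------------
# p-value machinery
# ---------------------------------------------------------------------------

def combine_pvalues_fisher(p_list: Iterable[float]) -> float:
    """Fisher's sum-of-logs combination: X2 = -2 sum(ln p), chi2 on 2k df."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise MetaAnalysisError("no p-values to combine")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise MetaAnalysisError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("combine_pvalues_fisher: clamping %d zero p-value(s)", (p == 0).sum())
        p = np.maximum(p, P_CLAMP)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def _fisher_matrix(P: np.ndarray) -> np.ndarray:
    """Column-wise Fisher combination of a (k x n) matrix with NaN studies."""
    ok = np.isfinite(P)
    clamped = np.clip(np.where(ok, P, 1.0), P_CLAMP, 1.0)
    x2 = -2.0 * np.log(clamped).sum(axis=0)
    k = ok.sum(axis=0)
    out = stats.chi2.sf(x2, df=2 * k)
    out[k == 0] = np.nan
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise MetaAnalysisError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_meta(
    datasets: Sequence[ExpressionDataset],
    model: PoolingModel = "random_dl",
    min_fraction: float = 1.0,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene meta-analysis over a list of cohorts.

    Returns a DataFrame indexed by gene with columns ``summary_es``,
    ``summary_se``, ``z``, ``p_es``, ``q_es``, ``tau2``, ``cochran_q``,
    ``p_fisher_up``, ``p_fisher_down`` and ``n_studies``.  Genes degenerate
    (zero pooled SD or missing) in a study are pooled over the remaining
    studies; genes usable in fewer than two studies are dropped.
    """
    if len(datasets) < 2:
        raise MetaAnalysisError("need at least 2 datasets")
    if universe is None:
        universe = shared_gene_universe(datasets, min_fraction=min_fraction)
    universe = list(universe)
    if not universe:
        raise MetaAnalysisError("gene universe is empty")

    G, V, T, DF = study_effect_matrices(datasets, universe)
    pooled = _pool_matrix(G, V, model)

    with np.errstate(invalid="ignore"):
        p_up = stats.t.sf(T, DF)    # one-sided: over-expressed in cases
        p_down = stats.t.cdf(T, DF)
    p_up[~np.isfinite(T)] = np.nan
    p_down[~np.isfinite(T)] = np.nan

    out = pd.DataFrame(pooled, index=pd.Index(universe, name="gene"))
    out["p_fisher_up"] = _fisher_matrix(p_up)
    out["p_fisher_down"] = _fisher_matrix(p_down)
    out = out[out["n_studies"] >= 2].copy()
    if out.empty:
        raise MetaAnalysisError("no gene usable in >= 2 studies")
    out["q_es"] = bh_fdr(out["p_es"].to_numpy())
    out["n_studies"] = out["n_studies"].astype(int)
    cols = [
        "summary_es", "summary_se", "z", "p_es", "q_es", "tau2",
        "cochran_q", "p_fisher_up", "p_fisher_down", "n_studies",
    ]
    return out[cols]


def lodo_filter(
    datasets: Sequence[ExpressionDataset],
    model: PoolingModel = "random_dl",
    fdr_threshold: float = 0.01,
    min_fraction: float = 1.0,
    full: pd.DataFrame | None = None,
) -> pd.Series:
    """Leave-one-dataset-out robustness filter.

    A gene passes iff it stays below the FDR threshold with a consistent
    effect-size sign in the full analysis and in every leave-one-out rerun.
    Requires at least 3 cohorts so each rerun still pools >= 2.
    """
    k = len(datasets)
    if k < 3:
        raise MetaAnalysisError("LODO needs at least 3 datasets")
    universe = shared_gene_universe(datasets, min_fraction=min_fraction)
    if full is None:
        full = run_meta(datasets, model=model, universe=universe)
    passing = (full["q_es"] < fdr_threshold) & (full["summary_es"] != 0)
    sign = np.sign(full["summary_es"])
    for i in range(k):
        subset = [ds for j, ds in enumerate(datasets) if j != i]
        sub = run_meta(subset, model=model, universe=universe)
        sub = sub.reindex(full.index)
        passing &= (sub["q_es"] < fdr_threshold).fillna(False)
        passing &= (np.sign(sub["summary_es"]) == sign).fillna(False)
    passing.name = "lodo_pass"
    return passing


@dataclass
class GeneSignature:
    """Signed disease gene signature: over- and under-expressed gene lists.

    ``up`` and ``down`` are ordered (gene, summary_es) pairs, sorted by
    |summary_es| descending with lexicographic tie-break; all up effects are
    positive, all down effects negative, and the two lists are disjoint.
    """

    up: list[tuple[str, float]]
    down: list[tuple[str, float]]
    thresholds: tuple[float, float] = (0.01, 0.0)
    provenance: dict = field(default_factory=dict)

    @property
    def up_genes(self) -> list[str]:
        return [g for g, _ in self.up]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, _ in self.down]

    @property
    def genes(self) -> list[str]:
        return self.up_genes + self.down_genes

    def effects(self) -> pd.Series:
        """Gene -> summary effect size over the whole signature."""
        return pd.Series(dict(self.up) | dict(self.down), name="summary_es")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, es, "up") for g, es in self.up]
        rows += [(g, es, "down") for g, es in self.down]
        return pd.DataFrame(rows, columns=["gene", "summary_es", "direction"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GeneSignature":
        df = pd.read_csv(path, sep="\t")
        up = [(r.gene, r.summary_es) for r in df.itertuples() if r.summary_es > 0]
        down = [(r.gene, r.summary_es) for r in df.itertuples() if r.summary_es < 0]
        return cls(up=up, down=down)


def select_signature(
    meta: pd.DataFrame,
    lodo: pd.Series | None = None,
    fdr: float = 0.01,
    abs_es: float = 0.0,
) -> GeneSignature:
    """Threshold the meta-analysis table into a signed gene signature."""
    keep = (meta["q_es"] < fdr) & (meta["summary_es"].abs() >= abs_es)
    if lodo is not None:
        keep &= lodo.reindex(meta.index).fillna(False).astype(bool)
    sel = meta[keep]
    if sel.empty:
        logger.warning("select_signature: empty signature at fdr=%g, abs_es=%g", fdr, abs_es)

    def _ordered(sub: pd.DataFrame) -> list[tuple[str, float]]:
        sub = sub.sort_index()  # lexicographic tie-break
        sub = sub.iloc[np.argsort(-sub["summary_es"].abs().to_numpy(), kind="mergesort")]
        return list(zip(sub.index, sub["summary_es"]))

    return GeneSignature(
        up=_ordered(sel[sel["summary_es"] > 0]),
        down=_ordered(sel[sel["summary_es"] < 0]),
        thresholds=(fdr, abs_es),
        provenance={"n_input_genes": int(len(meta)), "lodo": lodo is not None},
    )


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def signature_score(ds: ExpressionDataset, sig: GeneSignature) -> pd.Series:
    """Per-sample signature score: geometric mean of up genes minus
    geometric mean of down genes, on a min-shifted (log-safe) matrix,
    z-scored across the samples of the dataset."""
    up = [g for g in sig.up_genes if g in ds.expr.index]
    down = [g for g in sig.down_genes if g in ds.expr.index]
    if not up and not down:
        raise MetaAnalysisError("no signature gene present in the dataset")
    vals = ds.expr.to_numpy(dtype=float)
    shift = max(0.0, 1.0 - np.nanmin(vals))
    shifted = ds.expr + shift

    def _geomean(genes: list[str]) -> np.ndarray:
        if not genes:
            return np.zeros(ds.expr.shape[1])
        return np.exp(np.log(shifted.loc[genes].to_numpy(dtype=float)).mean(axis=0))

    raw = _geomean(up) - _geomean(down)
    sd = raw.std(ddof=0)
    if sd == 0:
        logger.warning("signature_score: zero variance across samples; scores set to 0")
        return pd.Series(np.zeros_like(raw), index=ds.expr.columns, name="score")
    return pd.Series((raw - raw.mean()) / sd, index=ds.expr.columns, name="score")


def auroc(scores, labels) -> float:
    """AUROC of scores for the case class, Mann–Whitney form (ties get 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == "case"] if y.dtype.kind in "OU" else s[y.astype(bool)]
    neg = s[y == "control"] if y.dtype.kind in "OU" else s[~y.astype(bool)]
    if pos.size == 0 or neg.size == 0:
        raise MetaAnalysisError("need both classes to compute AUROC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
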