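"""Signature-reversal drug ranking against a perturbation compendium.

Each drug carries a per-gene perturbation effect-size profile (the compendium
emulates LINCS L1000 Level-5 data, optionally restricted to the "gold"
reliable-gene mask).  Drugs are scored by the Pearson correlation between
their profile and the disease signature's summary effect sizes over the
shared genes; strongly negative correlations mark candidate reversers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta_analysis import GeneSignature, bh_fdr, select_signature

logger = logging.getLogger(__name__)

MIN_SHARED_GENES = 3


class RepositioningError(ValueError):
    pass


@dataclass
class DrugProfile:
    """Per-drug perturbation effect sizes and reliable-gene mask."""

    drug_id: str
    effects: pd.Series            # gene -> effect size vs control
    gold_mask: pd.Series | None = None   # gene -> bool, subset of effects index
    cell_context: str = ""

    def __post_init__(self) -> None:
        if self.effects.empty:
            raise RepositioningError(f"{self.drug_id}: empty effect profile")
        if self.gold_mask is not None:
            extra = self.gold_mask.index.difference(self.effects.index)
            if len(extra):
                raise RepositioningError(
                    f"{self.drug_id}: gold mask covers genes absent from the profile"
                )

    def usable_effects(self, gold_only: bool = True) -> pd.Series:
        if gold_only and self.gold_mask is not None:
            keep = self.gold_mask.index[self.gold_mask.astype(bool)]
            return self.effects.loc[keep]
        return self.effects


def profiles_from_table(
    effects: pd.DataFrame, gold: pd.DataFrame | None = None, cell_context: str = ""
) -> list[DrugProfile]:
    """Build profiles from a genes x drugs effect table (+ optional mask)."""
    profiles = []
    for drug in effects.columns:
        col = effects[drug].dropna()
        mask = None
        if gold is not None and drug in gold.columns:
            mask = gold[drug].reindex(col.index).fillna(False).astype(bool)
        profiles.append(DrugProfile(drug, col, mask, cell_context))
    return profiles


def average_contexts(profiles: Sequence[DrugProfile]) -> DrugProfile:
    """Collapse multiple cell-context profiles of one drug by per-gene mean."""
    if not profiles:
        raise RepositioningError("no profiles to average")
    drug = profiles[0].drug_id
    eff = pd.concat([p.effects for p in profiles], axis=1).mean(axis=1)
    masks = [p.gold_mask for p in profiles if p.gold_mask is not None]
    gold = None
    if masks:
        gold = pd.concat(masks, axis=1).fillna(False).any(axis=1).reindex(eff.index).fillna(False)
    return DrugProfile(drug, eff, gold, cell_context="mean")


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t transform on n-2 df."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def disease_drug_correlation(
    sig: GeneSignature, profile: DrugProfile, gold_only: bool = True
) -> tuple[float, float, int]:
    """Pearson correlation between disease and drug effect sizes.

    Computed over genes present in both the signature and the (optionally
    gold-masked) profile; two-sided p from the t transform on n-2 df.
    Zero variance in either vector yields (nan, nan, n) — the caller
    excludes such drugs from ranking.
    """
    sig_es = sig.effects()
    eff = profile.usable_effects(gold_only)
    shared = sig_es.index.intersection(eff.index)
    n = len(shared)
    if n < MIN_SHARED_GENES:
        raise RepositioningError(
            f"{profile.drug_id}: only {n} shared gene(s) with the signature"
        )
    x = sig_es.loc[shared].to_numpy(dtype=float)
    y = eff.loc[shared].to_numpy(dtype=float)
    r, p = _pearson(x, y)
    if np.isnan(r):
        logger.warning("%s: zero variance, correlation undefined", profile.drug_id)
    return r, p, n


def _score_profiles(
    sig: GeneSignature, profiles: Sequence[DrugProfile], gold_only: bool
) -> list[dict]:
    """Per-drug correlation rows; pre-aligns once when profiles share a
    gene index (the common compendium layout) to avoid repeated index ops."""
    first = profiles[0].effects.index
    aligned = all(p.effects.index.equals(first) for p in profiles)
    if not aligned:
        rows = []
        for prof in profiles:
            r, p, n = disease_drug_correlation(sig, prof, gold_only=gold_only)
            rows.append({"drug_id": prof.drug_id, "n_shared_genes": n, "r": r, "p": p})
        return rows
    sig_arr = sig.effects().reindex(first).to_numpy(dtype=float)
    in_sig = np.isfinite(sig_arr)
    rows = []
    for prof in profiles:
        y = prof.effects.to_numpy(dtype=float)
        m = in_sig & np.isfinite(y)
        if gold_only and prof.gold_mask is not None:
            m &= prof.gold_mask.reindex(first).fillna(False).to_numpy(dtype=bool)
        n = int(m.sum())
        if n < MIN_SHARED_GENES:
            raise RepositioningError(
                f"{prof.drug_id}: only {n} shared gene(s) with the signature"
            )
        r, p = _pearson(sig_arr[m], y[m])
        rows.append({"drug_id": prof.drug_id, "n_shared_genes": n, "r": r, "p": p})
    return rows


def rank_drugs(
    sig: GeneSignature, profiles: Sequence[DrugProfile], gold_only: bool = True,
    by: str = "reversal",
) -> pd.DataFrame:
    """Score every drug and rank (rank 1 = most negative correlation).

    BH correction runs across drugs with a defined correlation; drugs with
    undefined (zero-variance) profiles are reported with NaN and no rank.
    ``by='abs'`` ranks by |r| descending instead (exploratory mode).
    """
    if not profiles:
        raise RepositioningError("no drug profiles supplied")
    rows = _score_profiles(sig, profiles, gold_only)
    out = pd.DataFrame(rows)
    ok = out["r"].notna()
    if not ok.any():
        raise RepositioningError("all drug profiles degenerate; nothing to rank")
    out["q"] = np.nan
    out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    key = out.loc[ok, "r"] if by == "reversal" else -out.loc[ok, "r"].abs()
    ranked = out.loc[ok].assign(_key=key).sort_values(
        ["_key", "q", "drug_id"], kind="mergesort"
    )
    out["rank"] = pd.Series(np.nan, index=out.index)
    out.loc[ranked.index, "rank"] = np.arange(1, ok.sum() + 1)
    out = out.sort_values("rank", na_position="last").reset_index(drop=True)
    return out


def reversal_gene_set(sig: GeneSignature, profile: DrugProfile, gold_only: bool = True
                      ) -> tuple[list[str], float]:
    """Genes moved in the opposite direction by the drug, and their fraction
    of the genes shared between signature and profile."""
    sig_es = sig.effects()
    eff = profile.usable_effects(gold_only)
    shared = sig_es.index.intersection(eff.index)
    if len(shared) == 0:
        raise RepositioningError("no shared genes")
    opposite = [g for g in shared if np.sign(sig_es[g]) * np.sign(eff[g]) < 0]
    return sorted(opposite), len(opposite) / len(shared)


@dataclass
class GridReport:
    """Sensitivity grid over (FDR, |ES|) signature thresholds."""

    top_sets: dict        # (fdr, es) -> list of top-n drug ids, or None if empty cell
    per_drug_r: pd.DataFrame   # drugs x cells correlation matrix
    stability: float      # mean pairwise Jaccard of top-n sets across non-empty cells
    top_n: int = 10


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0


def sensitivity_grid(
    meta: pd.DataFrame,
    lodo: pd.Series | None,
    profiles: Sequence[DrugProfile],
    fdr_grid: Sequence[float] = (0.01, 0.05, 0.10, 0.20),
    es_grid: Sequence[float] = (0.6, 0.8, 1.0, 1.2),
    gold_only: bool = True,
    top_n: int = 10,
) -> GridReport:
    """Re-select the signature at each (FDR, |ES|) threshold pair and re-rank.

    Cells whose signature is empty (or too small to correlate) are marked
    empty and excluded from the stability score, which is the mean pairwise
    Jaccard similarity of the top-n drug sets across the remaining cells
    (1.0 by convention when fewer than two cells remain).
    """
    cells = list(itertools.product(sorted(fdr_grid), sorted(es_grid)))
    top_sets: dict = {}
    r_cols = {}
    for fdr, es in cells:
        sig = select_signature(meta, lodo, fdr=fdr, abs_es=es)
        if len(sig) == 0:
            top_sets[(fdr, es)] = None
            continue
        try:
            table = rank_drugs(sig, profiles, gold_only=gold_only)
        except RepositioningError:
            top_sets[(fdr, es)] = None
            continue
        top = table.nsmallest(top_n, "rank")["drug_id"].tolist()
        top_sets[(fdr, es)] = top
        r_cols[(fdr, es)] = table.set_index("drug_id")["r"]
    per_drug_r = pd.DataFrame(r_cols)
    nonempty = [set(v) for v in top_sets.values() if v is not None]
    if len(nonempty) < 2:
        stability = 1.0
    else:
        pairs = list(itertools.combinations(nonempty, 2))
        stability = float(np.mean([_jaccard(a, b) for a, b in pairs]))
    return GridReport(top_sets=top_sets, per_drug_r=per_drug_r,
                      stability=stability, top_n=top_n)
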