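"""Overrepresentation analysis (ORA) of a gene signature against gene sets.

Gene sets come in GMT format; each set is tested against the signature by
the one-sided hypergeometric (Fisher's exact) upper tail over the measured
gene universe, sets smaller than a floor are dropped before testing, and
p-values are Benjamini–Hochberg corrected across the tested sets only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta_analysis import GeneSignature, bh_fdr

logger = logging.getLogger(__name__)


class GMTFormatError(ValueError):
    pass


class EnrichmentError(ValueError):
    pass


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: per line 'name<TAB>description<TAB>gene1<TAB>...'."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            sets[name] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(collection: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *sorted(set(genes))]) + "\n")


def ora_fisher(
    signature_genes: set[str], gene_set: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """One-sided enrichment test of a gene set against a signature.

    Hypergeometric upper tail P(X >= k) with N = |universe|,
    K = |set ∩ universe|, n = |signature|, k = |overlap|; the odds ratio
    comes from the 2x2 table with a Haldane 0.5 correction when any cell
    is zero.  Returns (p, odds_ratio, overlap).
    """
    if not universe:
        raise EnrichmentError("empty gene universe")
    sig = set(signature_genes) & set(universe)
    gset = set(gene_set) & set(universe)
    N, K, n = len(universe), len(gset), len(sig)
    k = len(sig & gset)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b = k, n - k
    c, d = K - k, N - K - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return p, float(odds), k


def enrich(
    signature: GeneSignature | Iterable[str],
    collection: Mapping[str, set[str]],
    universe: Iterable[str],
    min_size: int = 5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """ORA of a signature over a gene-set collection.

    Sets with fewer than ``min_size`` genes inside the universe are excluded
    *before* testing (so the BH correction runs over exactly the tested
    sets).  Result rows are sorted by q then p, with a ``significant`` flag
    at q <= fdr_threshold.
    """
    sig_genes = set(signature.genes) if isinstance(signature, GeneSignature) else set(signature)
    uni = set(universe)
    rows = []
    for name, genes in collection.items():
        inside = set(genes) & uni
        if len(inside) < min_size:
            continue
        p, odds, k = ora_fisher(sig_genes, inside, uni)
        rows.append({
            "set_name": name,
            "set_size": len(inside),
            "overlap": k,
            "overlap_genes": ",".join(sorted(sig_genes & inside)),
            "odds_ratio": odds,
            "p": p,
        })
    if not rows:
        logger.warning("enrich: no gene set passed the min_size=%d filter", min_size)
        return pd.DataFrame(
            columns=["set_name", "set_size", "overlap", "overlap_genes",
                     "odds_ratio", "p", "q", "significant"]
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr_threshold
    return out.sort_values(["q", "p", "set_name"]).reset_index(drop=True)


def pathway_overlap_edges(
    collection: Mapping[str, set[str]], names: Sequence[str]
) -> pd.DataFrame:
    """Pairwise shared-gene counts between named sets (edge list)."""
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = len(set(collection[a]) & set(collection[b]))
            if shared:
                rows.append({"set_a": a, "set_b": b, "shared_genes": shared})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "shared_genes"])
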