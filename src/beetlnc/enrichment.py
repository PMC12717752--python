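"""Over-representation analysis by the upper-tail hypergeometric test.

For a selected gene set of size ``n`` drawn from a universe of ``N`` genes of
which ``K`` carry the term, the enrichment p-value of an overlap ``k`` is
``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  Terms are flagged
enriched at BH-adjusted ``q <= 0.05`` (inclusive).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .core_io import TermMap, ValidationError
from .diffexp import bh_fdr


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(
            f"hypergeometric parameters out of range: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected_genes: set[str] | list[str],
    term_map: TermMap,
    universe: set[str] | list[str],
    q_max: float = 0.05,
    drop_zero_overlap: bool = True,
) -> pd.DataFrame:
    """One row per term: N, K, n, k, p, BH q, gene_ratio, enriched flag.

    BH correction runs across all tested terms; terms with zero overlap are
    dropped by default (they carry p = 1 and can only dilute the correction).
    """
    universe = set(universe)
    selected = set(selected_genes)
    outside = sorted(selected - universe)
    if outside:
        raise ValidationError(f"selected genes outside universe: {outside[:10]}")
    if not term_map.terms:
        raise ValidationError("empty term map")
    N, n = len(universe), len(selected)
    rows = []
    for term in sorted(term_map.terms):
        genes = term_map.terms[term] & universe
        K = len(genes)
        k = len(genes & selected)
        if k == 0 and drop_zero_overlap:
            continue
        rows.append(
            {
                "term": term,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": hypergeom_upper(N, K, n, k),
                "gene_ratio": k / n if n else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p", "gene_ratio"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = []
    df["enriched"] = df["q"] <= q_max
    return df.reset_index(drop=True)
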