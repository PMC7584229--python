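"""Hypergeometric over-representation analysis with BH q-values.

One-sided over-representation: for a term annotating K of the N
background genes, observing k hits in a candidate set of size n has
p = P(X >= k), X ~ Hypergeometric(N, K, n). P-values across terms are
corrected by the Benjamini-Hochberg step-up and the study's significance
rule is strict: Q < 0.05. Candidate genes not annotated to any term stay
in n — they still inform the null.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

Q_MAX = 0.05


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= min(K, n) and k <= K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_qvalues(p_values):
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = list(p_values)
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeom_enrich(candidate_genes, term_to_genes, background_genes,
                     term_names=None) -> pd.DataFrame:
    """Test every term for over-representation of the candidate set.

    ``candidate_genes`` must be a subset of ``background_genes``; term
    memberships are restricted to the background before testing. Returns
    a DataFrame (term, name, k, K, n, N, p_value, q_value) sorted by
    ascending q then p.
    """
    background = set(background_genes)
    candidates = set(candidate_genes)
    stray = sorted(candidates - background)
    if stray:
        raise ValueError(f"candidate genes absent from background: {stray}")
    n, N = len(candidates), len(background)
    term_names = term_names or {}
    rows = []
    for term, genes in term_to_genes.items():
        members = set(genes) & background
        if not members:
            continue
        k = len(members & candidates)
        K = len(members)
        rows.append((term, term_names.get(term, term), k, K, n, N,
                     hypergeom_pvalue(k, K, n, N)))
    df = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p_value"])
    df["q_value"] = bh_qvalues(df["p_value"]) if len(df) else []
    return df.sort_values(["q_value", "p_value", "term"]).reset_index(drop=True)


def filter_significant(tests: pd.DataFrame, q_max: float = Q_MAX) -> pd.DataFrame:
    """Keep terms with q strictly below ``q_max``, sorted ascending by q."""
    return (tests[tests["q_value"] < q_max]
            .sort_values(["q_value", "p_value", "term"]).reset_index(drop=True))
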