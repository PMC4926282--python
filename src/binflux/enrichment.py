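"""Hypergeometric functional-category enrichment per genome bin.

For a bin holding n of the community's g annotated genes, of which f
carry a given functional category (KEGG pathway or SEED subsystem), the
enrichment statistic is the upper tail of the hypergeometric
distribution — the probability of finding at least k category genes in
a random draw of n genes:

    P(X >= k) = sum_{j=k}^{min(n,f)} C(f,j) C(g-f, n-j) / C(g,n)

The tail is summed in log space (log-binomials via gammaln, compensated
by log-sum-exp) so it stays accurate at community scales of 1e5-1e6
genes; an exact rational mode is available for validation at small g.
Genes mapped to multiple categories count once in n and g but once per
category in k and f.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

ADJUST_METHODS = ("none", "bonferroni", "bh")


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts feeding one hypergeometric test.

    k: category genes in the bin; n: genes in the bin; f: category
    genes community-wide; g: genes community-wide.
    """

    k: int
    n: int
    f: int
    g: int

    def validate(self) -> None:
        if self.g < 0 or self.n < 0 or self.f < 0 or self.k < 0:
            raise ValueError("counts must be nonnegative")
        if self.n > self.g:
            raise ValueError(f"bound violated: n={self.n} > g={self.g}")
        if self.f > self.g:
            raise ValueError(f"bound violated: f={self.f} > g={self.g}")
        if self.k > min(self.n, self.f):
            raise ValueError(
                f"bound violated: k={self.k} > min(n={self.n}, f={self.f})"
            )
        # k below the support minimum n-(g-f) stays valid: asking for "at
        # least k" hits below the guaranteed overlap yields probability 1
        # (the degenerate n = g bin is the canonical case).


def _log_comb(a: int, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeometric_tail(inp: EnrichmentInput, exact: bool = False) -> float:
    """Upper-tail probability P(X >= k) of the hypergeometric law.

    ``exact=True`` sums exact rationals (integer binomials); intended
    for validation at small g (say g <= 1000). The default log-space
    path is accurate for community-scale g.
    """
    inp.validate()
    k, n, f, g = inp.k, inp.n, inp.f, inp.g
    j_hi = min(n, f)
    if k <= max(0, n - (g - f)):
        return 1.0
    j = np.arange(k, j_hi + 1)
    if j.size == 0:
        # k exceeds the support (caught by validate); defensive
        return 0.0
    if exact:
        total = sum(
            Fraction(comb(f, int(jj)) * comb(g - f, n - int(jj)), comb(g, n))
            for jj in j
        )
        return float(total)
    log_terms = _log_comb(f, j) + _log_comb(g - f, n - j) - _log_comb(g, np.array([n]))
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def _count_table(
    annotations: pd.DataFrame,
) -> tuple[pd.Series, pd.Series, int, pd.Series]:
    """Per-(bin,category) k, per-category f, and community gene total g."""
    genes_per_bin = annotations.groupby("bin_id")["gene_id"].nunique()
    k = annotations.groupby(["bin_id", "category_id"])["gene_id"].nunique()
    f = annotations.groupby("category_id")["gene_id"].nunique()
    g = annotations["gene_id"].nunique()
    return k, f, g, genes_per_bin


def test_bin_category(
    annotations: pd.DataFrame, bin_id: str, category_id: str
) -> tuple[EnrichmentInput, float]:
    """Hypergeometric test of one category in one bin (unadjusted).

    Counts are taken from the annotation table: a gene with several
    categories contributes to each category's k and f but only once to
    the bin's n and the community's g.
    """
    if bin_id not in set(annotations["bin_id"]):
        raise KeyError(f"unknown bin {bin_id!r}")
    if category_id not in set(annotations["category_id"]):
        raise KeyError(f"unknown category {category_id!r}")
    k_tab, f_tab, g, genes_per_bin = _count_table(annotations)
    k = int(k_tab.get((bin_id, category_id), 0))
    n = int(genes_per_bin[bin_id])
    f = int(f_tab[category_id])
    inp = EnrichmentInput(k=k, n=n, f=f, g=g)
    return inp, hypergeometric_tail(inp)


def enrich_all(
    annotations: pd.DataFrame,
    bins: list[str] | None = None,
    alpha: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Test every (bin, category) pair with k >= 1.

    The multiplicity adjustment (``none``/``bonferroni``/``bh``) runs
    across all tested pairs; ``enriched`` flags adjusted_p <= alpha.
    Output rows are sorted by (bin_id, category_id).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ADJUST_METHODS:
        raise ValueError(f"method must be one of {ADJUST_METHODS}")
    if bins is not None:
        unknown = set(bins) - set(annotations["bin_id"])
        if unknown:
            raise KeyError(f"unknown bin(s) {sorted(unknown)}")
    # f and g stay community-wide even when only a bin subset is tested
    k_tab, f_tab, g, genes_per_bin = _count_table(annotations)

    bin_set = None if bins is None else set(bins)
    rows = []
    pairs = sorted(
        (b, c) for (b, c) in k_tab.index if bin_set is None or b in bin_set
    )
    for b, c in pairs:
        inp = EnrichmentInput(
            k=int(k_tab[(b, c)]),
            n=int(genes_per_bin[b]),
            f=int(f_tab[c]),
            g=int(g),
        )
        rows.append(
            {
                "bin_id": b,
                "category_id": c,
                "k": inp.k,
                "n": inp.n,
                "f": inp.f,
                "g": inp.g,
                "p_value": hypergeometric_tail(inp),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["bin_id", "category_id", "k", "n", "f", "g", "p_value"],
    )
    if len(result) == 0:
        result["adjusted_p"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
        return result
    p = result["p_value"].to_numpy()
    if method == "none":
        adj = p.copy()
    elif method == "bonferroni":
        adj = multipletests(p, alpha=alpha, method="bonferroni")[1]
    else:
        adj = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    result["adjusted_p"] = adj
    result["enriched"] = result["adjusted_p"] <= alpha
    return result.reset_index(drop=True)
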