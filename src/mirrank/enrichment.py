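"""Local over-representation analysis (ORA) against GMT gene-set libraries.

Runs a one-sided hypergeometric test per library term for a query gene set
(e.g. the aggregated targets of one miRNA), controls the FDR per library by
Benjamini-Hochberg, and summarizes which terms are significant across
several queries as a binary overlap matrix.  This is a deterministic,
offline ORA; it does not reproduce any remote enrichment service's combined
ranking statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_upper_tail",
    "benjamini_hochberg",
    "enrich",
    "overlap_matrix",
]


@dataclass
class GeneSetLibrary:
    """A named GMT-style library: term name -> set of gene symbols."""

    name: str
    terms: dict[str, set[str]]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out


@dataclass
class EnrichmentResult:
    term: str
    k: int  # overlap size
    K: int  # term size (within universe)
    n: int  # query size (within universe)
    N: int  # universe size
    p_value: float
    odds_ratio: float
    q_value: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.q_value < 0.05


def read_gmt(path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT file (term TAB description TAB gene ...) into a library."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in terms:
                raise ValueError(f"duplicate term {parts[0]!r} in {path}")
            terms[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return GeneSetLibrary(name=name or str(path), terms=terms)


def write_gmt(library_or_sets, path) -> None:
    """Write a :class:`GeneSetLibrary` or list of gene sets to GMT."""
    with open(path, "w") as fh:
        if isinstance(library_or_sets, GeneSetLibrary):
            items = [(t, "na", g) for t, g in library_or_sets.terms.items()]
        else:  # list of gene_sets.GeneSet
            items = [(gs.label, gs.kind, gs.genes) for gs in library_or_sets]
        for term, desc, genes in items:
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), computed in log space.

    N = universe size, K = annotated genes, n = query size, k = overlap.
    """
    if k < 0 or K < 0 or n < 0 or N < 0:
        raise ValueError("counts must be non-negative")
    if k > K or k > n or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    lo = max(k, K + n - N)
    hi = min(K, n)
    i = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(np.exp(logsumexp(logpmf)), 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    library: GeneSetLibrary,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric ORA of ``query`` against every library term.

    ``query`` may be a set of gene symbols or any object with a ``genes``
    attribute.  The universe defaults to the union of all library genes;
    query genes outside it are dropped with a warning.  Terms with zero
    overlap are excluded before FDR adjustment.  Results are sorted by
    p-value ascending; ``significant`` means q < alpha.
    """
    qgenes = set(getattr(query, "genes", query))
    qgenes = {str(g).strip().upper() for g in qgenes}
    uni = set(universe) if universe is not None else library.universe()
    if not uni:
        raise ValueError("universe is empty")
    dropped = qgenes - uni
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    q_in = qgenes & uni
    n, N = len(q_in), len(uni)

    results: list[EnrichmentResult] = []
    for term, genes in library.terms.items():
        tg = genes & uni
        k, K = len(q_in & tg), len(tg)
        if k == 0:
            continue
        p = hypergeometric_upper_tail(k, K, n, N)
        a, b, c, d = k, K - k, n - k, N - K - n + k
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        results.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N,
                p_value=p, odds_ratio=(a * d) / (b * c),
            )
        )
    if results:
        qvals = benjamini_hochberg([r.p_value for r in results])
        for r, qv in zip(results, qvals):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.term))
    _ = alpha  # significance threshold carried by caller via r.q_value < alpha
    return results


def overlap_matrix(per_mirna_terms: dict[str, list[str]]) -> pd.DataFrame:
    """Binary term x miRNA matrix of significant terms, with a ``margin``
    column counting the miRNAs per term; rows sorted by margin descending
    then term name."""
    if not per_mirna_terms:
        raise ValueError("need at least one miRNA")
    mirnas = list(per_mirna_terms)
    all_terms = sorted({t for terms in per_mirna_terms.values() for t in terms})
    mat = pd.DataFrame(0, index=pd.Index(all_terms, name="term"), columns=mirnas, dtype=int)
    for m, terms in per_mirna_terms.items():
        mat.loc[list(set(terms)), m] = 1
    mat["margin"] = mat[mirnas].sum(axis=1)
    mat = mat.sort_values(by=["margin", "term"], ascending=[False, True], kind="mergesort")
    return mat
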