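"""DEG selection and GO over-representation analysis (ORA).

Up-regulated genes (log2FC > 0.5, BH-adjusted p < 0.05, both strict) are
tested per GO term with the one-sided hypergeometric upper tail against
the universe of genes present in the expression table, and terms with
BH-adjusted p < 0.01 across tissues form the enriched-term set consumed by
the switch filter cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .formats import DEGTable

log = logging.getLogger(__name__)

DEFAULT_LOG2FC_MIN = 0.5
DEFAULT_DEG_ADJP_MAX = 0.05
DEFAULT_ORA_ADJP_MAX = 0.01


@dataclass(frozen=True)
class ORAResult:
    """One term's over-representation test: k of n DEGs hit a term with K of
    N universe genes annotated."""

    term: str
    k: int
    K: int
    n: int
    N: int
    pvalue: float
    adj_p: float
    tissue: str = ""


def select_degs(
    table: DEGTable,
    log2fc_min: float = DEFAULT_LOG2FC_MIN,
    adjp_max: float = DEFAULT_DEG_ADJP_MAX,
) -> set[str]:
    """Up-regulated differentially expressed genes, strict thresholds on both
    log2FC (>) and adjusted p (<)."""
    df = table.frame
    mask = (df.log2fc > log2fc_min) & (df.adj_p < adjp_max)
    return set(df.gene[mask])


def hypergeom_ora(
    deg_set: set[str],
    universe: set[str],
    term_annotations: Mapping[str, Iterable[str]],
    tissue: str = "",
) -> list[ORAResult]:
    """One-sided hypergeometric ORA with BH correction across tested terms.

    ``term_annotations`` maps term → annotated genes; annotations are
    restricted to the universe and terms with no universe gene are skipped.
    P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    if not deg_set <= universe:
        raise ValueError("DEG set must be a subset of the universe")
    N, n = len(universe), len(deg_set)
    rows = []
    for term in sorted(term_annotations):
        genes = set(term_annotations[term]) & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & deg_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [
        ORAResult(term=t, k=k, K=K, n=n, N=N, pvalue=p, adj_p=float(a), tissue=tissue)
        for (t, k, K, p), a in zip(rows, adj)
    ]


def enriched_terms(
    ora_results_per_tissue: Sequence[Sequence[ORAResult]],
    adjp_max: float = DEFAULT_ORA_ADJP_MAX,
) -> set[str]:
    """Union over tissues of terms significant at adjusted p < ``adjp_max``."""
    if not ora_results_per_tissue:
        raise ValueError("need at least one tissue's ORA results")
    out: set[str] = set()
    for results in ora_results_per_tissue:
        out |= {r.term for r in results if r.adj_p < adjp_max}
    if not out:
        log.warning("no term is enriched at adj_p < %g in any tissue; the "
                    "enrichment filter will remove every switch", adjp_max)
    return out


def ora_frame(results: Sequence[ORAResult]) -> pd.DataFrame:
    """Tabulate ORA results for export."""
    return pd.DataFrame(
        [(r.term, r.k, r.K, r.n, r.N, r.pvalue, r.adj_p, r.tissue) for r in results],
        columns=["term", "k", "K", "n", "N", "pvalue", "adj_p", "tissue"],
    )
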