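"""Over-representation analysis (ORA) of a query gene set against gene sets.

The test is the one-sided hypergeometric upper tail (equivalently one-sided
Fisher's exact): with a universe of N genes of which K belong to the set and
a query of n genes, the p-value is P(X >= k) for the observed overlap k.
Multiple testing is handled by Benjamini–Hochberg step-up FDR; raw p-values
are reported alongside since published tables often print them unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import GeneSetCollection
from .symbols import GeneSymbol


def hypergeom_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when drawing ``n`` genes without replacement from a
    universe of ``N`` genes containing ``K`` set members. Stable for N up to
    at least 1e5 (survival-function evaluation, no explicit factorials).
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0  # P(X >= 0); also covers the empty universe
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank downwards, cap at 1. Inputs must lie in (0, 1].
    """
    if not p_values:
        return []
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    return list(multipletests(p_values, method="fdr_bh")[1])


@dataclass
class EnrichmentRow:
    """One tested gene set: counts, raw p, BH-adjusted p, overlap members."""

    set_id: str
    name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    p_adjusted: float
    overlap_genes: set[GeneSymbol] = field(default_factory=set)


def enrich(
    query: set[GeneSymbol],
    annotation: GeneSetCollection,
    universe_mode: str = "annotation_union",
    universe: set[GeneSymbol] | None = None,
    top_n: int | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric ORA of ``query`` against every set in ``annotation``.

    Parameters
    ----------
    query
        Normalized gene symbols; genes outside the universe are dropped
        from the test (they carry no information under the sampling model).
    annotation
        The gene sets to test.
    universe_mode
        ``"annotation_union"`` (default): universe = union of all annotated
        genes. ``"explicit"``: use ``universe`` (or ``annotation.universe``).
    top_n
        Keep only the first ``top_n`` rows after sorting; ``None`` keeps all.

    Returns
    -------
    list of EnrichmentRow
        One row per gene set with overlap >= 1, sorted by overlap count
        descending, then raw p ascending, then set_id alphabetical. BH
        adjustment is computed across all tested (overlap >= 1) sets before
        truncation.
    """
    if not annotation.sets:
        raise ValueError("annotation collection is empty")
    if universe_mode == "annotation_union":
        uni = annotation.union()
    elif universe_mode == "explicit":
        uni = universe if universe is not None else annotation.universe
        if uni is None:
            raise ValueError("explicit universe_mode needs a universe")
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")

    N = len(uni)
    q = query & uni
    n = len(q)

    tested: list[EnrichmentRow] = []
    for sid, (name, members) in annotation.sets.items():
        members_u = members & uni
        K = len(members_u)
        overlap_genes = q & members_u
        k = len(overlap_genes)
        if k == 0:
            continue
        p = hypergeom_p(N, K, n, k)
        tested.append(
            EnrichmentRow(
                set_id=sid,
                name=name,
                universe_size=N,
                set_size=K,
                query_size=n,
                overlap=k,
                p_value=p,
                p_adjusted=1.0,  # filled below
                overlap_genes=overlap_genes,
            )
        )
    if not tested:
        warnings.warn("query overlaps no annotated gene set", stacklevel=2)
        return []

    adjusted = bh_adjust([r.p_value for r in tested])
    for row, padj in zip(tested, adjusted):
        row.p_adjusted = padj

    tested.sort(key=lambda r: (-r.overlap, r.p_value, r.set_id))
    if top_n is not None:
        tested = tested[: max(top_n, 0)]
    return tested


def enrichment_table(rows: list[EnrichmentRow]):
    """Rows as a pandas DataFrame (column order mirrors EnrichmentRow)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "name": r.name,
                "universe_size": r.universe_size,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "overlap_genes": ", ".join(sorted(r.overlap_genes)),
            }
            for r in rows
        ]
    )
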