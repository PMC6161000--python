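"""Literature prominence of mapped vs unmapped metabolites.

Each metabolite is linked, through its PubChem CID, to the number of
PubMed articles citing it (supplied as a local table standing in for the
PubChem web API).  Two questions are asked: do unmapped metabolites have
fewer articles than mapped ones (Wilcoxon rank-sum on counts, restricted
to metabolites with at least one article), and is *having any article at
all* associated with being mapped (Fisher's exact test on the 2x2 table,
with Pearson residuals showing which cells drive the association)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, rankdata

from .coverage import CoverageLabels

__all__ = [
    "PublicationRecord",
    "attach_publications",
    "literature_tests",
    "wilcoxon_rank_sum",
    "pearson_residuals",
]

log = logging.getLogger(__name__)

#: exact permutation enumeration is used when the number of group
#: assignments is at most this; beyond it, the normal approximation with
#: continuity and tie correction takes over
MAX_EXACT_COMBINATIONS = 20_000


@dataclass
class PublicationRecord:
    node: str
    pubchem_cid: int | None
    n_articles: int | None  # None = CID missing or not queryable


def read_publication_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns (cid, n_articles)."""
    df = pd.read_csv(path, sep="\t")
    if not {"cid", "n_articles"}.issubset(df.columns):
        raise ValueError(f"publication table {path} needs columns cid, n_articles")
    return df


def attach_publications(
    nodes: dict[str, int | None] | pd.DataFrame,
    pub_table: pd.DataFrame | str | Path,
) -> list[PublicationRecord]:
    """Join nodes to article counts through their PubChem CID.

    ``nodes`` maps node id -> CID (or None when the metabolite has no
    PubChem entry; such nodes are flagged unknown and excluded from the
    statistical tests, mirroring compounds the literature query cannot
    reach).
    """
    if isinstance(pub_table, (str, Path)):
        pub_table = read_publication_table(pub_table)
    counts = dict(zip(pub_table["cid"].astype(int), pub_table["n_articles"].astype(int)))
    if isinstance(nodes, pd.DataFrame):
        nodes = dict(zip(nodes["node"], nodes["cid"]))
    records = []
    n_unknown = 0
    for node, cid in nodes.items():
        if cid is None or (isinstance(cid, float) and np.isnan(cid)):
            records.append(PublicationRecord(node, None, None))
            n_unknown += 1
            continue
        cid = int(cid)
        records.append(PublicationRecord(node, cid, counts.get(cid)))
        if cid not in counts:
            n_unknown += 1
    if n_unknown:
        log.info("attach_publications: %d node(s) without retrievable count", n_unknown)
    return records


def wilcoxon_rank_sum(x, y, *, exact: bool | None = None) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    Small samples are handled by full permutation enumeration of group
    assignments over the pooled mid-ranks (exact even under ties); larger
    samples use the normal approximation with tie correction and
    continuity correction.  The p-value depends on the data only through
    ranks, hence is invariant under strictly monotone transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    if exact is None:
        exact = comb(n1 + n2, n1) <= MAX_EXACT_COMBINATIONS
    if exact:
        mean_w = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(w_obs - mean_w)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mean_w) >= dev - 1e-12:
                hits += 1
        return float(w_obs), hits / total
    _, p = mannwhitneyu(x, y, alternative="two-sided", use_continuity=True,
                        method="asymptotic")
    return float(w_obs), float(p)


def pearson_residuals(table: np.ndarray) -> np.ndarray:
    """(observed - expected) / sqrt(expected) per cell; the squares sum to
    the chi-squared statistic of the table."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return (table - expected) / np.sqrt(expected)


def literature_tests(
    records: list[PublicationRecord],
    labels: CoverageLabels,
    *,
    alternative: str = "two-sided",
) -> dict:
    """Run the two literature association tests.

    Returns a JSON-ready report with (i) the Wilcoxon rank-sum comparison
    of article counts between mapped and unmapped metabolites, restricted
    to metabolites with >= 1 article; (ii) Fisher's exact test on
    (has >= 1 article) x (mapped), with Pearson residuals per cell; and
    the group sizes and exclusion counts.  The tests are two-sided by
    default; sidedness of the Fisher test is configurable.
    """
    known = [r for r in records if r.n_articles is not None]
    n_excluded = len(records) - len(known)

    mapped_counts = [r.n_articles for r in known if labels.mapped.get(r.node)]
    unmapped_counts = [r.n_articles for r in known if not labels.mapped.get(r.node)]

    # (a) counts among metabolites with at least one article
    mpos = [c for c in mapped_counts if c > 0]
    upos = [c for c in unmapped_counts if c > 0]
    if len(mpos) < 2 or len(upos) < 2:
        raise ValueError("need >= 2 metabolites with >= 1 article per group")
    w_stat, w_p = wilcoxon_rank_sum(mpos, upos)

    # (b) has-article x mapped contingency table
    table = np.array(
        [
            [sum(c > 0 for c in mapped_counts), sum(c == 0 for c in mapped_counts)],
            [sum(c > 0 for c in unmapped_counts), sum(c == 0 for c in unmapped_counts)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table (empty row or column): {table.tolist()}")
    odds, fisher_p = fisher_exact(table, alternative=alternative)
    residuals = pearson_residuals(table)

    return {
        "wilcoxon": {
            "statistic_rank_sum_mapped": w_stat,
            "p_value": w_p,
            "n_mapped": len(mpos),
            "n_unmapped": len(upos),
            "median_mapped": float(np.median(mpos)),
            "median_unmapped": float(np.median(upos)),
        },
        "fisher": {
            "table": table.tolist(),
            "odds_ratio": float(odds),
            "p_value": float(fisher_p),
            "pearson_residuals": residuals.tolist(),
        },
        "n_records": len(records),
        "n_excluded_no_cid_or_count": n_excluded,
    }
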