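"""Hypergeometric term over-representation for DMG lists.

For each annotation term with at least one gene in the background and one
in the query list, the upper-tail hypergeometric probability of drawing at
least the observed number of annotated genes is computed, then adjusted
across terms with Benjamini–Hochberg; terms with FDR below the cutoff are
flagged significant.  Term structure (GO graph propagation, pathway
topology) is out of scope: annotations are taken as flat gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stats import bh_adjust, hypergeom_upper_tail


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    genes: frozenset[str]


def read_annotation(path, name_map_path=None) -> list[TermAnnotation]:
    """Two-column TSV (gene_id, term_id) plus an optional term-name map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], comment="#")
    names = {}
    if name_map_path is not None:
        nm = pd.read_csv(
            name_map_path, sep="\t", header=None, names=["term_id", "term_name"], comment="#"
        )
        names = dict(zip(nm["term_id"], nm["term_name"]))
    return [
        TermAnnotation(term, names.get(term, term), frozenset(grp["gene_id"]))
        for term, grp in df.groupby("term_id")
    ]


def enrich_terms(
    gene_list,
    annotations: list[TermAnnotation],
    universe,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of each term in ``gene_list`` against ``universe``.

    ``gene_list`` must be a subset of the universe.  One hypergeometric test
    per term with K ≥ 1 background genes and k ≥ 1 list genes; BH across all
    tested terms; sorted by FDR.  Columns mirror the usual enrichment-table
    layout: term, bg_count (K), list_count (k), universe (N), list_size (n),
    p, fdr, significant.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty background universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene list is not a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for ann in annotations:
        bg = ann.genes & universe
        K = len(bg)
        k = len(bg & genes)
        if K == 0 or k == 0:
            continue
        rows.append(
            {
                "term_id": ann.term_id,
                "term_name": ann.term_name,
                "bg_count": K,
                "list_count": k,
                "universe": N,
                "list_size": n,
                "p": hypergeom_upper_tail(N, K, n, k),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "bg_count", "list_count", "universe", "list_size", "p"],
    )
    if len(result):
        result["fdr"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["fdr"] < fdr_max
        result = result.sort_values(["fdr", "p", "term_id"]).reset_index(drop=True)
    else:
        result["fdr"] = []
        result["significant"] = []
    return result
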