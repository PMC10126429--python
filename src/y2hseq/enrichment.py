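"""Offline term over-representation analysis.

Hypergeometric (one-sided, upper tail) over-representation of an interactor
hit set against a user-supplied gene->term annotation, with Benjamini-
Hochberg correction across terms.  The universe defaults to all genes
identified in the screen — the proper background for a screening library —
not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError


@dataclass
class TermResult:
    term_id: str
    term_name: str
    n_universe: int
    n_term: int
    n_hits: int
    n_hit_term: int
    p_value: float
    q_value: float


def hypergeom_enrichment(
    hits: set[str],
    annotation: Mapping[str, set[str]],
    universe: set[str],
    term_names: Mapping[str, str] | None = None,
) -> list[TermResult]:
    """Test each term for over-representation among ``hits``.

    For a term with K annotated genes in a universe of N, and n hits of which
    k fall in the term, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Terms with
    no gene in the universe are skipped.  Results are sorted by ascending p
    (ties by term id) and carry BH q-values across all tested terms.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise InvalidInputError("empty universe")
    if not hits:
        raise InvalidInputError("empty hit set")
    if not hits <= universe:
        raise InvalidInputError("hits must be a subset of the universe")
    term_names = term_names or {}

    results: list[TermResult] = []
    N, n = len(universe), len(hits)
    for term_id in sorted(annotation):
        term_genes = set(annotation[term_id]) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            TermResult(
                term_id=term_id,
                term_name=term_names.get(term_id, ""),
                n_universe=N, n_term=K, n_hits=n, n_hit_term=k,
                p_value=min(p, 1.0), q_value=float("nan"),
            )
        )
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_to_frame(results: list[TermResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "n_universe": [r.n_universe for r in results],
            "n_term": [r.n_term for r in results],
            "n_hits": [r.n_hits for r in results],
            "n_hit_term": [r.n_hit_term for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )


def read_gene_term_tsv(path) -> dict[str, set[str]]:
    """Two-column (gene_id, term_id) TSV -> term -> gene set mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise InvalidInputError("annotation TSV must have columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for gid, tid in zip(df["gene_id"], df["term_id"]):
        out.setdefault(str(tid), set()).add(str(gid))
    return out


def write_gene_term_tsv(annotation: Mapping[str, set[str]], path) -> None:
    rows = [(g, t) for t in sorted(annotation) for g in sorted(annotation[t])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT format: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    annotation: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            annotation[parts[0]] = set(parts[2:])
            names[parts[0]] = parts[1]
    if not annotation:
        raise InvalidInputError(f"no gene sets in {path}")
    return annotation, names
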