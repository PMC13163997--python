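"""Hypergeometric over-representation analysis against GMT collections.

The background universe is supplied explicitly — in this pipeline it is the
union of all DEmRNAs across the expression datasets, not the whole genome —
and both the query and every gene set are restricted to it before testing.
Significance is one-sided (upper tail), BH-corrected across tested terms,
with q < 0.05 the conventional cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust
from .matrix import harmonize_symbol

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    term: str
    k: int   # overlap of query and set, within background
    K: int   # set size within background
    n: int   # query size within background
    N: int   # background size
    p: float
    q: float


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file into term -> gene set (symbols upper-cased).

    Lines with fewer than 3 fields are skipped and logged; the description
    field is discarded; duplicate genes within a set collapse.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d skipped line with < 3 fields", path, lineno)
                continue
            term = fields[0].strip()
            genes = {harmonize_symbol(g) for g in fields[2:] if g.strip()}
            sets[term] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def ora(
    query: set[str] | list[str],
    sets: dict[str, set[str]],
    background: set[str] | list[str],
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation test per term.

    Query genes outside the background are dropped (logged); terms with no
    background overlap are skipped.  p = P[X >= k] for X hypergeometric
    with N background genes, K in the set, n drawn.
    """
    bg = {harmonize_symbol(g) for g in background}
    if not bg:
        raise ValueError("empty background gene set")
    q_raw = {harmonize_symbol(g) for g in query}
    dropped = q_raw - bg
    if dropped:
        logger.info("ora: dropped %d query genes outside the background", len(dropped))
    q_set = q_raw & bg
    N, n = len(bg), len(q_set)

    records = []
    for term in sorted(sets):
        term_bg = {harmonize_symbol(g) for g in sets[term]} & bg
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & q_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 1e-300), 1.0)
        records.append(EnrichmentRecord(term=term, k=k, K=K, n=n, N=N, p=p, q=1.0))
    if records:
        qvals = bh_adjust([r.p for r in records])
        for r, qv in zip(records, qvals):
            r.q = float(qv)
    return records


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["term", "k", "K", "n", "N", "p", "q"])
    return df.sort_values(["q", "p", "term"]).reset_index(drop=True)
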