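"""Ingest, intersect, and filter miRNA-target interaction tables.

Two target predictors with complementary algorithms (a conservation-based
TargetScan-like dialect and a machine-learning miRDB-like dialect) are
intersected to obtain higher-confidence miRNA->mRNA edges than either alone;
no score-based filtering is applied on ingestion.  lncRNA-miRNA pairs come
in an ENCORI/starBase-like dialect carrying a CLIP-seq experiment count, and
only pairs with CLIP support survive the filter.  Finally, edges are
restricted to the differentially expressed consensus so that only
candidates with expression evidence feed network assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .matrix import harmonize_symbol

logger = logging.getLogger(__name__)

MIR_MRNA = "mir_mrna"
LNC_MIR = "lnc_mir"

#: Frozen column schemas for the supported file dialects.
DIALECTS: dict[str, dict[str, str]] = {
    # TargetScan-style predicted-targets export
    "targetscan_like": {"mirna": "miRNA", "gene": "Gene Symbol"},
    # miRDB-style target table (carries a score that is deliberately ignored)
    "mirdb_like": {"mirna": "miRNA Name", "gene": "Gene Symbol"},
    # ENCORI/starBase-style lncRNA-miRNA table with CLIP experiment counts
    "encori_like": {"mirna": "miRNAname", "gene": "geneName", "clip": "clipExpNum"},
}


def normalize_mirna(name: str) -> str:
    """Case-fold a miRNA name for matching (the hsa- prefix is kept)."""
    return str(name).strip().lower()


@dataclass(frozen=True)
class InteractionEdge:
    """A typed, evidence-annotated interaction pair.

    ``mir_mrna`` edges run miRNA -> mRNA; ``lnc_mir`` edges pair a lncRNA
    with a miRNA and carry the number of supporting CLIP-seq experiments.
    """

    source: str
    target: str
    edge_type: str
    evidence: frozenset = field(default_factory=frozenset, compare=False)
    clip_count: int = 0

    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.edge_type)


def read_predictions(path, dialect: str) -> list[InteractionEdge]:
    """Read a predictor TSV in one of the supported dialects.

    Names are normalized (miRNAs case-folded, gene symbols upper-cased),
    duplicates collapsed, scores ignored.  Malformed rows are skipped with
    their line numbers logged.
    """
    if dialect not in DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: {sorted(DIALECTS)}"
        )
    schema = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise ValueError(f"dialect {dialect!r} requires columns {missing}")

    edges: dict[tuple, InteractionEdge] = {}
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        mir = rec.get(schema["mirna"])
        gene = rec.get(schema["gene"])
        if not isinstance(mir, str) or not isinstance(gene, str) or not mir.strip() or not gene.strip():
            n_skipped += 1
            logger.warning("%s: skipped malformed row at line %d", path, i)
            continue
        mir = normalize_mirna(mir)
        gene = harmonize_symbol(gene)
        if dialect == "encori_like":
            raw = rec.get(schema["clip"], "0")
            try:
                clip = int(float(raw))
            except (TypeError, ValueError):
                n_skipped += 1
                logger.warning("%s: bad clip count at line %d", path, i)
                continue
            if clip == 0:
                logger.info("%s: edge %s-%s has no CLIP support (flagged)", path, gene, mir)
            edge = InteractionEdge(source=gene, target=mir, edge_type=LNC_MIR,
                                   evidence=frozenset({dialect}), clip_count=clip)
        else:
            edge = InteractionEdge(source=mir, target=gene, edge_type=MIR_MRNA,
                                   evidence=frozenset({dialect}))
        prev = edges.get(edge.key())
        if prev is not None:
            edge = InteractionEdge(
                source=edge.source, target=edge.target, edge_type=edge.edge_type,
                evidence=prev.evidence | edge.evidence,
                clip_count=max(prev.clip_count, edge.clip_count),
            )
        edges[edge.key()] = edge
    if n_skipped:
        logger.info("%s: skipped %d malformed rows", path, n_skipped)
    return sorted(edges.values(), key=InteractionEdge.key)


def intersect_predictors(
    edges_a: list[InteractionEdge], edges_b: list[InteractionEdge]
) -> list[InteractionEdge]:
    """Edges present in both predictor tables, evidence unioned."""
    for e in list(edges_a) + list(edges_b):
        if e.edge_type != MIR_MRNA:
            raise ValueError("intersect_predictors expects mir_mrna edges")
    by_key_b = {e.key(): e for e in edges_b}
    out = []
    seen = set()
    for e in edges_a:
        other = by_key_b.get(e.key())
        if other is not None and e.key() not in seen:
            seen.add(e.key())
            out.append(InteractionEdge(
                source=e.source, target=e.target, edge_type=MIR_MRNA,
                evidence=e.evidence | other.evidence,
                clip_count=max(e.clip_count, other.clip_count),
            ))
    return sorted(out, key=InteractionEdge.key)


def filter_clip(
    edges: list[InteractionEdge], min_experiments: int = 1
) -> list[InteractionEdge]:
    """Keep lncRNA-miRNA pairs with >= min_experiments CLIP-seq experiments."""
    for e in edges:
        if e.edge_type != LNC_MIR:
            raise ValueError("filter_clip expects lnc_mir edges")
    kept = [e for e in edges if e.clip_count >= min_experiments]
    logger.info("CLIP filter (>=%d): kept %d of %d lncRNA-miRNA edges",
                min_experiments, len(kept), len(edges))
    return sorted(kept, key=InteractionEdge.key)


def restrict_to_de(
    edges: list[InteractionEdge],
    de_directions: dict[str, str],
    which_end: str = "both",
) -> list[InteractionEdge]:
    """Keep edges whose designated endpoint(s) are differentially expressed.

    ``de_directions`` maps feature id -> 'up'/'down' (no 'ns' entries).
    """
    if which_end not in ("source", "target", "both"):
        raise ValueError("which_end must be source, target or both")
    if any(d == "ns" for d in de_directions.values()):
        raise ValueError("direction map must not contain 'ns' entries")
    out = []
    for e in edges:
        ok_source = e.source in de_directions
        ok_target = e.target in de_directions
        keep = {"source": ok_source, "target": ok_target,
                "both": ok_source and ok_target}[which_end]
        if keep:
            out.append(e)
    return sorted(out, key=InteractionEdge.key)


def edges_to_frame(edges: list[InteractionEdge],
                   de_directions: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for e in edges:
        row = {
            "source": e.source, "target": e.target, "edge_type": e.edge_type,
            "evidence": ",".join(sorted(e.evidence)), "clip_count": e.clip_count,
        }
        if de_directions is not None:
            row["source_direction"] = de_directions.get(e.source, "")
            row["target_direction"] = de_directions.get(e.target, "")
        rows.append(row)
    cols = ["source", "target", "edge_type", "evidence", "clip_count"]
    if de_directions is not None:
        cols += ["source_direction", "target_direction"]
    return pd.DataFrame(rows, columns=cols)


def write_edges(edges: list[InteractionEdge], path,
                de_directions: dict[str, str] | None = None,
                header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        edges_to_frame(edges, de_directions).to_csv(fh, sep="\t", index=False)
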