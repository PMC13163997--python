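"""Directional multi-dataset intersection of differential-expression calls.

A feature enters the consensus `up` set iff it is called up in at least
``min_datasets`` datasets and is never called down in any dataset
(symmetrically for `down`).  A direction conflict anywhere excludes the
feature entirely — concordance across series is the point of the exercise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .matrix import harmonize_symbol

logger = logging.getLogger(__name__)


@dataclass
class ConsensusSet:
    up: set[str]
    down: set[str]
    membership: dict[str, dict[str, str]]  # feature -> {dataset: direction}
    n_datasets: int
    venn_counts: dict[str, dict[tuple[str, ...], int]] = field(default_factory=dict)

    def directions(self) -> dict[str, str]:
        """Map consensus feature -> direction, for downstream stages."""
        out = {f: "up" for f in self.up}
        out.update({f: "down" for f in self.down})
        return out


def _calls_from_table(table: pd.DataFrame, name: str) -> dict[str, str]:
    """Extract feature -> direction (up/down only) from a DE table."""
    calls: dict[str, str] = {}
    for feat, direction in zip(table["feature"], table["direction"]):
        if direction == "ns":
            continue
        sym = harmonize_symbol(feat)
        if sym in calls and calls[sym] != direction:
            raise ValueError(
                f"conflicting duplicate rows for feature {sym!r} in table {name!r}"
            )
        calls[sym] = direction
    return calls


def intersect_directional(
    de_tables: list[pd.DataFrame],
    min_datasets: int | None = None,
    names: list[str] | None = None,
) -> ConsensusSet:
    """Intersect per-dataset DE calls, requiring directional concordance.

    Parameters
    ----------
    de_tables
        DE tables with ``feature`` and ``direction`` columns (from
        :func:`cernax.diffexp.call_de`).  Symbols are case-normalized.
    min_datasets
        Minimum number of datasets a feature must be called in (same
        direction); default: all of them.
    """
    if len(de_tables) < 2:
        raise ValueError("need at least 2 DE tables to intersect")
    names = names or [f"dataset_{i+1}" for i in range(len(de_tables))]
    k = len(de_tables)
    if min_datasets is None:
        min_datasets = k

    calls = [_calls_from_table(t, n) for t, n in zip(de_tables, names)]
    membership: dict[str, dict[str, str]] = {}
    for name, table_calls in zip(names, calls):
        for feat, direction in table_calls.items():
            membership.setdefault(feat, {})[name] = direction

    up, down = set(), set()
    for feat, per_ds in membership.items():
        dirs = set(per_ds.values())
        if dirs == {"up"} and len(per_ds) >= min_datasets:
            up.add(feat)
        elif dirs == {"down"} and len(per_ds) >= min_datasets:
            down.add(feat)

    venn = {d: _venn_counts(calls, names, d) for d in ("up", "down")}
    logger.info("consensus: %d up, %d down across %d datasets", len(up), len(down), k)
    return ConsensusSet(up=up, down=down, membership=membership,
                        n_datasets=k, venn_counts=venn)


def _venn_counts(
    calls: list[dict[str, str]], names: list[str], direction: str
) -> dict[tuple[str, ...], int]:
    """Exclusive Venn region sizes for one direction's call sets."""
    sets = {n: {f for f, d in c.items() if d == direction}
            for n, c in zip(names, calls)}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[combo] = len(inside - outside)
    return regions


def write_consensus(consensus: ConsensusSet, path, header_lines: list[str] | None = None) -> None:
    rows = [{"feature": f, "direction": d, "n_datasets_called": len(consensus.membership[f])}
            for f, d in sorted(consensus.directions().items())]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["feature", "direction", "n_datasets_called"]).to_csv(
            fh, sep="\t", index=False)
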