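"""Expression matrix container shared by every pipeline stage.

A matrix is features x samples, with a declared ``scale`` (``log2``,
``linear`` or ``counts``) and ``platform`` (``microarray`` or
``rnaseq_counts``).  Duplicate feature rows — a probe-to-gene situation on
microarrays — are collapsed at construction to the row with the highest mean
expression, the common GEO2R-era convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("log2", "linear", "counts")
PLATFORMS = ("microarray", "rnaseq_counts")


def harmonize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol: trim, uppercase, drop a trailing
    dot-version suffix (``Tp53.2`` -> ``TP53``)."""
    s = str(symbol).strip().upper()
    head, dot, tail = s.rpartition(".")
    if dot and tail.isdigit():
        return head
    return s


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values with scale/platform metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    scale
        One of ``log2``, ``linear``, ``counts``.
    platform
        One of ``microarray``, ``rnaseq_counts``.
    """

    values: pd.DataFrame
    scale: str = "log2"
    platform: str = "microarray"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"platform must be one of {PLATFORMS}, got {self.platform!r}"
            )
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.index.duplicated().any():
            self.values = _collapse_duplicates(self.values)
        if self.scale == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, scale or self.scale, self.platform, dict(self.meta))

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path, scale: str = "log2", platform: str = "microarray") -> "ExpressionMatrix":
        """Read a feature x sample TSV (first column = feature id; ``#``
        comment lines skipped)."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df, scale=scale, platform=platform)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="feature")


def _collapse_duplicates(values: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated feature id, the row with the highest mean."""
    means = values.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    deduped = values.iloc[order]
    deduped = deduped[~deduped.index.duplicated(keep="first")]
    kept = deduped.reindex(index=pd.unique(values.index))
    n_dropped = len(values) - len(kept)
    if n_dropped:
        logger.info("collapsed %d duplicate feature rows (max-mean rule)", n_dropped)
    return kept


def read_groups(path) -> pd.Series:
    """Read a two-column sample->group TSV (columns: sample, group)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("group file needs two columns: sample, group")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="group")
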