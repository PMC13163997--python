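"""Synthetic multi-dataset cohorts with planted ground truth.

The generator emulates the statistical structure of the study conditions
this pipeline targets: several small two-group expression series (down to
2-vs-8 and 3-vs-17 class sizes) in both microarray-like Gaussian-log2 and
RNA-seq negative-binomial flavors, two miRNA-target predictor tables plus a
CLIP-annotated lncRNA-miRNA table with planted true edges and decoys, and a
censored survival cohort whose hazard is linked to one gene's expression.
Every generator is deterministic under its seed, and the planted truth
(DE genes with directions and effects, the ceRNA axis, the hazard ratio,
and the decoy edges) is carried in a TruthTable so recovery is testable.

The planted axis mirrors the canonical shape of interest: one downregulated
lncRNA ("XIST-like") sponging six upregulated miRNAs that share one
downregulated mRNA target ("ZNF662-like").  Feature ids are synthetic so no
test depends on real annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

#: designated aliases for the planted axis anchors
AXIS_LNCRNA = "XIST-LIKE"
AXIS_MRNA = "ZNF662-LIKE"
AXIS_MIRNAS = tuple(f"hsa-mir-ax{i}-5p" for i in range(1, 7))

NB_DISPERSION = 0.1  # single dispersion per run keeps recovery tests analytic


@dataclass
class TruthTable:
    """Planted ground truth: DE genes, the ceRNA axis, hazard ratio, decoys.

    ``planted_de`` maps feature -> (direction, log2 effect); the axis is
    (lncRNA, miRNA tuple, mRNA).  ``planted_hr`` is the hazard ratio of the
    axis mRNA's high-expression group.  ``decoy_edges`` holds
    (source, target, edge_type) keys known to be false.
    """

    planted_de: dict[str, tuple[str, float]]
    axis: tuple[str, tuple[str, ...], str]
    planted_hr: float = 0.65
    decoy_edges: set[tuple[str, str, str]] = field(default_factory=set)
    de_threshold: float = 1.0

    def __post_init__(self) -> None:
        lnc, mirs, mrna = self.axis
        for node in (lnc, mrna, *mirs):
            if node not in self.planted_de:
                raise ValueError(f"axis member {node!r} missing from planted_de")
        d_lnc = self.planted_de[lnc][0]
        d_mrna = self.planted_de[mrna][0]
        if d_lnc != d_mrna:
            raise ValueError("axis lncRNA and mRNA must share a direction")
        for m in mirs:
            if self.planted_de[m][0] == d_lnc:
                raise ValueError(f"axis miRNA {m!r} must oppose the lncRNA/mRNA direction")
        for feat, (direction, eff) in self.planted_de.items():
            if direction not in ("up", "down"):
                raise ValueError(f"{feat!r}: direction must be up or down")
            if abs(eff) <= self.de_threshold:
                raise ValueError(
                    f"{feat!r}: |log2 effect| {abs(eff)} must exceed the DE "
                    f"threshold {self.de_threshold}")
            if (direction == "up") != (eff > 0):
                raise ValueError(f"{feat!r}: direction and effect sign disagree")

    def signed_effect(self, feature: str) -> float:
        return self.planted_de[feature][1]

    def axis_members(self) -> set[str]:
        lnc, mirs, mrna = self.axis
        return {lnc, mrna, *mirs}


@dataclass
class CohortSpec:
    """Shape and noise of one synthetic two-group expression dataset."""

    n_tumor: int
    n_normal: int
    n_features: int
    platform: str = "microarray"  # microarray | rnaseq_counts
    noise_sd: float = 0.5         # log2 scale
    library_size_range: tuple[int, int] = (500_000, 1_500_000)
    nb_dispersion: float = NB_DISPERSION  # counts only; fixed per run
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("need at least one sample per group")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.platform not in ("microarray", "rnaseq_counts"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def default_truth(
    n_extra_up: int = 15, n_extra_down: int = 9,
    effect: float = 2.5, planted_hr: float = 0.65,
) -> TruthTable:
    """The standard planted truth: the XIST-like axis plus extra shared DE
    mRNAs (defaults give 15 up + 10 down mRNAs, the downregulated axis mRNA
    counted among the 10)."""
    planted: dict[str, tuple[str, float]] = {
        AXIS_LNCRNA: ("down", -effect),
        AXIS_MRNA: ("down", -effect),
    }
    for m in AXIS_MIRNAS:
        planted[m] = ("up", effect)
    for i in range(n_extra_up):
        planted[f"UPGENE{i+1:03d}"] = ("up", effect)
    for i in range(n_extra_down):
        planted[f"DNGENE{i+1:03d}"] = ("down", -effect)
    return TruthTable(planted_de=planted,
                      axis=(AXIS_LNCRNA, AXIS_MIRNAS, AXIS_MRNA),
                      planted_hr=planted_hr)


# ------------------------------------------------------------------ cohorts

def generate_cohort(
    spec: CohortSpec,
    truth: TruthTable,
    features: list[str] | None = None,
    planted: dict[str, tuple[str, float]] | None = None,
    prefix: str = "G",
) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate one two-group expression dataset.

    Microarray: Gaussian log2 intensities, baseline + planted group shift +
    N(0, noise_sd).  Counts: negative binomial (dispersion 0.1) whose
    log2 fold change in expected counts equals the planted effect exactly.
    Returns the matrix and a sample -> {tumor, normal} label Series.
    """
    planted = truth.planted_de if planted is None else planted
    if features is None:
        if spec.n_features < len(planted):
            raise ValueError(
                f"n_features={spec.n_features} is smaller than the "
                f"{len(planted)} planted features")
        features = list(planted)
        features += [f"{prefix}FILL{i+1:05d}"
                     for i in range(max(0, spec.n_features - len(features)))]
        features = features[: spec.n_features]
    for feat in planted:
        if feat not in features:
            raise ValueError(f"planted feature {feat!r} not in the feature universe")

    rng = np.random.default_rng(spec.seed)
    n_feat = len(features)
    n = spec.n_tumor + spec.n_normal
    samples = [f"T{i+1:03d}" for i in range(spec.n_tumor)] + \
              [f"N{i+1:03d}" for i in range(spec.n_normal)]
    labels = pd.Series(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal,
                       index=samples, name="group")

    baseline = rng.uniform(5.0, 9.0, size=n_feat)
    effects = np.array([planted[f][1] if f in planted else 0.0 for f in features])
    # planted features stay off the extremes of the intensity range: a
    # shifted feature whose baseline already sits at the boundary occupies
    # the same extreme rank in both groups, and rank-based (quantile)
    # normalization then pins it to the reference tail, erasing the shift
    planted_mask = effects != 0.0
    if planted_mask.any():
        baseline[planted_mask] = rng.uniform(5.4, 8.6, size=planted_mask.sum())
    tumor_mask = np.array([True] * spec.n_tumor + [False] * spec.n_normal)

    if spec.platform == "microarray":
        mean = baseline[:, None] + np.where(tumor_mask[None, :], effects[:, None], 0.0)
        noise = rng.normal(0.0, spec.noise_sd, size=(n_feat, n)) if spec.noise_sd > 0 \
            else np.zeros((n_feat, n))
        values = pd.DataFrame(mean + noise, index=features, columns=samples)
        return ExpressionMatrix(values, scale="log2", platform="microarray"), labels

    # RNA-seq counts: expected count = lib * prop, tumor prop scaled 2^effect
    lo, hi = spec.library_size_range
    libs = rng.integers(lo, hi + 1, size=n).astype(float)
    base_prop = 2.0 ** baseline
    base_prop = base_prop / base_prop.sum()
    mu = libs[None, :] * base_prop[:, None] * \
        np.where(tumor_mask[None, :], 2.0 ** effects[:, None], 1.0)
    # biological noise on the log2 scale before NB sampling
    if spec.noise_sd > 0:
        mu = mu * 2.0 ** rng.normal(0.0, spec.noise_sd, size=mu.shape)
    r = 1.0 / spec.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    values = pd.DataFrame(counts, index=features, columns=samples)
    return ExpressionMatrix(values, scale="counts", platform="rnaseq_counts"), labels


# --------------------------------------------------------- interaction data

class InteractionTables(NamedTuple):
    predictor_a: pd.DataFrame   # targetscan_like dialect
    predictor_b: pd.DataFrame   # mirdb_like dialect
    lnc_mir: pd.DataFrame       # encori_like dialect
    decoy_edges: set[tuple[str, str, str]]


def generate_interaction_tables(
    truth: TruthTable,
    n_decoys_per_predictor: int = 50,
    predictor_overlap_fraction: float = 0.2,
    seed: int = 0,
    n_lnc_decoys: int = 20,
) -> InteractionTables:
    """Predictor tables with all true axis edges plus decoys.

    Every true miRNA->mRNA edge appears in both predictor tables; every
    true lncRNA-miRNA pair appears in the CLIP table with clip count >= 1.
    Exactly round(fraction * n_decoys) decoys are shared between the two
    predictors; about half the lncRNA decoys carry clip count 0 so the
    CLIP filter has something to remove.
    """
    if n_decoys_per_predictor < 0 or n_lnc_decoys < 0:
        raise ValueError("decoy counts must be non-negative")
    if not 0.0 <= predictor_overlap_fraction <= 1.0:
        raise ValueError("overlap fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lnc, mirs, mrna = truth.axis

    true_pairs = [(m, mrna) for m in mirs]
    n_shared = round(predictor_overlap_fraction * n_decoys_per_predictor)
    n_unique = n_decoys_per_predictor - n_shared

    def decoy_pair(tag: str, i: int) -> tuple[str, str]:
        return (f"hsa-mir-{tag}{i+1:03d}-5p", f"DECOY-{tag.upper()}{i+1:03d}")

    shared = [decoy_pair("sh", i) for i in range(n_shared)]
    only_a = [decoy_pair("pa", i) for i in range(n_unique)]
    only_b = [decoy_pair("pb", i) for i in range(n_unique)]

    rows_a = true_pairs + shared + only_a
    rows_b = true_pairs + shared + only_b
    pred_a = pd.DataFrame({"miRNA": [m for m, _ in rows_a],
                           "Gene Symbol": [g for _, g in rows_a]})
    pred_b = pd.DataFrame({"miRNA Name": [m for m, _ in rows_b],
                           "Gene Symbol": [g for _, g in rows_b],
                           "Target Score": rng.integers(50, 101, len(rows_b))})

    lnc_rows = [(lnc, m, int(rng.integers(1, 11))) for m in mirs]
    decoys: set[tuple[str, str, str]] = set()
    for i in range(n_lnc_decoys):
        dl = f"LNC-DECOY{i+1:03d}"
        dm = f"hsa-mir-ld{i+1:03d}-5p"
        clip = 0 if i % 2 == 0 else int(rng.integers(1, 6))
        lnc_rows.append((dl, dm, clip))
        decoys.add((dl, dm, "lnc_mir"))
    lnc_df = pd.DataFrame({"geneName": [r[0] for r in lnc_rows],
                           "miRNAname": [r[1] for r in lnc_rows],
                           "clipExpNum": [r[2] for r in lnc_rows]})

    for m, g in shared + only_a + only_b:
        decoys.add((m, g, "mir_mrna"))
    return InteractionTables(pred_a, pred_b, lnc_df, decoys)


# ------------------------------------------------------------------ survival

def generate_survival(
    n_patients: int,
    expression: np.ndarray | None = None,
    planted_hr: float = 0.65,
    baseline_hazard: float = 0.05,
    censoring_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Censored survival cohort with an expression-linked hazard.

    Event times are exponential; patients whose expression exceeds the
    cohort median have their hazard multiplied by ``planted_hr``.
    Censoring is independent, with per-patient censoring hazard chosen so
    the expected censored fraction equals ``censoring_rate``.  Returns a
    DataFrame (index: patient) with columns time, event, expression, group.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if planted_hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if expression is None:
        expression = rng.normal(8.0, 1.0, size=n_patients)
    expression = np.asarray(expression, float)
    if len(expression) != n_patients:
        raise ValueError("expression length must match n_patients")

    high = expression > np.median(expression)
    hazard = baseline_hazard * np.where(high, planted_hr, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        cens_hazard = hazard * censoring_rate / (1.0 - censoring_rate)
        cens_time = rng.exponential(1.0 / cens_hazard)
    else:
        cens_time = np.full(n_patients, math.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    patients = [f"P{i+1:04d}" for i in range(n_patients)]
    return pd.DataFrame({"time": time, "event": event,
                         "expression": expression,
                         "group": np.where(high, "high", "low")},
                        index=pd.Index(patients, name="patient"))
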