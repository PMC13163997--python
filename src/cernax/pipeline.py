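"""Config-driven orchestration of the full ceRNA-axis discovery run.

Stage order mirrors the analysis it implements: per-dataset differential
expression (each dataset analyzed independently, no cross-dataset batch
correction), directional consensus over the mRNA series, predictor
intersection and CLIP filtering, restriction to DE features,
sign-consistent triplet assembly and network export, then joint evaluation
of the network mRNAs by median-split survival screening and per-dataset
ROC, plus over-representation of the panel genes against a GMT collection
with the union of all DEmRNAs as background.  The final axis report ranks
candidates deterministically: survival significance first, then log-rank
p, then best AUC, then DE concordance count.

Every output table carries a provenance header (stage, config hash, seed)
and a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import diagnostics, diffexp, enrichment, interactions, network, simulate
from . import survival as survival_mod
from .matrix import ExpressionMatrix, read_groups

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- config

@dataclass
class DatasetConfig:
    name: str
    expression: str
    groups: str
    role: str = "mrna"            # mrna | mirna | lncrna
    platform: str = "microarray"  # microarray | rnaseq_counts
    scale: str = "log2"           # log2 | linear | counts


@dataclass
class SimulationConfig:
    """Shapes of the synthetic bundle; defaults emulate the study cohorts
    (167/45, 6/6, 5/2, 3/3 mRNA; 17/3 miRNA; 8/2 lncRNA; survival n=499)
    at scaled-down feature counts."""

    n_features_mrna: int = 300
    n_features_mirna: int = 150
    n_features_lncrna: int = 200
    noise_sd_microarray: float = 0.5
    noise_sd_rnaseq: float = 0.3
    nb_dispersion: float = 0.1
    n_private_de: int = 10
    n_extra_up: int = 15
    n_extra_down: int = 9
    effect: float = 2.5
    planted_hr: float = 0.65
    n_decoys_per_predictor: int = 40
    predictor_overlap_fraction: float = 0.25
    n_lnc_decoys: int = 20
    n_panel_extra: int = 20
    n_patients: int = 499
    censoring_rate: float = 0.5
    baseline_hazard: float = 0.05
    mrna_shapes: tuple = ((167, 45, "microarray"), (6, 6, "microarray"),
                          (5, 2, "rnaseq_counts"), (3, 3, "rnaseq_counts"))
    mirna_shape: tuple = (17, 3, "microarray")
    lncrna_shape: tuple = (8, 2, "rnaseq_counts")

    @classmethod
    def clean_fixture(cls, **overrides) -> "SimulationConfig":
        """Strong effects, modest noise: the configuration under which the
        planted axis is expected to be recovered in full.  The default
        effect size (2.5 log2 units) with tiny count cohorts (5v2, 3v3)
        leaves a non-negligible per-gene miss probability — partly CPM
        compositional compression, partly plain small-n noise — so
        recovery guarantees are stated for this fixture.  The fixture also
        keeps the DE fraction small (large null-feature universe): with
        many strongly shifted features, quantile normalization visibly
        distorts null genes."""
        params = dict(effect=3.0, noise_sd_microarray=0.3,
                      noise_sd_rnaseq=0.15, nb_dispersion=0.02,
                      n_features_mrna=1000, n_features_mirna=200,
                      n_features_lncrna=400)
        params.update(overrides)
        return cls(**params)


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    datasets: list[DatasetConfig] = field(default_factory=list)
    lfc_cut: float = 1.0
    fdr_cut: float = 0.05
    consensus_min_datasets: int | None = None
    clip_min_experiments: int = 1
    predictor_a: str | None = None     # targetscan_like TSV
    predictor_b: str | None = None     # mirdb_like TSV
    lnc_mir_table: str | None = None   # encori_like TSV
    survival_table: str | None = None
    gmt: str | None = None
    n_boot: int = 400
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0 or not 0 < self.fdr_cut < 1:
            raise ValueError("thresholds must be positive (fdr in (0,1))")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["datasets"] = [DatasetConfig(**d) for d in raw.get("datasets", [])]
        if raw.get("simulation") is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    outdir: Path
    de_tables: dict[str, pd.DataFrame]
    consensus: "consensus_mod.ConsensusSet | None" = None
    panel: list[str] = field(default_factory=list)
    network: "network.CeRNANetwork | None" = None
    survival_table: pd.DataFrame | None = None
    roc_table: pd.DataFrame | None = None
    enrichment_table: pd.DataFrame | None = None
    axis_report: pd.DataFrame | None = None
    message: str = ""


def _sub_seed(seed: int, tag: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2^31)."""
    return (seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _write_table(df: pd.DataFrame, path: Path, stage: str,
                 cfg_hash: str, seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n# config_hash: {cfg_hash}\n# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=index)


# --------------------------------------------------------------- simulate

def simulate_bundle(config: PipelineConfig) -> tuple[PipelineConfig, simulate.TruthTable]:
    """Write a complete synthetic input bundle and return a config wired to
    it, plus the planted TruthTable (also serialized as TSV)."""
    if config.simulation is None:
        raise ValueError("config has no simulation block")
    sim = config.simulation
    outdir = Path(config.outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    truth = simulate.default_truth(
        n_extra_up=sim.n_extra_up, n_extra_down=sim.n_extra_down,
        effect=sim.effect, planted_hr=sim.planted_hr)

    mrna_planted = {f: v for f, v in truth.planted_de.items()
                    if f not in truth.axis_members() or f == truth.axis[2]}
    mirna_planted = {m: truth.planted_de[m] for m in truth.axis[1]}
    lnc_planted = {truth.axis[0]: truth.planted_de[truth.axis[0]]}

    # shared mRNA universe: planted + per-dataset private DE + fillers
    private: dict[str, dict[str, tuple[str, float]]] = {}
    for i in range(len(sim.mrna_shapes)):
        name = f"mrna_{chr(97 + i)}"
        private[name] = {}
        for j in range(sim.n_private_de):
            sign = 1 if j % 2 == 0 else -1
            private[name][f"{name.upper()}-PRIV{j+1:03d}"] = (
                "up" if sign > 0 else "down", sign * sim.effect)
    all_private = [g for d in private.values() for g in d]
    mrna_features = list(mrna_planted) + all_private
    mrna_features += [f"MFILL{i+1:05d}" for i in
                      range(max(0, sim.n_features_mrna - len(mrna_features)))]

    datasets: list[DatasetConfig] = []
    for i, (n_t, n_n, platform) in enumerate(sim.mrna_shapes):
        name = f"mrna_{chr(97 + i)}"
        noise = sim.noise_sd_microarray if platform == "microarray" else sim.noise_sd_rnaseq
        spec = simulate.CohortSpec(
            n_tumor=n_t, n_normal=n_n, n_features=len(mrna_features),
            platform=platform, noise_sd=noise,
            nb_dispersion=sim.nb_dispersion, seed=_sub_seed(seed, name))
        planted = {**mrna_planted, **private[name]}
        mat, labels = simulate.generate_cohort(spec, truth, features=mrna_features,
                                               planted=planted)
        datasets.append(_write_dataset(inputs, name, "mrna", mat, labels))

    # miRNA dataset: axis miRNAs (DE) + decoy miRNA features (null) + fillers
    mirna_features = list(mirna_planted)
    mirna_features += [f"hsa-mir-null{i+1:04d}-5p" for i in
                       range(max(0, sim.n_features_mirna - len(mirna_features)))]
    n_t, n_n, platform = sim.mirna_shape
    spec = simulate.CohortSpec(
        n_tumor=n_t, n_normal=n_n, n_features=len(mirna_features),
        platform=platform, noise_sd=sim.noise_sd_microarray,
        nb_dispersion=sim.nb_dispersion, seed=_sub_seed(seed, "mirna"))
    mat, labels = simulate.generate_cohort(spec, truth, features=mirna_features,
                                           planted=mirna_planted)
    datasets.append(_write_dataset(inputs, "mirna", "mirna", mat, labels))

    # lncRNA dataset
    lnc_features = list(lnc_planted)
    lnc_features += [f"LNCFILL{i+1:04d}" for i in
                     range(max(0, sim.n_features_lncrna - len(lnc_features)))]
    n_t, n_n, platform = sim.lncrna_shape
    spec = simulate.CohortSpec(
        n_tumor=n_t, n_normal=n_n, n_features=len(lnc_features),
        platform=platform,
        noise_sd=(sim.noise_sd_microarray if platform == "microarray"
                  else sim.noise_sd_rnaseq),
        nb_dispersion=sim.nb_dispersion, seed=_sub_seed(seed, "lncrna"))
    mat, labels = simulate.generate_cohort(spec, truth, features=lnc_features,
                                           planted=lnc_planted)
    datasets.append(_write_dataset(inputs, "lncrna", "lncrna", mat, labels))

    # interaction tables; extra predictor rows point decoy miRNAs at planted
    # genes so the DE-supported target panel has more than the axis mRNA
    tables = simulate.generate_interaction_tables(
        truth, n_decoys_per_predictor=sim.n_decoys_per_predictor,
        predictor_overlap_fraction=sim.predictor_overlap_fraction,
        seed=_sub_seed(seed, "interactions"), n_lnc_decoys=sim.n_lnc_decoys)
    panel_genes = [g for g in mrna_planted if g != truth.axis[2]][: sim.n_panel_extra]
    extra = pd.DataFrame({
        "mir": [f"hsa-mir-panel{i+1:03d}-5p" for i in range(len(panel_genes))],
        "gene": panel_genes})
    pred_a = pd.concat([tables.predictor_a,
                        extra.rename(columns={"mir": "miRNA", "gene": "Gene Symbol"})],
                       ignore_index=True)
    pred_b_extra = extra.rename(columns={"mir": "miRNA Name", "gene": "Gene Symbol"})
    pred_b_extra["Target Score"] = 90
    pred_b = pd.concat([tables.predictor_b, pred_b_extra], ignore_index=True)
    decoys = set(tables.decoy_edges) | {
        (m, g, "mir_mrna") for m, g in zip(extra["mir"], extra["gene"])}
    truth.decoy_edges = decoys

    pred_a.to_csv(inputs / "predictor_a.tsv", sep="\t", index=False)
    pred_b.to_csv(inputs / "predictor_b.tsv", sep="\t", index=False)
    tables.lnc_mir.to_csv(inputs / "lnc_mir.tsv", sep="\t", index=False)

    # survival cohort: hazard linked to the axis mRNA's expression
    surv = simulate.generate_survival(
        n_patients=sim.n_patients, planted_hr=sim.planted_hr,
        baseline_hazard=sim.baseline_hazard,
        censoring_rate=sim.censoring_rate, seed=_sub_seed(seed, "survival"))
    expr_rng = np.random.default_rng(_sub_seed(seed, "survival_expr"))
    surv_expr = pd.DataFrame(
        expr_rng.normal(8.0, 1.0, size=(len(mrna_planted), sim.n_patients)),
        index=list(mrna_planted), columns=surv.index)
    surv_expr.loc[truth.axis[2]] = surv["expression"].to_numpy()
    surv[["time", "event"]].to_csv(inputs / "survival.tsv", sep="\t")
    surv_expr.to_csv(inputs / "survival_expression.tsv", sep="\t",
                     index_label="feature")

    # GMT: an EMT-like program drawn from the planted panel plus null terms
    rng = np.random.default_rng(_sub_seed(seed, "gmt"))
    emt = set(panel_genes[: max(5, len(panel_genes) // 2)]) | {truth.axis[2]}
    gmt_sets = {"HALLMARK_EMT_LIKE": emt}
    fillers = [f for f in mrna_features if f.startswith("MFILL")]
    for i in range(5):
        pick = rng.choice(len(fillers), size=min(25, len(fillers)), replace=False)
        gmt_sets[f"NULL_PROGRAM_{i+1}"] = {fillers[j] for j in pick}
    enrichment.write_gmt(gmt_sets, inputs / "collections.gmt")

    truth_rows = [{"feature": f, "direction": d, "log2_effect": e,
                   "axis_member": f in truth.axis_members()}
                  for f, (d, e) in sorted(truth.planted_de.items())]
    pd.DataFrame(truth_rows).to_csv(inputs / "truth.tsv", sep="\t", index=False)

    wired = PipelineConfig(
        outdir=str(outdir), seed=seed, datasets=datasets,
        lfc_cut=config.lfc_cut, fdr_cut=config.fdr_cut,
        consensus_min_datasets=config.consensus_min_datasets,
        clip_min_experiments=config.clip_min_experiments,
        predictor_a=str(inputs / "predictor_a.tsv"),
        predictor_b=str(inputs / "predictor_b.tsv"),
        lnc_mir_table=str(inputs / "lnc_mir.tsv"),
        survival_table=str(inputs / "survival.tsv"),
        gmt=str(inputs / "collections.gmt"),
        n_boot=config.n_boot, simulation=sim)
    return wired, truth


def _write_dataset(inputs: Path, name: str, role: str,
                   mat: ExpressionMatrix, labels: pd.Series) -> DatasetConfig:
    expr_path = inputs / f"{name}_expression.tsv"
    group_path = inputs / f"{name}_groups.tsv"
    mat.to_tsv(expr_path)
    labels.rename_axis("sample").reset_index().to_csv(group_path, sep="\t", index=False)
    return DatasetConfig(name=name, expression=str(expr_path),
                         groups=str(group_path), role=role,
                         platform=mat.platform, scale=mat.scale)


# --------------------------------------------------------------- pipeline

def _run_de(ds: DatasetConfig, config: PipelineConfig) -> pd.DataFrame:
    mat = ExpressionMatrix.from_tsv(ds.expression, scale=ds.scale,
                                    platform=ds.platform)
    groups = read_groups(ds.groups)
    if ds.scale == "counts":
        logcpm, weights = diffexp.voom_transform(mat, groups)
        fit, table = diffexp.fit_and_moderate(
            logcpm, groups, weights=weights,
            lfc_cut=config.lfc_cut, fdr_cut=config.fdr_cut)
    else:
        mat = diffexp.maybe_log2(mat)
        mat = diffexp.quantile_normalize(mat)
        fit, table = diffexp.fit_and_moderate(
            mat, groups, lfc_cut=config.lfc_cut, fdr_cut=config.fdr_cut)
    return table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage the config supports and write the output tree."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    seed = config.seed

    for ds in config.datasets:
        for p in (ds.expression, ds.groups):
            if not Path(p).exists():
                raise FileNotFoundError(
                    f"stage differential_expression: missing input {p} "
                    f"(dataset {ds.name})")

    # ---- stage 1: per-dataset DE (independent fits, no batch correction)
    de_tables: dict[str, pd.DataFrame] = {}
    roles: dict[str, str] = {}
    for ds in config.datasets:
        table = _run_de(ds, config)
        de_tables[ds.name] = table
        roles[ds.name] = ds.role
        _write_table(table, outdir / f"de_{ds.name}.tsv",
                     "differential_expression", cfg_hash, seed)

    result = PipelineResult(outdir=outdir, de_tables=de_tables)

    # ---- stage 2: directional consensus across mRNA datasets
    mrna_names = [n for n, r in roles.items() if r == "mrna"]
    if len(mrna_names) < 2:
        result.message = "fewer than two mRNA datasets: consensus skipped"
        logger.warning(result.message)
        return result
    cons = consensus_mod.intersect_directional(
        [de_tables[n] for n in mrna_names],
        min_datasets=config.consensus_min_datasets, names=mrna_names)
    consensus_mod.write_consensus(
        cons, outdir / "consensus.tsv",
        header_lines=[f"stage: consensus", f"config_hash: {cfg_hash}",
                      f"seed: {seed}"])
    result.consensus = cons

    mirna_names = [n for n, r in roles.items() if r == "mirna"]
    lnc_names = [n for n, r in roles.items() if r == "lncrna"]
    if not mirna_names or not lnc_names or not all(
            (config.predictor_a, config.predictor_b, config.lnc_mir_table)):
        result.message = ("only mRNA evidence available: stopping after "
                          "consensus (need miRNA and lncRNA datasets plus "
                          "interaction tables for network assembly)")
        logger.warning(result.message)
        return result

    # ---- stage 3: interaction ingestion, intersection, filters
    edges_a = interactions.read_predictions(config.predictor_a, "targetscan_like")
    edges_b = interactions.read_predictions(config.predictor_b, "mirdb_like")
    mir_mrna = interactions.intersect_predictors(edges_a, edges_b)
    lnc_mir = interactions.read_predictions(config.lnc_mir_table, "encori_like")
    lnc_mir = interactions.filter_clip(lnc_mir, config.clip_min_experiments)

    mirna_dirs = _role_directions(de_tables, mirna_names)
    lnc_dirs = _role_directions(de_tables, lnc_names)
    cons_dirs = cons.directions()

    # panel: consensus genes supported as predicted targets (gene end only)
    panel = sorted({e.target for e in mir_mrna} & set(cons_dirs))
    result.panel = panel

    directions = {**cons_dirs, **mirna_dirs, **lnc_dirs}
    mir_mrna_de = interactions.restrict_to_de(mir_mrna, directions, "both")
    mir_mrna_de = [e for e in mir_mrna_de if e.target in cons_dirs
                   and e.source in mirna_dirs]
    lnc_mir_de = interactions.restrict_to_de(lnc_mir, directions, "both")
    lnc_mir_de = [e for e in lnc_mir_de if e.source in lnc_dirs
                  and e.target in mirna_dirs]
    interactions.write_edges(
        mir_mrna_de, outdir / "edges_mir_mrna.tsv", directions,
        header_lines=[f"stage: interactions", f"config_hash: {cfg_hash}",
                      f"seed: {seed}"])
    interactions.write_edges(
        lnc_mir_de, outdir / "edges_lnc_mir.tsv", directions,
        header_lines=[f"stage: interactions", f"config_hash: {cfg_hash}",
                      f"seed: {seed}"])

    # ---- stage 4: sign-consistent triplets and network exports
    triplets = network.assemble_triplets(lnc_mir_de, mir_mrna_de, directions)
    net = network.build_network(triplets)
    result.network = net
    for fmt, fname in (("sif", "network.sif"), ("graphml", "network.graphml"),
                       ("edge_tsv", "network_edges.tsv"),
                       ("node_tsv", "network_nodes.tsv")):
        network.export_network(net, outdir / fname, fmt)

    net_mrnas = sorted(n for n, d in net.graph.nodes(data=True)
                       if d["node_type"] == "mRNA")

    # ---- stage 5: survival screen on the network mRNAs
    surv_table = None
    if config.survival_table and net_mrnas:
        surv = survival_mod.read_survival_tsv(config.survival_table)
        expr_path = Path(config.survival_table).with_name(
            "survival_expression.tsv")
        if expr_path.exists():
            expr = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
            surv_table = survival_mod.survival_screen(net_mrnas, expr, surv)
            _write_table(surv_table, outdir / "survival_screen.tsv",
                         "survival", cfg_hash, seed)
    result.survival_table = surv_table

    # ---- stage 6: per-dataset ROC for network members
    roc_rows = []
    for ds in config.datasets:
        table_feats = _dataset_features(ds)
        candidates = [n for n in net.graph.nodes if n in table_feats.index]
        if not candidates:
            continue
        groups = read_groups(ds.groups)
        y = (groups == "tumor").astype(int)
        for cand in sorted(candidates):
            scores = table_feats.loc[cand, groups.index].to_numpy(float)
            res = diagnostics.auc_ci_bootstrap(
                scores, y.to_numpy(), pos_label=1, n_boot=config.n_boot,
                seed=_sub_seed(seed, f"roc:{ds.name}:{cand}"))
            roc_rows.append({
                "dataset": ds.name, "feature": cand, "auc": res.auc,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "ci_method": res.ci_method, "oriented": res.oriented,
                "strong": res.strong, "n_pos": res.n_pos, "n_neg": res.n_neg})
    roc_table = pd.DataFrame(
        roc_rows, columns=["dataset", "feature", "auc", "ci_low", "ci_high",
                           "ci_method", "oriented", "strong", "n_pos", "n_neg"])
    _write_table(roc_table, outdir / "roc_results.tsv", "diagnostics",
                 cfg_hash, seed)
    result.roc_table = roc_table

    # ---- stage 7: ORA of the panel against the DEmRNA-union background
    if config.gmt and panel:
        background = set()
        for n in mrna_names:
            t = de_tables[n]
            background |= set(t.loc[t["direction"] != "ns", "feature"])
        sets = enrichment.read_gmt(config.gmt)
        records = enrichment.ora(panel, sets, background)
        enr = enrichment.enrichment_table(records)
        _write_table(enr, outdir / "enrichment.tsv", "enrichment",
                     cfg_hash, seed)
        result.enrichment_table = enr

    # ---- stage 8: joint axis prioritization
    report = _axis_report(net_mrnas, de_tables, mrna_names, roc_table,
                          surv_table)
    _write_table(report, outdir / "axis_report.tsv", "axis_report",
                 cfg_hash, seed)
    result.axis_report = report
    return result


def _role_directions(de_tables, names) -> dict[str, str]:
    out: dict[str, str] = {}
    for n in names:
        t = de_tables[n]
        for feat, d in zip(t["feature"], t["direction"]):
            if d != "ns":
                out[feat] = d
    return out


def _dataset_features(ds: DatasetConfig) -> pd.DataFrame:
    mat = ExpressionMatrix.from_tsv(ds.expression, scale=ds.scale,
                                    platform=ds.platform)
    if ds.scale == "counts":
        logcpm, _ = diffexp.voom_transform(mat)
        return logcpm.values
    return diffexp.maybe_log2(mat).values


def _axis_report(net_mrnas, de_tables, mrna_names, roc_table,
                 surv_table) -> pd.DataFrame:
    rows = []
    for gene in net_mrnas:
        concordance = 0
        for n in mrna_names:
            t = de_tables[n]
            hit = t.loc[(t["feature"] == gene) & (t["direction"] != "ns")]
            if len(hit):
                concordance += 1
        sub = roc_table.loc[roc_table["feature"] == gene] if len(roc_table) else None
        best_auc = float(sub["auc"].max()) if sub is not None and len(sub) else float("nan")
        strong = bool(sub["strong"].any()) if sub is not None and len(sub) else False
        if surv_table is not None and gene in set(surv_table["gene"]):
            srow = surv_table.loc[surv_table["gene"] == gene].iloc[0]
            hr, p, sig = float(srow["hr"]), float(srow["logrank_p"]), bool(srow["significant"])
        else:
            hr, p, sig = float("nan"), float("nan"), False
        rows.append({"gene": gene, "in_network": True,
                     "de_concordance": concordance, "best_auc": best_auc,
                     "strong_auc": strong, "hr": hr, "logrank_p": p,
                     "survival_significant": sig})
    df = pd.DataFrame(rows, columns=["gene", "in_network", "de_concordance",
                                     "best_auc", "strong_auc", "hr",
                                     "logrank_p", "survival_significant"])
    if len(df):
        df = df.sort_values(
            by=["survival_significant", "logrank_p", "best_auc",
                "de_concordance", "gene"],
            ascending=[False, True, False, False, True],
            na_position="last").reset_index(drop=True)
        df.insert(1, "rank", np.arange(1, len(df) + 1))
    else:
        df.insert(1, "rank", [])
    return df
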