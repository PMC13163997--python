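"""The full six-dataset pipeline end to end on a synthetic bundle.

Simulates four mRNA cohorts (167/45, 6/6, 5/2, 3/3), one miRNA cohort
(17/3), one lncRNA cohort (8/2), interaction tables with decoys, a
499-patient survival cohort and a gene-set collection — all with a planted
XIST-like -> 6 miRNA -> ZNF662-like axis — then runs every stage and prints
the axis prioritization report.
"""

import tempfile

from cernax import PipelineConfig, SimulationConfig, run_pipeline, simulate_bundle

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(outdir=tmp, seed=1,
                            simulation=SimulationConfig.clean_fixture())
    wired, truth = simulate_bundle(config)
    result = run_pipeline(wired)

    print(f"consensus mRNAs : {len(result.consensus.up)} up, "
          f"{len(result.consensus.down)} down")
    print(f"target panel    : {len(result.panel)} genes")
    print(f"network         : {result.network.counts_by_type()}")
    print(f"planted axis    : {sorted(truth.axis_members())}")
    print(f"recovered nodes : {sorted(result.network.graph.nodes)}")
    print("\naxis report (ranked by survival significance, log-rank p, AUC):")
    cols = ["rank", "gene", "de_concordance", "best_auc", "hr", "logrank_p",
            "survival_significant"]
    print(result.axis_report[cols].round(4).to_string(index=False))
    enr = result.enrichment_table
    print("\nenrichment hits (q < 0.05):",
          enr.loc[enr["q"] < 0.05, "term"].tolist())
    print("\nEvery planted axis member — and nothing else — should appear in "
          "the network, with the planted mRNA ranked first and only the "
          "planted EMT-like program enriched.")
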