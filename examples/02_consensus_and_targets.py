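"""Directional consensus across datasets plus dual-predictor target filtering.

Builds four DE call tables sharing 15 up / 10 down genes (with
dataset-private noise calls), intersects them directionally, then reads two
miRNA-target predictor tables and a CLIP-annotated lncRNA table generated
with planted true edges and decoys, and reduces them to the high-confidence
edge set.
"""

import tempfile
from pathlib import Path

import pandas as pd

from cernax import (default_truth, filter_clip, generate_interaction_tables,
                    intersect_directional, intersect_predictors,
                    read_predictions, restrict_to_de)

# --- consensus over four synthetic DE tables ---------------------------
shared = {f"UP{i}": "up" for i in range(15)} | {f"DN{i}": "down" for i in range(10)}
tables = []
for d in range(4):
    calls = dict(shared, **{f"PRIV{d}_{j}": "up" for j in range(6)})
    tables.append(pd.DataFrame({"feature": list(calls),
                                "direction": list(calls.values())}))
cons = intersect_directional(tables)
print(f"consensus: {len(cons.up)} up, {len(cons.down)} down "
      "(private calls fall out; only genes concordant in all 4 series stay)")

# --- predictor intersection + CLIP filter ------------------------------
truth = default_truth()
tabs = generate_interaction_tables(truth, n_decoys_per_predictor=30,
                                   predictor_overlap_fraction=0.3, seed=1)
with tempfile.TemporaryDirectory() as d:
    d = Path(d)
    tabs.predictor_a.to_csv(d / "a.tsv", sep="\t", index=False)
    tabs.predictor_b.to_csv(d / "b.tsv", sep="\t", index=False)
    tabs.lnc_mir.to_csv(d / "l.tsv", sep="\t", index=False)
    edges_a = read_predictions(d / "a.tsv", "targetscan_like")
    edges_b = read_predictions(d / "b.tsv", "mirdb_like")
    lnc_edges = read_predictions(d / "l.tsv", "encori_like")

both = intersect_predictors(edges_a, edges_b)
print(f"predictor A: {len(edges_a)} edges, B: {len(edges_b)}, "
      f"intersection: {len(both)}")

clip_ok = filter_clip(lnc_edges, min_experiments=1)
print(f"lncRNA-miRNA pairs: {len(lnc_edges)} ingested, "
      f"{len(clip_ok)} with CLIP-seq support")

lnc, mirs, mrna = truth.axis
de = {lnc: "down", mrna: "down", **{m: "up" for m in mirs}}
final = restrict_to_de(both, de, which_end="both")
print(f"after restriction to DE features: {len(final)} miRNA->mRNA edges "
      "(exactly the planted axis; decoys had non-DE endpoints)")
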