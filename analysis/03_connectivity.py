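"""Compute parcel-pair Fisher-z FC matrices and the category-level seed tables.

Publishes the group-mean FC from the language seed to each ventral visual
target category and from the VWFA seed to each frontotemporal category — the
quantities the fingerprint and ANOVA steps consume.
"""

import pandas as pd

from common import RESULTS, WORKDIR, ensure_stages, publish
from protoconn import pipeline as pl
from protoconn.pipeline import PipelineConfig

cfg = ensure_stages("connectivity")

fcs, atlas = pl._load_fcs(cfg)
rows = []
for seed, targets in cfg.analyses:
    table = pl.long_fc_table(fcs, seed, targets, atlas.category_of)
    mean = table.groupby(["group", "target"], sort=False)["value"].mean()
    for (group, target), value in mean.items():
        rows.append((seed, group, target, value))
summary = pd.DataFrame(rows, columns=["seed", "group", "target", "mean_z"])
RESULTS.mkdir(exist_ok=True)
summary.to_csv(RESULTS / "category_fc_group_means.tsv", sep="\t",
               index=False, float_format="%.4f")
print("group-mean category-level Fisher-z FC:")
print(summary.to_string(index=False))
print("[driver] wrote results/category_fc_group_means.tsv")
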