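"""Voxel-wise percentile-threshold Dice sweep within the VTC search space.

Seed-to-voxel FC maps (language seed) are binarized at the 50th...95th
percentile; the overlap of the suprathreshold voxels with each VTC parcel is
summarized per group, and the VWFA-vs-other-parcels paired t-tests per
percentile are published.
"""

import pandas as pd

from common import WORKDIR, ensure_stages, publish

ensure_stages("dice")

summary = pd.read_csv(WORKDIR / "dice" / "dice_group.tsv", sep="\t")
best = (summary.sort_values("dice_mean", ascending=False)
        .groupby("percentile").first()["region"])
print("region with max mean Dice per percentile:")
print(best.to_string())

publish(WORKDIR / "dice" / "dice_group.tsv", "dice_group_summary.tsv")
publish(WORKDIR / "dice" / "dice_tests.tsv", "dice_group_tests.tsv")
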