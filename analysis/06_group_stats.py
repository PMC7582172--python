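"""Group-level inference: factorial ANOVA (group x target) and post-hoc
paired/independent t-tests with BH-FDR, for both analysis directions.
"""

import pandas as pd

from common import WORKDIR, ensure_stages, publish

ensure_stages("stats")

for seed in ("language", "VWFA"):
    aov = pd.read_csv(WORKDIR / "stats" / f"{seed}_anova.tsv", sep="\t")
    print(f"\n{seed} seed ANOVA:")
    print(aov[["test", "statistic", "df1", "df2", "p_raw", "effect"]]
          .to_string(index=False))
    posthoc = pd.read_csv(WORKDIR / "stats" / f"{seed}_posthoc.tsv", sep="\t")
    sig = posthoc[posthoc["p_adj"] < 0.05]
    print(f"{len(sig)}/{len(posthoc)} post-hoc comparisons significant after BH")
    publish(WORKDIR / "stats" / f"{seed}_anova.tsv", f"{seed}_anova.tsv")
    publish(WORKDIR / "stats" / f"{seed}_posthoc.tsv", f"{seed}_posthoc.tsv")
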