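"""Build mean-centered connectivity fingerprints and test pattern dissimilarity.

For each analysis direction (language seed over visual targets, VWFA seed over
frontotemporal targets) this publishes the per-subject fingerprints and the
three within/between-group dissimilarity t-tests (BH-corrected).
"""

import pandas as pd

from common import WORKDIR, ensure_stages, publish

ensure_stages("fingerprint")

for seed in ("language", "VWFA"):
    tests = pd.read_csv(WORKDIR / "fingerprint" / f"{seed}_dissimilarity_tests.tsv",
                        sep="\t")
    print(f"\n{seed} seed, dissimilarity comparisons:")
    print(tests[["test", "statistic", "p_raw", "p_adj"]].to_string(index=False))
    publish(WORKDIR / "fingerprint" / f"{seed}_fingerprints.tsv",
            f"{seed}_fingerprints.tsv")
    publish(WORKDIR / "fingerprint" / f"{seed}_dissimilarity_tests.tsv",
            f"{seed}_dissimilarity_tests.tsv")
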