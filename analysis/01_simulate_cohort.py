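"""Simulate the synthetic two-group resting-state cohort.

Generates 12 neonates and 12 adults on the default 20-parcel atlas with the
default group coupling matrices (language-VWFA strongest in both groups;
neonatal language-objects nearly as strong as language-VWFA), writes BOLD runs,
masks, atlas volumes and motion tables, and publishes the cohort manifest and
parcel inventory.
"""

import pandas as pd

import protoconn as pc
from common import WORKDIR, ensure_stages, publish

cfg = ensure_stages("simulate")

manifest = pd.read_csv(WORKDIR / "data" / "manifest.tsv", sep="\t")
atlas = pc.finalize_synthetic_atlas(pc.make_synthetic_atlas())
inventory = pc.category_inventory(atlas)
inventory.to_csv(WORKDIR / "data" / "inventory.tsv", sep="\t", index=False)

print(f"cohort: {len(manifest)} subjects "
      f"({(manifest['group'] == 'neonate').sum()} neonates, "
      f"{(manifest['group'] == 'adult').sum()} adults), "
      f"{cfg.n_timepoints} frames at TR {cfg.tr_seconds}s")
print(f"atlas: {inventory['n_parcels'].sum()} parcels in {len(inventory)} "
      "categories after overlap resolution and tissue exclusion")
print(inventory.to_string(index=False))

publish(WORKDIR / "data" / "manifest.tsv", "cohort_manifest.tsv")
publish(WORKDIR / "data" / "inventory.tsv", "atlas_inventory.tsv")
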