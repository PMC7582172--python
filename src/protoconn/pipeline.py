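"""End-to-end orchestration: simulate -> preprocess -> FC -> fingerprints ->
dice sweep -> group statistics, with on-disk stage isolation and deterministic
seeding.

Two entry styles are provided: the in-memory helpers (``subject_fc_matrices``,
``fingerprint_analysis``, ...) used by tests and scripts, and the disk-based
stages driven by :func:`run_pipeline` / the ``protoconn`` CLI, each of which
can be rerun from its predecessor's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import connectivity as conn
from . import dice as dice_mod
from . import fingerprint as fp_mod
from . import preprocess as pp
from . import stats as stats_mod
from . import synthetic as syn
from .core import (indices_to_mask, read_bold, read_mask, read_motion_table,
                   write_bold, write_labels, write_mask)
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)

MODEL_FACTORIES = {
    "default": syn.default_ground_truth,
    "recovery": syn.fingerprint_recovery_ground_truth,
    "planted": syn.planted_signal_ground_truth,
    "null": syn.null_ground_truth,
}

#: The two analysis directions: language seed against ventral visual targets,
#: and VWFA seed against frontotemporal targets.
DEFAULT_ANALYSES = (
    ("language", ("VWFA", "faces", "scenes", "objects")),
    ("VWFA", ("language", "MD", "speech", "A1")),
)


@dataclass
class PipelineConfig:
    output_dir: str = "scratch/pipeline"
    n_per_group: int = 4
    n_timepoints: int = 200
    tr_seconds: float = 0.72
    master_seed: int = 0
    model: str = "default"
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    analyses: tuple = DEFAULT_ANALYSES
    dice_seed: str = "language"
    dice_space: str = "VTC"
    dice_regions_from: str = "VTC"       # regions = parcels inside this space
    percentiles: tuple = dice_mod.DEFAULT_PERCENTILES
    centered_fingerprints: bool = True
    dice_union_formula: bool = False
    fdr_method: str = "bh"
    alpha: float = 0.05
    anova_repeated: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp_cfg = pp.PreprocessConfig(**raw.pop("preprocess", {}))
        analyses = raw.pop("analyses", None)
        cfg = cls(preprocess=pp_cfg, **raw)
        if analyses is not None:
            cfg.analyses = tuple((a["seed"], tuple(a["targets"])) for a in analyses)
        return cfg

    def out(self) -> Path:
        return Path(self.output_dir)

    def validate_categories(self) -> None:
        known = {cat for _, cat in syn.DEFAULT_PARCEL_INVENTORY}
        for seed, targets in self.analyses:
            for cat in (seed, *targets):
                if cat not in known:
                    raise ValidationError(f"unknown category {cat!r} in analysis config")
        if self.dice_seed not in known:
            raise ValidationError(f"unknown dice seed category {self.dice_seed!r}")


def quick_config(output_dir: str, seed: int = 0) -> PipelineConfig:
    """Desk-scale smoke preset: 4 subjects/group, T=200."""
    return PipelineConfig(output_dir=output_dir, n_per_group=4, n_timepoints=200,
                          master_seed=seed)


# ---------------------------------------------------------------------------
# In-memory analysis helpers (shared by stages, tests and acceptance)


def subject_fc_matrices(cohort: syn.SyntheticCohort, final_atlas: atlas_mod.ParcelAtlas,
                        masks: dict | None = None,
                        preprocess_config: pp.PreprocessConfig | None = None) -> dict:
    """Preprocess (optional) and compute each subject's parcel FC matrix.

    Returns group label -> list of FCMatrix in cohort order.  With ``masks``
    None the runs are used as-is (no preprocessing).
    """
    by_group: dict[str, list] = {}
    for rec in cohort.subjects:
        run = rec.run
        if masks is not None:
            run = pp.preprocess_run(run, masks, preprocess_config)
        by_group.setdefault(rec.group, []).append(conn.parcel_fc_matrix(run, final_atlas))
    return by_group


def long_fc_table(fcs_by_group: dict, seed: str, targets, category_of: dict) -> pd.DataFrame:
    """Tidy subject x target table of category-level FC for one seed."""
    rows = []
    for group, fcs in fcs_by_group.items():
        for fc in fcs:
            for target in targets:
                rows.append((fc.subject_id, group, target,
                             conn.category_fc(fc, seed, target, category_of)))
    return pd.DataFrame(rows, columns=["subject", "group", "target", "value"])


def fingerprints_by_group(fcs_by_group: dict, seed: str, targets, category_of: dict,
                          centered: bool = True) -> dict:
    return {group: [fp_mod.fingerprint_from_fc(fc, seed, targets, category_of,
                                               centered=centered)
                    for fc in fcs]
            for group, fcs in fcs_by_group.items()}


def posthoc_tests(table: pd.DataFrame, reference_target: str,
                  fdr_method: str = "bh") -> list:
    """Within-group paired tests of the reference target against each other
    target, plus between-group tests on each contrast; one FDR family."""
    wide = table.pivot_table(index=["group", "subject"], columns="target",
                             values="value")
    targets = [t for t in table["target"].unique() if t != reference_target]
    groups = list(table["group"].unique())
    tests = []
    for group in groups:
        sub = wide.loc[group]
        for target in targets:
            tests.append(stats_mod.paired_ttest(
                sub[reference_target], sub[target],
                name=f"{group}:{reference_target}_vs_{target}"))
    if len(groups) == 2:
        g1, g2 = groups
        for target in targets:
            c1 = wide.loc[g1, reference_target] - wide.loc[g1, target]
            c2 = wide.loc[g2, reference_target] - wide.loc[g2, target]
            tests.append(stats_mod.independent_ttest(
                c1, c2, name=f"{g1}_vs_{g2}:{reference_target}-{target}"))
    return stats_mod.attach_fdr(tests, fdr_method)


def dice_sweep_for_group(cohort_runs, final_atlas: atlas_mod.ParcelAtlas, seed_category: str,
                         space_name: str, percentiles=dice_mod.DEFAULT_PERCENTILES,
                         union_formula: bool = False, return_maps: bool = False):
    """Seed-to-voxel maps and dice sweeps for a list of (already preprocessed)
    runs; regions are the parcels lying inside the search space."""
    space = final_atlas.search_spaces[space_name]
    regions = {name: voxels for name, voxels in final_atlas.parcels.items()
               if np.isin(voxels, space).all()}
    if not regions:
        raise PipelineError(f"no parcels inside search space {space_name!r}")
    seed_voxels = final_atlas.category_voxels(seed_category)
    results, maps = [], []
    for run in cohort_runs:
        seed_map = conn.seed_to_voxel_fc(run, seed_voxels, space,
                                         seed_name=seed_category, space_name=space_name)
        maps.append(seed_map)
        results.append(dice_mod.run_dice_sweep(seed_map, regions, percentiles,
                                               union_formula))
    return (results, maps) if return_maps else results


def write_seed_map(seed_map, grid_shape, voxel_size_mm: float, path) -> None:
    """Materialize a seed-to-voxel map as a 3-D NIfTI in the subject grid
    (zeros outside the search space)."""
    vol = np.zeros(int(np.prod(grid_shape)), dtype=np.float32)
    vol[seed_map.voxels] = seed_map.z
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol.reshape(grid_shape), affine), str(path))


# ---------------------------------------------------------------------------
# Disk-based stages


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(cfg: PipelineConfig):
    cfg.validate_categories()
    out = cfg.out() / "data"
    out.mkdir(parents=True, exist_ok=True)
    synth = syn.make_synthetic_atlas()
    factory = MODEL_FACTORIES[cfg.model]
    model = factory(tr_seconds=cfg.tr_seconds, n_timepoints=cfg.n_timepoints)
    cohort = syn.simulate_cohort(model, cfg.n_per_group, synth, cfg.master_seed)

    write_labels(_raw_label_volume(synth), synth.voxel_size_mm, out / "atlas_labels.nii.gz")
    pd.DataFrame([(i + 1, n, synth.category_of[n])
                  for i, n in enumerate(synth.raw_parcels)],
                 columns=["label", "name", "category"]).to_csv(
        out / "atlas_parcels.tsv", sep="\t", index=False)
    for name, mask in synth.masks.items():
        write_mask(mask, synth.voxel_size_mm, out / f"mask_{name}.nii.gz")
    for name, voxels in synth.search_spaces.items():
        write_mask(indices_to_mask(voxels, synth.grid_shape), synth.voxel_size_mm,
                   out / f"space_{name}.nii.gz")
    for rec in cohort.subjects:
        write_bold(rec.run, out / f"sub-{rec.subject_id}_bold.nii.gz")
        rec.motion.to_csv(out / f"sub-{rec.subject_id}_motion.tsv", sep="\t", index=False)
    manifest = cohort.manifest()
    manifest["seed"] = cfg.master_seed
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    logger.info("simulate: wrote %d subjects to %s", len(cohort.subjects), out)
    return cohort, synth


def _raw_label_volume(synth: syn.SyntheticAtlas) -> np.ndarray:
    vol = np.zeros(int(np.prod(synth.grid_shape)), dtype=np.int16)
    for i, (name, voxels) in enumerate(synth.raw_parcels.items(), start=1):
        vol[voxels] = i   # later parcels win raw overlaps; finalization re-resolves
    return vol.reshape(synth.grid_shape)


def _load_atlas_from_disk(data_dir: Path):
    labels = np.asarray(nib.load(str(data_dir / "atlas_labels.nii.gz")).dataobj)
    parcel_table = pd.read_csv(data_dir / "atlas_parcels.tsv", sep="\t")
    masks = {name: read_mask(data_dir / f"mask_{name}.nii.gz")
             for name in ("gray", "white", "csf", "cerebellum")}
    spaces = {}
    for path in sorted(data_dir.glob("space_*.nii.gz")):
        name = path.name[len("space_"):-len(".nii.gz")]
        spaces[name] = np.flatnonzero(read_mask(path).ravel())
    raw = {row["name"]: np.flatnonzero(labels.ravel() == row["label"])
           for _, row in parcel_table.iterrows()}
    category_of = dict(zip(parcel_table["name"], parcel_table["category"]))
    return raw, category_of, masks, spaces, labels.shape


def stage_preprocess(cfg: PipelineConfig) -> None:
    data_dir = cfg.out() / "data"
    out = cfg.out() / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    _, _, masks, _, _ = _load_atlas_from_disk(data_dir)
    fd_rows = []
    for sid in manifest["subject_id"]:
        try:
            run = read_bold(data_dir / f"sub-{sid}_bold.nii.gz", subject_id=sid)
            clean = pp.preprocess_run(run, masks, cfg.preprocess)
            write_bold(clean, out / f"sub-{sid}_bold.nii.gz")
            motion = read_motion_table(data_dir / f"sub-{sid}_motion.tsv")
            summary = pp.compute_framewise_displacement(motion, cfg.preprocess.fd_radius_mm)
            fd_rows.append((sid, summary.fd_mean))
        except Exception as exc:
            raise PipelineError(f"stage preprocess failed for subject {sid}: {exc}") from exc
    pd.DataFrame(fd_rows, columns=["subject_id", "fd_mean"]).to_csv(
        out / "fd.tsv", sep="\t", index=False, float_format="%.6f")
    logger.info("preprocess: %d subjects done", len(fd_rows))


def _final_atlas_from_disk(data_dir: Path) -> atlas_mod.ParcelAtlas:
    raw, category_of, masks, spaces, grid = _load_atlas_from_disk(data_dir)
    return atlas_mod.finalize_atlas(raw, category_of, masks, spaces, grid)


def stage_connectivity(cfg: PipelineConfig) -> None:
    data_dir = cfg.out() / "data"
    pre_dir = cfg.out() / "preproc"
    out = cfg.out() / "fc"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    final_atlas = _final_atlas_from_disk(data_dir)
    for sid in manifest["subject_id"]:
        try:
            run = read_bold(pre_dir / f"sub-{sid}_bold.nii.gz", subject_id=sid)
            fc = conn.parcel_fc_matrix(run, final_atlas)
            fc.to_frame().to_csv(out / f"sub-{sid}_fc.tsv", sep="\t", float_format="%.8f")
        except Exception as exc:
            raise PipelineError(f"stage connectivity failed for subject {sid}: {exc}") from exc
    logger.info("connectivity: %d FC matrices written", len(manifest))


def _load_fcs(cfg: PipelineConfig) -> dict:
    data_dir = cfg.out() / "data"
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    final_atlas = _final_atlas_from_disk(data_dir)
    fcs: dict[str, list] = {}
    for _, row in manifest.iterrows():
        frame = pd.read_csv(cfg.out() / "fc" / f"sub-{row['subject_id']}_fc.tsv",
                            sep="\t", index_col=0)
        fcs.setdefault(row["group"], []).append(
            conn.FCMatrix(row["subject_id"], list(frame.columns), frame.to_numpy()))
    return fcs, final_atlas


def stage_fingerprint(cfg: PipelineConfig) -> None:
    out = cfg.out() / "fingerprint"
    out.mkdir(parents=True, exist_ok=True)
    fcs, final_atlas = _load_fcs(cfg)
    for seed, targets in cfg.analyses:
        fps = fingerprints_by_group(fcs, seed, targets, final_atlas.category_of,
                                    cfg.centered_fingerprints)
        rows = [(fp.subject_id, group, *fp.values)
                for group, group_fps in fps.items() for fp in group_fps]
        pd.DataFrame(rows, columns=["subject_id", "group", *targets]).to_csv(
            out / f"{seed}_fingerprints.tsv", sep="\t", index=False, float_format="%.8f")
        records, tests = fp_mod.group_dissimilarity_table(fps, cfg.fdr_method)
        records.to_csv(out / f"{seed}_dissimilarity.tsv", sep="\t", index=False,
                       float_format="%.8f")
        stats_mod.results_table(tests).to_csv(out / f"{seed}_dissimilarity_tests.tsv",
                                              sep="\t", index=False, float_format="%.8f")
        _plot_fingerprints(fps, targets, seed, out / f"{seed}_fingerprint.png")
        _plot_dissimilarity(records, seed, out / f"{seed}_dissimilarity.png")
    logger.info("fingerprint: wrote tables for %d analyses", len(cfg.analyses))


def stage_dice(cfg: PipelineConfig) -> None:
    data_dir = cfg.out() / "data"
    pre_dir = cfg.out() / "preproc"
    out = cfg.out() / "dice"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    final_atlas = _final_atlas_from_disk(data_dir)
    (out / "maps").mkdir(exist_ok=True)
    all_results = []
    for group in manifest["group"].unique():
        sids = manifest.loc[manifest["group"] == group, "subject_id"]
        runs = [read_bold(pre_dir / f"sub-{sid}_bold.nii.gz", subject_id=sid)
                for sid in sids]
        results, maps = dice_sweep_for_group(runs, final_atlas, cfg.dice_seed,
                                             cfg.dice_space, cfg.percentiles,
                                             cfg.dice_union_formula, return_maps=True)
        for run, seed_map in zip(runs, maps):
            write_seed_map(seed_map, run.grid_shape, run.voxel_size_mm,
                           out / "maps" / f"sub-{seed_map.subject_id}_{cfg.dice_seed}"
                                          f"_{cfg.dice_space}_z.nii.gz")
        for r in results:
            frame = r.to_long()
            frame.insert(1, "group", group)
            all_results.append((group, r, frame))
    long = pd.concat([f for _, _, f in all_results], ignore_index=True)
    long.to_csv(out / "dice_long.tsv", sep="\t", index=False, float_format="%.8f")
    focal = "VWFA" if "VWFA" in all_results[0][1].dice.columns else all_results[0][1].dice.columns[0]
    others = [c for c in all_results[0][1].dice.columns if c != focal]
    test_rows = []
    for group in manifest["group"].unique():
        tests = dice_mod.sweep_group_test([r for g, r, _ in all_results if g == group],
                                          focal, others, cfg.fdr_method)
        frame = stats_mod.results_table(tests)
        frame.insert(0, "group", group)
        test_rows.append(frame)
    pd.concat(test_rows, ignore_index=True).to_csv(out / "dice_tests.tsv", sep="\t",
                                                   index=False, float_format="%.8f")
    summary = dice_mod.group_dice_summary([r for _, r, _ in all_results])
    summary.to_csv(out / "dice_group.tsv", sep="\t", index=False, float_format="%.8f")
    _plot_dice(long, out / "dice_curves.png")
    logger.info("dice: sweep written for %d subjects", len(manifest))


def stage_stats(cfg: PipelineConfig) -> None:
    out = cfg.out() / "stats"
    out.mkdir(parents=True, exist_ok=True)
    fcs, final_atlas = _load_fcs(cfg)
    for seed, targets in cfg.analyses:
        table = long_fc_table(fcs, seed, targets, final_atlas.category_of)
        anova = stats_mod.factorial_anova(table, repeated=cfg.anova_repeated)
        stats_mod.results_table(anova.values()).to_csv(
            out / f"{seed}_anova.tsv", sep="\t", index=False, float_format="%.8f")
        tests = posthoc_tests(table, targets[0], cfg.fdr_method)
        stats_mod.results_table(tests).to_csv(
            out / f"{seed}_posthoc.tsv", sep="\t", index=False, float_format="%.8f")
    logger.info("stats: ANOVA + posthoc written for %d analyses", len(cfg.analyses))


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "connectivity": stage_connectivity,
    "fingerprint": stage_fingerprint,
    "dice": stage_dice,
    "stats": stage_stats,
}
STAGE_ORDER = ("simulate", "preprocess", "connectivity", "fingerprint", "dice", "stats")


def run_pipeline(cfg: PipelineConfig, stages=STAGE_ORDER) -> Path:
    """Run the requested stages in order and write an artifact manifest."""
    cfg.validate_categories()
    for stage in stages:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        logger.info("stage %s starting", stage)
        STAGES[stage](cfg)
    manifest = {str(p.relative_to(cfg.out())): _checksum(p)
                for p in sorted(cfg.out().rglob("*")) if p.is_file() and p.suffix != ".json"}
    (cfg.out() / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cfg.out()


# ---------------------------------------------------------------------------
# Plots


def _plot_fingerprints(fps_by_group: dict, targets, seed: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(len(targets))
    for group, fps in fps_by_group.items():
        mean, sem = fp_mod.group_fingerprint(fps)
        ax.plot(x, mean, marker="o", label=group)
        ax.fill_between(x, mean - sem, mean + sem, alpha=0.25)
    ax.set_xticks(x, targets)
    ax.set_ylabel("mean-centered Fisher z")
    ax.set_title(f"FC fingerprint of {seed}")
    ax.axhline(0, color="gray", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_dissimilarity(records: pd.DataFrame, seed: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    summary = records.groupby(["group", "comparison"])["distance"].agg(["mean", "sem"])
    labels = [f"{g}\n{c}" for g, c in summary.index]
    ax.bar(range(len(summary)), summary["mean"], yerr=summary["sem"], capsize=3)
    ax.set_xticks(range(len(summary)), labels, fontsize=8)
    ax.set_ylabel("Euclidean distance")
    ax.set_title(f"{seed}: FC pattern dissimilarity")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_dice(long: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(1, long["group"].nunique(), figsize=(9, 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (group, sub) in zip(axes, long.groupby("group")):
        for region, reg in sub.groupby("region"):
            curve = reg.groupby("percentile")["dice"].agg(["mean", "sem"])
            ax.errorbar(curve.index, curve["mean"], yerr=curve["sem"], label=region,
                        marker=".", capsize=2)
        ax.set_title(group)
        ax.set_xlabel("FC percentile threshold")
    axes[0].set_ylabel("Dice coefficient")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
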