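"""Synthetic multi-subject BOLD generator with known group-level coupling.

The generator emulates the statistical structure that seed-based functional
connectivity estimates converge to: each functional *system* (language, VWFA,
faces, ...) carries a band-limited latent signal, and the latent signals of a
subject are drawn with a prescribed cross-system correlation matrix that may
differ between groups (neonates vs adults).  Every voxel of a system receives
that system's latent plus a shared physiological nuisance signal (also injected
into white-matter and CSF voxels, which is what makes aCompCor identifiable)
plus white voxel noise.  No hemodynamics or spatial autocorrelation beyond the
shared signals is modeled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MOTION_COLUMNS, BoldRun, block_indices
from .errors import GeometryError, ValidationError
from .preprocess import bandpass_filter

DEFAULT_SYSTEMS = ("language", "VWFA", "faces", "scenes", "objects", "speech", "A1", "MD")

#: The 20-parcel / 8-category inventory used throughout: 7 language parcels,
#: 1 speech, 1 A1, 5 multiple-demand, 1 VWFA, 2 face, 1 scene, 2 object parcels.
DEFAULT_PARCEL_INVENTORY: tuple[tuple[str, str], ...] = (
    ("AntTemp", "language"),
    ("MidAntTemp", "language"),
    ("MidPostTemp", "language"),
    ("PostTemp", "language"),
    ("AngG", "language"),
    ("IFG", "language"),
    ("IFGorb", "language"),
    ("SpeechSTG", "speech"),
    ("A1", "A1"),
    ("MFGorb", "MD"),
    ("Insula", "MD"),
    ("IFGop", "MD"),
    ("SMA", "MD"),
    ("ACC", "MD"),
    ("VWFA", "VWFA"),
    ("FFA", "faces"),
    ("OFA", "faces"),
    ("PPA", "scenes"),
    ("LO", "objects"),
    ("PFS", "objects"),
)

DEFAULT_GRID_SHAPE = (12, 12, 8)

# Hand-placed 2x2x2 blocks: ventral "VTC" sheet (z=2..3, y<7) holds the visual
# parcels, the posterior sheet (z=2..3, y>=7) the temporal parcels, and the
# superior sheet (z=5..6) the frontal parcels.  Origins assume the default grid.
_DEFAULT_BLOCK_ORIGINS = {
    "VWFA": (1, 1, 2),
    "FFA": (4, 1, 2),
    "OFA": (7, 1, 2),
    "PPA": (1, 4, 2),
    "LO": (4, 4, 2),
    "PFS": (7, 4, 2),
    "AntTemp": (1, 7, 2),
    "MidAntTemp": (4, 7, 2),
    "MidPostTemp": (7, 7, 2),
    "PostTemp": (10, 7, 2),
    "AngG": (1, 10, 2),
    "SpeechSTG": (4, 10, 2),
    "A1": (7, 10, 2),
    "IFG": (1, 1, 5),
    "IFGorb": (4, 1, 5),
    "MFGorb": (7, 1, 5),
    "Insula": (10, 1, 5),
    "SMA": (1, 4, 5),
    "ACC": (4, 4, 5),
    "IFGop": (7, 4, 5),
}


def coupling_matrix(pairs: dict[tuple[str, str], float], systems=DEFAULT_SYSTEMS,
                    baseline: float = 0.15) -> np.ndarray:
    """Symmetric unit-diagonal coupling matrix from named pair overrides."""
    k = len(systems)
    index = {s: i for i, s in enumerate(systems)}
    c = np.full((k, k), baseline)
    np.fill_diagonal(c, 1.0)
    for (a, b), v in pairs.items():
        c[index[a], index[b]] = c[index[b], index[a]] = v
    return c


_ADULT_PAIRS = {
    ("language", "VWFA"): 0.50,
    ("language", "faces"): 0.30,
    ("language", "scenes"): 0.25,
    ("language", "objects"): 0.30,
    ("language", "speech"): 0.45,
    ("language", "A1"): 0.35,
    ("language", "MD"): 0.30,
    ("VWFA", "speech"): 0.25,
    ("VWFA", "A1"): 0.20,
    ("VWFA", "MD"): 0.25,
    ("speech", "A1"): 0.45,
}

_NEONATE_PAIRS = dict(_ADULT_PAIRS)
_NEONATE_PAIRS.update({
    ("language", "VWFA"): 0.45,
    ("language", "scenes"): 0.27,
    ("language", "objects"): 0.42,   # neonatal object regions track VWFA closely
    ("VWFA", "speech"): 0.30,
    ("VWFA", "A1"): 0.28,
})


@dataclass(frozen=True)
class GroundTruthModel:
    """Generative coupling structure plus acquisition parameters.

    ``coupling_by_group`` maps a group label to the target cross-system
    correlation matrix of the latent signals; gains are unitless multipliers on
    the latent signal (``signal_gain``), the shared physiological nuisance
    (``physio_gain``) and white voxel noise (``noise_gain``).
    """

    systems: tuple[str, ...] = DEFAULT_SYSTEMS
    coupling_by_group: dict = field(default_factory=dict)
    signal_gain: float = 1.0
    physio_gain: float = 0.5
    noise_gain: float = 2.0
    tr_seconds: float = 0.72
    n_timepoints: int = 600
    band_hz: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        if self.n_timepoints < 50:
            raise ValidationError("n_timepoints must be >= 50")
        for gain in (self.signal_gain, self.physio_gain, self.noise_gain):
            if gain < 0:
                raise ValidationError("gains must be non-negative")
        if not self.coupling_by_group:
            raise ValidationError("coupling_by_group must not be empty")
        k = len(self.systems)
        for group, c in self.coupling_by_group.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (k, k):
                raise ValidationError(f"coupling for {group!r} must be {k}x{k}")
            if not np.allclose(c, c.T, atol=1e-12):
                raise ValidationError(f"coupling for {group!r} is not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-12):
                raise ValidationError(f"coupling for {group!r} must have unit diagonal")
            if np.any(np.abs(c) > 1 + 1e-12):
                raise ValidationError(f"coupling for {group!r} has entries outside [-1, 1]")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValidationError(
                    f"coupling for {group!r} is not positive semi-definite")

    def coupling(self, group: str) -> np.ndarray:
        if group not in self.coupling_by_group:
            raise ValidationError(f"unknown group {group!r}")
        return np.asarray(self.coupling_by_group[group], dtype=float)

    def system_index(self, name: str) -> int:
        return self.systems.index(name)


def default_ground_truth(tr_seconds: float = 0.72, n_timepoints: int = 600,
                         **kwargs) -> GroundTruthModel:
    """Desk-scale default: adult/neonate couplings with language-VWFA highest.

    The neonate matrix keeps language-objects close to language-VWFA, mimicking
    the qualitative adult/neonate difference the analysis is meant to detect.
    """
    return GroundTruthModel(
        coupling_by_group={"adult": coupling_matrix(_ADULT_PAIRS),
                           "neonate": coupling_matrix(_NEONATE_PAIRS)},
        tr_seconds=tr_seconds, n_timepoints=n_timepoints, **kwargs)


def fingerprint_recovery_ground_truth(tr_seconds: float = 0.72,
                                      n_timepoints: int = 600,
                                      **kwargs) -> GroundTruthModel:
    """Recovery condition: language-VWFA exceeds faces/scenes/objects by >= 0.15
    in both groups, so the planted fingerprint ranking is unambiguous."""
    adult = dict(_ADULT_PAIRS)
    neonate = dict(_ADULT_PAIRS)
    neonate.update({("language", "VWFA"): 0.45, ("language", "scenes"): 0.27})
    return GroundTruthModel(
        coupling_by_group={"adult": coupling_matrix(adult),
                           "neonate": coupling_matrix(neonate)},
        tr_seconds=tr_seconds, n_timepoints=n_timepoints, **kwargs)


def planted_signal_ground_truth(tr_seconds: float = 0.72, n_timepoints: int = 600,
                                **kwargs) -> GroundTruthModel:
    """Seed-coupled signal planted in the VWFA system only (both groups alike);
    all other couplings sit at the 0.15 baseline."""
    c = coupling_matrix({("language", "VWFA"): 0.60})
    return GroundTruthModel(coupling_by_group={"adult": c, "neonate": c},
                            tr_seconds=tr_seconds, n_timepoints=n_timepoints, **kwargs)


def null_ground_truth(tr_seconds: float = 0.72, n_timepoints: int = 200,
                      **kwargs) -> GroundTruthModel:
    """Identical generative couplings in both groups (type-I calibration)."""
    c = coupling_matrix(_ADULT_PAIRS)
    return GroundTruthModel(coupling_by_group={"adult": c, "neonate": c},
                            tr_seconds=tr_seconds, n_timepoints=n_timepoints, **kwargs)


# ---------------------------------------------------------------------------
# Atlas construction


@dataclass
class SyntheticAtlas:
    """Raw (pre-finalization) parcels plus tissue masks and search spaces."""

    grid_shape: tuple[int, int, int]
    raw_parcels: dict            # name -> flat voxel indices (possibly overlapping)
    category_of: dict            # name -> category label
    masks: dict                  # gray / white / csf / cerebellum -> 3-D bool arrays
    search_spaces: dict          # VTC / temporal / frontal -> flat voxel indices
    voxel_size_mm: float = 2.15

    def system_voxels(self, system: str) -> np.ndarray:
        """Union of raw parcel voxels whose category equals ``system``."""
        parts = [v for n, v in self.raw_parcels.items() if self.category_of[n] == system]
        if not parts:
            return np.array([], dtype=np.intp)
        return np.unique(np.concatenate(parts))


def make_synthetic_atlas(grid_shape=DEFAULT_GRID_SHAPE, parcel_specs=None,
                         include_overlap_pair: bool = False,
                         voxel_size_mm: float = 2.15) -> SyntheticAtlas:
    """Build the default 20-parcel atlas (or custom blocks) with tissue masks.

    Masks partition the grid into slabs: white matter at z=0, CSF at z=1, gray
    matter at z>=2, with a small cerebellum carved out of one gray corner.
    With ``include_overlap_pair`` the FFA block is widened so that exactly one
    parcel pair (FFA, OFA) shares voxels, exercising overlap resolution.
    """
    grid_shape = tuple(int(v) for v in grid_shape)
    if any(g < 8 for g in grid_shape):
        raise GeometryError(f"grid must be at least (8,8,8)-sized in every axis, got {grid_shape}")

    if parcel_specs is None:
        if grid_shape[0] < 12 or grid_shape[1] < 12 or grid_shape[2] < 8:
            raise GeometryError(
                f"default parcel layout needs a grid of at least (12,12,8), got {grid_shape}")
        parcel_specs = []
        for name, category in DEFAULT_PARCEL_INVENTORY:
            origin = _DEFAULT_BLOCK_ORIGINS[name]
            shape = (2, 2, 2)
            if include_overlap_pair and name == "FFA":
                shape = (4, 2, 2)   # grows into OFA's x-range: FFA/OFA share 4 voxels
            parcel_specs.append((name, category, origin, shape))

    raw_parcels: dict[str, np.ndarray] = {}
    category_of: dict[str, str] = {}
    for name, category, origin, shape in parcel_specs:
        voxels = block_indices(origin, shape, grid_shape)
        if voxels.size == 0:
            raise ValidationError(f"parcel {name!r} is empty")
        raw_parcels[name] = voxels
        category_of[name] = category

    x, y, z = np.meshgrid(*(np.arange(g) for g in grid_shape), indexing="ij")
    white = z == 0
    csf = z == 1
    gray = z >= 2
    cerebellum = gray & (x == 0) & (y < 4) & (z < 4)

    if include_overlap_pair:
        inter = np.intersect1d(raw_parcels["FFA"], raw_parcels["OFA"])
        assert inter.size >= 1

    def _space(xlo, xhi, ylo, yhi, zlo, zhi):
        sel = gray & ~cerebellum & (x >= xlo) & (x < xhi) & (y >= ylo) & (y < yhi) \
            & (z >= zlo) & (z < zhi)
        return np.flatnonzero(sel.ravel())

    gx, gy, gz = grid_shape
    search_spaces = {
        "VTC": _space(1, min(11, gx), 1, 7, 2, 4),
        "temporal": _space(1, gx, 7, gy, 2, 4),
        "frontal": _space(1, gx, 1, 7, 5, min(7, gz)),
    }

    return SyntheticAtlas(grid_shape=grid_shape, raw_parcels=raw_parcels,
                          category_of=category_of,
                          masks={"gray": gray, "white": white, "csf": csf,
                                 "cerebellum": cerebellum},
                          search_spaces=search_spaces, voxel_size_mm=voxel_size_mm)


# ---------------------------------------------------------------------------
# BOLD simulation


def _band_limited_rows(rows: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Band-pass white rows and restandardize each to zero mean, unit variance."""
    filtered = bandpass_filter(rows, tr, band[0], band[1], axis=1)
    sd = filtered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return filtered / sd


def simulate_subject(model: GroundTruthModel, group: str, atlas: SyntheticAtlas,
                     seed) -> BoldRun:
    """Simulate one subject's standardized voxel x time BOLD run.

    Latents are white Gaussian series band-limited to ``model.band_hz``, mixed
    by the Cholesky factor of the group coupling matrix; the physiological
    nuisance is a single band-limited series shared by gray, WM and CSF voxels.
    """
    c = model.coupling(group)
    rng = np.random.default_rng(seed)
    k = len(model.systems)
    t = model.n_timepoints

    latents = _band_limited_rows(rng.standard_normal((k, t)), model.tr_seconds, model.band_hz)
    physio = _band_limited_rows(rng.standard_normal((1, t)), model.tr_seconds, model.band_hz)[0]
    mixed = np.linalg.cholesky(c + 1e-12 * np.eye(k)) @ latents

    n_vox = int(np.prod(atlas.grid_shape))
    data = model.noise_gain * rng.standard_normal((n_vox, t))
    data += model.physio_gain * physio    # shared nuisance in every tissue class
    for s, system in enumerate(model.systems):
        voxels = atlas.system_voxels(system)
        if voxels.size:
            data[voxels] += model.signal_gain * mixed[s]

    data -= data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    data /= sd
    return BoldRun(data.reshape(atlas.grid_shape + (t,)), model.tr_seconds,
                   atlas.voxel_size_mm)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    sex: str
    run: BoldRun
    motion: pd.DataFrame


@dataclass
class SyntheticCohort:
    subjects: list
    master_seed: int

    def by_group(self, group: str) -> list:
        return [s for s in self.subjects if s.group == group]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.subject_id, s.group, s.sex) for s in self.subjects],
            columns=["subject_id", "group", "sex"])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.subjects:
            h.update(s.subject_id.encode())
            h.update(np.ascontiguousarray(s.run.data).tobytes())
            h.update(s.motion.to_csv(index=False).encode())
        return h.hexdigest()


#: Random-walk step scale (mm for translations; rad for rotations) per group.
DEFAULT_MOTION_SCALES = {"neonate": (0.030, 4e-4), "adult": (0.015, 2e-4)}


def _motion_table(rng: np.random.Generator, t: int, trans_scale: float,
                  rot_scale: float) -> pd.DataFrame:
    steps = rng.standard_normal((t, 6)) * np.r_[[trans_scale] * 3, [rot_scale] * 3]
    steps[0] = 0.0
    return pd.DataFrame(np.cumsum(steps, axis=0), columns=MOTION_COLUMNS)


def simulate_cohort(model: GroundTruthModel, n_per_group: int, atlas: SyntheticAtlas,
                    master_seed: int, groups=("neonate", "adult"),
                    motion_scales=None) -> SyntheticCohort:
    """Simulate ``n_per_group`` subjects per group with alternating sexes.

    Per-subject seeds are spawned deterministically from ``master_seed`` so the
    same master seed reproduces the cohort bit-for-bit.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    motion_scales = motion_scales or DEFAULT_MOTION_SCALES
    root = np.random.SeedSequence(master_seed)
    children = iter(root.spawn(2 * n_per_group * len(groups)))
    subjects = []
    for group in groups:
        trans_scale, rot_scale = motion_scales.get(group, DEFAULT_MOTION_SCALES["adult"])
        for i in range(n_per_group):
            sid = f"{group[:3]}{i:03d}"
            sex = "F" if i % 2 == 0 else "M"
            run = simulate_subject(model, group, atlas, next(children))
            run.subject_id = sid
            motion = _motion_table(np.random.default_rng(next(children)),
                                   model.n_timepoints, trans_scale, rot_scale)
            subjects.append(SubjectRecord(sid, group, sex, run, motion))
    return SyntheticCohort(subjects=subjects, master_seed=master_seed)
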