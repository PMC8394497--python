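"""Synthetic dual-echo phantom cohorts with known ground truth.

Each phantom subject is a 3D grid of ellipsoidal "regions" arranged as
mirrored left/right pairs about the mid-sagittal plane (grid centre along
the x axis; left = lower x) plus midline regions symmetric about that
plane. Voxels in a region with true relaxation time T2_r produce echo
signals ``S0 * exp(-TE / T2_r)`` at each of the two echo times, with
optional additive Gaussian noise per echo. Progressor-group (MCIp)
subjects receive per-pair additive T2 shifts, including left/right
asymmetry shifts, in designated regions; this plants a known group effect
and a known contralateral asymmetry for downstream recovery tests. The
anatomical image and its label map are the echo-space geometry moved by a
known 6-parameter rigid misalignment, giving registration a ground-truth
transform to recover. Neuropsychological scores are Gaussian with
group-dependent means for a memory summary score and ADAS-11, mimicking a
cohort where those two tests separate stable from progressing subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy.ndimage import gaussian_filter

from t2asym.atlas import RegionAtlas, make_atlas
from t2asym.io import grid_affine, save_nifti, to_sitk, from_sitk
from t2asym.t2map import EchoVolume

GROUPS = ("MCIs", "MCIp")

NEUROPSYCH_SCORES = [
    "mmse", "bnt", "gds", "adas11",
    "adni_ef", "adni_vs", "adni_lan", "adni_mem",
]

# (mean MCIs, mean MCIp, sd); adas11 and adni_mem carry the group shift.
DEFAULT_NEUROPSYCH_PARAMS = {
    "mmse": (27.5, 27.0, 1.8),
    "bnt": (26.0, 25.5, 3.0),
    "gds": (1.5, 1.7, 1.2),
    "adas11": (9.0, 13.0, 3.5),
    "adni_ef": (0.2, 0.0, 0.7),
    "adni_vs": (0.1, 0.0, 0.6),
    "adni_lan": (0.2, 0.0, 0.6),
    "adni_mem": (0.30, -0.30, 0.45),
}


@dataclass
class PhantomSpec:
    """Full description of a phantom cohort; all ground truth lives here.

    ``region_t2_ms`` holds one baseline T2 per pair followed by one per
    midline region. ``effect_map`` maps a pair index to
    ``{"mean_shift": ms, "asym_shift": ms}``: MCIp subjects get
    ``mean_shift`` added to both sides of that pair and ``asym_shift``
    added to the right side only. ``misalignment`` is
    (rot_x, rot_y, rot_z in degrees, t_x, t_y, t_z in mm), the rigid map
    from echo-space to anatomical-space coordinates about the grid centre.
    """

    grid_shape: tuple = (64, 64, 48)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    n_pairs: int = 6
    n_midline: int = 1
    te_a_ms: float = 10.0
    te_b_ms: float = 110.0
    s0_mean: float = 1000.0
    s0_sd: float = 50.0
    noise_sd: float = 10.0
    region_t2_ms: tuple = None
    effect_map: dict = field(default_factory=lambda: {0: {"mean_shift": 6.0, "asym_shift": 10.0}})
    misalignment: tuple = (0.0, 0.0, 3.0, 2.0, 2.0, 0.0)
    n_mcis: int = 22
    n_mcip: int = 18
    seed: int = 0
    pair_radii_vox: tuple = (3, 4, 3)
    midline_radii_vox: tuple = (3, 4, 3)
    neuropsych_params: dict = field(default_factory=lambda: dict(DEFAULT_NEUROPSYCH_PARAMS))

    def __post_init__(self):
        if not (self.te_b_ms > self.te_a_ms > 0):
            raise ValueError(f"need te_b > te_a > 0, got {self.te_a_ms}, {self.te_b_ms}")
        if self.n_mcis < 2 or self.n_mcip < 2:
            raise ValueError("group sizes must be >= 2")
        if self.n_pairs < 1 or self.n_midline < 0:
            raise ValueError("need n_pairs >= 1 and n_midline >= 0")
        if self.region_t2_ms is None:
            pair_t2 = np.linspace(75.0, 115.0, self.n_pairs)
            mid_t2 = np.linspace(85.0, 180.0, self.n_midline) if self.n_midline else []
            self.region_t2_ms = tuple(np.round(np.concatenate([pair_t2, mid_t2]), 2))
        self.region_t2_ms = tuple(float(t) for t in self.region_t2_ms)
        if len(self.region_t2_ms) != self.n_pairs + self.n_midline:
            raise ValueError("region_t2_ms must have n_pairs + n_midline entries")
        if any(t <= 0 for t in self.region_t2_ms):
            raise ValueError("all T2 values must be > 0")

    @property
    def affine(self) -> np.ndarray:
        return grid_affine(self.voxel_size_mm)


@dataclass
class PhantomSubject:
    subject_id: str
    group: str
    echo_a: EchoVolume
    echo_b: EchoVolume
    anatomical: np.ndarray
    labels: np.ndarray          # anatomical-space label image
    labels_echo: np.ndarray     # ground-truth labels in echo space
    truth: dict                 # region name -> true T2 (ms)
    neuropsych: dict
    age: float = 75.0
    sex: str = "M"
    education: float = 16.0


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def build_atlas_geometry(spec: PhantomSpec):
    """Place mirrored ellipsoidal regions; return (label image, RegionAtlas).

    Left-hemisphere ellipsoids sit on a lattice away from the mid-sagittal
    plane and are mirrored voxel-exactly (``np.flip`` along x) into the
    right hemisphere; midline ellipsoids are centred on the plane and are
    flip-symmetric. Raises if the lattice cannot host all regions or any
    two regions overlap.
    """
    nx, ny, nz = spec.grid_shape
    rx, ry, rz = spec.pair_radii_vox
    mrx = spec.midline_radii_vox[0]
    slab_halfwidth = mrx + 1  # midline ellipsoids own the central slab

    x_lo, x_hi = rx + 1, nx // 2 - slab_halfwidth - rx - 1
    xs = list(range(x_lo, x_hi + 1, 2 * rx + 3))
    ys = list(range(ry + 1, ny - ry - 1, 2 * ry + 3))
    zs = list(range(rz + 1, nz - rz - 1, 2 * rz + 3))
    centers = [(x, y, z) for z in zs for y in ys for x in xs]
    if len(centers) < spec.n_pairs:
        raise ValueError(
            f"grid {spec.grid_shape} fits only {len(centers)} pair sites, "
            f"need {spec.n_pairs}; regions would overlap"
        )

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    atlas = make_atlas(spec.n_pairs, spec.n_midline)
    for i in range(spec.n_pairs):
        left = _ellipsoid_mask(spec.grid_shape, centers[i], (rx, ry, rz))
        right = np.flip(left, axis=0)
        for mask, lab in ((left, 2 * i + 1), (right, 2 * i + 2)):
            if (labels[mask] != 0).any():
                raise ValueError(f"region overlap while placing pair {i}")
            labels[mask] = lab

    mid_sites = list(dict.fromkeys((c[1], c[2]) for c in centers))  # unique y/z sites
    cx = (nx - 1) / 2.0
    for j in range(spec.n_midline):
        if j >= len(mid_sites):
            raise ValueError(f"no midline site left for region {j}")
        y, z = mid_sites[j]
        mask = _ellipsoid_mask(spec.grid_shape, (cx, y, z), spec.midline_radii_vox)
        if (labels[mask] != 0).any():
            raise ValueError(f"region overlap while placing midline region {j}")
        labels[mask] = 2 * spec.n_pairs + 1 + j
    return labels, atlas


def true_t2_table(spec: PhantomSpec, group: str) -> dict:
    """Region name -> true T2 (ms) for a subject of the given group."""
    atlas = make_atlas(spec.n_pairs, spec.n_midline)
    table = {}
    for i, (l, r) in enumerate(atlas.pairs):
        base = spec.region_t2_ms[i]
        t2_l = t2_r = base
        if group == "MCIp" and i in spec.effect_map:
            eff = spec.effect_map[i]
            t2_l = base + eff.get("mean_shift", 0.0)
            t2_r = base + eff.get("mean_shift", 0.0) + eff.get("asym_shift", 0.0)
        table[atlas.regions[l]] = t2_l
        table[atlas.regions[r]] = t2_r
    for j, lab in enumerate(atlas.unpaired):
        table[atlas.regions[lab]] = spec.region_t2_ms[spec.n_pairs + j]
    return table


def misalignment_transform(spec: PhantomSpec) -> sitk.Euler3DTransform:
    """The rigid map from echo-space points to anatomical-space points."""
    rx, ry, rz, tx, ty, tz = spec.misalignment
    t = sitk.Euler3DTransform()
    center = [(n - 1) * s / 2.0 for n, s in zip(spec.grid_shape, spec.voxel_size_mm)]
    t.SetCenter(center)
    t.SetRotation(np.deg2rad(rx), np.deg2rad(ry), np.deg2rad(rz))
    t.SetTranslation((tx, ty, tz))
    return t


def _move_to_anatomical_space(arr, spec, interpolator, default=0.0):
    """Resample an echo-space image into the misaligned anatomical space."""
    m = misalignment_transform(spec)
    img = to_sitk(np.asarray(arr, dtype=np.float64), spec.voxel_size_mm)
    out = sitk.Resample(img, img, m.GetInverse(), interpolator, default, sitk.sitkFloat64)
    return from_sitk(out)


def simulate_subject(
    spec: PhantomSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
    geometry=None,
) -> PhantomSubject:
    """Draw one phantom subject: echo pair, anatomical image, labels, truth.

    The forward model per voxel in region r is
    ``S(TE) = S0 * exp(-TE / T2_r) + eps``, with S0 ~ N(s0_mean, s0_sd)
    per voxel and eps ~ N(0, noise_sd) independent per echo and voxel.
    Background voxels carry zero signal (plus noise). Deterministic for a
    given ``rng`` state.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    labels_echo, atlas = geometry if geometry is not None else build_atlas_geometry(spec)
    truth = true_t2_table(spec, group)

    t2_vox = np.zeros(spec.grid_shape, dtype=float)
    for lab, name in atlas.regions.items():
        t2_vox[labels_echo == lab] = truth[name]

    shape = spec.grid_shape
    s0 = (
        rng.normal(spec.s0_mean, spec.s0_sd, shape)
        if spec.s0_sd > 0
        else np.full(shape, spec.s0_mean)
    )
    fg = labels_echo > 0
    echo_a = np.zeros(shape)
    echo_b = np.zeros(shape)
    with np.errstate(divide="ignore"):
        echo_a[fg] = s0[fg] * np.exp(-spec.te_a_ms / t2_vox[fg])
        echo_b[fg] = s0[fg] * np.exp(-spec.te_b_ms / t2_vox[fg])
    if spec.noise_sd > 0:
        echo_a = echo_a + rng.normal(0, spec.noise_sd, shape)
        echo_b = echo_b + rng.normal(0, spec.noise_sd, shape)

    # anatomical contrast: distinct per-region intensity, lightly smoothed
    anat_echo = np.where(fg, 60.0 + 12.0 * labels_echo, 5.0)
    anat_echo = gaussian_filter(anat_echo, sigma=0.8)
    anatomical = _move_to_anatomical_space(anat_echo, spec, sitk.sitkLinear)
    labels_anat = _move_to_anatomical_space(
        labels_echo, spec, sitk.sitkNearestNeighbor
    ).astype(np.int16)

    shift = 1 if group == "MCIp" else 0
    neuropsych = {
        name: float(rng.normal(params[shift], params[2]))
        for name, params in spec.neuropsych_params.items()
    }
    aff = spec.affine
    return PhantomSubject(
        subject_id=subject_id,
        group=group,
        echo_a=EchoVolume(echo_a, spec.voxel_size_mm, aff, spec.te_a_ms),
        echo_b=EchoVolume(echo_b, spec.voxel_size_mm, aff, spec.te_b_ms),
        anatomical=anatomical,
        labels=labels_anat,
        labels_echo=labels_echo,
        truth=truth,
        neuropsych=neuropsych,
        age=float(np.clip(rng.normal(75.3, 3.0), 70, 80)),
        sex="M" if rng.random() < 0.8 else "F",
        education=float(np.clip(rng.normal(15.7, 3.0), 8, 22)),
    )


def simulate_cohort(spec: PhantomSpec, out_dir=None):
    """Simulate the full cohort; optionally write NIfTI/CSV/JSON to disk.

    Returns (subjects, cohort DataFrame, RegionAtlas). Subject i is drawn
    from the independent stream ``default_rng([spec.seed, i])``, so the
    cohort is reproducible and each subject is independent of cohort order.
    """
    geometry = build_atlas_geometry(spec)
    groups = ["MCIs"] * spec.n_mcis + ["MCIp"] * spec.n_mcip
    subjects, rows = [], []
    for i, group in enumerate(groups):
        rng = np.random.default_rng([spec.seed, i])
        sid = f"S{i + 1:03d}"
        subj = simulate_subject(spec, group, rng, subject_id=sid, geometry=geometry)
        subjects.append(subj)
        row = {
            "subject_id": sid, "group": group, "age": subj.age,
            "sex": subj.sex, "education": subj.education,
        }
        row.update({f"score_{k + 1}": subj.neuropsych[n] for k, n in enumerate(NEUROPSYCH_SCORES)})
        rows.append(row)
    cohort = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv", index=False)
        for subj in subjects:
            sdir = out / subj.subject_id
            sdir.mkdir(exist_ok=True)
            subj.echo_a.to_nifti(sdir / "echo_a.nii.gz")
            subj.echo_b.to_nifti(sdir / "echo_b.nii.gz")
            save_nifti(subj.anatomical, spec.voxel_size_mm, sdir / "anatomical.nii.gz")
            save_nifti(subj.labels, spec.voxel_size_mm, sdir / "labels.nii.gz", dtype=np.int16)
            with open(sdir / "truth.json", "w") as fh:
                json.dump(
                    {
                        "group": subj.group,
                        "t2_ms": subj.truth,
                        "te_a_ms": spec.te_a_ms,
                        "te_b_ms": spec.te_b_ms,
                        "misalignment": list(spec.misalignment),
                    },
                    fh,
                    indent=1,
                )
    return subjects, cohort, geometry[1]
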