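"""Rigid registration of the anatomical image onto the T2 map space.

Segmentation labels are defined on the anatomical (MP-RAGE-like) image;
a rigid transform suffices to correct the small within-session head
motion between it and the echo images. Registration maximises Mattes
mutual information with a regular-step gradient-descent optimiser over a
versor rigid transform, then labels are resampled with nearest-neighbour
interpolation so no new label values are invented. The quantitative T2
map is always the fixed image — only the labels are ever resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from t2asym.io import to_sitk, from_sitk


@dataclass
class RigidTransform:
    """6-parameter rigid transform (versor rotation + translation).

    Maps fixed-space (T2 map) physical coordinates to moving-space
    (anatomical) physical coordinates, SimpleITK resampling convention.
    """

    versor: tuple            # (vx, vy, vz) rotation versor components
    translation_mm: tuple
    center_mm: tuple

    def to_sitk(self) -> sitk.VersorRigid3DTransform:
        t = sitk.VersorRigid3DTransform()
        t.SetCenter(self.center_mm)
        t.SetParameters(tuple(self.versor) + tuple(self.translation_mm))
        return t

    @classmethod
    def from_sitk(cls, t) -> "RigidTransform":
        p = t.GetParameters()
        return cls(tuple(p[:3]), tuple(p[3:6]), tuple(t.GetFixedParameters()[:3]))

    def rotation_angle_deg(self) -> float:
        """Total rotation angle encoded by the versor."""
        s = min(1.0, float(np.linalg.norm(self.versor)))
        return float(np.rad2deg(2 * np.arcsin(s)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "versor": list(self.versor),
                    "translation_mm": list(self.translation_mm),
                    "center_mm": list(self.center_mm),
                    "convention": "maps fixed-space points to moving-space points (ITK resampling)",
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["versor"]), tuple(d["translation_mm"]), tuple(d["center_mm"]))


@dataclass
class RegistrationConfig:
    """Optimizer/metric settings; defaults favour robustness at desk scale."""

    n_histogram_bins: int = 32
    sampling_fraction: float = 1.0
    sampling_seed: int = 121213
    learning_rate: float = 4.0
    min_step: float = 1e-6
    max_iterations: int = 1000
    shrink_factors: tuple = (4, 2, 1)
    smoothing_sigmas: tuple = (2.0, 1.0, 0.0)


def registration_image(t2map, echo_b, max_invalid_fraction: float = 0.5) -> np.ndarray:
    """Pick the fixed image that drives mutual information.

    The quantitative T2 map is preferred, but when most of its voxels are
    invalid (e.g. air background dominates the field of view) the metric
    is steadier on the raw T2-weighted echo intensity, which shares the
    map's grid. Returns the chosen 3D array.
    """
    invalid_fraction = 1.0 - float(np.asarray(t2map.valid_mask).mean())
    if invalid_fraction > max_invalid_fraction:
        return echo_b.data
    return t2map.t2_ms


class RegistrationError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing_mm,
    config: RegistrationConfig | None = None,
):
    """Rigid registration of ``moving`` onto ``fixed``.

    Parameters
    ----------
    fixed : ndarray
        The T2 map (or, when it has large invalid areas, the T2-weighted
        echo intensity) on the reference grid.
    moving : ndarray
        The anatomical image.
    spacing_mm : tuple
        Shared voxel spacing of both grids.
    config : RegistrationConfig, optional

    Returns
    -------
    (RigidTransform, list of per-iteration metric values)

    Raises
    ------
    RegistrationError
        If the metric is non-finite at convergence (e.g. disjoint fields
        of view), carrying the optimisation trace.
    """
    cfg = config or RegistrationConfig()
    f = to_sitk(np.asarray(fixed, dtype=np.float64), spacing_mm)
    m = to_sitk(np.asarray(moving, dtype=np.float64), spacing_mm)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(cfg.n_histogram_bins)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.sampling_seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=cfg.learning_rate,
        minStep=cfg.min_step,
        numberOfIterations=cfg.max_iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.VersorRigid3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()

    trace: list = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))

    try:
        result = reg.Execute(f, m)
    except RuntimeError as exc:  # optimizer blew up / no overlap
        raise RegistrationError(f"registration failed: {exc}", trace) from exc
    final_metric = reg.GetMetricValue()
    if not np.isfinite(final_metric):
        raise RegistrationError(
            f"registration metric non-finite ({final_metric}); "
            "fields of view may not overlap", trace
        )
    # Mattes MI is strictly negative when the images share information; a
    # near-zero optimum (or an optimizer that never moved) means there was
    # nothing to align and the result would be a silent identity.
    if not trace or final_metric > -1e-3:
        raise RegistrationError(
            f"registration found no shared image information "
            f"(final metric {final_metric:.3g}); fields of view may not overlap",
            trace,
        )
    versor = sitk.VersorRigid3DTransform(result.GetNthTransform(0)) if isinstance(
        result, sitk.CompositeTransform
    ) else sitk.VersorRigid3DTransform(result)
    return RigidTransform.from_sitk(versor), trace


def resample_labels(
    labels: np.ndarray,
    transform: RigidTransform,
    reference_shape,
    spacing_mm,
) -> np.ndarray:
    """Resample a categorical label image into the reference grid.

    Nearest-neighbour interpolation only; points mapping outside the
    source grid get label 0. The output label set is always a subset of
    the input label set plus {0}.
    """
    src = to_sitk(np.asarray(labels, dtype=np.float64), spacing_mm)
    ref = to_sitk(np.zeros(tuple(int(n) for n in reference_shape)), spacing_mm)
    out = sitk.Resample(src, ref, transform.to_sitk(), sitk.sitkNearestNeighbor, 0.0)
    return from_sitk(out).astype(np.int16)


def dice_per_region(labels_a: np.ndarray, labels_b: np.ndarray, label_ids) -> dict:
    """Dice overlap per label between two label images on the same grid."""
    out = {}
    for lab in label_ids:
        a = labels_a == lab
        b = labels_b == lab
        denom = a.sum() + b.sum()
        out[lab] = 2.0 * np.logical_and(a, b).sum() / denom if denom else np.nan
    return out
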