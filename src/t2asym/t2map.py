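"""Two-point T2 map estimation from a dual fast spin-echo pair.

A spin-echo signal follows mono-exponential transverse decay,
``S(TE) = S0 * exp(-TE / T2)``. With two echoes Sa (short TE, PD-weighted)
and Sb (long TE, T2-weighted) of the same anatomy, T2 has the closed form

    T2 = (TE_b - TE_a) / (ln Sa - ln Sb)

per voxel. Voxels where the log-ratio is undefined or non-positive
(``Sa <= 0``, ``Sb <= 0`` or ``Sa <= Sb``, i.e. apparent signal *growth*
with echo time) carry no physical T2 and are masked invalid. Valid values
outside a configurable physiological clip range are clamped to the range
bounds and stay valid, so downstream regional histograms remain bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

DEFAULT_CLIP_RANGE_MS = (1.0, 3000.0)


@dataclass
class EchoVolume:
    """A 3D scalar image acquired at a single echo time.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Signal intensity in arbitrary units.
    spacing_mm : tuple of 3 floats
        Voxel size along each array axis.
    affine : (4, 4) ndarray
        Grid-to-world map (nibabel convention).
    te_ms : float
        Echo time in milliseconds, strictly positive.
    """

    data: np.ndarray
    spacing_mm: tuple
    affine: np.ndarray
    te_ms: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        if self.te_ms <= 0:
            raise ValueError(f"te_ms must be > 0, got {self.te_ms}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive floats, got {self.spacing_mm}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @classmethod
    def from_nifti(cls, path, te_ms: float) -> "EchoVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj, dtype=float), spacing, img.affine, te_ms)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass
class T2Map:
    """Voxel-wise T2 values (ms) with a validity mask.

    Invalid voxels hold ``t2_ms == 0``; valid voxels lie inside
    ``clip_range_ms`` (clamped values included).
    """

    t2_ms: np.ndarray
    valid_mask: np.ndarray
    clip_range_ms: tuple
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.t2_ms.astype(np.float32), self.affine), str(path))


def _check_geometry(echo_a: EchoVolume, echo_b: EchoVolume) -> None:
    if echo_a.data.shape != echo_b.data.shape:
        raise ValueError(
            f"echo geometry mismatch: shape {echo_a.data.shape} != {echo_b.data.shape}"
        )
    if echo_a.spacing_mm != echo_b.spacing_mm:
        raise ValueError(
            f"echo geometry mismatch: spacing_mm {echo_a.spacing_mm} != {echo_b.spacing_mm}"
        )
    if not np.allclose(echo_a.affine, echo_b.affine):
        raise ValueError("echo geometry mismatch: affine matrices differ")


def compute_t2_map(
    echo_a: EchoVolume,
    echo_b: EchoVolume,
    clip_range_ms: tuple = DEFAULT_CLIP_RANGE_MS,
) -> T2Map:
    """Closed-form two-point T2 estimate, per voxel.

    ``t2 = (TE_b - TE_a) / (ln Sa - ln Sb)``. Voxels with non-positive
    signal in either echo, or with ``Sa <= Sb`` (non-decaying signal), are
    invalid and set to 0. Valid estimates outside ``clip_range_ms`` are
    clamped to the bounds and remain valid.

    Parameters
    ----------
    echo_a, echo_b : EchoVolume
        Short-TE (PD-weighted) and long-TE (T2-weighted) images on the same
        grid; requires ``echo_a.te_ms < echo_b.te_ms``.
    clip_range_ms : (low, high)
        Physiological clamp for valid values.

    Returns
    -------
    T2Map
    """
    _check_geometry(echo_a, echo_b)
    if echo_a.te_ms >= echo_b.te_ms:
        raise ValueError(
            f"TE_a must be < TE_b, got TE_a={echo_a.te_ms}, TE_b={echo_b.te_ms}"
        )
    lo, hi = clip_range_ms
    if not (0 < lo < hi):
        raise ValueError(f"clip_range_ms must satisfy 0 < low < high, got {clip_range_ms}")

    sa, sb = echo_a.data, echo_b.data
    valid = (sa > 0) & (sb > 0) & (sa > sb)
    t2 = np.zeros(sa.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.log(np.where(valid, sa, 1.0)) - np.log(np.where(valid, sb, np.e))
        t2[valid] = (echo_b.te_ms - echo_a.te_ms) / denom[valid]
    t2[valid] = np.clip(t2[valid], lo, hi)
    return T2Map(t2, valid, (float(lo), float(hi)), echo_a.spacing_mm, echo_a.affine)


def t2_fit_quality(echo_a: EchoVolume, echo_b: EchoVolume, t2map: T2Map) -> np.ndarray:
    """Per-voxel RMS log-residual of the mono-exponential refit.

    For each valid voxel the stored T2 is re-fit against the two measured
    echoes with ``ln S0`` chosen by least squares. The exact two-point
    solution reproduces both echoes, so the residual is 0 everywhere except
    where clamping to the clip range altered the value. Invalid voxels get 0.
    """
    _check_geometry(echo_a, echo_b)
    valid = t2map.valid_mask & (echo_a.data > 0) & (echo_b.data > 0)
    res = np.zeros(echo_a.data.shape, dtype=float)
    if not valid.any():
        return res
    la = np.log(echo_a.data[valid])
    lb = np.log(echo_b.data[valid])
    inv_t2 = 1.0 / t2map.t2_ms[valid]
    # least-squares ln S0 given fixed decay rate
    ln_s0 = 0.5 * ((la + echo_a.te_ms * inv_t2) + (lb + echo_b.te_ms * inv_t2))
    ra = la - (ln_s0 - echo_a.te_ms * inv_t2)
    rb = lb - (ln_s0 - echo_b.te_ms * inv_t2)
    res[valid] = np.sqrt(0.5 * (ra**2 + rb**2))
    return res
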