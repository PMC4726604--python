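"""Diffusion-tensor scalar maps.

Fits the single-tensor model to diffusion-weighted volumes by ordinary
least squares on the log-attenuation, and derives the four scalar maps the
histogram analysis runs on: fractional anisotropy (FA), mean diffusivity
(MD), radial diffusivity (RD) and axial diffusivity (AD).  Also provides
the two preprocessing averages applied before fitting: geometric averaging
of opposite-polarity gradient pairs (which cancels gradient cross-terms)
and arithmetic averaging of the b=0 volumes.

Diffusivities are in mm^2 s^-1 throughout; FA is unitless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalarVolume",
    "TensorField",
    "geometric_average_polarity_pairs",
    "average_b0",
    "fit_tensor_loglinear",
    "tensor_eigenvalues",
    "tensor_scalars",
]

#: order of the unique tensor components along the last axis
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class ScalarVolume:
    """One 3-D map of a tensor-derived quantity.

    Parameters
    ----------
    data
        Voxel values; NaN marks voxels where the tensor is undefined.
    measure
        One of ``FA``, ``MD``, ``RD``, ``AD``.
    spacing
        Voxel edge lengths in mm.
    """

    data: np.ndarray
    measure: str
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)

    @property
    def units(self) -> str:
        return "1" if self.measure == "FA" else "mm^2/s"

    def __post_init__(self) -> None:
        if self.measure not in {"FA", "MD", "RD", "AD"}:
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor, stored as its 6 unique
    components (order :data:`TENSOR_COMPONENTS`) along the last axis."""

    components: np.ndarray  # (..., 6)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    #: True where the voxel could not be fitted (e.g. non-positive b0)
    invalid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.components.shape[-1] != 6:
            raise ValueError("components must have 6 entries on the last axis")

    def as_matrices(self) -> np.ndarray:
        """Expand to full (..., 3, 3) symmetric matrices."""
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3), dtype=c.dtype)
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, **kw) -> "TensorField":
        c = np.stack(
            [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
             m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
            axis=-1,
        )
        return cls(components=c, **kw)


def geometric_average_polarity_pairs(dwi_pos: np.ndarray, dwi_neg: np.ndarray) -> np.ndarray:
    """Voxelwise geometric mean of a gradient direction and its negative.

    Averaging the signals acquired with +g and -g as sqrt(S+ * S-)
    cancels the imaging-gradient cross-terms in the effective b-matrix,
    so the averaged signal obeys the nominal diffusion weighting.
    """
    dwi_pos = np.asarray(dwi_pos, dtype=float)
    dwi_neg = np.asarray(dwi_neg, dtype=float)
    if dwi_pos.shape != dwi_neg.shape:
        raise ValueError(
            f"shape mismatch: {dwi_pos.shape} vs {dwi_neg.shape}")
    if (dwi_pos < 0).any() or (dwi_neg < 0).any():
        raise ValueError("DWI intensities must be non-negative")
    return np.sqrt(dwi_pos * dwi_neg)


def average_b0(b0_stack: np.ndarray) -> np.ndarray:
    """Arithmetic voxelwise mean of the non-diffusion-weighted volumes.

    ``b0_stack`` has the volumes along the first axis; one volume is
    acceptable and returned unchanged (as float).
    """
    b0_stack = np.asarray(b0_stack, dtype=float)
    if b0_stack.ndim < 1 or b0_stack.shape[0] == 0:
        raise ValueError("empty b0 stack")
    return b0_stack.mean(axis=0)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of -b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]."""
    g = bvecs
    cols = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    )
    return -bvals[:, None] * cols


def fit_tensor_loglinear(
    dwi: np.ndarray,
    b0: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    *,
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5),
) -> TensorField:
    """Ordinary least-squares tensor fit on log(S/S0).

    Parameters
    ----------
    dwi
        Diffusion-weighted volumes, shape ``(..., n_dirs)`` (last axis is
        the gradient direction).
    b0
        Mean non-weighted volume, shape ``(...)``.
    bvals, bvecs
        b-values (s mm^-2, shape ``(n_dirs,)``) and unit gradient
        directions (shape ``(n_dirs, 3)``).

    Voxels with non-positive b0 or any non-positive weighted signal are
    returned as NaN tensors and flagged in ``invalid``.
    """
    dwi = np.asarray(dwi, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape == (3, bvals.size) and bvals.size != 3:
        bvecs = bvecs.T
    if (bvals < 0).any():
        raise ValueError("negative b-value")
    norms = np.linalg.norm(bvecs, axis=1)
    if not np.allclose(norms[bvals > 0], 1.0, atol=1e-6):
        raise ValueError("gradient directions must be unit vectors")
    B = _design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(B) < 6:
        raise ValueError("rank-deficient gradient scheme: "
                         "need >=6 non-collinear directions")

    vol_shape = dwi.shape[:-1]
    invalid = (b0 <= 0) | (dwi <= 0).any(axis=-1)
    ok = ~invalid.reshape(-1)
    S = dwi.reshape(-1, bvals.size)
    S0 = b0.reshape(-1)

    comps = np.full((S.shape[0], 6), np.nan)
    if ok.any():
        y = np.log(S[ok] / S0[ok, None])
        sol, *_ = np.linalg.lstsq(B, y.T, rcond=None)
        comps[ok] = sol.T
    return TensorField(
        components=comps.reshape(vol_shape + (6,)),
        spacing=spacing,
        invalid=invalid,
    )


def tensor_eigenvalues(field: TensorField) -> np.ndarray:
    """Eigenvalues per voxel, sorted descending (lambda1 >= lambda2 >= lambda3).

    NaN tensors yield NaN eigenvalues.
    """
    m = field.as_matrices()
    bad = ~np.isfinite(m).all(axis=(-2, -1))
    m = np.where(bad[..., None, None], np.eye(3), m)
    ev = np.linalg.eigvalsh(m)[..., ::-1]  # eigvalsh sorts ascending
    ev[bad] = np.nan
    return ev


def tensor_scalars(
    field: TensorField, *, clamp_negative: bool = True
) -> tuple[dict[str, ScalarVolume], np.ndarray]:
    """FA/MD/RD/AD maps from a tensor field.

    MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2 and
    FA = sqrt(3/2) * ||l - mean(l)|| / ||l||, with FA defined as 0 where
    all eigenvalues vanish.  Negative eigenvalues (possible in noisy
    log-linear fits) are clamped to zero before the scalars are computed
    and the affected voxels are flagged in the returned QC mask, so FA
    stays within [0, 1] and diffusivities non-negative.

    Returns
    -------
    (maps, qc_mask)
        ``maps`` keyed by measure name; ``qc_mask`` is True where a
        negative eigenvalue was clamped or the tensor was undefined.
    """
    ev = tensor_eigenvalues(field)
    qc = ~np.isfinite(ev).all(axis=-1)
    neg = np.nan_to_num(ev, nan=0.0) < 0
    qc |= neg.any(axis=-1)
    if clamp_negative:
        ev = np.where(neg, 0.0, ev)

    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    md = (l1 + l2 + l3) / 3.0
    ad = l1
    rd = (l2 + l3) / 2.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num) / np.sqrt(den)
    fa = np.where(den == 0, 0.0, fa)
    fa[~np.isfinite(l1)] = np.nan

    maps = {
        "FA": ScalarVolume(fa, "FA", field.spacing),
        "MD": ScalarVolume(md, "MD", field.spacing),
        "RD": ScalarVolume(rd, "RD", field.spacing),
        "AD": ScalarVolume(ad, "AD", field.spacing),
    }
    return maps, qc
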