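"""SVD deconvolution of the bolus-tracking convolution model.

The tissue concentration obeys

    C(t) = F * integral AIF(t - tau) R(tau) dtau

with flow ``F`` (assumed constant per voxel over the scan) and residue
function ``R`` (``R(0)=1``, non-increasing in ideal tissue).  Discretized
on the frame grid this is a matrix equation ``C = A x`` with
``A[i, j] = dt * AIF[i - j]`` and ``x = F * R``; the ill-posed inverse is
regularized by truncated singular value decomposition.

Two operator variants are provided:

* ``simple`` — lower-triangular Toeplitz (causal) matrix.  Sensitive to a
  bolus delay between artery and tissue: if the tissue curve lags the AIF,
  flow is underestimated.
* ``circulant`` — block-circulant matrix built from the zero-padded AIF
  (circular convolution equals linear convolution once padded), which makes
  the estimate insensitive to such delays.

CBF is the peak of the recovered ``F*R(t)``, CBV its area (negative SVD
oscillations are zeroed before the area but not before the peak), and MTT
is CBV/CBF by the central volume principle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.linalg

from .concentration import ConcentrationSeries

__all__ = [
    "ConvolutionSystem",
    "ResidueCurve",
    "PerfusionParams",
    "PerfusionMaps",
    "DeconvolutionError",
    "build_convolution_matrix",
    "svd_deconvolve",
    "perfusion_parameters",
    "compute_maps",
]

#: Default truncation threshold (fraction of the largest singular value).
DEFAULT_TRUNCATION = {"simple": 0.2, "circulant": 0.1}


class DeconvolutionError(RuntimeError):
    pass


@dataclass
class ConvolutionSystem:
    """Discretized AIF convolution operator plus its truncated SVD."""

    matrix: np.ndarray
    mode: str
    dt: float
    n_frames: int
    pad_length: int
    truncation: float
    _svd: tuple | None = field(default=None, repr=False, compare=False)

    def svd(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._svd is None:
            self._svd = scipy.linalg.svd(self.matrix)
        return self._svd

    def pseudoinverse(self) -> np.ndarray:
        """Truncated-SVD pseudoinverse of the operator."""
        u, s, vt = self.svd()
        if s[0] <= 0:
            raise DeconvolutionError("degenerate (all-zero) AIF: no invertible component")
        keep = s >= self.truncation * s[0]
        inv_s = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
        return (vt.T * inv_s) @ u.T


@dataclass(frozen=True)
class ResidueCurve:
    """Flow-scaled residue function ``F * R(t)`` on the frame grid."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("residue curve contains non-finite values")
        object.__setattr__(self, "values", values)


class PerfusionParams(NamedTuple):
    cbf: float
    cbv: float
    mtt: float
    flagged: bool


@dataclass(frozen=True)
class PerfusionMaps:
    """Voxelwise CBF, CBV and MTT volumes plus QC metadata.

    ``flagged`` marks in-mask voxels with a non-positive residue peak
    (their parameters are set to 0); ``mask`` is the brain mask the maps
    were computed in.  ``mtt * cbf == cbv`` holds exactly wherever
    ``cbf > 0``.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray
    qc: dict


def build_convolution_matrix(
    aif,
    dt: float,
    mode: str = "circulant",
    pad_length: int | None = None,
    truncation: float | None = None,
) -> ConvolutionSystem:
    """Build the discretized AIF operator for SVD deconvolution.

    Parameters
    ----------
    aif:
        AIF concentration samples (1D array) or an object with a ``curve``
        attribute.
    mode:
        ``"simple"`` (lower-triangular Toeplitz) or ``"circulant"``
        (delay-insensitive, zero-padded block-circulant).
    pad_length:
        Zero padding for circulant mode; defaults to the AIF length
        (operator dimension ``2 n``), the standard anti-aliasing choice.
        Must be at least the AIF length.
    truncation:
        Fraction of the largest singular value below which components are
        discarded; defaults to 0.2 (simple) / 0.1 (circulant).
    """
    curve = np.asarray(getattr(aif, "curve", aif), dtype=float)
    if curve.ndim != 1 or curve.size < 2:
        raise ValueError("AIF must be a 1D curve with at least 2 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mode not in ("simple", "circulant"):
        raise ValueError(f"mode must be 'simple' or 'circulant', got {mode!r}")
    if truncation is None:
        truncation = DEFAULT_TRUNCATION[mode]
    if not 0 < truncation < 1:
        raise ValueError("truncation must be in (0, 1)")
    n = curve.size

    if mode == "simple":
        matrix = dt * scipy.linalg.toeplitz(curve, np.zeros(n))
        pad_length = 0
    else:
        if pad_length is None:
            pad_length = n
        if pad_length < n:
            raise ValueError(
                f"circulant pad_length must be >= AIF length ({n}), got {pad_length}"
            )
        padded = np.concatenate([curve, np.zeros(pad_length)])
        matrix = dt * scipy.linalg.circulant(padded)
    return ConvolutionSystem(
        matrix=matrix,
        mode=mode,
        dt=dt,
        n_frames=n,
        pad_length=pad_length,
        truncation=truncation,
    )


def _pad_curve(system: ConvolutionSystem, curve: np.ndarray) -> np.ndarray:
    m = system.matrix.shape[0]
    if curve.shape[-1] == m:
        return curve
    if curve.shape[-1] != system.n_frames:
        raise ValueError(
            f"curve length {curve.shape[-1]} incompatible with system "
            f"(n_frames={system.n_frames}, dimension={m})"
        )
    pad = [(0, 0)] * (curve.ndim - 1) + [(0, m - system.n_frames)]
    return np.pad(curve, pad)


def svd_deconvolve(system: ConvolutionSystem, conc_curve) -> ResidueCurve:
    """Recover ``F * R(t)`` from a tissue concentration curve."""
    curve = _pad_curve(system, np.asarray(conc_curve, dtype=float))
    x = system.pseudoinverse() @ curve
    return ResidueCurve(values=x[: system.n_frames], dt=system.dt)


def perfusion_parameters(residue: ResidueCurve) -> PerfusionParams:
    """CBF / CBV / MTT from a flow-scaled residue curve.

    CBF is the peak of ``F*R(t)`` over all time points (tolerant to
    residual delay); CBV is ``dt`` times the sum of the positive part;
    MTT = CBV / CBF.  A non-positive peak flags the voxel and returns
    all-zero parameters.  CBV is stored as ``mtt * cbf`` so the central
    volume identity holds to the last bit.
    """
    values = residue.values
    cbf = float(values.max())
    if cbf <= 0:
        return PerfusionParams(0.0, 0.0, 0.0, True)
    area = float(residue.dt * np.clip(values, 0.0, None).sum())
    mtt = area / cbf
    return PerfusionParams(cbf, mtt * cbf, mtt, False)


def compute_maps(
    conc: ConcentrationSeries,
    aif,
    mode: str = "circulant",
    truncation: float | None = None,
    pad_length: int | None = None,
) -> PerfusionMaps:
    """Voxelwise deconvolution of a concentration series into CBF/CBV/MTT maps.

    The AIF operator and its SVD are computed once and applied to every
    in-mask voxel as a single matrix product.  Outside the brain mask all
    maps are exactly zero.
    """
    system = build_convolution_matrix(
        aif, conc.dt, mode=mode, pad_length=pad_length, truncation=truncation
    )
    if system.n_frames != conc.n_frames:
        raise ValueError("AIF and concentration series have different frame counts")
    pinv = system.pseudoinverse()

    mask = conc.brain_mask
    curves = _pad_curve(system, conc.data[mask])
    residues = (curves @ pinv.T)[:, : system.n_frames]

    cbf = residues.max(axis=1)
    ok = cbf > 0
    area = conc.dt * np.clip(residues, 0.0, None).sum(axis=1)
    mtt = np.where(ok, area / np.where(ok, cbf, 1.0), 0.0)
    cbf = np.where(ok, cbf, 0.0)
    cbv = mtt * cbf  # exact central-volume identity by construction

    shape = conc.grid_shape
    out = {name: np.zeros(shape) for name in ("cbf", "cbv", "mtt")}
    out["cbf"][mask] = cbf
    out["cbv"][mask] = cbv
    out["mtt"][mask] = mtt
    flagged = np.zeros(shape, dtype=bool)
    flagged[mask] = ~ok

    qc = {
        "mode": mode,
        "truncation": system.truncation,
        "n_voxels": int(mask.sum()),
        "n_flagged": int(np.count_nonzero(~ok)),
        "negative_residue_fraction": float(np.mean(residues < 0)),
    }
    return PerfusionMaps(
        cbf=out["cbf"], cbv=out["cbv"], mtt=out["mtt"],
        mask=mask, flagged=flagged, qc=qc,
    )
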