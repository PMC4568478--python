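"""Conversion of a raw 4D bolus-tracking signal into contrast concentration.

Dynamic susceptibility contrast (DSC) MRI records a T2*-weighted signal
``S(x, t)`` that dips as a paramagnetic contrast bolus transits the tissue.
Under the standard single-exponential T2* model the voxelwise contrast
concentration is

    C(t) = -ln(S(t) / S0) / (k * TE)

where ``S0`` is the pre-bolus baseline signal, ``TE`` the echo time and
``k`` an (arbitrary) relaxivity constant.  Because the downstream analysis
is relative (surgical over contralateral hemisphere), the absolute scale of
``k`` is irrelevant and defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PerfusionSeries",
    "ConcentrationSeries",
    "estimate_baseline",
    "signal_to_concentration",
]

MIN_FRAMES = 20


@dataclass(frozen=True)
class PerfusionSeries:
    """A 4D perfusion-weighted signal series ``S(x, y, z, t)``.

    Parameters
    ----------
    data:
        4D float array, time on the last axis, arbitrary signal units.
    dt:
        Frame interval (repetition time) in seconds.
    te:
        Echo time in seconds.
    affine:
        4x4 voxel-to-world matrix (NIfTI convention).
    """

    data: np.ndarray
    dt: float
    te: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected a 4D (x, y, z, t) array, got ndim={data.ndim}")
        if data.shape[-1] < MIN_FRAMES:
            raise ValueError(
                f"need at least {MIN_FRAMES} time frames, got {data.shape[-1]}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("signal series contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.te <= 0:
            raise ValueError("te must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (first frame at t=0)."""
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class ConcentrationSeries:
    """Voxelwise contrast concentration ``C(x, y, z, t)``.

    Concentration is identically zero outside ``brain_mask``.  ``n_floored``
    counts signal samples that had to be floored to a positive value before
    the logarithm (a QC indicator of pathological noise).
    """

    data: np.ndarray
    s0: np.ndarray
    brain_mask: np.ndarray
    dt: float
    te: float
    n_floored: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.brain_mask, dtype=bool)
        if data.ndim != 4:
            raise ValueError("concentration data must be 4D")
        if mask.shape != data.shape[:3]:
            raise ValueError("brain_mask shape does not match the spatial grid")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "s0", np.asarray(self.s0, dtype=float))
        object.__setattr__(self, "brain_mask", mask)

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def estimate_baseline(
    series: PerfusionSeries,
    n_baseline: int = 8,
    mask_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the pre-bolus baseline map S0 and a brain mask.

    S0 is the per-voxel mean of the first ``n_baseline`` frames (the
    contrast arrives after scan start).  The brain mask keeps voxels whose
    baseline exceeds ``mask_fraction`` of the robust (99th percentile)
    image maximum — a simple, reproducible air/background rejection.

    Returns
    -------
    (s0, brain_mask):
        3D float baseline map and 3D boolean mask.
    """
    if not 1 <= n_baseline < series.n_frames:
        raise ValueError(
            f"n_baseline must be in [1, {series.n_frames - 1}], got {n_baseline}"
        )
    s0 = series.data[..., :n_baseline].mean(axis=-1)
    robust_max = np.percentile(s0, 99)
    brain_mask = s0 > mask_fraction * robust_max
    return s0, brain_mask


def signal_to_concentration(
    series: PerfusionSeries,
    s0: np.ndarray,
    brain_mask: np.ndarray,
    k: float = 1.0,
    floor_fraction: float = 1e-3,
) -> ConcentrationSeries:
    """Convert signal to concentration via ``C = -ln(S/S0) / (k TE)``.

    Negative concentrations (signal above baseline, from noise) are
    retained: clipping them would bias the arterial input function peak.
    Non-positive signal samples inside the mask are floored at
    ``floor_fraction * S0`` before the logarithm and counted in
    ``n_floored``.

    Raises
    ------
    ValueError
        If S0 is not strictly positive everywhere inside the mask.
    """
    if k <= 0:
        raise ValueError("relaxivity constant k must be positive")
    s0 = np.asarray(s0, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if s0.shape != series.grid_shape or brain_mask.shape != series.grid_shape:
        raise ValueError("s0 / brain_mask shape does not match the series grid")
    if np.any(s0[brain_mask] <= 0):
        raise ValueError("baseline S0 must be strictly positive inside the brain mask")

    sig = series.data[brain_mask]  # (n_voxels, n_frames)
    base = s0[brain_mask][:, None]
    floor = floor_fraction * base
    n_floored = int(np.count_nonzero(sig < floor))
    sig = np.maximum(sig, floor)

    conc = np.zeros_like(series.data)
    conc[brain_mask] = -np.log(sig / base) / (k * series.te)
    return ConcentrationSeries(
        data=conc,
        s0=s0,
        brain_mask=brain_mask,
        dt=series.dt,
        te=series.te,
        n_floored=n_floored,
    )
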