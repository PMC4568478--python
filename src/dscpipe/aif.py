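"""Automatic arterial input function (AIF) selection.

Arterial voxels are located by screening per-voxel concentration curve
features: an arterial curve arrives early (low time-to-peak), is narrow
(low first-moment transit time) and tall (high peak concentration).  The
selection rule is deterministic: candidates fall below chosen quantiles of
TTP and first-moment MTT, and from those the ``n_aif`` highest-peak voxels
are averaged into the AIF.  An optional ROI mask restricts candidates to
an anatomically plausible neighbourhood, and a peak-dominance QC check
refuses a selection whose mean curve looks like tissue rather than artery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .concentration import ConcentrationSeries

__all__ = [
    "CurveFeatures",
    "ArterialInputFunction",
    "AifSelectionError",
    "compute_curve_features",
    "select_aif_voxels",
]


class AifSelectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class CurveFeatures:
    """Per-voxel screening features (NaN outside the brain mask).

    peak:
        Maximum concentration.
    ttp:
        Time to peak, seconds (``dt * argmax``).
    fm_mtt:
        First moment of the positive part of the curve minus the bolus
        arrival time — a transit-time (curve width) proxy, seconds.
    """

    peak: np.ndarray
    ttp: np.ndarray
    fm_mtt: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class ArterialInputFunction:
    """Averaged AIF curve plus the voxels and thresholds that produced it."""

    curve: np.ndarray
    voxel_ids: np.ndarray  # (n, 3) integer voxel coordinates
    thresholds_used: dict
    dt: float
    saturated: bool = False  # fewer candidates than requested

    def __post_init__(self) -> None:
        object.__setattr__(self, "curve", np.asarray(self.curve, dtype=float))
        object.__setattr__(self, "voxel_ids", np.asarray(self.voxel_ids, dtype=int))


def compute_curve_features(
    conc: ConcentrationSeries, arrival_fraction: float = 0.05
) -> CurveFeatures:
    """Peak, time-to-peak and first-moment width of every in-mask curve.

    The bolus arrival time is the first frame at which the curve reaches
    ``arrival_fraction`` of its peak; the first moment is computed over
    the positive part of the curve only (noise can push samples negative).
    """
    mask = conc.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    curves = conc.data[mask]  # (n_voxels, n_frames)
    dt = conc.dt
    t = np.arange(conc.n_frames) * dt

    peak = curves.max(axis=1)
    ttp = t[np.argmax(curves, axis=1)]

    positive = np.clip(curves, 0.0, None)
    total = positive.sum(axis=1)
    safe_total = np.where(total > 0, total, 1.0)
    first_moment = (positive * t).sum(axis=1) / safe_total

    arrived = curves >= arrival_fraction * np.maximum(peak, 1e-300)[:, None]
    arrival = t[np.argmax(arrived, axis=1)]
    fm = np.where(total > 0, np.maximum(first_moment - arrival, 1e-3 * dt), np.nan)

    shape = conc.grid_shape
    out_peak = np.full(shape, np.nan)
    out_ttp = np.full(shape, np.nan)
    out_fm = np.full(shape, np.nan)
    out_peak[mask] = peak
    out_ttp[mask] = ttp
    out_fm[mask] = fm
    return CurveFeatures(peak=out_peak, ttp=out_ttp, fm_mtt=out_fm, mask=mask)


def select_aif_voxels(
    conc: ConcentrationSeries,
    features: CurveFeatures | None = None,
    n_aif: int = 10,
    ttp_quantile: float = 0.1,
    mtt_quantile: float = 0.2,
    roi_mask: np.ndarray | None = None,
    min_peak_dominance: float = 3.0,
) -> ArterialInputFunction:
    """Select arterial voxels and average their curves into the AIF.

    Candidates are in-mask voxels whose TTP and first-moment MTT both fall
    below the stated quantiles of their whole-brain distributions (early,
    narrow curves); among candidates the ``n_aif`` voxels with the highest
    peak are kept (ties broken by lower TTP, then voxel order).  If
    ``roi_mask`` is given, candidates are further restricted to it.

    The selected mean curve must have a peak at least
    ``min_peak_dominance`` times the median in-mask peak; otherwise the
    selection is rejected rather than silently returning a tissue curve.

    Raises
    ------
    AifSelectionError
        If no candidate survives the thresholds, or the selection fails
        the peak-dominance check.
    """
    if n_aif < 1:
        raise ValueError("n_aif must be >= 1")
    for name, q in (("ttp_quantile", ttp_quantile), ("mtt_quantile", mtt_quantile)):
        if not 0 < q < 1:
            raise ValueError(f"{name} must be in (0, 1), got {q}")
    if features is None:
        features = compute_curve_features(conc)

    mask = features.mask
    usable = mask & np.isfinite(features.fm_mtt)
    ttp_cut = float(np.quantile(features.ttp[usable], ttp_quantile))
    fm_cut = float(np.quantile(features.fm_mtt[usable], mtt_quantile))
    candidates = usable & (features.ttp <= ttp_cut) & (features.fm_mtt <= fm_cut)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != mask.shape:
            raise ValueError("roi_mask shape does not match the grid")
        candidates &= roi_mask
    thresholds = {
        "ttp_quantile": ttp_quantile,
        "mtt_quantile": mtt_quantile,
        "ttp_cut_s": ttp_cut,
        "fm_mtt_cut_s": fm_cut,
        "n_aif": n_aif,
    }
    coords = np.argwhere(candidates)
    if coords.shape[0] == 0:
        raise AifSelectionError(
            f"no AIF candidates below ttp <= {ttp_cut:.3g}s and "
            f"fm_mtt <= {fm_cut:.3g}s"
            + (" within the ROI" if roi_mask is not None else "")
        )

    cand_peak = features.peak[candidates]
    cand_ttp = features.ttp[candidates]
    # sort by (-peak, ttp, voxel order); argwhere is already in index order
    order = np.lexsort((np.arange(coords.shape[0]), cand_ttp, -cand_peak))
    selected = order[:n_aif]
    saturated = coords.shape[0] < n_aif
    voxel_ids = coords[selected]

    curve = conc.data[tuple(voxel_ids.T)].mean(axis=0)
    median_peak = float(np.median(features.peak[usable]))
    if median_peak > 0 and curve.max() < min_peak_dominance * median_peak:
        raise AifSelectionError(
            "selected AIF is not artery-like: mean-curve peak "
            f"{curve.max():.3g} < {min_peak_dominance} x median voxel peak "
            f"{median_peak:.3g} (is the ROI excluding the artery?)"
        )
    return ArterialInputFunction(
        curve=curve,
        voxel_ids=voxel_ids,
        thresholds_used=thresholds,
        dt=conc.dt,
        saturated=saturated,
    )
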