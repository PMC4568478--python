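"""Synthetic DSC-MRI phantoms and paired pre/intra surgical cohorts.

Every downstream stage of the pipeline is testable against ground truth
generated here: a territory-labelled digital brain phantom, a
gamma-variate contrast bolus, exponential (well-mixed compartment) residue
functions with territory-specific CBF/CBV/MTT, multiplicative T2* signal
formation and Gaussian magnitude noise.  A paired cohort generator adds a
group-specific surgical-side flow change (a cerebral hyperperfusion
effect at the terminal MCA territory for the CHS group against a non-CHS
null) with between-subject variability.

Units: flow is expressed as a volume-fraction rate in 1/s (0.01 /s
corresponds to 60 mL/100g/min), so CBV = CBF x MTT lands at the
physiological few-percent blood volume and signal attenuation is realistic
with relaxivity k = 1.  Only relative (side-ratio) values are analyzed
downstream, so the absolute flow scale never enters the statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .concentration import PerfusionSeries
from .territories import SIDES, TERRITORIES, TerritoryAtlas

__all__ = [
    "PhantomSpec",
    "TerritoryTruth",
    "CohortSpec",
    "AifParams",
    "SessionTruth",
    "SimulatedCohort",
    "ARTERY_LABEL",
    "gamma_variate_aif",
    "simulate_tissue_curve",
    "build_phantom_atlas",
    "default_territory_truths",
    "simulate_phantom_session",
    "simulate_cohort",
    "write_cohort",
]

ARTERY_LABEL = 11
GROUPS = ("CHS", "non-CHS")

#: Default per-territory (cbf [1/s], mtt [s]) ground truth; cbf ~0.01/s is
#: gray-matter-like flow, mtt 3.8-4.6 s spans normal transit times.
DEFAULT_TERRITORY_PARAMS: dict[str, tuple[float, float]] = {
    "ACA-terminal": (0.0090, 4.2),
    "ACA-central": (0.0085, 4.4),
    "MCA-terminal": (0.0105, 4.0),
    "MCA-central": (0.0100, 3.8),
    "PCA-terminal": (0.0095, 4.6),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Acquisition and noise parameters of a simulated perfusion scan.

    Defaults follow a clinical bolus-tracking protocol: frame interval
    1.5 s (TR), echo time 30 ms, 60 frames on a 32x32x10 grid.  Noise is
    Gaussian on the *signal* (MR magnitude noise at high SNR), not on
    concentration.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 10)
    n_frames: int = 60
    dt: float = 1.5
    te: float = 0.030
    s0: float = 100.0
    noise_sd: float = 0.5
    seed: int = 0
    k: float = 1.0  # arbitrary relaxivity; only relative values matter

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 dimensions of at least 4 voxels")
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.te <= 0:
            raise ValueError("te must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class TerritoryTruth:
    """Ground-truth hemodynamics of one labelled territory.

    ``cbv`` is derived as ``cbf * mtt`` (central volume principle) and is
    exact by construction.
    """

    label: int
    side: str
    cbf: float
    mtt: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError("cbf must be nonnegative")
        if self.mtt <= 0:
            raise ValueError("mtt must be positive")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    @property
    def cbv(self) -> float:
        return self.cbf * self.mtt


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate bolus: arrival t0, shape alpha, scale beta [s], peak amplitude."""

    t0: float = 12.0
    alpha: float = 3.0
    beta: float = 1.5
    amplitude: float = 60.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a paired pre/intra surgical cohort.

    ``effect_map`` maps group name to ``{territory: fractional intra/pre
    CBF change on the surgical side}`` (0.143 = +14.3%).  Each subject's
    realized effect is the group effect plus a Gaussian perturbation of SD
    ``between_subject_sd``.  ``baseline_asymmetry_sd`` sets pre-surgical
    side-to-side spread; ``mtt_jitter_sd`` sets session-to-session MTT
    variability on the surgical side (both multiplicative fractions).
    """

    n_chs: int = 5
    n_nonchs: int = 9
    effect_map: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "CHS": {"MCA-terminal": 0.143},
            "non-CHS": {"MCA-terminal": 0.0},
        }
    )
    between_subject_sd: float = 0.07
    baseline_asymmetry_sd: float = 0.10
    mtt_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chs < 1 or self.n_nonchs < 1:
            raise ValueError("each group needs at least one subject")
        for group, effects in self.effect_map.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} in effect_map")
            unknown = set(effects) - set(TERRITORIES)
            if unknown:
                raise ValueError(f"unknown territories in effect_map: {sorted(unknown)}")
        for name in ("between_subject_sd", "baseline_asymmetry_sd", "mtt_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gamma_variate_aif(t, t0: float = 12.0, alpha: float = 3.0,
                      beta: float = 1.5, amplitude: float = 60.0) -> np.ndarray:
    """Gamma-variate bolus ``A ((t-t0)/(a b))^a exp(a - (t-t0)/b)``.

    Zero for ``t <= t0``, nonnegative, single-peaked with its maximum
    (value ``amplitude``) at ``t0 + alpha * beta``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > t0
    x = t[pos] - t0
    out[pos] = amplitude * (x / (alpha * beta)) ** alpha * np.exp(alpha - x / beta)
    return out


def _residue_weights(n: int, mtt: float, dt: float) -> np.ndarray:
    """Bin-averaged exponential residue ``(1/dt) int_{j dt}^{(j+1) dt} e^{-u/mtt} du``.

    Averaging over each frame interval (rather than point sampling) keeps
    the discrete convolution exact in integral: ``dt * sum(w)`` equals the
    captured residue area ``mtt (1 - e^{-n dt / mtt})``, so the
    tissue-curve area identity and the impulse limit ``mtt << dt`` both
    hold without a fine simulation grid.
    """
    j = np.arange(n)
    return (mtt / dt) * np.exp(-j * dt / mtt) * (-np.expm1(-dt / mtt))


def simulate_tissue_curve(aif, truth: TerritoryTruth, dt: float) -> np.ndarray:
    """Tissue concentration ``C(t) = F dt sum AIF(t - tau - delay) R(tau)``.

    ``R`` is the exponential residue ``exp(-tau/MTT)`` (bin-averaged per
    frame).  A nonzero ``truth.delay`` shifts the AIF by linear
    interpolation on the frame grid.
    """
    aif = np.asarray(getattr(aif, "curve", aif), dtype=float)
    if aif.ndim != 1:
        raise ValueError("AIF must be a 1D curve")
    if aif.size < 2:
        raise ValueError("AIF must have at least 2 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = aif.size
    if truth.delay > 0:
        t = np.arange(n) * dt
        aif = np.interp(t - truth.delay, t, aif, left=0.0, right=0.0)
    weights = _residue_weights(n, truth.mtt, dt)
    return truth.cbf * dt * np.convolve(aif, weights)[:n]


def build_phantom_atlas(grid_shape: tuple[int, int, int] = (32, 32, 10)) -> TerritoryAtlas:
    """Geometric territory atlas: left/right hemispheres (split along x),
    five territory bands along y, a small midline artery block, and a
    one-voxel background rim."""
    nx, ny, nz = grid_shape
    if nx < 12 or ny < 12 or nz < 4:
        raise ValueError("grid too small for the 12-label phantom atlas")
    labels = np.zeros(grid_shape, dtype=np.int16)
    mid = nx // 2
    y_edges = np.linspace(1, ny - 1, 6).round().astype(int)
    for ti in range(5):
        ysl = slice(y_edges[ti], y_edges[ti + 1])
        labels[1:mid, ysl, 1:nz - 1] = 1 + ti
        labels[mid:nx - 1, ysl, 1:nz - 1] = 6 + ti
    az = slice(max(1, nz // 2 - 1), min(nz - 1, nz // 2 + 1))
    labels[mid - 2:mid + 2, ny // 2 - 1:ny // 2 + 1, az] = ARTERY_LABEL
    dictionary = {}
    for ti, name in enumerate(TERRITORIES):
        dictionary[1 + ti] = (name, "left")
        dictionary[6 + ti] = (name, "right")
    dictionary[ARTERY_LABEL] = ("artery", "midline")
    return TerritoryAtlas(labels=labels, dictionary=dictionary)


def default_territory_truths(
    atlas: TerritoryAtlas,
    params: Mapping[str, tuple[float, float]] | None = None,
) -> dict[int, TerritoryTruth]:
    """Hemispherically symmetric ground truth for every territory label."""
    params = dict(DEFAULT_TERRITORY_PARAMS if params is None else params)
    truths = {}
    for label, (name, side) in atlas.dictionary.items():
        if side not in SIDES:
            continue
        cbf, mtt = params[name]
        truths[label] = TerritoryTruth(label=label, side=side, cbf=cbf, mtt=mtt)
    return truths


@dataclass(frozen=True)
class SessionTruth:
    """Exact per-label ground truth attached to a simulated session."""

    truths: dict[int, TerritoryTruth]
    aif_params: AifParams
    phantom: PhantomSpec

    def truth_maps(self, atlas: TerritoryAtlas) -> dict[str, np.ndarray]:
        """Exact per-voxel CBF/CBV/MTT volumes (zero outside territories)."""
        maps = {p: np.zeros(atlas.labels.shape) for p in ("cbf", "cbv", "mtt")}
        for label, truth in self.truths.items():
            sel = atlas.labels == label
            maps["cbf"][sel] = truth.cbf
            maps["cbv"][sel] = truth.cbv
            maps["mtt"][sel] = truth.mtt
        return maps

    def to_dict(self) -> dict:
        return {
            "labels": {
                str(label): {
                    "side": t.side, "cbf": t.cbf, "cbv": t.cbv,
                    "mtt": t.mtt, "delay": t.delay,
                }
                for label, t in self.truths.items()
            },
            "aif_params": vars(self.aif_params).copy(),
            "phantom": {
                "grid_shape": list(self.phantom.grid_shape),
                "n_frames": self.phantom.n_frames,
                "dt": self.phantom.dt,
                "te": self.phantom.te,
                "s0": self.phantom.s0,
                "noise_sd": self.phantom.noise_sd,
                "seed": self.phantom.seed,
                "k": self.phantom.k,
            },
        }


def simulate_phantom_session(
    phantom: PhantomSpec,
    atlas: TerritoryAtlas,
    truths: Mapping[int, TerritoryTruth],
    aif_params: AifParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PerfusionSeries, SessionTruth]:
    """Render one 4D signal series from territory ground truth.

    Tissue voxels carry the convolved concentration curve of their label;
    voxels of the dedicated artery label carry the pure AIF; signal is
    formed as ``S = S0 exp(-k TE C)`` with additive Gaussian noise.
    Background (label 0) is set to a low constant signal so the brain mask
    excludes it.  Identical ``(phantom, truths, seed)`` give bit-identical
    output.
    """
    if aif_params is None:
        aif_params = AifParams()
    if atlas.labels.shape != tuple(phantom.grid_shape):
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match phantom grid "
            f"{tuple(phantom.grid_shape)}"
        )
    tissue_labels = {
        label for label, (name, side) in atlas.dictionary.items() if side in SIDES
    }
    missing = tissue_labels - set(truths)
    if missing:
        raise ValueError(f"missing TerritoryTruth for labels: {sorted(missing)}")

    t = phantom.times
    aif = gamma_variate_aif(t, **vars(aif_params))
    conc = np.zeros(phantom.grid_shape + (phantom.n_frames,))
    for label in sorted(tissue_labels):
        sel = atlas.labels == label
        if sel.any():
            conc[sel] = simulate_tissue_curve(aif, truths[label], phantom.dt)
    artery = atlas.labels == ARTERY_LABEL
    conc[artery] = aif

    signal = phantom.s0 * np.exp(-phantom.k * phantom.te * conc)
    signal[atlas.labels == 0] = 0.01 * phantom.s0
    if phantom.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(phantom.seed)
        signal = signal + rng.normal(0.0, phantom.noise_sd, signal.shape)
        # magnitude images are nonnegative
        signal = np.maximum(signal, 0.0)
    series = PerfusionSeries(data=signal, dt=phantom.dt, te=phantom.te)
    sidecar = SessionTruth(truths=dict(truths), aif_params=aif_params, phantom=phantom)
    return series, sidecar


@dataclass(frozen=True)
class SimulatedCohort:
    """A paired pre/intra cohort: manifest plus per-session ground truth."""

    spec: CohortSpec
    phantom: PhantomSpec
    aif_params: AifParams
    manifest: pd.DataFrame
    truths: dict[tuple[str, str], dict[int, TerritoryTruth]]
    atlas: TerritoryAtlas

    def session_truth(self, subject_id: str, session: str) -> SessionTruth:
        return SessionTruth(
            truths=self.truths[(subject_id, session)],
            aif_params=self.aif_params,
            phantom=self.phantom,
        )

    def render_session(self, subject_id: str, session: str) -> tuple[PerfusionSeries, SessionTruth]:
        """Render the 4D signal for one session with a session-unique,
        deterministic noise stream."""
        row = self.manifest[
            (self.manifest.subject_id == subject_id) & (self.manifest.session == session)
        ]
        if row.empty:
            raise KeyError(f"no session {session!r} for subject {subject_id!r}")
        idx = int(row.index[0])
        rng = np.random.default_rng([self.phantom.seed, self.spec.seed, idx])
        return simulate_phantom_session(
            self.phantom, self.atlas, self.truths[(subject_id, session)],
            self.aif_params, rng=rng,
        )

    def relative_truth_table(self) -> pd.DataFrame:
        """Exact per-subject relative values implied by the ground truth.

        One row per (subject, session, territory) with the surgical-over-
        contralateral ratio of CBF/CBV/MTT — the noiseless limit of the
        full imaging pipeline.
        """
        rows = []
        meta = self.manifest.drop_duplicates("subject_id").set_index("subject_id")
        for (subject, session), truths in self.truths.items():
            surgical = meta.loc[subject, "surgical_side"]
            group = meta.loc[subject, "group"]
            contra = SIDES[1 - SIDES.index(surgical)]
            by_key = {(t.side, self.atlas.dictionary[lab][0]): t for lab, t in truths.items()}
            for name in TERRITORIES:
                s, c = by_key[(surgical, name)], by_key[(contra, name)]
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "session": session,
                        "territory": name,
                        "relative_cbf": s.cbf / c.cbf,
                        "relative_cbv": s.cbv / c.cbv,
                        "relative_mtt": s.mtt / c.mtt,
                    }
                )
        return pd.DataFrame(rows)


def simulate_cohort(
    cohort: CohortSpec,
    phantom: PhantomSpec | None = None,
    base_truths: Mapping[str, tuple[float, float]] | None = None,
    aif_params: AifParams | None = None,
) -> SimulatedCohort:
    """Draw a paired pre/intra cohort of territory ground truths.

    For each subject the surgical-side pre-surgical CBF and MTT get a
    multiplicative baseline asymmetry; the intra-surgical surgical-side
    CBF is ``pre * (1 + group effect + N(0, between_subject_sd))`` and the
    surgical-side MTT gets an independent session jitter.  The
    contralateral hemisphere is identical in both sessions.
    """
    if phantom is None:
        phantom = PhantomSpec()
    if aif_params is None:
        aif_params = AifParams()
    atlas = build_phantom_atlas(phantom.grid_shape)
    base = dict(DEFAULT_TERRITORY_PARAMS if base_truths is None else base_truths)
    rng = np.random.default_rng(cohort.seed)

    n_total = cohort.n_chs + cohort.n_nonchs
    subjects = [f"sub-{i + 1:02d}" for i in range(n_total)]
    groups = ["CHS"] * cohort.n_chs + ["non-CHS"] * cohort.n_nonchs
    sides = rng.choice(SIDES, size=n_total)

    def _factor(x: float) -> float:
        return max(float(x), 0.05)  # keep truths strictly positive

    truths: dict[tuple[str, str], dict[int, TerritoryTruth]] = {}
    manifest_rows = []
    for subject, group, surgical in zip(subjects, groups, sides):
        effects = dict(cohort.effect_map.get(group, {}))
        pre: dict[int, TerritoryTruth] = {}
        intra: dict[int, TerritoryTruth] = {}
        for label, (name, side) in sorted(atlas.dictionary.items()):
            if side not in SIDES:
                continue
            cbf0, mtt0 = base[name]
            if side == surgical:
                a_cbf = rng.normal(0.0, cohort.baseline_asymmetry_sd)
                a_mtt = rng.normal(0.0, cohort.baseline_asymmetry_sd)
                delta = rng.normal(0.0, cohort.between_subject_sd)
                eta = rng.normal(0.0, cohort.mtt_jitter_sd)
                pre_cbf = cbf0 * _factor(1.0 + a_cbf)
                pre_mtt = mtt0 * _factor(1.0 + a_mtt)
                intra_cbf = pre_cbf * _factor(1.0 + effects.get(name, 0.0) + delta)
                intra_mtt = pre_mtt * _factor(1.0 + eta)
            else:
                pre_cbf = intra_cbf = cbf0
                pre_mtt = intra_mtt = mtt0
            pre[label] = TerritoryTruth(label=label, side=side, cbf=pre_cbf, mtt=pre_mtt)
            intra[label] = TerritoryTruth(label=label, side=side, cbf=intra_cbf, mtt=intra_mtt)
        truths[(subject, "pre")] = pre
        truths[(subject, "intra")] = intra
        for session in ("pre", "intra"):
            manifest_rows.append(
                {
                    "subject_id": subject,
                    "session": session,
                    "group": group,
                    "surgical_side": surgical,
                    "series_path": "",
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    return SimulatedCohort(
        spec=cohort, phantom=phantom, aif_params=aif_params,
        manifest=manifest, truths=truths, atlas=atlas,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Render and write every session to disk.

    Writes 4D NIfTI signal series, the 3D label atlas, a per-session
    ground-truth JSON sidecar and ``manifest.csv`` with file paths.
    Returns the manifest path.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(
        nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), affine),
        out / "atlas.nii.gz",
    )
    with open(out / "atlas_labels.json", "w") as fh:
        json.dump(
            {str(k): list(v) for k, v in cohort.atlas.dictionary.items()}, fh, indent=2
        )
    manifest = cohort.manifest.copy()
    for i, row in manifest.iterrows():
        series, sidecar = cohort.render_session(row.subject_id, row.session)
        stem = f"{row.subject_id}_{row.session}"
        path = out / f"{stem}_pwi.nii.gz"
        nib.save(nib.Nifti1Image(series.data.astype(np.float32), affine), path)
        with open(out / f"{stem}_truth.json", "w") as fh:
            json.dump(sidecar.to_dict(), fh, indent=2)
        manifest.loc[i, "series_path"] = path.name
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
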