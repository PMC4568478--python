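"""End-to-end orchestration: NIfTI I/O, per-session runs, cohort statistics.

``run_session`` takes one 4D perfusion series from raw signal to regional
relative-perfusion statistics (baseline -> concentration -> AIF selection
-> SVD deconvolution -> territory aggregation) and writes CBF/CBV/MTT
NIfTI maps, a regional CSV, and an AIF QC JSON.  ``run_cohort`` iterates a
manifest of paired pre/intra sessions and emits the three comparison
tables plus a machine-readable statistics JSON.  Registration is out of
scope: series and atlas must already share grid and affine.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import aif as aif_mod
from . import deconv, stats
from .concentration import PerfusionSeries, estimate_baseline, signal_to_concentration
from .territories import RegionalSummary, TerritoryAtlas, regional_means, relative_parameters

__all__ = ["RunConfig", "run_session", "run_cohort", "read_series", "read_atlas"]

logger = logging.getLogger("dscpipe")

AFFINE_TOL = 1e-4


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    atlas_path: str = "atlas.nii.gz"
    atlas_labels_path: str = "atlas_labels.json"
    manifest_path: str = "manifest.csv"
    out_dir: str = "out"
    # acquisition
    dt: float = 1.5
    te: float = 0.030
    n_baseline: int = 8
    k: float = 1.0
    # AIF selection
    aif_n: int = 10
    aif_ttp_quantile: float = 0.1
    aif_mtt_quantile: float = 0.2
    # deconvolution
    mode: str = "circulant"
    truncation: float | None = None
    pad_length: int | None = None
    # statistics
    fdr_q: float = 0.2
    equal_var: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _require(path: str | Path, what: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return path


def read_series(path: str | Path, dt: float, te: float) -> PerfusionSeries:
    """Load a 4D NIfTI perfusion series (.nii / .nii.gz)."""
    img = nib.load(_require(path, "perfusion series"))
    return PerfusionSeries(
        data=np.asarray(img.dataobj, dtype=float), dt=dt, te=te, affine=img.affine
    )


def read_atlas(path: str | Path, labels_path: str | Path) -> tuple[TerritoryAtlas, np.ndarray]:
    """Load a 3D integer label atlas and its label dictionary JSON."""
    img = nib.load(_require(path, "atlas"))
    labels = np.asarray(img.dataobj).astype(np.int32)
    with open(_require(labels_path, "atlas label dictionary")) as fh:
        raw = json.load(fh)
    dictionary = {int(k): tuple(v) for k, v in raw.items()}
    return TerritoryAtlas(labels=labels, dictionary=dictionary), img.affine


def _check_affines(series_affine: np.ndarray, atlas_affine: np.ndarray) -> None:
    if not np.allclose(series_affine, atlas_affine, atol=AFFINE_TOL):
        raise ValueError(
            "series and atlas affines differ beyond tolerance "
            f"{AFFINE_TOL}; images must be pre-registered to a shared grid"
        )


def _setup_run_logging(out_dir: Path) -> None:
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == out_dir / "run.log"
        for h in logger.handlers
    ):
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)


def run_session(
    config: RunConfig,
    series_path: str | Path,
    surgical_side: str,
    subject: str = "",
    session: str = "",
    out_dir: str | Path | None = None,
    atlas: TerritoryAtlas | None = None,
    atlas_affine: np.ndarray | None = None,
) -> tuple[deconv.PerfusionMaps, RegionalSummary]:
    """Run the full per-session pipeline and write its outputs.

    Writes ``<stem>_{cbf,cbv,mtt}.nii.gz``, ``<stem>_regional.csv`` and
    ``<stem>_aif_qc.json`` (selected AIF voxel coordinates for the manual
    audit) into ``out_dir``.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    _setup_run_logging(out)
    if atlas is None:
        atlas, atlas_affine = read_atlas(config.atlas_path, config.atlas_labels_path)

    stage = "load series"
    try:
        series = read_series(series_path, config.dt, config.te)
        if atlas_affine is not None:
            _check_affines(series.affine, atlas_affine)
        if atlas.labels.shape != series.grid_shape:
            raise ValueError(
                f"atlas grid {atlas.labels.shape} != series grid {series.grid_shape}"
            )
        stage = "baseline estimation"
        s0, mask = estimate_baseline(series, n_baseline=config.n_baseline)
        stage = "concentration conversion"
        conc = signal_to_concentration(series, s0, mask, k=config.k)
        stage = "AIF selection"
        aif = aif_mod.select_aif_voxels(
            conc,
            n_aif=config.aif_n,
            ttp_quantile=config.aif_ttp_quantile,
            mtt_quantile=config.aif_mtt_quantile,
        )
        stage = "deconvolution"
        maps = deconv.compute_maps(
            conc, aif, mode=config.mode,
            truncation=config.truncation, pad_length=config.pad_length,
        )
        stage = "territory aggregation"
        means = regional_means(maps, atlas)
        summary = relative_parameters(means, surgical_side, subject=subject, session=session)
    except Exception as exc:
        logger.error("stage %r failed for %s: %s", stage, series_path, exc)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stem = f"{subject}_{session}" if subject else Path(series_path).name.split(".")[0]
    affine = series.affine
    for name in ("cbf", "cbv", "mtt"):
        nib.save(
            nib.Nifti1Image(getattr(maps, name).astype(np.float32), affine),
            out / f"{stem}_{name}.nii.gz",
        )
    summary.means.to_csv(out / f"{stem}_regional.csv", index=False)
    qc = {
        "subject": subject,
        "session": session,
        "n_floored_signal_samples": conc.n_floored,
        "aif_voxels": aif.voxel_ids.tolist(),
        "aif_thresholds": aif.thresholds_used,
        "aif_saturated": aif.saturated,
        "deconvolution": maps.qc,
    }
    with open(out / f"{stem}_aif_qc.json", "w") as fh:
        json.dump(qc, fh, indent=2)
    logger.info(
        "session %s/%s: %d AIF voxels, %d flagged voxels",
        subject, session, len(aif.voxel_ids), maps.qc["n_flagged"],
    )
    return maps, summary


def run_cohort(config: RunConfig) -> stats.CohortResult:
    """Run every manifest session and build the cohort comparison tables.

    The manifest CSV needs columns ``subject_id, session, group,
    surgical_side, series_path`` (paths relative to the manifest).  Every
    subject must have both a ``pre`` and an ``intra`` session.
    """
    out = Path(config.out_dir)
    _setup_run_logging(out)
    logger.info("run-cohort config hash %s seed %d", config.config_hash(), config.seed)
    manifest_path = _require(config.manifest_path, "manifest")
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "session", "group", "surgical_side", "series_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    incomplete = [
        subject
        for subject, grp in manifest.groupby("subject_id")
        if {"pre", "intra"} - set(grp.session)
    ]
    if incomplete:
        raise ValueError(f"subjects missing a pre or intra session: {incomplete}")

    atlas, atlas_affine = read_atlas(config.atlas_path, config.atlas_labels_path)
    base = manifest_path.parent
    rows = []
    for _, row in manifest.iterrows():
        series_path = Path(row.series_path)
        if not series_path.is_absolute():
            series_path = base / series_path
        _, summary = run_session(
            config, series_path, row.surgical_side,
            subject=row.subject_id, session=row.session,
            out_dir=out, atlas=atlas, atlas_affine=atlas_affine,
        )
        rel = summary.relative.reset_index()
        rel.insert(0, "subject", row.subject_id)
        rel.insert(1, "group", row.group)
        rel.insert(2, "session", row.session)
        rows.append(rel)
    summaries = pd.concat(rows, ignore_index=True)
    summaries.to_csv(out / "relative_summaries.csv", index=False)

    result = stats.build_comparison_tables(
        summaries, q=config.fdr_q, equal_var=config.equal_var
    )
    result.to_csv(out)
    with open(out / "cohort_stats.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    logger.info("cohort tables written to %s", out)
    return result
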