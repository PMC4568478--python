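"""Vascular-territory aggregation and hemispheric asymmetry statistics.

Perfusion maps are summarized over an integer-labelled arterial-territory
atlas (ACA/MCA central and terminal regions plus the PCA terminal region,
split into left and right hemispheres).  The semiquantitative statistics
are the *relative* parameters — surgical-side regional mean divided by the
contralateral homologue — which cancel scanner scale, contrast dose and
deconvolution calibration, and the per-subject percentage increase between
a pre-surgical and an intra-surgical session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TERRITORIES",
    "SIDES",
    "TerritoryAtlas",
    "RegionalSummary",
    "regional_means",
    "relative_parameters",
    "percent_increase",
]

#: Territories analyzed in the group comparison, in canonical report order.
TERRITORIES = (
    "ACA-terminal",
    "ACA-central",
    "MCA-terminal",
    "MCA-central",
    "PCA-terminal",
)
SIDES = ("left", "right")
PARAMETERS = ("cbf", "cbv", "mtt")


@dataclass(frozen=True)
class TerritoryAtlas:
    """A 3D integer label volume plus a label dictionary.

    ``dictionary`` maps each nonzero label to a ``(territory, side)`` pair.
    Labels whose side is not ``left``/``right`` (e.g. an artery seed region
    used by the synthetic phantom) are carried through regional means but
    excluded from relative (side-ratio) statistics.
    """

    labels: np.ndarray
    dictionary: Mapping[int, tuple[str, str]]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        present = set(np.unique(labels)) - {0}
        unknown = present - set(self.dictionary)
        if unknown:
            raise ValueError(f"labels present in volume but not in dictionary: {sorted(unknown)}")
        # every left/right territory must exist on both sides
        sided: dict[str, set[str]] = {}
        for _, (name, side) in self.dictionary.items():
            if side in SIDES:
                sided.setdefault(name, set()).add(side)
        incomplete = [name for name, sides in sided.items() if sides != set(SIDES)]
        if incomplete:
            raise ValueError(f"territories missing one hemisphere: {sorted(incomplete)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "dictionary", dict(self.dictionary))

    def label_for(self, territory: str, side: str) -> int:
        for label, (name, s) in self.dictionary.items():
            if name == territory and s == side:
                return label
        raise KeyError(f"no label for territory={territory!r}, side={side!r}")

    @property
    def territory_names(self) -> tuple[str, ...]:
        names = []
        for _, (name, side) in sorted(self.dictionary.items()):
            if side in SIDES and name not in names:
                names.append(name)
        return tuple(names)


@dataclass(frozen=True)
class RegionalSummary:
    """Per-session regional means and surgical/contralateral ratios.

    Attributes
    ----------
    means:
        DataFrame with one row per (territory, side): voxel counts and mean
        CBF/CBV/MTT.
    relative:
        DataFrame indexed by territory with ``relative_cbf``,
        ``relative_cbv``, ``relative_mtt`` columns (surgical over
        contralateral).
    """

    subject: str
    session: str
    surgical_side: str
    means: pd.DataFrame
    relative: pd.DataFrame


def regional_means(maps, atlas: TerritoryAtlas) -> pd.DataFrame:
    """Arithmetic mean of CBF/CBV/MTT over each labelled region.

    Voxels flagged as degenerate by the deconvolution (non-positive
    residue peak) and voxels outside the brain mask are excluded so they
    do not dilute the regional mean.

    Returns a DataFrame with columns
    ``territory, side, label, n_voxels, cbf, cbv, mtt``.
    """
    if atlas.labels.shape != maps.cbf.shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match maps grid {maps.cbf.shape}"
        )
    valid = maps.mask & ~maps.flagged
    rows = []
    for label, (name, side) in sorted(atlas.dictionary.items()):
        sel = (atlas.labels == label) & valid
        n = int(np.count_nonzero(sel))
        if n == 0:
            raise ValueError(f"region {name!r} ({side}, label {label}) has no usable voxels")
        rows.append(
            {
                "territory": name,
                "side": side,
                "label": label,
                "n_voxels": n,
                "cbf": float(maps.cbf[sel].mean()),
                "cbv": float(maps.cbv[sel].mean()),
                "mtt": float(maps.mtt[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def relative_parameters(
    means: pd.DataFrame,
    surgical_side: str,
    subject: str = "",
    session: str = "",
) -> RegionalSummary:
    """Surgical-side / contralateral ratio of each regional mean parameter.

    Raises
    ------
    ValueError
        If the surgical side is invalid, a territory lacks one hemisphere,
        or a contralateral mean is non-positive (ratio undefined).
    """
    if surgical_side not in SIDES:
        raise ValueError(f"surgical_side must be one of {SIDES}, got {surgical_side!r}")
    contralateral = SIDES[1 - SIDES.index(surgical_side)]
    indexed = means.set_index(["territory", "side"])
    territories = [
        t for t in indexed.index.get_level_values("territory").unique()
        if {(t, "left"), (t, "right")} <= set(indexed.index)
    ]
    if not territories:
        raise ValueError("no bilateral territories found in regional means")
    rows = {}
    bad = []
    for territory in territories:
        surg = indexed.loc[(territory, surgical_side)]
        contra = indexed.loc[(territory, contralateral)]
        if any(contra[p] <= 0 for p in PARAMETERS):
            bad.append(territory)
            continue
        rows[territory] = {
            f"relative_{p}": float(surg[p]) / float(contra[p]) for p in PARAMETERS
        }
    if bad:
        raise ValueError(f"non-positive contralateral mean in territories: {bad}")
    relative = pd.DataFrame.from_dict(rows, orient="index")
    relative.index.name = "territory"
    return RegionalSummary(
        subject=subject,
        session=session,
        surgical_side=surgical_side,
        means=means,
        relative=relative,
    )


def percent_increase(pre_value, intra_value):
    """Signed percentage change ``100 * (intra - pre) / pre``.

    Accepts scalars or arrays; every pre value must be strictly positive.
    """
    pre = np.asarray(pre_value, dtype=float)
    intra = np.asarray(intra_value, dtype=float)
    if np.any(pre <= 0):
        raise ValueError("pre value must be strictly positive")
    out = 100.0 * (intra - pre) / pre
    if out.ndim == 0:
        return float(out)
    return out
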