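"""Regional reduction of parametric maps and hemispheric analyses.

Three analyses operate on the long-format region table:

* per-(region, hemisphere) means of a parametric map over the atlas labels,
  with per-modality region filters (the cerebellum is dropped from
  MRI-derived maps because of shim/EPI distortion near the skull base;
  ventricles enter the diffusion analysis only; the single-slice ASL
  acquisition covers only four regions);
* the relative left-right difference of the whole-hemisphere value, with
  "whole hemisphere" defined as the unweighted mean of the regional means,
  referenced to the left (irradiated) hemisphere: d = (L - R) / L;
* region-by-region Pearson correlation between the left and right
  hemispheres, pooling all subjects and time points within a dose group
  (cell (i, j) correlates left region i with right region j).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import REGIONS, AtlasLabels, ParametricMap

__all__ = [
    "DEFAULT_REGION_SETS",
    "REGION_TABLE_COLUMNS",
    "extract_regions",
    "hemispheric_relative_difference",
    "hemisphere_correlation",
    "whole_brain_series",
]

#: Regions entering each modality's analysis by default (overridable).
DEFAULT_REGION_SETS = {
    "SUV": ("thalamus", "cortex", "hypothalamus", "hippocampus", "cerebellum",
            "amygdala", "striatum"),
    "ADC": ("ventricles", "thalamus", "cortex", "hypothalamus", "hippocampus",
            "amygdala"),
    "K1": ("cortex", "hippocampus", "hypothalamus", "thalamus"),
}

REGION_TABLE_COLUMNS = [
    "subject",
    "dose_Gy",
    "timepoint",
    "time_days",
    "modality",
    "region",
    "hemisphere",
    "mean_value",
    "voxel_count",
]


def extract_regions(
    pmap: ParametricMap,
    atlas: AtlasLabels,
    exclude: set[str] | None = None,
    modality: str | None = None,
    **row_keys,
) -> pd.DataFrame:
    """Mean map value per (region, hemisphere) over in-mask atlas voxels.

    ``exclude`` names regions to drop; when None it defaults to the
    complement of ``DEFAULT_REGION_SETS[modality]`` (or nothing for an
    unknown modality).  Extra keyword arguments (subject, timepoint, ...)
    are copied into every row, so callers can assemble a full RegionTable.
    Regions with zero in-mask voxels are dropped with a warning row count.
    """
    if pmap.shape != tuple(atlas.labels.shape) or not np.allclose(
        pmap.voxel_size, atlas.voxel_size
    ):
        raise ValueError("map and atlas are not on one grid")
    modality = modality or pmap.quantity
    if exclude is None:
        keep = DEFAULT_REGION_SETS.get(modality, REGIONS)
        exclude = set(REGIONS) - set(keep)
    rows = []
    for lab, (region, hemi) in sorted(atlas.legend.items()):
        if region in exclude:
            continue
        sel = (atlas.labels == lab) & pmap.mask
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(
            dict(
                modality=modality,
                region=region,
                hemisphere=hemi,
                mean_value=float(pmap.values[sel].mean()),
                voxel_count=n,
                **row_keys,
            )
        )
    return pd.DataFrame(rows)


def _check_table(table: pd.DataFrame) -> None:
    if "mean_value" not in table or "hemisphere" not in table:
        raise ValueError("not a region table")
    if (table.get("voxel_count", pd.Series([1])) < 1).any():
        raise ValueError("voxel_count must be >= 1 for every reported mean")


def hemispheric_relative_difference(table: pd.DataFrame) -> pd.DataFrame:
    """Relative left-right whole-hemisphere difference per scan.

    For each (subject, timepoint, modality): L and R are the unweighted
    means of the regional means in that hemisphere and d = (L - R)/L, also
    reported as |d| in percent.  Raises if any left mean is zero.
    """
    _check_table(table)
    keys = [k for k in ("subject", "timepoint", "modality") if k in table.columns]
    out = []
    for key_vals, grp in table.groupby(keys, sort=False):
        hemi_means = grp.groupby("hemisphere")["mean_value"].mean()
        if "left" not in hemi_means or "right" not in hemi_means:
            raise ValueError("both hemispheres required for the difference")
        lbar, rbar = float(hemi_means["left"]), float(hemi_means["right"])
        if lbar == 0:
            raise ZeroDivisionError("left-hemisphere mean is zero")
        d = (lbar - rbar) / lbar
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec.update(left_mean=lbar, right_mean=rbar, rel_diff=d, abs_rel_diff_pct=abs(d) * 100)
        out.append(rec)
    return pd.DataFrame(out)


def hemisphere_correlation(
    table: pd.DataFrame,
    modality: str | None = None,
    dose: float | None = None,
    regions: tuple[str, ...] | None = None,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-vs-right Pearson correlation matrix among brain regions.

    Observations are pooled over subjects and time points (within one dose
    group when ``dose`` is given).  Cell (i, j) is the Pearson r between
    left-region-i and right-region-j means over the pooled scans; cells
    with fewer than ``min_pairs`` complete observations are NaN.

    Returns ``(r_matrix, n_matrix)`` as region-indexed DataFrames
    (rows = left regions, columns = right regions).
    """
    _check_table(table)
    sub = table
    if modality is not None:
        sub = sub[sub["modality"] == modality]
    if dose is not None:
        sub = sub[sub["dose_Gy"] == dose]
    if regions is None:
        present = [r for r in REGIONS if r in set(sub["region"])]
        regions = tuple(present)
    obs_keys = [k for k in ("subject", "timepoint") if k in sub.columns]
    wide = {}
    for hemi in ("left", "right"):
        h = sub[sub["hemisphere"] == hemi]
        wide[hemi] = h.pivot_table(
            index=obs_keys, columns="region", values="mean_value", aggfunc="mean"
        )
    idx = wide["left"].index.union(wide["right"].index)
    left = wide["left"].reindex(idx)
    right = wide["right"].reindex(idx)
    r = pd.DataFrame(np.nan, index=list(regions), columns=list(regions))
    n = pd.DataFrame(0, index=list(regions), columns=list(regions))
    for ri in regions:
        for rj in regions:
            if ri not in left.columns or rj not in right.columns:
                continue
            x = left[ri].to_numpy(dtype=float)
            y = right[rj].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n.loc[ri, rj] = int(ok.sum())
            if ok.sum() < min_pairs:
                continue
            xv, yv = x[ok], y[ok]
            if np.std(xv) == 0 or np.std(yv) == 0:
                continue
            r.loc[ri, rj] = float(np.corrcoef(xv, yv)[0, 1])
    return r, n


def whole_brain_series(
    table: pd.DataFrame, modality: str, regions: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Whole-brain value per scan: mean over the included regional means of
    both hemispheres (the input to the longitudinal trend model)."""
    _check_table(table)
    sub = table[table["modality"] == modality]
    if regions is not None:
        sub = sub[sub["region"].isin(regions)]
    keys = [k for k in ("subject", "dose_Gy", "timepoint", "time_days") if k in sub.columns]
    out = sub.groupby(keys, sort=False)["mean_value"].mean().reset_index()
    return out.rename(columns={"mean_value": "whole_brain"})
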