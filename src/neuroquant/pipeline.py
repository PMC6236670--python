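"""End-to-end orchestration: simulate a cohort tree, quantify it, analyse it.

The pipeline mirrors the study design: two dose groups (5 and 20 Gy, six
subjects each) scanned at five sessions (pre-irradiation and 3, 7, 30 and
60 days after).  ``simulate_cohort_tree`` writes a BIDS-like directory of
NIfTI volumes + JSON sidecars with known ground truth; ``run_pipeline``
reads such a tree (simulated or real, as long as it follows the layout),
fits every parametric map, reduces them to a region table and produces the
hemispheric statistics, correlation heat maps and longitudinal mixed-model
trend fits.  ``run_demo`` chains the two.

Tree layout::

    <root>/atlas.nii.gz (+ atlas.json legend)
    <root>/scans.csv                  subject, session, time_days, dose_Gy
    <root>/sub-<id>/ses-<tp>/dwi_dir{1,2,3}.nii.gz (+ .json)
    <root>/sub-<id>/ses-<tp>/fair_{selective,nonselective}.nii.gz (+ .json)
    <root>/sub-<id>/ses-<tp>/pet.nii.gz (+ .json)
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_core, maps, phantom, roi, trend
from .config import PipelineConfig
from .io_core import AtlasLabels
from .maps import AslModelConstants
from .phantom import CohortDesign, GroundTruth

logger = logging.getLogger("neuroquant")

__all__ = ["simulate_cohort_tree", "run_pipeline", "run_demo", "DEMO_TREND_DESIGNS"]

#: Relative-change trajectories used by the demo generator, one per
#: modality: glucose uptake rises towards two months, diffusion dips around
#: one month and stays low, perfusion shows no time trend.  Coefficients
#: are on the scaled-time axis (t = days/60) and act multiplicatively on
#: the regional ground truth, (1 + y).
DEMO_TREND_DESIGNS = {
    "SUV": dict(beta0=0.0, beta_t=-0.10, beta_t2=0.35),
    "ADC": dict(beta0=0.0, beta_t=-0.35, beta_t2=0.25),
    "K1": dict(beta0=0.0, beta_t=0.0, beta_t2=0.0),
}
_DEMO_RE = dict(sd_intercept=0.03, sd_slope=0.03, sd_residual=0.02)


def _scan_design(config: PipelineConfig, modality: str, seed: int) -> CohortDesign:
    return CohortDesign(
        subjects_per_dose=config.subjects_per_dose,
        rng_seed=seed,
        **DEMO_TREND_DESIGNS[modality],
        **_DEMO_RE,
    )


def simulate_cohort_tree(
    config: PipelineConfig, root: str | Path, truth: GroundTruth | None = None
) -> Path:
    """Write a full synthetic longitudinal cohort to ``root``.

    Every scan's regional means are the baseline ground truth scaled by
    (1 + y_it), where y_it follows the random-intercept/slope quadratic
    process of :class:`CohortDesign` with the per-modality demo
    coefficients.  The drawn y values are stored in ``ground_truth.json``
    for recovery checks.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = GroundTruth(
            sigma_mri=config.sigma_mri,
            sigma_pet=config.sigma_pet,
            asl_constants=AslModelConstants(**config.asl_constants.model_dump()),
        )
    atlas = phantom.make_label_phantom(config.phantom_shape, rng_seed=config.rng_seed)
    io_core.write_atlas(atlas, root / "atlas.nii.gz")

    ss = np.random.SeedSequence(config.rng_seed)
    mod_seeds = {m: int(s.generate_state(1)[0] % 2**31) for m, s in
                 zip(("SUV", "ADC", "K1"), ss.spawn(3))}
    # subject-level latent trajectories per modality (table-level process)
    latent = {}
    for m in ("SUV", "ADC", "K1"):
        tab, _ = phantom.simulate_cohort(_scan_design(config, m, mod_seeds[m]), modality=m)
        y = tab.groupby(["subject", "dose_Gy", "timepoint", "time_days"], sort=False)[
            "mean_value"
        ].first().reset_index()
        latent[m] = y

    scan_rows = []
    gt_records = []
    scan_seed = np.random.SeedSequence([config.rng_seed, 917])
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in scan_seed.spawn(4096))
    for _, row in latent["SUV"].iterrows():
        sid, tp, days, dose = row["subject"], row["timepoint"], row["time_days"], row["dose_Gy"]
        sdir = root / f"sub-{sid}" / f"ses-{tp}"
        sdir.mkdir(parents=True, exist_ok=True)
        y_of = {
            m: float(
                latent[m].loc[
                    (latent[m]["subject"] == sid) & (latent[m]["timepoint"] == tp),
                    "mean_value",
                ].iloc[0]
            )
            for m in ("SUV", "ADC", "K1")
        }
        scan_truth = dataclasses.replace(
            truth,
            suv={k: v * (1 + y_of["SUV"]) for k, v in truth.suv.items()},
            adc={k: v * (1 + y_of["ADC"]) for k, v in truth.adc.items()},
            delta_t1={k: v * (1 + y_of["K1"]) for k, v in truth.delta_t1.items()},
        )
        dwi = phantom.simulate_dwi(atlas, scan_truth, rng_seed=next(seeds))
        for series in dwi:
            io_core.write_series(series, sdir / f"dwi_dir{series.direction_id}.nii.gz")
        sel, nsel = phantom.simulate_fair(
            atlas, scan_truth, rng_seed=next(seeds), magnitude=config.fair_magnitude
        )
        io_core.write_series(sel, sdir / "fair_selective.nii.gz")
        io_core.write_series(nsel, sdir / "fair_nonselective.nii.gz")
        pet = phantom.simulate_pet(atlas, scan_truth, rng_seed=next(seeds))
        io_core.write_pet_frame(pet, sdir / "pet.nii.gz")
        scan_rows.append(dict(subject=sid, session=tp, time_days=days, dose_Gy=dose))
        gt_records.append(dict(subject=sid, session=tp, **{f"y_{m}": y_of[m] for m in y_of}))
    pd.DataFrame(scan_rows).to_csv(root / "scans.csv", index=False)
    with open(root / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "baseline": {
                    "adc": truth.adc,
                    "t1_nonselective": truth.t1_nonselective,
                    "delta_t1": truth.delta_t1,
                    "suv": truth.suv,
                    "s0": truth.s0,
                    "sigma_mri": truth.sigma_mri,
                    "sigma_pet": truth.sigma_pet,
                },
                "scans": gt_records,
            },
            fh,
            indent=1,
        )
    return root


def _quantify_scan(sdir: Path, atlas: AtlasLabels, config: PipelineConfig,
                   constants: AslModelConstants) -> dict[str, "maps.ParametricMap"]:
    brain = atlas.brain_mask
    out = {}
    adc_maps = []
    for d in (1, 2, 3):
        series = io_core.read_series(sdir / f"dwi_dir{d}.nii.gz")
        adc_maps.append(maps.fit_adc_direction(series, mask=brain, method=config.adc_method))
    out["ADC"] = maps.mean_adc(adc_maps)
    sel = io_core.read_series(sdir / "fair_selective.nii.gz")
    nsel = io_core.read_series(sdir / "fair_nonselective.nii.gz")
    fit_s = maps.fit_inversion_recovery(sel, mask=brain, magnitude=config.fair_magnitude)
    fit_ns = maps.fit_inversion_recovery(nsel, mask=brain, magnitude=config.fair_magnitude)
    out["K1"] = maps.compute_k1(fit_s.r1_map(), fit_ns.r1_map(), constants)
    out["T1"] = fit_ns.t1_map()
    pet = io_core.read_pet_frame(sdir / "pet.nii.gz")
    out["SUV"] = maps.compute_suv(pet, mask=brain)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Quantify and analyse a cohort tree; returns the result bundle.

    Reads ``config.input_dir`` (simulating one first if it is None), writes
    CSV tables, correlation matrices, heat-map and trend figures, fitted
    maps for the first scan, and a provenance record to
    ``config.output_dir``.
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.input_dir is None:
        config = config.model_copy(update={"input_dir": str(outdir / "simulated")})
        simulate_cohort_tree(config, config.input_dir)
    indir = Path(config.input_dir)
    atlas = io_core.read_atlas(indir / "atlas.nii.gz")
    scans = pd.read_csv(indir / "scans.csv")
    constants = AslModelConstants(**config.asl_constants.model_dump())

    rows = []
    example_written = False
    for _, scan in scans.iterrows():
        sdir = indir / f"sub-{scan.subject}" / f"ses-{scan.session}"
        fitted = _quantify_scan(sdir, atlas, config, constants)
        logger.info("quantified %s (%d in-mask voxels)", sdir, int(atlas.brain_mask.sum()))
        for modality in config.modalities:
            pmap = fitted[modality]
            exclude = set(config.exclude_regions.get(modality, [])) or None
            rows.append(
                roi.extract_regions(
                    pmap,
                    atlas,
                    exclude=exclude,
                    modality=modality,
                    subject=scan.subject,
                    dose_Gy=float(scan.dose_Gy),
                    timepoint=scan.session,
                    time_days=float(scan.time_days),
                )
            )
        if not example_written:
            for modality, pmap in fitted.items():
                io_core.write_map(pmap, outdir / f"example_{modality}.nii.gz")
            example_written = True
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(outdir / "region_table.csv", index=False)

    hemi = pd.concat(
        [
            roi.hemispheric_relative_difference(table[table.modality == m])
            for m in config.modalities
        ],
        ignore_index=True,
    )
    hemi.to_csv(outdir / "hemispheric_difference.csv", index=False)

    correlations = {}
    doses = sorted(table["dose_Gy"].unique())
    for m in config.modalities:
        for dose in doses:
            r, n = roi.hemisphere_correlation(table, modality=m, dose=dose)
            tag = f"{m}_{dose:g}Gy"
            r.to_csv(outdir / f"correlation_{tag}.csv")
            correlations[tag] = r
            _heatmap(r, outdir / f"correlation_{tag}.png",
                     f"{m}: left vs right regions, {dose:g} Gy")

    trends = {}
    for m in config.modalities:
        wb = roi.whole_brain_series(table, m)
        fit = trend.fit_trend(wb)
        trends[m] = fit
        with open(outdir / f"trend_{m}.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=1)
        tt = np.linspace(0, 60, 61)
        curves = [trend.predict_trend(fit, tt, dose) for dose in fit.dose_levels]
        pd.concat(curves, keys=[f"{d:g}Gy" for d in fit.dose_levels]).to_csv(
            outdir / f"trend_curve_{m}.csv"
        )
        _trend_plot(wb, fit, outdir / f"trend_{m}.png", m)

    provenance = {
        "config": config.model_dump(),
        "n_scans": int(len(scans)),
        "elapsed_s": round(time.time() - t_start, 2),
        "versions": _versions(),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    return dict(table=table, hemispheric=hemi, correlations=correlations, trends=trends,
                outdir=outdir)


def run_demo(config: PipelineConfig | None = None, seed: int = 0,
             output_dir: str | None = None) -> dict:
    """One-command demonstration: simulate the full two-dose cohort, fit all
    maps, and run every analysis stage."""
    if config is None:
        config = PipelineConfig(rng_seed=seed)
    if output_dir is not None:
        config = config.model_copy(update={"output_dir": output_dir})
    return run_pipeline(config)


def _heatmap(r: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(r.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(len(r.index)), r.index, fontsize=7)
    ax.set_xlabel("right hemisphere")
    ax.set_ylabel("left hemisphere")
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _trend_plot(wb: pd.DataFrame, fit: "trend.TrendFit", path: Path, modality: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    tt = np.linspace(0, wb["time_days"].max(), 121)
    for dose, color in zip(fit.dose_levels, ("tab:blue", "tab:red")):
        sub = wb[wb["dose_Gy"] == dose]
        ax.plot(sub["time_days"], sub["whole_brain"], "o", ms=3, alpha=0.5, color=color)
        curve = trend.predict_trend(fit, tt, dose)
        ax.plot(tt, curve["fitted"], color=color, label=f"{dose:g} Gy")
        ax.fill_between(tt, curve["lo"], curve["hi"], color=color, alpha=0.15)
    ax.set_xlabel("days after irradiation")
    ax.set_ylabel(f"whole-brain {modality}")
    ax.set_title(
        f"{modality}: quadratic mixed-model trend "
        f"(p_quad={fit.p_quadratic:.3g}, p_dose={fit.p_dose:.3g})",
        fontsize=9,
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _versions() -> dict:
    import nibabel
    import scipy
    import statsmodels

    from . import __version__

    return {
        "neuroquant": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "statsmodels": statsmodels.__version__,
    }
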