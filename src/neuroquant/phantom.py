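"""Synthetic digital phantoms with known ground truth.

This module generates everything the quantification chain consumes:

* a mirror-symmetric labeled brain phantom (eight regions per hemisphere,
  ellipsoids on a regular layout) standing in for an atlas-registered mouse
  brain;
* diffusion-weighted series S(b) = S0·exp(−b·ADC) with Rician magnitude
  noise;
* FAIR inversion-recovery pairs S(TI) = c + S0·(1 − 2·exp(−TI·R1)), one
  slice-selective and one non-selective series, where perfusion shortens the
  selective T1 (R1,s ≥ R1,ns);
* a static FDG-PET activity-concentration frame, A_conc = SUV·(A_inj/BW),
  with additive Gaussian noise;
* a longitudinal two-dose cohort whose region means follow the exact
  data-generating process of the random-intercept/random-slope quadratic
  mixed model, so mixed-model recovery can be tested against known
  coefficients.

Ground-truth K1 is always *derived* from (T1_selective, T1_nonselective)
through the one-compartment formula — the generator can never contradict
the model it is meant to exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import (
    HEMISPHERES,
    REGIONS,
    AcquisitionSeries,
    AtlasLabels,
    ImageVolume,
    PetFrame,
)
from .maps import AslModelConstants, k1_from_r1

__all__ = [
    "GroundTruth",
    "CohortDesign",
    "PAPER_BVALUES",
    "PAPER_TI_SCHEDULE",
    "make_label_phantom",
    "simulate_dwi",
    "simulate_fair",
    "simulate_pet",
    "simulate_cohort",
    "rician",
    "rice_mean",
]

#: Diffusion weightings of the acquisition protocol, s/mm².
PAPER_BVALUES = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0)

#: FAIR inversion times: 22 TIs from 26 ms in 200 ms increments, seconds.
PAPER_TI_SCHEDULE = tuple(0.026 + 0.2 * k for k in range(22))


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Corrupt a noiseless magnitude signal with Rician noise of scale sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, size=np.shape(signal))
    im = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.hypot(re, im)


def rice_mean(nu: float, sigma: float) -> float:
    """Analytic mean of a Rice(nu, sigma) variate.

    E|X| = sigma·sqrt(pi/2)·L_{1/2}(−nu²/2sigma²) with the Laguerre function
    expressed through modified Bessel functions.
    """
    from scipy.special import i0e, i1e

    if sigma == 0:
        return float(nu)
    x = nu**2 / (2.0 * sigma**2)
    # L_{1/2}(-x) = e^{-x/2}[(1+x) I0(x/2) + x I1(x/2)]; use scaled Bessels.
    lag = (1.0 + x) * i0e(x / 2.0) + x * i1e(x / 2.0)
    return float(sigma * np.sqrt(np.pi / 2.0) * lag)


# default per-region ground truth, field-realistic values for adult mouse
# brain at 7 T: ADC in mm²/s, T1 in s, SUV in g/mL.  The selective FAIR T1
# is shorter than the non-selective one by the perfusion-driven relaxation
# enhancement (the generator's perfusion dial).
_DEFAULT_ADC = {
    "thalamus": 0.71e-3,
    "cortex": 0.73e-3,
    "hypothalamus": 0.72e-3,
    "hippocampus": 0.75e-3,
    "cerebellum": 0.70e-3,
    "amygdala": 0.74e-3,
    "striatum": 0.72e-3,
    "ventricles": 2.2e-3,
}
_DEFAULT_T1_NS = {
    "thalamus": 1.75,
    "cortex": 1.85,
    "hypothalamus": 1.80,
    "hippocampus": 1.90,
    "cerebellum": 1.78,
    "amygdala": 1.82,
    "striatum": 1.76,
    "ventricles": 3.50,
}
# perfusion-driven shortening of the selective T1, seconds
_DEFAULT_DELTA_T1 = {r: 0.05 for r in REGIONS} | {"ventricles": 0.01}
_DEFAULT_SUV = {
    "thalamus": 1.7,
    "cortex": 1.6,
    "hypothalamus": 1.4,
    "hippocampus": 1.5,
    "cerebellum": 1.8,
    "amygdala": 1.3,
    "striatum": 1.7,
    "ventricles": 0.4,
}


@dataclass
class GroundTruth:
    """True per-region quantities and noise levels for the simulators.

    Keys of the per-quantity dicts are region names; a ``(region,
    hemisphere)`` tuple key overrides the region-wide value for one
    hemisphere (used to break mirror symmetry deliberately).

    ``sigma_mri`` is the Rician noise scale on magnitude MRI signals
    (default 25 for ``s0``=1000, i.e. SNR 40 at b=0); ``sigma_pet`` is the
    additive Gaussian noise on PET activity concentration in kBq/mL.
    """

    adc: dict = field(default_factory=lambda: dict(_DEFAULT_ADC))
    t1_nonselective: dict = field(default_factory=lambda: dict(_DEFAULT_T1_NS))
    delta_t1: dict = field(default_factory=lambda: dict(_DEFAULT_DELTA_T1))
    suv: dict = field(default_factory=lambda: dict(_DEFAULT_SUV))
    s0: float = 1000.0
    sigma_mri: float = 25.0
    sigma_pet: float = 20.0
    asl_constants: AslModelConstants = field(default_factory=AslModelConstants)

    def __post_init__(self) -> None:
        if self.sigma_mri < 0 or self.sigma_pet < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        for region in REGIONS:
            for hemi in HEMISPHERES:
                if self.t1_selective(region, hemi) > self.t1_ns(region, hemi):
                    raise ValueError("T1_selective must be <= T1_nonselective")
                for q in (self.get(self.adc, region, hemi),
                          self.t1_ns(region, hemi),
                          self.get(self.suv, region, hemi)):
                    if q < 0:
                        raise ValueError("ground-truth quantities must be non-negative")

    @staticmethod
    def get(d: dict, region: str, hemisphere: str) -> float:
        if (region, hemisphere) in d:
            return float(d[(region, hemisphere)])
        return float(d[region])

    def t1_ns(self, region: str, hemisphere: str = "left") -> float:
        return self.get(self.t1_nonselective, region, hemisphere)

    def t1_selective(self, region: str, hemisphere: str = "left") -> float:
        return self.t1_ns(region, hemisphere) - self.get(self.delta_t1, region, hemisphere)

    def k1(self, region: str, hemisphere: str = "left") -> float:
        """True K1, defined through the one-compartment formula from the
        selective/non-selective relaxation rates (never set independently)."""
        r1s = 1.0 / self.t1_selective(region, hemisphere)
        r1ns = 1.0 / self.t1_ns(region, hemisphere)
        return k1_from_r1(r1s, r1ns, self.asl_constants)

    def scaled(self, factor: float) -> "GroundTruth":
        """Ground truth with every regional mean multiplied by ``factor``
        (used to impose a longitudinal relative change on rendered scans)."""

        def _mul(d: dict) -> dict:
            return {k: v * factor for k, v in d.items()}

        return replace(self, adc=_mul(self.adc), suv=_mul(self.suv))


@dataclass
class CohortDesign:
    """Longitudinal two-dose study design and its data-generating process.

    The response of subject i in dose group d at (scaled) time t is

        y_it = b0 + b_dose·1[d=20] + b_t·t + b_t2·t² + u0_i + u1_i·t + e_it

    with subject random effects (u0, u1) ~ N(0, G) and residual e ~ N(0, s²).
    Time is entered in days scaled by 1/60, so t ∈ [0, 1] over the follow-up.
    The coefficient defaults describe a dip-and-recover trajectory with no
    mean dose difference.
    """

    doses: tuple[float, float] = (5.0, 20.0)
    subjects_per_dose: int = 6
    timepoints_days: tuple[float, ...] = (0.0, 3.0, 7.0, 30.0, 60.0)
    beta0: float = 1.0
    beta_dose: float = 0.0
    beta_t: float = -0.5
    beta_t2: float = 0.6
    sd_intercept: float = 0.05
    sd_slope: float = 0.05
    re_correlation: float = 0.0
    sd_residual: float = 0.05
    regional_sd: float = 0.0
    time_scale_days: float = 60.0
    rng_seed: int = 0

    TIMEPOINT_NAMES = {0.0: "pre", 3.0: "p3d", 7.0: "p7d", 30.0: "p30d", 60.0: "p60d"}

    def __post_init__(self) -> None:
        if self.sd_residual <= 0:
            raise ValueError("residual sd must be > 0")
        if not (-1.0 <= self.re_correlation <= 1.0):
            raise ValueError("random-effect correlation must lie in [-1, 1]")
        if self.sd_intercept < 0 or self.sd_slope < 0:
            raise ValueError("random-effect sds must be non-negative")
        if min(np.linalg.eigvalsh(self.re_cov)) < -1e-12:
            raise ValueError("random-effect covariance must be positive semi-definite")

    @property
    def re_cov(self) -> np.ndarray:
        c = self.re_correlation * self.sd_intercept * self.sd_slope
        return np.array(
            [[self.sd_intercept**2, c], [c, self.sd_slope**2]]
        )

    def timepoint_name(self, days: float) -> str:
        return self.TIMEPOINT_NAMES.get(float(days), f"d{days:g}")


# ---------------------------------------------------------------------------
# label phantom
# ---------------------------------------------------------------------------


def make_label_phantom(
    shape: tuple[int, int, int] = (32, 32, 16),
    rng_seed: int = 0,
    voxel_size: tuple[float, float, float] = (0.234, 0.234, 1.0),
) -> AtlasLabels:
    """Build a mirror-symmetric ellipsoidal label phantom.

    Eight regions per hemisphere are placed on a 2x4 layout inside the left
    half of the grid and mirrored across the mid-sagittal plane (first
    axis), so left/right voxel counts are identical by construction.  The
    construction is deterministic; the seed is accepted for interface
    symmetry with the signal simulators.

    Each axis must be at least 16 voxels so every region holds >= 50 voxels.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError("phantom shape must be 3 axes of at least 16 voxels each")
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # semi-axes scaled to the grid; chosen so the smallest allowed grid
    # (16^3) still yields >= 50 voxels per ellipsoid with no overlap
    ax, ay, az = 0.105 * nx, 0.115 * ny, 0.31 * nz
    legend: dict[int, tuple[str, str]] = {}
    for k, region in enumerate(REGIONS):
        cx = 0.25 * nx + (0.11 * nx if k % 2 else -0.11 * nx)
        cy = (0.125 + 0.25 * (k // 2)) * ny
        cz = 0.5 * nz
        inside = (
            ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2
        ) <= 1.0
        left_label = k + 1
        right_label = k + 1 + len(REGIONS)
        left = inside & (xs < nx // 2)
        labels[left] = left_label
        labels[left[::-1, :, :]] = right_label  # mirror across mid-sagittal plane
        legend[left_label] = (region, "left")
        legend[right_label] = (region, "right")
        n_left = int(left.sum())
        if n_left < 50:
            raise ValueError(
                f"region {region!r} has only {n_left} voxels; enlarge the grid"
            )
    return AtlasLabels(labels=labels, legend=legend, voxel_size=voxel_size)


def _region_value_volume(
    atlas: AtlasLabels, value_of, dtype=float
) -> np.ndarray:
    """Paint a per-(region, hemisphere) scalar into the label geometry."""
    out = np.zeros(atlas.labels.shape, dtype=dtype)
    for lab, (region, hemi) in atlas.legend.items():
        out[atlas.labels == lab] = value_of(region, hemi)
    return out


def _vol(voxels: np.ndarray, atlas: AtlasLabels, frame: str) -> ImageVolume:
    return ImageVolume(voxels=voxels, voxel_size=atlas.voxel_size, frame_of_reference=frame)


# ---------------------------------------------------------------------------
# signal simulators
# ---------------------------------------------------------------------------


def simulate_dwi(
    atlas: AtlasLabels,
    truth: GroundTruth,
    bvalues: tuple[float, ...] = PAPER_BVALUES,
    n_directions: int = 3,
    rng_seed: int = 0,
) -> list[AcquisitionSeries]:
    """Simulate one diffusion-weighted series per direction.

    The noiseless voxel signal is exactly monoexponential,
    S(b) = S0·exp(−b·ADC_region), identical across directions (isotropic
    phantom), then corrupted by Rician magnitude noise.
    """
    bvalues = tuple(float(b) for b in bvalues)
    if 0.0 not in bvalues:
        raise ValueError("b-value table must include b=0")
    if any(b < 0 for b in bvalues):
        raise ValueError("b-values must be non-negative")
    rng = np.random.default_rng(rng_seed)
    adc_vol = _region_value_volume(atlas, lambda r, h: truth.get(truth.adc, r, h))
    s0_vol = np.where(atlas.brain_mask, truth.s0, 0.0)
    series = []
    for d in range(1, n_directions + 1):
        frames = []
        for b in bvalues:
            clean = s0_vol * np.exp(-b * adc_vol)
            noisy = rician(clean, truth.sigma_mri, rng)
            frames.append(_vol(noisy, atlas, f"dwi-dir{d}"))
        series.append(
            AcquisitionSeries(
                frames=frames,
                axis_kind="bvalue",
                axis_values=np.asarray(bvalues),
                direction_id=d,
            )
        )
    return series


def fair_signal(ti: np.ndarray, c: float, s0: float, r1: np.ndarray | float) -> np.ndarray:
    """Inversion-recovery signal S(TI) = c + S0·(1 − 2·exp(−TI·R1))."""
    return c + s0 * (1.0 - 2.0 * np.exp(-np.multiply.outer(r1, ti)))


def simulate_fair(
    atlas: AtlasLabels,
    truth: GroundTruth,
    ti_schedule: tuple[float, ...] = PAPER_TI_SCHEDULE,
    rng_seed: int = 0,
    c: float = 0.0,
    magnitude: bool = False,
) -> tuple[AcquisitionSeries, AcquisitionSeries]:
    """Simulate the (selective, nonselective) FAIR inversion-recovery pair.

    Signals follow S(TI) = c + S0·(1 − 2·e^(−TI·R1)) with the regional
    selective or non-selective R1.  By default the signed recovery curve is
    simulated with additive Gaussian noise (real-channel acquisition); with
    ``magnitude=True`` the noiseless signal's magnitude receives Rician
    noise instead.
    """
    ti = np.asarray(ti_schedule, dtype=float)
    if ti.size < 5:
        raise ValueError("TI schedule needs at least 5 points")
    if np.any(np.diff(ti) <= 0):
        raise ValueError("TI schedule must be strictly increasing")
    rng = np.random.default_rng(rng_seed)
    out = []
    for state in ("selective", "nonselective"):
        if state == "selective":
            t1_vol = _region_value_volume(atlas, truth.t1_selective)
        else:
            t1_vol = _region_value_volume(atlas, truth.t1_ns)
        r1_vol = np.where(atlas.brain_mask, 1.0 / np.where(t1_vol > 0, t1_vol, 1.0), 0.0)
        frames = []
        for t in ti:
            clean = np.where(
                atlas.brain_mask,
                c + truth.s0 * (1.0 - 2.0 * np.exp(-t * r1_vol)),
                0.0,
            )
            if magnitude:
                noisy = rician(np.abs(clean), truth.sigma_mri, rng)
            else:
                noisy = clean + rng.normal(0.0, truth.sigma_mri, size=clean.shape) \
                    if truth.sigma_mri > 0 else clean
            frames.append(_vol(noisy, atlas, f"fair-{state}"))
        out.append(
            AcquisitionSeries(
                frames=frames, axis_kind="inversion_time", axis_values=ti, label_state=state
            )
        )
    return out[0], out[1]


def simulate_pet(
    atlas: AtlasLabels,
    truth: GroundTruth,
    injected_activity: float = 5.05,
    body_weight: float = 20.0,
    rng_seed: int = 0,
) -> PetFrame:
    """Simulate a static FDG frame: A_conc = SUV_true·(A_inj/BW) + noise.

    ``injected_activity`` in MBq (converted to kBq in the concentration so
    the frame's units are kBq/mL), ``body_weight`` in g.  The noiseless
    regional mean concentration implies exactly the true SUV.
    """
    if injected_activity <= 0 or body_weight <= 0:
        raise ValueError("injected activity and body weight must be positive")
    rng = np.random.default_rng(rng_seed)
    suv_vol = _region_value_volume(atlas, lambda r, h: truth.get(truth.suv, r, h))
    conc = suv_vol * (injected_activity * 1e3 / body_weight)  # kBq/mL
    if truth.sigma_pet > 0:
        conc = conc + rng.normal(0.0, truth.sigma_pet, size=conc.shape)
    return PetFrame(
        activity_concentration=_vol(conc, atlas, "pet"),
        injected_activity=injected_activity,
        body_weight=body_weight,
        injection_to_scan_interval=None,
    )


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    design: CohortDesign,
    modality: str = "SUV",
    regions: tuple[str, ...] = REGIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one longitudinal cohort from the mixed-model generating process.

    Returns ``(table, effects)``: a long-format region table with one row
    per (subject, timepoint, region, hemisphere) whose ``mean_value`` is the
    subject-level response y_it (identical in both hemispheres, i.e. a
    common bilateral subject-by-time effect) plus an optional independent
    regional perturbation of sd ``design.regional_sd``; and the drawn
    per-subject random effects for recovery tests.

    The subject-level response is
    y_it = b0 + b_dose·1[d=20] + b_t·t + b_t2·t² + u0_i + u1_i·t + e_it
    with t = days / ``design.time_scale_days``.
    """
    rng = np.random.default_rng(design.rng_seed)
    chol = np.linalg.cholesky(design.re_cov + 1e-15 * np.eye(2))
    rows, eff_rows = [], []
    subj = 0
    for dose in design.doses:
        for _ in range(design.subjects_per_dose):
            subj += 1
            sid = f"s{subj:02d}"
            u = chol @ rng.standard_normal(2)
            eff_rows.append(dict(subject=sid, dose_Gy=dose, u0=u[0], u1=u[1]))
            for days in design.timepoints_days:
                t = days / design.time_scale_days
                eps = rng.normal(0.0, design.sd_residual)
                y = (
                    design.beta0
                    + design.beta_dose * (dose == max(design.doses))
                    + design.beta_t * t
                    + design.beta_t2 * t * t
                    + u[0]
                    + u[1] * t
                    + eps
                )
                for region in regions:
                    for hemi in HEMISPHERES:
                        val = y
                        if design.regional_sd > 0:
                            val = y + rng.normal(0.0, design.regional_sd)
                        rows.append(
                            dict(
                                subject=sid,
                                dose_Gy=dose,
                                timepoint=design.timepoint_name(days),
                                time_days=days,
                                modality=modality,
                                region=region,
                                hemisphere=hemi,
                                mean_value=val,
                                voxel_count=1,
                            )
                        )
    return pd.DataFrame(rows), pd.DataFrame(eff_rows)
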