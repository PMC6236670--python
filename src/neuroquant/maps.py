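"""Voxel-wise parametric mapping: ADC, inversion-recovery T1/R1, K1, SUV.

The three quantitative models implemented here are

* monoexponential diffusion decay, ``S(b) = S0·exp(−b·ADC)``, fitted per
  voxel and direction, then averaged over the three orthogonal directions;
* the FAIR inversion-recovery curve ``S(TI) = c + S0·(1 − 2·exp(−TI·R1))``,
  fitted per voxel by three-parameter least squares for the selective and
  non-selective series;
* the one-tissue-compartment perfusion uptake rate derived from the two
  fitted relaxation rates,

      K1 = V_d · R1,a · (R1,s − R1,ns) / R1,ns,

  with the water distribution volume V_d = 0.95 mL H2O/mL and arterial
  T1,a = 2 s (so R1,a = 0.5 1/s) as fixed model constants — under free
  transcapillary water exchange K1 equals cerebral blood flow;
* the standardized uptake value ``SUV = A_conc / (A_inj / BW)``, with the
  injected activity decay-corrected to scan start using the F-18 half-life
  when the injection-to-scan interval is known.

The inversion-recovery fit uses variable projection: for a trial T1 the
offset c and amplitude S0 are linear and solved in closed form, leaving a
one-dimensional problem in T1 that is bracketed on a coarse logarithmic
grid and polished by a vectorized golden-section search.  The estimator is
exactly the three-parameter least-squares minimizer, computed without any
per-voxel Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import AcquisitionSeries, ImageVolume, ParametricMap, PetFrame

__all__ = [
    "AslModelConstants",
    "IrFitResult",
    "F18_HALF_LIFE_MIN",
    "T1_BOUNDS",
    "k1_from_r1",
    "default_mask",
    "fit_adc_direction",
    "mean_adc",
    "fit_inversion_recovery",
    "compute_k1",
    "compute_suv",
]

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77

#: Admissible T1 range for the inversion-recovery fit, seconds.
T1_BOUNDS = (0.05, 10.0)


@dataclass(frozen=True)
class AslModelConstants:
    """Fixed constants of the one-compartment ASL model.

    v_d : water volume of distribution in tissue, mL H2O per mL tissue.
    t1_arterial : longitudinal relaxation time of arterial water, seconds
        (the model uses its reciprocal R1,a).
    """

    v_d: float = 0.95
    t1_arterial: float = 2.0

    def __post_init__(self) -> None:
        if self.v_d <= 0 or self.t1_arterial <= 0:
            raise ValueError("ASL model constants must be strictly positive")

    @property
    def r1_arterial(self) -> float:
        return 1.0 / self.t1_arterial


def k1_from_r1(r1_selective, r1_nonselective, constants: AslModelConstants | None = None):
    """One-compartment uptake rate from the two relaxation rates.

    K1 = V_d · R1,a · (R1,s − R1,ns) / R1,ns.  This single function owns the
    algebraic grouping of the formula; swap it to explore the alternative
    reading K1 = V_d·(R1,s − R1,ns).
    """
    constants = constants or AslModelConstants()
    r1_selective = np.asarray(r1_selective, dtype=float)
    r1_nonselective = np.asarray(r1_nonselective, dtype=float)
    return (
        constants.v_d
        * constants.r1_arterial
        * (r1_selective - r1_nonselective)
        / r1_nonselective
    )


def default_mask(series: AcquisitionSeries, fraction: float = 0.05) -> np.ndarray:
    """Foreground mask: reference signal above ``fraction`` of its in-volume
    99th percentile.

    The reference is the b=0 frame for a diffusion series and the maximum
    absolute signal over TIs for an inversion-recovery series.
    """
    if series.axis_kind == "bvalue":
        ref = series.frames[int(np.argmin(series.axis_values))].voxels
    else:
        ref = np.max(np.abs(series.data), axis=-1)
    thresh = fraction * np.percentile(ref, 99)
    return ref > thresh


# ---------------------------------------------------------------------------
# ADC
# ---------------------------------------------------------------------------


def fit_adc_direction(
    series: AcquisitionSeries,
    mask: np.ndarray | None = None,
    method: str = "loglinear",
    clamp_max: float = 4e-3,
) -> ParametricMap:
    """Fit the monoexponential diffusion model per voxel for one direction.

    Parameters
    ----------
    series
        A b-value series with at least 3 distinct b-values including b=0.
    mask
        Boolean foreground mask; defaults to :func:`default_mask`.
    method
        ``"loglinear"`` (default): weighted linear regression of ln S on b
        with weights proportional to S², the deterministic closed form that
        is exact at zero noise.  ``"nls"``: per-voxel nonlinear least
        squares on the exponential model, seeded by the log-linear solution.

    Negative fitted ADCs are clamped to 0 and flagged; values above
    ``clamp_max`` (free water at body temperature is ≈3e−3 mm²/s) are
    clamped likewise.  Voxels with any non-positive signal cannot be fitted
    and are excluded from the output mask.
    """
    if series.axis_kind != "bvalue":
        raise ValueError("fit_adc_direction requires a b-value series")
    b = series.axis_values
    if len(np.unique(b)) < 3:
        raise ValueError("need at least 3 distinct b-values")
    if mask is None:
        mask = default_mask(series)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    data = series.data  # (nx, ny, nz, nb)
    sig = data[mask]  # (N, nb)
    fit_ok = np.all(sig > 0, axis=1)
    s = np.clip(sig, 1e-30, None)
    y = np.log(s)
    w = s**2
    # weighted straight-line fit of y on b, slope = -ADC
    sw = w.sum(axis=1)
    bw = (w * b).sum(axis=1) / sw
    yw = (w * y).sum(axis=1) / sw
    cov = (w * (b - bw[:, None]) * (y - yw[:, None])).sum(axis=1)
    var = (w * (b - bw[:, None]) ** 2).sum(axis=1)
    slope = cov / var
    adc = -slope
    s0_fit = np.exp(yw + slope * (-bw))
    if method == "nls":
        adc, s0_fit = _adc_nls(b, sig, adc, s0_fit)
    elif method != "loglinear":
        raise ValueError(f"unknown ADC method {method!r}")
    model = s0_fit[:, None] * np.exp(-np.outer(adc, b))
    resid = np.sqrt(((sig - model) ** 2).sum(axis=1))
    clamped_flat = (adc < 0) | (adc > clamp_max)
    adc = np.clip(adc, 0.0, clamp_max)

    values = np.zeros(mask.shape)
    out_mask = np.zeros(mask.shape, dtype=bool)
    clamped = np.zeros(mask.shape, dtype=bool)
    diag = np.full(mask.shape, np.nan)
    idx = np.where(mask)
    values[idx] = np.where(fit_ok, adc, 0.0)
    out_mask[idx] = fit_ok
    clamped[idx] = clamped_flat & fit_ok
    diag[idx] = resid
    return ParametricMap(
        values=values,
        quantity="ADC",
        mask=out_mask,
        voxel_size=series.voxel_size,
        fit_diagnostics=diag,
        clamped=clamped,
    )


def _adc_nls(b: np.ndarray, sig: np.ndarray, adc0: np.ndarray, s00: np.ndarray):
    """Gauss-Newton refinement of (S0, ADC) per voxel, vectorized."""
    s0, adc = s00.copy(), adc0.copy()
    for _ in range(50):
        e = np.exp(-np.outer(adc, b))
        model = s0[:, None] * e
        r = sig - model
        j_s0 = e
        j_adc = -model * b
        a11 = (j_s0**2).sum(1)
        a12 = (j_s0 * j_adc).sum(1)
        a22 = (j_adc**2).sum(1)
        g1 = (j_s0 * r).sum(1)
        g2 = (j_adc * r).sum(1)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ds0 = (a22 * g1 - a12 * g2) / det
        dadc = (a11 * g2 - a12 * g1) / det
        s0 = s0 + ds0
        adc = adc + dadc
        if max(np.abs(dadc).max(initial=0), np.abs(ds0).max(initial=0)) < 1e-14:
            break
    return adc, s0


def mean_adc(maps: list[ParametricMap]) -> ParametricMap:
    """Direction-averaged ADC: voxel-wise mean of the per-direction maps.

    The output mask is the intersection of the input masks.
    """
    if len(maps) == 0:
        raise ValueError("no maps given")
    ref = maps[0]
    for m in maps[1:]:
        if m.shape != ref.shape or not np.allclose(m.voxel_size, ref.voxel_size):
            raise ValueError("ADC maps are not on one grid")
        if m.quantity != "ADC":
            raise ValueError("mean_adc expects ADC maps")
    mask = np.logical_and.reduce([m.mask for m in maps])
    values = np.where(mask, np.mean([m.values for m in maps], axis=0), 0.0)
    clamped = np.logical_or.reduce(
        [m.clamped if m.clamped is not None else np.zeros_like(mask) for m in maps]
    )
    return ParametricMap(
        values=values,
        quantity="ADC",
        mask=mask,
        voxel_size=ref.voxel_size,
        clamped=clamped & mask,
    )


# ---------------------------------------------------------------------------
# inversion recovery
# ---------------------------------------------------------------------------


@dataclass
class IrFitResult:
    """Per-voxel three-parameter inversion-recovery fit.

    Arrays share the grid shape: offset ``c``, amplitude ``s0``, relaxation
    time ``t1`` (seconds), per-voxel ``residual_norm``, the fitted-voxel
    ``mask``, and ``at_bounds`` flagging voxels whose T1 landed on a bound
    of the admissible range (degenerate recovery curves).
    """

    c: np.ndarray
    s0: np.ndarray
    t1: np.ndarray
    residual_norm: np.ndarray
    mask: np.ndarray
    at_bounds: np.ndarray
    voxel_size: tuple[float, float, float]
    converged_fraction: float

    def t1_map(self) -> ParametricMap:
        return ParametricMap(
            values=np.where(self.mask, self.t1, 0.0),
            quantity="T1",
            mask=self.mask & ~self.at_bounds,
            voxel_size=self.voxel_size,
            fit_diagnostics=self.residual_norm,
        )

    def r1_map(self) -> ParametricMap:
        r1 = np.where(self.mask & (self.t1 > 0), 1.0 / np.where(self.t1 > 0, self.t1, 1.0), 0.0)
        return ParametricMap(
            values=r1,
            quantity="R1",
            mask=self.mask & ~self.at_bounds,
            voxel_size=self.voxel_size,
            fit_diagnostics=self.residual_norm,
        )


def _varpro_sse(sig: np.ndarray, phi: np.ndarray):
    """Closed-form (c, S0) and SSE for basis [1, phi] per voxel.

    ``sig`` and ``phi`` are (N, nTI); returns (c, s0, sse) of shape (N,).
    """
    n = sig.shape[1]
    a12 = phi.sum(axis=1)
    a22 = (phi * phi).sum(axis=1)
    b1 = sig.sum(axis=1)
    b2 = (sig * phi).sum(axis=1)
    det = n * a22 - a12**2
    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
    c = (a22 * b1 - a12 * b2) / det
    s0 = (n * b2 - a12 * b1) / det
    # explicit residual sum (not the ||S||^2 - ... shortcut) to avoid
    # catastrophic cancellation near a perfect fit
    resid = sig - c[:, None] - s0[:, None] * phi
    return c, s0, (resid * resid).sum(axis=1)


def _ir_sse_at(ti: np.ndarray, sig: np.ndarray, t1: np.ndarray):
    phi = 1.0 - 2.0 * np.exp(-ti[None, :] / t1[:, None])
    return _varpro_sse(sig, phi)


def fit_inversion_recovery(
    series: AcquisitionSeries,
    mask: np.ndarray | None = None,
    t1_bounds: tuple[float, float] = T1_BOUNDS,
    n_grid: int = 60,
    magnitude: bool = False,
) -> IrFitResult:
    """Fit S(TI) = c + S0·(1 − 2·exp(−TI/T1)) per voxel.

    Variable projection reduces the fit to one dimension in T1: a coarse
    logarithmic grid brackets the optimum per voxel and a vectorized
    golden-section search polishes it; c and S0 then follow in closed form.
    With ``magnitude=True`` the data are assumed to be magnitudes of the
    signed recovery curve and polarity is restored by testing every
    early-TI sign-flip point and keeping the best fit.

    Non-convergence cannot occur (the search is exhaustive in its bracket);
    voxels whose T1 lands on a bound are flagged ``at_bounds`` and removed
    from the T1/R1 map masks.
    """
    if series.axis_kind != "inversion_time":
        raise ValueError("fit_inversion_recovery requires an inversion-time series")
    ti = series.axis_values
    if ti.size < 5:
        raise ValueError("need at least 5 inversion times")
    if mask is None:
        mask = default_mask(series)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    sig = series.data[mask]  # (N, nTI)
    if magnitude:
        sig = _restore_polarity(ti, np.abs(sig), t1_bounds, n_grid)

    lo, hi = t1_bounds
    grid = np.geomspace(lo, hi, n_grid)
    sse_grid = np.empty((n_grid, sig.shape[0]))
    for g, t1g in enumerate(grid):
        _, _, sse_grid[g] = _ir_sse_at(ti, sig, np.full(sig.shape[0], t1g))
    best = np.argmin(sse_grid, axis=0)
    log_grid = np.log(grid)
    a = log_grid[np.maximum(best - 1, 0)]
    b = log_grid[np.minimum(best + 1, n_grid - 1)]
    # vectorized golden-section search on log T1 (both probes re-evaluated
    # each iteration: a little redundant work, per-voxel-loop free)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    _, _, f1 = _ir_sse_at(ti, sig, np.exp(x1))
    _, _, f2 = _ir_sse_at(ti, sig, np.exp(x2))
    for _ in range(70):
        take1 = f1 < f2
        b = np.where(take1, x2, b)
        a = np.where(take1, a, x1)
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        _, _, f1 = _ir_sse_at(ti, sig, np.exp(x1))
        _, _, f2 = _ir_sse_at(ti, sig, np.exp(x2))
    t1 = np.exp((a + b) / 2.0)
    t1 = np.clip(t1, lo, hi)
    c, s0, sse = _ir_sse_at(ti, sig, t1)
    # a vanishing amplitude leaves T1 unidentified (constant signal, fully
    # recovered): pin it to the lower bound and flag it
    degenerate = np.abs(s0) <= 1e-8 * np.maximum(np.abs(sig).max(axis=1), 1e-30)
    t1 = np.where(degenerate, lo, t1)
    at_bounds_flat = degenerate | (t1 <= lo * 1.02) | (t1 >= hi * 0.98)

    shape = mask.shape
    out = {k: np.zeros(shape) for k in ("c", "s0", "t1")}
    resid = np.full(shape, np.nan)
    bounds_map = np.zeros(shape, dtype=bool)
    idx = np.where(mask)
    out["c"][idx], out["s0"][idx], out["t1"][idx] = c, s0, t1
    resid[idx] = np.sqrt(sse)
    bounds_map[idx] = at_bounds_flat
    return IrFitResult(
        c=out["c"],
        s0=out["s0"],
        t1=out["t1"],
        residual_norm=resid,
        mask=mask,
        at_bounds=bounds_map,
        voxel_size=series.voxel_size,
        converged_fraction=float(1.0 - at_bounds_flat.mean()),
    )


def _restore_polarity(ti, absig, t1_bounds, n_grid):
    """Choose the early-TI sign-flip point minimizing the fit SSE per voxel."""
    n = absig.shape[1]
    best_sse = np.full(absig.shape[0], np.inf)
    best_sig = absig.copy()
    grid = np.geomspace(t1_bounds[0], t1_bounds[1], n_grid)
    for k in range(n + 1):
        trial = absig.copy()
        trial[:, :k] *= -1.0
        sse_k = np.full(absig.shape[0], np.inf)
        for t1g in grid:
            _, _, sse = _ir_sse_at(ti, trial, np.full(absig.shape[0], t1g))
            sse_k = np.minimum(sse_k, sse)
        better = sse_k < best_sse
        best_sse = np.where(better, sse_k, best_sse)
        best_sig[better] = trial[better]
    return best_sig


# ---------------------------------------------------------------------------
# K1 and SUV
# ---------------------------------------------------------------------------


def compute_k1(
    r1_selective: ParametricMap,
    r1_nonselective: ParametricMap,
    constants: AslModelConstants | None = None,
) -> ParametricMap:
    """Perfusion uptake-rate map from the selective/non-selective R1 maps.

    Negative K1 (selective relaxing slower than non-selective, physically a
    zero-perfusion voxel plus noise) is clamped to 0 and flagged.
    """
    constants = constants or AslModelConstants()
    if r1_selective.shape != r1_nonselective.shape or not np.allclose(
        r1_selective.voxel_size, r1_nonselective.voxel_size
    ):
        raise ValueError("R1 maps are not on one grid")
    if r1_selective.quantity != "R1" or r1_nonselective.quantity != "R1":
        raise ValueError("compute_k1 expects two R1 maps")
    mask = r1_selective.mask & r1_nonselective.mask
    r1ns = r1_nonselective.values
    if np.any(r1ns[mask] <= 0):
        raise ValueError("non-positive non-selective R1 inside the mask")
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = np.where(
            mask, k1_from_r1(r1_selective.values, np.where(mask, r1ns, 1.0), constants), 0.0
        )
    clamped = mask & (k1 < 0)
    k1 = np.where(clamped, 0.0, k1)
    return ParametricMap(
        values=k1,
        quantity="K1",
        mask=mask,
        voxel_size=r1_selective.voxel_size,
        clamped=clamped,
    )


def compute_suv(pet: PetFrame, mask: np.ndarray | None = None) -> ParametricMap:
    """Standardized uptake value map, SUV = A_conc / (A_inj / BW).

    Concentration is kBq/mL, injected activity MBq (converted to kBq) and
    body weight g, giving SUV in g/mL.  When the frame records an
    injection-to-scan interval, the injected activity is decay-corrected to
    scan start with the F-18 half-life (109.77 min), which raises the SUV by
    2^(interval/T_half).  Negative concentrations (noise) clamp to SUV 0.
    """
    a_inj_kbq = pet.injected_activity * 1e3
    if pet.injection_to_scan_interval is not None:
        a_inj_kbq *= 2.0 ** (-pet.injection_to_scan_interval / F18_HALF_LIFE_MIN)
    denom = a_inj_kbq / pet.body_weight
    if denom <= 0:
        raise ValueError("non-positive SUV denominator")
    vol = pet.activity_concentration
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    suv = vol.voxels / denom
    clamped = mask & (suv < 0)
    suv = np.where(suv < 0, 0.0, suv)
    return ParametricMap(
        values=np.where(mask, suv, 0.0),
        quantity="SUV",
        mask=np.asarray(mask, dtype=bool),
        voxel_size=vol.voxel_size,
        clamped=clamped,
    )
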