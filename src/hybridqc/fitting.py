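"""Inverse problems: optical properties from DTOF+IRF, hemoglobin and StO2
from two-wavelength absorption, and blood-flow index / beta from g2.

TRS fitting follows the deconvolution-by-convolution approach: the
semi-infinite diffusion model is convolved with the measured IRF and
compared with the histogram by nonlinear least squares with a free amplitude
(solved analytically at each step) and Poisson weighting.  DCS fitting is
sequential: beta from the early-delay plateau of g2, then the blood-flow
index from the normalized field autocorrelation
``g1 = sqrt((g2 - 1) / beta)`` restricted to points above a cutoff
(default g1 >= 0.3).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from hybridqc.errors import (
    ConfigurationError,
    DomainError,
    DynamicRangeError,
    EstimationError,
    InsufficientDecayError,
)
from hybridqc.instrument import DTOFHistogram, G2Curve, IRF, convolve_with_irf
from hybridqc.optics import (
    DCS_GEOMETRY,
    ModelCurve,
    OpticalProperties,
    ProbeGeometry,
    TRS_GEOMETRY,
    dcs_g1,
    FlowSpec,
    trs_reflectance,
)

LN10 = float(np.log(10.0))

#: Fitted BFI below this value is flagged unreliable (cm^2/s): the
#: measurement may no longer be ergodic at such low flow.
BFI_UNRELIABLE = 3e-10

#: Default g1 cutoff for the DCS fit: points with g1 below this level are
#: excluded from the fit.
DCS_CUTOFF = 0.3

#: Delay knee below which g2 - 1 is treated as the beta plateau (s).
BETA_PLATEAU_KNEE = 3e-7

#: Coherence parameter below this floor means the g2 contrast is not
#: resolvable above the correlator noise; the decay cannot be analyzed.
BETA_FLOOR = 0.05

#: RMS residual of the g1 fit above which the homogeneous model is flagged
#: as disagreeing with the data.
POOR_FIT_RNORM = 0.015

#: TRS fit range: from the rising edge at this fraction of the peak ...
FIT_RANGE_RISE = 0.80
#: ... down the falling edge to this fraction of the peak.
FIT_RANGE_TAIL = 0.01

#: Optimizer bounds for the TRS inverse problem (1/cm).
TRS_BOUNDS = ((0.001, 1.0), (1.0, 30.0))


@dataclass
class TRSFit:
    """Result of a DTOF fit: optical properties, free amplitude, diagnostics."""

    mua: float
    musp: float
    scale: float
    fit_range: tuple[float, float]
    residual: float
    converged: bool
    wavelength: float
    background: float = 0.0
    n_points: int = 0


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients per wavelength.

    ``entries`` maps wavelength (nm) to ``(eps_hbo2, eps_hhb)`` in
    cm^-1/(mol/L), base-10 convention: ``mua = ln(10) * (eps @ C)``.
    """

    entries: Mapping[float, tuple[float, float]]
    source: str = "packaged"

    def __post_init__(self) -> None:
        for lam, (e1, e2) in self.entries.items():
            if e1 <= 0 or e2 <= 0:
                raise ConfigurationError(f"extinction coefficients must be positive at {lam} nm")
        for lam in (687.0, 830.0):
            if lam not in self.entries:
                raise ConfigurationError(f"extinction table missing device wavelength {lam} nm")

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Packaged literature compilation (see data/extinction_coefficients.csv)."""
        text = resources.files("hybridqc.data").joinpath("extinction_coefficients.csv").read_text()
        df = pd.read_csv(_io.StringIO(text), comment="#")
        entries = {
            float(r.wavelength_nm): (float(r.eps_hbo2), float(r.eps_hhb))
            for r in df.itertuples()
        }
        return cls(entries=entries, source="packaged compilation")

    def eps(self, wavelength: float) -> tuple[float, float]:
        try:
            return self.entries[float(wavelength)]
        except KeyError:
            raise ConfigurationError(f"no extinction entry for {wavelength} nm") from None

    def mua_from_concentrations(
        self, wavelength: float, c_hbo2_uM: float, c_hhb_uM: float
    ) -> float:
        """Absorption (1/cm) from oxy/deoxy concentrations in micromolar."""
        e1, e2 = self.eps(wavelength)
        return LN10 * (e1 * c_hbo2_uM + e2 * c_hhb_uM) * 1e-6


@dataclass
class Hemodynamics:
    """Hemoglobin concentrations (micromolar) and oxygen saturation (%)."""

    c_hbo2: float
    c_hhb: float
    thc: float
    sto2: float
    physical: bool = True


@dataclass
class DCSFit:
    """Result of a g2 fit: blood-flow index, beta, diagnostics.

    ``reliability_flag`` is ``"ok"`` or a semicolon-joined list of
    ``"unreliable"`` (BFI below the ergodicity bound) and
    ``"poor model agreement"`` (homogeneous model misfits the curve).
    """

    bfi: float
    beta: float
    residual: float
    cutoff_value: float
    converged: bool
    reliability_flag: str = "ok"
    n_points: int = 0


def _background_window(dtof: DTOFHistogram, irf: IRF) -> np.ndarray:
    """Boolean mask of pre-pulse bins: earlier than IRF peak - 5 IRF FWHM."""
    return dtof.t_grid < (irf.peak_time - 5.0 * irf.fwhm)


def fit_dtof(
    dtof: DTOFHistogram,
    irf: IRF,
    init: OpticalProperties | None = None,
    geom: ProbeGeometry = TRS_GEOMETRY,
    rise_frac: float = FIT_RANGE_RISE,
    tail_frac: float = FIT_RANGE_TAIL,
) -> TRSFit:
    """Recover (mua, musp) from a DTOF histogram and its IRF.

    Nonlinear least squares of ``scale * (model convolved with IRF)`` against
    the background-subtracted counts, Poisson-weighted, over the range from
    the rising edge at 80% of the peak down to the falling edge at 1% of the
    peak (bounds configurable).

    Raises
    ------
    DynamicRangeError
        If the histogram peak is less than one decade above the mean
        pre-pulse background ("insufficient dynamic range"): the absorption
        slope of the tail is not resolved and a diffusion-model fit would
        not be meaningful.
    """
    if dtof.t_grid.shape != irf.t_grid.shape or not np.allclose(
        dtof.t_grid, irf.t_grid, rtol=1e-9, atol=0
    ):
        raise DomainError("DTOF and IRF must share the same time grid")
    counts = dtof.counts
    bg_mask = _background_window(dtof, irf)
    if bg_mask.sum() >= 5:
        background = float(counts[bg_mask].mean())
    else:
        background = float(dtof.background_level)
    peak = float(counts.max())
    decades = np.log10(max(peak, 1.0) / max(background, 1.0))
    if decades < 1.0:
        raise DynamicRangeError(
            f"insufficient dynamic range: {decades:.2f} decades "
            f"(peak {peak:.0f} over background {background:.1f})"
        )

    y = counts - background
    ipk = int(np.argmax(y))
    ypk = y[ipk]
    # rising edge: last bin before the peak still below rise_frac * peak
    above = np.nonzero(y[: ipk + 1] < rise_frac * ypk)[0]
    i_start = int(above[-1]) + 1 if above.size else 0
    # falling edge: first bin after the peak below tail_frac * peak
    below = np.nonzero(y[ipk:] < tail_frac * ypk)[0]
    i_end = ipk + int(below[0]) if below.size else y.size
    sel = slice(i_start, i_end)
    n_points = i_end - i_start
    fit_range = (float(dtof.t_grid[i_start]), float(dtof.t_grid[min(i_end, y.size - 1)]))
    if n_points < 10:
        return TRSFit(
            mua=np.nan, musp=np.nan, scale=np.nan, fit_range=fit_range,
            residual=np.inf, converged=False, wavelength=dtof.wavelength,
            background=background, n_points=n_points,
        )

    sigma = np.sqrt(np.maximum(counts[sel], 1.0))
    y_sel = y[sel]
    t_grid = dtof.t_grid

    def model_counts(mua: float, musp: float) -> np.ndarray:
        curve = trs_reflectance(t_grid, OpticalProperties(mua, musp, dtof.wavelength), geom)
        return convolve_with_irf(curve, irf)[sel]

    def residuals(x: np.ndarray) -> np.ndarray:
        m = model_counts(x[0], x[1])
        w2 = 1.0 / sigma**2
        denom = float(np.sum(m * m * w2))
        s = float(np.sum(m * y_sel * w2)) / denom if denom > 0 else 0.0
        return (s * m - y_sel) / sigma

    x0 = np.array([init.mua, init.musp]) if init is not None else np.array([0.1, 10.0])
    lo = np.array([TRS_BOUNDS[0][0], TRS_BOUNDS[1][0]])
    hi = np.array([TRS_BOUNDS[0][1], TRS_BOUNDS[1][1]])
    x0 = np.clip(x0, lo, hi)
    res = least_squares(residuals, x0, bounds=(lo, hi), x_scale=[0.1, 10.0], xtol=1e-12, ftol=1e-12)
    mua, musp = float(res.x[0]), float(res.x[1])
    m = model_counts(mua, musp)
    w2 = 1.0 / sigma**2
    scale = float(np.sum(m * y_sel * w2) / np.sum(m * m * w2))
    resid = float(np.sum(((scale * m - y_sel) / sigma) ** 2) / n_points)
    converged = bool(res.success and np.isfinite(resid))
    return TRSFit(
        mua=mua, musp=musp, scale=scale, fit_range=fit_range, residual=resid,
        converged=converged, wavelength=dtof.wavelength, background=background,
        n_points=n_points,
    )


def compute_hemodynamics(
    fit687: TRSFit, fit830: TRSFit, eps: ExtinctionTable | None = None
) -> Hemodynamics:
    """Oxy/deoxyhemoglobin and StO2 from two-wavelength absorption.

    Solves the 2x2 linear system
    ``mua(lambda) = ln(10) * [eps_HbO2(lambda) C_HbO2 + eps_HHb(lambda) C_HHb]``
    exactly; ``StO2 = 100 * C_HbO2 / (C_HbO2 + C_HHb)``.  Negative
    concentrations are reported as-is with ``physical=False`` rather than
    clipped.
    """
    if eps is None:
        eps = ExtinctionTable.default()
    if not (fit687.converged and fit830.converged):
        raise DomainError("both wavelength fits must have converged")
    lams = (fit687.wavelength, fit830.wavelength)
    E = np.array([eps.eps(lam) for lam in lams], dtype=float)
    b = np.array([fit687.mua, fit830.mua], dtype=float) / LN10
    det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
    if abs(det) < 1e-12 * abs(E).max() ** 2:
        raise ConfigurationError("extinction matrix is singular; wavelengths not independent")
    c = np.linalg.solve(E, b)  # mol/L
    c_uM = c * 1e6
    thc = float(c_uM.sum())
    sto2 = 100.0 * float(c_uM[0]) / thc if thc != 0 else np.nan
    physical = bool(np.all(c_uM >= 0))
    return Hemodynamics(
        c_hbo2=float(c_uM[0]), c_hhb=float(c_uM[1]), thc=thc, sto2=float(sto2),
        physical=physical,
    )


def estimate_beta(g2: G2Curve, knee: float = BETA_PLATEAU_KNEE) -> float:
    """Coherence parameter beta from the early-delay plateau of g2.

    beta is the intercept of ``g2 - 1`` extrapolated linearly to zero delay
    over the plateau (delays below the knee, default 3e-7 s).  Within the
    plateau the field correlation decays linearly in tau to first order, so
    the intercept removes the downward bias a plain plateau mean picks up
    when the decay is fast (high blood-flow index).
    """
    mask = g2.tau_grid < knee
    if mask.sum() < 3:
        raise EstimationError(
            f"no plateau detected: fewer than 3 delay points below {knee:.1e} s"
        )
    tau = g2.tau_grid[mask]
    w = g2.values[mask] - 1.0
    if np.all(w > 0):
        # sqrt scale: sqrt(g2-1) = sqrt(beta) g1 is linear in tau to a very
        # good approximation within the plateau, so the squared intercept is
        # nearly bias-free even at high blood-flow index
        _, intercept = np.polyfit(tau, np.sqrt(w), 1)
        return float(intercept**2) if intercept > 0 else 0.0
    # noise-dominated plateau (nonpositive contrast): plain linear intercept
    _, intercept = np.polyfit(tau, w, 1)
    return float(intercept)


def g1_from_g2(g2: G2Curve, beta: float) -> np.ndarray:
    """Invert the Siegert relation: ``g1 = sqrt(max(g2 - 1, 0) / beta)``."""
    if not (beta > 0):
        raise DomainError(f"beta must be > 0, got {beta}")
    return np.sqrt(np.maximum(g2.values - 1.0, 0.0) / beta)


def fit_g2(
    g2: G2Curve,
    props: OpticalProperties,
    geom: ProbeGeometry = DCS_GEOMETRY,
    cutoff: float = DCS_CUTOFF,
    beta: float | None = None,
) -> DCSFit:
    """Recover the blood-flow index and beta from a measured g2 curve.

    Sequential procedure: beta from the early plateau (unless supplied),
    then a bounded least-squares fit of the homogeneous semi-infinite
    correlation-diffusion model to ``g1 = sqrt((g2-1)/beta)`` over the
    leading run of points with ``g1 >= cutoff`` (default 0.3; later points
    are excluded because the deep tail is noise- and
    heterogeneity-dominated).

    Raises
    ------
    InsufficientDecayError
        "insufficient decay sampled" -- when beta is not estimable or below
        :data:`BETA_FLOOR` (the curve carries no resolvable coherence
        plateau, e.g. a noise-dominated acquisition), or when fewer than 5
        leading points lie above the cutoff.
    """
    if beta is None:
        try:
            beta = estimate_beta(g2)
        except EstimationError as exc:
            raise InsufficientDecayError(f"insufficient decay sampled: {exc}") from exc
    if beta < BETA_FLOOR:
        raise InsufficientDecayError(
            f"insufficient decay sampled: coherence plateau not resolvable "
            f"(beta={beta:.3f} < {BETA_FLOOR})"
        )
    g1d = g1_from_g2(g2, beta)
    below = np.nonzero(g1d < cutoff)[0]
    n_lead = int(below[0]) if below.size else g1d.size
    if n_lead < 5:
        raise InsufficientDecayError(
            f"insufficient decay sampled: only {n_lead} leading points with g1 >= {cutoff}"
        )
    tau_sel = g2.tau_grid[:n_lead]
    y_sel = g1d[:n_lead]

    def residuals(x: np.ndarray) -> np.ndarray:
        model = dcs_g1(tau_sel, props, FlowSpec(bfi=10.0 ** x[0]), geom)
        return model.values - y_sel

    res = least_squares(residuals, x0=np.array([-8.0]), bounds=([-12.0], [-4.0]), xtol=1e-14, ftol=1e-14)
    bfi = float(10.0 ** res.x[0])
    rnorm = float(np.sqrt(np.mean(res.fun**2)))
    flags = []
    if bfi < BFI_UNRELIABLE:
        flags.append("unreliable")
    if rnorm > POOR_FIT_RNORM:
        flags.append("poor model agreement")
    return DCSFit(
        bfi=bfi,
        beta=float(beta),
        residual=rnorm,
        cutoff_value=cutoff,
        converged=bool(res.success),
        reliability_flag="; ".join(flags) if flags else "ok",
        n_points=n_lead,
    )
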