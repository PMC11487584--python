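"""Figures of merit and the rule-based trustworthiness classifier.

The figures of merit mirror bedside practice for hybrid diffuse optics:
FWHM of DTOF and IRF, their ratio (rFWHM) and difference (dFWHM), SNR as
DTOF peak over the pre-pulse background noise, dynamic range in decades,
DTOF-vs-IRF peak delay, DCS count rate, beta, BFI, and the g1 tail level.

The classifier splits violations into *hard* failures (data that should not
be analyzed at all: SNR or dynamic range too low, count rate below the
noise floor, a refused fit) which yield ``reject``, and *plausibility*
failures (values exist but should be distrusted: beta or BFI out of range,
non-zero g1 tail, secondary decay, implausible StO2, insufficient DTOF
broadening) which yield ``suspect``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import yaml

from hybridqc.errors import ConfigurationError, DomainError, EstimationError, UndefinedWidthError
from hybridqc.fitting import DCSFit, Hemodynamics, g1_from_g2
from hybridqc.instrument import DTOFHistogram, G2Curve, IRF
from hybridqc.optics import (
    DCS_GEOMETRY,
    FlowSpec,
    ModelCurve,
    OpticalProperties,
    ProbeGeometry,
    dcs_g1,
)

#: Delay at which the g1 tail plateau is evaluated (s).
TAIL_TAU = 1e-3


def _xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, DTOFHistogram):
        return curve.t_grid, curve.counts
    if isinstance(curve, IRF):
        return curve.t_grid, curve.values
    if isinstance(curve, G2Curve):
        return curve.tau_grid, curve.values
    if isinstance(curve, ModelCurve):
        return curve.abscissa, curve.values
    x, y = curve
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fwhm(curve) -> float:
    """Full width at half maximum, linearly interpolated between samples.

    Accepts any curve object of the package or an ``(x, y)`` pair.  Raises
    :class:`UndefinedWidthError` when the curve does not drop below half its
    maximum on both sides of the peak.
    """
    x, y = _xy(curve)
    if y.size < 3:
        raise UndefinedWidthError("too few samples to measure a width")
    ipk = int(np.argmax(y))
    peak = y[ipk]
    if peak <= 0:
        raise DomainError("curve maximum must be positive")
    half = 0.5 * peak

    left = np.nonzero(y[:ipk] < half)[0]
    right = np.nonzero(y[ipk:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise UndefinedWidthError("curve never drops below half maximum on both sides")
    i = int(left[-1])  # y[i] < half <= y[i+1]
    x_left = x[i] + (half - y[i]) * (x[i + 1] - x[i]) / (y[i + 1] - y[i])
    j = ipk + int(right[0])  # y[j-1] >= half > y[j]
    x_right = x[j - 1] + (half - y[j - 1]) * (x[j] - x[j - 1]) / (y[j] - y[j - 1])
    return float(x_right - x_left)


@dataclass
class QCMetrics:
    """Figures of merit for one measurement; fields are None when undefined."""

    fwhm_dtof: float | None = None
    fwhm_irf: float | None = None
    rfwhm: float | None = None
    dfwhm: float | None = None
    snr: float | None = None
    dynamic_range: float | None = None
    peak_delay: float | None = None
    count_rate: float | None = None
    beta: float | None = None
    bfi: float | None = None
    tail_plateau: float | None = None
    residual_norm: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCRuleSet:
    """Thresholds of the trustworthiness rules.

    Defaults encode bedside guidelines for this instrument class: SNR >= 10
    (non-strict exclusion bound), >= 3 decades of dynamic range, DTOF peak
    delayed >= 0.7 ns from the IRF peak, rFWHM > 1 and dFWHM > 0 (diffusive
    broadening), DCS count rate within [0.5, 200] kHz (noise floor to
    saturation), beta within [0.35, 0.55] ("near 0.5"), BFI within
    [1e-9, 8e-8] cm^2/s with fits below 3e-10 unreliable, g1 tail at 1 ms
    below 0.05, and StO2 within [50, 75]%.
    """

    snr_min: float = 10.0
    dynamic_range_min: float = 3.0
    peak_delay_min: float = 0.7
    rfwhm_min: float = 1.0
    dfwhm_min: float = 0.0
    count_rate_window: tuple[float, float] = (0.5, 200.0)
    beta_window: tuple[float, float] = (0.35, 0.55)
    bfi_window: tuple[float, float] = (1e-9, 8e-8)
    bfi_unreliable: float = 3e-10
    tail_plateau_max: float = 0.05
    sto2_window: tuple[float, float] = (50.0, 75.0)

    def __post_init__(self) -> None:
        for name in ("count_rate_window", "beta_window", "bfi_window", "sto2_window"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ConfigurationError(f"{name} must be ordered (lo < hi), got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        for name in ("snr_min", "dynamic_range_min", "peak_delay_min", "bfi_unreliable",
                     "tail_plateau_max"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QCRuleSet":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown rule fields: {sorted(unknown)}")
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "QCRuleSet":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError(f"rule file {path} must contain a mapping")
        return cls.from_dict(d)


@dataclass
class Reason:
    """One violated rule: identifier, observed value and the bound applied."""

    rule: str
    observed: float | str | None
    bound: str
    severity: Literal["hard", "plausibility"]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCVerdict:
    """Trust label with the complete list of violated rules."""

    label: Literal["acceptable", "suspect", "reject"]
    reasons: list[Reason] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"label": self.label, "reasons": [r.to_dict() for r in self.reasons]}


def trs_qc_metrics(dtof: DTOFHistogram, irf: IRF, min_background_bins: int = 20) -> QCMetrics:
    """TRS figures of merit from a DTOF and its IRF.

    The background window is every bin earlier than (IRF peak - 5 IRF FWHM),
    i.e. safely before the light pulse.  SNR is the DTOF maximum over the
    standard deviation of that window; dynamic range is
    ``log10(peak / max(mean background, 1))`` in decades.

    Raises
    ------
    ConfigurationError
        If the background window holds fewer than ``min_background_bins``
        bins, or its variance is exactly zero (noiseless simulation with no
        background: SNR would be silently infinite).
    """
    mask = dtof.t_grid < (irf.peak_time - 5.0 * irf.fwhm)
    if mask.sum() < min_background_bins:
        raise ConfigurationError(
            f"background window has {int(mask.sum())} bins "
            f"(< {min_background_bins}); IRF peak too early in the grid"
        )
    bg = dtof.counts[mask]
    bg_std = float(bg.std())
    peak = float(dtof.counts.max())
    if bg_std == 0.0 or float(bg.max()) < 1e-9 * peak:
        raise ConfigurationError(
            "background window has zero variance (noiseless curve with no "
            "background); SNR undefined"
        )
    w_dtof = fwhm(dtof)
    w_irf = fwhm(irf)
    return QCMetrics(
        fwhm_dtof=w_dtof,
        fwhm_irf=w_irf,
        rfwhm=w_dtof / w_irf,
        dfwhm=w_dtof - w_irf,
        snr=peak / bg_std,
        dynamic_range=float(np.log10(peak / max(float(bg.mean()), 1.0))),
        peak_delay=dtof.peak_time - irf.peak_time,
    )


def dcs_qc_metrics(g2: G2Curve, fit: DCSFit | None) -> QCMetrics:
    """DCS figures of merit; fields from a refused fit are left None.

    ``tail_plateau`` is the beta-normalized g1 interpolated at 1 ms delay --
    a healthy curve has decayed to ~0 there, so a sizable value reveals a
    slow second component (heterogeneous dynamics).
    """
    metrics = QCMetrics(count_rate=g2.count_rate)
    if fit is None:
        return metrics
    metrics.beta = fit.beta
    metrics.bfi = fit.bfi if fit.converged else None
    metrics.residual_norm = fit.residual
    if fit.beta and fit.beta > 0:
        tau = g2.tau_grid
        # Noise-conservative plateau estimate over the final portion of the
        # curve (2e-3 to 1e-2 s), where even a slow homogeneous decay has
        # reached zero: averaging g2-1 *before* the square root avoids the
        # strong positive bias that sqrt(max(g2-1, 0)) takes on pure noise;
        # subtracting two standard errors makes the estimate a lower bound,
        # so a plateau is only reported when resolved above the noise.
        mask = (tau >= 2.0 * TAIL_TAU) & (tau <= 10.0 * TAIL_TAU)
        if mask.sum() >= 4:
            w = g2.values[mask] - 1.0
            m = float(w.mean())
            sem = float(w.std(ddof=1) / np.sqrt(w.size))
            metrics.tail_plateau = float(np.sqrt(max(m - 2.0 * sem, 0.0) / fit.beta))
        elif tau[0] <= TAIL_TAU <= tau[-1]:
            g1d = g1_from_g2(g2, fit.beta)
            metrics.tail_plateau = float(np.interp(np.log10(TAIL_TAU), np.log10(tau), g1d))
    return metrics


@dataclass
class SecondaryDecay:
    """Result of the two-component g1 decomposition."""

    present: bool
    slow_weight: float | None
    slow_bfi: float | None
    ssr_single: float
    ssr_double: float


def detect_secondary_decay(
    g1: ModelCurve,
    props: OpticalProperties | None = None,
    geom: ProbeGeometry = DCS_GEOMETRY,
    improvement: float = 0.5,
    min_slow_weight: float = 0.15,
    sigma: np.ndarray | None = None,
) -> SecondaryDecay:
    """Detect a secondary (slower) exponential decay in a g1 curve.

    Fits a one-component semi-infinite model and a two-component mixture
    ``w g1(BFI_fast) + (1-w) g1(BFI_slow)``; the secondary decay is present
    when the mixture reduces the squared residual by at least ``improvement``
    (default 50%) *and* the slow weight is at least ``min_slow_weight``
    (default 0.15).  The medium optical properties default to the curve's
    ``meta`` entries, else to (mua=0.1, musp=10) at 785 nm.

    For measured curves, pass per-point standard deviations ``sigma``: the
    beta normalization ``g1 = sqrt((g2-1)/beta)`` strongly amplifies noise
    where g1 is small, so unweighted residuals would be dominated by the
    meaningless tail; weighting by 1/sigma restores the comparison.

    Raises
    ------
    EstimationError
        "no decay to analyze" when the curve is essentially flat.
    """
    if g1.kind != "g1":
        raise DomainError(f"expected a g1 curve, got kind={g1.kind!r}")
    tau = g1.abscissa
    y = g1.values
    if tau[-1] < TAIL_TAU:
        raise DomainError(f"g1 must be sampled to at least {TAIL_TAU} s")
    if float(y.min()) > 0.95:
        raise EstimationError("no decay to analyze: g1 never falls below 0.95")
    if props is None:
        props = OpticalProperties(
            mua=float(g1.meta.get("mua", 0.1)),
            musp=float(g1.meta.get("musp", 10.0)),
            wavelength=785.0,
        )
    w_inv = np.ones_like(y) if sigma is None else 1.0 / np.asarray(sigma, dtype=float)

    def model(log_bfi: float) -> np.ndarray:
        return dcs_g1(tau, props, FlowSpec(bfi=10.0**log_bfi), geom).values

    from scipy.optimize import least_squares

    # both nested models carry a free amplitude: on measured curves the
    # beta normalization leaves a small residual scale error that must not
    # masquerade as a second component
    res1 = least_squares(
        lambda x: (x[1] * model(x[0]) - y) * w_inv, x0=np.array([-8.0, 1.0]),
        bounds=([-12.0, 0.5], [-4.0, 1.5]), xtol=1e-13, ftol=1e-13,
    )
    ssr1 = float(np.sum(res1.fun**2))

    def resid2(x: np.ndarray) -> np.ndarray:
        w = x[2]
        return (x[3] * (w * model(x[0]) + (1 - w) * model(x[1])) - y) * w_inv

    res2 = least_squares(
        resid2,
        x0=np.array([float(res1.x[0]), float(res1.x[0]) - 2.0, 0.8, float(res1.x[1])]),
        bounds=([-12, -12, 0.0, 0.5], [-4, -4, 1.0, 1.5]),
        xtol=1e-13,
        ftol=1e-13,
    )
    ssr2 = float(np.sum(res2.fun**2))
    # order components: the slow one has the smaller BFI
    log_f, log_s, w_fast = res2.x[:3]
    if log_f < log_s:
        log_f, log_s = log_s, log_f
        w_fast = 1.0 - w_fast
    slow_weight = float(1.0 - w_fast)
    slow_bfi = float(10.0**log_s)
    # a near-perfect single-component fit cannot be meaningfully improved
    # (guard only meaningful for unweighted, noiseless comparisons)
    if sigma is None and ssr1 <= y.size * (1e-6) ** 2:
        present = False
    else:
        present = ssr2 <= (1.0 - improvement) * ssr1 and slow_weight >= min_slow_weight
    return SecondaryDecay(
        present=bool(present),
        slow_weight=slow_weight if present else None,
        slow_bfi=slow_bfi if present else None,
        ssr_single=ssr1,
        ssr_double=ssr2,
    )


def classify(
    metrics: QCMetrics,
    hemo: Hemodynamics | None = None,
    rules: QCRuleSet | None = None,
    secondary: SecondaryDecay | None = None,
    refusals: Sequence[str] = (),
) -> QCVerdict:
    """Rule-based trust label for one measurement.

    ``reject`` when any hard rule fails (low SNR, low dynamic range, count
    rate below the noise floor, or a refused fit passed via ``refusals``);
    ``suspect`` when any plausibility rule fails; ``acceptable`` otherwise.
    ``reasons`` enumerates every violation, so the label is reproducible
    from the reasons alone.
    """
    if rules is None:
        rules = QCRuleSet()
    reasons: list[Reason] = []

    def hard(rule: str, observed, bound: str) -> None:
        reasons.append(Reason(rule=rule, observed=observed, bound=bound, severity="hard"))

    def plaus(rule: str, observed, bound: str) -> None:
        reasons.append(Reason(rule=rule, observed=observed, bound=bound, severity="plausibility"))

    for msg in refusals:
        hard("fit_refused", msg, "fit must succeed")

    m = metrics
    if m.snr is not None and m.snr < rules.snr_min:
        hard("snr_low", m.snr, f"snr >= {rules.snr_min}")
    if m.dynamic_range is not None and m.dynamic_range < rules.dynamic_range_min:
        hard("dynamic_range_low", m.dynamic_range, f"dynamic_range >= {rules.dynamic_range_min}")
    if m.count_rate is not None and m.count_rate < rules.count_rate_window[0]:
        hard("count_rate_below_noise_level", m.count_rate,
             f"count_rate >= {rules.count_rate_window[0]} kHz")

    if m.count_rate is not None and m.count_rate > rules.count_rate_window[1]:
        plaus("count_rate_saturated", m.count_rate,
              f"count_rate <= {rules.count_rate_window[1]} kHz")
    if m.rfwhm is not None and m.rfwhm <= rules.rfwhm_min:
        plaus("rfwhm_not_broadened", m.rfwhm, f"rfwhm > {rules.rfwhm_min}")
    if m.dfwhm is not None and m.dfwhm <= rules.dfwhm_min:
        plaus("dfwhm_not_positive", m.dfwhm, f"dfwhm > {rules.dfwhm_min}")
    if m.peak_delay is not None and m.peak_delay < rules.peak_delay_min:
        plaus("peak_delay_short", m.peak_delay, f"peak_delay >= {rules.peak_delay_min} ns")
    if m.beta is not None:
        if m.beta < rules.beta_window[0]:
            plaus("beta_low", m.beta, f"beta >= {rules.beta_window[0]}")
        elif m.beta > rules.beta_window[1]:
            plaus("beta_high", m.beta, f"beta <= {rules.beta_window[1]}")
    if m.bfi is not None:
        if m.bfi < rules.bfi_unreliable:
            plaus("bfi_unreliable", m.bfi, f"bfi >= {rules.bfi_unreliable} cm^2/s")
        elif m.bfi < rules.bfi_window[0]:
            plaus("bfi_below_normal_range", m.bfi, f"bfi >= {rules.bfi_window[0]} cm^2/s")
        elif m.bfi > rules.bfi_window[1]:
            plaus("bfi_above_normal_range", m.bfi, f"bfi <= {rules.bfi_window[1]} cm^2/s")
    if m.tail_plateau is not None and m.tail_plateau > rules.tail_plateau_max:
        plaus("g1_tail_not_zero", m.tail_plateau, f"tail_plateau <= {rules.tail_plateau_max}")
    if secondary is not None and secondary.present:
        plaus("secondary_decay_present", secondary.slow_weight, "single-component decay expected")
    if hemo is not None and np.isfinite(hemo.sto2):
        if not hemo.physical:
            plaus("nonphysical_concentrations", min(hemo.c_hbo2, hemo.c_hhb),
                  "concentrations >= 0")
        elif hemo.sto2 < rules.sto2_window[0]:
            plaus("sto2_low", hemo.sto2, f"sto2 >= {rules.sto2_window[0]} %")
        elif hemo.sto2 > rules.sto2_window[1]:
            plaus("sto2_high", hemo.sto2, f"sto2 <= {rules.sto2_window[1]} %")

    if any(r.severity == "hard" for r in reasons):
        label = "reject"
    elif reasons:
        label = "suspect"
    else:
        label = "acceptable"
    return QCVerdict(label=label, reasons=reasons)
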