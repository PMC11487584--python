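"""Instrument realism for TRS and DCS acquisitions.

Adds to the ideal forward models everything a real photon-counting device
imposes on the data: a finite instrument response function (IRF), Poisson
counting noise and a flat pre-pulse background for the DTOF; correlator
noise and detector afterpulsing for g2; and the averaging / peak
normalization conventions used when reporting curves.

Default grids: DTOFs live on a uniform 0-10 ns grid with 4096 bins
(~2.44 ps, resolving sub-100-ps IRFs while keeping convolution cheap);
g2 lives on 60 log-spaced delays between 1e-7 and 1e-2 s, emulating a
multi-tau correlator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from hybridqc.errors import DomainError, GridError, ResolutionError
from hybridqc.optics import ModelCurve, OpticalProperties, ProbeGeometry, TRS_GEOMETRY, trs_reflectance

#: Default DTOF time axis: bin centers of 4096 uniform bins spanning 0-10 ns.
DEFAULT_T_GRID = (np.arange(4096) + 0.5) * (10.0 / 4096)

#: Default multi-tau-like delay grid: 60 log-spaced points, 1e-7 to 1e-2 s.
DEFAULT_TAU_GRID = np.logspace(-7, -2, 60)

#: Default IRF width (ns); typical of this instrument class.
DEFAULT_IRF_FWHM = 0.4

#: Scale of the per-point g2 noise model; the standard deviation per point is
#: ``G2_NOISE_SCALE / sqrt(count_rate_kHz * duration_s)``.  A simplified
#: stand-in for full correlator noise formulas, sufficient for QC-threshold
#: work (documented as approximate in the methods note).
G2_NOISE_SCALE = 0.5


@dataclass
class IRF:
    """Instrument response function sampled on the DTOF grid.

    ``values`` integrate to unit area (``sum(values) * dt == 1``); ``fwhm``
    is the nominal full width at half maximum in ns.  The FWHM of the IRF
    sets the temporal resolution of the device.
    """

    t_grid: np.ndarray
    values: np.ndarray
    fwhm: float

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_grid.shape != self.values.shape or self.t_grid.ndim != 1:
            raise GridError("t_grid and values must be 1-D arrays of equal length")
        if np.any(self.values < 0):
            raise DomainError("IRF values must be nonnegative")
        if not (self.fwhm > 0):
            raise DomainError("IRF fwhm must be > 0")
        dt = self.t_grid[1] - self.t_grid[0]
        area = float(self.values.sum() * dt)
        if abs(area - 1.0) > 1e-9:
            raise DomainError(f"IRF area must be 1 (got {area})")

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0])

    @property
    def peak_time(self) -> float:
        return float(self.t_grid[int(np.argmax(self.values))])


@dataclass
class DTOFHistogram:
    """Binned photon arrival-time counts for one wavelength."""

    t_grid: np.ndarray
    counts: np.ndarray
    wavelength: float
    n_averaged: int = 1
    background_level: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t_grid.shape != self.counts.shape or self.t_grid.ndim != 1:
            raise GridError("t_grid and counts must be 1-D arrays of equal length")
        diffs = np.diff(self.t_grid)
        # tolerance accommodates text round trips at 12 significant digits
        if diffs.size and not np.allclose(diffs, diffs[0], rtol=1e-6, atol=0):
            raise GridError("t_grid must be uniform")
        if np.any(self.counts < 0):
            raise DomainError("counts must be nonnegative")
        if self.n_averaged < 1:
            raise DomainError("n_averaged must be >= 1")
        if self.background_level < 0:
            raise DomainError("background_level must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0])

    @property
    def peak_time(self) -> float:
        return float(self.t_grid[int(np.argmax(self.counts))])


@dataclass
class G2Curve:
    """Measured intensity autocorrelation with acquisition bookkeeping.

    ``count_rate`` is the detected intensity in kHz; ``n_channels`` counts
    the detection channels averaged into the curve; ``duration`` is the
    integration time in seconds.
    """

    tau_grid: np.ndarray
    values: np.ndarray
    count_rate: float
    n_channels: int = 1
    duration: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.tau_grid.shape != self.values.shape or self.tau_grid.ndim != 1:
            raise GridError("tau_grid and values must be 1-D arrays of equal length")
        if not np.all(np.diff(self.tau_grid) > 0):
            raise GridError("tau_grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("g2 values must be finite")
        if self.count_rate < 0:
            raise DomainError("count_rate must be >= 0")
        if not (self.duration > 0):
            raise DomainError("duration must be > 0")
        if self.n_channels < 1:
            raise DomainError("n_channels must be >= 1")


def make_irf(
    fwhm: float = DEFAULT_IRF_FWHM,
    t0: float = 3.0,
    t_grid: np.ndarray | None = None,
) -> IRF:
    """Unimodal symmetric (Gaussian) IRF with given FWHM and peak position.

    Parameters
    ----------
    fwhm : float
        Requested full width at half maximum (ns); must span at least two
        grid bins, otherwise a :class:`ResolutionError` is raised.
    t0 : float
        Peak position (ns), must lie inside the grid.
    t_grid : array, optional
        Time axis; defaults to the package DTOF grid.
    """
    t = DEFAULT_T_GRID.copy() if t_grid is None else np.asarray(t_grid, dtype=float)
    dt = t[1] - t[0]
    if not (fwhm > 0):
        raise DomainError("fwhm must be > 0")
    if fwhm < 2 * dt:
        raise ResolutionError(f"fwhm {fwhm} ns below twice the bin width {dt:.3g} ns")
    if not (t[0] <= t0 <= t[-1]):
        raise DomainError(f"t0={t0} outside the grid [{t[0]}, {t[-1]}]")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    vals /= vals.sum() * dt
    return IRF(t_grid=t, values=vals, fwhm=fwhm)


def convolve_with_irf(model: ModelCurve, irf: IRF) -> np.ndarray:
    """Discrete linear convolution of a model curve with the IRF.

    Computed on the shared grid, truncated to the grid length; no circular
    wrap-around.  Total area is preserved for signals that decay within the
    grid.  The model's time origin is the light launch; convolution shifts
    it by the IRF peak position.
    """
    if model.abscissa.shape != irf.t_grid.shape or not np.allclose(
        model.abscissa, irf.t_grid, rtol=1e-9, atol=0
    ):
        raise GridError("model and IRF must share the same time grid")
    full = fftconvolve(model.values, irf.values * irf.dt)
    out = full[: model.values.size]
    return np.maximum(out, 0.0)


def simulate_dtof(
    props: OpticalProperties,
    geom: ProbeGeometry = TRS_GEOMETRY,
    irf: IRF | None = None,
    total_counts: float = 1e6,
    background_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> DTOFHistogram:
    """Simulate a photon-counting DTOF measurement.

    The expected histogram is the diffusion-model reflectance convolved with
    the IRF, rescaled so its sum equals ``total_counts``, plus a flat
    background of ``background_rate`` expected counts per bin.  Counts are
    drawn independently per bin from a Poisson law; identical seeds yield
    identical histograms.
    """
    if not (total_counts > 0):
        raise DomainError("total_counts must be > 0")
    if background_rate < 0:
        raise DomainError("background rate must be >= 0")
    if irf is None:
        irf = make_irf()
    model = trs_reflectance(irf.t_grid, props, geom)
    expected_signal = convolve_with_irf(model, irf)
    expected_signal = expected_signal * (total_counts / expected_signal.sum())
    expected = expected_signal + background_rate
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    return DTOFHistogram(
        t_grid=irf.t_grid.copy(),
        counts=counts,
        wavelength=props.wavelength,
        n_averaged=1,
        background_level=background_rate,
        meta={
            "mua": props.mua,
            "musp": props.musp,
            "rho": geom.rho,
            "total_counts": total_counts,
            "expected": expected,
        },
    )


def simulate_g2_measurement(
    g2_ideal: ModelCurve,
    count_rate: float,
    duration: float = 1.0,
    afterpulsing_amp: float = 0.0,
    afterpulsing_tau: float = 1e-6,
    seed: int | np.random.Generator | None = None,
    n_channels: int = 1,
) -> G2Curve:
    """Measure an ideal g2 with correlator noise and detector afterpulsing.

    Output values are::

        g2(tau) + afterpulsing_amp * exp(-tau / afterpulsing_tau) + noise

    Afterpulsing (spurious delayed detector pulses correlated with real
    detections) adds an artificial short-delay component, inflating g2 near
    tau = 0 and hence any beta estimated from the early plateau.  The noise
    is zero-mean Gaussian with per-point standard deviation
    ``G2_NOISE_SCALE / sqrt(count_rate * duration)`` -- a simplified model
    standing in for full correlation-noise formulas.
    """
    if g2_ideal.kind != "g2":
        raise DomainError(f"expected a g2 curve, got kind={g2_ideal.kind!r}")
    if count_rate < 0:
        raise DomainError("count_rate must be >= 0")
    if not (duration > 0):
        raise DomainError("duration must be > 0")
    if afterpulsing_amp < 0:
        raise DomainError("afterpulsing_amp must be >= 0")
    if not (afterpulsing_tau > 0):
        raise DomainError("afterpulsing_tau must be > 0")
    tau = g2_ideal.abscissa
    rng = np.random.default_rng(seed)
    sd = G2_NOISE_SCALE / np.sqrt(max(count_rate, 1e-12) * duration * n_channels)
    vals = (
        g2_ideal.values
        + afterpulsing_amp * np.exp(-tau / afterpulsing_tau)
        + rng.normal(0.0, sd, size=tau.size)
    )
    return G2Curve(
        tau_grid=tau.copy(),
        values=vals,
        count_rate=count_rate,
        n_channels=n_channels,
        duration=duration,
        meta={"afterpulsing_amp": afterpulsing_amp, "afterpulsing_tau": afterpulsing_tau},
    )


def average_curves(curves: Sequence[DTOFHistogram] | Sequence[G2Curve]):
    """Pointwise arithmetic mean of repeated acquisitions.

    Mirrors the device convention of averaging a hundred consecutive 1-s
    DTOFs, and g2 over consecutive measurements and detection channels.
    Bookkeeping fields (``n_averaged`` / ``n_channels``, ``duration``) are
    summed.
    """
    if not curves:
        raise DomainError("cannot average an empty list of curves")
    first = curves[0]
    if isinstance(first, DTOFHistogram):
        if not all(isinstance(c, DTOFHistogram) for c in curves):
            raise DomainError("cannot mix curve kinds in an average")
        for c in curves[1:]:
            if c.t_grid.shape != first.t_grid.shape or not np.allclose(
                c.t_grid, first.t_grid, rtol=1e-9, atol=0
            ):
                raise GridError("all DTOFs must share the same time grid")
            if c.wavelength != first.wavelength:
                raise DomainError("cannot average DTOFs from different wavelengths")
        mean_counts = np.mean([c.counts for c in curves], axis=0)
        return DTOFHistogram(
            t_grid=first.t_grid.copy(),
            counts=mean_counts,
            wavelength=first.wavelength,
            n_averaged=sum(c.n_averaged for c in curves),
            background_level=float(np.mean([c.background_level for c in curves])),
            meta=dict(first.meta),
        )
    if isinstance(first, G2Curve):
        if not all(isinstance(c, G2Curve) for c in curves):
            raise DomainError("cannot mix curve kinds in an average")
        for c in curves[1:]:
            if c.tau_grid.shape != first.tau_grid.shape or not np.allclose(
                c.tau_grid, first.tau_grid, rtol=1e-9, atol=0
            ):
                raise GridError("all g2 curves must share the same delay grid")
        mean_vals = np.mean([c.values for c in curves], axis=0)
        return G2Curve(
            tau_grid=first.tau_grid.copy(),
            values=mean_vals,
            count_rate=float(np.mean([c.count_rate for c in curves])),
            n_channels=sum(c.n_channels for c in curves),
            duration=sum(c.duration for c in curves),
            meta=dict(first.meta),
        )
    raise DomainError(f"cannot average curves of type {type(first).__name__}")


def normalize_to_peak(curve):
    """Scale a curve so its maximum equals 1 (simple division by the peak).

    Works on :class:`DTOFHistogram`, :class:`G2Curve` and
    :class:`~hybridqc.optics.ModelCurve`; returns a new object of the same
    type with ratios between points preserved.
    """
    if isinstance(curve, DTOFHistogram):
        peak = curve.counts.max() if curve.counts.size else 0.0
        if peak <= 0:
            raise DomainError("cannot normalize a curve with nonpositive maximum")
        return replace(curve, counts=curve.counts / peak)
    if isinstance(curve, G2Curve):
        peak = curve.values.max() if curve.values.size else 0.0
        if peak <= 0:
            raise DomainError("cannot normalize a curve with nonpositive maximum")
        return replace(curve, values=curve.values / peak)
    if isinstance(curve, ModelCurve):
        peak = curve.values.max() if curve.values.size else 0.0
        if peak <= 0:
            raise DomainError("cannot normalize a curve with nonpositive maximum")
        return ModelCurve(
            abscissa=curve.abscissa.copy(),
            values=curve.values / peak,
            kind=curve.kind,
            meta=dict(curve.meta),
        )
    raise DomainError(f"cannot normalize curves of type {type(curve).__name__}")
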