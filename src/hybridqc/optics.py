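"""Closed-form photon-diffusion and correlation-diffusion forward models.

Homogeneous semi-infinite medium with an extrapolated boundary handled by the
method of image sources.  Two solutions are provided:

- time-domain diffuse reflectance ``R(rho, t)`` for TRS (shape only; the
  absolute amplitude is a free scale carried by the fits), and
- the normalized field autocorrelation ``g1(tau)`` for DCS under Brownian
  scatterer dynamics, ``<dr^2(tau)> = 6 * BFI * tau``.

Units are fixed package-wide: mua and musp in 1/cm, source-detector
separation rho in cm, TRS time in ns, DCS delay time in s, BFI in cm^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from hybridqc.errors import DomainError, GridError

#: Vacuum speed of light in cm/ns.
C_CM_PER_NS = 29.9792458

#: Device wavelengths (nm): TRS sources and the DCS source.
DEVICE_WAVELENGTHS = (687.0, 830.0, 785.0)


class DiffusionValidityWarning(UserWarning):
    """Reduced scattering does not dominate absorption (musp <= mua)."""


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of the medium at one wavelength.

    Parameters
    ----------
    mua : float
        Absorption coefficient (1/cm).
    musp : float
        Reduced scattering coefficient (1/cm).
    wavelength : float
        Light wavelength (nm).
    """

    mua: float
    musp: float
    wavelength: float

    def __post_init__(self) -> None:
        if not (self.mua > 0):
            raise DomainError(f"mua must be > 0, got {self.mua}")
        if not (self.musp > 0):
            raise DomainError(f"musp must be > 0, got {self.musp}")
        if not (self.wavelength > 0):
            raise DomainError(f"wavelength must be > 0, got {self.wavelength}")

    @property
    def diffusive(self) -> bool:
        """True when scattering dominates absorption (diffusion regime)."""
        return self.musp > self.mua


@dataclass(frozen=True)
class ProbeGeometry:
    """Source-detector separation and refractive indices.

    The default 3.0-cm separation is the TRS interfiber distance of the
    emulated device; DCS probes typically sit closer (default 2.5 cm, see
    :data:`DCS_GEOMETRY`).
    """

    rho: float = 3.0
    n_tissue: float = 1.4
    n_outside: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rho > 0):
            raise DomainError(f"rho must be > 0, got {self.rho}")
        if self.n_tissue < 1:
            raise DomainError(f"n_tissue must be >= 1, got {self.n_tissue}")
        if not (self.n_outside > 0):
            raise DomainError(f"n_outside must be > 0, got {self.n_outside}")


#: Default TRS probe geometry (30-mm interfiber distance).
TRS_GEOMETRY = ProbeGeometry(rho=3.0)
#: Default DCS probe geometry (25-mm separation, a package default: the
#: emulated device's DCS separation is not specified).
DCS_GEOMETRY = ProbeGeometry(rho=2.5)


def boundary_coefficient(n_rel: float) -> float:
    """Internal-reflection boundary coefficient A from the relative index.

    Effective-reflection approximation: the diffuse reflectance of the
    boundary is expressed through a cubic polynomial fit in ``1/n`` and the
    coefficient ``A = (1 + r_d) / (1 - r_d)`` rescales the extrapolated
    boundary distance ``zb = 2 A D``.  For matched indices A = 1.
    """
    if n_rel <= 0:
        raise DomainError(f"relative refractive index must be > 0, got {n_rel}")
    if n_rel == 1.0:
        return 1.0
    r_d = -1.440 * n_rel**-2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1 + r_d) / (1 - r_d)


@dataclass(frozen=True)
class DiffusionConstants:
    """Derived constants of the diffusion problem.

    Attributes
    ----------
    D : float
        Photon diffusion coefficient, ``1 / (3 musp)`` (cm).
    z0 : float
        Depth of the isotropic image source, ``1 / musp`` (cm).
    zb : float
        Extrapolated-boundary distance, ``2 A D`` (cm).
    v : float
        Speed of light in tissue (cm/ns).
    k0 : float
        In-medium optical wavenumber ``2 pi n / lambda`` (1/cm).
    """

    D: float
    z0: float
    zb: float
    v: float
    k0: float

    @classmethod
    def from_medium(cls, props: OpticalProperties, geom: ProbeGeometry) -> "DiffusionConstants":
        D = 1.0 / (3.0 * props.musp)
        z0 = 1.0 / props.musp
        A = boundary_coefficient(geom.n_tissue / geom.n_outside)
        zb = 2.0 * A * D
        v = C_CM_PER_NS / geom.n_tissue
        k0 = 2.0 * np.pi * geom.n_tissue / (props.wavelength * 1e-7)
        return cls(D=D, z0=z0, zb=zb, v=v, k0=k0)

    def K(self, tau: np.ndarray, props: OpticalProperties, flow: "FlowSpec") -> np.ndarray:
        """Correlation decay wavenumber K(tau) (1/cm).

        ``K(tau)^2 = 3 mua musp + musp^2 k0^2 <dr^2(tau)>`` with the Brownian
        mean-square displacement ``<dr^2> = 6 BFI tau``.
        """
        msd = flow.msd(np.asarray(tau, dtype=float))
        return np.sqrt(3.0 * props.mua * props.musp + props.musp**2 * self.k0**2 * msd)


@dataclass(frozen=True)
class FlowSpec:
    """Scatterer-dynamics specification for DCS.

    Only the Brownian-motion model is implemented: moving scatterers (red
    blood cells) with an effective diffusion coefficient equal to the
    blood-flow index, ``<dr^2(tau)> = 6 * BFI * tau``.
    """

    bfi: float
    model: Literal["brownian"] = "brownian"

    def __post_init__(self) -> None:
        if self.bfi < 0:
            raise DomainError(f"bfi must be >= 0, got {self.bfi}")
        if self.model != "brownian":
            raise DomainError(f"only the 'brownian' model is implemented, got {self.model!r}")

    def msd(self, tau: np.ndarray) -> np.ndarray:
        """Mean-square displacement (cm^2) at delay tau (s)."""
        return 6.0 * self.bfi * tau


CurveKind = Literal["reflectance", "g1", "g2"]


@dataclass
class ModelCurve:
    """A model curve on an ordered abscissa.

    ``kind`` distinguishes time-of-flight reflectance (abscissa ns) from
    correlation curves (abscissa s).  ``meta`` carries free-form provenance
    (warnings, parameters) and does not affect equality of the numbers.
    """

    abscissa: np.ndarray
    values: np.ndarray
    kind: CurveKind
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.values.shape:
            raise GridError("abscissa and values must be 1-D arrays of equal length")
        if not np.all(np.diff(self.abscissa) > 0):
            raise GridError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("curve values must be finite")
        if self.kind == "g1":
            if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
                raise DomainError("g1 values must lie in [0, 1]")
            # normalization pins g1 to 1 at zero delay; log-spaced grids start
            # later, where g1 may already have decayed slightly
            if self.abscissa[0] == 0.0 and abs(self.values[0] - 1.0) > 1e-9:
                raise DomainError("g1 must equal 1 at zero delay")


def trs_reflectance(
    t_grid: Sequence[float] | np.ndarray,
    props: OpticalProperties,
    geom: ProbeGeometry = TRS_GEOMETRY,
) -> ModelCurve:
    """Time-domain diffuse reflectance of a semi-infinite medium.

    Extrapolated-boundary image-source solution::

        R(rho, t) ~ t^(-5/2) * exp(-mua v t - rho^2 / (4 D v t))
                    * [ z0 exp(-z0^2 / (4 D v t))
                        + (z0 + 2 zb) exp(-(z0 + 2 zb)^2 / (4 D v t)) ]

    The absolute amplitude is a free scale (fits carry their own scale
    factor), so constant prefactors are dropped.  Absorption enters only
    through the Beer-Lambert factor ``exp(-mua v t)``.

    Parameters
    ----------
    t_grid : array
        Times of flight (ns), strictly positive.
    props, geom
        Medium and probe description.

    Returns
    -------
    ModelCurve
        ``kind='reflectance'``; if ``musp <= mua`` a
        :class:`DiffusionValidityWarning` is emitted and recorded in
        ``meta['diffusion_valid'] = False``.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t <= 0):
        raise DomainError("t_grid must be strictly positive (ns)")
    dc = DiffusionConstants.from_medium(props, geom)
    den = 4.0 * dc.D * dc.v * t
    image_term = dc.z0 * np.exp(-(dc.z0**2) / den) + (dc.z0 + 2 * dc.zb) * np.exp(
        -((dc.z0 + 2 * dc.zb) ** 2) / den
    )
    vals = t**-2.5 * np.exp(-props.mua * dc.v * t - geom.rho**2 / den) * image_term
    meta = {"mua": props.mua, "musp": props.musp, "rho": geom.rho, "diffusion_valid": props.diffusive}
    if not props.diffusive:
        warnings.warn(
            f"musp ({props.musp}) <= mua ({props.mua}): diffusion approximation invalid",
            DiffusionValidityWarning,
            stacklevel=2,
        )
    return ModelCurve(abscissa=t, values=vals, kind="reflectance", meta=meta)


def dcs_g1(
    tau_grid: Sequence[float] | np.ndarray,
    props: OpticalProperties,
    flow: FlowSpec,
    geom: ProbeGeometry = DCS_GEOMETRY,
) -> ModelCurve:
    """Normalized field autocorrelation g1(tau) of a semi-infinite medium.

    Correlation-diffusion solution with image source::

        G1(tau) ~ exp(-K(tau) r1) / r1 - exp(-K(tau) rb) / rb

    with ``r1 = sqrt(rho^2 + z0^2)``, ``rb = sqrt(rho^2 + (z0 + 2 zb)^2)``
    and ``K(tau)^2 = 3 mua musp + musp^2 k0^2 * 6 BFI tau`` (Brownian
    dynamics).  Returned normalized so ``g1(tau=0) = 1``; the first grid
    point need not be 0, normalization always uses K at tau = 0.
    """
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau < 0):
        raise DomainError("delay times must be nonnegative (s)")
    if tau.size > 1 and not np.all(np.diff(tau) > 0):
        raise GridError("tau_grid must be strictly increasing")
    dc = DiffusionConstants.from_medium(props, geom)
    r1 = np.hypot(geom.rho, dc.z0)
    rb = np.hypot(geom.rho, dc.z0 + 2 * dc.zb)

    def G1(K: np.ndarray) -> np.ndarray:
        return np.exp(-K * r1) / r1 - np.exp(-K * rb) / rb

    K_tau = dc.K(tau, props, flow)
    K_0 = dc.K(np.array(0.0), props, FlowSpec(bfi=flow.bfi))
    vals = G1(K_tau) / G1(K_0)
    vals = np.clip(vals, 0.0, 1.0)
    # Grids not starting at tau=0 still satisfy the container's g1(first)=1
    # requirement only if tau[0] is effectively zero decay; store as generic
    # g1 with an explicit leading 1 when tau starts at 0, else keep values.
    meta = {"bfi": flow.bfi, "rho": geom.rho, "mua": props.mua, "musp": props.musp}
    if tau.size and tau[0] == 0.0:
        vals[0] = 1.0
    return ModelCurve(abscissa=tau, values=vals, kind="g1", meta=meta)


def siegert_g2(g1: ModelCurve, beta: float) -> ModelCurve:
    """Intensity autocorrelation from the Siegert relation g2 = 1 + beta |g1|^2.

    ``beta`` is the instrument coherence parameter, near 0.5 for unpolarized
    single-mode detection; must lie in (0, 1].
    """
    if g1.kind != "g1":
        raise DomainError(f"expected a g1 curve, got kind={g1.kind!r}")
    if not (0 < beta <= 1):
        raise DomainError(f"beta must be in (0, 1], got {beta}")
    vals = 1.0 + beta * np.abs(g1.values) ** 2
    meta = dict(g1.meta)
    meta["beta"] = beta
    return ModelCurve(abscissa=g1.abscissa.copy(), values=vals, kind="g2", meta=meta)


def mix_g1(components: Sequence[tuple[ModelCurve, float]]) -> ModelCurve:
    """Intensity-weighted mixture of field-correlation curves.

    ``g1_mix(tau) = sum_i w_i g1_i(tau)`` with nonnegative weights summing to
    one.  Mimics a heterogeneous probed volume (e.g. a shallow hematoma with
    slow scatterer dynamics under perfused cortex): the mixture shows a
    secondary, slower decay and a non-zero tail plateau.
    """
    if not components:
        raise DomainError("at least one component required")
    curves, weights = zip(*components)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise DomainError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise DomainError(f"weights must sum to 1 (got {w.sum()!r})")
    ref = curves[0]
    for c in curves[1:]:
        if c.abscissa.shape != ref.abscissa.shape or not np.allclose(
            c.abscissa, ref.abscissa, rtol=0, atol=0
        ):
            raise GridError("mixture components must share the same abscissa")
    for c in curves:
        if c.kind != "g1":
            raise DomainError(f"all components must be g1 curves, got {c.kind!r}")
    vals = sum(wi * c.values for wi, c in zip(w, curves))
    meta = {"components": [(float(wi), dict(c.meta)) for wi, c in zip(w, curves)]}
    return ModelCurve(abscissa=ref.abscissa.copy(), values=vals, kind="g1", meta=meta)
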