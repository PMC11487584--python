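"""Forward models: a DTOF reflectance curve and a DCS autocorrelation pair.

Evaluates the semi-infinite photon-diffusion solution for a healthy-head
medium and the correlation-diffusion g1/g2 pair, and prints the landmarks a
bedside operator looks at: where the reflectance peaks, how fast g1 decays,
and the Siegert-transformed g2 range.
"""
import numpy as np

from hybridqc import (
    FlowSpec,
    OpticalProperties,
    ProbeGeometry,
    dcs_g1,
    siegert_g2,
    trs_reflectance,
)

props = OpticalProperties(mua=0.14, musp=11.0, wavelength=687.0)
t = np.linspace(0.005, 10.0, 4000)  # ns
curve = trs_reflectance(t, props, ProbeGeometry(rho=3.0))
t_peak = t[int(np.argmax(curve.values))]
print(f"DTOF model peak at {t_peak:.2f} ns after launch "
      f"(mua={props.mua}, musp'={props.musp} 1/cm, rho=3 cm)")

tau = np.logspace(-7, -2, 60)  # s
g1 = dcs_g1(tau, OpticalProperties(0.14, 11.0, 785.0), FlowSpec(bfi=1.2e-8))
i_half = int(np.argmax(g1.values < 0.5))
print(f"g1 falls below 0.5 at tau = {tau[i_half]:.2e} s and below 0.01 at "
      f"tau = {tau[int(np.argmax(g1.values < 0.01))]:.2e} s (BFI 1.2e-8 cm^2/s)")

g2 = siegert_g2(g1, beta=0.49)
print(f"g2 spans [{g2.values.min():.3f}, {g2.values.max():.3f}] "
      "(Siegert relation with beta = 0.49: intercept 1+beta, baseline 1)")
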