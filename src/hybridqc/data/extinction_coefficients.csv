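# Molar extinction coefficients of human hemoglobin, base-10 convention.
# Units: cm^-1 / (mol/L).  Compiled from standard in-vitro hemoglobin
# absorption spectra (Prahl-style tabulation), interpolated to the device
# wavelengths.  mua(lambda) = ln(10) * [eps_hbo2*C_HbO2 + eps_hhb*C_HHb],
# concentrations in mol/L.
wavelength_nm,eps_hbo2,eps_hhb
687,294.0,2180.0
785,735.0,1030.0
830,974.0,693.0
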