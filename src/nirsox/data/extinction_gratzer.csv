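# Hemoglobin extinction coefficients, Gratzer/Prahl compilation (v1).
# units: eps_* in cm^-1 uM^-1, base-10 (decadic) convention.
wavelength_nm,eps_hbo,eps_hb
730,0.000390,0.0011022
800,0.000816,0.00076172
850,0.001058,0.00069132
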