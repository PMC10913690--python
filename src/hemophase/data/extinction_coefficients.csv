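wavelength_nm,eps_hbo2,eps_hb,units,source
650,0.368,3.7501,1/(mM*cm),approximate values from the standard tabulated hemoglobin molar extinction compilation (base-10)
930,1.2140,0.7300,1/(mM*cm),approximate values from the standard tabulated hemoglobin molar extinction compilation (base-10)
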