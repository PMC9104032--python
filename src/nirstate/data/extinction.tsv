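# Molar extinction coefficients for oxy- and deoxy-hemoglobin, cm^-1 M^-1.
# Compiled values of W. B. Gratzer (Med. Res. Council Labs) and N. Kollias,
# as tabulated by S. Prahl (Oregon Medical Laser Center).
# wavelength_nm	eps_hbo	eps_hbr
760	586.00	1548.52
850	1058.00	691.32
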