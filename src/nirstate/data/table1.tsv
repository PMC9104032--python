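# Per-subject two-class decoding accuracy (%), calibration and online
# sessions; online entries missing for three subjects (recording errors).
subject	calibration	online
A	80	50
B	88
C	83	42
D	82	70
E	95	75
F	95	41
G	100	78
H	75	60
I	95
J	90	55
K	80
L	100	78
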