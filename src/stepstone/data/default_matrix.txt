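# Default residue-pair interaction matrix (reduced energy units).
# Derived from the Kyte-Doolittle hydropathy scale h_a via
#   eps(a, b) = -h_a * h_b / 10
# so like residues (hydrophobic-hydrophobic, polar-polar) attract and
# unlike pairs repel.  Symmetric by construction; fully pluggable.
A C D E F G H I K L M N P Q R S T V W Y
A -0.3240 -0.4500 0.6300 0.6300 -0.5040 0.0720 0.5760 -0.8100 0.7020 -0.6840 -0.3420 0.6300 0.2880 0.6300 0.8100 0.1440 0.1260 -0.7560 0.1620 0.2340
C -0.4500 -0.6250 0.8750 0.8750 -0.7000 0.1000 0.8000 -1.1250 0.9750 -0.9500 -0.4750 0.8750 0.4000 0.8750 1.1250 0.2000 0.1750 -1.0500 0.2250 0.3250
D 0.6300 0.8750 -1.2250 -1.2250 0.9800 -0.1400 -1.1200 1.5750 -1.3650 1.3300 0.6650 -1.2250 -0.5600 -1.2250 -1.5750 -0.2800 -0.2450 1.4700 -0.3150 -0.4550
E 0.6300 0.8750 -1.2250 -1.2250 0.9800 -0.1400 -1.1200 1.5750 -1.3650 1.3300 0.6650 -1.2250 -0.5600 -1.2250 -1.5750 -0.2800 -0.2450 1.4700 -0.3150 -0.4550
F -0.5040 -0.7000 0.9800 0.9800 -0.7840 0.1120 0.8960 -1.2600 1.0920 -1.0640 -0.5320 0.9800 0.4480 0.9800 1.2600 0.2240 0.1960 -1.1760 0.2520 0.3640
G 0.0720 0.1000 -0.1400 -0.1400 0.1120 -0.0160 -0.1280 0.1800 -0.1560 0.1520 0.0760 -0.1400 -0.0640 -0.1400 -0.1800 -0.0320 -0.0280 0.1680 -0.0360 -0.0520
H 0.5760 0.8000 -1.1200 -1.1200 0.8960 -0.1280 -1.0240 1.4400 -1.2480 1.2160 0.6080 -1.1200 -0.5120 -1.1200 -1.4400 -0.2560 -0.2240 1.3440 -0.2880 -0.4160
I -0.8100 -1.1250 1.5750 1.5750 -1.2600 0.1800 1.4400 -2.0250 1.7550 -1.7100 -0.8550 1.5750 0.7200 1.5750 2.0250 0.3600 0.3150 -1.8900 0.4050 0.5850
K 0.7020 0.9750 -1.3650 -1.3650 1.0920 -0.1560 -1.2480 1.7550 -1.5210 1.4820 0.7410 -1.3650 -0.6240 -1.3650 -1.7550 -0.3120 -0.2730 1.6380 -0.3510 -0.5070
L -0.6840 -0.9500 1.3300 1.3300 -1.0640 0.1520 1.2160 -1.7100 1.4820 -1.4440 -0.7220 1.3300 0.6080 1.3300 1.7100 0.3040 0.2660 -1.5960 0.3420 0.4940
M -0.3420 -0.4750 0.6650 0.6650 -0.5320 0.0760 0.6080 -0.8550 0.7410 -0.7220 -0.3610 0.6650 0.3040 0.6650 0.8550 0.1520 0.1330 -0.7980 0.1710 0.2470
N 0.6300 0.8750 -1.2250 -1.2250 0.9800 -0.1400 -1.1200 1.5750 -1.3650 1.3300 0.6650 -1.2250 -0.5600 -1.2250 -1.5750 -0.2800 -0.2450 1.4700 -0.3150 -0.4550
P 0.2880 0.4000 -0.5600 -0.5600 0.4480 -0.0640 -0.5120 0.7200 -0.6240 0.6080 0.3040 -0.5600 -0.2560 -0.5600 -0.7200 -0.1280 -0.1120 0.6720 -0.1440 -0.2080
Q 0.6300 0.8750 -1.2250 -1.2250 0.9800 -0.1400 -1.1200 1.5750 -1.3650 1.3300 0.6650 -1.2250 -0.5600 -1.2250 -1.5750 -0.2800 -0.2450 1.4700 -0.3150 -0.4550
R 0.8100 1.1250 -1.5750 -1.5750 1.2600 -0.1800 -1.4400 2.0250 -1.7550 1.7100 0.8550 -1.5750 -0.7200 -1.5750 -2.0250 -0.3600 -0.3150 1.8900 -0.4050 -0.5850
S 0.1440 0.2000 -0.2800 -0.2800 0.2240 -0.0320 -0.2560 0.3600 -0.3120 0.3040 0.1520 -0.2800 -0.1280 -0.2800 -0.3600 -0.0640 -0.0560 0.3360 -0.0720 -0.1040
T 0.1260 0.1750 -0.2450 -0.2450 0.1960 -0.0280 -0.2240 0.3150 -0.2730 0.2660 0.1330 -0.2450 -0.1120 -0.2450 -0.3150 -0.0560 -0.0490 0.2940 -0.0630 -0.0910
V -0.7560 -1.0500 1.4700 1.4700 -1.1760 0.1680 1.3440 -1.8900 1.6380 -1.5960 -0.7980 1.4700 0.6720 1.4700 1.8900 0.3360 0.2940 -1.7640 0.3780 0.5460
W 0.1620 0.2250 -0.3150 -0.3150 0.2520 -0.0360 -0.2880 0.4050 -0.3510 0.3420 0.1710 -0.3150 -0.1440 -0.3150 -0.4050 -0.0720 -0.0630 0.3780 -0.0810 -0.1170
Y 0.2340 0.3250 -0.4550 -0.4550 0.3640 -0.0520 -0.4160 0.5850 -0.5070 0.4940 0.2470 -0.4550 -0.2080 -0.4550 -0.5850 -0.1040 -0.0910 0.5460 -0.1170 -0.1690
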