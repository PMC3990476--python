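# Per-residue physicochemical properties (EMBOSS-data-style, whitespace table).
# hydropathy: Kyte-Doolittle hydropathy index (unitless)
# charge: formal side-chain charge at physiological pH, -1/0/+1 (His treated as neutral)
# polarity: side-chain polarity, binary 0/1
# vdw_volume: side-chain van der Waals volume (A^3)
# avg_mass: average mass of the free amino acid (Da) = average residue mass + H2O
# frequency: naturally occurring residue frequency (fraction; renormalized on load)
# residue hydropathy charge polarity vdw_volume avg_mass frequency
A  1.8  0 0  67  89.09404 0.0825
R -4.5  1 1 148 174.20274 0.0553
N -3.5  0 1  96 132.11904 0.0406
D -3.5 -1 1  91 133.10384 0.0545
C  2.5  0 0  86 121.15404 0.0137
Q -3.5  0 1 114 146.14594 0.0393
E -3.5 -1 1 109 147.13074 0.0675
G -0.4  0 0  48  75.06714 0.0707
H -3.2  0 1 118 155.15634 0.0227
I  4.5  0 0 124 131.17464 0.0596
L  3.8  0 0 124 131.17464 0.0966
K -3.9  1 1 135 146.18934 0.0584
M  1.9  0 0 124 149.20784 0.0242
F  2.8  0 0 135 165.19184 0.0386
P -1.6  0 0  90 115.13194 0.0470
S -0.8  0 1  73 105.09344 0.0656
T -0.7  0 1  93 119.12034 0.0534
W -0.9  0 0 163 204.22844 0.0108
Y -1.3  0 1 141 181.19124 0.0292
V  4.2  0 0 105 117.14784 0.0687
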