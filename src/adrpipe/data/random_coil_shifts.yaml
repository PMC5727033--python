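# Residue-type-typical chemical shifts (ppm) used by the synthetic-data
# generator: random-coil-style means for backbone 15N, 1HN, 13CA and 13CB.
#
# version: 1
#
# These are standard random-coil reference values (Wishart-style tables,
# rounded to 0.1 ppm).  They only have to be *typical*; the generator adds
# seeded per-residue jitter on top, so the exact means are a generator
# choice, not a measured quantity.  Proline carries no amide proton.

A: {N: 123.8, H: 8.24, CA: 52.5, CB: 19.1}
R: {N: 120.5, H: 8.23, CA: 56.0, CB: 30.9}
N: {N: 118.7, H: 8.40, CA: 53.1, CB: 38.9}
D: {N: 120.4, H: 8.34, CA: 54.2, CB: 41.1}
C: {N: 118.8, H: 8.32, CA: 58.2, CB: 28.0}
Q: {N: 119.8, H: 8.32, CA: 55.7, CB: 29.4}
E: {N: 120.2, H: 8.36, CA: 56.6, CB: 29.9}
G: {N: 108.8, H: 8.33, CA: 45.1}
H: {N: 118.2, H: 8.42, CA: 55.0, CB: 29.0}
I: {N: 119.9, H: 8.00, CA: 61.1, CB: 38.8}
L: {N: 121.8, H: 8.16, CA: 55.1, CB: 42.4}
K: {N: 120.4, H: 8.29, CA: 56.2, CB: 33.1}
M: {N: 119.6, H: 8.28, CA: 55.4, CB: 32.9}
F: {N: 120.3, H: 8.30, CA: 57.7, CB: 39.6}
P: {N: 135.0, CA: 63.3, CB: 32.1}
S: {N: 115.7, H: 8.31, CA: 58.3, CB: 63.8}
T: {N: 113.6, H: 8.15, CA: 61.8, CB: 69.8}
W: {N: 121.3, H: 8.25, CA: 57.5, CB: 29.6}
Y: {N: 120.3, H: 8.12, CA: 57.9, CB: 38.8}
V: {N: 119.2, H: 8.03, CA: 62.2, CB: 32.9}
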