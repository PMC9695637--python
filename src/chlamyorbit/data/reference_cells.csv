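# Published per-cell angular velocity and revolution radius of monoflagellate
# C. reinhardtii, measured by high-speed video tracking of the cell center.
cell,omega_rad_s,R_um
1,28.81,0.89
2,34.42,0.84
3,24.05,0.80
4,33.66,1.43
5,23.91,0.68
6,18.52,0.98
7,28.57,1.59
8,16.87,1.55
9,9.48,1.87
10,16.36,1.07
11,15.81,0.99
12,22.54,1.23
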