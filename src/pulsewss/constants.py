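"""Reference physical constants shared across the package.

Blood is treated as an incompressible fluid with the high-shear (Newtonian
reference) viscosity of the rheology table.  The density below is the value
consistent with the tabulated Womersley numbers and Reynolds numbers of the
seven aneurysm cases; 1060 kg/m3, while common in the literature, is not.
"""

#: Blood density, kg/m3.
RHO_BLOOD = 1050.0

#: Newtonian reference (infinite-shear) dynamic viscosity, Pa*s.
MU_REFERENCE = 0.00345

#: Cardiac cycle period, s.
CARDIAC_PERIOD = 1.0

#: Canonical cycle-averaged inlet speed, m/s (back-computed from the mean
#: Reynolds numbers of the case table with the density above).
MEAN_INLET_SPEED = 0.0647

#: Peak-to-mean inlet speed ratio (ratio of peak to mean Reynolds number).
PEAK_TO_MEAN_RATIO = 4.483

#: Number of Fourier modes used when building Womersley inlet profiles.
N_FOURIER_MODES = 14

#: Default number of uniform time samples per cardiac cycle (0.005 s step).
N_TIME_SAMPLES = 200

#: Thrombus-prone thresholds: TAWSS below, OSI above, RRT above.
TAWSS_LOW_THRESHOLD = 0.4     # Pa
OSI_HIGH_THRESHOLD = 0.3      # dimensionless
RRT_HIGH_THRESHOLD = 10.0     # 1/Pa
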