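"""Independent 1-D radial quadrature oracle for spherically symmetric fields.

Brute-force trapezoidal integration with 1e5 radial points; deliberately
separate from the multicenter grid engine it cross-checks.
"""

import numpy as np

N_RADIAL = 100_000


def radial_integral(fn, rmax=40.0, n=N_RADIAL):
    """int_0^rmax fn(r) 4 pi r^2 dr by the trapezoid rule."""
    r = np.linspace(1e-10, rmax, n)
    return float(np.trapezoid(fn(r) * 4.0 * np.pi * r**2, r))
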