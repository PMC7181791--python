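"""Independent numerical oracle for cantilever deflection.

Two-pass trapezoidal integration of the Euler-Bernoulli curvature equation
v''(s) = M(s) / (E I) with a point load F at height a:
M(s) = F (a - s) for s < a and 0 above, v(0) = v'(0) = 0.

Kept independent of the package's closed form: only the geometry/material
numbers of the spec are used, in raw SI-consistent units.
"""

import numpy as np
from scipy.integrate import cumulative_trapezoid


def ode_deflection_um(force_un, spec, load_height_mm, measure_height_mm, n=4001):
    """Deflection (µm) at ``measure_height_mm`` by direct ODE integration."""
    s = np.union1d(np.linspace(0.0, spec.length_mm, n), [load_height_mm])
    ei = spec.youngs_modulus_mpa * (spec.width_mm * spec.thickness_mm**3 / 12.0)
    force_n = force_un * 1e-6
    moment = force_n * np.clip(load_height_mm - s, 0.0, None)
    slope = cumulative_trapezoid(moment / ei, s, initial=0.0)
    v_mm = cumulative_trapezoid(slope, s, initial=0.0)
    return float(np.interp(measure_height_mm, s, v_mm)) * 1e3
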