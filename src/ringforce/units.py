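"""Unit conventions and the single geometry/force unit conversion.

Convention used throughout the package:

* cantilever geometry (length, width, thickness, load heights) — millimetres
* elastic modulus — megapascals (1 MPa = 1 N/mm**2)
* measured displacement / deflection — micrometres
* force — micronewtons

Keeping geometry in mm and modulus in MPa matches how elastomer posts are
specified on the bench; deflections and forces are reported in the µm / µN
range actually measured.
"""

UM_PER_MM = 1_000.0

#: Deflection in µm produced by 1 µN acting through a beam "geometry factor"
#: of 1 mm**3 on a beam with E·I = 1 MPa·mm**4.  Derivation: with force in
#: newtons and lengths in mm, F·g / (E·I) has units
#: N·mm**3 / ((N/mm**2)·mm**4) = mm.  A µN is 1e-6 N and a mm is 1e3 µm, so
#: the µN/µm-scale factor is 1e-6 · 1e3 = 1e-3.
UM_PER_UN_GEOMETRY = 1e-3


def beam_deflection_um(
    force_un: float,
    geometry_mm3: float,
    youngs_modulus_mpa: float,
    second_moment_mm4: float,
) -> float:
    """Evaluate a linear-elastic beam deflection in micrometres.

    Parameters
    ----------
    force_un
        Applied point load, µN.
    geometry_mm3
        The load/measurement geometry factor of the Euler-Bernoulli solution
        (e.g. ``a**3 / 3`` for tip load measured at the tip), mm**3.
    youngs_modulus_mpa
        Young's modulus E, MPa.
    second_moment_mm4
        Second moment of area I of the cross-section, mm**4.

    Returns
    -------
    float
        Deflection in µm.
    """
    return UM_PER_UN_GEOMETRY * force_un * geometry_mm3 / (
        youngs_modulus_mpa * second_moment_mm4
    )
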