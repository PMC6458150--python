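"""Physical constants and tabulated material properties.

Viscosities of glycerol-water mixtures are taken from standard glycerine
tables (Glycerine Producers' Association, "Physical properties of glycerine
and its solutions", 1963; values at 25 degC), interpolated at the two mixing
ratios used for nanosphere phantoms.  Refractive indices follow the phantom
description: polystyrene 1.60, 90% glycerol 1.46, 70% glycerol 1.44,
sapphire substrate 1.77.
"""

BOLTZMANN_J_PER_K = 1.380649e-23

#: dynamic viscosity of glycerol-water (w/w) at 25 degC, Pa*s
GLYCEROL_VISCOSITY_PA_S = {
    90: 0.219,
    70: 0.0227,
}

#: refractive indices of phantom media at visible wavelengths
GLYCEROL_REFRACTIVE_INDEX = {
    90: 1.46,
    70: 1.44,
}

POLYSTYRENE_RI = 1.60
SAPPHIRE_RI = 1.77
WATER_VISCOSITY_25C_PA_S = 8.9e-4

DEFAULT_TEMPERATURE_K = 298.15


def fresnel_reflectance(n1: float, n2: float) -> float:
    """Normal-incidence intensity reflectance at an n1/n2 interface."""
    r = (n1 - n2) / (n1 + n2)
    return r * r
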