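import numpy as np
import pytest

from biosorb import SLMRGParams

# SLMRG parameter sets of the three adsorbents at the three study
# temperatures (steric exponent n, site density Nm mg/g, cohesion pressure a
# in 1e-23 J L/mg, co-volume b L/mg, energetic parameter w mg/L), together
# with the published saturation capacities they imply.
TABLE1 = {
    ("OWP", 293): dict(n=2.037, nm=50.391, a=8.46, b=0.0080, w=9.283),
    ("OWP", 303): dict(n=2.422, nm=45.050, a=8.47, b=0.0080, w=11.646),
    ("OWP", 313): dict(n=1.787, nm=73.937, a=8.48, b=0.0041, w=14.424),
    ("OWPSA", 293): dict(n=2.860, nm=44.712, a=8.75, b=0.0071, w=10.788),
    ("OWPSA", 303): dict(n=2.874, nm=48.622, a=8.60, b=0.0077, w=12.726),
    ("OWPSA", 313): dict(n=2.0020, nm=67.544, a=9.60, b=0.0096, w=9.032),
    ("alginate", 293): dict(n=0.696, nm=314.370, a=10.59, b=0.0084, w=70.965),
    ("alginate", 303): dict(n=0.614, nm=424.471, a=54.90, b=0.0084, w=12.481),
    ("alginate", 313): dict(n=0.481, nm=532.179, a=67.10, b=0.0087, w=38.338),
}

# Published equilibrium-constant series and the thermodynamic parameters
# derived from them (dH kJ/mol, dS kJ/(mol K), per-T dG kJ/mol).
THERMO_TABLE = {
    "OWP": dict(
        temperatures=(293.0, 303.0, 313.0),
        kads=(1.4981, 1.5442, 1.5887),
        dg=(-0.985, -1.095, -1.205),
        dh=2.2384,
        ds=0.011,
    ),
    "OWPSA": dict(
        temperatures=(293.0, 303.0, 313.0),
        kads=(1.6829, 2.0825, 2.5422),
        dg=(-1.268, -1.848, -2.428),
        dh=15.726,
        ds=0.058,
    ),
    "alginate": dict(
        temperatures=(293.0, 303.0, 313.0),
        kads=(1.2283, 1.4131, 1.6111),
        dg=(-0.501, -0.871, -1.241),
        dh=10.34,
        ds=0.037,
    ),
}

# Frontier-orbital energies (eV) and the published descriptor table derived
# from them: gap, chemical potential mu, electronegativity chi, hardness
# eta, electrophilicity omega, single-species charge-transfer index dNmax.
ORBITAL_TABLE = {
    "Cu2+": dict(e_homo=-17.855, e_lumo=-9.767, gap=8.088, mu=-13.811,
                 chi=13.811, eta=4.044, omega=23.582, dn_max=3.415),
    "alginate": dict(e_homo=-4.928, e_lumo=-0.525, gap=4.403, mu=-2.727,
                     chi=2.727, eta=2.201, omega=1.689, dn_max=1.239),
    "cellulose": dict(e_homo=-5.776, e_lumo=0.260, gap=6.036, mu=-2.758,
                      chi=2.758, eta=3.018, omega=1.260, dn_max=0.914),
    "hemicellulose": dict(e_homo=-4.626, e_lumo=-0.950, gap=3.677, mu=-2.788,
                          chi=2.788, eta=1.838, omega=2.114, dn_max=1.517),
    "lignin": dict(e_homo=-5.211, e_lumo=-3.110, gap=2.101, mu=-4.160,
                   chi=4.160, eta=1.050, omega=8.239, dn_max=3.960),
}

QSAT_TABLE = {
    ("OWP", 293): 102.647,
    ("OWP", 303): 109.111,
    ("OWP", 313): 132.125,
    ("OWPSA", 293): 127.869,
    ("OWPSA", 303): 139.755,
    ("OWPSA", 313): 135.224,
    ("alginate", 293): 218.707,
    ("alginate", 303): 260.497,
    ("alginate", 313): 256.085,
}


@pytest.fixture
def owp_293_params() -> SLMRGParams:
    return SLMRGParams(**TABLE1[("OWP", 293)])


@pytest.fixture
def ce_grid_owp():
    return np.geomspace(1.0, 0.8 / TABLE1[("OWP", 293)]["b"], 15)
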