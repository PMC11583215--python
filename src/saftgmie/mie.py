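"""Mie-potential primitives for the third-order Barker-Henderson perturbation
expansion of the monomer free energy.

The working quantities follow the standard high-temperature expansion for Mie
segments: the mean-value-theorem first-order term ``a1`` with its low-density
correction ``B``, the fluctuation term ``a2`` with its finite-density
correction factor ``chi``, the empirical third-order term ``a3``, and the
contact value of the Mie radial distribution function used by the chain term.
All routines are written to be transparent to complex arguments so that
volume and mole-number derivatives of the Helmholtz energy can be obtained by
complex-step differentiation.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

from .constants import K_B

# Effective packing fraction of the mean-value theorem: zeta_eff = c . [z, z^2, z^3, z^4]
# with c = A_ZETA @ [1, 1/lam, 1/lam^2, 1/lam^3].
A_ZETA = np.array(
    [
        [0.81096, 1.7888, -37.578, 92.284],
        [1.0205, -19.341, 151.26, -463.50],
        [-1.9057, 22.845, -228.14, 973.92],
        [1.0885, -6.1962, 106.98, -677.64],
    ]
)

# Rational-function coefficients of f_1..f_6 (chi and a3) and the f_7 row used
# by the second-order correction of the chain radial distribution function:
# f_k(alpha) = sum_{n=0..3} PHI[k-1, n] alpha^n / (1 + sum_{n=4..6} PHI[k-1, n] alpha^{n-3})
PHI = np.array(
    [
        [7.5365557, -359.44, 1550.9, -1.19932, -1911.28, 9236.9, 10.0],
        [-37.60463, 1825.6, -5070.1, 9.063632, 21390.175, -129430.0, 10.0],
        [71.745953, -3168.0, 6534.6, -17.9482, -51320.7, 357230.0, 0.57],
        [-46.83552, 1884.2, -3288.7, 11.34027, 37064.54, -315530.0, -6.7],
        [-2.467982, -0.82376, -0.90093, 20.52142, 1103.742, 1390.2, -8.0],
        [-0.50272, -3.1935, 3.7090, -7.46432, -228.161, -3566.65, 0.0],
        [8.0956883, 3.7090, 0.0, -0.57757, -0.15754, -0.00043102, 0.0],
    ]
)

# gamma_c correction of g2 (tanh switch): coefficients phi_{7,0..4} of the
# published table, i.e. the trailing column read across rows.
GAMMA_C = np.array([10.0, 10.0, 0.57, -6.7, -8.0])

# Dimensionless association kernel I(rho*, T*): lower-triangular polynomial
# fit, I = sum_{n,m} C_ASSOC[n, m] rho*^n T*^m.
C_ASSOC = np.zeros((11, 11))
_c_rows = [
    [0.0756425183020431, -0.128667137050961, 0.128350632316055,
     -0.0725321780970292, 0.0257782547511452, -0.00601170055221687,
     0.000933363147191978, -9.55607377143667e-05, 6.19576039900837e-06,
     -2.30466608213628e-07, 3.74605718435540e-09],
    [0.134228218276565, -0.182682168504886, 0.0771662412959262,
     -0.000717458641164565, -0.00872427344283170, 0.00297971836051287,
     -0.000484863997651451, 4.35262491516424e-05, -2.07789181640066e-06,
     4.13749349344802e-08],
    [-0.565116428942893, 1.00930692226792, -0.660166945915607,
     0.214492212294301, -0.0388462990166792, 0.00406016982985030,
     -0.000239515566373142, 7.25488368831468e-06, -8.58904640281928e-08],
    [-0.387336382687019, -0.211614570109503, 0.450442894490509,
     -0.176931752538907, 0.0317171522104923, -0.00291368915845693,
     0.000130193710011706, -2.14505500786531e-06],
    [2.13713180911797, -2.02798460133021, 0.336709255682693,
     0.00118106507393722, -0.00600058423301506, 0.000626343952584415,
     -2.03636395699819e-05],
    [-0.300527494795524, 2.89920714512243, -0.567134839686498,
     0.0518085125423494, -0.00239326776760414, 4.15107362643844e-05],
    [-6.21028065719194, -1.92883360342573, 0.284109761066570,
     -0.0157606767372364, 0.000368599073256615],
    [11.6083532818029, 0.742215544511197, -0.0823976531246117,
     0.00186167650098254],
    [-10.2632535542427, -0.125035689035085, 0.0114299144831867],
    [4.65297446837297, -0.00192518067137033],
    [-0.867296219639940],
]
for _n, _row in enumerate(_c_rows):
    C_ASSOC[_n, : len(_row)] = _row

_GL_X, _GL_W = leggauss(100)


def mie_prefactor(lam_r, lam_a):
    """C(lambda_r, lambda_a) normalising the Mie well depth to -epsilon."""
    lr, la = np.asarray(lam_r, float), np.asarray(lam_a, float)
    return lr / (lr - la) * (lr / la) ** (la / (lr - la))


def mie_potential(r, sigma, epsilon, lam_r, lam_a):
    """Mie pair potential u(r) in the units of ``epsilon``."""
    c = mie_prefactor(lam_r, lam_a)
    sr = sigma / r
    return c * epsilon * (sr ** lam_r - sr ** lam_a)


def bh_diameter(T, sigma, epsilon_K, lam_r, lam_a):
    """Barker-Henderson effective hard-sphere diameter.

    d(T) = int_0^sigma [1 - exp(-u(r)/kT)] dr, evaluated with a fixed
    100-point Gauss-Legendre rule. ``epsilon_K`` is epsilon/k_B in kelvin;
    ``sigma`` and the returned diameter share the same length unit.
    """
    sigma = np.atleast_1d(np.asarray(sigma, float))
    epsilon_K = np.atleast_1d(np.asarray(epsilon_K, float))
    lam_r = np.atleast_1d(np.asarray(lam_r, float))
    lam_a = np.atleast_1d(np.asarray(lam_a, float))
    # nodes on (0, sigma); integrand ~ 1 near r = 0 (hard core)
    r = 0.5 * sigma[:, None] * (_GL_X[None, :] + 1.0)
    with np.errstate(over="ignore", divide="ignore"):
        beta_u = np.where(
            r > 0,
            mie_potential(np.where(r > 0, r, 1.0), sigma[:, None],
                          epsilon_K[:, None], lam_r[:, None], lam_a[:, None]) / T,
            np.inf,
        )
        integrand = 1.0 - np.exp(-np.clip(beta_u, -700, 700))
    d = 0.5 * sigma * (integrand * _GL_W[None, :]).sum(axis=1)
    # epsilon = 0 switches off the whole (repulsion + dispersion) Mie
    # interaction; the hard-sphere fixture convention keeps d = sigma there
    d = np.where(epsilon_K > 0, d, sigma)
    out = np.where(sigma > 0, d, 0.0)
    return out if out.shape != (1,) else out[0]


def zeta_coeffs(lam):
    """c1..c4 of the effective packing fraction for exponent ``lam``."""
    lam = np.asarray(lam, float)
    inv = np.stack([np.ones_like(lam), 1 / lam, 1 / lam ** 2, 1 / lam ** 3])
    return np.tensordot(A_ZETA, inv, axes=([1], [0]))  # shape (4, ...)


def f_alpha(k, alpha):
    """Rational function f_k(alpha), k = 1..6."""
    p = PHI[k - 1]
    alpha = np.asarray(alpha, float)
    num = p[0] + p[1] * alpha + p[2] * alpha ** 2 + p[3] * alpha ** 3
    den = 1.0 + p[4] * alpha + p[5] * alpha ** 2 + p[6] * alpha ** 3
    return num / den


def s_channel(lam, c, x0, zeta_x, want_derivative=False):
    """Density-scaled sum (a1s + B)/(2 pi rho_s eps d^3) for one exponent.

    ``lam`` and ``x0`` are pair arrays, ``c`` the matching (4, ...) effective
    packing-fraction coefficients, ``zeta_x`` the (possibly complex) packing
    fraction. Returns ``s`` and, optionally, ``ds/dzeta_x``.
    """
    zeff = c[0] * zeta_x + c[1] * zeta_x ** 2 + c[2] * zeta_x ** 3 + c[3] * zeta_x ** 4
    one = 1.0 - zeff
    p = -(1.0 / (lam - 3.0)) * (1.0 - zeff / 2.0) / one ** 3
    I = -(x0 ** (3.0 - lam) - 1.0) / (lam - 3.0)
    J = -(x0 ** (4.0 - lam) * (lam - 3.0) - x0 ** (3.0 - lam) * (lam - 4.0) - 1.0) / (
        (lam - 3.0) * (lam - 4.0)
    )
    onex = 1.0 - zeta_x
    q = (1.0 - zeta_x / 2.0) / onex ** 3 * I - 4.5 * zeta_x * (1.0 + zeta_x) / onex ** 3 * J
    s = p + q
    if not want_derivative:
        return s
    dzeff = c[0] + 2 * c[1] * zeta_x + 3 * c[2] * zeta_x ** 2 + 4 * c[3] * zeta_x ** 3
    dp = -(1.0 / (lam - 3.0)) * (2.5 - zeff) / one ** 4 * dzeff
    dq = (I * (2.5 - zeta_x) - 4.5 * J * (1.0 + 4.0 * zeta_x + zeta_x ** 2)) / onex ** 4
    return s, dp + dq


def k_hs(zeta_x, want_derivative=False):
    """Isothermal-compressibility factor of the hard-sphere reference."""
    q = 1.0 + 4.0 * zeta_x + 4.0 * zeta_x ** 2 - 4.0 * zeta_x ** 3 + zeta_x ** 4
    k = (1.0 - zeta_x) ** 4 / q
    if not want_derivative:
        return k
    dq = 4.0 + 8.0 * zeta_x - 12.0 * zeta_x ** 2 + 4.0 * zeta_x ** 3
    dk = (-4.0 * (1.0 - zeta_x) ** 3 * q - (1.0 - zeta_x) ** 4 * dq) / q ** 2
    return k, dk


def g_hs_contact(x0, zeta_x):
    """Contact value of the hard-sphere RDF at the averaged diameter."""
    one = 1.0 - zeta_x
    k0 = -np.log(one) + (42.0 * zeta_x - 39.0 * zeta_x ** 2 + 9.0 * zeta_x ** 3
                         - 2.0 * zeta_x ** 4) / (6.0 * one ** 3)
    k1 = (zeta_x ** 4 + 6.0 * zeta_x ** 2 - 12.0 * zeta_x) / (2.0 * one ** 3)
    k2 = -3.0 * zeta_x ** 2 / (8.0 * one ** 2)
    k3 = (-zeta_x ** 4 + 3.0 * zeta_x ** 2 + 3.0 * zeta_x) / (6.0 * one ** 3)
    return np.exp(k0 + k1 * x0 + k2 * x0 ** 2 + k3 * x0 ** 3)


def association_kernel(rho_star, t_star):
    """Dimensionless bonding integral I(rho*, T*) of the association term.

    ``rho_star`` is a scalar reduced segment density (complex-safe);
    ``t_star`` an array of pair reduced temperatures of any shape.
    """
    n = np.arange(11)
    rp = rho_star ** n  # (11,)
    t = np.asarray(t_star)
    tp = t[..., None] ** n  # (..., 11)
    return (tp * (rp @ C_ASSOC)).sum(axis=-1)
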