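"""Electrostatic free-energy contributions for charged groups.

Ion-ion Coulomb interactions use the mean spherical approximation (MSA) for
an arbitrary mixture of charged hard spheres, with the screening parameter
Gamma obtained from its implicit closure; ion-solvent interactions use the
classical Born charging energy of a spherical cavity in a dielectric
continuum whose relative static permittivity follows a density- and
temperature-explicit solvent model.

Non-spherical charged chain species are mapped onto equivalent-volume
spheres, either group-wise (Model G: each charged group becomes a sphere,
neutral groups do not contribute) or molecule-wise (Model M: the whole chain
becomes one sphere carrying the net charge). Zwitterions - species with a
zero net charge - contribute nothing to either term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM3, E_CHARGE, EPS_0, K_B, N_A, PI


@dataclass
class IonMapping:
    """Spherical-entity view of the charged species.

    ``counts[e, i]`` is the number of entities of type ``e`` contributed by
    one molecule of component ``i`` (zero for components without net charge).
    """

    mode: str
    entities: list
    charges: np.ndarray
    sigma_msa: np.ndarray   # m
    sigma_born: np.ndarray  # m
    counts: np.ndarray      # (n_entities, n_components)


@dataclass
class ScreeningState:
    gamma: float      # 1/m
    delta: float
    p_n: float
    omega: float
    kappa_debye: float


def map_ions(components, specs, nu, mode="G") -> IonMapping:
    """Build the equal-volume sphere mapping of the charged species."""
    from .constants import ANGSTROM

    nc = len(components)
    z_comp = np.array([c.net_charge for c in components], float)
    entities, charges, s_msa, s_born, counts = [], [], [], [], []
    if mode == "G":
        for k, g in enumerate(specs):
            if g.charge == 0:
                continue
            row = np.where(z_comp != 0, nu[:, k], 0.0)
            if not row.any():
                continue
            entities.append(g.name)
            charges.append(float(g.charge))
            scale = g.nu_star ** (1.0 / 3.0)
            s_msa.append(scale * g.sigma * ANGSTROM)
            s_born.append(scale * g.sigma_born * ANGSTROM)
            counts.append(row)
    elif mode == "M":
        for i, comp in enumerate(components):
            if z_comp[i] == 0:
                continue
            v_msa = 0.0
            v_born = 0.0
            for g, cnt in comp.groups:
                v_msa += cnt * g.nu_star * (g.sigma * ANGSTROM) ** 3
                sb = g.sigma_born if g.charge != 0 else g.sigma
                v_born += cnt * g.nu_star * (sb * ANGSTROM) ** 3
            entities.append(comp.name)
            charges.append(z_comp[i])
            s_msa.append(v_msa ** (1.0 / 3.0))
            s_born.append(v_born ** (1.0 / 3.0))
            row = np.zeros(nc)
            row[i] = 1.0
            counts.append(row)
    else:
        raise ValueError("mode must be 'G' or 'M'")
    return IonMapping(
        mode=mode, entities=entities,
        charges=np.array(charges), sigma_msa=np.array(s_msa),
        sigma_born=np.array(s_born),
        counts=np.array(counts).reshape(len(entities), nc),
    )


def relative_permittivity(T, V, n, components, solvent_idx):
    """D(T, rho_solv, x') from the solvent dielectric coefficients.

    Only solvent species (no charged groups, not zwitterions) contribute;
    their salt-free mole fractions weight the pairwise-averaged coefficient
    d_ij = (d_ii + d_jj)/2 with d_ii = d_V (d_T / T - 1).
    """
    n = np.asarray(n)
    ns = np.array([n[i] for i in solvent_idx])
    total = ns.sum()
    if np.abs(total) == 0:
        raise ValueError("no solvent amount present")
    xp = ns / total
    d_ii = []
    for i in solvent_idx:
        c = components[i]
        if c.dielectric_dV is None or c.dielectric_dT is None:
            raise ValueError(f"solvent {c.name} lacks dielectric coefficients")
        d_ii.append(c.dielectric_dV * ANGSTROM3 * (c.dielectric_dT / T - 1.0))
    d_ii = np.array(d_ii)
    d_mix = 0.5 * (xp[:, None] * xp[None, :] * (d_ii[:, None] + d_ii[None, :])).sum()
    rho_solv = total * N_A / V
    return 1.0 + rho_solv * d_mix


def debye_kappa(rho_e, charges, D, T):
    """Inverse Debye length kappa_D (1/m) of the entity set."""
    return np.sqrt(
        E_CHARGE ** 2 * (rho_e * charges ** 2).sum() / (EPS_0 * D * K_B * T)
    )


def _msa_aux(gamma, rho_e, charges, sigma):
    delta = 1.0 - (PI / 6.0) * (rho_e * sigma ** 3).sum()
    denom = 1.0 + gamma * sigma
    omega = 1.0 + (PI / (2.0 * delta)) * (rho_e * sigma ** 3 / denom).sum()
    p_n = (rho_e * sigma * charges / denom).sum() / omega
    q_e = (charges - (PI / (2.0 * delta)) * p_n * sigma ** 2) / denom
    return delta, omega, p_n, q_e


def solve_screening(rho_e, charges, sigma, D, T, tol=1e-12, max_iter=200):
    """Solve the implicit MSA closure for the screening parameter Gamma.

    Fixed-point iteration Gamma = alpha/2 * sqrt(sum rho Q(Gamma)^2) from the
    Debye-Hueckel start Gamma_0 = kappa_D / 2; transparent to complex-valued
    densities (complex-step differentiation).
    """
    rho_e = np.asarray(rho_e)
    alpha2 = E_CHARGE ** 2 / (EPS_0 * D * K_B * T)
    kappa = np.sqrt(alpha2 * (rho_e * charges ** 2).sum())
    if np.abs(kappa) == 0:
        return ScreeningState(0.0, 1.0, 0.0, 1.0, 0.0)
    gamma = kappa / 2.0
    for it in range(max_iter):
        delta, omega, p_n, q_e = _msa_aux(gamma, rho_e, charges, sigma)
        gamma_new = 0.5 * np.sqrt(alpha2 * (rho_e * q_e ** 2).sum())
        err = np.abs(gamma_new - gamma) / np.abs(gamma_new)
        gamma = gamma_new
        if err < tol:
            break
    else:
        raise RuntimeError("MSA screening-length iteration did not converge")
    delta, omega, p_n, _ = _msa_aux(gamma, rho_e, charges, sigma)
    return ScreeningState(gamma, delta, p_n, omega, kappa)


def a_ion(rho_e, charges, sigma, D, T, scr: ScreeningState):
    """A_ion / (V k_B T) (per volume, dimensionless x m^-3)."""
    gamma = scr.gamma
    if np.abs(gamma) == 0:
        return 0.0
    denom = 1.0 + gamma * sigma
    u_msa_per_v = -(E_CHARGE ** 2 / (4.0 * PI * EPS_0 * D)) * (
        gamma * (rho_e * charges ** 2 / denom).sum()
        + (PI / (2.0 * scr.delta)) * scr.omega * scr.p_n ** 2
    )
    return u_msa_per_v / (K_B * T) + gamma ** 3 / (3.0 * PI)


def a_born(rho_e, charges, sigma_born, D, T):
    """A_Born / (V k_B T): classical charging energy of each ionic cavity,
    cavity radius sigma_born / 2."""
    if np.abs(D - 1.0) == 0:
        return 0.0
    return (
        -(E_CHARGE ** 2 / (4.0 * PI * EPS_0 * K_B * T)) * (1.0 - 1.0 / D)
        * (rho_e * charges ** 2 / sigma_born).sum()
    )
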