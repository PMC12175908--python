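import numpy as np
import pytest

from idpre.ensemble import Ensemble


def nerf_place(a, b, c, bond, angle, torsion):
    """Place a fourth atom from three reference atoms and internal coordinates.

    Standard natural-extension-of-reference-frame construction; ``angle`` and
    ``torsion`` in radians.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi, omega=np.pi):
    """Ideal polyalanine backbone (N, CA, C per residue) from φ/ψ lists.

    Independent oracle geometry for torsion extraction: residue i is built
    with torsions φ_i (C_{i-1}, N_i, CA_i, C_i) and ψ_i (N_i, CA_i, C_i,
    N_{i+1}).  Returns coords (n_atoms, 3), residue ids and atom names.
    """
    b_n_ca, b_ca_c, b_c_n = 1.458, 1.525, 1.329
    a_n_ca_c = np.deg2rad(111.2)
    a_ca_c_n = np.deg2rad(116.2)
    a_c_n_ca = np.deg2rad(121.7)
    n_res = len(phi_psi)
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([b_n_ca, 0.0, 0.0]),
    ]
    coords.append(
        coords[1]
        + b_ca_c * np.array([np.cos(np.pi - a_n_ca_c), np.sin(np.pi - a_n_ca_c), 0.0])
    )
    for i in range(1, n_res):
        phi, psi = phi_psi[i]
        psi_prev = phi_psi[i - 1][1]
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_new = nerf_place(n_prev, ca_prev, c_prev, b_c_n, a_ca_c_n, psi_prev)
        ca_new = nerf_place(ca_prev, c_prev, n_new, b_n_ca, a_c_n_ca, omega)
        c_new = nerf_place(c_prev, n_new, ca_new, b_ca_c, a_n_ca_c, phi)
        coords.extend([n_new, ca_new, c_new])
    res_ids = np.repeat(np.arange(1, n_res + 1), 3)
    atom_names = np.tile(["N", "CA", "C"], n_res)
    return np.array(coords), res_ids, atom_names


@pytest.fixture
def backbone_helix_ensemble():
    """Single-frame ideal α-helix backbone ensemble (φ=−57°, ψ=−47°)."""
    phi_psi = [(np.deg2rad(-57.0), np.deg2rad(-47.0))] * 12
    coords, res_ids, atom_names = build_backbone(phi_psi)
    return Ensemble(
        chains={"A": coords[None, :, :]},
        residue_numbers={"A": res_ids},
        atom_names={"A": atom_names},
    )


@pytest.fixture
def toy_two_chain_ensemble():
    """Deterministic random two-chain coarse ensemble for contact tests."""
    rng = np.random.default_rng(42)
    nf, na, nb = 20, 24, 12
    a = rng.uniform(0, 40, size=(nf, na, 3))
    b = rng.uniform(0, 40, size=(nf, nb, 3))
    return Ensemble(chains={"A": a, "B": b})
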