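"""Torsion extraction and corrected Shannon entropy estimation."""

import numpy as np
import pytest

from idpre.ensemble import Ensemble
from idpre.entropy import (
    GAS_CONSTANT,
    dihedral,
    entropy_contact_comparison,
    extract_torsions,
    residue_entropy_profile,
    torsion_entropy,
)


def uniform_angles(n_bins=35, repeats=100):
    centers = (np.arange(n_bins) + 0.5) / n_bins * 2 * np.pi - np.pi
    return np.tile(centers, repeats)


class TestTorsionEntropy:
    def test_uniform_closed_form(self):
        # S -> ln(n) - ln(h) = ln(35^2 / 2pi) = 5.273 nats as N -> inf
        s = torsion_entropy(uniform_angles(), correction="none")
        assert s == pytest.approx(np.log(35**2 / (2 * np.pi)), abs=1e-9)
        assert s == pytest.approx(5.273, abs=1e-3)

    def test_delta_closed_form(self):
        # all mass in one bin: S -> -ln(h) = 1.718 nats
        s = torsion_entropy(np.zeros(500), correction="none")
        assert s == pytest.approx(-np.log(2 * np.pi / 35), abs=1e-9)
        assert s == pytest.approx(1.718, abs=1e-3)

    def test_finite_sample_correction_as_printed(self):
        angles = uniform_angles(35, 100)[:1000]
        s = torsion_entropy(angles, n_frames=1000)
        s_none = torsion_entropy(angles, correction="none")
        assert s == pytest.approx(s_none - 34 / 2000, abs=1e-12)

    def test_miller_madow_adds_correction(self):
        angles = uniform_angles(35, 10)
        s_mm = torsion_entropy(angles, correction="miller-madow")
        s_ap = torsion_entropy(angles, correction="subtracted")
        n = angles.size
        assert s_mm - s_ap == pytest.approx(2 * 34 / (2 * n))

    def test_uniform_weights_reproduce_unweighted(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(-np.pi, np.pi, size=400)
        w = np.full(400, 1 / 400)
        assert torsion_entropy(angles, w) == pytest.approx(
            torsion_entropy(angles), abs=1e-12
        )

    def test_uniform_distribution_maximizes_entropy(self):
        rng = np.random.default_rng(5)
        s_uniform = torsion_entropy(uniform_angles(), correction="none")
        for _ in range(25):
            angles = rng.vonmises(rng.uniform(-3, 3), rng.uniform(0.1, 5), 2000)
            assert torsion_entropy(angles, correction="none") <= s_uniform + 1e-9

    def test_reweighting_moves_entropy(self):
        # concentrating weight on one angle value lowers the entropy
        angles = uniform_angles(35, 10)
        w = np.full(angles.size, 1e-6)
        w[0] = 1.0
        assert torsion_entropy(angles, w) < torsion_entropy(angles)


class TestExtractTorsions:
    def test_ideal_helix_backbone_angles(self, backbone_helix_ensemble):
        tors = extract_torsions(backbone_helix_ensemble, "A")
        for res in range(3, 10):
            assert np.rad2deg(tors.angles[res]["phi"][0]) == pytest.approx(
                -57.0, abs=0.5
            )
            assert np.rad2deg(tors.angles[res]["psi"][0]) == pytest.approx(
                -47.0, abs=0.5
            )

    def test_terminal_residues_partial(self, backbone_helix_ensemble):
        tors = extract_torsions(backbone_helix_ensemble, "A")
        assert "phi" not in tors.angles.get(1, {})
        assert "psi" in tors.angles[1]
        assert "psi" not in tors.angles[12]

    def test_coarse_chain_pseudo_dihedrals(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(6, 10, 3)) * 5
        ens = Ensemble(chains={"A": coords})
        tors = extract_torsions(ens, "A")
        # residues 2..8 (1-based) have a full 4-bead window
        assert sorted(tors.angles) == list(range(2, 9))
        assert all("eta" in v for v in tors.angles.values())

    def test_single_residue_chain_has_no_torsions(self):
        ens = Ensemble(chains={"A": np.zeros((2, 1, 3))})
        assert extract_torsions(ens, "A").angles == {}

    def test_dihedral_sign_convention(self):
        p0 = np.array([1.0, 0, 0])
        p1 = np.array([0.0, 0, 0])
        p2 = np.array([0.0, 1.0, 0])
        p3 = np.array([0.0, 1.0, 1.0])
        assert dihedral(p0, p1, p2, p3) == pytest.approx(-np.pi / 2)


class TestResidueProfile:
    def test_rt_conversion(self):
        # S = 1 nat -> RT at 310 K = 2.577 kJ/mol
        assert GAS_CONSTANT * 310 == pytest.approx(2.577, abs=1e-3)
        rng = np.random.default_rng(0)
        ens = Ensemble(chains={"A": rng.normal(size=(50, 8, 3)) * 8})
        tors = extract_torsions(ens, "A")
        prof = residue_entropy_profile(tors)
        assert np.allclose(
            prof.table["entropy_rt"], prof.table["entropy"] * GAS_CONSTANT * 310
        )

    def test_additivity_over_torsions(self, backbone_helix_ensemble):
        ens = backbone_helix_ensemble
        coords = np.repeat(ens.chains["A"], 30, axis=0)
        coords += np.random.default_rng(2).normal(scale=0.1, size=coords.shape)
        big = Ensemble(
            chains={"A": coords},
            residue_numbers=ens.residue_numbers,
            atom_names=ens.atom_names,
        )
        tors = extract_torsions(big, "A")
        prof = residue_entropy_profile(tors)
        for _, row in prof.table.iterrows():
            parts = sum(
                torsion_entropy(a, n_frames=tors.n_frames)
                for a in tors.angles[row["residue"]].values()
            )
            assert row["entropy"] == pytest.approx(parts)

    def test_frozen_residue_minimizes_profile(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(80, 10, 3)) * 6
        coords[:, 4:8] = coords[0, 4:8]  # beads 5-8 identical in every frame
        ens = Ensemble(chains={"A": coords})
        prof = residue_entropy_profile(extract_torsions(ens, "A"))
        tab = prof.table.set_index("residue")["entropy"]
        assert tab.loc[6] == tab.min()


class TestContactComparison:
    def _profile(self, entropies):
        import pandas as pd

        from idpre.entropy import EntropyProfile

        df = pd.DataFrame(
            {
                "residue": np.arange(1, len(entropies) + 1),
                "entropy": entropies,
                "entropy_rt": np.asarray(entropies) * GAS_CONSTANT * 310,
                "n_torsions": 1,
            }
        )
        return EntropyProfile(table=df, temperature=310.0)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        ent = rng.normal(5, 0.5, size=40)
        freq = {r: (0.1 if r <= 20 else 0.9) for r in range(1, 41)}
        # same entropy distribution in both groups
        out = entropy_contact_comparison(self._profile(ent), freq)
        assert out["p_value"] > 0.05
        assert out["significance"] == "NS"

    def test_planted_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        ent = rng.normal(5, 0.5, size=40)
        ent[20:] -= 2 * 0.5  # high-contact group lowered by 2 SD
        freq = {r: (0.1 if r <= 20 else 0.9) for r in range(1, 41)}
        out = entropy_contact_comparison(self._profile(ent), freq)
        assert out["p_value"] < 0.01
        assert out["significance"] == "**"

    def test_threshold_partition(self):
        ent = np.linspace(4, 6, 10)
        freq = {r: f for r, f in zip(range(1, 11), np.linspace(0, 1, 10))}
        out = entropy_contact_comparison(self._profile(ent), freq, low=0.2,
                                         high=0.6)
        assert out["n_low"] == sum(1 for v in freq.values() if v < 0.2)
        assert out["n_high"] == sum(1 for v in freq.values() if v > 0.6)

    def test_small_group_skipped(self):
        ent = np.full(5, 5.0)
        freq = {1: 0.1, 2: 0.9, 3: 0.9, 4: 0.9, 5: 0.9}
        out = entropy_contact_comparison(self._profile(ent), freq)
        assert out["significance"] == "skipped"
        assert not out["tested"]
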