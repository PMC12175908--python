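"""Ground-truth ensemble generator and synthetic observables."""

import numpy as np
import pytest

from idpre.landscape import radius_of_gyration
from idpre.pre import PhysicalConstants
from idpre.synthetic import (
    ChainSpec,
    ComplexStateSpec,
    GenerationError,
    GroundTruth,
    build_receptor,
    default_sites,
    default_states,
    sample_apo_ensemble,
    sample_complex_ensemble,
    synthesize_pre,
    synthesize_titration,
)
from idpre.titration import fraction_bound


class TestChainSpec:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ChainSpec(length=50, helical_segments={"a": (3, 14), "b": (10, 20)})

    def test_out_of_range_segment_rejected(self):
        with pytest.raises(ValueError):
            ChainSpec(length=10, helical_segments={"a": (5, 14)})


class TestApoSampler:
    def test_single_bead_chain_has_zero_rg(self):
        ens = sample_apo_ensemble(
            ChainSpec(length=1, helical_segments={}), 5, seed=0
        )
        rg, _ = radius_of_gyration(ens)
        assert np.allclose(rg, 0.0)

    def test_two_bead_chain_rg_is_half_bond(self):
        ens = sample_apo_ensemble(
            ChainSpec(length=2, helical_segments={}), 8, seed=0
        )
        rg, _ = radius_of_gyration(ens)
        assert np.allclose(rg, 1.9, atol=1e-9)

    def test_deterministic_under_seed(self):
        spec = ChainSpec(length=40, helical_segments={"a": (10, 18)})
        e1 = sample_apo_ensemble(spec, 6, seed=11)
        e2 = sample_apo_ensemble(spec, 6, seed=11)
        assert np.array_equal(e1.chains["A"], e2.chains["A"])

    def test_bond_lengths_fixed(self):
        ens = sample_apo_ensemble(
            ChainSpec(length=60, helical_segments={"h": (20, 31)}), 5, seed=2
        )
        bl = np.linalg.norm(np.diff(ens.chains["A"], axis=1), axis=2)
        assert np.allclose(bl, 3.8, atol=0.05)

    def test_excluded_volume_respected(self):
        spec = ChainSpec(length=50, excluded_volume_radius=2.0,
                         helical_segments={})
        ens = sample_apo_ensemble(spec, 5, seed=3)
        x = ens.chains["A"]
        d = np.linalg.norm(x[:, :, None, :] - x[:, None, :, :], axis=-1)
        i, j = np.triu_indices(50, k=2)
        assert d[:, i, j].min() >= 2 * spec.excluded_volume_radius - 1e-9

    def test_helical_segment_is_helix_like(self):
        spec = ChainSpec(length=60, helical_segments={"h": (20, 31)})
        ens = sample_apo_ensemble(spec, 4, seed=5)
        seg = ens.chains["A"][:, 19:31]
        d13 = np.linalg.norm(seg[:, 3:] - seg[:, :-3], axis=2)
        # i,i+3 Cα distance in an α-helix is ~5 Å, far below extended ~11 Å
        assert d13.max() < 7.0

    def test_mean_rg_in_configured_band(self):
        ens = sample_apo_ensemble(ChainSpec(), 120, seed=1)
        _, summ = radius_of_gyration(ens)
        assert 52.0 <= summ["all"]["mean"] <= 59.0

    def test_infeasible_excluded_volume_raises(self):
        # hard-sphere diameter far above the bond length is unsatisfiable
        spec = ChainSpec(length=30, excluded_volume_radius=4.0,
                         helical_segments={})
        with pytest.raises(GenerationError, match="excluded-volume"):
            sample_apo_ensemble(spec, 3, seed=0, max_rounds=2)


class TestComplexSampler:
    def test_state_spec_invariants(self):
        with pytest.raises(ValueError, match="two motifs"):
            ComplexStateSpec("X", {"LD2": "a2a3"})
        with pytest.raises(ValueError, match="distinct faces"):
            ComplexStateSpec("X", {"LD2": "a2a3", "LD1": "a2a3"})

    def test_single_state_labels(self):
        truth = GroundTruth(state_weights={"I": 1.0})
        ens = sample_complex_ensemble(
            ChainSpec(), [default_states()[0]], truth, 5
        )
        assert set(ens.states) == {"I"}

    def test_equal_truth_weights_aggregate_to_quarter(self):
        truth = GroundTruth()
        ens = sample_complex_ensemble(ChainSpec(), default_states(), truth, 4)
        for s in "I II III IV".split():
            assert ens.true_weights[ens.states == s].sum() == pytest.approx(0.25)
        assert ens.true_weights.sum() == pytest.approx(1.0)

    def test_anchored_motifs_near_receptor_sites(self):
        truth = GroundTruth()
        receptor = build_receptor()
        ens = sample_complex_ensemble(
            ChainSpec(), default_states(), truth, 5, receptor=receptor
        )
        chain = ChainSpec()
        for spec_state in default_states():
            frames = np.flatnonzero(ens.states == spec_state.state_id)
            for motif, face in spec_state.anchored_motifs.items():
                s, e = chain.helical_segments[motif]
                mids = ens.chains["A"][frames, s - 1 : e].mean(axis=1)
                off = np.linalg.norm(mids - receptor.anchor_sites[face], axis=1)
                assert off.max() < 2.5

    def test_unknown_motif_raises_with_state_id(self):
        truth = GroundTruth(state_weights={"Z": 1.0})
        bad = ComplexStateSpec("Z", {"LD9": "a1a4", "LD2": "a2a3"})
        with pytest.raises(GenerationError, match="state Z"):
            sample_complex_ensemble(ChainSpec(), [bad], truth, 2)

    def test_deterministic_under_seed(self):
        truth = GroundTruth(seed=9)
        e1 = sample_complex_ensemble(ChainSpec(), default_states()[:2], truth, 3)
        e2 = sample_complex_ensemble(ChainSpec(), default_states()[:2], truth, 3)
        assert np.array_equal(e1.chains["A"], e2.chains["A"])

    def test_complex_rg_near_scattering_target(self):
        truth = GroundTruth(seed=4)
        ens = sample_complex_ensemble(ChainSpec(), default_states(), truth, 40)
        _, summ = radius_of_gyration(ens, weights=ens.true_weights)
        assert summ["all"]["mean"] == pytest.approx(35.0, rel=0.10)


class TestSynthesizePRE:
    def test_zero_noise_is_forward_model_fixed_point(self):
        truth = GroundTruth(noise_sd=0.0, seed=2)
        ens = sample_complex_ensemble(
            ChainSpec(length=40, helical_segments={"LD2": (10, 17), "LD1": (25, 32)}),
            [ComplexStateSpec("I", {"LD2": "a2a3", "LD1": "a1a4"})],
            truth,
            6,
        )
        out = synthesize_pre(ens, default_sites()[:2], truth, PhysicalConstants())
        assert np.allclose(out.table["ratio"], out.table["true_ratio"])
        assert set(out.gamma2) == {"B984", "B1006"}
        assert out.gamma2["B984"].shape == (40, 6)

    def test_noise_is_multiplicative_and_clipped(self):
        truth = GroundTruth(noise_sd=0.3, seed=2)
        ens = sample_complex_ensemble(
            ChainSpec(length=40, helical_segments={"LD2": (10, 17), "LD1": (25, 32)}),
            [ComplexStateSpec("I", {"LD2": "a2a3", "LD1": "a1a4"})],
            truth,
            6,
        )
        out = synthesize_pre(ens, default_sites()[:1], truth, PhysicalConstants())
        assert (out.table["ratio"] <= 1.2).all()
        assert (out.table["ratio"] >= 0.0).all()
        assert not np.allclose(out.table["ratio"], out.table["true_ratio"])


class TestSynthesizeTitration:
    def test_zero_noise_matches_isotherm(self):
        series = synthesize_titration({"LD2": 7.0}, noise_sd=0.0, seed=0)
        grp = series.data[series.data["residue"] == 144]
        expect = 1 - fraction_bound(grp["ligand_conc"].to_numpy(), 100.0, 7.0)
        assert np.allclose(grp["ratio"], expect)

    def test_non_increasing_series_rejected(self):
        with pytest.raises(ValueError):
            synthesize_titration({"LD2": 7.0}, ligand_series=(10, 10, 20))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            synthesize_titration({"LD2": 7.0}, ligand_series=(0, 10))


def test_ground_truth_validation():
    with pytest.raises(ValueError):
        GroundTruth(state_weights={"I": 0.5, "II": 0.2})
    with pytest.raises(ValueError):
        GroundTruth(noise_sd=-0.1)


def test_default_sites_match_receptor_numbering():
    receptor = build_receptor()
    residues = set(receptor.residue_numbers.tolist())
    assert {s.residue for s in default_sites()} <= residues
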