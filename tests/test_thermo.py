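"""Boltzmann weights, per-site substructure probabilities, structural entropy."""

import math

import numpy as np
import pandas as pd
import pytest

from aluedit.structure import parse_dot_bracket
from aluedit.thermo import (
    BODY_TEMPERATURE,
    GAS_CONSTANT,
    BoltzmannEnsemble,
    boltzmann_weights,
    ensemble_profiles,
    entropy_profile,
    structural_entropy,
    substructure_probabilities,
)

RT = GAS_CONSTANT * BODY_TEMPERATURE


class TestBoltzmannWeights:
    def test_equal_energies_split_evenly(self):
        assert np.allclose(boltzmann_weights([-10.0, -10.0]), [0.5, 0.5])

    def test_single_structure(self):
        assert np.allclose(boltzmann_weights([-10.0]), [1.0])

    def test_two_state_closed_form(self):
        g = -12.0
        w = boltzmann_weights([g, g + RT * math.log(2)])
        assert np.allclose(w, [2 / 3, 1 / 3])

    def test_energy_offset_invariance(self):
        g = np.array([-10.0, -8.5, -8.0])
        assert np.allclose(boltzmann_weights(g), boltzmann_weights(g + 123.4))

    def test_temperature_limits(self):
        g = [-10.0, -9.0, -5.0]
        hot = boltzmann_weights(g, temperature=1e9)
        assert np.allclose(hot, 1 / 3, atol=1e-6)
        cold = boltzmann_weights(g, temperature=1e-2)
        assert cold[0] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_weights([])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = boltzmann_weights(rng.normal(-20, 5, size=rng.integers(1, 12)))
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()


def two_fold_ensemble(seq="GGGAAAACCC", db1="(((....)))", db2="..........",
                      energies=(-5.0, -5.0)):
    pts = [
        parse_dot_bracket(seq, db, energy=e, structure_id=f"s{i}")
        for i, (db, e) in enumerate(zip([db1, db2], energies))
    ]
    return BoltzmannEnsemble(pts)


class TestSubstructureProbabilities:
    def test_site_always_helix(self):
        ens = two_fold_ensemble(db2="(((....)))")
        p = substructure_probabilities(ens, 1)
        assert p["helix"] == pytest.approx(1.0)
        assert sum(p.values()) == pytest.approx(1.0)

    def test_two_equal_weight_folds(self):
        ens = two_fold_ensemble()  # helix vs exterior strand at position 1
        p = substructure_probabilities(ens, 1)
        assert p["helix"] == pytest.approx(0.5)
        assert p["strand"] == pytest.approx(0.5)

    def test_three_folds_weighted_indicator_sum(self):
        seq = "GGGAAAACCC"
        g = -8.0
        energies = [g, g + RT * math.log(2), g + RT * math.log(2)]
        pts = [
            parse_dot_bracket(seq, db, energy=e, structure_id=str(i))
            for i, (db, e) in enumerate(
                zip(["(((....)))", "(((....)))", ".((....))."], energies)
            )
        ]
        ens = BoltzmannEnsemble(pts)
        p = substructure_probabilities(ens, 1)  # helix, helix, strand
        assert p["helix"] == pytest.approx(0.75)
        assert p["strand"] == pytest.approx(0.25)

    def test_mismatched_sequences_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannEnsemble(
                [
                    parse_dot_bracket("AAAA", "....", energy=-1.0),
                    parse_dot_bracket("AAAAA", ".....", energy=-1.0),
                ]
            )

    def test_out_of_range_site(self):
        with pytest.raises(IndexError):
            substructure_probabilities(two_fold_ensemble(), 11)


class TestStructuralEntropy:
    def test_pure_state_is_zero(self):
        assert structural_entropy((1, 0, 0, 0, 0, 0)) == 0.0

    def test_two_state_is_ln2(self):
        h = structural_entropy((0.5, 0.5, 0, 0, 0, 0))
        assert h == pytest.approx(math.log(2))
        assert round(h, 1) == 0.7

    def test_uniform_is_ln6(self):
        assert structural_entropy([1 / 6] * 6) == pytest.approx(math.log(6))

    def test_accepts_kind_dict(self):
        assert structural_entropy({"helix": 0.5, "interior": 0.5}) == pytest.approx(
            math.log(2)
        )

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            structural_entropy((0.5, 0.4, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            structural_entropy((1.5, -0.5, 0, 0, 0, 0))

    def test_bounds_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            h = structural_entropy(p)
            assert 0 <= h <= math.log(6) + 1e-12


class TestEnsembleProfiles:
    def test_offset_invariance_end_to_end(self):
        ens1 = two_fold_ensemble(energies=(-5.0, -4.0))
        ens2 = two_fold_ensemble(energies=(95.0, 96.0))
        p1 = ensemble_profiles(ens1, range(1, 11))
        p2 = ensemble_profiles(ens2, range(1, 11))
        pd.testing.assert_frame_equal(p1, p2)

    def test_ground_state_tie_breaks_to_first(self):
        ens = two_fold_ensemble(energies=(-5.0, -5.0))
        prof = ensemble_profiles(ens, [1])
        assert prof["ground_state_kind"].iloc[0] == "helix"

    def test_probabilities_sum_to_one(self):
        ens = two_fold_ensemble(energies=(-5.0, -4.2))
        prof = ensemble_profiles(ens, range(1, 11))
        psum = prof[[c for c in prof.columns if c.startswith("p_")]].sum(axis=1)
        assert np.allclose(psum, 1.0)


class TestEntropyProfile:
    @staticmethod
    def frame(entropies, edited, kind="helix"):
        return pd.DataFrame(
            {"entropy": entropies, "is_edited": edited, "ground_state_kind": kind}
        )

    def test_all_zero_entropy_single_bin(self):
        df = self.frame([0.0] * 40, [True] * 4 + [False] * 36)
        prof = entropy_profile(df, n_bins=5)
        assert len(prof) == 1
        assert prof["freq"].iloc[0] == pytest.approx(0.1)
        assert prof["flag"].iloc[0] == "unbinned"

    def test_two_bin_toy_exact_frequencies(self):
        low = self.frame([0.0] * 100, [True] * 10 + [False] * 90)
        high = self.frame([0.5] * 100, [True] * 5 + [False] * 95)
        prof = entropy_profile(pd.concat([low, high], ignore_index=True), n_bins=2)
        assert list(prof["freq"]) == [pytest.approx(0.10), pytest.approx(0.05)]
        assert list(prof["n_sites"]) == [100, 100]

    def test_strata_are_separate(self):
        df = pd.concat(
            [
                self.frame([0.0] * 10, [True] * 10, kind="helix"),
                self.frame([0.0] * 10, [False] * 10, kind="interior"),
            ],
            ignore_index=True,
        )
        prof = entropy_profile(df, n_bins=2)
        freqs = dict(zip(prof["stratum"], prof["freq"]))
        assert freqs == {"helix": 1.0, "interior": 0.0}
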