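"""Frequency, enrichment and contingency statistics."""

import numpy as np
import pandas as pd
import pytest

from aluedit.stats import (
    asymmetry_profile,
    bonferroni,
    enrichment_factors,
    frequency_by,
    load_reference_joint_table,
    neighbor_chi2,
    neighbor_enrichment,
    two_proportion_test,
    wilson_interval,
)


def sites_frame(n, n_edited, **columns):
    df = pd.DataFrame({"is_edited": [True] * n_edited + [False] * (n - n_edited)})
    for k, v in columns.items():
        df[k] = v
    return df


class TestFrequencyBy:
    def test_direct_count(self):
        df = sites_frame(62, 3, kind="helix")
        row = frequency_by(df, "kind").iloc[0]
        assert row["n_sites"] == 62 and row["n_edited"] == 3
        assert row["freq"] == pytest.approx(3 / 62)
        assert row["ci_low"] <= row["freq"] <= row["ci_high"]

    def test_zero_edited_group(self):
        row = frequency_by(sites_frame(50, 0, kind="bulge"), "kind").iloc[0]
        assert row["freq"] == 0.0
        assert row["ci_low"] == 0.0

    def test_multiple_keys(self):
        df = pd.concat(
            [
                sites_frame(10, 1, kind="helix", strand_len=5),
                sites_frame(20, 4, kind="helix", strand_len=6),
            ],
            ignore_index=True,
        )
        out = frequency_by(df, ["kind", "strand_len"])
        assert list(out["n_sites"]) == [10, 20]
        assert list(out["freq"]) == [pytest.approx(0.1), pytest.approx(0.2)]


class TestWilson:
    def test_coverage_at_small_p(self):
        """Wilson 95% CI covers the true proportion >= 93% of the time at
        n = 100, p = 0.05 (1000 seeded replicates)."""
        rng = np.random.default_rng(42)
        covered = 0
        for _ in range(1000):
            k = rng.binomial(100, 0.05)
            lo, hi = wilson_interval(int(k), 100)
            covered += lo <= 0.05 <= hi
        assert covered / 1000 >= 0.93

    def test_empty_group(self):
        lo, hi = wilson_interval(0, 0)
        assert np.isnan(lo) and np.isnan(hi)


class TestAsymmetryProfile:
    def test_uniform_editing_gives_unit_ratio(self):
        rows = []
        for asym in (-2, -1, 0, 1, 2):
            rows.append(
                sites_frame(100, 10, kind="interior", strand_len=2, asymmetry=asym)
            )
        prof = asymmetry_profile(pd.concat(rows, ignore_index=True))
        assert np.allclose(prof["normalized_freq"], 1.0)

    def test_strand_length_five_excluded(self):
        df = sites_frame(100, 10, kind="interior", strand_len=5, asymmetry=0)
        assert asymmetry_profile(df).empty

    def test_symmetric_boost_recovered(self):
        rows = [
            sites_frame(4000, 800, kind="interior", strand_len=1, asymmetry=0),
            sites_frame(4000, 400, kind="interior", strand_len=1, asymmetry=1),
        ]
        prof = asymmetry_profile(pd.concat(rows, ignore_index=True))
        by_asym = dict(zip(prof["asymmetry"], prof["normalized_freq"]))
        assert by_asym[0] / by_asym[1] == pytest.approx(2.0)


class TestEnrichment:
    def test_null_feature_enrichment_one(self):
        rng = np.random.default_rng(3)
        n = 8000
        df = pd.DataFrame(
            {
                "is_edited": rng.random(n) < 0.05,
                "kind": "helix",
                "up1": rng.choice(list("ACGT"), n),
            }
        )
        out = enrichment_factors(df, "up1", stratum="helix")
        assert np.allclose(out["enrichment"], 1.0, atol=0.25)

    def test_share_weighted_mean_is_one(self):
        rng = np.random.default_rng(4)
        n = 5000
        up1 = rng.choice(list("ACGT"), n, p=[0.1, 0.2, 0.3, 0.4])
        p = np.where(up1 == "T", 0.12, 0.04)
        df = pd.DataFrame(
            {"is_edited": rng.random(n) < p, "kind": "helix", "up1": up1}
        )
        out = enrichment_factors(df, "up1", stratum="helix")
        weighted = (out["enrichment"] * out["n_sites"]).sum() / out["n_sites"].sum()
        assert weighted == pytest.approx(1.0)

    def test_shared_baseline_consistency(self):
        rng = np.random.default_rng(5)
        n = 3000
        df = pd.DataFrame(
            {
                "is_edited": rng.random(n) < 0.1,
                "kind": "interior",
                "up1": rng.choice(list("ACGT"), n),
                "dn1": rng.choice(list("ACGT"), n),
                "op_nuc": rng.choice(["A", "C", "G", "undefined"], n),
            }
        )
        out = enrichment_factors(df, "joint_up_dn_op", stratum="interior", min_support=5)
        base = out["freq"] / out["enrichment"]
        base = base[out["enrichment"] > 0]
        assert np.allclose(base, base.iloc[0])
        # opNuc-undefined sites are excluded from the eligible set
        assert not out["context"].str.endswith("undefined").any()

    def test_low_support_flagged(self):
        df = sites_frame(30, 3, kind="helix", up1="T")
        out = enrichment_factors(df, "up1", stratum="helix", min_support=50)
        assert out["low_support"].all()


class TestNeighborChi2:
    def test_identical_distributions_zero(self):
        df = pd.concat(
            [
                sites_frame(40, 40, up1=list("ACGT") * 10),
                sites_frame(40, 0, up1=list("ACGT") * 10),
            ],
            ignore_index=True,
        )
        out = neighbor_chi2(df, offsets=[-1])
        assert out["chi2"].iloc[0] == pytest.approx(0.0)

    def test_disjoint_distributions_hand_value(self):
        # E1 = (10,0,0,0), E0 = (0,10,0,0) -> Pearson chi2 = 20
        df = pd.concat(
            [sites_frame(10, 10, dn1="A"), sites_frame(10, 0, dn1="C")],
            ignore_index=True,
        )
        out = neighbor_chi2(df, offsets=[1])
        assert out["chi2"].iloc[0] == pytest.approx(20.0)
        # expected cells are exactly 5, so the low-expected flag must not fire
        assert out["flag"].iloc[0] == ""
        small = pd.concat(
            [sites_frame(4, 4, dn1="A"), sites_frame(4, 0, dn1="C")],
            ignore_index=True,
        )
        assert neighbor_chi2(small, offsets=[1])["flag"].iloc[0] == "low_expected"

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "is_edited": rng.random(400) < 0.3,
                "up2": rng.choice(list("ACGT"), 400),
            }
        )
        a = neighbor_chi2(df, offsets=[-2])["chi2"].iloc[0]
        swapped = df.assign(is_edited=~df["is_edited"])
        b = neighbor_chi2(swapped, offsets=[-2])["chi2"].iloc[0]
        assert a == pytest.approx(b)

    def test_edge_sites_skipped_per_offset(self):
        df = pd.concat(
            [
                sites_frame(8, 4, up1=["A"] * 4 + [None] * 4),
            ],
            ignore_index=True,
        )
        out = neighbor_chi2(df, offsets=[-1])
        assert out["n_e1"].iloc[0] + out["n_e0"].iloc[0] == 4


class TestNeighborEnrichment:
    def test_baseline_share_weighted_unity(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "is_edited": rng.random(2000) < 0.05,
                "kind": "helix",
                "dn9": rng.choice(list("ACGT"), 2000),
            }
        )
        out = neighbor_enrichment(df, 9, stratum="helix")
        weighted = (out["enrichment"] * out["n_sites"]).sum() / out["n_sites"].sum()
        assert weighted == pytest.approx(1.0)


class TestTwoProportion:
    def test_printed_brain_comparison(self):
        assert two_proportion_test(1376, 2966, 452, 1076) == pytest.approx(
            0.013, abs=5e-4
        )

    def test_equal_proportions(self):
        assert two_proportion_test(50, 100, 50, 100) == 1.0

    def test_extreme_difference(self):
        assert two_proportion_test(0, 10, 10, 10) < 1e-4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_proportion_test(1, 0, 1, 2)
        with pytest.raises(ValueError):
            two_proportion_test(5, 4, 1, 2)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.013], m=1) == [0.013]
        assert bonferroni([0.013], m=4) == [pytest.approx(0.052)]
        assert bonferroni([0.5], m=3) == [1.0]

    def test_m_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


class TestReferenceTable:
    def test_loads_48_contexts(self):
        ref = load_reference_joint_table()
        assert len(ref) == 48
        assert set(["context", "freq", "enrichment", "n_sites"]) <= set(ref.columns)
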