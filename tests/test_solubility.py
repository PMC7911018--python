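"""Surrogate solubility profiles, structural correction and hotspots."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from nanograft import (
    compute_sasa,
    detect_hotspots,
    hotspot_report,
    intrinsic_profile,
    profile_from_scores,
    structural_correction,
)
from nanograft.solubility import KYTE_DOOLITTLE, _smooth
from nanograft.synthetic import (
    make_shielding_pair,
    make_structure,
    make_two_patch_fixture,
)


class TestIntrinsicProfile:
    def test_polyserine_more_soluble_than_polyvaline(self):
        seq = "S" * 20 + "V" * 20
        profile = intrinsic_profile(seq)
        assert profile[:20].mean() > profile[20:].mean()

    def test_uniform_sequence_gives_flat_profile(self):
        profile = intrinsic_profile("A" * 40)
        np.testing.assert_allclose(profile, 0.0, atol=1e-12)

    def test_profile_is_z_scaled(self):
        profile = intrinsic_profile("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ")
        assert profile.mean() == pytest.approx(0.0, abs=1e-9)
        assert profile.std() == pytest.approx(1.0, abs=1e-9)

    def test_rank_correlation_with_inverted_hydropathy_window(self):
        """The surrogate must stay recognisably hydropathy-driven."""
        rng = np.random.default_rng(17)
        alphabet = list(KYTE_DOOLITTLE)
        correlations = []
        for _ in range(10):
            seq = "".join(rng.choice(alphabet, size=80))
            surrogate = intrinsic_profile(seq)
            inverted_kd = _smooth(
                np.array([-KYTE_DOOLITTLE[a] for a in seq]), 7
            )
            correlations.append(spearmanr(surrogate, inverted_kd).statistic)
        assert min(correlations) >= 0.6

    def test_charge_term_responds_to_ph(self):
        # aspartate is charged (soluble) at pH 7 but neutral at pH 2
        assert intrinsic_profile("A" * 10 + "D" * 10)[15] > \
            intrinsic_profile("A" * 10 + "D" * 10, pH=2.0)[15]


class TestStructuralCorrection:
    def test_uniform_intrinsic_profile_stays_uniform(self):
        structure, _, _ = make_two_patch_fixture()
        corrected = structural_correction(
            structure, np.full(structure.n_residues, 0.7)
        )
        np.testing.assert_allclose(corrected.corrected, 0.7, atol=1e-12)

    def test_isolated_residues_keep_intrinsic_scores(self):
        ca = np.array([[0.0, 0, 0], [30.0, 0, 0]])
        structure = make_structure("FV", ca)
        intrinsic = np.array([-1.3, 0.4])
        profile = structural_correction(structure, intrinsic, patch_radius=10.0)
        np.testing.assert_allclose(profile.corrected, intrinsic, atol=1e-12)

    def test_matches_hand_computed_weighted_average(self):
        ca = np.array([[0.0, 0, 0], [5.0, 0, 0], [30.0, 0, 0]])
        structure = make_structure("FVS", ca)
        intrinsic = np.array([-2.0, 1.0, 0.5])
        sasa = compute_sasa(structure)
        w = np.maximum(sasa.relative, 0.1)
        profile = structural_correction(structure, intrinsic, sasa=sasa)
        expected_0 = (w[0] * -2.0 + w[1] * 1.0) / (w[0] + w[1])
        assert profile.corrected[0] == pytest.approx(expected_0, rel=1e-12)
        assert profile.corrected[2] == pytest.approx(0.5)

    def test_planted_poor_patch_drags_down_neighbours(self):
        structure, scores, truth = make_two_patch_fixture()
        intrinsic = np.asarray(scores)
        profile = structural_correction(structure, intrinsic)
        patch = [i for group in truth["memberships"] for i in group]
        background = [i for i in range(structure.n_residues)
                      if i not in patch and
                      min(abs(i - p) for p in patch) <= 2]
        assert profile.corrected[patch].mean() < profile.corrected[background].mean()

    def test_length_mismatch_rejected(self):
        structure, _, _ = make_two_patch_fixture()
        with pytest.raises(ValueError, match="residues"):
            structural_correction(structure, np.zeros(3))


class TestHotspots:
    def test_score_is_exact_sum_of_member_scores(self):
        structure, scores, _ = make_two_patch_fixture()
        profile = profile_from_scores(structure, scores)
        for hotspot in detect_hotspots(structure, profile):
            total = float(np.sum(profile.corrected[list(hotspot.members)]))
            assert hotspot.score == pytest.approx(total, rel=1e-12)

    def test_two_planted_patches_recovered_exactly(self):
        structure, scores, truth = make_two_patch_fixture()
        profile = profile_from_scores(structure, scores)
        hotspots = detect_hotspots(structure, profile)
        assert len(hotspots) == 2
        assert sorted(h.members for h in hotspots) == sorted(
            truth["memberships"]
        )

    def test_membership_monotone_in_hotspot_distance(self):
        structure, scores, _ = make_two_patch_fixture()
        profile = profile_from_scores(structure, scores)
        previous = None
        for distance in (3.0, 4.5, 6.0, 8.0, 12.0, 20.0):
            members = set()
            for h in detect_hotspots(structure, profile, hotspot_distance=distance):
                members |= set(h.members)
            if previous is not None:
                assert previous <= members
            previous = members

    def test_membership_matches_exhaustive_distance_oracle(self):
        structure, scores, _ = make_two_patch_fixture()
        profile = profile_from_scores(structure, scores)
        hotspots = detect_hotspots(structure, profile, hotspot_distance=6.0)
        detected = {i for h in hotspots for i in h.members}
        # oracle: all-pairs side-chain distance check, no spatial indexing
        exposed = profile.relative_sasa >= 0.25
        seeds = [i for i in range(structure.n_residues)
                 if exposed[i] and profile.corrected[i] < -1.0]
        oracle = set()
        for j in range(structure.n_residues):
            if not exposed[j]:
                continue
            for s in seeds:
                d = np.min(
                    np.linalg.norm(
                        structure.sidechain_coords(j)[:, None, :]
                        - structure.sidechain_coords(s)[None, :, :],
                        axis=-1,
                    )
                )
                if d <= 6.0:
                    oracle.add(j)
                    break
        assert detected == oracle

    def test_single_seed_without_neighbours_is_its_own_hotspot(self):
        ca = np.array([[0.0, 0, 0], [30.0, 0, 0], [60.0, 0, 0]])
        structure = make_structure("FSS", ca)
        profile = profile_from_scores(structure, np.array([-2.0, 0.5, 0.5]))
        hotspots = detect_hotspots(structure, profile)
        assert len(hotspots) == 1
        assert hotspots[0].members == (0,)
        assert hotspots[0].score == pytest.approx(profile.corrected[0])

    def test_close_seeds_merge_into_one_hotspot(self):
        ca = np.array([[0.0, 0, 0], [3.0, 0, 0], [40.0, 0, 0]])
        structure = make_structure("FFS", ca)
        profile = profile_from_scores(structure, np.array([-2.0, -1.8, 0.5]))
        hotspots = detect_hotspots(structure, profile)
        assert len(hotspots) == 1
        assert hotspots[0].members == (0, 1)
        assert hotspots[0].seeds == (0, 1)

    def test_no_seed_yields_empty_list(self):
        structure, scores, _ = make_two_patch_fixture()
        profile = profile_from_scores(structure, np.abs(scores))
        assert detect_hotspots(structure, profile) == []

    def test_hotspots_sorted_worst_first(self):
        structure, scores, _ = make_two_patch_fixture()
        scores = np.asarray(scores).copy()
        scores[4:7] = -3.0  # make the first patch clearly worse
        profile = profile_from_scores(structure, scores)
        hotspots = detect_hotspots(structure, profile)
        assert hotspots[0].score <= hotspots[1].score
        assert set(hotspots[0].members) == {4, 5, 6}

    def test_shielded_conformation_has_fewer_members(self):
        exposed, shielded, scores, _ = make_shielding_pair()
        n_exposed = sum(
            len(h)
            for h in detect_hotspots(
                exposed, profile_from_scores(exposed, scores)
            )
        )
        n_shielded = sum(
            len(h)
            for h in detect_hotspots(
                shielded, profile_from_scores(shielded, scores)
            )
        )
        assert n_shielded < n_exposed


class TestHotspotReport:
    def test_empty_hotspot_list_gives_header_only_table(self):
        structure, scores, _ = make_two_patch_fixture()
        profile = profile_from_scores(structure, np.abs(scores))
        report = hotspot_report({"X": (profile, [])})
        assert len(report) == 0
        assert list(report.columns[:4]) == [
            "construct", "hotspot", "score", "n_members"
        ]

    def test_two_constructs_two_hotspots_each(self):
        structure, scores, _ = make_two_patch_fixture()
        profile = profile_from_scores(structure, scores)
        hotspots = detect_hotspots(structure, profile)
        report = hotspot_report(
            {"A": (profile, hotspots), "B": (profile, hotspots)}
        )
        assert len(report) == 4
        assert set(report["hotspot"]) == {"hotspot1", "hotspot2"}
        assert set(report["score_source"]) == {"external"}

    def test_shielding_comparison_direction(self):
        """A conformation that buries a patch scores better (higher) on it."""
        exposed, shielded, scores, _ = make_shielding_pair()
        pe = profile_from_scores(exposed, scores)
        ps = profile_from_scores(shielded, scores)
        report = hotspot_report(
            {
                "exposed": (pe, detect_hotspots(exposed, pe)),
                "shielded": (ps, detect_hotspots(shielded, ps)),
            }
        )
        worst = report.groupby("construct")["score"].min()
        assert worst.get("shielded", 0.0) > worst["exposed"]
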