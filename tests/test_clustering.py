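"""Pairwise RMSD, the average-RMSD cutoff rule and gromos clustering."""

import numpy as np
import pytest
import biotite.structure as bst

from nanograft import (
    ConformationEnsemble,
    EnsembleError,
    auto_cutoff,
    gromos_cluster,
    rmsd_matrix,
    select_representatives,
)
from nanograft.clustering import kabsch_rmsd
from nanograft.synthetic import make_ensemble, make_structure


def brute_force_gromos(matrix, cutoff):
    """Literal greedy rule, written independently of the implementation."""
    matrix = np.asarray(matrix)
    remaining = list(range(len(matrix)))
    clusters = []
    while remaining:
        best, best_neighbors = None, None
        for i in remaining:
            neighbors = [
                j for j in remaining if j != i and matrix[i, j] <= cutoff
            ]
            if best is None or len(neighbors) > len(best_neighbors):
                best, best_neighbors = i, neighbors
        cluster = sorted([best] + best_neighbors)
        clusters.append((best, cluster))
        remaining = [i for i in remaining if i not in cluster]
    return clusters


def random_rmsd_matrix(rng, n):
    m = rng.uniform(0.1, 5.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestRmsdMatrix:
    def test_duplicate_conformations_have_zero_rmsd(self):
        ca = np.random.default_rng(0).uniform(0, 20, size=(10, 3))
        frames = [make_structure("A" * 10, ca) for _ in range(3)]
        matrix = rmsd_matrix(ConformationEnsemble.from_structures(frames))
        np.testing.assert_allclose(matrix, 0.0, atol=1e-9)

    def test_rigid_motion_is_removed_by_superposition(self):
        rng = np.random.default_rng(1)
        ca = rng.uniform(0, 20, size=(12, 3))
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        q *= np.sign(np.linalg.det(q))
        moved = ca @ q.T + np.array([5.0, -8.0, 3.0])
        frames = [make_structure("A" * 12, ca), make_structure("A" * 12, moved)]
        matrix = rmsd_matrix(ConformationEnsemble.from_structures(frames))
        assert matrix[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_independent_superposition_oracle(self):
        """Cross-check the closed-form Kabsch RMSD against biotite."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = rng.uniform(-10, 10, size=(7, 3))
            q = p + rng.normal(0, 1.5, size=p.shape)
            atoms_p = bst.AtomArray(7)
            atoms_p.coord = p
            atoms_q = bst.AtomArray(7)
            atoms_q.coord = q
            fitted, _ = bst.superimpose(atoms_p, atoms_q)
            expected = bst.rmsd(atoms_p, fitted)
            assert kabsch_rmsd(q, p) == pytest.approx(float(expected), rel=1e-6)

    def test_single_frame_rejected(self):
        ca = np.zeros((5, 3))
        ca[:, 0] = np.arange(5) * 7.0
        ensemble = ConformationEnsemble.from_structures(
            [make_structure("AAAAA", ca)]
        )
        with pytest.raises(EnsembleError):
            rmsd_matrix(ensemble)


class TestAutoCutoff:
    def test_uniform_matrix(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        assert auto_cutoff(m) == pytest.approx(2.0)

    def test_three_entry_mean(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[0, 2] = m[2, 0] = 2.0
        m[1, 2] = m[2, 1] = 3.0
        assert auto_cutoff(m) == pytest.approx(2.0)

    def test_matches_brute_force_upper_triangle_mean(self):
        rng = np.random.default_rng(7)
        m = random_rmsd_matrix(rng, 10)
        values = [m[i, j] for i in range(10) for j in range(i + 1, 10)]
        assert len(values) == 45
        assert auto_cutoff(m) == pytest.approx(np.mean(values))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            auto_cutoff(np.zeros((1, 1)))


class TestGromos:
    def test_identical_conformations_form_one_cluster(self):
        m = np.zeros((3, 3))
        result = gromos_cluster(m, cutoff=1.0)
        assert result.sizes == (3,)
        assert result.centers == (0,)  # lowest index on ties

    def test_two_separated_groups_recovered(self):
        n1, n2 = 6, 3
        n = n1 + n2
        m = np.full((n, n), 20.0)
        m[:n1, :n1] = 0.5
        m[n1:, n1:] = 0.5
        np.fill_diagonal(m, 0.0)
        result = gromos_cluster(m, cutoff=1.0)
        assert result.sizes == (6, 3)
        assert set(result.members(0)) == set(range(n1))
        assert set(result.members(1)) == set(range(n1, n))

    def test_oracle_equivalence_small_ensembles(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            m = random_rmsd_matrix(rng, n)
            cutoff = float(rng.uniform(0.5, 4.0))
            result = gromos_cluster(m, cutoff)
            expected = brute_force_gromos(m, cutoff)
            got = sorted(
                (result.centers[c], sorted(result.members(c)))
                for c in range(result.n_clusters)
            )
            assert got == sorted(expected)

    def test_greedy_property_on_random_matrices(self):
        """At extraction time no remaining frame beats the chosen center."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = 20
            m = random_rmsd_matrix(rng, n)
            cutoff = float(rng.uniform(1.0, 3.0))
            gromos_cluster(m, cutoff)  # must agree with the replay below
            removed = set()
            replay = brute_force_gromos(m, cutoff)
            for center, cluster in replay:
                candidates = set(range(n)) - removed
                counts = {
                    i: sum(
                        1 for j in candidates if j != i and m[i, j] <= cutoff
                    )
                    for i in candidates
                }
                assert counts[center] == max(counts.values())
                removed |= set(cluster)

    def test_sizes_sum_to_n_and_first_is_maximal(self):
        rng = np.random.default_rng(5)
        m = random_rmsd_matrix(rng, 15)
        result = gromos_cluster(m, 2.0)
        assert sum(result.sizes) == 15
        assert result.sizes[0] == max(result.sizes)
        assert np.all(np.bincount(result.labels) == np.array(result.sizes))

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            gromos_cluster(np.zeros((3, 3)), 0.0)


class TestPlantedBasins:
    def test_auto_cutoff_recovers_three_basins(self):
        ensemble, truth = make_ensemble(
            seed=42, n_frames=120, basin_proportions=(0.85, 0.10, 0.05)
        )
        matrix = rmsd_matrix(ensemble)
        result = gromos_cluster(matrix, auto_cutoff(matrix))
        assert result.n_clusters == 3
        assert 0.80 <= result.top_fraction() <= 0.90
        # recovered partition matches the planted basin labels exactly
        for cluster in range(3):
            planted = {truth["labels"][f] for f in result.members(cluster)}
            assert len(planted) == 1

    def test_representatives_deterministic_and_from_top_cluster(self):
        ensemble, truth = make_ensemble(seed=9, n_frames=60)
        matrix = rmsd_matrix(ensemble)
        result = gromos_cluster(matrix, auto_cutoff(matrix))
        reps_a, reference_a = select_representatives(ensemble, result)
        reps_b, reference_b = select_representatives(ensemble, result)
        np.testing.assert_array_equal(
            reference_a.atoms.coord, reference_b.atoms.coord
        )
        top_frame = result.centers[0]
        assert truth["labels"][top_frame] == truth["labels"][
            result.members(0)[0]
        ]
        single = [c for c, size in enumerate(result.sizes) if size == 1]
        for c in single:
            assert result.centers[c] == result.members(c)[0]
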