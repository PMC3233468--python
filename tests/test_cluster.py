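"""Connectivity clustering, hairpin populations, distance and SASA profiles."""

import numpy as np
import pytest

from remdens.cluster import (
    ConnectivityClustering,
    connectivity_cluster,
    distance_fe_profile,
    hairpin_population,
    hbond_distance_series,
    lvffa_sasa,
    pairwise_rmsd,
    rmsd_to_template_series,
    sasa_vs_distance,
)
from remdens.fes import R_GAS
from remdens.geometry import rmsd_ca
from remdens.synthetic import generate_ensemble, hairpin_template, spiked_hairpin_specs


class TestPairwiseRmsd:
    def test_identical_frames_zero_matrix(self, hairpin1_ref):
        from remdens.synthetic import Ensemble
        from remdens.geometry import default_topology

        an, ri, rn = default_topology()
        ens = Ensemble(np.repeat(hairpin1_ref.coords[None], 4, axis=0), an, ri, rn,
                       278.0, np.arange(4.0))
        M, idx = pairwise_rmsd(ens)
        assert np.allclose(M, 0.0, atol=1e-6)
        assert idx.tolist() == [0, 1, 2, 3]

    def test_symmetric_and_spot_checked(self, spiked_ensemble_small):
        ens, _ = spiked_ensemble_small
        M, idx = pairwise_rmsd(ens, stride=20)  # 50 frames
        assert np.allclose(M, M.T, atol=1e-12)
        rng = np.random.default_rng(1)
        ca = ens.ca_stack()[idx]
        for i, j in rng.integers(0, len(idx), size=(100, 2)):
            assert M[i, j] == pytest.approx(rmsd_ca(ca[i], ca[j]), abs=1e-8)

    def test_single_frame_is_1x1_zero(self, hairpin1_ref):
        from remdens.synthetic import Ensemble
        from remdens.geometry import default_topology

        an, ri, rn = default_topology()
        ens = Ensemble(hairpin1_ref.coords[None], an, ri, rn, 278.0, np.zeros(1))
        M, _ = pairwise_rmsd(ens)
        assert M.shape == (1, 1) and M[0, 0] == 0.0

    def test_invalid_stride(self, spiked_ensemble_small):
        with pytest.raises(ValueError):
            pairwise_rmsd(spiked_ensemble_small[0], stride=0)


class TestConnectivityClustering:
    def test_mutually_close_triple_one_cluster(self):
        D = np.full((3, 3), 0.05)
        np.fill_diagonal(D, 0.0)
        cs = connectivity_cluster(D, 0.15)
        assert cs.n_clusters == 1 and cs.populations[0] == 1.0

    def test_chained_frames_merge_by_connectivity(self):
        # A-B and B-C below cutoff, A-C above: still one cluster
        D = np.array([[0.0, 0.10, 0.28],
                      [0.10, 0.0, 0.10],
                      [0.28, 0.10, 0.0]])
        cs = connectivity_cluster(D, 0.15)
        assert cs.n_clusters == 1
        assert cs.representatives[0] == 1  # medoid is the bridging frame

    def test_far_frame_is_singleton(self):
        D = np.array([[0.0, 0.05, 0.9],
                      [0.05, 0.0, 0.9],
                      [0.9, 0.9, 0.0]])
        cs = connectivity_cluster(D, 0.15)
        assert cs.n_clusters == 2
        assert cs.populations.tolist() == [2 / 3, 1 / 3]

    def test_permutation_equivariance(self, spiked_ensemble_small):
        ens, _ = spiked_ensemble_small
        M, _ = pairwise_rmsd(ens, stride=10)
        labels = ConnectivityClustering(0.15).fit_predict(M)
        rng = np.random.default_rng(2)
        perm = rng.permutation(M.shape[0])
        labels_p = ConnectivityClustering(0.15).fit_predict(M[np.ix_(perm, perm)])
        # same partition: co-membership is preserved under the permutation
        co = labels[perm][:, None] == labels[perm][None, :]
        co_p = labels_p[:, None] == labels_p[None, :]
        assert (co == co_p).all()

    def test_populations_sum_to_one(self, spiked_ensemble_small):
        ens, _ = spiked_ensemble_small
        M, idx = pairwise_rmsd(ens, stride=5)
        cs = connectivity_cluster(M, 0.15, idx)
        assert cs.populations.sum() == pytest.approx(1.0)
        cs.validate()


class TestHairpinPopulation:
    def test_pure_hairpin_is_full_population(self, hairpin1_ref):
        spec, ref = hairpin_template("hairpin1")
        ens = generate_ensemble([spec.with_weight(1.0)], 50, 278.0, seed=40)
        M, idx = pairwise_rmsd(ens)
        cs = connectivity_cluster(M, 0.15, idx)
        assert hairpin_population(cs, ens, ref) == 1.0

    def test_spiked_fraction_recovered(self, spiked_ensemble_small):
        ens, ref = spiked_ensemble_small
        M, idx = pairwise_rmsd(ens)
        cs = connectivity_cluster(M, 0.15, idx)
        pop = hairpin_population(cs, ens, ref)
        true = (ens.provenance["labels"] == 0).mean()
        assert pop == pytest.approx(true, abs=0.01)

    @pytest.mark.parametrize("fraction", [0.04, 0.05, 0.07])
    def test_spike_levels_recovered_within_001(self, fraction):
        specs, ref = spiked_hairpin_specs("hairpin1", fraction)
        ens = generate_ensemble(specs, 2000, 278.0, seed=int(fraction * 1000))
        M, idx = pairwise_rmsd(ens)
        cs = connectivity_cluster(M, 0.15, idx)
        assert hairpin_population(cs, ens, ref) == pytest.approx(fraction, abs=0.01)

    def test_population_bounded_by_truth_cluster(self, spiked_ensemble_small):
        ens, ref = spiked_ensemble_small
        M, idx = pairwise_rmsd(ens)
        cs = connectivity_cluster(M, 0.15, idx)
        pop = hairpin_population(cs, ens, ref)
        labels_true = ens.provenance["labels"]
        clusters_with_hairpin = set(cs.labels[labels_true[idx] == 0])
        largest = max(cs.populations[c] for c in clusters_with_hairpin)
        assert pop <= largest + 1e-12

    def test_absent_template_gives_zero(self, hairpin2_ref):
        specs, _ = spiked_hairpin_specs("hairpin1", 0.2)
        ens = generate_ensemble(specs, 300, 278.0, seed=41)
        M, idx = pairwise_rmsd(ens)
        cs = connectivity_cluster(M, 0.15, idx)
        assert hairpin_population(cs, ens, hairpin2_ref) == 0.0


class TestTemplateSeries:
    def test_series_touches_zero_on_inserted_template(self, hairpin1_ref):
        spec, ref = hairpin_template("hairpin1")
        ens = generate_ensemble([spec.with_weight(1.0)], 10, 278.0, seed=42)
        ens.coords[3] = ref.coords
        series = rmsd_to_template_series(ens, ref)
        assert series[3] < 1e-6

    def test_cross_template_floor_above_cutoff(self, spiked_ensemble_small, hairpin2_ref):
        ens, _ = spiked_ensemble_small
        series = rmsd_to_template_series(ens, hairpin2_ref)
        assert series.min() > 0.15

    def test_own_template_floor_at_noise_scale(self, spiked_ensemble_small):
        ens, ref = spiked_ensemble_small
        series = rmsd_to_template_series(ens, ref)
        assert series.min() < 0.05


class TestHbondDistance:
    def test_hairpin1_turn_bond_closed(self, hairpin1_ref):
        from remdens.synthetic import Ensemble
        from remdens.geometry import default_topology

        an, ri, rn = default_topology()
        ens = Ensemble(hairpin1_ref.coords[None], an, ri, rn, 278.0, np.zeros(1))
        assert hbond_distance_series(ens, "hairpin1")[0] < 0.35

    def test_extended_chain_open(self, extended_conf):
        from remdens.synthetic import Ensemble
        from remdens.geometry import default_topology

        an, ri, rn = default_topology()
        ens = Ensemble(extended_conf.coords[None], an, ri, rn, 278.0, np.zeros(1))
        assert hbond_distance_series(ens, "hairpin1")[0] > 0.6
        assert hbond_distance_series(ens, "hairpin2")[0] > 0.6

    def test_translation_invariance(self, spiked_ensemble_small):
        ens, _ = spiked_ensemble_small
        d0 = hbond_distance_series(ens, "hairpin1")
        shifted = generate_shifted(ens, np.array([1.0, 2.0, -3.0]))
        assert np.allclose(hbond_distance_series(shifted, "hairpin1"), d0)

    def test_unknown_pair_rejected(self, spiked_ensemble_small):
        with pytest.raises(ValueError):
            hbond_distance_series(spiked_ensemble_small[0], "hairpin9")


def generate_shifted(ens, t):
    from remdens.synthetic import Ensemble

    return Ensemble(ens.coords + t, ens.atom_names, ens.residue_ids,
                    ens.residue_names, ens.temperature, ens.frame_times)


class TestDistanceProfile:
    def test_uniform_flat(self):
        series = np.tile(0.05 + 0.05 * np.arange(8), 100)  # equal mass per bin
        prof = distance_fe_profile(series + 0.001, 298.0, 0.05)
        assert np.allclose(prof.delta_f, 0.0)

    def test_80_20_gap(self):
        series = np.array([0.225] * 800 + [0.275] * 200)
        prof = distance_fe_profile(series, 298.0, 0.05)
        finite = prof.delta_f[np.isfinite(prof.delta_f)]
        assert finite.max() == pytest.approx(-R_GAS * 298.0 * np.log(0.25), abs=1e-9)
        assert prof.delta_f[prof.reference_bin] == 0.0

    def test_identical_blocks_zero_sd(self):
        block = [0.225] * 30 + [0.275] * 10
        prof = distance_fe_profile(np.array(block * 4), 298.0, 0.05, n_blocks=4)
        finite = prof.block_sd[np.isfinite(prof.block_sd)]
        assert np.allclose(finite, 0.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            distance_fe_profile(np.array([]), 298.0)


class TestSasaProfile:
    @pytest.fixture(scope="class")
    @staticmethod
    def compact_vs_extended():
        spec, _ = hairpin_template("hairpin1", cartesian_noise_nm=0.01)
        from remdens.synthetic import uniform_state

        ext = uniform_state("strand", 0.5, cartesian_noise_nm=0.01,
                            angular_noise_deg=1.0)
        return generate_ensemble([spec.with_weight(0.5), ext], 60, 278.0, seed=43)

    def test_fraction_in_unit_interval(self, compact_vs_extended):
        s, f = lvffa_sasa(compact_vs_extended, frames=np.arange(10), n_points=128)
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(s >= 0)

    def test_single_frame_profile_flagged(self, hairpin1_ref):
        from remdens.synthetic import Ensemble
        from remdens.geometry import default_topology

        an, ri, rn = default_topology()
        ens = Ensemble(hairpin1_ref.coords[None], an, ri, rn, 278.0, np.zeros(1))
        prof = sasa_vs_distance(ens, np.array([0.2]), n_points=96)
        assert np.isfinite(prof.s_lvffa).sum() == 1
        assert np.isnan(prof.s_lvffa_sd[np.isfinite(prof.s_lvffa)]).all()

    def test_two_state_bins_differ_as_constructed(self, compact_vs_extended):
        ens = compact_vs_extended
        dist = hbond_distance_series(ens, "hairpin1")
        labels = ens.provenance["labels"]
        # hairpin frames close the turn H-bond; extended frames do not
        assert dist[labels == 0].max() < dist[labels == 1].min()
        prof = sasa_vs_distance(ens, dist, bin_nm=0.4, n_points=128)
        ok = np.isfinite(prof.s_lvffa)
        first, last = np.flatnonzero(ok)[0], np.flatnonzero(ok)[-1]
        s_direct, _ = lvffa_sasa(ens, n_points=128)
        close_mean = s_direct[dist < prof.bin_centers[first] + 0.2].mean()
        far_mean = s_direct[dist > prof.bin_centers[last] - 0.2].mean()
        assert np.sign(prof.s_lvffa[last] - prof.s_lvffa[first]) == np.sign(far_mean - close_mean)
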