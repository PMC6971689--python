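"""Pairwise-distance statistics, motif scanning and 3C-model mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from astig3d import (PairwiseDistanceDistribution, SiteSet,
                     compare_distributions, map_sites_to_3c,
                     pairwise_distances, scan_iupac_motif, truncate_range)
from astig3d.genome import IUPAC_CODES, sites_from_track_summary


class TestPairwiseDistances:
    def test_right_triangle_hand_computation(self):
        s = SiteSet(np.array([[0, 0, 0], [1000, 0, 0], [0, 1000, 0]]))
        d = pairwise_distances(s)
        assert sorted(np.round(d.distances, 6)) == pytest.approx(
            [1000.0, 1000.0, 1000.0 * np.sqrt(2)])
        assert d.mean == pytest.approx((2000 + 1000 * np.sqrt(2)) / 3)
        assert d.mean == pytest.approx(1138.07, abs=0.01)

    def test_single_point_gives_empty_distribution(self):
        d = pairwise_distances(SiteSet(np.array([[1, 2, 3]])))
        assert d.n == 0
        assert np.isnan(d.mean)

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_pair_count_is_k_choose_2(self, k, rng):
        s = SiteSet(rng.uniform(0, 5000, (k, 3)))
        assert pairwise_distances(s).n == k * (k - 1) // 2

    def test_within_cell_pairing_respects_cell_ids(self):
        pts = np.array([[0, 0, 0], [1000, 0, 0],
                        [0, 0, 0], [2000, 0, 0], [5000, 0, 0]])
        s = SiteSet(pts, cell_ids=[1, 1, 2, 2, 2])
        d = pairwise_distances(s, within_cell=True)
        assert d.n == 1 + 3  # 2-choose-2 + 3-choose-2
        assert sorted(d.distances) == [1000, 2000, 3000, 5000]

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 3000, (8, 3))
        rot = Rotation.from_euler("zyx", [0.3, -1.1, 2.0]).as_matrix()
        moved = pts @ rot.T + np.array([500.0, -200.0, 900.0])
        d0 = np.sort(pairwise_distances(SiteSet(pts)).distances)
        d1 = np.sort(pairwise_distances(SiteSet(moved)).distances)
        assert np.allclose(d0, d1, atol=1e-6)

    def test_se_is_sd_over_sqrt_n(self, rng):
        d = pairwise_distances(SiteSet(rng.uniform(0, 3000, (6, 3))))
        assert d.se == pytest.approx(
            np.std(d.distances, ddof=1) / np.sqrt(d.n))


class TestTruncation:
    def test_working_range_cut_by_hand(self):
        d = PairwiseDistanceDistribution(np.array([500.0, 900.0, 1200.0]))
        t = truncate_range(d, 1000.0)
        assert sorted(t.distances) == [500, 900]
        assert t.mean == pytest.approx(700.0)
        assert t.n == 2

    def test_no_distance_above_cut_is_identity(self):
        d = PairwiseDistanceDistribution(np.array([10.0, 400.0, 999.0]))
        t = truncate_range(d)
        assert np.array_equal(t.distances, d.distances)

    def test_everything_above_cut_empties_distribution(self):
        t = truncate_range(PairwiseDistanceDistribution(
            np.array([1500.0, 2000.0])))
        assert t.n == 0

    def test_truncation_never_increases_mean(self, rng):
        for _ in range(50):
            d = PairwiseDistanceDistribution(rng.uniform(0, 2000, 30))
            cut = rng.uniform(d.distances.min(), 2000)
            t = truncate_range(d, cut)
            if t.n:
                assert t.mean <= d.mean + 1e-12


class TestComparison:
    def test_identical_samples_are_indistinguishable(self):
        d = PairwiseDistanceDistribution(np.array([100.0, 200.0, 300.0]))
        res = compare_distributions(d, d)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_pooled_t_oracle(self, rng):
        a = PairwiseDistanceDistribution(rng.normal(400, 80, 40))
        b = PairwiseDistanceDistribution(rng.normal(340, 60, 55))
        res = compare_distributions(a, b)
        na, nb = a.n, b.n
        sp2 = ((na - 1) * np.var(a.distances, ddof=1)
               + (nb - 1) * np.var(b.distances, ddof=1)) / (na + nb - 2)
        t_oracle = (a.mean - b.mean) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.t_statistic == pytest.approx(t_oracle, abs=1e-9)

    def test_separated_means_detected_as_different(self, rng):
        # means like the observed-vs-predicted separation scale (417 vs 330)
        pred = PairwiseDistanceDistribution(rng.normal(417, 150, 300))
        obs = PairwiseDistanceDistribution(rng.normal(330, 100, 300))
        res = compare_distributions(obs, pred)
        assert res.p_value < 1e-4

    def test_significance_ordering_matches_permutation_test(self, rng):
        a = rng.normal(400, 50, 30)
        b = rng.normal(430, 50, 30)
        res = compare_distributions(PairwiseDistanceDistribution(a),
                                    PairwiseDistanceDistribution(b))
        pooled = np.concatenate([a, b])
        obs_diff = abs(a.mean() - b.mean())
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:30].mean() - pooled[30:].mean()) >= obs_diff
        p_perm = count / n_perm
        assert (res.p_value < 0.05) == (p_perm < 0.05)

    def test_degenerate_distributions_rejected(self):
        a = PairwiseDistanceDistribution(np.array([100.0, 100.0]))
        b = PairwiseDistanceDistribution(np.array([200.0, 200.0]))
        with pytest.raises(ValueError, match="degenerate"):
            compare_distributions(a, b)


class TestMotifScan:
    def test_single_base_motif_counts_forward_hits(self):
        hits = scan_iupac_motif({"chr1": "AAA"}, "A")
        fwd = [h for h in hits if h[2] == "+"]
        assert [h[1] for h in fwd] == [1, 2, 3]
        # minus strand of AAA reads TTT: no "A" site there
        assert not [h for h in hits if h[2] == "-"]

    def test_palindromic_motif_hits_both_strands_at_same_bp(self):
        hits = scan_iupac_motif({"chr1": "ACGT"}, "ACGT")
        assert ("chr1", 1, "+") in hits
        assert ("chr1", 1, "-") in hits
        assert len(hits) == 2

    def test_degenerate_motif_matches_brute_force_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        motif = "SYGGRG"
        rc = "CYCCRS"
        hits = scan_iupac_motif({"c": seq}, motif)

        def matches(s, i, m):
            return all(s[i + j] in IUPAC_CODES[ch]
                       for j, ch in enumerate(m)) if i + len(m) <= len(s) \
                else False

        fwd_oracle = [i + 1 for i in range(len(seq))
                      if matches(seq, i, motif)]
        rev_oracle = [i + 1 for i in range(len(seq)) if matches(seq, i, rc)]
        assert [h[1] for h in hits if h[2] == "+"] == fwd_oracle
        assert [h[1] for h in hits if h[2] == "-"] == rev_oracle

    def test_overlapping_matches_reported(self):
        hits = scan_iupac_motif({"c": "AAAA"}, "AA")
        assert [h[1] for h in hits if h[2] == "+"] == [1, 2, 3]

    def test_n_in_sequence_never_matches(self):
        assert scan_iupac_motif({"c": "NNNN"}, "N") == []
        hits = scan_iupac_motif({"c": "ANGA"}, "N")
        assert [h[1] for h in hits if h[2] == "+"] == [1, 3, 4]

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_iupac_motif({"c": "ACGT"}, "AXG")

    def test_biopython_records_accepted(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        recs = [SeqRecord(Seq("GCGGAG"), id="chrI")]
        hits = scan_iupac_motif(recs, "SYGGRG")
        assert ("chrI", 1, "+") in hits


class TestModelMapping:
    @staticmethod
    def model(rows):
        return pd.DataFrame(rows, columns=["chrom", "bp", "x_nm", "y_nm",
                                           "z_nm"])

    def test_midpoint_between_anchors(self):
        m = self.model([("c1", 0, 0, 0, 0), ("c1", 100, 100, 0, 0)])
        sites = map_sites_to_3c([("c1", 50)], m)
        assert np.allclose(sites.points, [[50, 0, 0]])

    def test_site_exactly_on_anchor(self):
        m = self.model([("c1", 0, 0, 0, 0), ("c1", 100, 100, 50, -20)])
        sites = map_sites_to_3c([("c1", 100)], m)
        assert np.allclose(sites.points, [[100, 50, -20]])

    def test_random_sites_match_piecewise_linear_oracle(self, rng):
        bps = np.sort(rng.choice(np.arange(0, 10001), 8, replace=False))
        bps[0], bps[-1] = 0, 10000
        xyz = rng.uniform(-2000, 2000, (8, 3))
        m = self.model([("c1", b, *p) for b, p in zip(bps, xyz)])
        queries = rng.uniform(0, 10000, 30)
        sites = map_sites_to_3c([("c1", q) for q in queries], m)
        for point, q in zip(sites.points, queries):
            j = np.searchsorted(bps, q) - 1
            j = np.clip(j, 0, 6)
            w = (q - bps[j]) / (bps[j + 1] - bps[j])
            oracle = (1 - w) * xyz[j] + w * xyz[j + 1]
            assert np.allclose(point, oracle, atol=1e-9)

    def test_out_of_span_sites_dropped_with_warning(self):
        m = self.model([("c1", 100, 0, 0, 0), ("c1", 200, 10, 0, 0)])
        with pytest.warns(UserWarning, match="dropped"):
            sites = map_sites_to_3c([("c1", 50), ("c2", 150), ("c1", 150)], m)
        assert len(sites) == 1


def test_sites_from_summary_keeps_immobile_nuclear_tracks():
    df = pd.DataFrame([
        {"track_id": 0, "class": "immobile", "compartment": "nucleus",
         "cell_id": 1, "centroid_x_nm": 1.0, "centroid_y_nm": 2.0,
         "centroid_z_nm": 3.0},
        {"track_id": 1, "class": "mobile", "compartment": "nucleus",
         "cell_id": 1, "centroid_x_nm": 4.0, "centroid_y_nm": 5.0,
         "centroid_z_nm": 6.0},
        {"track_id": 2, "class": "immobile", "compartment": "cytoplasm",
         "cell_id": 1, "centroid_x_nm": 7.0, "centroid_y_nm": 8.0,
         "centroid_z_nm": 9.0},
    ])
    sites = sites_from_track_summary(df)
    assert len(sites) == 1
    assert np.allclose(sites.points, [[1, 2, 3]])
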