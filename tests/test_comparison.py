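"""Union catalogue geometry, specificity labels, CFR ranking, profiles."""

import numpy as np
import pytest
from scipy import stats

from seqdap.comparison import (
    UnionPeak,
    build_union_catalogue,
    cfr_rank_and_deciles,
    classify,
    profile_matrices,
)
from seqdap.genome_io import CoverageTrack
from seqdap.pooling import ConsensusPeak


def flat_tracks(value, length=60000, library=1e6):
    return [CoverageTrack({"c": np.full(length, float(value))}, library_size=library)]


class TestBuildUnionCatalogue:
    def test_identical_peaks_collapse(self):
        a = [ConsensusPeak("c", 1000, mean_norm_cov=5.0)]
        b = [ConsensusPeak("c", 1000, mean_norm_cov=3.0)]
        entries = build_union_catalogue(a, b, flat_tracks(5), flat_tracks(3))
        assert len(entries) == 1
        assert entries[0].origin == "both"
        assert entries[0].summit == 1000

    def test_offset_300_gives_two_new_peaks(self):
        # overlap 101/401 ~ 25%: more than 50% of each peak non-overlapping
        a = [ConsensusPeak("c", 1000, mean_norm_cov=5.0)]
        b = [ConsensusPeak("c", 1300, mean_norm_cov=5.0)]
        entries = build_union_catalogue(a, b, flat_tracks(5), flat_tracks(5))
        assert len(entries) == 2
        assert {e.origin for e in entries} == {"A_only", "B_only"}

    def test_a_only_peak_measures_b_coverage(self):
        a = [ConsensusPeak("c", 1000, mean_norm_cov=8.0)]
        entries = build_union_catalogue(a, [], flat_tracks(8), flat_tracks(2))
        (e,) = entries
        assert e.cov_b == pytest.approx(2.0)
        assert e.cfr == pytest.approx(4.0)

    def test_matched_summit_comes_from_higher_coverage_experiment(self):
        a = [ConsensusPeak("c", 1000, mean_norm_cov=2.0)]
        b = [ConsensusPeak("c", 1010, mean_norm_cov=9.0)]
        entries = build_union_catalogue(a, b, flat_tracks(2), flat_tracks(9))
        assert entries[0].summit == 1010

    def test_ambiguity_resolved_by_largest_overlap(self):
        a = [ConsensusPeak("c", 1000, mean_norm_cov=5.0)]
        b = [ConsensusPeak("c", 1060, mean_norm_cov=5.0),
             ConsensusPeak("c", 1010, mean_norm_cov=5.0)]
        entries = build_union_catalogue(a, b, flat_tracks(5), flat_tracks(5))
        matched = [e for e in entries if e.origin == "both"]
        assert len(matched) == 1
        assert matched[0].summit in (1000, 1010)
        assert sum(e.origin == "B_only" for e in entries) == 1


class TestClassify:
    @pytest.mark.parametrize(
        "cov_a,cov_b,label",
        [(10, 4, "A_specific"), (10, 6, "common"), (4, 10, "B_specific"),
         (10, 5, "A_specific"), (5, 10, "B_specific")],
    )
    def test_fold_rule(self, cov_a, cov_b, label):
        entry = UnionPeak("c", 1000, cov_a=cov_a, cov_b=cov_b)
        assert classify(entry) == label

    def test_double_zero_is_common_with_warning(self):
        entry = UnionPeak("c", 1000, cov_a=0.0, cov_b=0.0)
        with pytest.warns(UserWarning):
            assert classify(entry) == "common"


class TestCfrAndDeciles:
    def _entries(self, cfrs):
        out = []
        for k, c in enumerate(cfrs):
            out.append(UnionPeak("c", 1000 + 500 * k, cov_a=c, cov_b=1.0, cfr=c))
        return out

    def test_equal_count_deciles(self):
        ranked = cfr_rank_and_deciles(self._entries(np.linspace(10, 1, 20)))
        assert [e.decile for e in ranked].count(1) == 2
        assert ranked[0].cfr == 10 and ranked[0].decile == 1
        assert ranked[-1].decile == 10

    def test_ties_stable_by_coordinate(self):
        with pytest.warns(UserWarning):
            ranked = cfr_rank_and_deciles(self._entries([2.0] * 6))
        assert [e.summit for e in ranked] == sorted(e.summit for e in ranked)

    def test_cfr_values(self):
        e1 = UnionPeak("c", 1000, cov_a=8, cov_b=2, cfr=4.0)
        e2 = UnionPeak("c", 2000, cov_a=2, cov_b=8, cfr=0.25)
        with pytest.warns(UserWarning):
            ranked = cfr_rank_and_deciles([e2, e1])
        assert [e.cfr for e in ranked] == [4.0, 0.25]

    def test_infinite_cfr_excluded(self):
        entries = self._entries(np.linspace(10, 1, 12))
        entries.append(UnionPeak("c", 99000, cov_a=3, cov_b=0.0, cfr=float("inf")))
        ranked = cfr_rank_and_deciles(entries)
        assert len(ranked) == 12


class TestProfileMatrices:
    def test_constant_coverage_fills_matrix(self):
        entries = [UnionPeak("c", 5000, cov_a=1, cov_b=1, cfr=1.0)]
        mat_a, mat_b, mean_a, mean_b = profile_matrices(
            entries, flat_tracks(3, library=1e6), flat_tracks(3, library=1e6)
        )
        assert mat_a.shape == (1, 1000)
        np.testing.assert_allclose(mat_a, 3.0)
        np.testing.assert_allclose(mean_a, mat_a[0])

    def test_doubling_library_halves_values(self):
        entries = [UnionPeak("c", 5000, cov_a=1, cov_b=1, cfr=1.0)]
        m1, _, _, _ = profile_matrices(entries, flat_tracks(3, library=1e6), flat_tracks(3))
        m2, _, _, _ = profile_matrices(entries, flat_tracks(3, library=2e6), flat_tracks(3))
        np.testing.assert_allclose(m2, m1 / 2)

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            profile_matrices([], flat_tracks(1), flat_tracks(1), window=999)


class TestCatalogueInvariants:
    def test_labels_partition_catalogue(self, mixed_fixture):
        entries = mixed_fixture["entries"]
        counts = {
            label: sum(e.label == label for e in entries)
            for label in ("common", "A_specific", "B_specific")
        }
        assert sum(counts.values()) == len(entries)

    def test_swap_inverts_cfr_and_labels(self, mixed_fixture):
        cons = mixed_fixture["consensus"]
        tracks = mixed_fixture["tracks"]
        fwd = build_union_catalogue(
            cons["tetramer"], cons["dimer"], tracks["tetramer"], tracks["dimer"]
        )
        rev = build_union_catalogue(
            cons["dimer"], cons["tetramer"], tracks["dimer"], tracks["tetramer"]
        )
        fwd_by_pos = {(e.chrom, e.summit): e for e in fwd}
        swap = {"A_specific": "B_specific", "B_specific": "A_specific", "common": "common"}
        compared = 0
        for e in rev:
            mate = fwd_by_pos.get((e.chrom, e.summit))
            if mate is None:
                continue
            compared += 1
            assert e.label == swap[mate.label]
            if np.isfinite(e.cfr) and np.isfinite(mate.cfr) and mate.cfr > 0:
                assert e.cfr == pytest.approx(1.0 / mate.cfr)
        assert compared > 0.9 * len(rev)

    def test_planted_pairs_concentrate_in_top_deciles(self, mixed_fixture):
        """Regions holding a planted site pair sit in the low (strong-CFR)
        deciles of the tetramer/dimer ordering."""
        truth = mixed_fixture["truth"]
        ranked = mixed_fixture["ranked"]
        pair_pos = [(p["chrom"], (p["start1"] + p["start2"]) // 2) for p in truth.pairs]
        deciles, indicator = [], []
        for e in ranked:
            has_pair = any(
                c == e.chrom and e.interval.start <= pos < e.interval.end
                for c, pos in pair_pos
            )
            deciles.append(e.decile)
            indicator.append(1 if has_pair else 0)
        rho, p = stats.spearmanr(deciles, indicator)
        assert rho < 0
        assert p < 0.01
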