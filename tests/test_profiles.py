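"""Anchored averaging, ranking, activity calls, stratification, correlation."""

import numpy as np
import pytest

from nucshift import profiles as prof
from nucshift import density as dens
from nucshift.genome import ChromSizes, GeneAnnotation, SignalTrack, Site

SIZES = ChromSizes({"chr1": 10_000})


def _track(values):
    return SignalTrack(ChromSizes({"chr1": len(values)}), "t",
                       {"chr1": np.asarray(values, dtype=float)})


class TestAnchoredMatrix:
    def test_constant_track(self, flat_track):
        anchors = [prof.Anchor("chr1", p) for p in (2000, 5000)]
        mat = prof.anchored_matrix(flat_track, anchors, L=100)
        assert np.all(mat.data == 2.5)
        assert mat.offsets[0] == -100 and mat.offsets[-1] == 100

    def test_minus_strand_flips_axis(self):
        values = np.zeros(10_000)
        values[4900] = 7.0  # 100 bp 3' of a minus-strand TSS at 5000
        mat = prof.anchored_matrix(_track(values),
                                   [prof.Anchor("chr1", 5000, "-")], L=200)
        assert mat.data[0, np.flatnonzero(mat.offsets == 100)[0]] == 7.0

    def test_mean_equals_direct_per_offset_average(self):
        rng = np.random.default_rng(0)
        values = rng.random(10_000)
        anchors = [prof.Anchor("chr1", p, s)
                   for p, s in ((1000, "+"), (4000, "-"), (8000, "+"))]
        mat = prof.anchored_matrix(_track(values), anchors, L=50)
        avg = mat.mean()
        np.testing.assert_allclose(avg.values, mat.data.mean(axis=0))
        assert np.all(avg.n == 3)

    def test_edge_cells_missing_row_kept(self):
        mat = prof.anchored_matrix(flat := _track(np.ones(10_000)),
                                   [prof.Anchor("chr1", 30)], L=100)
        assert np.isnan(mat.data[0, 0])          # off-chromosome cell
        assert mat.data[0, -1] == 1.0

    def test_strand_flip_invariance(self):
        """Reversing the genome and all anchors leaves the averaged
        profile unchanged."""
        rng = np.random.default_rng(1)
        values = rng.random(10_000)
        anchors = [prof.Anchor("chr1", 3000, "+"), prof.Anchor("chr1", 7000, "-")]
        fwd = prof.anchored_matrix(_track(values), anchors, L=100).mean()
        flipped = [prof.Anchor("chr1", len(values) - 1 - a.pos,
                               "-" if a.strand == "+" else "+")
                   for a in anchors]
        rev = prof.anchored_matrix(_track(values[::-1]), flipped, L=100).mean()
        np.testing.assert_allclose(rev.values, fwd.values)


class TestScaledBodyMatrix:
    def _gene(self, tss, tts, strand="+"):
        return GeneAnnotation("g", "chr1", tss, tts, strand)

    def test_constant_track_flat_profile(self, flat_track):
        mat = prof.scaled_body_matrix(flat_track, [self._gene(2000, 3500)],
                                      body_length_target=3000, flank=500)
        assert np.all(mat.data == 2.5)
        assert mat.data.shape[1] == 3000 + 2 * 500

    def test_target_length_gene_is_identity(self):
        rng = np.random.default_rng(2)
        values = rng.random(10_000)
        mat = prof.scaled_body_matrix(_track(values), [self._gene(2000, 5000)],
                                      body_length_target=3000, flank=0)
        np.testing.assert_allclose(mat.data[0], values[2000:5000])

    def test_half_length_gene_interpolated(self):
        values = np.arange(10_000, dtype=float)
        mat = prof.scaled_body_matrix(_track(values), [self._gene(2000, 3500)],
                                      body_length_target=3000, flank=0)
        np.testing.assert_allclose(mat.data[0],
                                   np.linspace(2000, 3499, 3000), rtol=1e-12)


class TestRankAndBin:
    def test_even_split(self):
        bins = prof.rank_and_bin(list("abcdefghij"), range(10), 5)
        assert bins == [5, 5, 4, 4, 3, 3, 2, 2, 1, 1]  # highest keys in bin 1

    def test_remainder_goes_to_early_bins(self):
        bins = prof.rank_and_bin(range(11), [10 - i for i in range(11)], 5)
        sizes = [bins.count(b) for b in range(1, 6)]
        assert sizes == [3, 2, 2, 2, 2]

    def test_ties_stable_on_input_order(self):
        bins = prof.rank_and_bin(list("abcd"), [1, 1, 1, 1], 2)
        assert bins == [1, 1, 2, 2]

    def test_fewer_items_than_bins(self):
        with pytest.raises(ValueError, match="fewer items"):
            prof.rank_and_bin([1, 2], [1, 2], 5)

    def test_bins_partition_input(self):
        rng = np.random.default_rng(3)
        key = rng.random(57)
        bins = prof.rank_and_bin(range(57), key, 5)
        assert sorted(set(bins)) == [1, 2, 3, 4, 5]
        assert len(bins) == 57


class TestClassifyActivity:
    def test_zero_track_all_inactive(self, active_bundle):
        zero = SignalTrack(active_bundle.chrom_sizes)
        flags = prof.classify_activity(active_bundle.annotations, zero)
        assert not any(flags.values())

    def test_synthetic_track_recovers_truth_exactly(self):
        from nucshift import simulate as sim
        cfg = sim.SimConfig(gene_groups=[sim.gene_group("active", 30),
                                         sim.gene_group("inactive", 30)],
                            seed=21)
        bundle = sim.generate(cfg)
        flags = prof.classify_activity(bundle.annotations,
                                       bundle.tracks["H3K4me3"])
        for g in bundle.annotations:
            assert flags[g.gene_id] == g.active

    def test_scale_invariance(self, active_bundle):
        track = active_bundle.tracks["H3K4me3"]
        doubled = track.copy()
        for c in doubled.data:
            doubled.data[c] *= 2
        a = prof.classify_activity(active_bundle.annotations, track)
        b = prof.classify_activity(active_bundle.annotations, doubled)
        assert a == b


class TestStratifyByCofactor:
    def _site(self, reads):
        return Site("chr1", 100, "Su(Hw)", {"CP190": reads})

    def test_at_least_threshold_is_inclusive(self):
        plus, minus = prof.stratify_by_cofactor(
            [self._site(50), self._site(49)], "CP190", min_reads=50)
        assert [s.summit_reads["CP190"] for s in plus] == [50]
        assert [s.summit_reads["CP190"] for s in minus] == [49]

    def test_zero_threshold_takes_all(self):
        sites = [self._site(r) for r in (0, 10, 100)]
        plus, minus = prof.stratify_by_cofactor(sites, "CP190", min_reads=0)
        assert len(plus) == 3 and not minus

    def test_partition_is_exhaustive_and_disjoint(self):
        sites = [self._site(r) for r in range(0, 200, 7)]
        plus, minus = prof.stratify_by_cofactor(sites, "CP190", 50)
        assert len(plus) + len(minus) == len(sites)
        assert not set(id(s) for s in plus) & set(id(s) for s in minus)

    def test_missing_label_is_error(self):
        with pytest.raises(ValueError, match="DREF"):
            prof.stratify_by_cofactor([self._site(10)], "DREF")


class TestCorrelateAtSites:
    def _sites(self, n, spacing=40, halfwidth=250):
        return [Site("chr1", 500 + i * spacing, "x") for i in range(n)]

    def test_identical_tracks_r_one(self):
        rng = np.random.default_rng(4)
        t = _track(rng.random(10_000))
        assert prof.correlate_at_sites(t, t, self._sites(20)) == pytest.approx(1.0)

    def test_negated_track_r_minus_one(self):
        rng = np.random.default_rng(5)
        v = rng.random(10_000)
        r = prof.correlate_at_sites(_track(v), _track(-v + 3), self._sites(20))
        assert r == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(6)
        sizes = ChromSizes({"chr1": 200_000})
        a = SignalTrack(sizes, "a", {"chr1": rng.normal(size=200_000)})
        b = SignalTrack(sizes, "b", {"chr1": rng.normal(size=200_000)})
        sites = [Site("chr1", 500 + i * 990, "x") for i in range(200)]
        assert abs(prof.correlate_at_sites(a, b, sites)) < 0.2

    def test_zero_variance_is_error(self, flat_track):
        with pytest.raises(ValueError, match="undefined correlation"):
            prof.correlate_at_sites(flat_track, flat_track, self._sites(5))

    def test_too_few_sites(self, flat_track):
        with pytest.raises(ValueError, match="at least 2"):
            prof.correlate_at_sites(flat_track, flat_track, self._sites(1))

    def test_cofactor_track_correlates_with_reads(self, sites_bundle):
        """The generator's CP190 track correlates with summit read counts at
        insulator sites (machinery check on a realistic bundle)."""
        ins = [s for s in sites_bundle.sites if "CP190" in s.summit_reads]
        track = sites_bundle.tracks["CP190"]
        reads = np.array([s.summit_reads["CP190"] for s in ins], dtype=float)
        means = np.array([track.values(s.chrom)
                          [s.summit - 50:s.summit + 50].mean() for s in ins])
        assert np.corrcoef(reads, means)[0, 1] > 0.99
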