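"""Shift calling, region merging, feature enrichment and Hilbert layout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from nucshift import density as dens
from nucshift import shifts as sh
from nucshift import simulate as sim
from nucshift.genome import ChromSizes

SIZES = ChromSizes({"chr1": 2000})


def _dyad_counts(wt_by_window, mut_by_window, w=50, sizes=SIZES):
    dw, dm = dens.DyadCounts(sizes), dens.DyadCounts(sizes)
    for i, n in enumerate(wt_by_window):
        dw.data["chr1"][i * w] = n
    for i, n in enumerate(mut_by_window):
        dm.data["chr1"][i * w] = n
    return dw, dm


class TestCallShifts:
    def test_hand_arithmetic_oracle(self):
        # equal total depths; window 0 has wt 40 / mut 5 -> log2(6/41) = -2.77
        dw, dm = _dyad_counts([40, 5], [5, 40])
        win = sh.call_shifts(dw, dm)
        assert win.loc[0, "log2fc"] == pytest.approx(np.log2(6 / 41), abs=1e-12)
        assert bool(win.loc[0, "is_shift"])
        assert win.loc[1, "log2fc"] == pytest.approx(np.log2(41 / 6), abs=1e-12)

    def test_equal_counts_not_a_shift(self):
        dw, dm = _dyad_counts([30, 7], [30, 7])
        win = sh.call_shifts(dw, dm)
        assert np.all(win["log2fc"] == 0)
        assert not win["is_shift"].any()

    @given(hst.lists(hst.tuples(hst.integers(0, 500), hst.integers(0, 500)),
                     min_size=2, max_size=20))
    def test_condition_swap_antisymmetry(self, pairs):
        wt = [p[0] for p in pairs]
        mut = [p[1] for p in pairs]
        if sum(wt) == 0 or sum(mut) == 0:
            return
        dw, dm = _dyad_counts(wt, mut)
        fwd = sh.call_shifts(dw, dm)
        rev = sh.call_shifts(dm, dw)
        np.testing.assert_allclose(rev["log2fc"], -fwd["log2fc"], atol=1e-9)
        assert (rev["is_shift"] == fwd["is_shift"]).all()

    def test_depth_invariance_under_duplication(self):
        # duplicating one library rescales both normalized counts by sqrt(2),
        # so log2fc can move only through the pseudocount: |delta| < 0.5
        dw, dm = _dyad_counts([40, 5, 12], [5, 40, 12])
        base = sh.call_shifts(dw, dm)
        dm2 = dens.DyadCounts(SIZES, {"chr1": dm.counts("chr1") * 2})
        doubled = sh.call_shifts(dw, dm2)
        assert np.abs(doubled["log2fc"] - base["log2fc"]).max() < 0.5
        big = base["log2fc"].abs() > 2.5
        assert (doubled.loc[big, "is_shift"] == base.loc[big, "is_shift"]).all()

    def test_zero_total_library_is_error(self):
        dw = dens.DyadCounts(SIZES)
        dm, _ = _dyad_counts([5], [5])
        with pytest.raises(ValueError, match="zero-total"):
            sh.call_shifts(dw, dm)

    def test_windows_tile_without_overlap(self):
        dw, dm = _dyad_counts([1] * 10, [1] * 10)
        win = sh.call_shifts(dw, dm, w=50)
        assert (win["end"] - win["start"]).eq(50).all()
        assert list(win["start"]) == list(range(0, 2000, 50))  # partial dropped

    def test_one_sided_option(self):
        dw, dm = _dyad_counts([40, 5], [5, 40])
        win = sh.call_shifts(dw, dm, one_sided=True)
        assert list(win["is_shift"][:2]) == [False, True]  # only mutant gain


class TestMergeShifts:
    def _windows(self, shifted_starts, w=50):
        starts = list(range(0, 500, w))
        return pd.DataFrame({
            "chrom": "chr1", "start": starts,
            "end": [s + w for s in starts],
            "log2fc": [3.0 if s in shifted_starts else 0.0 for s in starts],
            "is_shift": [s in shifted_starts for s in starts]})

    def test_adjacent_windows_merge(self):
        regions = sh.merge_shifts(self._windows({0, 50}))
        assert len(regions) == 1
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (0, 100)
        assert regions.loc[0, "n_windows"] == 2

    def test_separated_windows_stay_separate(self):
        regions = sh.merge_shifts(self._windows({0, 100}))
        assert len(regions) == 2

    def test_no_shifts_empty(self):
        assert len(sh.merge_shifts(self._windows(set()))) == 0


class TestShiftFraction:
    def test_reported_genome_arithmetic(self):
        # 47,000 shifted nucleosomes, 175 Mb female genome, 185 bp repeat
        frac = sh.shift_fraction(47_000, 175e6, 185)
        assert frac == pytest.approx(100 * 47_000 * 185 / 175e6, abs=1e-12)
        assert frac == pytest.approx(4.9686, abs=1e-3)
        assert frac < 5.0

    def test_degenerate_values(self):
        assert sh.shift_fraction(0, 175e6, 185) == 0.0
        g, nrl = 1_000_000, 200
        assert sh.shift_fraction(g // nrl, g, nrl) == pytest.approx(100.0)


@pytest.fixture(scope="module")
def gene_bundle():
    return sim.generate(sim.single_gene_config("active", n=60, seed=9))


class TestFeatureEnrichment:

    def _uniform_regions(self, chrom_sizes, n, seed):
        rng = np.random.default_rng(seed)
        chrom = next(iter(chrom_sizes))
        starts = rng.integers(0, chrom_sizes[chrom] - 50, size=n)
        return pd.DataFrame({"chrom": chrom, "start": starts,
                             "end": starts + 50})

    def test_null_uniform_regions_unenriched(self, gene_bundle):
        regions = self._uniform_regions(gene_bundle.chrom_sizes, 2000, seed=4)
        res = sh.feature_enrichment(regions, gene_bundle.annotations,
                                    gene_bundle.chrom_sizes)
        assert res["shift_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert res["genome_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        common = res[res["genome_fraction"] > 0.05]
        assert np.all(np.abs(common["fold_enrichment"] - 1) < 0.25)
        assert (res["padj"] < 0.01).sum() == 0

    def test_all_upstream_regions(self, gene_bundle):
        genes = gene_bundle.annotations
        rows = []
        for g in genes:
            mid = g.oriented(-700)
            rows.append({"chrom": g.chrom, "start": mid - 25, "end": mid + 25})
        res = sh.feature_enrichment(pd.DataFrame(rows), genes,
                                    gene_bundle.chrom_sizes)
        res = res.set_index("feature")
        up = res.loc["upstream_1.5kb"]
        assert up["shift_fraction"] == pytest.approx(1.0)
        assert up["fold_enrichment"] == pytest.approx(1 / up["genome_fraction"])
        assert up["padj"] < 1e-6
        assert res.drop("upstream_1.5kb")["shift_fraction"].sum() == 0

    def test_promoter_architecture_enriches_upstream(self):
        """End-to-end: remodeler-dependent elements placed upstream of TSSs
        produce shift regions enriched upstream and depleted on CDS exons."""
        cfg_genes = sim.single_gene_config("active", n=40, seed=13)
        layout = sim.generate(cfg_genes)
        summits = [g.oriented(-800) for g in layout.annotations]
        grp = sim.site_group("insulator", n=len(summits))
        grp.summits = summits
        cfg = sim.single_gene_config("active", n=40, seed=13)
        cfg.site_groups = [grp]
        bundle = sim.generate(cfg)
        dy = {c: dens.fragments_to_dyads(bundle.fragments[c], bundle.chrom_sizes)
              for c in ("wt", "mut")}
        regions = sh.merge_shifts(sh.call_shifts(dy["wt"], dy["mut"]))
        assert len(regions) > 20
        res = sh.feature_enrichment(regions, bundle.annotations,
                                    bundle.chrom_sizes).set_index("feature")
        assert res.loc["upstream_1.5kb", "fold_enrichment"] > 1.5
        assert res.loc["cds_exon", "fold_enrichment"] < 1.0


class TestHilbert:
    def test_order_one_mapping(self):
        assert [sh.hilbert_d2xy(1, d) for d in range(4)] == \
            [(0, 0), (0, 1), (1, 1), (1, 0)]

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_bijective_and_local(self, order):
        n = 1 << order
        cells = [sh.hilbert_d2xy(order, d) for d in range(n * n)]
        assert len(set(cells)) == n * n                      # bijection
        assert all(0 <= x < n and 0 <= y < n for x, y in cells)
        for (x1, y1), (x2, y2) in zip(cells, cells[1:]):     # locality
            assert max(abs(x1 - x2), abs(y1 - y2)) <= 1

    def test_matrix_counts_conserved(self):
        sizes = ChromSizes({"chr1": 4096})
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 4000, size=37)
        regions = pd.DataFrame({"chrom": "chr1", "start": starts,
                                "end": starts + 50})
        mat = sh.hilbert_layout(regions, "chr1", sizes, order=3)
        assert mat.shape == (8, 8)
        assert mat.sum() == 37

    def test_adjacent_regions_land_in_adjacent_cells(self):
        sizes = ChromSizes({"chr1": 4096})
        # midpoints 65 and 135 fall in consecutive 64-bp bins (1 and 2)
        regions = pd.DataFrame({"chrom": "chr1", "start": [60, 130],
                                "end": [70, 140]})
        mat = sh.hilbert_layout(regions, "chr1", sizes, order=3)
        ys, xs = np.nonzero(mat)
        assert len(xs) == 2
        assert max(abs(xs[0] - xs[1]), abs(ys[0] - ys[1])) <= 1


class TestRecovery:
    def test_shift_windows_recover_ground_truth(self, sites_bundle):
        """Windows flagged shifted recover the analytically true shifted
        windows with sensitivity and specificity >= 0.9."""
        b = sites_bundle
        dy = {c: dens.fragments_to_dyads(b.fragments[c], b.chrom_sizes)
              for c in ("wt", "mut")}
        called = sh.call_shifts(dy["wt"], dy["mut"])
        truth = b.truth.shifted_windows(w=50, tau=2.0)
        merged = called.merge(truth[["start", "is_shift"]], on="start",
                              suffixes=("", "_true"))
        pos = merged[merged["is_shift_true"]]
        neg = merged[~merged["is_shift_true"]]
        assert len(pos) > 1000
        sensitivity = pos["is_shift"].mean()
        specificity = 1.0 - neg["is_shift"].mean()
        assert sensitivity >= 0.9
        assert specificity >= 0.9
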