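"""Offset profiles, the bootstrap null, and the empirical P-value rule."""

import numpy as np
import pytest
from scipy import stats

from rg4coloc import (
    BindingSite,
    RegionLabel,
    RG4Site,
    assign_region,
    bootstrap_random_sites,
    classify_pattern,
    coloc_test,
    density_profile,
    empirical_pvalue,
    site_rg4_offsets,
    windowed_stat,
)
from rg4coloc.coloc import ColocResult

from conftest import simple_tx


def make_site(tm, start, end):
    return BindingSite("R", tm.tx_id, start, end, assign_region(tm, (start + end) // 2))


class TestOffsets:
    def test_signed_midpoint_offset(self):
        tm = simple_tx("T1", 50, 200, 300)
        site = make_site(tm, 110, 130)
        rg4 = RG4Site("T1", 90, 110, 25)
        assert site_rg4_offsets([site], [rg4], [tm]) == [20]

    def test_zero_offset_when_midpoints_coincide(self):
        tm = simple_tx("T1", 50, 200, 300)
        assert site_rg4_offsets(
            [make_site(tm, 95, 105)], [RG4Site("T1", 90, 110, 25)], [tm]
        ) == [0]

    def test_all_pairs_not_nearest_only(self):
        tm = simple_tx("T1", 50, 400, 300)
        rg4s = [RG4Site("T1", p, p + 20, 25) for p in (100, 200, 300)]
        sites = [make_site(tm, 150, 170), make_site(tm, 250, 270)]
        offsets = site_rg4_offsets(sites, rg4s, [tm], W=500)
        # exhaustive pair enumeration
        expected = sorted(
            s.mid - r.mid for s in sites for r in rg4s if abs(s.mid - r.mid) <= 500
        )
        assert sorted(offsets) == expected and len(offsets) == 6

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration_random(self, seed):
        rng = np.random.default_rng(seed)
        n_tx = int(rng.integers(1, 21))
        tms = [
            simple_tx(f"T{i}", 50, int(rng.integers(100, 500)), 200)
            for i in range(n_tx)
        ]
        sites, rg4s = [], []
        for _ in range(int(rng.integers(1, 40))):
            tm = tms[int(rng.integers(0, n_tx))]
            s = int(rng.integers(0, tm.length - 20))
            sites.append(make_site(tm, s, s + 20))
        for _ in range(int(rng.integers(1, 20))):
            tm = tms[int(rng.integers(0, n_tx))]
            s = int(rng.integers(0, tm.length - 15))
            rg4s.append(RG4Site(tm.tx_id, s, s + 15, 25))
        W = int(rng.integers(20, 300))
        got = sorted(site_rg4_offsets(sites, rg4s, tms, W=W))
        expected = sorted(
            s.mid - r.mid
            for s in sites
            for r in rg4s
            if s.tx_id == r.tx_id and abs(s.mid - r.mid) <= W
        )
        assert got == expected

    def test_region_filter_applies_to_both_features(self):
        tm = simple_tx("T1", 100, 300, 600)
        rg4_cds = RG4Site("T1", 200, 220, 25)
        rg4_3utr = RG4Site("T1", 500, 520, 25)
        site_cds = make_site(tm, 230, 250)
        site_3utr = make_site(tm, 450, 470)
        offs = site_rg4_offsets(
            [site_cds, site_3utr], [rg4_cds, rg4_3utr], [tm],
            region_filter=RegionLabel.CDS, W=1000,
        )
        assert offs == [site_cds.mid - rg4_cds.mid]


class TestProfileAndStat:
    def test_single_offset_profile(self):
        prof = density_profile([0], W=10, binwidth=1, n_anchors=1)
        assert prof.density[10] == 1.0
        assert prof.density.sum() == 1.0
        assert prof.n_pairs == 1

    def test_doubling_anchors_halves_density(self):
        offs = [-5, 0, 3]
        a = density_profile(offs, 10, 1, 1)
        b = density_profile(offs, 10, 1, 2)
        assert np.allclose(a.density, 2 * b.density)

    def test_conservation_identity(self):
        rng = np.random.default_rng(2)
        offs = rng.integers(-200, 201, size=500).tolist()
        prof = density_profile(offs, 200, 10, n_anchors=7)
        assert prof.density.sum() * prof.binwidth * prof.n_anchors == pytest.approx(
            len(offs)
        )

    def test_zero_anchors_errors(self):
        with pytest.raises(ValueError):
            density_profile([0], 10, 1, 0)

    def test_windowed_stat_counts_inclusive(self):
        offs = [-100, -50, 0, 10, 50]
        assert windowed_stat(offs, 1, (-80, 30)) == 3.0
        assert windowed_stat([], 1, (-80, 30)) == 0.0
        assert windowed_stat(offs, 2, (-200, 200)) == len(offs) / 2

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            windowed_stat([0], 1, (30, -80))


class TestEmpiricalP:
    @pytest.mark.parametrize(
        "obs,null,expected",
        [
            (5.0, [1, 2, 3], 0.0),
            (1.0, [1, 2, 3], 1.0),  # ties count as >=
            (2.5, [1, 2, 3], 1 / 3),
        ],
    )
    def test_tie_rule(self, obs, null, expected):
        assert empirical_pvalue(obs, null) == expected

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, [])


class TestBootstrapNull:
    def test_zero_sites_gives_empty_set(self):
        tm = simple_tx("T1", 100, 300, 600)
        assert bootstrap_random_sites([], [tm], seed=0) == []

    def test_placements_stay_inside_filtered_region(self):
        tms = [simple_tx(f"T{i}", 100, 300, 600) for i in range(3)]
        proto = [
            BindingSite("R", "T0", 500, 530, RegionLabel.THREE_UTR)
            for _ in range(100)
        ]
        for rep in range(100):  # 10^4 draws total
            rand = bootstrap_random_sites(
                proto, tms, region_filter=RegionLabel.THREE_UTR, seed=rep
            )
            assert len(rand) == len(proto)
            for s in rand:
                assert 400 <= s.start and s.end <= 1000
                assert s.end - s.start == 30

    def test_stratified_mode_preserves_region_counts(self):
        tms = [simple_tx(f"T{i}", 100, 300, 600) for i in range(5)]
        proto = (
            [BindingSite("R", "T0", 10, 30, RegionLabel.FIVE_UTR)] * 7
            + [BindingSite("R", "T0", 200, 220, RegionLabel.CDS)] * 13
            + [BindingSite("R", "T0", 600, 620, RegionLabel.THREE_UTR)] * 5
        )
        rand = bootstrap_random_sites(proto, tms, seed=3, mode="stratified")
        counts = {lab: 0 for lab in RegionLabel}
        for s in rand:
            counts[s.region] += 1
        assert counts == {
            RegionLabel.FIVE_UTR: 7,
            RegionLabel.CDS: 13,
            RegionLabel.THREE_UTR: 5,
        }

    def test_positions_uniform_chi_square(self):
        # single 1000-nt region, width-1 sites: positions must be uniform
        tm = simple_tx("T1", 1, 998, 1)  # CDS covers [1, 999)
        proto = [
            BindingSite("R", "T1", 500, 501, RegionLabel.CDS) for _ in range(1000)
        ]
        starts = []
        for rep in range(100):  # 10^5 draws
            rand = bootstrap_random_sites(
                proto, tm and [tm], region_filter=RegionLabel.CDS, seed=rep
            )
            starts.extend(s.start for s in rand)
        counts, _ = np.histogram(starts, bins=20)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestColocTest:
    def _dataset(self, seed=0, n_tx=5, planted=True):
        rng = np.random.default_rng(seed)
        tms = [simple_tx(f"T{i}", 100, 600, 800) for i in range(n_tx)]
        rg4s, sites = [], []
        for tm in tms:
            for _ in range(3):
                s = int(rng.integers(0, tm.length - 20))
                rg4s.append(RG4Site(tm.tx_id, s, s + 20, 25))
        for tm in tms:
            for _ in range(10):
                if planted and rng.random() < 0.5:
                    anchor = rg4s[int(rng.integers(0, len(rg4s)))]
                    tm2 = next(t for t in tms if t.tx_id == anchor.tx_id)
                    mid = int(np.clip(anchor.mid + rng.integers(-30, 10), 15, tm2.length - 16))
                    sites.append(make_site(tm2, mid - 15, mid + 15))
                else:
                    s = int(rng.integers(0, tm.length - 30))
                    sites.append(make_site(tm, s, s + 30))
        return tms, rg4s, sites

    def test_determinism_identical_seeds(self):
        tms, rg4s, sites = self._dataset()
        a = coloc_test(sites, rg4s, tms, B=50, seed=7)
        b = coloc_test(sites, rg4s, tms, B=50, seed=7)
        assert a == b

    def test_different_seeds_differ(self):
        tms, rg4s, sites = self._dataset()
        a = coloc_test(sites, rg4s, tms, B=50, seed=7)
        b = coloc_test(sites, rg4s, tms, B=50, seed=8)
        assert a.null_stats != b.null_stats

    def test_observed_stat_matches_windowed_stat(self):
        tms, rg4s, sites = self._dataset()
        res = coloc_test(sites, rg4s, tms, B=5, seed=1, W=200)
        offs = site_rg4_offsets(sites, rg4s, tms, W=200)
        n_anchors = len(rg4s)
        assert res.observed_stat == pytest.approx(
            windowed_stat(offs, n_anchors, (-80, 30))
        )

    def test_empirical_p_matches_null_stats(self):
        tms, rg4s, sites = self._dataset()
        res = coloc_test(sites, rg4s, tms, B=40, seed=2)
        assert res.empirical_p == empirical_pvalue(res.observed_stat, res.null_stats)
        assert len(res.null_stats) == 40

    def test_requires_anchor_and_site(self):
        tms, rg4s, sites = self._dataset()
        with pytest.raises(ValueError):
            coloc_test(sites, [], tms, B=10)
        with pytest.raises(ValueError):
            coloc_test([], rg4s, tms, B=10)
        with pytest.raises(ValueError):
            coloc_test(sites, rg4s, tms, B=0)


class TestPower:
    def test_rejection_rate_monotone_in_rho(self):
        """Power grows with the planted colocalized fraction."""
        from rg4coloc import SimConfig, simulate_dataset

        rates = []
        for rho in (0.0, 0.25, 0.5):
            rej = 0
            for rep in range(20):
                cfg = SimConfig(
                    n_tx=20, n_sites=150, rho=rho, offset_sd=10.0, seed=700 + rep
                )
                _, tms, truth, sites = simulate_dataset(cfg)
                res = coloc_test(
                    sites, truth.rg4_sites, tms, B=100, seed=800 + rep
                )
                rej += res.empirical_p <= 0.05
            rates.append(rej)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestClassifyPattern:
    def _results(self, p5, pc, p3):
        mk = lambda lab, p: ColocResult(lab.value, 1.0, [0.0], p, (-80, 30), 10, 0, 1, 1)
        return {
            RegionLabel.FIVE_UTR: mk(RegionLabel.FIVE_UTR, p5),
            RegionLabel.CDS: mk(RegionLabel.CDS, pc),
            RegionLabel.THREE_UTR: mk(RegionLabel.THREE_UTR, p3),
        }

    def test_reference_pattern_is_same(self):
        # P = 1 for 5'UTR, 0.004 for CDS, 0 for 3'UTR
        assert classify_pattern(self._results(1.0, 0.004, 0.0)) == "same"

    def test_no_signal_is_different(self):
        assert classify_pattern(self._results(1.0, 1.0, 1.0)) == "different"

    def test_significant_5utr_is_different(self):
        assert classify_pattern(self._results(0.04, 0.004, 0.0)) == "different"

    def test_missing_region_errors(self):
        res = self._results(1.0, 0.004, 0.0)
        del res[RegionLabel.CDS]
        with pytest.raises(ValueError, match="CDS"):
            classify_pattern(res)
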