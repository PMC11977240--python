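"""Peak mapping, region proportions, densities and RG4-overlap fractions."""

import numpy as np
import pytest

from rg4coloc import (
    BindingSite,
    GenomicInterval,
    RegionLabel,
    RG4Site,
    TranscriptModel,
    assign_region,
    density_per_kb,
    fraction_bound_mrnas_with_rg4,
    map_peaks,
    region_proportions,
)
from rg4coloc.binding_sites import write_annotated_sites
from rg4coloc.transcript_model import REGION_ORDER

from conftest import simple_tx


@pytest.fixture
def tx1000():
    """Coding transcript on chr1 [0,1000), CDS tx[50,350)."""
    return TranscriptModel(
        "TX1", "G1", "chr1", "+", (GenomicInterval("chr1", 0, 1000, "+"),), 50, 350
    )


class TestMapPeaks:
    def test_midpoint_sets_region(self, tx1000):
        (site,) = map_peaks([("chr1", 390, 410, None)], [tx1000])
        assert site.region is RegionLabel.THREE_UTR  # midpoint 400 >= 350

    def test_intergenic_peak_excluded(self, tx1000):
        assert map_peaks([("chr2", 10, 30, None)], [tx1000]) == []

    def test_summit_policy_overrides_midpoint(self, tx1000):
        peak = ("chr1", 340, 360, 2)  # midpoint 350 -> 3'UTR, summit 342 -> CDS
        (by_mid,) = map_peaks([peak], [tx1000])
        (by_summit,) = map_peaks([peak], [tx1000], summit_policy="summit")
        assert by_mid.region is RegionLabel.THREE_UTR
        assert by_summit.region is RegionLabel.CDS

    def test_straddling_peak_needs_exonic_midpoint(self):
        tm = TranscriptModel(
            "TX1",
            "G1",
            "chr1",
            "+",
            (
                GenomicInterval("chr1", 100, 150, "+"),
                GenomicInterval("chr1", 300, 400, "+"),
            ),
            10,
            100,
        )
        # midpoint 225 is intronic -> unmapped
        assert map_peaks([("chr1", 140, 310, None)], [tm]) == []
        # midpoint 145 exonic; transcript extent covers only exonic bases
        (site,) = map_peaks([("chr1", 130, 160, None)], [tm])
        assert (site.start, site.end) == (30, 50)

    def test_tie_goes_to_longest_cds(self):
        a = TranscriptModel(
            "TXA", "GA", "chr1", "+", (GenomicInterval("chr1", 0, 1000, "+"),), 0, 300
        )
        b = TranscriptModel(
            "TXB", "GB", "chr1", "+", (GenomicInterval("chr1", 0, 1000, "+"),), 0, 600
        )
        (site,) = map_peaks([("chr1", 100, 120, None)], [a, b])
        assert site.tx_id == "TXB"

    def test_transcript_frame(self, tx1000):
        (site,) = map_peaks([("TX1", 40, 60, None)], [tx1000], frame="transcript")
        assert site.region is assign_region(tx1000, 50)

    def test_region_label_invariant(self, tx1000):
        rng = np.random.default_rng(0)
        peaks = []
        for _ in range(200):
            s = int(rng.integers(0, 980))
            peaks.append(("chr1", s, s + int(rng.integers(2, 21)), None))
        for site in map_peaks(peaks, [tx1000]):
            assert site.region is assign_region(tx1000, site.mid)

    def test_deterministic_output(self, tx1000, tmp_path):
        rng = np.random.default_rng(1)
        peaks = [
            ("chr1", int(s), int(s) + 20, None)
            for s in rng.integers(0, 980, size=100)
        ]
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_annotated_sites(map_peaks(peaks, [tx1000]), out1)
        write_annotated_sites(map_peaks(peaks, [tx1000]), out2)
        assert out1.read_bytes() == out2.read_bytes()


class TestRegionStats:
    def _sites(self, n5, nc, n3, tx="TX1"):
        mk = lambda region, i: BindingSite("R", tx, i * 10, i * 10 + 5, region)
        out = []
        i = 0
        for region, n in zip(REGION_ORDER, (n5, nc, n3)):
            for _ in range(n):
                out.append(mk(region, i))
                i += 1
        return out

    def test_proportions(self):
        props = region_proportions(self._sites(2, 5, 3))
        assert props == {
            RegionLabel.FIVE_UTR: 0.2,
            RegionLabel.CDS: 0.5,
            RegionLabel.THREE_UTR: 0.3,
        }
        assert region_proportions(self._sites(0, 4, 0)) == {
            RegionLabel.FIVE_UTR: 0.0,
            RegionLabel.CDS: 1.0,
            RegionLabel.THREE_UTR: 0.0,
        }

    def test_proportions_empty_errors(self):
        with pytest.raises(ValueError):
            region_proportions([])

    def test_proportions_match_recount_and_sum_to_one(self):
        rng = np.random.default_rng(5)
        tm = simple_tx("TX1", 100, 600, 800)
        sites = []
        for _ in range(1000):
            s = int(rng.integers(0, tm.length - 10))
            sites.append(
                BindingSite("R", "TX1", s, s + 10, assign_region(tm, s + 5))
            )
        props = region_proportions(sites)
        assert sum(props.values()) == pytest.approx(1.0)
        for lab in REGION_ORDER:
            direct = sum(1 for s in sites if s.region is lab) / len(sites)
            assert props[lab] == direct
            assert props[lab] * len(sites) == pytest.approx(
                sum(1 for s in sites if s.region is lab)
            )

    def test_density_per_kb(self):
        tm = simple_tx("TX1", 100, 400, 2500)
        sites = [
            BindingSite("R", "TX1", 600 + i, 620 + i, RegionLabel.THREE_UTR)
            for i in range(5)
        ]
        dens = density_per_kb(sites, [tm])
        assert dens[RegionLabel.THREE_UTR] == pytest.approx(2.0)
        assert dens[RegionLabel.CDS] == 0.0
        # conservation: sum density * length_kb = feature count
        from rg4coloc import region_lengths

        lengths = region_lengths([tm])
        total = sum(dens[lab] * lengths[lab] / 1000 for lab in REGION_ORDER)
        assert total == pytest.approx(len(sites))

    def test_density_accepts_rg4_features(self):
        tm = simple_tx("TX1", 100, 400, 2500)
        rg4s = [RG4Site("TX1", 700, 720, 25), RG4Site("TX1", 50, 70, 25)]
        dens = density_per_kb(rg4s, [tm])
        assert dens[RegionLabel.THREE_UTR] == pytest.approx(1 / 2.5)
        assert dens[RegionLabel.FIVE_UTR] == pytest.approx(10.0)


class TestBoundFractions:
    def test_simple_fraction(self):
        sites = [
            BindingSite("R", f"T{i}", 0, 10, RegionLabel.CDS) for i in range(4)
        ]
        rg4s = [RG4Site("T0", 5, 20, 25), RG4Site("T1", 5, 20, 25)]
        assert fraction_bound_mrnas_with_rg4(sites, rg4s) == 0.5
        assert fraction_bound_mrnas_with_rg4(sites, []) == 0.0

    def test_zero_bound_errors(self):
        with pytest.raises(ValueError):
            fraction_bound_mrnas_with_rg4([], [])

    def test_per_region_matches_set_algebra(self):
        rng = np.random.default_rng(9)
        tms = [simple_tx(f"T{i}", 100, 300, 600) for i in range(20)]
        by_tx = {tm.tx_id: tm for tm in tms}
        sites, rg4s = [], []
        for _ in range(60):
            tm = tms[int(rng.integers(0, 20))]
            s = int(rng.integers(0, tm.length - 12))
            sites.append(
                BindingSite("R", tm.tx_id, s, s + 12, assign_region(tm, s + 6))
            )
        for _ in range(25):
            tm = tms[int(rng.integers(0, 20))]
            s = int(rng.integers(0, tm.length - 15))
            rg4s.append(RG4Site(tm.tx_id, s, s + 15, 25))
        got = fraction_bound_mrnas_with_rg4(sites, rg4s, per_region=True, tms=tms)
        for lab in REGION_ORDER:
            bound = {s.tx_id for s in sites if s.region is lab}
            withr = {
                r.tx_id
                for r in rg4s
                if assign_region(by_tx[r.tx_id], r.mid) is lab
            }
            expected = len(bound & withr) / len(bound) if bound else 0.0
            assert got[lab] == expected
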