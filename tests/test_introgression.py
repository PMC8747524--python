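"""Informative loci, window scanning, segment merging, CIR intersection."""

import numpy as np
import pandas as pd
import pytest

from nilscan.genotypes import GenotypeMatrix
from nilscan.introgression import (
    IntrogressionSegment,
    find_informative_loci,
    find_segments,
    intersect_nils,
    merge_segments,
    nil_donor_calls,
    scan_windows,
)


def toy_matrix(rows):
    """rows: (chrom, pos, donor_code, recurrent_code, nil codes...)."""
    sites = pd.DataFrame(
        [(r[0], r[1], "A", "G", "SNP", 60.0) for r in rows],
        columns=["chrom", "pos", "ref", "alt", "vtype", "mq"],
    )
    n_nils = len(rows[0]) - 4
    cols = ["DONOR", "REC"] + [f"NIL{i+1}" for i in range(n_nils)]
    calls = pd.DataFrame([list(r[2:]) for r in rows], columns=cols, dtype=str)
    return GenotypeMatrix(sites=sites, calls=calls)


class TestInformativeLoci:
    def test_opposite_homozygotes_are_informative(self):
        m = toy_matrix([("chr1", 100, "h", "l", "h"), ("chr1", 200, "l", "h", "l")])
        loci, tallies = find_informative_loci(m, "DONOR", "REC")
        assert tallies["informative"] == 2
        assert loci[0].donor_allele == "G" and loci[0].recurrent_allele == "A"
        assert loci[1].donor_allele == "A" and loci[1].recurrent_allele == "G"

    @pytest.mark.parametrize("donor_code,key", [("e", "het"), ("u", "unclassified"), ("l", "concordant")])
    def test_non_informative_categories_tallied(self, donor_code, key):
        m = toy_matrix([("chr1", 100, donor_code, "l", "h")])
        loci, tallies = find_informative_loci(m, "DONOR", "REC")
        assert not loci
        assert tallies[key] == 1

    def test_same_sample_twice_rejected(self):
        m = toy_matrix([("chr1", 100, "h", "l", "h")])
        with pytest.raises(ValueError):
            find_informative_loci(m, "DONOR", "DONOR")

    def test_recovers_simulated_divergent_loci(self, sim_bundle):
        m = sim_bundle["matrix"]
        loci, _ = find_informative_loci(m, "DRD", "SBA")
        # at error-free depth 30, essentially all divergent loci are recovered
        assert len(loci) / len(sim_bundle["variants"]) >= 0.999
        assert all(l.donor_allele == l.alt for l in loci)


def toy_calls(positions, donor_flags, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "donor": donor_flags,
            "het": [False] * len(positions),
            "classified": [True] * len(positions),
        }
    )


class TestScanWindows:
    def test_empty_window_not_flagged(self):
        calls = toy_calls([50, 1_000_050], [False, False])
        w = scan_windows(calls, window_size=1_000_000, min_donor_loci=1,
                         min_donor_frac=0.0)
        # min_donor_frac 0 with min_donor_loci 1 flags exactly windows
        # holding >= 1 donor call: none here
        assert not w["flagged"].any()

    def test_degenerate_parameters_flag_any_donor_window(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), 500, replace=False))
        donor = rng.random(500) < 0.3
        calls = toy_calls(list(pos), list(donor))
        w = scan_windows(calls, 1_000_000, min_donor_loci=1, min_donor_frac=0.0)
        expect = {
            int(k): bool(d.any())
            for k, d in pd.Series(donor).groupby((pos - 1) // 1_000_000)
        }
        for _, row in w.iterrows():
            assert row["flagged"] == expect[row["start"] // 1_000_000]

    def test_all_donor_chromosome_flags_every_populated_window(self):
        pos = list(range(100_000, 5_000_000, 100_000))
        calls = toy_calls(pos, [True] * len(pos))
        w = scan_windows(calls, 1_000_000, min_donor_loci=5, min_donor_frac=0.8)
        assert w["flagged"].all()


class TestMergeSegments:
    def test_boundaries_refined_to_outermost_donor_locus(self):
        # donor loci spanning 24.06-24.99 Mb inside flagged windows 24 and 25
        pos = list(range(24_060_000, 25_000_000, 60_000))
        calls = toy_calls(pos, [True] * len(pos), chrom="chr6")
        w = scan_windows(calls, 1_000_000, 5, 0.8)
        segs = merge_segments(w, calls, nil="NIL")
        assert len(segs) == 1
        assert segs[0].start == 24_060_000 - 1
        assert segs[0].end == pos[-1]

    def test_gap_of_one_window_is_bridged(self):
        pos = (
            list(range(3_000_010, 4_000_000, 100_000))
            + list(range(5_000_010, 6_000_000, 100_000))
        )
        calls = toy_calls(pos, [True] * len(pos))
        w = scan_windows(calls, 1_000_000, 5, 0.8)
        assert len(merge_segments(w, calls, max_gap_windows=1)) == 1
        assert len(merge_segments(w, calls, max_gap_windows=0)) == 2

    def test_no_flagged_windows_gives_no_segments(self):
        calls = toy_calls([100, 200], [False, False])
        w = scan_windows(calls, 1_000_000, 5, 0.8)
        assert merge_segments(w, calls) == []


class TestIntersectNils:
    def seg(self, nil, chrom, start, end, n=10):
        return IntrogressionSegment(nil, chrom, start, end, n, n)

    def test_overlap_is_clipped_to_common_interval(self):
        segs = {
            "A": [self.seg("A", "chr6", 24_000_000, 26_000_000)],
            "B": [self.seg("B", "chr6", 21_000_000, 27_000_000)],
        }
        cirs = intersect_nils(segs)
        assert len(cirs) == 1
        assert (cirs[0].start, cirs[0].end) == (24_000_000, 26_000_000)

    def test_disjoint_segments_give_no_cir(self):
        segs = {
            "A": [self.seg("A", "chr1", 0, 1_000_000)],
            "B": [self.seg("B", "chr1", 2_000_000, 3_000_000)],
        }
        assert intersect_nils(segs) == []

    def test_single_nil_rejected(self):
        with pytest.raises(ValueError):
            intersect_nils({"A": [self.seg("A", "chr1", 0, 10)]})

    def test_common_snp_counts_match_set_intersection(self):
        """Constructed overlap: per-NIL 897 and 948 donor loci, 894 shared."""
        rng = np.random.default_rng(12)
        n_loci = 1000
        pos = np.sort(rng.choice(np.arange(2, 5_000_000), n_loci, replace=False))
        a_donor = np.zeros(n_loci, bool)
        b_donor = np.zeros(n_loci, bool)
        shared_idx = rng.choice(n_loci, 894, replace=False)
        a_donor[shared_idx] = b_donor[shared_idx] = True
        a_only = rng.choice(np.setdiff1d(np.arange(n_loci), shared_idx), 3, replace=False)
        a_donor[a_only] = True
        b_only = rng.choice(
            np.setdiff1d(np.arange(n_loci), np.concatenate([shared_idx, a_only])),
            54, replace=False,
        )
        b_donor[b_only] = True
        rows = []
        for p, da, db in zip(pos, a_donor, b_donor):
            rows.append(("chr1", int(p), "h", "l", "h" if da else "l", "h" if db else "l"))
        m = toy_matrix(rows)
        loci, _ = find_informative_loci(m, "DONOR", "REC")
        segs = {
            "NIL1": [self.seg("NIL1", "chr1", 0, 5_000_000)],
            "NIL2": [self.seg("NIL2", "chr1", 0, 5_000_000)],
        }
        cirs = intersect_nils(segs, matrix=m, loci=loci)
        assert len(cirs) == 1
        cir = cirs[0]
        assert cir.per_nil_counts == {"NIL1": 897, "NIL2": 948}
        assert cir.n_common == 894
        assert cir.n_common <= min(cir.per_nil_counts.values())

    def test_cir_contained_in_every_contributing_segment(self, sim_bundle):
        m = sim_bundle["matrix"]
        loci, _ = find_informative_loci(m, "DRD", "SBA")
        segs = find_segments(m, loci, "NIL")
        donor_segs = find_segments(m, loci, "DRD")
        both = {"NIL": segs, "DRD": donor_segs}
        for cir in intersect_nils(both, m, loci):
            for nil_segs in both.values():
                assert any(
                    s.chrom == cir.chrom and s.start <= cir.start and cir.end <= s.end
                    for s in nil_segs
                )


class TestEndToEndRecovery:
    def test_detected_segments_overlap_truth(self, sim_bundle):
        m = sim_bundle["matrix"]
        truth = sim_bundle["truth"]
        loci, _ = find_informative_loci(m, "DRD", "SBA")
        segs = find_segments(m, loci, "NIL")
        chrom, sel_pos = sim_bundle["selected_locus"]
        sel_truth = next(
            (s, e) for s, e in truth[chrom] if s < sel_pos <= e
        )
        assert any(
            sg.chrom == chrom and sg.overlaps(*sel_truth) for sg in segs
        ), "selected introgression must be detected"
        # every detected segment overlaps some truth interval
        for sg in segs:
            assert any(sg.overlaps(s, e) for s, e in truth.get(sg.chrom, []))
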