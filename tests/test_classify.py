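"""Z classification, sex inference, PAR segmentation, reversal detection."""

import numpy as np
import pandas as pd
import pytest

from zparcall import classify as zc
from zparcall import io as zio


def paf_frame(rows):
    """rows: (qname, qlen, qstart, qend, strand, tstart, tend) on ref_chrZ."""
    recs = [(q, ql, qs, qe, st, "ref_chrZ", 10_000_000, ts, te,
             qe - qs, qe - qs, 60) for q, ql, qs, qe, st, ts, te in rows]
    return pd.DataFrame(recs, columns=zio.PAF_COLUMNS)


def norm_windows(scaffold_values, window=5000):
    """scaffold -> list of normalized depths; builds a normalized table."""
    frames = []
    for scaffold, vals in scaffold_values.items():
        n = len(vals)
        frames.append(pd.DataFrame({
            "scaffold": scaffold, "start": np.arange(n) * window,
            "end": (np.arange(n) + 1) * window,
            "mean_depth": np.asarray(vals) * 30.0,
            "normalized_depth": np.asarray(vals, dtype=float),
            "partial": False}))
    return pd.concat(frames, ignore_index=True)


def zcalls_frame(calls):
    return pd.DataFrame({"scaffold": list(calls), "length": 1_000_000,
                         "call": [calls[s] for s in calls]})


class TestAlignmentSummaries:
    def test_overlapping_blocks_merged_before_rate(self):
        paf = paf_frame([("s1", 1_000_000, 0, 600_000, "+", 0, 600_000),
                         ("s1", 1_000_000, 400_000, 900_000, "+", 400_000, 900_000)])
        out = zc.summarize_alignment_rates(paf, pd.Series({"s1": 1_000_000}),
                                           "ref_chrZ")
        assert out["aligned_bases"].iloc[0] == 900_000
        assert out["alignment_rate"].iloc[0] == pytest.approx(0.9)

    def test_scaffold_without_blocks_has_zero_rate(self):
        paf = paf_frame([("s1", 100, 0, 50, "+", 0, 50)])
        out = zc.summarize_alignment_rates(paf, pd.Series({"s1": 100, "s2": 100}),
                                           "ref_chrZ")
        assert out.set_index("scaffold").loc["s2", "alignment_rate"] == 0.0

    def test_majority_strand_by_aligned_base_weight(self):
        paf = paf_frame([("s1", 1000, 0, 600, "-", 0, 600),
                         ("s1", 1000, 600, 1000, "+", 600, 1000)])
        out = zc.summarize_alignment_rates(paf, pd.Series({"s1": 1000}), "ref_chrZ")
        assert out["majority_strand"].iloc[0] == "-"

    def test_blocks_to_other_targets_ignored(self):
        paf = paf_frame([("s1", 1000, 0, 800, "+", 0, 800)])
        paf.loc[0, "target_name"] = "chr1"
        out = zc.summarize_alignment_rates(paf, pd.Series({"s1": 1000}), "ref_chrZ")
        assert out["alignment_rate"].iloc[0] == 0.0

    def test_unknown_scaffold_rejected(self):
        paf = paf_frame([("ghost", 1000, 0, 800, "+", 0, 800)])
        with pytest.raises(zc.ClassifyError, match="absent"):
            zc.summarize_alignment_rates(paf, pd.Series({"s1": 1000}), "ref_chrZ")

    @pytest.mark.parametrize("seed", range(10))
    def test_union_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        starts = rng.integers(0, 9000, n)
        lens = rng.integers(1, 1500, n)
        ivs = list(zip(starts.tolist(), (starts + lens).tolist()))
        mask = np.zeros(12_000, dtype=bool)  # oracle: per-base painting
        for s, e in ivs:
            mask[s:e] = True
        assert zc.union_length(ivs) == int(mask.sum())


class TestZCalls:
    def test_high_rate_is_candidate_and_edge_is_not(self):
        summaries = pd.DataFrame({
            "scaffold": ["a", "b", "c"], "length": [100] * 3,
            "aligned_bases": [90, 50, 10],
            "alignment_rate": [0.9, 0.5, 0.1],
            "majority_strand": ["+"] * 3, "anchor_position": [1.0] * 3,
            "n_blocks": [1] * 3})
        calls = zc.classify_z_scaffolds(summaries)
        assert calls.set_index("scaffold")["call"].tolist() == [
            zc.Z_CANDIDATE, zc.NOT_Z, zc.NOT_Z]  # exactly 0.5 excluded

    def test_every_scaffold_called(self):
        summaries = pd.DataFrame({
            "scaffold": [f"s{i}" for i in range(9)], "length": [10] * 9,
            "aligned_bases": range(9),
            "alignment_rate": np.linspace(0, 1, 9),
            "majority_strand": ["+"] * 9, "anchor_position": [0.0] * 9,
            "n_blocks": [1] * 9})
        calls = zc.classify_z_scaffolds(summaries)
        assert set(calls["call"]) <= {zc.Z_CANDIDATE, zc.NOT_Z}
        assert len(calls) == 9

    def test_raising_rate_threshold_never_adds_candidates(self):
        rng = np.random.default_rng(0)
        summaries = pd.DataFrame({
            "scaffold": [f"s{i}" for i in range(200)], "length": [10] * 200,
            "aligned_bases": 0, "alignment_rate": rng.random(200),
            "majority_strand": "+", "anchor_position": 0.0, "n_blocks": 1})
        counts = [(zc.classify_z_scaffolds(summaries, t)["call"]
                   == zc.Z_CANDIDATE).sum() for t in np.linspace(0, 1, 11)]
        assert counts == sorted(counts, reverse=True)


class TestSexInference:
    def test_female_pattern(self):
        win = norm_windows({"z": [0.5] * 150, "a": [1.0] * 150})
        sex = zc.infer_sex(win, zcalls_frame({"z": zc.Z_CANDIDATE,
                                              "a": zc.NOT_Z}))
        assert sex.call == "FEMALE"
        assert sex.z_modal_depth == pytest.approx(0.5, abs=0.02)
        assert sex.not_z_modal_depth == pytest.approx(1.0, abs=0.02)

    def test_male_pattern_both_peaks_at_one(self):
        win = norm_windows({"z": [1.0] * 150, "a": [1.0] * 150})
        sex = zc.infer_sex(win, zcalls_frame({"z": zc.Z_CANDIDATE,
                                              "a": zc.NOT_Z}))
        assert sex.call == "MALE"

    def test_intermediate_mode_is_undetermined(self):
        win = norm_windows({"z": [0.76] * 150, "a": [1.0] * 150})
        sex = zc.infer_sex(win, zcalls_frame({"z": zc.Z_CANDIDATE,
                                              "a": zc.NOT_Z}))
        assert sex.call == "UNDETERMINED"

    def test_no_z_candidates_is_an_error(self):
        win = norm_windows({"a": [1.0] * 150})
        with pytest.raises(zc.ClassifyError, match="sex"):
            zc.infer_sex(win, zcalls_frame({"a": zc.NOT_Z}))


FEMALE_CALL = zc.SexCall("FEMALE", 0.5, 1.0)


class TestParScaffolds:
    def test_median_rule_with_strict_threshold(self):
        win = norm_windows({"par": [0.95] * 10, "dr": [0.5] * 10,
                            "edge": [0.7] * 10, "a": [1.0] * 10})
        calls = zcalls_frame({"par": zc.Z_CANDIDATE, "dr": zc.Z_CANDIDATE,
                              "edge": zc.Z_CANDIDATE, "a": zc.NOT_Z})
        out = zc.call_par_scaffolds(win, calls, FEMALE_CALL).set_index("scaffold")
        assert bool(out.loc["par", "par_candidate"])
        assert not bool(out.loc["dr", "par_candidate"])
        assert not bool(out.loc["edge", "par_candidate"])  # exactly 0.7 excluded
        assert "a" not in out.index

    def test_requires_female_sample(self):
        win = norm_windows({"z": [1.0] * 10})
        calls = zcalls_frame({"z": zc.Z_CANDIDATE})
        with pytest.raises(zc.ClassifyError, match="FEMALE"):
            zc.call_par_scaffolds(win, calls, zc.SexCall("MALE", 1.0, 1.0))


def track(values, window=5000):
    n = len(values)
    return pd.DataFrame({"pseudo_start": np.arange(n) * window,
                         "pseudo_end": (np.arange(n) + 1) * window,
                         "normalized_depth": np.asarray(values, dtype=float)})


class TestSegmentation:
    def test_all_low_gives_no_par(self):
        seg = zc.segment_depth_track(track([0.5] * 50))
        assert (seg["label"] == "DR").all()
        assert seg["end"].iloc[-1] - seg["start"].iloc[0] == 250_000

    def test_all_high_gives_single_par_span(self):
        seg = zc.segment_depth_track(track([1.0] * 50))
        assert seg["label"].tolist() == ["PAR"]
        assert (seg["start"].iloc[0], seg["end"].iloc[0]) == (0, 250_000)

    def test_short_noise_run_discarded(self):
        seg = zc.segment_depth_track(track([0.5] * 20 + [1.0] * 2 + [0.5] * 20))
        assert (seg["label"] == "DR").all()

    def test_small_gap_closed_inside_par(self):
        vals = [1.0] * 10 + [0.5] * 2 + [1.0] * 10 + [0.5] * 30
        seg = zc.segment_depth_track(track(vals))
        par = seg[seg["label"] == "PAR"]
        assert len(par) == 1
        assert (par["start"].iloc[0], par["end"].iloc[0]) == (0, 110_000)

    def test_large_gap_splits_par(self):
        vals = [1.0] * 10 + [0.5] * 5 + [1.0] * 10 + [0.5] * 30
        seg = zc.segment_depth_track(track(vals))
        assert (seg["label"] == "PAR").sum() == 2

    def test_segments_tile_extent(self):
        rng = np.random.default_rng(8)
        seg = zc.segment_depth_track(track(rng.choice([0.5, 1.0], 200)))
        assert (seg["start"].iloc[1:].to_numpy() == seg["end"].iloc[:-1].to_numpy()).all()

    def test_unordered_windows_rejected(self):
        t = track([1.0] * 10).iloc[::-1]
        with pytest.raises(zc.ClassifyError, match="ordered"):
            zc.segment_depth_track(t)

    def test_raising_depth_threshold_never_grows_par(self):
        rng = np.random.default_rng(9)
        t = track(rng.uniform(0.3, 1.2, 500))
        totals = []
        for thr in np.linspace(0.3, 1.1, 9):
            seg = zc.segment_depth_track(t, depth_threshold=thr)
            par = seg[seg["label"] == "PAR"]
            totals.append(int((par["end"] - par["start"]).sum()))
        assert totals == sorted(totals, reverse=True)


class TestReversal:
    def segments(self, par_len):
        return pd.DataFrame({"start": [0, par_len], "end": [par_len, 70_000_000],
                             "label": ["PAR", "DR"], "mean_norm_depth": [1.0, 0.5],
                             "n_windows": [par_len // 5000, 1]})

    def test_30mb_par_flags_reversal(self):
        flag = zc.detect_reversal(self.segments(30_000_000), 610_563)
        assert flag.flagged
        assert flag.total_par_length == 30_000_000

    def test_conserved_600kb_par_does_not_flag(self):
        assert not zc.detect_reversal(self.segments(600_000), 610_563).flagged

    def test_exactly_threshold_does_not_flag(self):
        assert not zc.detect_reversal(self.segments(5_000_000), 610_563).flagged

    def test_ancestral_dr_overlap_reported(self):
        flag = zc.detect_reversal(self.segments(30_000_000), 610_563,
                                  ancestral_dr=[(610_563, 70_000_000)])
        assert flag.ancestral_dr_overlap == 30_000_000 - 610_563


class TestGeneCounting:
    def test_majority_span_assignment(self):
        seg = pd.DataFrame({"start": [0, 100], "end": [100, 200],
                            "label": ["PAR", "DR"]})
        genes = pd.DataFrame({"start": [10, 90, 150], "end": [30, 130, 190],
                              "name": ["a", "b", "c"]})
        out = zc.count_genes_in_segments(seg, genes)
        # b spans [90,130): 10 bp in PAR vs 30 bp in DR -> counted in DR only
        assert out["gene_count"].tolist() == [1, 2]

    def test_empty_annotation_gives_zero_counts(self):
        seg = pd.DataFrame({"start": [0], "end": [100], "label": ["PAR"]})
        out = zc.count_genes_in_segments(seg, pd.DataFrame(columns=["start", "end", "name"]))
        assert out["gene_count"].tolist() == [0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.sort(rng.choice(np.arange(1, 1000), 20, replace=False))
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [1000]])
        seg = pd.DataFrame({"start": starts, "end": ends,
                            "label": rng.choice(["PAR", "DR"], len(starts))})
        gs = rng.integers(0, 980, 100)
        genes = pd.DataFrame({"start": gs, "end": gs + rng.integers(1, 20, 100),
                              "name": [f"g{i}" for i in range(100)]})
        out = zc.count_genes_in_segments(seg, genes)
        oracle = np.zeros(len(seg), dtype=int)  # quadratic all-pairs
        for g in genes.itertuples(index=False):
            ovs = [max(0, min(g.end, e) - max(g.start, s))
                   for s, e in zip(seg["start"], seg["end"])]
            best = int(np.argmax(ovs))
            if ovs[best] > 0:
                oracle[best] += 1
        assert out["gene_count"].tolist() == oracle.tolist()
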