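"""Consensus peaks (greedy oracle equivalence), filtering, annotation,
motif scanning and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from persisterlab.peaks_regulatory import (
    HALF_WIDTH,
    PEAK_WIDTH,
    MotifModel,
    annotate_peaks,
    build_consensus,
    feature_proportions,
    filter_peak_counts,
    motif_enrichment,
    motif_scan,
    regulatory_overlap_delta,
)


def naive_consensus(summits: pd.DataFrame) -> pd.DataFrame:
    """Independent O(n^2) re-implementation of the greedy maximal-score
    non-overlapping selection."""
    df = summits.copy().reset_index(drop=True)
    df["start"] = df["summit"].astype(int) - HALF_WIDTH
    df["end"] = df["start"] + PEAK_WIDTH
    order = df.sort_values(["score", "chrom", "start"],
                           ascending=[False, True, True],
                           kind="mergesort").index
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if (df.at[i, "chrom"] == df.at[j, "chrom"]
                    and df.at[i, "start"] < df.at[j, "end"]
                    and df.at[j, "start"] < df.at[i, "end"]):
                ok = False
                break
        if ok:
            kept.append(i)
    out = df.loc[kept, ["chrom", "start", "end", "summit", "score"]]
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def random_summits(rng, n):
    return pd.DataFrame({
        "sample": rng.choice(["s1", "s2", "s3"], size=n),
        "chrom": rng.choice(["chr1", "chr2"], size=n),
        "summit": rng.integers(300, 100_000, size=n),
        "score": np.round(rng.uniform(1, 100, size=n), 3),
    })


class TestConsensus:
    def test_overlap_greedy_rule(self):
        summits = pd.DataFrame({
            "sample": ["s1", "s2"], "chrom": ["chr1", "chr1"],
            "summit": [1000, 1200], "score": [10.0, 8.0]})
        out = build_consensus(summits)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 750 and out.iloc[0]["end"] == 1250
        # the losing sample still flags the retained peak
        assert out.iloc[0]["called_s1"] and out.iloc[0]["called_s2"]

    def test_disjoint_summits_both_kept(self):
        summits = pd.DataFrame({
            "sample": ["s1", "s1"], "chrom": ["chr1", "chr1"],
            "summit": [1000, 2000], "score": [10.0, 8.0]})
        assert len(build_consensus(summits)) == 2

    def test_matches_naive_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            summits = random_summits(rng, int(rng.integers(5, 200)))
            fast = build_consensus(summits)[["chrom", "start", "end", "score"]]
            slow = naive_consensus(summits)[["chrom", "start", "end", "score"]]
            pd.testing.assert_frame_equal(fast, slow)

    def test_idempotent_and_nonoverlapping(self):
        rng = np.random.default_rng(1)
        summits = random_summits(rng, 300)
        out = build_consensus(summits)
        # non-overlap within each chromosome
        for _, grp in out.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()
        # rerun on own output: identical intervals
        again = build_consensus(
            out.assign(sample="x")[["sample", "chrom", "summit", "score"]])
        pd.testing.assert_frame_equal(
            out[["chrom", "start", "end", "score"]],
            again[["chrom", "start", "end", "score"]])

    def test_every_discarded_window_overlaps_a_better_one(self):
        rng = np.random.default_rng(2)
        summits = random_summits(rng, 200)
        out = build_consensus(summits)
        for _, row in summits.iterrows():
            s = int(row["summit"]) - HALF_WIDTH
            e = s + PEAK_WIDTH
            over = out[(out["chrom"] == row["chrom"]) & (out["start"] < e)
                       & (s < out["end"])]
            assert len(over) >= 1
            assert over["score"].max() >= row["score"] - 1e-9

    def test_chrom_end_clipping(self):
        summits = pd.DataFrame({"sample": ["s1"], "chrom": ["chr1"],
                                "summit": [100], "score": [5.0]})
        out = build_consensus(summits, chrom_sizes={"chr1": 1000})
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 350

    def test_out_of_bounds_rejected_without_sizes(self):
        summits = pd.DataFrame({"sample": ["s1"], "chrom": ["chr1"],
                                "summit": [100], "score": [5.0]})
        with pytest.raises(ValueError):
            build_consensus(summits)


class TestPeakFilter:
    def _fixture(self):
        counts = pd.DataFrame(
            {"a1": [400_000, 400_000, 1], "a2": [400_000, 400_000, 1],
             "a3": [400_000, 400_000, 1], "b1": [1, 400_000, 1],
             "b2": [1, 400_000, 1], "b3": [1, 400_000, 1]},
            index=["p1", "p2", "p3"])
        called = pd.DataFrame(True, index=counts.index, columns=counts.columns)
        groups = {"a1": "A", "a2": "A", "a3": "A",
                  "b1": "B", "b2": "B", "b3": "B"}
        return counts, called, groups

    def test_abundant_and_reproducible_retained(self):
        counts, called, groups = self._fixture()
        kept = filter_peak_counts(counts, called, groups)
        assert "p1" in kept and "p2" in kept and "p3" not in kept

    def test_partial_replicate_calls_dropped(self):
        counts, called, groups = self._fixture()
        called.loc["p1", ["a1", "b1"]] = False  # 2/3 in every group
        kept = filter_peak_counts(counts, called, groups)
        assert "p1" not in kept

    def test_shape_mismatch_rejected(self):
        counts, called, groups = self._fixture()
        with pytest.raises(ValueError):
            filter_peak_counts(counts, called.iloc[:, :3], groups)


class TestAnnotation:
    def _genes(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "start": [10_000, 400_000], "end": [20_000, 420_000],
            "strand": ["+", "-"], "tss": [10_000, 420_000]})

    def test_promoter_assignment(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [10_750],
                              "end": [11_250]})
        ann = annotate_peaks(peaks, self._genes())
        assert ann.iloc[0]["gene_id"] == "g1"
        assert ann.iloc[0]["tss_distance"] == 1000
        assert ann.iloc[0]["feature"] == "promoter"

    def test_100kb_rule(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [259_750],
                              "end": [260_250]})  # 250 kb from g1, 160 kb from g2
        ann = annotate_peaks(peaks, self._genes())
        assert ann.iloc[0]["gene_id"] is None
        assert ann.iloc[0]["feature"] == "distal_intergenic"

    def test_gene_body_class_and_strand_sign(self):
        peaks = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [14_750, 417_750],
                              "end": [15_250, 418_250]})
        ann = annotate_peaks(peaks, self._genes())
        assert ann.iloc[0]["feature"] == "gene_body"
        # minus-strand gene: a peak before the TSS coordinate is downstream
        assert ann.iloc[1]["gene_id"] == "g2"
        assert ann.iloc[1]["tss_distance"] == 2000

    def test_strand_flip_preserves_distance_magnitude(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [12_750],
                              "end": [13_250]})
        genes = self._genes()
        d1 = annotate_peaks(peaks, genes).iloc[0]["tss_distance"]
        flipped = genes.assign(strand=genes["strand"].map({"+": "-", "-": "+"}))
        d2 = annotate_peaks(peaks, flipped).iloc[0]["tss_distance"]
        assert abs(d1) == abs(d2)

    def test_proportions_partition(self):
        rng = np.random.default_rng(3)
        peaks = pd.DataFrame({
            "chrom": "chr1",
            "start": rng.integers(0, 500_000, 50)})
        peaks["end"] = peaks["start"] + PEAK_WIDTH
        props = feature_proportions(annotate_peaks(peaks, self._genes()))
        assert props.sum() == pytest.approx(1.0)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            annotate_peaks(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                           pd.DataFrame())


class TestRegulatoryOverlap:
    def _elements(self):
        return pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [1000, 5000, 9000],
            "end": [1200, 5200, 9200],
            "cls": ["PLS", "dELS", "dELS"]})

    def test_identical_sets_zero_delta(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [1100], "end": [1600]})
        out = regulatory_overlap_delta({"all": peaks, "up": peaks},
                                       self._elements())
        assert np.allclose(out["delta_up"], 0.0)

    def test_constructed_delta(self):
        all_peaks = pd.DataFrame({
            "chrom": "chr1", "start": [100, 300_000, 400_000, 500_000,
                                       600_000, 700_000, 800_000, 900_000,
                                       950_000, 5_100],
            "end": [600, 300_500, 400_500, 500_500, 600_500, 700_500,
                    800_500, 900_500, 950_500, 5_600]})
        up = pd.DataFrame({"chrom": ["chr1"], "start": [5_100], "end": [5_600]})
        out = regulatory_overlap_delta({"all": all_peaks, "up": up},
                                       self._elements())
        dels = out[out["cls"] == "dELS"].iloc[0]
        assert dels["pct_all"] == pytest.approx(10.0)
        assert dels["pct_up"] == pytest.approx(100.0)
        assert dels["delta_up"] == pytest.approx(90.0)

    def test_empty_elements(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        out = regulatory_overlap_delta(
            {"all": peaks, "up": peaks},
            pd.DataFrame(columns=["chrom", "start", "end", "cls"]))
        assert (out.filter(like="pct_").to_numpy() == 0).all()


def _deterministic_motif(consensus="ACGT"):
    pfm = np.zeros((4, len(consensus)))
    for k, b in enumerate(consensus):
        pfm["ACGT".index(b), k] = 1.0
    return MotifModel(id=f"M_{consensus}", pfm=pfm)


class TestMotifScan:
    def test_consensus_scores_two_bits_per_base(self):
        m = _deterministic_motif("ACGT")
        hits = motif_scan("ACGT", m, threshold=7.9)
        fwd = hits[hits.strand == "+"]
        assert len(fwd) == 1
        # pseudocount 1e-3 shaves a hair off the ideal 8 bits
        assert fwd.iloc[0]["bits"] == pytest.approx(4 * np.log2(1 / 0.25), abs=0.02)

    def test_reverse_complement_symmetry(self):
        m = _deterministic_motif("ACGG")
        seq = "TTACGGTTTTCCGTAA"
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        h1 = motif_scan(seq, m, threshold=7.5)
        h2 = motif_scan(rc, m, threshold=7.5)
        assert len(h1) == len(h2)
        assert sorted(h1["strand"]) == sorted(
            {"+": "-", "-": "+"}[s] for s in h2["strand"])

    def test_occurrences_match_string_count_oracle(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        m = _deterministic_motif("ACGT")
        hits = motif_scan(seq, m, threshold=7.9)
        rc = "ACGT"[::-1].translate(str.maketrans("ACGT", "TGCA"))
        expected = sum(seq[i:i + 4] == "ACGT" for i in range(len(seq) - 3))
        expected_rc = sum(seq[i:i + 4] == rc for i in range(len(seq) - 3))
        # palindromic check avoided: ACGT's revcomp is ACGT itself
        assert rc == "ACGT"
        assert len(hits) == expected + expected_rc

    def test_motif_longer_than_sequence(self):
        assert len(motif_scan("ACG", _deterministic_motif("ACGT"))) == 0

    def test_n_bases_score_as_background(self):
        m = _deterministic_motif("ACGT")
        hits = motif_scan("NCGT", m, threshold=5.9)  # 3 matched bases = ~6 bits
        assert len(hits[hits.strand == "+"]) == 1


class TestMotifEnrichment:
    def test_exact_hypergeometric_case(self):
        """Universe 10, 5 hits total, 4 targets all hits:
        p = C(5,4) C(5,0) / C(10,4)."""
        m = _deterministic_motif("ACGTACGT")
        hit_seq = "ACGTACGT" + "A" * 8
        miss_seq = "C" * 16
        targets = {f"t{i}": hit_seq for i in range(4)}
        background = {"b0": hit_seq, **{f"b{i}": miss_seq for i in range(1, 6)}}
        tab = motif_enrichment(targets, background, [m])
        from math import comb
        expected = comb(5, 4) * comb(5, 0) / comb(10, 4)
        assert tab.iloc[0]["p"] == pytest.approx(expected)

    def test_null_motif_not_enriched(self):
        rng = np.random.default_rng(5)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=60))
                for i in range(60)}
        targets = {k: v for k, v in list(seqs.items())[:20]}
        background = {k: v for k, v in list(seqs.items())[20:]}
        m = _deterministic_motif("ACGT")
        tab = motif_enrichment(targets, background, [m], threshold=7.9)
        assert tab.iloc[0]["p"] > 0.01

    def test_hypergeometric_matches_permutation_null(self):
        """Label-shuffling null reproduces the hypergeometric tail."""
        rng = np.random.default_rng(6)
        n_t, n_b = 30, 70
        hits = np.zeros(n_t + n_b, dtype=bool)
        hits[rng.choice(n_t + n_b, size=40, replace=False)] = True
        obs = int(hits[:n_t].sum())
        p_exact = stats.hypergeom.sf(obs - 1, n_t + n_b, 40, n_t)
        draws = 10_000
        count = 0
        for _ in range(draws):
            perm = rng.permutation(hits)
            if perm[:n_t].sum() >= obs:
                count += 1
        p_mc = count / draws
        assert p_mc == pytest.approx(p_exact, abs=4 * np.sqrt(p_exact / draws) + 0.01)

    def test_overlapping_universe_rejected(self):
        m = _deterministic_motif("ACGT")
        with pytest.raises(ValueError):
            motif_enrichment({"x": "ACGT"}, {"x": "ACGT"}, [m])
        with pytest.raises(ValueError):
            motif_enrichment({}, {"x": "ACGT"}, [m])
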