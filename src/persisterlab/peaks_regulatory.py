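"""Consensus-peak construction, peak filtering/annotation, and PWM motif
scanning/enrichment for ATAC-seq-style accessibility data.

Consensus peaks follow the fixed-width convention: each per-sample peak
summit is expanded to a 500 bp window (summit +/- 250 bp) and a
non-overlapping genome-wide set is selected greedily by descending score.
Peaks are annotated to the nearest transcription start site (TSS) and
assigned to a gene only within 100 kb. Motifs are position frequency
matrices scored as log2-odds against a background nucleotide model on both
strands.

Coordinates are 0-based half-open throughout; narrowPeak I/O converts per
the BED convention (summit stored as an offset from the window start).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust, normalize_log_cpm

__all__ = [
    "PEAK_WIDTH",
    "MotifModel",
    "build_consensus",
    "filter_peak_counts",
    "annotate_peaks",
    "feature_proportions",
    "regulatory_overlap_delta",
    "motif_scan",
    "motif_enrichment",
]

PEAK_WIDTH = 500
HALF_WIDTH = PEAK_WIDTH // 2

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifModel:
    """A transcription-factor binding motif as a position frequency matrix.

    ``pfm`` has shape (4, width) with rows A, C, G, T; columns are
    normalised to sum to 1 after adding ``pseudocount``. Scores are
    log2-odds against ``background`` (A, C, G, T frequencies).
    """

    id: str
    pfm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 8.0  # bits
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()
        p = self.pfm + self.pseudocount
        self._probs = p / p.sum(axis=0, keepdims=True)
        self._logodds = np.log2(self._probs / self.background[:, None])

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self._probs, axis=0))

    def max_score(self) -> float:
        return float(self._logodds.max(axis=0).sum())


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to row indices; N (or anything else) -> 4."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.full(len(seq), 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        idx[raw == ord(base)] = i
    return idx


# ---------------------------------------------------------------------------
# consensus peaks


def build_consensus(summits: pd.DataFrame,
                    chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Greedy maximal-score non-overlapping consensus peaks.

    Parameters
    ----------
    summits
        Per-sample peak summits: columns ``sample``, ``chrom``, ``summit``
        (absolute bp) and ``score``. Each summit is expanded to a 500 bp
        window (summit-250, summit+250).
    chrom_sizes
        Optional chromosome lengths used to clip windows at ends (clipped
        windows still count as nominal 500 bp width downstream).

    Returns
    -------
    DataFrame with columns chrom, start, end, summit, score,
    ``called_<sample>`` boolean flags (a sample calls a consensus peak when
    any of its windows overlaps it), sorted by (chrom, start).
    """
    req = {"sample", "chrom", "summit", "score"}
    if not req.issubset(summits.columns):
        raise ValueError(f"summits must have columns {sorted(req)}")
    if len(summits) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "summit", "score"])
    df = summits.copy().reset_index(drop=True)
    df["start"] = df["summit"].astype(int) - HALF_WIDTH
    df["end"] = df["start"] + PEAK_WIDTH
    if chrom_sizes is not None:
        for chrom, size in chrom_sizes.items():
            m = df["chrom"] == chrom
            df.loc[m, "start"] = df.loc[m, "start"].clip(lower=0)
            df.loc[m, "end"] = df.loc[m, "end"].clip(upper=size)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("malformed summit window (out of chromosome bounds?)")

    # greedy by descending score; ties resolved leftmost (chrom, start)
    order = df.sort_values(["score", "chrom", "start"],
                           ascending=[False, True, True],
                           kind="mergesort").index
    kept_starts: dict[str, list[int]] = {}
    kept_ends: dict[str, list[int]] = {}
    kept_idx: list[int] = []
    for i in order:
        chrom = df.at[i, "chrom"]
        s, e = int(df.at[i, "start"]), int(df.at[i, "end"])
        starts = kept_starts.setdefault(chrom, [])
        ends = kept_ends.setdefault(chrom, [])
        j = bisect.bisect_right(starts, s)
        # overlap with predecessor or successor retained interval?
        if j > 0 and ends[j - 1] > s:
            continue
        if j < len(starts) and starts[j] < e:
            continue
        starts.insert(j, s)
        ends.insert(j, e)
        kept_idx.append(i)

    kept = df.loc[kept_idx, ["chrom", "start", "end", "summit", "score"]].copy()
    kept = kept.sort_values(["chrom", "start"]).reset_index(drop=True)

    # per-sample called flags via interval overlap with all input windows
    samples = sorted(summits["sample"].unique())
    flags = {s: np.zeros(len(kept), dtype=bool) for s in samples}
    for chrom, grp in df.groupby("chrom", sort=False):
        sel = (kept["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        kstart = kept.loc[sel, "start"].to_numpy()
        kend = kept.loc[sel, "end"].to_numpy()
        kpos = np.flatnonzero(sel)
        for s0, e0, sample in zip(grp["start"], grp["end"], grp["sample"]):
            lo = int(np.searchsorted(kend, s0, side="right"))
            hi = int(np.searchsorted(kstart, e0, side="left"))
            if hi > lo:
                flags[sample][kpos[lo:hi]] = True
    for sample in samples:
        kept[f"called_{sample}"] = flags[sample]
    return kept


def filter_peak_counts(counts: pd.DataFrame, called: pd.DataFrame,
                       groups: dict[str, str], min_log_cpm: float = 2.0,
                       prior_count: float = 0.5) -> pd.Index:
    """Retain peaks with (max over groups of group-mean log2 CPM) >= 2 AND
    called in all replicates of at least one group.

    ``counts`` and ``called`` are peak x sample (identical indexing);
    ``groups`` maps sample -> experimental group.
    """
    if counts.shape != called.shape or list(counts.columns) != list(called.columns):
        raise ValueError("counts and called-flag matrices must align")
    logcpm = normalize_log_cpm(counts, prior_count=prior_count)
    group_of = pd.Series(groups)
    abundant = pd.Series(False, index=counts.index)
    reproducible = pd.Series(False, index=counts.index)
    for g in group_of.unique():
        cols = group_of.index[group_of == g]
        abundant |= logcpm[cols].mean(axis=1) >= min_log_cpm
        reproducible |= called[cols].all(axis=1)
    return counts.index[abundant & reproducible]


# ---------------------------------------------------------------------------
# annotation


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                   max_distance: int = 100_000,
                   promoter_window: int = 2_000) -> pd.DataFrame:
    """Annotate peaks with nearest gene TSS and a feature class.

    ``genes`` needs columns gene_id, chrom, tss, strand, start, end.
    A peak is assigned to its nearest TSS only when the peak center lies
    within ``max_distance`` (default 100 kb). Feature classes: ``promoter``
    when the center lies within TSS +/- ``promoter_window``; else
    ``gene_body`` when it lies within any gene's extent; else
    ``distal_intergenic``. The signed distance is center - TSS, flipped
    for minus-strand genes so positive means downstream of the TSS.
    """
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    out = peaks.reset_index(drop=True).copy()
    centers = ((out["start"] + out["end"]) // 2).to_numpy()
    gene_id = np.full(len(out), None, dtype=object)
    distance = np.full(len(out), np.nan)
    feature = np.full(len(out), "distal_intergenic", dtype=object)

    for chrom, gsub in genes.groupby("chrom", sort=False):
        sel = (out["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        c = centers[sel]
        order = np.argsort(gsub["tss"].to_numpy())
        gs = gsub.iloc[order]
        tss_sorted = gs["tss"].to_numpy()
        pos = np.searchsorted(tss_sorted, c)
        best_j = np.zeros(len(c), dtype=int)
        best_d = np.full(len(c), np.inf)
        for cand in (pos - 1, pos):
            ok = (cand >= 0) & (cand < len(tss_sorted))
            safe = np.clip(cand, 0, len(tss_sorted) - 1)
            d = np.where(ok, np.abs(c - tss_sorted[safe]), np.inf)
            better = d < best_d
            best_d = np.where(better, d, best_d)
            best_j = np.where(better, safe, best_j)
        g = gs.iloc[best_j]
        within = best_d <= max_distance
        idx = np.flatnonzero(sel)
        signed = (c - g["tss"].to_numpy()) * np.where(
            g["strand"].to_numpy() == "-", -1, 1)
        gene_id[idx[within]] = g["gene_id"].to_numpy()[within]
        distance[idx[within]] = signed[within]
        prom = best_d <= promoter_window
        feature[idx[within & prom]] = "promoter"
        # gene body: center within any gene extent on this chromosome
        gb = gsub.sort_values("start")
        starts = gb["start"].to_numpy()
        cummax_end = np.maximum.accumulate(gb["end"].to_numpy())
        k = np.searchsorted(starts, c, side="right") - 1
        safe_k = np.clip(k, 0, None)
        in_body = (k >= 0) & (cummax_end[safe_k] > c)
        feature[idx[within & ~prom & in_body]] = "gene_body"
    out["gene_id"] = gene_id
    out["tss_distance"] = distance
    out["feature"] = feature
    return out


def feature_proportions(annotated: pd.DataFrame) -> pd.Series:
    """Proportion of peaks per feature class (sums to 1)."""
    counts = annotated["feature"].value_counts()
    for cls in ("promoter", "gene_body", "distal_intergenic"):
        if cls not in counts.index:
            counts.loc[cls] = 0
    return (counts / counts.sum()).sort_index()


def _overlap_fraction(peaks: pd.DataFrame, elements: pd.DataFrame) -> float:
    """Fraction of peaks overlapping >= 1 element."""
    if len(peaks) == 0:
        return float("nan")
    if len(elements) == 0:
        return 0.0
    hit = np.zeros(len(peaks), dtype=bool)
    peaks = peaks.reset_index(drop=True)
    for chrom, esub in elements.groupby("chrom", sort=False):
        sel = (peaks["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        es = esub.sort_values("start")
        estarts = es["start"].to_numpy()
        cummax_end = np.maximum.accumulate(es["end"].to_numpy())
        ps = peaks.loc[sel, "start"].to_numpy()
        pe = peaks.loc[sel, "end"].to_numpy()
        j = np.searchsorted(estarts, pe, side="left") - 1
        ok = (j >= 0) & (cummax_end[np.clip(j, 0, None)] > ps)
        hit[np.flatnonzero(sel)] |= ok
    return float(hit.mean())


def regulatory_overlap_delta(peak_sets: dict[str, pd.DataFrame],
                             elements: pd.DataFrame) -> pd.DataFrame:
    """Percent of peaks overlapping each regulatory-element class, and the
    difference (percentage points) of each non-reference set versus the
    ``all`` consensus set.

    ``elements`` needs columns chrom, start, end, cls (e.g. dELS / pELS /
    PLS as in ENCODE SCREEN).
    """
    if "all" not in peak_sets:
        raise ValueError("peak_sets must include an 'all' reference set")
    classes = sorted(elements["cls"].unique()) if len(elements) else ["PLS", "dELS", "pELS"]
    rows = []
    for cls in classes:
        esub = elements[elements["cls"] == cls] if len(elements) else elements
        pct = {name: 100.0 * _overlap_fraction(df, esub)
               for name, df in peak_sets.items()}
        row: dict[str, object] = {"cls": cls}
        for name, v in pct.items():
            row[f"pct_{name}"] = v
            if name != "all":
                row[f"delta_{name}"] = v - pct["all"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motifs


def motif_scan(sequence: str, motif: MotifModel,
               threshold: float | None = None) -> pd.DataFrame:
    """Scan a sequence with a PWM on both strands.

    Returns occurrences with columns offset (0-based position of the match
    window on the forward strand), strand (+/-) and bits (log2-odds
    score). N positions contribute 0 bits (background odds). A motif
    longer than the sequence yields an empty result.
    """
    thr = motif.threshold if threshold is None else threshold
    w = motif.width
    cols = ["offset", "strand", "bits"]
    if w > len(sequence):
        return pd.DataFrame(columns=cols)
    seq = sequence.upper()
    lo = np.vstack([motif._logodds, np.zeros(w)])  # row 4 = N -> 0 bits
    lo_rc = lo[[3, 2, 1, 0, 4]][:, ::-1]  # reverse-complement PWM
    idx = _encode(seq)
    n_pos = len(seq) - w + 1
    offsets = np.arange(n_pos)
    fwd = np.zeros(n_pos)
    rev = np.zeros(n_pos)
    for k in range(w):
        fwd += lo[idx[k:k + n_pos], k]
        rev += lo_rc[idx[k:k + n_pos], k]
    rows = []
    for strand, scores in (("+", fwd), ("-", rev)):
        sel = scores >= thr
        for off, bits in zip(offsets[sel], scores[sel]):
            rows.append({"offset": int(off), "strand": strand, "bits": float(bits)})
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["offset", "strand"]).reset_index(drop=True)


def motif_enrichment(target_seqs: dict[str, str], background_seqs: dict[str, str],
                     motifs: list[MotifModel],
                     threshold: float | None = None) -> pd.DataFrame:
    """Hypergeometric motif enrichment of target vs background peaks.

    A peak is a hit for a motif when it contains >= 1 occurrence at or
    above threshold. The universe is targets + background (disjoint); the
    one-sided (enrichment) hypergeometric upper-tail p is adjusted across
    motifs by Benjamini-Hochberg and the table ranked by ascending FDR.
    """
    if len(target_seqs) == 0:
        raise ValueError("no target sequences")
    overlap = set(target_seqs) & set(background_seqs)
    if overlap:
        raise ValueError(f"targets and background overlap: {sorted(overlap)[:3]}")
    n_t, n_b = len(target_seqs), len(background_seqs)
    N = n_t + n_b
    rows = []
    for motif in motifs:
        t_hits = sum(len(motif_scan(s, motif, threshold)) > 0
                     for s in target_seqs.values())
        b_hits = sum(len(motif_scan(s, motif, threshold)) > 0
                     for s in background_seqs.values())
        K = t_hits + b_hits
        p = float(stats.hypergeom.sf(t_hits - 1, N, K, n_t))
        rows.append(
            {
                "motif": motif.id,
                "target_hits": t_hits,
                "target_fraction": t_hits / n_t,
                "background_hits": b_hits,
                "background_fraction": b_hits / n_b if n_b else float("nan"),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["fdr", "p", "motif"]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
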