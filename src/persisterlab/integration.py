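"""Cross-cell-line meta-analysis, RNA-ATAC concordance, merged enrichment.

Differential peak tables from individual cell lines are intersected on
their genomic intervals; peaks present in every line are summarised by
the arithmetic mean log2 fold change and a Fisher combination of the
per-line adjusted p-values (X = -2 sum ln p compared to chi-square with
2k degrees of freedom). Genes are then classified by whether expression
and linked chromatin accessibility change together (concordant up/down:
at least two-fold in the same direction in both assays at FDR < 0.005),
and merged RNA+ATAC evidence genes are tested against gene sets with a
one-sided hypergeometric test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "fisher_combine",
    "meta_intersect",
    "classify_concordance",
    "merged_enrichment",
    "CONCORDANCE_CLASSES",
]

CONCORDANCE_CLASSES = (
    "concordant_up",
    "concordant_down",
    "discordant",
    "rna_only",
    "atac_only",
    "ns",
)


def fisher_combine(pvalues) -> tuple[float, float]:
    """Fisher's method: returns (X, combined_p) with X = -2 sum ln p and
    combined_p the upper tail of chi-square with 2k degrees of freedom."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, 1e-300, 1.0)
    X = float(-2.0 * np.log(p).sum())
    return X, float(stats.chi2.sf(X, 2 * len(p)))


def meta_intersect(tables: dict[str, pd.DataFrame],
                   min_reciprocal_overlap: float = 0.5) -> pd.DataFrame:
    """Intersect per-cell-line differential peak tables on genome intervals.

    Each table needs columns chrom, start, end, log2fc, adj_p. The first
    table's intervals anchor the output; an anchor is kept when every
    other line has a peak overlapping it reciprocally by at least
    ``min_reciprocal_overlap`` of both widths (the best-overlapping peak
    is used if several qualify). Records where all contributing fold
    changes share a sign are marked ``consistent_direction``; inconsistent
    records are retained but flagged. The average fold change and the
    Fisher combination of the contributing adjusted p-values summarise
    each record.
    """
    if len(tables) == 0:
        raise ValueError("no cell-line tables given")
    lines = list(tables)
    anchor = tables[lines[0]].reset_index(drop=True)
    per_line_match: dict[str, pd.DataFrame] = {lines[0]: anchor}
    keep = np.ones(len(anchor), dtype=bool)
    for line in lines[1:]:
        other = tables[line].reset_index(drop=True)
        match_idx = np.full(len(anchor), -1)
        for chrom, osub in other.groupby("chrom", sort=False):
            sel = (anchor["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            ostart = osub["start"].to_numpy()
            oend = osub["end"].to_numpy()
            order = np.argsort(ostart)
            ostart_s, oend_s = ostart[order], oend[order]
            oidx = osub.index.to_numpy()[order]
            for i in np.flatnonzero(sel):
                s, e = anchor.at[i, "start"], anchor.at[i, "end"]
                lo = np.searchsorted(oend_s, s, side="right")
                hi = np.searchsorted(ostart_s, e, side="left")
                best, best_ov = -1, 0
                for k in range(lo, hi):
                    ov = min(e, oend_s[k]) - max(s, ostart_s[k])
                    w_a, w_o = e - s, oend_s[k] - ostart_s[k]
                    if (ov >= min_reciprocal_overlap * w_a
                            and ov >= min_reciprocal_overlap * w_o
                            and ov > best_ov):
                        best, best_ov = oidx[k], ov
                match_idx[i] = best
        keep &= match_idx >= 0
        per_line_match[line] = other.reindex(
            np.where(match_idx >= 0, match_idx, 0))

    rows = []
    for i in np.flatnonzero(keep):
        lfcs = [float(per_line_match[ln].iloc[i]["log2fc"]) for ln in lines]
        ps = [float(per_line_match[ln].iloc[i]["adj_p"]) for ln in lines]
        X, combined = fisher_combine(ps)
        signs = np.sign(lfcs)
        row = {
            "chrom": anchor.at[i, "chrom"],
            "start": int(anchor.at[i, "start"]),
            "end": int(anchor.at[i, "end"]),
            "n_lines": len(lines),
            "avg_log2fc": float(np.mean(lfcs)),
            "consistent_direction": bool(np.all(signs == signs[0]) and signs[0] != 0),
            "fisher_statistic": X,
            "combined_p": combined,
        }
        for ln, lfc, p in zip(lines, lfcs, ps):
            row[f"log2fc_{ln}"] = lfc
            row[f"adj_p_{ln}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def classify_concordance(rna: pd.DataFrame, atac: pd.DataFrame,
                         links: pd.DataFrame, fdr_cut: float = 0.005,
                         lfc_cut: float = 1.0,
                         multi_peak: str = "mean") -> pd.DataFrame:
    """Classify genes by joint RNA/ATAC behaviour.

    Parameters
    ----------
    rna
        Per-gene table indexed by gene_id with columns log2fc, fdr.
    atac
        Per-peak table indexed by peak_id with columns log2fc, fdr.
    links
        peak -> gene links (columns peak_id, gene_id), e.g. from
        nearest-TSS annotation within 100 kb.
    multi_peak
        "mean" averages log2fc over a gene's significant linked peaks;
        "strongest" takes the peak with the largest |log2fc|.

    Returns one row per RNA gene with the ATAC summary and a class in
    ``CONCORDANCE_CLASSES``; classes partition the gene list. A gene is
    significant in an assay when FDR < fdr_cut and |log2fc| >= lfc_cut;
    concordant_up/down require significance and the same direction in
    both assays.
    """
    if rna.index.duplicated().any():
        raise ValueError("duplicate gene rows in RNA table")
    sig_peaks = atac[(atac["fdr"] < fdr_cut) & (atac["log2fc"].abs() >= lfc_cut)]
    linked = links.merge(sig_peaks, left_on="peak_id", right_index=True)
    if multi_peak == "mean":
        atac_by_gene = linked.groupby("gene_id")["log2fc"].mean()
    elif multi_peak == "strongest":
        best_idx = linked.groupby("gene_id")["log2fc"].apply(
            lambda s: s.abs().idxmax())
        atac_by_gene = linked.loc[best_idx].set_index("gene_id")["log2fc"]
    else:
        raise ValueError(f"unknown multi_peak {multi_peak!r}")
    atac_fdr_by_gene = linked.groupby("gene_id")["fdr"].min()

    rows = []
    for gene, r in rna.iterrows():
        rna_sig = (r["fdr"] < fdr_cut) and (abs(r["log2fc"]) >= lfc_cut)
        a_lfc = float(atac_by_gene.get(gene, np.nan))
        a_fdr = float(atac_fdr_by_gene.get(gene, np.nan))
        atac_sig = np.isfinite(a_lfc)  # by construction passed both cuts
        if rna_sig and atac_sig:
            if r["log2fc"] > 0 and a_lfc > 0:
                cls = "concordant_up"
            elif r["log2fc"] < 0 and a_lfc < 0:
                cls = "concordant_down"
            else:
                cls = "discordant"
        elif rna_sig:
            cls = "rna_only"
        elif atac_sig:
            cls = "atac_only"
        else:
            cls = "ns"
        rows.append(
            {
                "gene_id": gene,
                "rna_log2fc": float(r["log2fc"]),
                "rna_fdr": float(r["fdr"]),
                "atac_log2fc": a_lfc,
                "atac_fdr": a_fdr,
                "cls": cls,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def merged_enrichment(rna: pd.DataFrame, atac: pd.DataFrame,
                      links: pd.DataFrame, gene_sets: dict[str, list[str]],
                      lfc_cut: float = 1.0, p_cut: float = 0.005
                      ) -> pd.DataFrame:
    """Hypergeometric pathway enrichment of merged RNA+ATAC evidence genes.

    Evidence genes are the union of RNA genes and (via peak->gene links)
    ATAC genes passing |log2fc| >= lfc_cut (two-fold by default) and
    adjusted p < p_cut. The universe is all RNA-tested genes. Per set the
    one-sided upper-tail hypergeometric p of the evidence overlap is BH
    adjusted across sets; per-gene evidence labels (rna/atac/both) are
    reported.
    """
    universe = list(rna.index)
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    rna_ev = set(rna.index[(rna["fdr"] < p_cut) & (rna["log2fc"].abs() >= lfc_cut)])
    sig_peaks = atac[(atac["fdr"] < p_cut) & (atac["log2fc"].abs() >= lfc_cut)]
    atac_ev = set(links.merge(sig_peaks, left_on="peak_id",
                              right_index=True)["gene_id"]) & set(universe)
    evidence = rna_ev | atac_ev
    N, K = len(universe), len(evidence)
    uni = set(universe)
    rows = []
    for name, members in gene_sets.items():
        members_in = sorted(set(members) & uni)
        n = len(members_in)
        hits = sorted(set(members_in) & evidence)
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        labels = []
        for g in hits:
            src = ("both" if g in rna_ev and g in atac_ev
                   else "rna" if g in rna_ev else "atac")
            labels.append(f"{g}:{src}")
        rows.append(
            {
                "gene_set": name,
                "set_size": n,
                "overlap": k,
                "evidence_size": K,
                "universe": N,
                "p": p,
                "evidence_genes": ";".join(labels),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["fdr", "p", "gene_set"]).reset_index(drop=True)
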