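"""Synthetic multi-omics data under the persister study design.

Generates, with ground truth attached to everything planted:

* a small synthetic genome (chromosomes, non-overlapping genes with TSS
  and strand, regulatory elements classed PLS/pELS/dELS by TSS distance);
* RNA-seq-style gene x sample negative-binomial count matrices under the
  treatment time course (DMSO, acute, DTP, short/long washout) with
  temporal-archetype effects and cell-line-dominant baseline structure;
* ATAC-seq-style per-sample peak calls with jittered summits plus a
  peak x sample count matrix, with gained peaks optionally linked to
  concordantly regulated genes within 100 kb of their TSS;
* peak sequences with a PWM motif planted at a controlled occupancy;
* a signed directed regulator->target network with one planted active
  regulator.

All generators are deterministic in their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks_regulatory import MotifModel, PEAK_WIDTH

__all__ = [
    "SyntheticGenome",
    "DesignMatrixSpec",
    "TREATMENTS",
    "ARCHETYPES",
    "make_genome",
    "make_effects",
    "simulate_counts",
    "make_peak_effects",
    "simulate_peaks",
    "embed_motifs",
    "make_network",
]

TREATMENTS = ("DMSO", "acute", "DTP", "short_washout", "long_washout")

# temporal archetypes of log2 fold change vs DMSO across the time course,
# emulating the recurring cluster shapes: (acute, DTP, short, long washout)
ARCHETYPES: dict[int, dict[str, float]] = {
    1: {"acute": -2.0, "DTP": -1.0, "short_washout": -0.5, "long_washout": 0.0},
    2: {"acute": 2.0, "DTP": 0.0, "short_washout": 0.0, "long_washout": 0.0},
    3: {"acute": 0.0, "DTP": 2.0, "short_washout": 2.0, "long_washout": 1.5},
    4: {"acute": 0.0, "DTP": -2.0, "short_washout": -2.0, "long_washout": -1.5},
}


@dataclass
class SyntheticGenome:
    """Chromosomes, genes (with TSS/strand/extent) and regulatory elements."""

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, start, end
    elements: pd.DataFrame  # chrom, start, end, cls

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass(frozen=True)
class DesignMatrixSpec:
    """Experimental design: cell lines x treatments x replicates."""

    cell_lines: tuple[str, ...] = ("PC9s", "H1975s", "HCC827s", "HCC2935s")
    treatments: tuple[str, ...] = TREATMENTS
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group for variance estimation")

    def samples(self) -> pd.DataFrame:
        rows = [
            {
                "sample": f"{line}_{tr}_r{rep}",
                "cell_line": line,
                "treatment": tr,
                "replicate": rep,
            }
            for line in self.cell_lines
            for tr in self.treatments
            for rep in range(1, self.replicates + 1)
        ]
        return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# genome


def _place_nonoverlapping(rng: np.random.Generator, chrom_len: int,
                          lengths: np.ndarray) -> np.ndarray:
    """Starts for non-overlapping intervals of given lengths on [0, chrom_len)."""
    total = int(lengths.sum())
    free = chrom_len - total
    if free < 0:
        raise ValueError("genome too small to place features")
    gaps = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return starts


def make_genome(n_chrom: int = 2, n_genes: int = 200, n_elements: int = 300,
                chrom_length: int = 2_000_000, seed: int = 0,
                element_max_distance: int | None = None) -> SyntheticGenome:
    """Build a synthetic genome.

    Genes are uniformly placed without overlap; elements are placed
    uniformly (or within ``element_max_distance`` of a random TSS when
    given) and classed by the distance of their center to the nearest TSS:
    promoter-like (PLS) within 200 bp, proximal enhancer-like (pELS)
    within 2 kb, distal enhancer-like (dELS) beyond.
    """
    if n_chrom < 1 or n_genes < 0 or n_elements < 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]

    gene_rows = []
    per_chrom = np.array_split(np.arange(n_genes), n_chrom)
    for (chrom, clen), idx in zip(chroms, per_chrom):
        if len(idx) == 0:
            continue
        lengths = rng.integers(2_000, 20_000, size=len(idx))
        starts = _place_nonoverlapping(rng, clen, lengths)
        strands = rng.choice(["+", "-"], size=len(idx))
        for g, s, L, st in zip(idx, starts, lengths, strands):
            end = int(s + L)
            gene_rows.append(
                {
                    "gene_id": f"gene{g + 1:04d}",
                    "chrom": chrom,
                    "start": int(s),
                    "end": end,
                    "strand": st,
                    "tss": int(s) if st == "+" else end,
                }
            )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )

    elem_rows = []
    if n_elements and len(genes):
        tss_by_chrom = {c: np.sort(g["tss"].to_numpy())
                        for c, g in genes.groupby("chrom")}
        for i in range(n_elements):
            width = int(rng.integers(150, 350))
            if element_max_distance is not None:
                g = genes.iloc[int(rng.integers(0, len(genes)))]
                offset = int(rng.integers(-element_max_distance, element_max_distance + 1))
                chrom = g["chrom"]
                clen = dict(chroms)[chrom]
                center = int(np.clip(g["tss"] + offset, width // 2, clen - width // 2))
            else:
                chrom, clen = chroms[int(rng.integers(0, n_chrom))]
                center = int(rng.integers(width // 2, clen - width // 2))
            start = center - width // 2
            tss = tss_by_chrom.get(chrom, np.array([]))
            if len(tss):
                j = np.searchsorted(tss, center)
                cands = [tss[k] for k in (j - 1, j) if 0 <= k < len(tss)]
                dist = min(abs(center - t) for t in cands)
            else:
                dist = np.inf
            cls = "PLS" if dist <= 200 else ("pELS" if dist <= 2_000 else "dELS")
            elem_rows.append(
                {"chrom": chrom, "start": start, "end": start + width, "cls": cls}
            )
    elements = pd.DataFrame(elem_rows, columns=["chrom", "start", "end", "cls"])
    return SyntheticGenome(chromosomes=chroms, genes=genes, elements=elements)


# ---------------------------------------------------------------------------
# RNA counts


def make_effects(genome: SyntheticGenome, n_diff: int = 200,
                 lfc_scale: float = 1.0, dispersion: float = 0.05,
                 concordant_fraction: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Per-gene effect table: archetype id (0 = null), per-treatment log2
    fold change vs DMSO, baseline mean, NB dispersion, concordant flag.

    ``lfc_scale`` multiplies the archetype magnitudes; a ``concordant``
    subset of the DTP-responsive genes is flagged for same-direction
    chromatin effects downstream.
    """
    rng = np.random.default_rng(seed)
    genes = genome.genes["gene_id"].tolist()
    n_diff = min(n_diff, len(genes))
    diff_idx = rng.choice(len(genes), size=n_diff, replace=False)
    arch = np.zeros(len(genes), dtype=int)
    arch[diff_idx] = rng.integers(1, len(ARCHETYPES) + 1, size=n_diff)
    rows = []
    for i, g in enumerate(genes):
        a = int(arch[i])
        lfc = {t: 0.0 for t in TREATMENTS[1:]}
        if a:
            lfc = {t: ARCHETYPES[a][t] * lfc_scale for t in TREATMENTS[1:]}
        dtp_responsive = a in (3, 4)
        rows.append(
            {
                "gene_id": g,
                "archetype": a,
                **{f"lfc_{t}": lfc[t] for t in TREATMENTS[1:]},
                "baseline": float(np.exp(rng.normal(5.0, 1.2))),
                "dispersion": dispersion,
                "concordant": bool(dtp_responsive and rng.random() < concordant_fraction),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2); phi = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ValueError("negative NB means")
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        n = 1.0 / phi[~pois]
        p = n / (n + mean[~pois])
        out[~pois] = rng.negative_binomial(n, p)
    return out


def simulate_counts(genome: SyntheticGenome, design: DesignMatrixSpec,
                    effects: pd.DataFrame, seed: int = 0,
                    line_sd: float = 1.0, size_factor_sd: float = 0.1
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample negative-binomial counts under the design.

    Mean = baseline * cell-line offset * 2^lfc(treatment) * size factor.
    Per-(gene, cell line) lognormal baseline offsets create the
    cell-line-dominant variance structure typical of cell-panel RNA-seq;
    library size factors are lognormal(0, ``size_factor_sd``).

    Returns (counts, samples) where samples is the design sample sheet.
    """
    rng = np.random.default_rng(seed)
    samples = design.samples()
    genes = effects.index
    base = effects["baseline"].to_numpy()[:, None]
    phi = effects["dispersion"].to_numpy()[:, None]
    line_offsets = {
        line: np.exp(rng.normal(0.0, line_sd, size=len(genes)))
        for line in design.cell_lines
    }
    sf = np.exp(rng.normal(0.0, size_factor_sd, size=len(samples)))
    lfc_cols = {t: effects[f"lfc_{t}"].to_numpy()
                for t in design.treatments if f"lfc_{t}" in effects.columns}
    means = np.empty((len(genes), len(samples)))
    for j, (_, row) in enumerate(samples.iterrows()):
        lfc = lfc_cols.get(row["treatment"], np.zeros(len(genes)))
        means[:, j] = (base[:, 0] * line_offsets[row["cell_line"]]
                       * 2.0 ** lfc * sf[j])
    counts = _nb_draw(rng, means, phi)
    return pd.DataFrame(counts, index=genes, columns=samples.index), samples


# ---------------------------------------------------------------------------
# ATAC peaks


def make_peak_effects(genome: SyntheticGenome, rna_effects: pd.DataFrame,
                      n_peaks: int = 1000, frac_gained: float = 0.1,
                      frac_lost: float = 0.05, lfc: float = 2.0,
                      dispersion: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """True peak locations with planted DTP accessibility changes.

    Gained peaks are preferentially placed within 100 kb of the TSS of
    genes flagged ``concordant`` with archetype 3 (up in DTPs), and lost
    peaks near concordant archetype-4 genes, so the RNA and ATAC effects
    agree in direction for those genes. Remaining peaks are background.
    """
    rng = np.random.default_rng(seed)
    sizes = genome.chrom_sizes
    n_gain = int(round(n_peaks * frac_gained))
    n_loss = int(round(n_peaks * frac_lost))
    if n_gain + n_loss > n_peaks:
        raise ValueError("frac_gained + frac_lost exceed 1")

    genes = genome.genes.set_index("gene_id")
    up_genes = rna_effects.index[(rna_effects["archetype"] == 3)
                                 & rna_effects["concordant"]]
    dn_genes = rna_effects.index[(rna_effects["archetype"] == 4)
                                 & rna_effects["concordant"]]

    rows: list[dict] = []

    def near_gene_position(gene_id: str) -> tuple[str, int]:
        # close enough to the TSS that the linked gene is also the nearest
        # gene at typical synthetic gene densities (well inside 100 kb)
        g = genes.loc[gene_id]
        clen = sizes[g["chrom"]]
        offset = int(rng.integers(-5_000, 5_001))
        center = int(np.clip(g["tss"] + offset, PEAK_WIDTH, clen - PEAK_WIDTH))
        return g["chrom"], center

    for i in range(n_peaks):
        if i < n_gain:
            direction, dlfc = "gained", lfc
            gene = str(up_genes[i % len(up_genes)]) if len(up_genes) else None
        elif i < n_gain + n_loss:
            direction, dlfc = "lost", -lfc
            gene = str(dn_genes[i % len(dn_genes)]) if len(dn_genes) else None
        else:
            direction, dlfc, gene = "stable", 0.0, None
        if gene is not None:
            chrom, center = near_gene_position(gene)
        else:
            ci = int(rng.integers(0, len(genome.chromosomes)))
            chrom, clen = genome.chromosomes[ci]
            center = int(rng.integers(PEAK_WIDTH, clen - PEAK_WIDTH))
        rows.append(
            {
                "peak_id": f"peak{i + 1:05d}",
                "chrom": chrom,
                "summit": center,
                "direction": direction,
                "lfc_DTP": dlfc,
                "linked_gene": gene,
                "baseline": float(np.exp(rng.normal(4.5, 0.8))),
                "dispersion": dispersion,
            }
        )
    df = pd.DataFrame(rows).set_index("peak_id")
    # enforce spacing so planted peaks stay distinct after 500 bp expansion
    df = df.sort_values(["chrom", "summit"])
    keep, last = [], {}
    for pid, row in df.iterrows():
        if row["chrom"] in last and row["summit"] - last[row["chrom"]] < PEAK_WIDTH:
            continue
        last[row["chrom"]] = row["summit"]
        keep.append(pid)
    return df.loc[keep].sort_index()


def simulate_peaks(genome: SyntheticGenome, design: DesignMatrixSpec,
                   peak_effects: pd.DataFrame, seed: int = 0,
                   jitter_sd: float = 20.0, call_rate: float = 0.97,
                   size_factor_sd: float = 0.1
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample peak calls with jittered summits, plus a count matrix.

    Each true peak is reported by each sample with probability
    ``call_rate`` (DTP samples always report gained peaks; DMSO samples
    never report gained peaks at elevated counts but may still call the
    location at baseline). Summits are jittered N(0, jitter_sd); MACS2-like
    scores scale with abundance. Counts are NB with the planted DTP lfc.

    Returns (calls, counts, samples): ``calls`` long-format with columns
    sample, chrom, summit, score; counts is peak x sample.
    """
    rng = np.random.default_rng(seed)
    samples = design.samples()
    peaks = peak_effects
    sf = np.exp(rng.normal(0.0, size_factor_sd, size=len(samples)))
    base = peaks["baseline"].to_numpy()
    phi = peaks["dispersion"].to_numpy()
    lfc = peaks["lfc_DTP"].to_numpy()

    means = np.empty((len(peaks), len(samples)))
    for j, (_, row) in enumerate(samples.iterrows()):
        # accessibility effect applies in the DTP state (and, attenuated,
        # in short washout, mirroring persistent chromatin change)
        if row["treatment"] == "DTP":
            eff = lfc
        elif row["treatment"] == "short_washout":
            eff = 0.8 * lfc
        else:
            eff = np.zeros_like(lfc)
        means[:, j] = base * 2.0 ** eff * sf[j]
    counts = _nb_draw(rng, means, phi[:, None])
    counts_df = pd.DataFrame(counts, index=peaks.index, columns=samples.index)

    call_rows = []
    for j, sample in enumerate(samples.index):
        called = rng.random(len(peaks)) < call_rate
        # a sample only calls peaks that are reasonably covered in it
        called &= means[:, j] >= 8.0
        jit = rng.normal(0.0, jitter_sd, size=len(peaks)) if jitter_sd > 0 else \
            np.zeros(len(peaks))
        summits = (peaks["summit"].to_numpy() + np.round(jit)).astype(int)
        scores = 10.0 * np.log10(1.0 + counts[:, j]) + rng.normal(0, 0.5, len(peaks))
        for pid, c, s, sc in zip(peaks.index[called], peaks["chrom"][called],
                                 summits[called], scores[called]):
            call_rows.append({"sample": sample, "peak_id": pid, "chrom": c,
                              "summit": int(s), "score": float(max(sc, 0.1))})
    calls = pd.DataFrame(call_rows)
    return calls, counts_df, samples


# ---------------------------------------------------------------------------
# sequences with motifs


def embed_motifs(peak_ids: list[str], motif: MotifModel, occupancy: float,
                 gc: float = 0.41, length: int = PEAK_WIDTH, seed: int = 0
                 ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random sequences with a PWM instance planted in a fraction of peaks.

    Background bases are i.i.d. at the stated GC content; in ``occupancy``
    of the peaks a motif instance sampled from the PWM is inserted at a
    random offset on a random strand.

    Returns (sequences, truth) where truth records offset/strand per peak
    (-1 / '.' when no instance was planted).
    """
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must lie in [0, 1]")
    if motif.width > length:
        raise ValueError("motif longer than peak sequence")
    rng = np.random.default_rng(seed)
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seqs: dict[str, str] = {}
    truth_rows = []
    for pid in peak_ids:
        seq = rng.choice(bases, size=length, p=p_bg)
        planted = rng.random() < occupancy
        offset, strand = -1, "."
        if planted:
            inst = [bases[rng.choice(4, p=motif._probs[:, k])]
                    for k in range(motif.width)]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = [comp[b] for b in reversed(inst)]
            offset = int(rng.integers(0, length - motif.width + 1))
            seq[offset:offset + motif.width] = inst
        seqs[pid] = "".join(seq)
        truth_rows.append({"peak_id": pid, "planted": planted,
                           "offset": offset, "strand": strand})
    return seqs, pd.DataFrame(truth_rows).set_index("peak_id")


def random_motif(id: str, width: int = 8, sharpness: float = 25.0,
                 seed: int = 0) -> MotifModel:
    """A random informative PFM (Dirichlet columns peaked on one base),
    with its hit threshold set relative to its own maximum score."""
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(width):
        alpha = np.full(4, 0.5)
        alpha[rng.integers(0, 4)] = sharpness
        cols.append(rng.dirichlet(alpha))
    m = MotifModel(id=id, pfm=np.array(cols).T)
    m.threshold = 0.75 * m.max_score()
    return m


# ---------------------------------------------------------------------------
# signed regulator network


def make_network(n_regulators: int = 20, targets_per_regulator: int = 50,
                 positive_sign_fraction: float = 0.6,
                 planted_regulator: str = "REG01",
                 planted_direction: int = 1, concordance: float = 1.0,
                 n_genes: int = 1000, seed: int = 0
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random bipartite signed regulator->target network with one planted
    active regulator.

    Observed gene directions agree with (edge sign x planted direction)
    for the planted regulator's targets at the stated ``concordance``
    rate; every other gene's direction is a fair coin.

    Returns (edges, observed) where edges has columns source/target/sign
    and observed has gene_id -> direction with a ``target_of_planted``
    truth flag.
    """
    if n_regulators < 1 or targets_per_regulator < 1:
        raise ValueError("network sizes must be positive")
    rng = np.random.default_rng(seed)
    regulators = [f"REG{i + 1:02d}" for i in range(n_regulators)]
    if planted_regulator not in regulators:
        raise ValueError(f"{planted_regulator!r} not among generated regulators")
    genes = [f"tgene{i + 1:04d}" for i in range(n_genes)]
    edge_rows = []
    for reg in regulators:
        targets = rng.choice(n_genes, size=min(targets_per_regulator, n_genes),
                             replace=False)
        signs = np.where(rng.random(len(targets)) < positive_sign_fraction, 1, -1)
        for t, s in zip(targets, signs):
            edge_rows.append({"source": reg, "target": genes[t], "sign": int(s)})
    edges = pd.DataFrame(edge_rows).drop_duplicates(["source", "target"])

    direction = pd.Series(
        np.where(rng.random(n_genes) < 0.5, 1, -1), index=genes, name="direction"
    )
    planted_edges = edges[edges["source"] == planted_regulator]
    for _, e in planted_edges.iterrows():
        expected = planted_direction * e["sign"]
        if rng.random() < concordance:
            direction.loc[e["target"]] = expected
        # else the target keeps its random direction
    observed = direction.to_frame()
    observed["target_of_planted"] = observed.index.isin(planted_edges["target"])
    return edges, observed
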