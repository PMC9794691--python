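"""Causal upstream-regulator inference on a signed directed network.

Given an observed signature (the top differentially expressed genes with
their up/down directions) and a network of signed regulator->target
edges, each candidate regulator is scored one level up: under the
hypothesis that regulator R moved in direction h (+1 or -1), an edge
(R -> g, sign s) predicts direction h*s for g. Targets in the signature
are counted as correct or incorrect predictions.

Two significance scores are attached: an analytic binomial upper tail on
the number of correct predictions at the signature's background match
rate, and a permutation p-value from reassigning observed directions over
signature genes (exhaustive enumeration for small target sets). The
analytic score is a documented stand-in for proprietary causal-reasoning
scores and is labelled as such in outputs.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_network",
    "build_signature",
    "score_regulators",
]


def load_network(edges: pd.DataFrame) -> pd.DataFrame:
    """Validate a signed edge list (columns source, target, sign in {-1,+1}).

    Regulator/target pairs appearing with both signs are ambiguous and are
    excluded with a warning; exact duplicates are dropped silently.
    """
    req = {"source", "target", "sign"}
    if not req.issubset(edges.columns):
        raise ValueError(f"edge list needs columns {sorted(req)}")
    if not set(edges["sign"].unique()) <= {-1, 1}:
        raise ValueError("edge signs must be +1 or -1")
    edges = edges.drop_duplicates(["source", "target", "sign"])
    dup = edges.duplicated(["source", "target"], keep=False)
    if dup.any():
        bad = edges.loc[dup, ["source", "target"]].drop_duplicates()
        warnings.warn(
            f"excluding {len(bad)} ambiguous both-sign regulations",
            stacklevel=2,
        )
        edges = edges.loc[~dup]
    return edges.reset_index(drop=True)


def build_signature(table: pd.DataFrame, n: int = 500) -> pd.Series:
    """Top-n differential genes by ascending FDR, as gene -> direction.

    Ties in FDR break by descending |log2fc|, then by gene id. Genes with
    log2fc == 0 carry no direction and are skipped (the next gene is
    promoted). If fewer than n genes are available, all are used with a
    warning.
    """
    req = {"log2fc", "fdr"}
    if not req.issubset(table.columns):
        raise ValueError(f"differential table needs columns {sorted(req)}")
    t = table.copy()
    t = t[t["log2fc"] != 0]
    t["_abs"] = t["log2fc"].abs()
    t = t.sort_index(kind="mergesort")  # id tie-break baseline
    t = t.sort_values(["fdr", "_abs"], ascending=[True, False], kind="mergesort")
    t = t[~t.index.duplicated(keep="first")]
    if len(t) < n:
        warnings.warn(
            f"signature truncated: only {len(t)} usable genes (< {n})",
            stacklevel=2,
        )
    top = t.head(n)
    sig = pd.Series(np.sign(top["log2fc"]).astype(int).to_numpy(),
                    index=top.index, name="direction")
    return sig


def _regulator_counts(edges: pd.DataFrame, signature: pd.Series,
                      hypothesis: int) -> pd.DataFrame:
    """Per regulator: n_correct / n_incorrect / n_unobserved for one h."""
    e = edges.copy()
    e["predicted"] = hypothesis * e["sign"]
    obs = signature.reindex(e["target"]).to_numpy()
    e["observed"] = obs
    e["match"] = e["predicted"] == e["observed"]
    grouped = e.groupby("source")
    out = pd.DataFrame(
        {
            "n_correct": grouped.apply(
                lambda g: int((g["match"] & g["observed"].notna()).sum()),
                include_groups=False),
            "n_incorrect": grouped.apply(
                lambda g: int((~g["match"] & g["observed"].notna()).sum()),
                include_groups=False),
            "n_unobserved": grouped.apply(
                lambda g: int(g["observed"].isna().sum()), include_groups=False),
        }
    )
    return out


def score_regulators(edges: pd.DataFrame, signature: pd.Series,
                     permutations: int = 10_000, seed: int = 0,
                     exact_max_targets: int = 12) -> pd.DataFrame:
    """Score every regulator under both hypothesized directions.

    Parameters
    ----------
    edges
        Signed edge list (validated via :func:`load_network`).
    signature
        gene -> direction (+1/-1), e.g. from :func:`build_signature`.
    permutations
        Monte Carlo reassignments of observed directions over signature
        genes; regulators whose observed target count is at most
        ``exact_max_targets`` instead enumerate all direction assignments
        exactly (each target independently +1 with the signature's overall
        up-fraction).

    Returns a table ranked by (analytic_p, permutation_p) with one row per
    (regulator, hypothesized direction).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    edges = load_network(edges)
    if len(edges) == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    f_up = float((signature == 1).mean())
    sig_values = signature.to_numpy()

    rows = []
    for h in (1, -1):
        counts = _regulator_counts(edges, signature, h)
        for reg, c in counts.iterrows():
            m = int(c["n_correct"] + c["n_incorrect"])
            if m == 0:
                analytic = 1.0
                perm_p = 1.0
            else:
                e = edges[edges["source"] == reg]
                pred = (h * e["sign"]).to_numpy()
                observed_mask = e["target"].isin(signature.index).to_numpy()
                pred = pred[observed_mask]
                # per-edge background probability of a chance match
                p_edge = np.where(pred == 1, f_up, 1.0 - f_up)
                p_bar = float(p_edge.mean())
                analytic = float(stats.binom.sf(int(c["n_correct"]) - 1, m, p_bar))
                obs_score = int(c["n_correct"] - c["n_incorrect"])
                if m <= exact_max_targets:
                    perm_p = _exact_tail(pred, p_edge, obs_score)
                else:
                    perm_p = _mc_tail(pred, sig_values, obs_score,
                                      permutations, rng)
            rows.append(
                {
                    "regulator": reg,
                    "direction": h,
                    "n_correct": int(c["n_correct"]),
                    "n_incorrect": int(c["n_incorrect"]),
                    "n_unobserved": int(c["n_unobserved"]),
                    "analytic_p": analytic,
                    "permutation_p": perm_p,
                }
            )
    out = pd.DataFrame(rows).sort_values(
        ["analytic_p", "permutation_p", "regulator", "direction"],
        kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _exact_tail(pred: np.ndarray, p_edge: np.ndarray, obs_score: int) -> float:
    """Exact tail P(score >= obs) enumerating independent +/-1 directions,
    each target +1 with the signature's background up-probability."""
    m = len(pred)
    total = 0.0
    for assign in itertools.product((1, -1), repeat=m):
        a = np.asarray(assign)
        prob = np.prod(np.where(a == 1,
                                np.where(pred == 1, p_edge, 1 - p_edge),
                                np.where(pred == 1, 1 - p_edge, p_edge)))
        score = int((a == pred).sum() - (a != pred).sum())
        if score >= obs_score:
            total += float(prob)
    return min(total, 1.0)


def _mc_tail(pred: np.ndarray, sig_values: np.ndarray, obs_score: int,
             B: int, rng: np.random.Generator) -> float:
    """Monte Carlo tail: permute the multiset of observed directions over
    signature genes and rescore the regulator's observed targets."""
    m = len(pred)
    count = 0
    for _ in range(B):
        perm = rng.choice(sig_values, size=m, replace=False)
        score = int((perm == pred).sum() - (perm != pred).sum())
        if score >= obs_score:
            count += 1
    return (1 + count) / (B + 1)
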