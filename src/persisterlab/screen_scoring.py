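"""AUC-based scoring and hit calling for persister combination screens.

Each well's confluence time course is reduced to a trapezoidal area under
the curve (AUC, percent*hours over the full assay window). Per
(cell line, compound), the screen's two effect sizes are

* combination activity  = AUC(osimertinib-DTP arm) - AUC(combination arm)
* monotherapy activity  = AUC(DMSO) - AUC(test-compound monotherapy)

A compound is a hit in a cell line when its combination activity exceeds
the format threshold (upfront 10,000; sequential 7,500 percent*hours) AND
is more than ``mono_multiplier`` (default 2) times the monotherapy
activity; compounds passing the threshold but failing the 2x rule are
flagged separately. A compound is a common hit when it is a hit in at
least ``min_models`` cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_sim import Arm, ConfluenceTrace

__all__ = [
    "HitRule",
    "ScreenResult",
    "compute_auc",
    "summarize_replicates",
    "score_combination",
    "score_screen",
    "cross_model_summary",
    "evaluate_against_truth",
]


@dataclass(frozen=True)
class HitRule:
    """Hit-calling thresholds (percent*hours) per screen format."""

    threshold_upfront: float = 10_000.0
    threshold_sequential: float = 7_500.0
    mono_multiplier: float = 2.0
    min_models: int = 3

    def __post_init__(self) -> None:
        if self.threshold_upfront <= 0 or self.threshold_sequential <= 0:
            raise ValueError("thresholds must be > 0")
        if self.mono_multiplier < 1:
            raise ValueError("mono_multiplier must be >= 1")
        if self.min_models < 1:
            raise ValueError("min_models must be >= 1")

    def threshold(self, format: str) -> float:
        if format == "upfront":
            return self.threshold_upfront
        if format == "sequential":
            return self.threshold_sequential
        raise ValueError(f"unknown screen format {format!r}")


@dataclass
class ScreenResult:
    """Scored result for one (cell line, compound, format)."""

    cell_line: str
    compound: str
    format: str
    auc_dmso: float
    auc_mono: float
    auc_dtp: float
    auc_combo: float
    combination_activity: float
    monotherapy_activity: float
    hit: bool
    hit_low_mono_support: bool


def compute_auc(trace) -> float:
    """Trapezoidal AUC of a confluence trace, in percent*hours.

    Accepts a :class:`~persisterlab.growth_sim.ConfluenceTrace` or any
    (times, confluence) pair of arrays. No baseline subtraction; the full
    observed window is integrated.
    """
    if isinstance(trace, ConfluenceTrace):
        t, y = trace.times, trace.confluence
    else:
        t, y = trace
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points for an AUC")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    return float(np.trapezoid(y, t))


def summarize_replicates(aucs) -> float:
    """Median replicate AUC (mean of the central pair for even counts)."""
    aucs = np.asarray(list(aucs), dtype=float)
    if aucs.size == 0:
        raise ValueError("no replicate AUCs provided")
    return float(np.median(aucs))


def score_combination(
    auc_dmso: float,
    auc_mono: float,
    auc_dtp: float,
    auc_combo: float,
    format: str,
    rule: HitRule = HitRule(),
    *,
    cell_line: str = "",
    compound: str = "",
) -> ScreenResult:
    """Apply the combination-activity hit rule to one compound/line."""
    for v in (auc_dmso, auc_mono, auc_dtp, auc_combo):
        if v < 0:
            raise ValueError("AUCs must be >= 0")
    thr = rule.threshold(format)  # raises on unknown format
    combination = auc_dtp - auc_combo
    monotherapy = auc_dmso - auc_mono
    passes_threshold = combination > thr
    passes_mono = combination > rule.mono_multiplier * monotherapy
    return ScreenResult(
        cell_line=cell_line,
        compound=compound,
        format=format,
        auc_dmso=auc_dmso,
        auc_mono=auc_mono,
        auc_dtp=auc_dtp,
        auc_combo=auc_combo,
        combination_activity=combination,
        monotherapy_activity=monotherapy,
        hit=bool(passes_threshold and passes_mono),
        hit_low_mono_support=bool(passes_threshold and not passes_mono),
    )


_ARM_FOR_FORMAT = {"upfront": Arm.C_upfront.value, "sequential": Arm.D_sequential.value}


def score_screen(traces: pd.DataFrame, format: str,
                 rule: HitRule = HitRule()) -> pd.DataFrame:
    """Score a long-format trace table (as written by ``simulate_screen``).

    Replicate AUCs are summarised by the median before activities are
    computed. Control arms may appear either under compound="control" or
    relabelled per compound; per-compound control rows take precedence.
    """
    combo_arm = _ARM_FOR_FORMAT.get(format)
    if combo_arm is None:
        raise ValueError(f"unknown screen format {format!r}")

    aucs = (
        traces.groupby(["cell_line", "compound", "arm", "replicate"], sort=True)
        .apply(
            lambda g: compute_auc((g["time_h"].to_numpy(), g["confluence_pct"].to_numpy())),
            include_groups=False,
        )
        .rename("auc")
        .reset_index()
    )
    med = (
        aucs.groupby(["cell_line", "compound", "arm"], sort=True)["auc"]
        .median()
        .reset_index()
    )

    rows = []
    for line, grp in med.groupby("cell_line", sort=True):
        by = {(c, a): v for c, a, v in zip(grp["compound"], grp["arm"], grp["auc"])}

        def lookup(compound: str, arm: str) -> float | None:
            if (compound, arm) in by:
                return by[(compound, arm)]
            return by.get(("control", arm))

        compounds = sorted(set(grp["compound"]) - {"control"})
        for compound in compounds:
            auc_dmso = lookup(compound, Arm.DMSO.value)
            auc_mono = lookup(compound, Arm.A_mono.value)
            auc_dtp = lookup(compound, Arm.B_osi.value)
            auc_combo = lookup(compound, combo_arm)
            missing = [n for n, v in [("DMSO", auc_dmso), ("A_mono", auc_mono),
                                      ("B_osi", auc_dtp), (combo_arm, auc_combo)]
                       if v is None]
            if missing:
                raise ValueError(
                    f"missing arms {missing} for {compound!r} in {line!r}"
                )
            res = score_combination(
                auc_dmso, auc_mono, auc_dtp, auc_combo, format, rule,
                cell_line=str(line), compound=compound,
            )
            rows.append(vars(res))
    return pd.DataFrame(rows)


def cross_model_summary(results: pd.DataFrame,
                        rule: HitRule = HitRule()) -> pd.DataFrame:
    """Summarise hits across cell lines: a compound is a common hit when it
    is a hit in at least ``rule.min_models`` models. For common hits, cell
    lines where the compound passed the threshold with weak (<2x)
    monotherapy support are also listed."""
    if len(results) == 0:
        return pd.DataFrame(
            columns=["compound", "n_models", "n_models_hit", "common_hit",
                     "low_mono_models"]
        )
    if results.duplicated(["compound", "cell_line"]).any():
        raise ValueError("duplicate (compound, cell_line) entries")
    rows = []
    for compound, grp in results.groupby("compound", sort=True):
        n_hit = int(grp["hit"].sum())
        common = n_hit >= rule.min_models
        low_mono = sorted(grp.loc[grp["hit_low_mono_support"], "cell_line"]) if common else []
        rows.append(
            {
                "compound": compound,
                "n_models": len(grp),
                "n_models_hit": n_hit,
                "common_hit": common,
                "low_mono_models": ",".join(low_mono),
            }
        )
    return pd.DataFrame(rows)


def evaluate_against_truth(results: pd.DataFrame,
                           truth: pd.DataFrame) -> dict[str, float]:
    """Confusion summary of called hits against simulator ground truth,
    over (compound, cell line) pairs."""
    merged = results.merge(truth, on=["cell_line", "compound"], how="outer",
                           indicator=True)
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both",
                             ["cell_line", "compound"]]
        raise ValueError(f"results/truth mismatch for:\n{missing}")
    called = merged["hit"].astype(bool)
    true = merged["true_hit"].astype(bool)
    tp = int((called & true).sum())
    fp = int((called & ~true).sum())
    fn = int((~called & true).sum())
    tn = int((~called & ~true).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sensitivity, "fpr": fpr,
    }
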