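"""Confluence time-course simulator for drug-tolerant persister (DTP) screens.

Emulates IncuCyte-style live-cell confluence readouts for the five screen
arms used in long-term persister combination screens:

* ``DMSO``          -- vehicle control, logistic growth to confluence.
* ``A_mono``        -- test compound alone (targets the persister pool).
* ``B_osi``         -- osimertinib alone; sensitive cells die, a small
  persister subpopulation survives, and the well regrows after washout.
* ``C_upfront``     -- osimertinib + test compound co-dosed from day 0.
* ``D_sequential``  -- osimertinib first, crossed over to the test compound
  once the DTP state is established.

The model is a deterministic two-compartment ODE (sensitive pool S,
persister pool P) integrated with fixed-step RK4, with multiplicative
log-normal measurement noise applied to the observed confluence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "RegimenSpec",
    "SimParams",
    "ConfluenceTrace",
    "simulate_well",
    "simulate_screen",
    "default_panel",
    "logistic_closed_form",
    "TRUE_HIT_E_DRUG",
]


class Arm(str, enum.Enum):
    """Dosing arm of a screen well."""

    DMSO = "DMSO"
    A_mono = "A_mono"
    B_osi = "B_osi"
    C_upfront = "C_upfront"
    D_sequential = "D_sequential"


@dataclass(frozen=True)
class RegimenSpec:
    """Dosing schedule of a well, in days (sampling interval in hours).

    ``dtp_day`` is the day the DTP state is declared established: arm D
    crosses over from osimertinib to the test compound on that day.
    ``washout_day`` is the day drug is removed for arms A-C. Arm D keeps
    the test compound (and no osimertinib) until the horizon.
    """

    arm: Arm
    dtp_day: float = 14.0
    washout_day: float = 24.0
    horizon: float = 35.0
    sample_interval: float = 6.0  # hours

    def __post_init__(self) -> None:
        if not (0 < self.dtp_day <= self.washout_day <= self.horizon):
            raise ValueError(
                "require 0 < dtp_day <= washout_day <= horizon, got "
                f"dtp_day={self.dtp_day}, washout_day={self.washout_day}, "
                f"horizon={self.horizon}"
            )
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        object.__setattr__(self, "arm", Arm(self.arm))


@dataclass(frozen=True)
class SimParams:
    """Kinetic and noise parameters of a simulated well.

    Rates are per hour. ``f`` is the persister fraction of the inoculum;
    ``d`` the osimertinib kill rate on sensitive cells; ``e_drug`` the test
    compound's kill multiplier on the persister pool (kill rate e_drug * d);
    ``lag`` the regrowth lag after washout; ``sigma`` the log-scale SD of
    multiplicative measurement noise.
    """

    r: float = 0.03
    r_p: float = 0.002
    K: float = 100.0
    c0: float = 10.0
    f: float = 0.05
    d: float = 0.05
    e_drug: float = 0.0
    lag: float = 24.0
    sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r", "r_p", "d", "e_drug", "lag", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.f <= 1:
            raise ValueError("persister fraction f must lie in [0, 1]")
        if not 0 < self.c0 < self.K:
            raise ValueError("require 0 < c0 < K")


@dataclass
class ConfluenceTrace:
    """One well's time-stamped percent-confluence series."""

    cell_line: str
    compound: str
    arm: Arm
    replicate: int
    times: np.ndarray  # hours, strictly increasing
    confluence: np.ndarray  # percent, within [0, K]
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.confluence = np.asarray(self.confluence, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.confluence):
            raise ValueError("times and confluence must be 1-D and equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_line": self.cell_line,
                "compound": self.compound,
                "arm": self.arm.value,
                "replicate": self.replicate,
                "time_h": self.times,
                "confluence_pct": self.confluence,
            }
        )


def logistic_closed_form(t: np.ndarray, r: float, K: float, c0: float) -> np.ndarray:
    """Closed-form logistic solution C(t) = K c0 e^{rt} / (K + c0 (e^{rt} - 1))."""
    t = np.asarray(t, dtype=float)
    e = np.exp(r * t)
    return K * c0 * e / (K + c0 * (e - 1.0))


def _phase_rates(arm: Arm, t: float, reg: RegimenSpec, p: SimParams):
    """Return (osi_on, compound_on, growing) flags for time t (hours)."""
    dtp_h = reg.dtp_day * 24.0
    wash_h = reg.washout_day * 24.0
    if arm is Arm.DMSO:
        return False, False, True
    if arm is Arm.A_mono:
        return False, t < wash_h, True
    if arm is Arm.B_osi:
        return t < wash_h, False, t >= wash_h + p.lag
    if arm is Arm.C_upfront:
        return t < wash_h, t < wash_h, t >= wash_h + p.lag
    if arm is Arm.D_sequential:
        # osimertinib until crossover, test compound thereafter; persisters
        # revert to sensitive growth once osimertinib is gone (after lag)
        return t < dtp_h, t >= dtp_h, t >= dtp_h + p.lag
    raise ValueError(f"unknown arm {arm!r}")


def _deriv(arm: Arm, t: float, S: float, P: float, reg: RegimenSpec, p: SimParams):
    osi_on, compound_on, recovered = _phase_rates(arm, t, reg, p)
    N = S + P
    cap = max(1.0 - N / p.K, 0.0) if N < p.K else 0.0
    if arm is Arm.DMSO:
        return p.r * S * cap, p.r * P * cap
    if arm is Arm.A_mono:
        dS = p.r * S * cap
        dP = p.r * P * cap - (p.e_drug * p.d * P if compound_on else 0.0)
        return dS, dP
    # arms B, C, D share the osimertinib-phase structure
    if osi_on:
        dS = -p.d * S
        dP = p.r_p * P * cap
        if compound_on:  # arm C co-dose
            dP -= p.e_drug * p.d * P
        return dS, dP
    if arm is Arm.D_sequential:
        # post-crossover: no osimertinib, so persisters revert to sensitive
        # growth after the lag while the test compound kills them
        grow = p.r if recovered else 0.0
        dS = grow * S * cap
        dP = grow * P * cap - p.e_drug * p.d * P
        return dS, dP
    # arms B/C after washout: lag, then full reversion to sensitive growth
    if recovered:
        return p.r * S * cap, p.r * P * cap
    return 0.0, 0.0


def _rk4(arm: Arm, reg: RegimenSpec, p: SimParams, times: np.ndarray,
         n_substeps: int = 5) -> np.ndarray:
    S = p.c0 * (1.0 - p.f)
    P = p.c0 * p.f
    out = np.empty_like(times)
    out[0] = S + P
    for i in range(1, len(times)):
        t0, t1 = times[i - 1], times[i]
        h = (t1 - t0) / n_substeps
        for k in range(n_substeps):
            t = t0 + k * h
            k1s, k1p = _deriv(arm, t, S, P, reg, p)
            k2s, k2p = _deriv(arm, t + h / 2, S + h / 2 * k1s, P + h / 2 * k1p, reg, p)
            k3s, k3p = _deriv(arm, t + h / 2, S + h / 2 * k2s, P + h / 2 * k2p, reg, p)
            k4s, k4p = _deriv(arm, t + h, S + h * k3s, P + h * k3p, reg, p)
            S += h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
            P += h / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
            S = max(S, 0.0)
            P = max(P, 0.0)
        out[i] = S + P
    return np.minimum(out, p.K)


def simulate_well(params: SimParams, regimen: RegimenSpec, seed: int | None = None,
                  *, cell_line: str = "line1", compound: str = "compound",
                  replicate: int = 1, n_substeps: int = 5) -> ConfluenceTrace:
    """Simulate one well and return its (noisy) confluence trace.

    Deterministic in (params, regimen, seed): identical inputs give an
    identical trace. ``seed`` defaults to ``params.seed``.
    """
    if regimen.horizon * 24.0 < regimen.dtp_day * 24.0:
        raise ValueError("horizon shorter than dtp_day")
    seed = params.seed if seed is None else int(seed)
    times = np.arange(0.0, regimen.horizon * 24.0 + 1e-9, regimen.sample_interval)
    clean = _rk4(regimen.arm, regimen, params, times, n_substeps=n_substeps)
    if params.sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = clean * np.exp(rng.normal(0.0, params.sigma, size=clean.shape))
        observed = np.clip(noisy, 0.0, params.K)
    else:
        observed = clean
    return ConfluenceTrace(
        cell_line=cell_line,
        compound=compound,
        arm=regimen.arm,
        replicate=replicate,
        times=times,
        confluence=observed,
        truth={"e_drug": params.e_drug, "f": params.f},
    )


# arms dosed per compound; the B_osi rows of each compound reuse the cell
# line's shared control trace (same child seed) so the control is literally
# shared across the panel
_COMPOUND_ARMS = (Arm.A_mono, Arm.B_osi, Arm.C_upfront, Arm.D_sequential)
_CONTROL_ARMS = (Arm.DMSO, Arm.B_osi)

TRUE_HIT_E_DRUG = 0.5
"""Planted-effect cutoff: a compound is a ground-truth hit in a cell line
when its persister kill multiplier is at least this value."""


def simulate_screen(
    panel: Sequence[tuple[str, float]],
    cell_lines: Sequence[str],
    replicates: int,
    params_by_line: dict[str, SimParams] | None = None,
    seed: int = 0,
    regimen_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full combination screen.

    Parameters
    ----------
    panel
        Sequence of ``(compound_name, e_drug)`` pairs.
    cell_lines
        Cell line labels; each gets its own (or a shared default) SimParams.
    replicates
        Wells per (cell line, compound, arm).
    params_by_line
        Optional per-line kinetic parameters; defaults to ``SimParams()``.
    seed
        Master seed; child seeds are spawned deterministically.

    Returns
    -------
    traces, truth
        Long-format trace table (cell_line, compound, arm, replicate,
        time_h, confluence_pct) and a truth table with one row per
        (cell_line, compound) marking planted hits.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(panel) == 0:
        raise ValueError("panel must not be empty")
    names = [c for c, _ in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate compound names in panel")

    regimen_kwargs = dict(regimen_kwargs or {})
    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    entropy = np.random.SeedSequence(seed).entropy

    def child_seed(*key: int) -> int:
        ss = np.random.SeedSequence(entropy=entropy, spawn_key=key)
        return int(ss.generate_state(1)[0] >> 1)  # keep below 2**31

    arm_index = {arm: i for i, arm in enumerate(Arm)}
    for li, line in enumerate(cell_lines):
        base = (params_by_line or {}).get(line, SimParams())
        # shared control wells (ci slot 0 reserved for controls)
        control_traces: dict[tuple[Arm, int], ConfluenceTrace] = {}
        for arm in _CONTROL_ARMS:
            for rep in range(1, replicates + 1):
                s = child_seed(li, 0, arm_index[arm], rep)
                reg = RegimenSpec(arm=arm, **regimen_kwargs)
                tr = simulate_well(base, reg, seed=s, cell_line=line,
                                   compound="control", replicate=rep)
                control_traces[(arm, rep)] = tr
                frames.append(tr.to_frame())
        for ci, (compound, e_drug) in enumerate(panel):
            p = replace(base, e_drug=float(e_drug))
            for arm in _COMPOUND_ARMS:
                for rep in range(1, replicates + 1):
                    if arm is Arm.B_osi:
                        # shared osimertinib control, relabelled for this compound
                        shared = control_traces[(Arm.B_osi, rep)]
                        tr = ConfluenceTrace(
                            cell_line=line, compound=compound, arm=arm,
                            replicate=rep, times=shared.times.copy(),
                            confluence=shared.confluence.copy(),
                            truth=shared.truth,
                        )
                    else:
                        s = child_seed(li, ci + 1, arm_index[arm], rep)
                        reg = RegimenSpec(arm=arm, **regimen_kwargs)
                        tr = simulate_well(p, reg, seed=s, cell_line=line,
                                           compound=compound, replicate=rep)
                    frames.append(tr.to_frame())
            truth_rows.append(
                {
                    "cell_line": line,
                    "compound": compound,
                    "e_drug": float(e_drug),
                    "true_hit": bool(e_drug >= TRUE_HIT_E_DRUG),
                }
            )
    traces = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return traces, truth


def default_panel(n_compounds: int = 20, n_true_hits: int = 5,
                  seed: int = 0) -> list[tuple[str, float]]:
    """Default screen panel: a few strong persister-killing compounds among
    pharmacologically inactive decoys, mirroring a focused combination
    screen. Decoy kill multipliers are kept well below the persister net
    growth rate so decoy wells regrow after washout."""
    rng = np.random.default_rng(seed)
    panel: list[tuple[str, float]] = []
    for i in range(n_compounds):
        if i < n_true_hits:
            e = float(rng.uniform(2.0, 4.0))
        else:
            e = float(rng.uniform(0.0, 0.02))
        panel.append((f"cmpd{i + 1:02d}", e))
    return panel
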