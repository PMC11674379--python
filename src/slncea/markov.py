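"""Annual-cycle Markov cohort model over the 20-year follow-up horizon.

State space (in order): the three post-treatment substates produced by the
decision tree, a combined regional/distant recurrence state, and death.

Transition inputs are published as 5-year cumulative probabilities per
treatment group; they are converted to annual probabilities under a
constant-hazard assumption.  Cancer mortality is modelled as a case
fatality *after* recurrence (everyone who dies of cancer first recurs), so
the 5-year mortality in excess of background is spread over the recurrence
state.  Background mortality comes from the female life table and applies
everywhere as an independent competing risk.

By default the 5-year recurrence rates operate during the first five
cycles only (patients disease-free at five years are considered cured and
face background mortality alone); flag ``failure_window=lifetime`` applies
the annualized rates across the whole horizon instead.

Vaginal recurrence is rare, salvageable, and handled *within* the
post-treatment state: an expected one-off salvage radiotherapy cost and a
proportional disutility per cycle at risk, with no state transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import SUBSTATES, TreeResult
from .fixtures import LifeTable
from .parameters import ParameterSet, Scenario

__all__ = [
    "STATES",
    "CohortTrace",
    "annualize",
    "recurrence_case_fatality",
    "build_transition_matrix",
    "run_cohort",
    "accumulate_outcomes",
    "cycle_ledger",
]

STATES = SUBSTATES + ("recurrence", "dead")
N_STATES = len(STATES)
_REC, _DEAD = STATES.index("recurrence"), STATES.index("dead")

#: which utility decrement a treatment modality's toxicity carries
TOX_UTILITY = {"ebrt": "u_rt_tox", "chemo": "u_chemo_tox",
               "both": "u_both_tox", "vbt": "u_rt_tox"}


def substate_group(substate: str, scenario: Scenario) -> str:
    """Treatment group indexing the 5-year rates for a post-treatment substate."""
    return {
        "pos_treated": scenario.value,
        "neg_vbt": "vbt_neg",
        "pos_missed": "vbt_pos",
    }[substate]


def annualize(p5: float, years: float = 5.0) -> float:
    """Annual probability equivalent to a cumulative ``years``-year one.

    Constant-hazard conversion: 1 − (1 − p5)^(1/years).
    """
    if not 0.0 <= p5 <= 1.0:
        raise ValueError(f"cumulative probability {p5} outside [0, 1]")
    return 1.0 - (1.0 - p5) ** (1.0 / years)


def background_5yr_mortality(lt: LifeTable, start_age: int) -> float:
    """Cumulative 5-year background death probability from ``start_age``."""
    q = lt.q_at(np.arange(start_age, start_age + 5))
    return float(1.0 - np.prod(1.0 - q))


def recurrence_case_fatality(
    group: str, ps: ParameterSet, lt: LifeTable | None = None
) -> float:
    """Annual probability of cancer death while in recurrence, per group.

    All cancer deaths pass through recurrence, so the 5-year case fatality
    among recurrers is the group's 5-year cancer mortality divided by its
    5-year recurrence probability, annualized.  The printed mortality rates
    are all-cause: when a life table is supplied (and flag
    ``mortality_input=all_cause``, the default) the background share over
    the first five years is subtracted first; without a life table the
    printed rate is used as-is.  Ratios above 1 are clipped with a warning.
    """
    r5 = ps.r5_rec(group)
    if r5 == 0.0:
        return 0.0
    m5 = ps.m5(group)
    if lt is not None and ps.flags.get("mortality_input", "all_cause") == "all_cause":
        m5 = max(0.0, m5 - background_5yr_mortality(lt, int(ps.start_age)))
    ratio = m5 / r5
    if ratio > 1.0:
        warnings.warn(
            f"group {group}: 5-yr cancer mortality {m5} exceeds 5-yr "
            f"recurrence {r5}; case fatality clipped to 1",
            stacklevel=2,
        )
        ratio = 1.0
    return annualize(ratio)


def calibrate_recurrence_mortality(
    group: str, ps: ParameterSet, lt: LifeTable
) -> float:
    """Annual cancer death probability in recurrence that reproduces m5.

    Solves, by bisection, for the constant annual probability ``d`` such
    that a cohort of the given group — recurring at the group's annualized
    rate during the first five cycles, with background mortality from the
    life table everywhere and recurrence deaths at
    1 − (1 − d)(1 − q) — reaches the printed 5-year all-cause mortality at
    the end of cycle 5.  Infeasible targets (the missed-metastases group's
    70% mortality nearly equals its 67% recurrence rate, so even instant
    death after recurrence barely reaches it) clip to 1 with a warning.
    """
    m5 = ps.m5(group)
    p_rec = annualize(ps.r5_rec(group))
    start = int(ps.start_age)
    qs = lt.q_at(np.arange(start, start + 5))

    def dead_at_5(d: float) -> float:
        post, rec, dead = 1.0, 0.0, 0.0
        for q in qs:
            d_rec = 1.0 - (1.0 - d) * (1.0 - q)
            dead += post * q + rec * d_rec
            rec = rec * (1.0 - d_rec) + post * p_rec
            post = post * (1.0 - p_rec - q)
        return dead

    if dead_at_5(1.0) < m5:
        warnings.warn(
            f"group {group}: printed 5-yr mortality {m5} unreachable even "
            "with immediate death after recurrence; using 1",
            stacklevel=2,
        )
        return 1.0
    if dead_at_5(0.0) >= m5:
        return 0.0
    lo, hi = 0.0, 1.0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if dead_at_5(mid) < m5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _cancer_active(ps: ParameterSet, cycle: int) -> bool:
    """Do the 5-year recurrence rates still operate in this cycle?"""
    return ps.flags["failure_window"] == "lifetime" or cycle <= 5


def _group_case_fatalities(
    scenario: Scenario, ps: ParameterSet, lt: LifeTable
) -> np.ndarray:
    """Annual cancer death probability in recurrence per substate of origin."""
    if ps.flags.get("recurrence_mortality", "calibrated") == "calibrated":
        fn = lambda g: calibrate_recurrence_mortality(g, ps, lt)  # noqa: E731
    else:
        fn = lambda g: recurrence_case_fatality(g, ps, lt)  # noqa: E731
    return np.array([fn(substate_group(s, scenario)) for s in SUBSTATES])


def _mixed_case_fatality(
    tree: TreeResult,
    scenario: Scenario,
    ps: ParameterSet,
    lt: LifeTable,
    rec_weights: np.ndarray | None = None,
    cfs: np.ndarray | None = None,
) -> float:
    """Case fatality of the recurrence state, weighted over origin groups.

    ``rec_weights`` is the composition of the recurrence state by
    substate of origin; when absent (a standalone matrix query) the
    expected incident flow at baseline — tree occupancy times annual
    recurrence rate — stands in.
    """
    if cfs is None:
        cfs = _group_case_fatalities(scenario, ps, lt)
    if rec_weights is None or rec_weights.sum() <= 0:
        rec_weights = np.array([
            tree.occupancy[s] * annualize(ps.r5_rec(substate_group(s, scenario)))
            for s in SUBSTATES
        ])
    total = rec_weights.sum()
    if total <= 0:
        return 0.0
    return float(rec_weights @ cfs / total)


def build_transition_matrix(
    tree: TreeResult,
    scenario: Scenario,
    ps: ParameterSet,
    lt: LifeTable,
    cycle: int,
    rec_weights: np.ndarray | None = None,
    _cfs: np.ndarray | None = None,
) -> np.ndarray:
    """One-cycle transition matrix for the given cycle (1-based).

    Post-treatment rows: recurrence at the group's annual rate, background
    death at q(age), remainder stays.  Recurrence row: death combines the
    case fatality — mixed over the recurrence state's composition by origin
    group (``rec_weights``) — and background mortality as independent
    competing risks (multiplicative survival).  Death is absorbing.
    """
    if cycle < 1 or cycle > ps.horizon:
        raise ValueError(f"cycle {cycle} outside 1..{int(ps.horizon)}")
    age = int(ps.start_age) + cycle - 1
    q = float(lt.q_at(age))
    m = np.zeros((N_STATES, N_STATES))
    active = _cancer_active(ps, cycle)
    for i, s in enumerate(SUBSTATES):
        g = substate_group(s, scenario)
        p_rec = annualize(ps.r5_rec(g)) if active else 0.0
        m[i, _REC] = p_rec
        m[i, _DEAD] = q
        m[i, i] = 1.0 - p_rec - q
    cf = _mixed_case_fatality(tree, scenario, ps, lt, rec_weights, _cfs)
    m[_REC, _DEAD] = 1.0 - (1.0 - cf) * (1.0 - q)
    m[_REC, _REC] = 1.0 - m[_REC, _DEAD]
    m[_DEAD, _DEAD] = 1.0
    rows = m.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-9) or m.min() < 0:
        raise ValueError(f"transition matrix rows failed to normalize: {rows}")
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle plus the incident flow into recurrence.

    ``occupancy[t]`` is the distribution after t cycles (t = 0..horizon);
    ``rec_inflow[t]`` the fraction of the cohort newly entering recurrence
    during cycle t (index 0 unused).
    """

    states: tuple[str, ...]
    occupancy: np.ndarray
    rec_inflow: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        horizon = self.occupancy.shape[0] - 1
        recs = [
            {"cycle": t, "state": s, "occupancy": self.occupancy[t, i]}
            for t in range(horizon + 1)
            for i, s in enumerate(self.states)
        ]
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(
    tree: TreeResult, scenario: Scenario, ps: ParameterSet, lt: LifeTable
) -> CohortTrace:
    """Propagate the decision-tree cohort through the Markov model.

    The recurrence state's composition by substate of origin is tracked as
    an auxiliary variable so its case fatality reflects who is actually in
    the state each cycle (patients whose metastases were missed recur more
    and die faster than node-negative recurrers).
    """
    horizon = int(ps.horizon)
    n_sub = len(SUBSTATES)
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, :n_sub] = [tree.occupancy[s] for s in SUBSTATES]
    inflow = np.zeros(horizon + 1)
    rec_by_group = np.zeros(n_sub)  # recurrence occupancy by origin substate
    cfs = _group_case_fatalities(scenario, ps, lt)
    tracked = ps.flags.get("recurrence_mixing", "static") == "tracked"
    for t in range(1, horizon + 1):
        weights = rec_by_group if tracked else None
        m = build_transition_matrix(tree, scenario, ps, lt, t, weights, cfs)
        inflow[t] = occ[t - 1, :n_sub] @ m[:n_sub, _REC]
        occ[t] = occ[t - 1] @ m
        # advance the composition with group-specific death rates
        q = float(lt.q_at(int(ps.start_age) + t - 1))
        survive = (1.0 - cfs) * (1.0 - q)
        rec_by_group = rec_by_group * survive + occ[t - 1, :n_sub] * m[:n_sub, _REC]
    if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
        raise RuntimeError("cohort trace lost probability mass")
    return CohortTrace(STATES, occ, inflow)


def _state_rewards(
    tree: TreeResult, scenario: Scenario, ps: ParameterSet, cycle: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state (cost, utility) rewards for one cycle.

    Alive states pay the follow-up visits.  Post-treatment substates add
    chronic lymphedema treatment (arm prevalence), the expected one-off
    vaginal-recurrence salvage radiotherapy, and carry disutilities for
    lymphedema, treatment toxicity (short-term in cycle 1, long-term
    after) and vaginal recurrence.  The recurrence state carries the
    regional/distant recurrence utility.
    """
    followup = ps.n_followup_visits_per_year * ps.c_followup_visit
    active = _cancer_active(ps, cycle)
    costs = np.zeros(N_STATES)
    utils = np.zeros(N_STATES)
    for i, s in enumerate(SUBSTATES):
        g = substate_group(s, scenario)
        mod = tree.modality[s]
        p_vag = annualize(ps.r5_vag(g)) if active else 0.0
        p_tox = (
            tree.first_cycle_tox[s]
            if cycle == 1
            else ps.value(f"p_lt_tox_{mod}")
        )
        costs[i] = (
            followup
            + tree.lymphedema_prev * ps.c_lymphedema_yearly
            + p_vag * ps.c_ebrt
        )
        utils[i] = (
            ps.u_perfect
            - tree.lymphedema_prev * (1.0 - ps.u_lymphedema)
            - p_tox * (1.0 - ps.value(TOX_UTILITY[mod]))
            - p_vag * (1.0 - ps.u_vag_rec)
        )
    costs[_REC] = followup
    utils[_REC] = ps.u_rec
    costs[_DEAD] = 0.0
    utils[_DEAD] = ps.u_dead
    return costs, utils


def accumulate_outcomes(
    trace: CohortTrace,
    tree: TreeResult,
    scenario: Scenario,
    ps: ParameterSet,
) -> tuple[float, float]:
    """Total discounted cost (EUR) and QALYs over the horizon.

    Costs discount at ``disc_costs`` (4%/yr), effects at ``disc_effects``
    (1.5%/yr).  Upfront tree costs fall at cycle 0, undiscounted.  Salvage
    chemotherapy is charged once on the incident flow into recurrence.
    With flag ``half_cycle=on`` state rewards use the mean of start- and
    end-of-cycle occupancy instead of end-of-cycle occupancy.
    """
    horizon = int(ps.horizon)
    total_cost = tree.upfront_cost
    total_qaly = 0.0
    half = ps.flags["half_cycle"] == "on"
    for t in range(1, horizon + 1):
        dc = (1.0 + ps.disc_costs) ** -t
        de = (1.0 + ps.disc_effects) ** -t
        occ = 0.5 * (trace.occupancy[t - 1] + trace.occupancy[t]) if half else trace.occupancy[t]
        costs, utils = _state_rewards(tree, scenario, ps, t)
        total_cost += dc * (occ @ costs + trace.rec_inflow[t] * ps.c_chemo)
        total_qaly += de * (occ @ utils)
    return total_cost, total_qaly


def cycle_ledger(
    trace: CohortTrace,
    tree: TreeResult,
    scenario: Scenario,
    ps: ParameterSet,
) -> pd.DataFrame:
    """Per-cycle audit of discounted cost and QALY contributions."""
    rows = []
    half = ps.flags["half_cycle"] == "on"
    for t in range(1, int(ps.horizon) + 1):
        dc = (1.0 + ps.disc_costs) ** -t
        de = (1.0 + ps.disc_effects) ** -t
        occ = 0.5 * (trace.occupancy[t - 1] + trace.occupancy[t]) if half else trace.occupancy[t]
        costs, utils = _state_rewards(tree, scenario, ps, t)
        rows.append(
            {
                "cycle": t,
                "alive": occ[:_DEAD].sum(),
                "state_cost": occ @ costs,
                "salvage_chemo": trace.rec_inflow[t] * ps.c_chemo,
                "disc_cost": dc * (occ @ costs + trace.rec_inflow[t] * ps.c_chemo),
                "disc_qaly": de * (occ @ utils),
            }
        )
    return pd.DataFrame(rows)
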