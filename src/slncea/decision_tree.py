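"""Surgical and diagnostic pathway of each lymph-node-assessment strategy.

Every patient undergoes hysterectomy with bilateral salpingo-oophorectomy
(identical across arms, hence not costed).  The arms differ in how nodes
are assessed:

* **LND** — routine pelvic lymphadenectomy on both sides, treated as the
  gold standard (no false negatives or positives).
* **SLN** — indocyanine-green sentinel node mapping; per side the mapping
  succeeds bilaterally (79%), unilaterally (16%, the unmapped side gets a
  side-specific lymphadenectomy) or fails (5%, full bilateral
  lymphadenectomy).

Detected node-positive patients receive the scenario's adjuvant therapy;
node-negative — and node-positive patients whose metastases the sentinel
node missed — receive vaginal brachytherapy.  The tree output is the cohort
split over the three post-treatment substates plus all cycle-0 costs and
the arm's complication burden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .parameters import ParameterSet, Scenario

__all__ = [
    "Strategy",
    "TreeResult",
    "SUBSTATES",
    "expected_surgical_cost",
    "cohort_split",
    "complication_burden",
    "build_tree_result",
    "adjuvant_cost",
]

#: post-treatment substates in state order of the Markov model
SUBSTATES = ("pos_treated", "neg_vbt", "pos_missed")


class Strategy(Enum):
    LND = "LND"  # routine pelvic lymphadenectomy
    SLN = "SLN"  # sentinel lymph node mapping (ICG)


def adjuvant_cost(scenario: Scenario, ps: ParameterSet) -> float:
    """Cost of the scenario's adjuvant course for a detected node-positive patient.

    The combined course is priced additively (no combined tariff exists).
    """
    return {
        Scenario.EBRT: ps.c_ebrt,
        Scenario.CHEMO: ps.c_chemo,
        Scenario.BOTH: ps.c_ebrt + ps.c_chemo,
    }[scenario]


def expected_surgical_cost(strategy: Strategy, ps: ParameterSet) -> float:
    """Expected cost of nodal assessment: OR time, tracer and histopathology.

    Only the lymph-node part of surgery is costed; hysterectomy/BSO and the
    one-day hospital stay are identical across arms and cancel out.  Times
    are per side: bilateral mapping = 2 SLN sides; unilateral mapping = one
    SLN side plus one side-specific lymphadenectomy; failed mapping = full
    bilateral lymphadenectomy.  ICG is charged once per patient.
    """
    if strategy is Strategy.LND:
        minutes = 2.0 * ps.t_lnd_unilateral
        return minutes * ps.c_or_per_min + ps.c_histo_lnd
    minutes = (
        ps.p_bilateral * 2.0 * ps.t_sln_unilateral
        + ps.p_unilateral * (ps.t_sln_unilateral + ps.t_lnd_unilateral)
        + ps.p_failed * 2.0 * ps.t_lnd_unilateral
    )
    return minutes * ps.c_or_per_min + ps.c_icg + ps.c_histo_sln


def cohort_split(strategy: Strategy, ps: ParameterSet) -> dict[str, float]:
    """Cohort fractions over post-treatment substates.

    Lymphadenectomy detects every metastasis.  Under SLN mapping a
    metastasis is missed with probability (1 − sensitivity), by default
    only among patients actually assessed by a sentinel node (weight
    1 − p_failed; failed mapping converts to a full lymphadenectomy and is
    gold standard).  Flag ``sensitivity_scope=all`` applies (1 − sens) to
    all node-positive patients instead.  Specificity is fixed at 1, so no
    node-negative patient is over-treated.
    """
    p = ps.p_lnm
    if strategy is Strategy.LND:
        missed = 0.0
    else:
        scope = 1.0 - ps.p_failed if ps.flags["sensitivity_scope"] == "mapped_only" else 1.0
        missed = p * (1.0 - ps.sens_sln) * scope
    return {
        "pos_treated": p - missed,
        "neg_vbt": 1.0 - p,
        "pos_missed": missed,
    }


def complication_burden(strategy: Strategy, ps: ParameterSet) -> tuple[float, float, float]:
    """(lymphedema prevalence, lymphocele prevalence, initial complication cost).

    Arm-level prevalences as published.  With flag
    ``complication_mixing=extent_weighted`` the SLN arm instead mixes the
    two profiles by the fraction undergoing any lymphadenectomy (failed
    mapping fully, unilateral mapping half).
    """
    if strategy is Strategy.LND:
        edema, cele = ps.p_lymphedema_lnd, ps.p_lymphocele_lnd
    elif ps.flags["complication_mixing"] == "arm_level":
        edema, cele = ps.p_lymphedema_sln, ps.p_lymphocele_sln
    else:
        w_lnd = ps.p_failed + 0.5 * ps.p_unilateral
        edema = (1 - w_lnd) * ps.p_lymphedema_sln + w_lnd * ps.p_lymphedema_lnd
        cele = (1 - w_lnd) * ps.p_lymphocele_sln + w_lnd * ps.p_lymphocele_lnd
    cost = edema * ps.c_lymphedema_init + cele * ps.c_lymphocele_drain
    return edema, cele, cost


@dataclass(frozen=True)
class TreeResult:
    """Decision-tree output feeding the Markov model.

    ``occupancy`` — cohort fractions over post-treatment substates (sums
    to 1); ``upfront_cost`` — cycle-0, undiscounted cost (surgery +
    histopathology + adjuvant therapy + initial complication treatment);
    ``modality`` — adjuvant modality received per substate, which fixes the
    toxicity probabilities and disutilities applied in the Markov part;
    ``first_cycle_tox`` — short-term toxicity probability per substate.
    """

    strategy: Strategy
    scenario: Scenario
    occupancy: dict[str, float]
    upfront_cost: float
    lymphedema_prev: float
    lymphocele_prev: float
    modality: dict[str, str]
    first_cycle_tox: dict[str, float]
    cost_components: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substate": s,
                "fraction": self.occupancy[s],
                "modality": self.modality[s],
                "short_term_tox": self.first_cycle_tox[s],
            }
            for s in SUBSTATES
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "strategy": self.strategy.value,
            "scenario": self.scenario.value,
            "occupancy": self.occupancy,
            "upfront_cost": self.upfront_cost,
            "cost_components": self.cost_components,
            "lymphedema_prev": self.lymphedema_prev,
            "lymphocele_prev": self.lymphocele_prev,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_tree_result(
    strategy: Strategy, scenario: Scenario, ps: ParameterSet
) -> TreeResult:
    """Assemble the full decision-tree result for one strategy and scenario."""
    occ = cohort_split(strategy, ps)
    surgical = expected_surgical_cost(strategy, ps)
    edema, cele, comp_cost = complication_burden(strategy, ps)
    adj = (
        occ["pos_treated"] * adjuvant_cost(scenario, ps)
        + (occ["neg_vbt"] + occ["pos_missed"]) * ps.c_vbt
    )
    modality = {
        "pos_treated": scenario.value,
        "neg_vbt": "vbt",
        "pos_missed": "vbt",
    }
    st_tox = {s: ps.value(f"p_st_tox_{m}") for s, m in modality.items()}
    components = {
        "surgery_and_histopathology": surgical,
        "adjuvant_therapy": adj,
        "initial_complications": comp_cost,
    }
    total = sum(components.values())
    assert abs(sum(occ.values()) - 1.0) < 1e-12
    return TreeResult(
        strategy=strategy,
        scenario=scenario,
        occupancy=occ,
        upfront_cost=total,
        lymphedema_prev=edema,
        lymphocele_prev=cele,
        modality=modality,
        first_cycle_tox=st_tox,
        cost_components=components,
    )
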