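"""Model parameter registry.

Every input of the decision model — probabilities from the diagnostic
pathway, 5-year failure/mortality rates by treatment group, unit costs in
2023 euros, health-state utilities, and analysis settings (discount rates,
willingness-to-pay, horizon) — lives here as a validated, overridable
:class:`ParamSpec`.  The base values reproduce the published Dutch
cost-effectiveness model of sentinel lymph node (SLN) mapping versus pelvic
lymphadenectomy in high-risk endometrial cancer.

Treatment groups are keyed ``ebrt``, ``chemo``, ``both`` (EBRT +
chemotherapy), ``vbt_pos`` (node-positive but treated with vaginal
brachytherapy only, i.e. metastases missed by SLN mapping) and ``vbt_neg``
(node-negative, vaginal brachytherapy).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "ParamSpec",
    "ParameterSet",
    "Scenario",
    "ParameterError",
    "default_parameters",
    "load_parameters",
    "perturbed_copy",
    "MAPPING_TRIO",
    "GROUPS",
]

#: exhaustive SLN-mapping outcomes; must stay on the probability simplex
MAPPING_TRIO = ("p_bilateral", "p_unilateral", "p_failed")

#: adjuvant-treatment groups used to index 5-year rate parameters
GROUPS = ("ebrt", "chemo", "both", "vbt_pos", "vbt_neg")

#: structural model conventions and their admissible values
FLAG_CHOICES = {
    # does SLN sensitivity apply only to the mapped fraction (failed
    # mapping gets a full side-specific lymphadenectomy, i.e. gold
    # standard) or to all node-positive patients?
    "sensitivity_scope": ("mapped_only", "all"),
    # are the 5-year recurrence rates spread over the first 5 cycles only
    # (cure model) or applied as a constant annual hazard for the whole
    # 20-year horizon?
    "failure_window": ("first5", "lifetime"),
    # half-cycle correction on state rewards (default on, matching common
    # cohort-model practice; "off" evaluates rewards at end-of-cycle
    # occupancy only)
    "half_cycle": ("on", "off"),
    # decision rule for the SLN-sensitivity threshold search
    "threshold_rule": ("dominance", "nmb"),
    # arm-level complication prevalences as printed, or mixed by the
    # fraction of the SLN arm that undergoes some lymphadenectomy
    "complication_mixing": ("arm_level", "extent_weighted"),
    # the printed 5-year mortality rates are all-cause: the background
    # (non-cancer) share is subtracted before deriving the cancer case
    # fatality.  "cancer_specific" skips the subtraction and reads the
    # printed rates as pure cancer mortality.
    "mortality_input": ("all_cause", "cancer_specific"),
    # how the recurrence state's death probability is mixed over the
    # contributing treatment groups: "static" weights by the expected
    # incident flow at baseline (tree occupancy x annual recurrence rate);
    # "tracked" follows the state's actual composition cycle by cycle.
    "recurrence_mixing": ("static", "tracked"),
    # how the annual death probability in the recurrence state is derived:
    # "calibrated" solves, per treatment group, for the constant annual
    # probability that reproduces the group's printed 5-year all-cause
    # mortality within the model; "case_fatality" uses the annualized
    # ratio of 5-year mortality to 5-year recurrence.
    "recurrence_mortality": ("calibrated", "case_fatality"),
}


class ParameterError(ValueError):
    """Configuration or validation failure in a parameter set."""


@dataclass(frozen=True)
class ParamSpec:
    """One model input: base value, uncertainty and sampling metadata.

    ``kind`` drives domain validation and the probabilistic-analysis
    distribution family (beta for probabilities/utilities, gamma for costs
    and durations).  ``events``/``trials`` carry the binomial counts printed
    for some probabilities; ``sd`` a directly printed standard deviation.
    ``ci_ok`` is False where the printed interval is inconsistent with the
    base value and must not be used for distribution fitting.
    """

    name: str
    value: float
    kind: str  # probability | utility | cost | minutes | setting
    low: float | None = None
    high: float | None = None
    dist_family: str = "auto"  # beta | gamma | fixed | normal-truncated | auto
    source_tag: str = ""
    events: int | None = None
    trials: int | None = None
    sd: float | None = None
    note: str = ""

    @property
    def ci_ok(self) -> bool:
        """Printed interval usable for fitting (exists, ordered, contains value)."""
        if self.low is None or self.high is None:
            return False
        return self.low <= self.value <= self.high and self.high > self.low

    def domain(self) -> tuple[float, float]:
        if self.kind in ("probability", "utility"):
            return (0.0, 1.0)
        if self.kind in ("cost", "minutes"):
            return (0.0, float("inf"))
        return (-float("inf"), float("inf"))

    def validate(self) -> tuple[list[str], list[str]]:
        """Return (errors, warnings) for this spec alone."""
        errors, warns = [], []
        lo, hi = self.domain()
        if not (lo <= self.value <= hi):
            errors.append(
                f"{self.name}: value {self.value} outside domain [{lo}, {hi}]"
            )
        if self.low is not None and self.high is not None:
            if self.dist_family != "fixed" and not self.ci_ok:
                warns.append(
                    f"{self.name}: base value {self.value} outside printed "
                    f"interval [{self.low}, {self.high}]; interval flagged "
                    "unreliable"
                )
        if self.note:
            warns.append(f"{self.name}: {self.note}")
        return errors, warns


class Scenario(Enum):
    """Adjuvant therapy given to node-positive patients.

    Node-negative and undetected node-positive patients always receive
    vaginal brachytherapy, whatever the scenario.
    """

    EBRT = "ebrt"
    CHEMO = "chemo"
    BOTH = "both"

    @property
    def label(self) -> str:
        return {
            "ebrt": "EBRT",
            "chemo": "chemotherapy",
            "both": "EBRT + chemotherapy",
        }[self.value]


def _p(name, value, low=None, high=None, *, events=None, trials=None,
       source="", note="", family="auto"):
    return ParamSpec(name, value, "probability", low, high, family, source,
                     events, trials, None, note)


def _c(name, value, low=None, high=None, *, source="", note="", family="auto"):
    return ParamSpec(name, value, "cost", low, high, family, source, note=note)


def _u(name, value, low=None, high=None, *, sd=None, source="", family="auto"):
    return ParamSpec(name, value, "utility", low, high, family, source, sd=sd)


def _default_specs() -> dict[str, ParamSpec]:
    s: list[ParamSpec] = [
        # --- diagnostic pathway -----------------------------------------
        _p("p_lnm", 0.21, 0.20, 0.23, source="pooled prevalence of lymph node metastases"),
        _p("p_bilateral", 0.79, events=179, trials=227, source="bilateral SLN detection"),
        _p("p_unilateral", 0.16, events=37, trials=227, source="unilateral SLN detection"),
        _p("p_failed", 0.05, events=11, trials=227, source="failed SLN detection"),
        _p("sens_sln", 0.97, events=35, trials=36, source="SLN mapping sensitivity"),
        _p("spec_sln", 1.0, family="fixed", source="SLN specificity assumed perfect"),
        # --- operating times (minutes per side) -------------------------
        ParamSpec("t_sln_unilateral", 10.0, "minutes", 8.0, 12.0, source_tag="unilateral SLN mapping time"),
        ParamSpec("t_lnd_unilateral", 30.0, "minutes", 24.0, 46.0, source_tag="unilateral lymphadenectomy time"),
        # --- short-term treatment toxicity ------------------------------
        _p("p_st_tox_ebrt", 0.44, events=145, trials=326, source="short-term toxicity, EBRT"),
        _p("p_st_tox_chemo", 0.90, events=325, trials=361, source="short-term toxicity, chemotherapy"),
        _p("p_st_tox_both", 0.96, events=332, trials=346, source="short-term toxicity, EBRT + chemo"),
        _p("p_st_tox_vbt", 0.21, 0.12, 0.34, source="short-term toxicity, VBT"),
        # --- long-term treatment toxicity -------------------------------
        _p("p_lt_tox_ebrt", 0.23, events=43, trials=187, source="long-term toxicity, EBRT"),
        _p("p_lt_tox_chemo", 0.35, events=125, trials=361, source="long-term toxicity, chemotherapy"),
        _p("p_lt_tox_both", 0.38, events=76, trials=201, source="long-term toxicity, EBRT + chemo"),
        _p("p_lt_tox_vbt", 0.26, 0.19, 0.34, source="long-term toxicity, VBT"),
        # --- surgical complications (arm-level prevalences) -------------
        _p("p_lymphedema_lnd", 0.19, 0.13, 0.18,
           source="lymphedema after lymphadenectomy",
           note="printed interval 13-18% excludes the 19% base value; interval not used for fitting"),
        _p("p_lymphedema_sln", 0.05, 0.00, 0.09, source="lymphedema after SLN mapping"),
        _p("p_lymphocele_lnd", 0.06, 0.04, 0.10, source="symptomatic lymphocele after lymphadenectomy"),
        _p("p_lymphocele_sln", 0.02, 0.01, 0.03, source="symptomatic lymphocele after SLN mapping"),
        # --- 5-year vaginal recurrence by group -------------------------
        _p("r5_vag_ebrt", 0.021, 0.010, 0.044, source="5-yr vaginal recurrence, LNM+ EBRT"),
        _p("r5_vag_chemo", 0.049, events=18, trials=348, source="5-yr vaginal recurrence, LNM+ chemo"),
        _p("r5_vag_both", 0.019, events=7, trials=370, source="5-yr vaginal recurrence, LNM+ EBRT+chemo"),
        _p("r5_vag_vbt_pos", 0.67, events=10, trials=15, source="5-yr vaginal recurrence, LNM+ VBT only"),
        _p("r5_vag_vbt_neg", 0.061, events=22, trials=363, source="5-yr vaginal recurrence, LNM- VBT"),
        # --- 5-year regional/distant recurrence by group -----------------
        _p("r5_rec_ebrt", 0.416, source="5-yr regional/distant recurrence, LNM+ EBRT"),
        _p("r5_rec_chemo", 0.42, 0.34, 0.502, source="5-yr regional/distant recurrence, LNM+ chemo"),
        _p("r5_rec_both", 0.291, 0.36, 0.47,
           source="5-yr regional/distant recurrence, LNM+ EBRT+chemo",
           note="printed interval 36-47% inconsistent with 29.1% base (columns appear shifted); interval not used"),
        _p("r5_rec_vbt_pos", 0.67, 0.226, 0.371,
           source="5-yr regional/distant recurrence, LNM+ VBT only",
           note="printed interval 22.6-37.1% inconsistent with 67% base (columns appear shifted); interval not used"),
        _p("r5_rec_vbt_neg", 0.25, source="5-yr regional/distant recurrence, LNM- VBT"),
        # --- 5-year all-cause mortality by group -------------------------
        _p("m5_ebrt", 0.315, 0.233, 0.388, source="5-yr mortality, LNM+ EBRT"),
        _p("m5_chemo", 0.235, events=86, trials=366, source="5-yr mortality, LNM+ chemo"),
        _p("m5_both", 0.215, 0.146, 0.278, source="5-yr mortality, LNM+ EBRT+chemo"),
        _p("m5_vbt_pos", 0.70, 0.60, 0.80, source="5-yr mortality, LNM+ VBT only (expert opinion)"),
        _p("m5_vbt_neg", 0.061, source="5-yr mortality, LNM- VBT"),
        # --- unit costs, EUR (2023) --------------------------------------
        _c("c_histo_lnd", 823.71, 658.97, 988.45, source="histopathology, lymphadenectomy"),
        _c("c_histo_sln", 1189.02, 951.22, 1426.82, source="histopathology, SLN (ultrastaging)"),
        _c("c_or_per_min", 11.08, 7.1, 11.8, source="operating-room time incl. medical specialists, per minute"),
        _c("c_icg", 35.18, 24.0, 36.0, source="indocyanine green, per patient"),
        _c("c_lymphedema_init", 1114.0, 760.0, 1140.0, source="initial lymphedema treatment"),
        _c("c_lymphedema_yearly", 2579.78, 1760.0, 2640.0, source="yearly lymphedema treatment"),
        _c("c_lymphocele_drain", 934.59, 637.6, 1147.68, source="lymphocele drainage"),
        _c("c_ebrt", 8237.72, 6092.0, 9138.0, source="external beam radiotherapy course"),
        _c("c_chemo", 8682.17, 5923.2, 8884.8, source="chemotherapy course"),
        _c("c_vbt", 9269.63, 6.572, 9858.0, source="vaginal brachytherapy course",
           note="printed lower bound 6.572 presumed a typo for 6572; stored as printed"),
        _c("c_followup_visit", 138.0, 88.0, 133.2, source="standard follow-up visit",
           note="printed interval 88.0-133.2 excludes the 138 base value; interval not used for fitting"),
        # --- utilities ----------------------------------------------------
        _u("u_perfect", 1.0, family="fixed", source="no recurrence, no toxicity"),
        _u("u_rt_tox", 0.866, 0.758, 0.946, source="radiotherapy-induced toxicity"),
        _u("u_chemo_tox", 0.50, sd=0.21, source="chemotherapy-induced toxicity"),
        _u("u_both_tox", 0.50, sd=0.21, source="combined chemo- and radiotherapy-induced toxicity"),
        _u("u_lymphedema", 0.925, 0.851, 0.998, source="lymphedema"),
        _u("u_vag_rec", 0.69, 0.58, 0.79, source="vaginal recurrence"),
        _u("u_rec", 0.38, 0.30, 0.45, source="regional/distant recurrence"),
        _u("u_dead", 0.0, family="fixed", source="death"),
        # --- analysis settings (never sampled, never DSA-varied) ----------
        ParamSpec("disc_costs", 0.04, "setting", dist_family="fixed", source_tag="annual discount rate, costs"),
        ParamSpec("disc_effects", 0.015, "setting", dist_family="fixed", source_tag="annual discount rate, effects"),
        ParamSpec("wtp", 20000.0, "setting", dist_family="fixed", source_tag="willingness-to-pay, EUR per QALY"),
        ParamSpec("horizon", 20, "setting", dist_family="fixed", source_tag="model horizon, annual cycles"),
        ParamSpec("cycle_length", 1.0, "setting", dist_family="fixed", source_tag="cycle length, years"),
        ParamSpec("start_age", 65, "setting", dist_family="fixed", source_tag="cohort age at surgery, years"),
        ParamSpec("n_followup_visits_per_year", 2, "setting", dist_family="fixed", source_tag="follow-up visits per alive year"),
    ]
    return {spec.name: spec for spec in s}


@dataclass
class ParameterSet:
    """Complete, validated registry of model inputs plus structural flags.

    Parameter values are readable as attributes (``ps.p_lnm``) or via
    :meth:`value`; the full :class:`ParamSpec` via :meth:`spec`.
    """

    specs: dict[str, ParamSpec] = field(default_factory=_default_specs)
    flags: dict[str, str] = field(
        default_factory=lambda: {k: v[0] for k, v in FLAG_CHOICES.items()}
    )

    # -- access -----------------------------------------------------------
    def __getattr__(self, name: str) -> float:
        specs = object.__getattribute__(self, "specs")
        if name in specs:
            return specs[name].value
        raise AttributeError(name)

    def value(self, name: str) -> float:
        try:
            return self.specs[name].value
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def spec(self, name: str) -> ParamSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def __iter__(self) -> Iterator[ParamSpec]:
        return iter(self.specs.values())

    def names(self) -> list[str]:
        return list(self.specs)

    # group-indexed helpers used by the Markov engine
    def r5_vag(self, group: str) -> float:
        return self.value(f"r5_vag_{group}")

    def r5_rec(self, group: str) -> float:
        return self.value(f"r5_rec_{group}")

    def m5(self, group: str) -> float:
        return self.value(f"m5_{group}")

    # -- mutation (copy-on-write) ------------------------------------------
    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Copy with one parameter replaced (no revalidation)."""
        spec = self.spec(name)
        new = copy.copy(self.specs)
        new[name] = replace(spec, value=float(value))
        return ParameterSet(new, dict(self.flags))

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        new = copy.copy(self.specs)
        for name, value in overrides.items():
            new[name] = replace(self.spec(name), value=float(value))
        return ParameterSet(new, dict(self.flags))

    # -- validation ---------------------------------------------------------
    def validate(self, strict: bool = True) -> list[str]:
        """Validate every spec and cross-parameter invariants.

        Printed-table inconsistencies (a base value outside its own
        interval, a suspect bound) warn rather than fail; hard domain or
        simplex violations raise :class:`ParameterError` when ``strict``.
        Returns the list of warning messages.
        """
        errors: list[str] = []
        warns: list[str] = []
        for spec in self:
            e, w = spec.validate()
            errors += e
            warns += w
        for msg in warns:
            warnings.warn(msg, stacklevel=2)
        trio = sum(self.value(n) for n in MAPPING_TRIO)
        if abs(trio - 1.0) > 1e-9:
            errors.append(f"SLN mapping outcomes sum to {trio}, expected 1")
        if self.horizon < 1:
            errors.append("horizon must be at least one cycle")
        for flag, val in self.flags.items():
            if flag not in FLAG_CHOICES or val not in FLAG_CHOICES[flag]:
                errors.append(f"invalid flag {flag}={val}")
        if errors and strict:
            raise ParameterError("; ".join(errors))
        return warns if not errors else warns + errors

    # -- serialization --------------------------------------------------------
    def to_config(self) -> dict:
        """Flat name→value mapping (plus flags); round-trips exactly."""
        cfg = {name: spec.value for name, spec in self.specs.items()}
        cfg.update({f"flag.{k}": v for k, v in self.flags.items()})
        return cfg

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.name,
                "value": s.value,
                "low": s.low,
                "high": s.high,
                "dist_family": s.dist_family,
                "source": s.source_tag,
            }
            for s in self
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_parameters() -> ParameterSet:
    """The base-case registry: every published input at its printed value."""
    ps = ParameterSet()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps.validate()
    return ps


def load_parameters(config_source: str | Path | Mapping | None) -> ParameterSet:
    """Defaults with flat key→value overrides from a mapping or YAML/JSON file.

    Unknown keys are rejected; the result is revalidated (hard errors raise
    :class:`ParameterError`, printed-inconsistency warnings are emitted via
    :mod:`warnings`).
    """
    if config_source is None:
        return default_parameters()
    if isinstance(config_source, Mapping):
        cfg = dict(config_source)
    else:
        path = Path(config_source)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        cfg = cfg or {}
    ps = default_parameters()
    flag_overrides = {}
    value_overrides = {}
    for key, val in cfg.items():
        if key.startswith("flag."):
            flag_overrides[key[5:]] = val
        elif key in FLAG_CHOICES:
            flag_overrides[key] = val
        elif key in ps.specs:
            value_overrides[key] = val
        else:
            raise ParameterError(f"unknown configuration key {key!r}")
    ps = ps.with_values(value_overrides)
    for flag, val in flag_overrides.items():
        if flag not in FLAG_CHOICES or val not in FLAG_CHOICES[flag]:
            raise ParameterError(f"invalid flag override {flag}={val!r}")
        ps.flags[flag] = val
    ps.validate()
    return ps


def perturbed_copy(ps: ParameterSet, name: str, factor: float) -> ParameterSet:
    """Copy with one value multiplied by ``(1 + factor)``.

    Probabilities and utilities are clipped to [0, 1] with a warning.  When a
    SLN-mapping outcome probability is perturbed, the other two are rescaled
    proportionally so the trio stays on the simplex.
    """
    spec = ps.spec(name)
    if spec.kind == "setting":
        raise ParameterError(f"{name!r} is an analysis setting, not a model parameter")
    new_value = spec.value * (1.0 + factor)
    lo, hi = spec.domain()
    if not (lo <= new_value <= hi):
        clipped = min(max(new_value, lo), hi)
        warnings.warn(
            f"perturbed {name} = {new_value:.6g} clipped to {clipped:.6g}",
            stacklevel=2,
        )
        new_value = clipped
    out = ps.with_value(name, new_value)
    if name in MAPPING_TRIO:
        others = [n for n in MAPPING_TRIO if n != name]
        rest = sum(ps.value(n) for n in others)
        target = 1.0 - new_value
        if rest > 0:
            out = out.with_values({n: ps.value(n) * target / rest for n in others})
    return out
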