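"""Model parameter catalogue.

Every input of the cost-utility model lives here as a point estimate with
provenance, plus the uncertainty distribution used in probabilistic
sensitivity analysis (PSA).  The catalogue covers:

* prevalence of bladder cancer among haematuria-clinic attenders (pooled
  from three clinic series),
* diagnostic accuracy of the biomarker triage test and of flexible
  cystoscopy (binomial counts),
* six-month natural-history transition probabilities (recurrence,
  progression, disease-specific mortality) for the Markov cohort,
* the false-negative track: relative risk of progression without treatment
  and the staged detection schedule,
* unit costs (GBP, 2014) and health-state utilities / procedure decrements,
* analysis settings (discounting, horizon, cycle length, start age).

All values can be overridden through :func:`build_base_case` or a YAML
config; overrides must name known fields.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .distributions import (
    DistributionSpec,
    beta_from_counts,
    beta_from_moments,
    beta_spec_from_range,
    fixed,
    lognormal_for_decrement,
    se_from_range,
)

__all__ = [
    "PrevalenceStudy",
    "TestAccuracy",
    "ParameterSet",
    "PREVALENCE_STUDIES",
    "aggregate_prevalence",
    "build_base_case",
    "default_psa_specs",
    "sample_parameter_set",
    "load_config",
    "catalogue_frame",
]


@dataclass(frozen=True)
class PrevalenceStudy:
    """One clinic series: bladder-cancer diagnoses out of patients seen."""

    cases: int
    n: int
    label: str = ""

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("study size must be positive")
        if not 0 <= self.cases <= self.n:
            raise ValueError("cases must lie in [0, n]")


#: The three haematuria-clinic series informing pooled prevalence.
PREVALENCE_STUDIES = (
    PrevalenceStudy(230, 1930, "haematuria clinic series A"),
    PrevalenceStudy(485, 4020, "haematuria clinic series B"),
    PrevalenceStudy(156, 778, "rapid diagnosis clinic series"),
)


def aggregate_prevalence(studies) -> float:
    """Pooled prevalence Σcases / Σn across clinic series."""
    studies = list(studies)
    if not studies:
        raise ValueError("need at least one study")
    total_n = sum(s.n for s in studies)
    if total_n == 0:
        raise ValueError("total denominator is zero")
    return sum(s.cases for s in studies) / total_n


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity/specificity of one diagnostic test, with source counts."""

    sensitivity: float
    specificity: float
    sens_counts: tuple[int, int] | None = None  # (successes, total)
    spec_counts: tuple[int, int] | None = None
    sens_ci: tuple[float, float] | None = None
    spec_ci: tuple[float, float] | None = None

    def __post_init__(self):
        for p in (self.sensitivity, self.specificity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("accuracy values must lie in [0, 1]")
        for counts, point in ((self.sens_counts, self.sensitivity),
                              (self.spec_counts, self.specificity)):
            if counts is not None:
                k, n = counts
                if round(k / n, 3) != round(point, 3):
                    raise ValueError(
                        f"counts {k}/{n} do not reproduce point {point} at 3 d.p.")


# ---------------------------------------------------------------------------
# The full parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """Point estimates for every model input. Frozen; use overrides to vary."""

    # epidemiology & test accuracy
    prevalence: float = 871 / 6728
    accuracy_dcrshp: TestAccuracy = field(default_factory=lambda: TestAccuracy(
        sensitivity=57 / 63, specificity=31 / 39,
        sens_counts=(57, 63), spec_counts=(31, 39),
        sens_ci=(0.804, 0.964), spec_ci=(0.635, 0.907)))
    accuracy_cysto: TestAccuracy = field(default_factory=lambda: TestAccuracy(
        sensitivity=145 / 148, specificity=562 / 599,
        sens_counts=(145, 148), spec_counts=(562, 599),
        sens_ci=(0.942, 0.996), spec_ci=(0.916, 0.956)))

    # case mix at diagnosis: LR-NMIBC, HR-BCG, HR-Cystectomy, MIBC, Metastasis
    diagnosis_split: tuple = (105 / 192, 47 / 192, 13 / 192, 14 / 192, 13 / 192)

    # six-month transition probabilities
    p_rec_lr: float = 0.0638          # LR NMIBC recurrence
    p_rec_hr: float = 0.1393          # HR NMIBC (BCG) recurrence
    p_prog_hrbcg_mibc: float = 0.030
    p_prog_hrbcg_met: float = 0.010
    p_prog_hrcyst_met: float = 0.030
    p_prog_mibc_met: float = 0.0771   # first 5 years from entry
    p_prog_mibc_met_late: float = 0.0060
    p_bcdeath_nmibc: float = 0.0048   # Well/BCG/Cystectomy disease-specific
    p_bcdeath_mibc: float = 0.0497
    p_bcdeath_mibc_late: float = 0.0327
    p_bcdeath_met: float = 0.236
    p_rec_cystectomy: float = 9 / 52  # recurrences converting to cystectomy
    p_cystectomy_mort: float = 96 / 4484
    p_turbt_mort: float = 0.008
    male_fraction: float = 0.796
    start_age: float = 60.0

    # false-negative (undiagnosed) track
    rr_untreated: float = 2.56        # RR on progression & BC mortality
    fn_detect_year1: float = 0.50     # cumulative detection by end of year 1
    fn_detect_year2: float = 0.75     # cumulative by end of year 2 (then 1.0)

    # costs, GBP 2014
    cost_cystectomy: float = 9816.0
    cost_turbt: float = 2435.0
    cost_palliative_day: float = 160.46
    palliative_days: float = 135.0
    palliative_per_day: bool = False  # True: charge tariff x 135 days
    cost_cisplatin_vial: float = 50.22
    chemo_vials_per_course: float = 3.0
    cost_ct: float = 395.0
    cost_cysto: float = 537.0
    cost_bcg_vial: float = 71.61
    dcrshp_price: float = 465.48      # free parameter of the analysis

    # utilities and event probabilities
    u_well: float = 1.0
    u_cancer: float = 0.78            # standing utility with bladder cancer
    u_postcyst: float = 0.96
    u_impotence: float = 0.91         # multiplies post-cystectomy utility
    p_impotence: float = 0.59
    u_cystectomy_period: float = 0.8  # utility during 60 d post-surgery
    p_cyst_compl: float = 0.267
    d_cyst_compl: float = 0.3         # over 60 d
    d_turbt: float = 0.1              # over 7 d
    d_bcg_induction: float = 0.02     # over 6 weeks
    p_bcg_compl: float = 0.286
    d_bcg_compl: float = 0.2          # over 6 months
    d_chemo: float = 0.36             # over 103 d
    p_chemo_response: float = 0.425
    u_met_responsive: float = 0.62
    u_met_unresponsive: float = 0.3
    cysto_utility_factor: float = 0.997  # per-cystoscopy cycle utility factor

    # analysis settings
    discount_rate: float = 0.035
    horizon_years: float = 5.0
    cycle_length: float = 0.5
    bc_death_in_well: bool = False    # apply 0.0048 to never-cancer Well?

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        probs = {
            "prevalence": self.prevalence,
            "p_rec_lr": self.p_rec_lr, "p_rec_hr": self.p_rec_hr,
            "p_prog_hrbcg_mibc": self.p_prog_hrbcg_mibc,
            "p_prog_hrbcg_met": self.p_prog_hrbcg_met,
            "p_prog_hrcyst_met": self.p_prog_hrcyst_met,
            "p_prog_mibc_met": self.p_prog_mibc_met,
            "p_prog_mibc_met_late": self.p_prog_mibc_met_late,
            "p_bcdeath_nmibc": self.p_bcdeath_nmibc,
            "p_bcdeath_mibc": self.p_bcdeath_mibc,
            "p_bcdeath_mibc_late": self.p_bcdeath_mibc_late,
            "p_bcdeath_met": self.p_bcdeath_met,
            "p_rec_cystectomy": self.p_rec_cystectomy,
            "p_cystectomy_mort": self.p_cystectomy_mort,
            "p_turbt_mort": self.p_turbt_mort,
            "male_fraction": self.male_fraction,
            "fn_detect_year1": self.fn_detect_year1,
            "fn_detect_year2": self.fn_detect_year2,
            "p_impotence": self.p_impotence,
            "p_cyst_compl": self.p_cyst_compl,
            "p_bcg_compl": self.p_bcg_compl,
            "p_chemo_response": self.p_chemo_response,
            "u_well": self.u_well, "u_cancer": self.u_cancer,
            "u_postcyst": self.u_postcyst, "u_impotence": self.u_impotence,
            "u_cystectomy_period": self.u_cystectomy_period,
            "u_met_responsive": self.u_met_responsive,
            "u_met_unresponsive": self.u_met_unresponsive,
            "cysto_utility_factor": self.cysto_utility_factor,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        for name in ("cost_cystectomy", "cost_turbt", "cost_palliative_day",
                     "cost_cisplatin_vial", "cost_ct", "cost_cysto",
                     "cost_bcg_vial", "dcrshp_price"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(sum(self.diagnosis_split) - 1.0) > 1e-9:
            raise ValueError("diagnosis_split must sum to 1")
        if self.rr_untreated < 1.0:
            raise ValueError("rr_untreated below 1 (untreated cannot fare better)")
        if not self.fn_detect_year1 <= self.fn_detect_year2 <= 1.0:
            raise ValueError("FN detection schedule must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length))


_ACCURACY_KEYS = {
    "sens_dcrshp": ("accuracy_dcrshp", "sensitivity"),
    "spec_dcrshp": ("accuracy_dcrshp", "specificity"),
    "sens_cysto": ("accuracy_cysto", "sensitivity"),
    "spec_cysto": ("accuracy_cysto", "specificity"),
}

_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}


def build_base_case(overrides: dict | None = None) -> ParameterSet:
    """Base-case parameter set, optionally with named overrides.

    Override keys are ``ParameterSet`` field names, plus the shorthand
    ``sens_dcrshp`` / ``spec_dcrshp`` / ``sens_cysto`` / ``spec_cysto``
    which replace a single accuracy value (dropping its source counts).
    """
    params = ParameterSet()
    if overrides:
        flat: dict = {}
        acc: dict[str, dict] = {}
        for key, value in overrides.items():
            if key in _ACCURACY_KEYS:
                attr, fld = _ACCURACY_KEYS[key]
                acc.setdefault(attr, {})[fld] = float(value)
            elif key in _FIELD_NAMES:
                if key == "diagnosis_split":
                    value = tuple(float(v) for v in value)
                flat[key] = value
            else:
                raise KeyError(f"unknown parameter override {key!r}")
        for attr, upd in acc.items():
            base_acc: TestAccuracy = flat.get(attr, getattr(params, attr))
            flat[attr] = TestAccuracy(
                sensitivity=upd.get("sensitivity", base_acc.sensitivity),
                specificity=upd.get("specificity", base_acc.specificity))
        params = dataclasses.replace(params, **flat)
    params.validate()
    return params


def load_config(path) -> dict:
    """Read a YAML config of parameter overrides (``provenance`` ignored)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping of parameter overrides")
    doc.pop("provenance", None)
    return doc


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

def _beta_counts_spec(k: float, n: float, source: str) -> DistributionSpec:
    a, b = beta_from_counts(k, n - k)
    return DistributionSpec(kind="beta_counts", params=(a, b), point=k / n,
                            source=source, degenerate=(b == 0))


def _beta_scaled_counts(point: float, events: float, n: float,
                        source: str) -> DistributionSpec:
    """Beta with mean = printed point and the *relative* SE of events/n.

    Used for six-month probabilities derived (via an unstated time
    conversion) from source counts: the point estimate is kept as printed and
    the source's proportional uncertainty is carried over.
    """
    phat = events / n
    rel_se = math.sqrt((1.0 - phat) / (phat * n))
    a, b = beta_from_moments(point, point * rel_se)
    return DistributionSpec(kind="beta_moments", params=(a, b), point=point,
                            source=source)


def default_psa_specs(base: ParameterSet) -> dict[str, DistributionSpec]:
    """Distribution for every sampled parameter, keyed by override name.

    Costs are fixed (no uncertainty reported); the test price is handled
    separately by the PSA driver (fixed or uniform over a price range).
    """
    specs: dict[str, DistributionSpec] = {}
    specs["prevalence"] = _beta_counts_spec(871, 6728, "pooled clinic series")
    specs["sens_dcrshp"] = _beta_counts_spec(57, 63, "triage test accuracy")
    specs["spec_dcrshp"] = _beta_counts_spec(31, 39, "triage test accuracy")
    specs["sens_cysto"] = _beta_counts_spec(145, 148, "cystoscopy accuracy")
    specs["spec_cysto"] = _beta_counts_spec(562, 599, "cystoscopy accuracy")
    specs["diagnosis_split"] = DistributionSpec(
        kind="dirichlet", params=(105.0, 47.0, 13.0, 14.0, 13.0),
        point=base.diagnosis_split, source="case mix at diagnosis (n=192)")

    # recurrence: printed point with CI -> Beta by moments
    for name, point, ci in (("p_rec_lr", base.p_rec_lr, (0.0622, 0.0654)),
                            ("p_rec_hr", base.p_rec_hr, (0.1368, 0.1417))):
        a, b = beta_from_moments(point, se_from_range(*ci))
        specs[name] = DistributionSpec("beta_moments", (a, b), point,
                                       source="recurrence probability (CI)")

    # progression / disease mortality: printed point, source-count relative SE
    specs["p_prog_hrbcg_mibc"] = _beta_scaled_counts(
        base.p_prog_hrbcg_mibc, 20, 80, "progression HR(BCG)->MIBC")
    specs["p_prog_hrbcg_met"] = _beta_scaled_counts(
        base.p_prog_hrbcg_met, 5, 80, "progression HR(BCG)->metastasis")
    specs["p_prog_hrcyst_met"] = _beta_scaled_counts(
        base.p_prog_hrcyst_met, 18, 72, "progression HR(cystectomy)->metastasis")
    specs["p_prog_mibc_met"] = _beta_scaled_counts(
        base.p_prog_mibc_met, 337, 1054, "MIBC progression to metastasis")
    specs["p_bcdeath_nmibc"] = _beta_scaled_counts(
        base.p_bcdeath_nmibc, 74, 1529, "BC death, NMIBC/post-cystectomy")
    specs["p_bcdeath_mibc"] = _beta_scaled_counts(
        base.p_bcdeath_mibc, 422, 1054, "BC death, MIBC")
    specs["p_bcdeath_met"] = _beta_scaled_counts(
        base.p_bcdeath_met, 179, 192, "BC death, metastasis")

    specs["p_rec_cystectomy"] = _beta_counts_spec(9, 52, "recurrence to cystectomy")
    specs["p_cystectomy_mort"] = _beta_counts_spec(96, 4484, "30-day cystectomy mortality")
    specs["p_turbt_mort"] = _beta_counts_spec(10, 1250, "TURBT mortality")

    # utilities with ranges -> Beta by moments
    specs["cysto_utility_factor"] = beta_spec_from_range(
        base.cysto_utility_factor, 0.95, 1.0, "cystoscopy cycle utility")
    specs["u_cancer"] = beta_spec_from_range(
        base.u_cancer, 0.52, 1.0, "bladder-cancer standing utility")
    specs["u_postcyst"] = beta_spec_from_range(
        base.u_postcyst, 0.72, 1.0, "post-cystectomy utility")
    specs["u_impotence"] = beta_spec_from_range(
        base.u_impotence, 0.69, 1.0, "impotence utility multiplier")
    specs["u_cystectomy_period"] = beta_spec_from_range(
        base.u_cystectomy_period, 0.5, 1.0, "utility during cystectomy recovery")
    specs["u_met_responsive"] = beta_spec_from_range(
        base.u_met_responsive, 0.31, 0.93, "metastasis, chemo-responsive")
    specs["u_met_unresponsive"] = beta_spec_from_range(
        base.u_met_unresponsive, 0.13, 0.62, "metastasis, unresponsive")

    # event probabilities with ranges
    specs["p_bcg_compl"] = beta_spec_from_range(
        base.p_bcg_compl, 0.18, 0.67, "BCG complication probability")
    specs["p_cyst_compl"] = beta_spec_from_range(
        base.p_cyst_compl, 0.20, 0.304, "short-term cystectomy complication")
    specs["p_impotence"] = beta_spec_from_range(
        base.p_impotence, 0.33, 1.0, "impotence probability")
    specs["p_chemo_response"] = beta_spec_from_range(
        base.p_chemo_response, 0.381, 0.57, "chemo response probability")

    # utility decrements -> log-normal on the magnitude
    specs["d_turbt"] = lognormal_for_decrement(base.d_turbt, 0.02, "TURBT decrement")
    specs["d_bcg_induction"] = lognormal_for_decrement(
        base.d_bcg_induction, se_from_range(0.0, 0.3), "BCG induction decrement")
    specs["d_bcg_compl"] = lognormal_for_decrement(
        base.d_bcg_compl, se_from_range(0.0, 0.4), "BCG complication decrement")
    specs["d_cyst_compl"] = lognormal_for_decrement(
        base.d_cyst_compl, se_from_range(0.0, 0.6), "cystectomy complication decrement")
    specs["d_chemo"] = lognormal_for_decrement(
        base.d_chemo, se_from_range(0.2, 0.9), "chemotherapy decrement")

    # relative risk without treatment: log-normal, mean 2.56, SE 1, floor 1
    specs["rr_untreated"] = dataclasses.replace(
        lognormal_for_decrement(base.rr_untreated, 1.0),
        source="RR progression/mortality untreated vs treated")
    return specs


def sample_parameter_set(base: ParameterSet,
                         specs: dict[str, DistributionSpec],
                         rng: np.random.Generator | int) -> ParameterSet:
    """One joint PSA draw, applied as overrides to ``base``.

    Parameters are drawn in sorted key order so the draw depends only on the
    generator state, not on dict insertion order.  RR draws below 1 are
    floored at 1 (untreated disease cannot progress more slowly than treated).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    overrides: dict = {}
    for key in sorted(specs):
        spec = specs[key]
        val = spec.sample(rng)
        if key == "rr_untreated":
            val = max(1.0, float(val))
        if key == "diagnosis_split":
            overrides[key] = tuple(np.asarray(val, dtype=float))
        else:
            overrides[key] = float(val)
    drawn = build_base_case({**overrides})
    return drawn


def catalogue_frame(base: ParameterSet | None = None,
                    specs: dict[str, DistributionSpec] | None = None) -> pd.DataFrame:
    """CSV-ready table of the catalogue: point values and PSA distributions."""
    base = base or build_base_case()
    specs = specs if specs is not None else default_psa_specs(base)
    rows = []
    for key in sorted(specs):
        s = specs[key]
        rows.append({"parameter": key, "point": s.point, "kind": s.kind,
                     "params": repr(tuple(np.round(np.atleast_1d(s.params), 6))),
                     "source": s.source})
    for name in ("cost_cystectomy", "cost_turbt", "cost_palliative_day",
                 "cost_cisplatin_vial", "cost_ct", "cost_cysto",
                 "cost_bcg_vial", "dcrshp_price", "discount_rate",
                 "horizon_years", "cycle_length", "start_age"):
        rows.append({"parameter": name, "point": getattr(base, name),
                     "kind": "fixed", "params": "", "source": "catalogue"})
    return pd.DataFrame(rows)
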