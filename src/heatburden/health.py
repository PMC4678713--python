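"""From PM2.5 emissions to population exposure, premature deaths and DALYs.

Emissions are converted to a population-average concentration increment with
an intake fraction (the fraction of emitted mass eventually inhaled by the
exposed population), avoiding dispersion modelling.  The concentration
increment enters a log-linear exposure-response function (relative risk per
10 µg/m³ of long-term PM2.5), the population attributable fraction
(RR−1)/RR is applied to background mortality, and deaths are converted to
DALYs with a years-of-life-lost scalar.  Only mortality is counted: the YLD
component of the DALY is zero by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import VALUE, IndexedTable, TableError, align_binary

DAYS_PER_YEAR = 365.25
UG_PER_TONNE = 1e12

ERF_FORMS = ("loglinear", "linear")


@dataclass
class HealthParameters:
    """Scalar parameters of the exposure-health chain.

    population: exposed persons.
    background_mortality: all-cause deaths per person per year.
    breathing_rate: m³ inhaled per person per day (nominal adult ~13).
    intake_fraction: inhaled mass / emitted mass (dimensionless).
    rr_per_10: relative risk of all-cause mortality per 10 µg/m³ PM2.5.
    yll_per_death: years of life lost per premature death.
    counterfactual: concentration (µg/m³) below which no risk is counted.
    erf_form: 'loglinear' (default) or 'linear' relative-risk model.
    """

    population: float
    background_mortality: float
    breathing_rate: float
    intake_fraction: float
    rr_per_10: float
    yll_per_death: float
    counterfactual: float = 0.0
    erf_form: str = "loglinear"

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise TableError("population must be positive")
        if self.breathing_rate <= 0:
            raise TableError("breathing rate must be positive")
        if not 0.0 < self.intake_fraction < 1.0:
            raise TableError("intake fraction must be in (0, 1)")
        if self.rr_per_10 < 1.0:
            raise TableError("relative risk per 10 µg/m³ must be ≥ 1")
        if self.yll_per_death <= 0:
            raise TableError("YLL per death must be positive")
        if self.erf_form not in ERF_FORMS:
            raise TableError(f"unknown ERF form {self.erf_form!r}")


# ----------------------------------------------------------- scalar formulas
def exposure_concentration(emission, hp: HealthParameters):
    """Population-average concentration increment, µg/m³, from t/a emitted.

    ΔC = emission · iF / (P · BR · 365.25), with tonnes converted to µg and
    the daily breathing rate to an annual inhaled volume.
    """
    em = np.asarray(emission, dtype=float)
    if (em < 0).any() if em.ndim else em < 0:
        raise TableError("emission must be non-negative")
    annual_volume = hp.population * hp.breathing_rate * DAYS_PER_YEAR
    return em * UG_PER_TONNE * hp.intake_fraction / annual_volume


def relative_risk(delta_c, hp: HealthParameters):
    """Relative risk at a concentration increment above the counterfactual."""
    dc = np.asarray(delta_c, dtype=float)
    excess = np.maximum(dc - hp.counterfactual, 0.0)
    if hp.erf_form == "linear":
        rr = 1.0 + (hp.rr_per_10 - 1.0) * excess / 10.0
    else:
        rr = np.exp(np.log(hp.rr_per_10) * excess / 10.0)
    return np.maximum(rr, 1.0)


def attributable_deaths(rr, hp: HealthParameters):
    """Premature deaths per year via the population attributable fraction."""
    r = np.asarray(rr, dtype=float)
    if (r < 1).any() if r.ndim else r < 1:
        raise TableError("relative risk below 1")
    return hp.population * hp.background_mortality * (r - 1.0) / r


def burden_daly(deaths, hp: HealthParameters):
    """DALY/a = deaths/a × YLL per death (mortality only, YLD = 0)."""
    d = np.asarray(deaths, dtype=float)
    return d * hp.yll_per_death


def deaths_from_emission(emission, hp: HealthParameters):
    """Full scalar chain: t/a emitted PM2.5 → premature deaths per year."""
    dc = exposure_concentration(emission, hp)
    return attributable_deaths(relative_risk(dc, hp), hp)


# ------------------------------------------------------------- table chain
_PARAM_NAMES = ("population", "background_mortality", "breathing_rate",
                "intake_fraction", "rr_per_10", "yll_per_death")


def _param(tables, name, unit) -> IndexedTable:
    v = tables[name]
    if isinstance(v, IndexedTable):
        return v
    return IndexedTable.scalar(float(v), unit, name)


def burden_from_emissions(pm: IndexedTable, params,
                          erf_form: str = "loglinear",
                          counterfactual: float = 0.0,
                          keep: tuple[str, ...] = ("Time",)):
    """Table version of the exposure-health chain.

    ``pm`` is PM2.5 emission (t/a), typically indexed by Time and Heating
    (source archetype).  ``params`` is a :class:`HealthParameters` or a
    mapping of parameter name to scalar or IndexedTable -- the intake
    fraction, for example, may be indexed by Heating to distinguish
    high-stack plants from ground-level sources, and any parameter may carry
    Iteration or decision columns from sampling.  Intake is summed over
    source archetypes before the (nonlinear) relative risk is applied.

    Returns ``(deaths, daly)`` tables indexed by ``keep`` plus any decision
    and Iteration columns.
    """
    if isinstance(params, HealthParameters):
        erf_form = params.erf_form
        counterfactual = params.counterfactual
        params = {n: getattr(params, n) for n in _PARAM_NAMES}
    if erf_form not in ERF_FORMS:
        raise TableError(f"unknown ERF form {erf_form!r}")

    iF = _param(params, "intake_fraction", "1")
    pop = _param(params, "population", "persons")
    br = _param(params, "breathing_rate", "m3/d")
    mort = _param(params, "background_mortality", "1/a")
    rr10 = _param(params, "rr_per_10", "1")
    yll = _param(params, "yll_per_death", "a")
    if (rr10.values < 1).any():
        raise TableError("relative risk per 10 µg/m³ must be ≥ 1")

    intake = align_binary(pm, iF, "*")  # t/a inhaled-equivalent
    keep_present = [c for c in keep if c in intake.index_cols]
    intake = intake.aggregate(keep_present)
    volume = align_binary(pop, br, "*").transform(lambda v: v * DAYS_PER_YEAR)
    dc = align_binary(intake, volume, "/").transform(
        lambda v: v * UG_PER_TONNE, unit="ug/m3")

    excess = dc.transform(lambda v: np.maximum(v - counterfactual, 0.0))
    if erf_form == "linear":
        slope = rr10.transform(lambda v: (v - 1.0) / 10.0)
        rr = align_binary(excess, slope, "*").transform(lambda v: 1.0 + v, unit="1")
    else:
        lnr = rr10.transform(np.log)
        rr = align_binary(excess.transform(lambda v: v / 10.0), lnr, "*").transform(
            np.exp, unit="1")
    af = rr.transform(lambda v: (v - 1.0) / v, unit="1")
    deaths = align_binary(align_binary(af, pop, "*"), mort, "*")
    deaths = IndexedTable(deaths.data, "deaths/a", "premature_deaths", deaths.decisions)
    daly = align_binary(deaths, yll, "*")
    daly = IndexedTable(daly.data, "DALY/a", "burden", daly.decisions)
    return deaths, daly
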