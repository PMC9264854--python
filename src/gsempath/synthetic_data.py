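"""Synthetic NFHS-like survey generator.

Generates individual women's records with the statistical structure the path
analysis assumes: exogenous demographics drawn independently from realistic
category margins, mediators (STI awareness, contraception use, number of
children) drawn from their logit-linked equations, the screening outcome drawn
from its logit equation given all predictors, and block missingness emulating
variables collected only in a survey subsample.

Defaults are calibrated to the published survey margins and use the published
path coefficients as generating truths, so parameter-recovery experiments test
the estimator against known effects at realistic prevalences.  Intercepts are
not published and are calibrated once, deterministically (bisection for binary
equations, a damped fixed point for multinomial ones), against a fixed internal
covariate sample — independent of the user's seed.

Known simplification: exogenous covariates are mutually independent (no
wealth x schooling association); association with the outcome flows only
through the declared equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .effects import load_reported_system
from .model_spec import PathDiagram, design_columns, encode_design
from . import model_spec

__all__ = [
    "Scenario",
    "default_scenario",
    "generate_population",
    "summarize_margins",
    "EXOGENOUS_MARGINS",
    "MEDIATOR_TARGETS",
    "SCREENING_PREVALENCE",
]

_CALIBRATION_SEED = 20150601   # fixed internal stream; never the user's seed
_CALIBRATION_N = 200_000

# Exogenous category margins from the published survey characteristics table
# (category totals over 699,686 respondents; autonomy and sex partners over
# the ~87k subsample in which they were collected).
EXOGENOUS_MARGINS: dict[str, dict[str, float]] = {
    "age": {"15-34": 459_957 / 699_686, "35-49": 239_729 / 699_686},
    "bmi": {
        "underweight": 150_659 / 687_156,
        "normal": 410_436 / 687_156,
        "overweight": 97_116 / 687_156,
        "obese": 28_945 / 687_156,
    },
    "facility_barrier": {
        "not_a_big_problem": 441_291 / 699_686,
        "distance_only": 50_396 / 699_686,
        "transport_only": 37_344 / 699_686,
        "transport_and_distance": 170_655 / 699_686,
    },
    "autonomy": {
        "alone": 9_438 / 86_811,
        "with_husband": 56_238 / 86_811,
        "husband_family": 21_135 / 86_811,
    },
    "sex_partners": {
        "one": 85_106 / 87_878,
        "two": 1_786 / 87_878,
        "more_than_two": 986 / 87_878,
    },
    "religion": {
        "hindu": 519_281 / 699_686,
        "muslim": 94_591 / 699_686,
        "christian": 52_113 / 699_686,
        "others": 33_701 / 699_686,
    },
    "wealth": {
        "poorest": 133_249 / 699_686,
        "poorer": 149_466 / 699_686,
        "middle": 147_168 / 699_686,
        "richer": 138_502 / 699_686,
        "richest": 131_301 / 699_686,
    },
}

# Years of schooling: three point masses plus a uniform remainder over 1-17,
# calibrated to median 7, quartiles (0, 10).
SCHOOLING_PMF: dict[int, float] = {k: 0.40 / 17 for k in range(1, 18)}
SCHOOLING_PMF[0] = 0.26
SCHOOLING_PMF[7] += 0.08
SCHOOLING_PMF[8] += 0.10
SCHOOLING_PMF[10] += 0.16

# Calibration targets for the endogenous variables' marginal frequencies.
MEDIATOR_TARGETS: dict[str, dict[str, float]] = {
    "sti_awareness": {"yes": 94_074 / 122_351},
    "contraception": {"condom": 29_517 / 699_686, "others": 231_741 / 699_686},
    "children": {
        "one_two": 251_584 / 699_686,
        "three_four": 165_910 / 699_686,
        "more_than_four": 59_125 / 699_686,
    },
}
SCREENING_PREVALENCE = 0.21

# Fraction of respondents administered the detail module that carries autonomy
# and lifetime-sex-partner questions (82,533 of 699,686 complete outcome rows).
SUBMODULE_OBSERVED = 82_533 / 699_686


@dataclass
class Scenario:
    """Generating truth for one synthetic population.

    ``equation_truths`` maps response -> contrast -> {term: coefficient}
    (including the calibrated ``Intercept``); terms absent from a contrast are
    zero.  ``co_missing_groups`` lists variable groups that are missing
    *jointly* (one Bernoulli per row per group), emulating survey submodules;
    ``missingness`` gives the per-variable (or per-group, read from the first
    member) missing probability.
    """

    n: int
    seed: int = 0
    exogenous_margins: dict[str, dict[str, float]] = field(default_factory=dict)
    schooling_pmf: dict[int, float] = field(default_factory=dict)
    equation_truths: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    co_missing_groups: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        for var, margin in self.exogenous_margins.items():
            total = sum(margin.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{var}: margin sums to {total}, not 1")
        if self.schooling_pmf and abs(sum(self.schooling_pmf.values()) - 1.0) > 1e-9:
            raise ValueError("schooling pmf does not sum to 1")
        for var, p in self.missingness.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{var}: missing probability {p} outside [0, 1)")


def _reported_truths() -> dict[str, dict[str, dict[str, float]]]:
    """Published path coefficients as generating truths (intercepts absent)."""
    system = load_reported_system()
    truths: dict[str, dict[str, dict[str, float]]] = {}
    for response, fit in system.fits.items():
        truths[response] = {c: {} for c in fit.contrasts}
        for (contrast, term), value in fit.coefficients.items():
            truths[response][contrast][term] = value
    return truths


def _coef_vector(truths_eq: dict[str, float], columns: list[str]) -> np.ndarray:
    return np.array([truths_eq.get(col, 0.0) for col in columns])


def _draw_categorical(rng: np.random.Generator, labels: list[str], probs, n: int):
    p = np.asarray(probs, dtype=float)
    codes = rng.choice(len(labels), size=n, p=p / p.sum())
    return np.array(labels, dtype=object)[codes]


def _draw_exogenous(rng, scenario: Scenario, diagram: PathDiagram, n: int) -> pd.DataFrame:
    data: dict[str, np.ndarray] = {}
    for var in diagram.variables:
        if var.name in scenario.exogenous_margins:
            margin = scenario.exogenous_margins[var.name]
            labels = [l for l in var.levels if l in margin]
            data[var.name] = _draw_categorical(rng, labels, [margin[l] for l in labels], n)
    support = sorted(scenario.schooling_pmf)
    pmf = np.array([scenario.schooling_pmf[k] for k in support], dtype=float)
    data["schooling"] = np.asarray(support)[rng.choice(len(support), size=n, p=pmf / pmf.sum())]
    return pd.DataFrame(data)


def _linear_predictors(
    frame: pd.DataFrame, diagram: PathDiagram, response: str,
    truths: dict[str, dict[str, float]],
) -> tuple[list[str], np.ndarray]:
    """Per-contrast linear predictors eta (n x C) for one equation, given a
    frame that already holds the equation's predictors."""
    eq = diagram.equation(response)
    cols = design_columns(diagram, eq)
    tmp = frame.copy()
    resp_var = diagram.variable(response)
    tmp[response] = resp_var.levels[0] if resp_var.is_categorical else 0.0
    design = encode_design(tmp, diagram, eq)
    contrasts = [c for c in truths]
    eta = np.column_stack(
        [design.X @ _coef_vector(truths[c], cols) for c in contrasts]
    )
    return contrasts, eta


def _draw_endogenous(
    rng, frame: pd.DataFrame, diagram: PathDiagram, response: str,
    truths: dict[str, dict[str, float]],
) -> np.ndarray:
    contrasts, eta = _linear_predictors(frame, diagram, response, truths)
    var = diagram.variable(response)
    base = var.reference_level
    # baseline-category probabilities: P(base) = 1/(1+sum e^eta)
    m = np.maximum(eta.max(axis=1), 0.0)
    denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
    probs = np.column_stack(
        [np.exp(-m) / denom] + [np.exp(eta[:, k] - m) / denom for k in range(len(contrasts))]
    )
    labels = [base] + contrasts
    u = rng.random(len(frame))
    cum = probs.cumsum(axis=1)
    codes = (u[:, None] > cum).sum(axis=1)
    return np.array(labels, dtype=object)[codes]


# ---------------------------------------------------------------------------
# intercept calibration (deterministic, user-seed independent)

def _calibrate_intercepts(
    diagram: PathDiagram,
    truths: dict[str, dict[str, dict[str, float]]],
    scenario_proto: Scenario,
) -> dict[str, dict[str, dict[str, float]]]:
    rng = np.random.default_rng(_CALIBRATION_SEED)
    frame = _draw_exogenous(rng, scenario_proto, diagram, _CALIBRATION_N)
    truths = {r: {c: dict(t) for c, t in cs.items()} for r, cs in truths.items()}

    order = [eq.response for eq in diagram.equations if eq.response != diagram.outcome]
    for response in order + [diagram.outcome]:
        var = diagram.variable(response)
        if response == diagram.outcome:
            targets = {var.non_reference_levels[0]: SCREENING_PREVALENCE}
        else:
            targets = MEDIATOR_TARGETS[response]
        eq_truths = truths[response]
        # slope-only linear predictors are fixed: intercepts shift eta additively
        for c in eq_truths:
            eq_truths[c].pop("Intercept", None)
        contrasts, eta0 = _linear_predictors(frame, diagram, response, eq_truths)
        if var.family == "bernoulli":
            (contrast,) = contrasts
            target = targets[contrast]
            lo, hi = -30.0, 30.0
            for _ in range(80):  # bisection on the mean response probability
                mid = 0.5 * (lo + hi)
                if np.mean(1.0 / (1.0 + np.exp(-(eta0[:, 0] + mid)))) < target:
                    lo = mid
                else:
                    hi = mid
            eq_truths[contrast]["Intercept"] = 0.5 * (lo + hi)
        else:
            icept = np.array(
                [np.log(targets[c] / (1 - sum(targets.values()))) for c in contrasts]
            )
            for _ in range(200):  # damped fixed point on the K-1 intercepts
                eta = eta0 + icept
                m = np.maximum(eta.max(axis=1), 0.0)
                denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
                current = (np.exp(eta - m[:, None]) / denom[:, None]).mean(axis=0)
                delta = np.log([targets[c] for c in contrasts]) - np.log(current)
                icept += 0.8 * delta
                if np.max(np.abs(delta)) < 1e-10:
                    break
            for k, c in enumerate(contrasts):
                eq_truths[c]["Intercept"] = float(icept[k])
        # mediators feed the outcome's calibration sample
        if response != diagram.outcome:
            frame[response] = _draw_endogenous(rng, frame, diagram, response, eq_truths)
    return truths


@lru_cache(maxsize=4)
def _default_truths_cached() -> tuple:
    proto = Scenario(
        n=0,
        exogenous_margins=EXOGENOUS_MARGINS,
        schooling_pmf=SCHOOLING_PMF,
    )
    truths = _calibrate_intercepts(model_spec.default_model(), _reported_truths(), proto)
    return tuple(
        (r, tuple((c, tuple(sorted(t.items()))) for c, t in cs.items()))
        for r, cs in truths.items()
    )


def default_scenario(n: int = 100_000, seed: int = 0) -> Scenario:
    """The survey-calibrated scenario: published coefficients as truths,
    published margins, ~21% screening prevalence, and the detail-module
    missingness that leaves ~11.8% of rows complete for the outcome equation."""
    truths = {
        r: {c: dict(t) for c, t in cs}
        for r, cs in _default_truths_cached()
    }
    return Scenario(
        n=n,
        seed=seed,
        exogenous_margins={k: dict(v) for k, v in EXOGENOUS_MARGINS.items()},
        schooling_pmf=dict(SCHOOLING_PMF),
        equation_truths=truths,
        missingness={
            "autonomy": 1.0 - SUBMODULE_OBSERVED,
            "sex_partners": 1.0 - SUBMODULE_OBSERVED,
        },
        co_missing_groups=(("autonomy", "sex_partners"),),
    )


def null_scenario(n: int = 100_000, seed: int = 0) -> Scenario:
    """All slope truths zero (intercepts kept): outcome independent of every
    covariate; useful for false-positive checks."""
    sc = default_scenario(n=n, seed=seed)
    truths = {
        r: {c: {t: (v if t == "Intercept" else 0.0) for t, v in terms.items()}
            for c, terms in cs.items()}
        for r, cs in sc.equation_truths.items()
    }
    return replace(sc, equation_truths=truths)


def generate_population(
    scenario: Scenario, diagram: Optional[PathDiagram] = None
) -> pd.DataFrame:
    """Simulate one population from a scenario (single seeded RNG stream;
    identical scenarios give identical output)."""
    diagram = diagram or model_spec.default_model()
    rng = np.random.default_rng(scenario.seed)
    columns = [v.name for v in diagram.variables]
    if scenario.n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})

    frame = _draw_exogenous(rng, scenario, diagram, scenario.n)
    for eq in diagram.equations:
        if eq.response == diagram.outcome:
            continue
        frame[eq.response] = _draw_endogenous(
            rng, frame, diagram, eq.response, scenario.equation_truths[eq.response]
        )
    frame[diagram.outcome] = _draw_endogenous(
        rng, frame, diagram, diagram.outcome, scenario.equation_truths[diagram.outcome]
    )

    grouped = [v for grp in scenario.co_missing_groups for v in grp]
    for group in scenario.co_missing_groups:
        p = scenario.missingness.get(group[0], 0.0)
        mask = rng.random(scenario.n) < p
        for v in group:
            frame[v] = frame[v].astype(object)
            frame.loc[mask, v] = None
    for v, p in scenario.missingness.items():
        if v in grouped or p <= 0:
            continue
        mask = rng.random(scenario.n) < p
        frame[v] = frame[v].astype(object)
        frame.loc[mask, v] = None
    return frame[columns]


def summarize_margins(
    dataset: pd.DataFrame,
    scenario: Optional[Scenario] = None,
    diagram: Optional[PathDiagram] = None,
) -> pd.DataFrame:
    """Observed per-variable category frequencies, with deltas against the
    scenario's targets when a scenario is given.  Diagnostic, not an assertion."""
    if dataset.empty:
        raise ValueError("empty dataset")
    diagram = diagram or model_spec.default_model()
    rows = []
    for var in diagram.variables:
        if not var.is_categorical:
            continue
        obs = dataset[var.name].dropna()
        freq = obs.value_counts(normalize=True) if len(obs) else pd.Series(dtype=float)
        for level in var.levels:
            observed = float(freq.get(level, 0.0))
            target = np.nan
            if scenario is not None:
                if var.name in scenario.exogenous_margins:
                    target = scenario.exogenous_margins[var.name].get(level, np.nan)
                elif var.name in MEDIATOR_TARGETS:
                    tmap = MEDIATOR_TARGETS[var.name]
                    target = tmap.get(level, 1.0 - sum(tmap.values()))
                elif var.role == "outcome":
                    target = (
                        SCREENING_PREVALENCE
                        if level != var.reference_level
                        else 1.0 - SCREENING_PREVALENCE
                    )
            rows.append(
                {
                    "variable": var.name,
                    "level": level,
                    "observed": observed,
                    "target": target,
                    "delta": observed - target if np.isfinite(target) else np.nan,
                    "n_observed": int(len(obs)),
                }
            )
    return pd.DataFrame(rows)
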