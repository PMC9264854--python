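"""Direct / indirect / total effect decomposition and odds-ratio transforms.

The fitted system is decomposed by the product-of-coefficients rule: the
direct effect of an exposure on the outcome is its outcome-equation
coefficient; the indirect effect through a mediator level is the product
``a * b`` of the exposure -> mediator-level coefficient and the
mediator-level -> outcome coefficient; a total effect is a direct effect plus
a sum of indirect effects.  All effects live on the linear-predictor
(log-odds) scale and exponentiate to (adjusted) odds ratios.

Standard errors are first-order delta-method.  For a single product with the
two factors estimated in different equations, Var(ab) = b^2 Var(a)
+ a^2 Var(b) (the Goodman cross term is omitted, matching the usual
nonlinear-combination practice).  For sums of products the full gradient is
propagated through each equation's coefficient covariance, including
within-equation covariances where available; coefficients from different
equations are treated as uncorrelated — the equations' linear predictors share
no parameters, and the residual correlation induced by fitting on overlapping
records is ignored (stated in the report footer).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .glm_engine import SystemFit, Z95
from .model_spec import MediationPath, PathDiagram, enumerate_mediation_paths, term_name

__all__ = [
    "EffectEstimate",
    "OREstimate",
    "direct_effect",
    "indirect_effect",
    "total_effect",
    "to_odds_ratio",
    "effect_table",
    "odds_ratio_table",
    "load_reported_system",
    "REPORT_FOOTER",
]

REPORT_FOOTER = (
    "Cross-equation coefficient covariance treated as zero; within-equation "
    "covariance used where available. 95% CIs are Wald (z = 1.959964)."
)


def _wald(estimate: float, se: float) -> tuple[tuple[float, float], float]:
    lo, hi = estimate - Z95 * se, estimate + Z95 * se
    if se > 0:
        p = float(2 * stats.norm.sf(abs(estimate) / se))
    else:
        p = 0.0 if estimate != 0 else 1.0
    return (lo, hi), p


@dataclass(frozen=True)
class EffectEstimate:
    """A direct, indirect, or total path effect on the log-odds scale."""

    kind: str                       # direct | indirect | total
    exposure: str
    exposure_level: Optional[str]
    paths: tuple[MediationPath, ...]
    estimate: float
    se: float
    ci95: tuple[float, float]
    p: float

    @property
    def exposure_term(self) -> str:
        return term_name(self.exposure, self.exposure_level)


@dataclass(frozen=True)
class OREstimate:
    """An exponentiated effect: odds ratio with exponentiated CI."""

    odds_ratio: float
    ci95: tuple[float, float]
    p: float


def _exposure_term_name(diagram: PathDiagram, exposure: str, level: Optional[str]) -> str:
    var = diagram.variable(exposure)
    if var.is_categorical:
        if level is None:
            raise ValueError(f"{exposure} is categorical; an exposure level is required")
        return term_name(exposure, level)
    return exposure


def direct_effect(
    system: SystemFit,
    diagram: PathDiagram,
    exposure: str,
    exposure_level: Optional[str] = None,
    response: Optional[str] = None,
    contrast: Optional[str] = None,
) -> EffectEstimate:
    """The fitted coefficient of an exposure term in ``response``'s equation
    (the outcome by default), with Wald SE, CI, and two-sided normal p."""
    response = response or diagram.outcome
    fit = system[response]
    var = diagram.variable(exposure)
    if var.is_categorical and exposure_level == var.reference_level:
        # reference contrast: zero by construction ("Ref" row)
        path = MediationPath(exposure, response, exposure_level)
        return EffectEstimate(
            "direct", exposure, exposure_level, (path,), 0.0, 0.0, (0.0, 0.0), np.nan
        )
    term = _exposure_term_name(diagram, exposure, exposure_level)
    if not fit.has(contrast, term):
        raise KeyError(f"term {term!r} is not in the {response!r} equation")
    est = fit.coef(term, contrast)
    se = fit.se(term, contrast)
    ci, p = _wald(est, se)
    path = MediationPath(exposure, response, exposure_level)
    return EffectEstimate("direct", exposure, exposure_level, (path,), est, se, ci, p)


def _path_coefs(system: SystemFit, diagram: PathDiagram, path: MediationPath):
    """(a, var_a, b, var_b) for a two-edge chain."""
    term = _exposure_term_name(diagram, path.exposure, path.exposure_level)
    med_fit = system[path.mediator]
    out_fit = system[diagram.outcome]
    med_contrast = path.mediator_level
    if not med_fit.has(med_contrast, term):
        raise KeyError(f"term {term!r} is not in the {path.mediator!r} equation")
    b_term = term_name(path.mediator, path.mediator_level)
    if not out_fit.has(None, b_term):
        raise KeyError(f"term {b_term!r} is not in the outcome equation")
    a = med_fit.coef(term, med_contrast)
    va = med_fit.se(term, med_contrast) ** 2
    b = out_fit.coef(b_term)
    vb = out_fit.se(b_term) ** 2
    return a, va, b, vb


def indirect_effect(
    system: SystemFit, diagram: PathDiagram, path: MediationPath
) -> EffectEstimate:
    """Product-of-coefficients indirect effect along one two-edge chain, with
    the first-order delta-method SE sqrt(b^2 Var a + a^2 Var b)."""
    if path.is_direct:
        raise ValueError("path has no mediator; use direct_effect")
    a, va, b, vb = _path_coefs(system, diagram, path)
    est = a * b
    se = float(np.sqrt(b * b * va + a * a * vb))
    ci, p = _wald(est, se)
    return EffectEstimate(
        "indirect", path.exposure, path.exposure_level, (path,), est, se, ci, p
    )


def total_effect(
    system: SystemFit,
    diagram: PathDiagram,
    exposure: str,
    exposure_level: Optional[str],
    included_paths: Iterable[MediationPath],
) -> EffectEstimate:
    """Direct effect plus the sum of the included indirect effects.

    The delta-method variance uses the gradient of direct + sum(a_i b_i):
    within each equation the coefficient block's covariance is applied to its
    part of the gradient (so two included paths sharing a mediator equation,
    and the direct coefficient sharing the outcome equation with the b_i,
    covary as estimated); coefficients in different equations are independent.
    """
    included = list(included_paths)
    labels = [p.label() for p in included]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicated path in included_paths")
    for p in included:
        if p.is_direct:
            raise ValueError("included_paths must be indirect (mediated) paths")
        if p.exposure != exposure or p.exposure_level != exposure_level:
            raise ValueError(f"path {p.label()} does not share the exposure term")

    term = _exposure_term_name(diagram, exposure, exposure_level)
    out_fit = system[diagram.outcome]
    if not out_fit.has(None, term):
        raise KeyError(f"term {term!r} is not in the outcome equation")
    d = out_fit.coef(term)
    estimate = d
    # gradient entries per equation: {equation: {(contrast, term): dT/dtheta}}
    grads: dict[str, dict[tuple[str, str], float]] = {
        diagram.outcome: {(out_fit.contrasts[0], term): 1.0}
    }
    for p in included:
        a, _, b, _ = _path_coefs(system, diagram, p)
        estimate += a * b
        med_key = (p.mediator_level, term)
        gmed = grads.setdefault(p.mediator, {})
        gmed[med_key] = gmed.get(med_key, 0.0) + b
        out_key = (out_fit.contrasts[0], term_name(p.mediator, p.mediator_level))
        gout = grads[diagram.outcome]
        gout[out_key] = gout.get(out_key, 0.0) + a

    var = 0.0
    for eqname, g in grads.items():
        fit = system[eqname]
        keys = list(g)
        vec = np.array([g[k] for k in keys])
        idx = [fit._index(c, t) for c, t in keys]
        cov = fit.covariance[np.ix_(idx, idx)]
        var += float(vec @ cov @ vec)
    se = float(np.sqrt(var))
    ci, p = _wald(estimate, se)
    all_paths = (MediationPath(exposure, diagram.outcome, exposure_level), *included)
    return EffectEstimate("total", exposure, exposure_level, all_paths, estimate, se, ci, p)


def to_odds_ratio(effect: EffectEstimate) -> OREstimate:
    """Exponentiate a log-odds effect and its CI endpoints; p carries over."""
    lo, hi = effect.ci95
    return OREstimate(float(np.exp(effect.estimate)), (float(np.exp(lo)), float(np.exp(hi))), effect.p)


# ---------------------------------------------------------------------------
# report assembly


def _effect_row(block: str, row_label: str, eff: EffectEstimate, extra: dict) -> dict:
    return {
        "block": block,
        "row": row_label,
        "kind": eff.kind,
        "exposure": eff.exposure,
        "exposure_level": eff.exposure_level if eff.exposure_level is not None else "",
        "estimate": eff.estimate,
        "se": eff.se,
        "ci_low": eff.ci95[0],
        "ci_high": eff.ci95[1],
        "p": eff.p,
        **extra,
    }


def _exposure_terms(diagram: PathDiagram, name: str):
    var = diagram.variable(name)
    if var.is_categorical:
        return [(name, lvl) for lvl in var.non_reference_levels]
    return [(name, None)]


def effect_table(
    system: SystemFit, diagram: PathDiagram, convention: str = "per_row"
) -> pd.DataFrame:
    """The full decomposition report: one block per equation contrast.

    The outcome block lists every direct effect on the outcome.  Each mediator
    block (one per non-baseline mediator level) lists, for every exposure in
    that mediator's equation, the exposure -> mediator direct effect, the
    indirect effect on the outcome through that mediator level, and total
    effects.

    ``convention`` controls totals:

    * ``"per_row"`` — totals appear in the blocks of the exposure's first
      mediator (equation-declaration order): one total per combination with
      each level of the exposure's *other* mediators (direct + this block's
      indirect + the other mediator-level indirect), or a single
      direct + indirect total if the exposure feeds no other mediator.
    * ``"grand_total"`` — a single total per exposure term, direct + all of
      its enumerated indirect paths, reported in its first mediator's first
      block.
    """
    if convention not in ("per_row", "grand_total"):
        raise ValueError(f"unknown total-effect convention {convention!r}")
    rows: list[dict] = []

    out_eq = diagram.outcome_equation
    for name in out_eq.predictors:
        for exp, lvl in _exposure_terms(diagram, name):
            eff = direct_effect(system, diagram, exp, lvl)
            rows.append(_effect_row(diagram.outcome, term_name(exp, lvl), eff, {"via": ""}))

    for med_eq in diagram.equations:
        if med_eq.response == diagram.outcome:
            continue
        med_var = diagram.variable(med_eq.response)
        for med_level in med_var.non_reference_levels:
            block = f"{med_eq.response}[{med_level}]"
            for name in med_eq.predictors:
                first_mediator = diagram.mediator_equations_with(name)[0].response
                for exp, lvl in _exposure_terms(diagram, name):
                    d_med = direct_effect(
                        system, diagram, exp, lvl,
                        response=med_eq.response, contrast=med_level,
                    )
                    rows.append(_effect_row(block, term_name(exp, lvl), d_med, {"via": ""}))
                    path = MediationPath(exp, diagram.outcome, lvl, med_eq.response, med_level)
                    ind = indirect_effect(system, diagram, path)
                    rows.append(_effect_row(block, term_name(exp, lvl), ind, {"via": block}))
                    if name in out_eq.predictors and first_mediator == med_eq.response:
                        rows.extend(
                            _total_rows(system, diagram, exp, lvl, path, block, convention)
                        )
    df = pd.DataFrame(rows)
    df.attrs["footer"] = REPORT_FOOTER
    df.attrs["convention"] = convention
    return df


def _total_rows(system, diagram, exp, lvl, this_path, block, convention):
    rows = []
    if convention == "grand_total":
        if this_path.mediator_level != diagram.variable(this_path.mediator).non_reference_levels[0]:
            return rows  # emit once, in the first block of the first mediator
        all_paths = [
            p for p in enumerate_mediation_paths(diagram, exp, lvl) if not p.is_direct
        ]
        tot = total_effect(system, diagram, exp, lvl, all_paths)
        rows.append(
            _effect_row(block, term_name(exp, lvl), tot, {"via": "all mediated paths"})
        )
        return rows
    other_eqs = [
        eq for eq in diagram.mediator_equations_with(exp)
        if eq.response != this_path.mediator
    ]
    if not other_eqs:
        tot = total_effect(system, diagram, exp, lvl, [this_path])
        rows.append(_effect_row(block, term_name(exp, lvl), tot, {"via": block}))
        return rows
    for eq in other_eqs:
        for other_level in diagram.variable(eq.response).non_reference_levels:
            other = MediationPath(exp, diagram.outcome, lvl, eq.response, other_level)
            tot = total_effect(system, diagram, exp, lvl, [this_path, other])
            rows.append(
                _effect_row(
                    block, term_name(exp, lvl), tot,
                    {"via": f"{block} + {eq.response}[{other_level}]"},
                )
            )
    return rows


def odds_ratio_table(system: SystemFit, diagram: PathDiagram) -> pd.DataFrame:
    """Adjusted odds ratios for every term of the outcome equation."""
    rows = []
    for name in diagram.outcome_equation.predictors:
        var = diagram.variable(name)
        terms = _exposure_terms(diagram, name)
        if var.is_categorical:
            rows.append(
                {"term": term_name(name, var.reference_level), "odds_ratio": 1.0,
                 "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "reference": True}
            )
        for exp, lvl in terms:
            orr = to_odds_ratio(direct_effect(system, diagram, exp, lvl))
            rows.append(
                {"term": term_name(exp, lvl), "odds_ratio": orr.odds_ratio,
                 "ci_low": orr.ci95[0], "ci_high": orr.ci95[1], "p": orr.p,
                 "reference": False}
            )
    return pd.DataFrame(rows)


def load_reported_system() -> SystemFit:
    """The published NFHS-4 screening path coefficients shipped with the
    package, assembled into a SystemFit for decomposition without refitting
    (SEs back-derived from the printed 95% CIs; covariances diagonal)."""
    ref = resources.files("gsempath").joinpath("data/nfhs4_reported_coefficients.csv")
    with ref.open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh)
    return SystemFit.from_coefficient_table(table)
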