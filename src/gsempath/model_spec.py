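"""Variable declarations, design coding, and the recursive path diagram.

A generalized structural equation model over categorical survey data is a
*recursive* (acyclic) system of regression equations: every endogenous
variable — the outcome and each mediator — has exactly one equation, and the
directed graph with an edge predictor -> response for every equation term
admits a topological order.  Because the system is recursive and every
variable is observed, the joint likelihood factorizes into the per-equation
likelihoods, which is what lets the system be fit equation by equation
(see :mod:`gsempath.glm_engine`).

This module owns the declarative layer: :class:`VariableSpec` (role, family,
category levels, reference level), :class:`EquationSpec`, diagram validation,
mediation-path enumeration, and dummy coding of a record table into a design
matrix with complete-case bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "EquationSpec",
    "PathDiagram",
    "MediationPath",
    "DiagramError",
    "CodingError",
    "build_path_diagram",
    "enumerate_mediation_paths",
    "encode_design",
    "load_model_config",
    "default_model",
]

ROLES = ("outcome", "mediator", "covariate")
FAMILIES = ("bernoulli", "multinomial", "continuous")

MISSING_MARKERS = ("", "NA")


class DiagramError(ValueError):
    """Raised when a variable or equation system is not a valid recursive model."""


class CodingError(ValueError):
    """Raised when a data value cannot be mapped onto the declared coding."""


@dataclass(frozen=True)
class VariableSpec:
    """A survey variable: its role in the system, family, and category coding.

    ``levels`` is the ordered list of category labels (empty for continuous
    variables); ``reference_level`` is the omitted category in dummy coding and
    the baseline of the multinomial contrasts when the variable is endogenous.
    """

    name: str
    role: str
    family: str
    levels: tuple[str, ...] = ()
    reference_level: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DiagramError(f"{self.name}: unknown role {self.role!r}")
        if self.family not in FAMILIES:
            raise DiagramError(f"{self.name}: unknown family {self.family!r}")
        object.__setattr__(self, "levels", tuple(str(l).strip() for l in self.levels))
        if self.family == "continuous":
            if self.levels or self.reference_level is not None:
                raise DiagramError(f"{self.name}: continuous variables take no levels")
            return
        if self.family == "bernoulli" and len(self.levels) != 2:
            raise DiagramError(f"{self.name}: bernoulli requires exactly 2 levels")
        if self.family == "multinomial" and len(self.levels) < 3:
            raise DiagramError(f"{self.name}: multinomial requires >= 3 levels")
        if len(set(self.levels)) != len(self.levels):
            raise DiagramError(f"{self.name}: duplicate levels")
        if self.reference_level is None:
            raise DiagramError(f"{self.name}: categorical variable needs a reference level")
        object.__setattr__(self, "reference_level", str(self.reference_level).strip())
        if self.reference_level not in self.levels:
            raise DiagramError(
                f"{self.name}: reference level {self.reference_level!r} not among levels"
            )

    @property
    def is_categorical(self) -> bool:
        return self.family != "continuous"

    @property
    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference_level)


@dataclass(frozen=True)
class EquationSpec:
    """One regression equation: an endogenous response and its predictors."""

    response: str
    predictors: tuple[str, ...]
    family: str
    baseline_category: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.family not in ("bernoulli", "multinomial"):
            raise DiagramError(
                f"equation for {self.response}: family must be bernoulli or multinomial"
            )
        if self.response in self.predictors:
            raise DiagramError(f"equation for {self.response}: response predicts itself")


@dataclass(frozen=True)
class MediationPath:
    """A direct path, or a two-edge exposure -> mediator-level -> outcome chain.

    ``exposure_level`` is None for a continuous exposure (and for path
    *templates* enumerated per exposure variable); ``mediator`` /
    ``mediator_level`` are None on the direct path.
    """

    exposure: str
    outcome: str
    exposure_level: Optional[str] = None
    mediator: Optional[str] = None
    mediator_level: Optional[str] = None

    @property
    def is_direct(self) -> bool:
        return self.mediator is None

    def with_exposure_level(self, level: Optional[str]) -> "MediationPath":
        return MediationPath(self.exposure, self.outcome, level, self.mediator, self.mediator_level)

    def label(self) -> str:
        head = self.exposure if self.exposure_level is None else f"{self.exposure}[{self.exposure_level}]"
        if self.is_direct:
            return f"{head} -> {self.outcome}"
        return f"{head} -> {self.mediator}[{self.mediator_level}] -> {self.outcome}"


@dataclass
class PathDiagram:
    """A validated recursive equation system."""

    variables: list[VariableSpec]
    equations: list[EquationSpec]
    outcome: str
    _by_name: dict[str, VariableSpec] = field(default_factory=dict, repr=False)
    _eq_by_response: dict[str, EquationSpec] = field(default_factory=dict, repr=False)

    def variable(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def equation(self, response: str) -> EquationSpec:
        return self._eq_by_response[response]

    @property
    def mediators(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "mediator"]

    @property
    def outcome_equation(self) -> EquationSpec:
        return self._eq_by_response[self.outcome]

    def mediator_equations_with(self, exposure: str) -> list[EquationSpec]:
        """Mediator equations that contain ``exposure`` as a predictor, in declaration order."""
        return [
            eq
            for eq in self.equations
            if eq.response != self.outcome and exposure in eq.predictors
        ]


def _toposort(equations: Sequence[EquationSpec]) -> list[str]:
    """Topological order of endogenous responses; raises naming a cycle."""
    endo = {eq.response for eq in equations}
    deps = {eq.response: [p for p in eq.predictors if p in endo] for eq in equations}
    order: list[str] = []
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = stack[stack.index(node):] + [node]
            raise DiagramError(f"not recursive: cycle {' -> '.join(cycle)}")
        state[node] = 0
        for dep in deps[node]:
            visit(dep, stack + [node])
        state[node] = 1
        order.append(node)

    for eq in equations:
        visit(eq.response, [])
    return order


def build_path_diagram(
    variables: Iterable[VariableSpec], equations: Iterable[EquationSpec]
) -> PathDiagram:
    """Validate a variable/equation system and return the recursive diagram.

    Checks: unique names, one equation per endogenous variable, references
    resolve, family/baseline consistency, acyclicity, every mediator predicts
    the outcome, and no mediator-of-mediator chains (only two-edge mediation
    chains are supported; deeper chains raise ``unsupported chain depth``).
    """
    variables = list(variables)
    equations = list(equations)
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DiagramError(f"duplicate variable declarations: {dupes}")
    by_name = {v.name: v for v in variables}

    responses = [eq.response for eq in equations]
    if len(set(responses)) != len(responses):
        dupes = sorted({r for r in responses if responses.count(r) > 1})
        raise DiagramError(f"duplicate equation for response(s): {dupes}")

    for eq in equations:
        for name in (eq.response, *eq.predictors):
            if name not in by_name:
                raise DiagramError(f"equation for {eq.response}: undeclared variable {name!r}")
        resp = by_name[eq.response]
        if resp.family == "continuous":
            raise DiagramError(f"{eq.response}: continuous responses are not supported")
        if resp.family != eq.family:
            raise DiagramError(
                f"{eq.response}: equation family {eq.family} != variable family {resp.family}"
            )
        baseline = eq.baseline_category
        if baseline is not None and baseline.strip() != resp.reference_level:
            raise DiagramError(
                f"{eq.response}: baseline {baseline!r} != declared reference "
                f"{resp.reference_level!r}"
            )

    outcomes = [v.name for v in variables if v.role == "outcome"]
    if len(outcomes) != 1:
        raise DiagramError(f"exactly one outcome variable required, got {outcomes}")
    outcome = outcomes[0]
    if outcome not in responses:
        raise DiagramError(f"outcome {outcome} has no equation")

    outcome_eq = next(eq for eq in equations if eq.response == outcome)
    for v in variables:
        if v.role == "mediator":
            if v.name not in responses:
                raise DiagramError(f"mediator {v.name} has no equation")
            if v.name not in outcome_eq.predictors:
                raise DiagramError(f"mediator {v.name} does not predict the outcome")
        if v.role == "covariate" and v.name in responses:
            raise DiagramError(f"covariate {v.name} must not have an equation")

    _toposort(equations)  # raises on cycles

    # only exposure -> mediator -> outcome chains: a mediator equation may not
    # contain another endogenous variable as predictor
    endo = set(responses)
    for eq in equations:
        if eq.response == outcome:
            continue
        chained = [p for p in eq.predictors if p in endo]
        if chained:
            raise DiagramError(
                f"unsupported chain depth: mediator {eq.response} is predicted by "
                f"endogenous {chained} (only two-edge mediation chains are supported)"
            )

    return PathDiagram(
        variables=variables,
        equations=equations,
        outcome=outcome,
        _by_name=by_name,
        _eq_by_response={eq.response: eq for eq in equations},
    )


def enumerate_mediation_paths(
    diagram: PathDiagram, exposure: str, exposure_level: Optional[str] = None
) -> list[MediationPath]:
    """All paths from an exposure to the outcome: direct first, then one
    indirect path per (mediator equation containing the exposure) x
    (non-baseline level of that mediator), mediators in equation-declaration
    order and levels in declared order.

    ``exposure_level`` (a non-reference level of a categorical exposure) is
    stamped onto the returned paths when given; otherwise paths are per-variable
    templates with ``exposure_level=None``.
    """
    if exposure not in diagram._by_name:
        raise DiagramError(f"{exposure!r} is not declared in the model")
    var = diagram.variable(exposure)
    if exposure_level is not None:
        if exposure_level not in var.non_reference_levels:
            raise DiagramError(
                f"{exposure_level!r} is not a non-reference level of {exposure}"
            )
    mediator_eqs = diagram.mediator_equations_with(exposure)
    in_outcome = exposure in diagram.outcome_equation.predictors
    if not in_outcome and not mediator_eqs:
        raise DiagramError(f"{exposure!r} appears in no equation of the model")

    paths: list[MediationPath] = []
    if in_outcome:
        paths.append(MediationPath(exposure, diagram.outcome, exposure_level))
    for eq in mediator_eqs:
        med = diagram.variable(eq.response)
        for level in med.non_reference_levels:
            paths.append(
                MediationPath(exposure, diagram.outcome, exposure_level, eq.response, level)
            )
    return paths


def term_name(variable: str, level: Optional[str] = None) -> str:
    """Canonical design-column / coefficient name for a model term."""
    return variable if level is None else f"{variable}[{level}]"


def design_columns(diagram: PathDiagram, equation: EquationSpec) -> list[str]:
    """Deterministic design-matrix column names for an equation."""
    cols = ["Intercept"]
    for name in equation.predictors:
        var = diagram.variable(name)
        if var.is_categorical:
            cols.extend(term_name(name, lvl) for lvl in var.non_reference_levels)
        else:
            cols.append(name)
    return cols


def _normalize_categorical(series: pd.Series, var: VariableSpec) -> pd.Series:
    isna = pd.isna(series)
    s = series.astype("object").astype(str).str.strip()
    s = s.where(~s.isin(MISSING_MARKERS) & ~isna, other=None)
    present = s.dropna()
    bad = present[~present.isin(var.levels)]
    if len(bad):
        raise CodingError(
            f"{var.name}: unknown category {bad.iloc[0]!r} at row {bad.index[0]}"
        )
    return s


@dataclass
class DesignMatrix:
    """Dummy-coded design for one equation, restricted to complete cases."""

    X: np.ndarray
    columns: list[str]
    response: np.ndarray          # integer level codes into response_levels
    response_levels: tuple[str, ...]
    baseline_index: int
    rows_dropped: int
    index: np.ndarray             # original row labels of the kept rows
    weights: np.ndarray           # frequency weights (all ones unless supplied)


def encode_design(
    records: pd.DataFrame,
    diagram: PathDiagram,
    equation: EquationSpec,
    weight_column: Optional[str] = None,
) -> DesignMatrix:
    """Dummy-code an equation's variables: one intercept, one indicator per
    non-reference level of each categorical predictor, continuous predictors
    passed through.  Rows with any missing value among the equation's variables
    (listwise within the equation) are dropped and counted.
    """
    needed = [equation.response, *equation.predictors]
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise CodingError(f"records lack column(s) {missing_cols}")

    cleaned: dict[str, pd.Series] = {}
    for name in needed:
        var = diagram.variable(name)
        col = records[name]
        if var.is_categorical:
            cleaned[name] = _normalize_categorical(col, var)
        else:
            num = pd.to_numeric(col.replace(list(MISSING_MARKERS), np.nan), errors="coerce")
            cleaned[name] = num

    frame = pd.DataFrame(cleaned)
    keep = frame.notna().all(axis=1)
    rows_dropped = int((~keep).sum())
    frame = frame.loc[keep]

    cols = design_columns(diagram, equation)
    n = len(frame)
    X = np.empty((n, len(cols)), dtype=float)
    X[:, 0] = 1.0
    j = 1
    for name in equation.predictors:
        var = diagram.variable(name)
        if var.is_categorical:
            vals = frame[name].to_numpy()
            for lvl in var.non_reference_levels:
                X[:, j] = vals == lvl
                j += 1
        else:
            X[:, j] = frame[name].to_numpy(dtype=float)
            j += 1

    resp_var = diagram.variable(equation.response)
    levels = resp_var.levels
    code = {lvl: k for k, lvl in enumerate(levels)}
    y = np.array([code[v] for v in frame[equation.response]], dtype=np.int64)

    if weight_column is not None and weight_column in records.columns:
        w = pd.to_numeric(records.loc[frame.index, weight_column]).to_numpy(dtype=float)
    else:
        w = np.ones(n)

    return DesignMatrix(
        X=X,
        columns=cols,
        response=y,
        response_levels=levels,
        baseline_index=code[resp_var.reference_level],
        rows_dropped=rows_dropped,
        index=frame.index.to_numpy(),
        weights=w,
    )


# ---------------------------------------------------------------------------
# configuration I/O

def load_model_config(source) -> PathDiagram:
    """Build a diagram from a YAML/JSON mapping with ``variables`` and
    ``equations`` blocks (path, file object, or already-parsed mapping)."""
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    variables = [
        VariableSpec(
            name=v["name"],
            role=v["role"],
            family=v["family"],
            levels=tuple(v.get("levels", ()) or ()),
            reference_level=v.get("reference"),
        )
        for v in cfg["variables"]
    ]
    equations = [
        EquationSpec(
            response=e["response"],
            predictors=tuple(e["predictors"]),
            family=e["family"],
            baseline_category=e.get("baseline"),
        )
        for e in cfg["equations"]
    ]
    return build_path_diagram(variables, equations)


def default_model() -> PathDiagram:
    """The cervical-cancer-screening model shipped with the package: a binary
    screening outcome, multinomial contraception and parity mediators, a binary
    STI-awareness mediator, and the NFHS demographic covariates."""
    ref = resources.files("gsempath").joinpath("data/nfhs4_model.yaml")
    return load_model_config(yaml.safe_load(ref.read_text(encoding="utf-8")))
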