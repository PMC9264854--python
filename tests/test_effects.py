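"""Product-of-coefficients decomposition, delta-method intervals, odds
ratios, and reconstruction of the published NFHS-4 decomposition table."""

import numpy as np
import pandas as pd
import pytest

from gsempath.effects import (
    direct_effect,
    effect_table,
    indirect_effect,
    odds_ratio_table,
    to_odds_ratio,
    total_effect,
)
from gsempath.glm_engine import SystemFit
from gsempath.model_spec import MediationPath, enumerate_mediation_paths


def _path(exposure, level, mediator, mlevel):
    return MediationPath(exposure, "screening", level, mediator, mlevel)


# ---------------------------------------------------------------------------
# golden values from the published coefficient set


def test_worked_indirect_effect_and_interval(reported_system, diagram):
    # poorer -> children(one or two) -> screening: 0.104 x 0.221 = 0.023,
    # delta-method CI (0.015, 0.030) with SEs back-derived from printed CIs
    eff = indirect_effect(
        reported_system, diagram, _path("wealth", "poorer", "children", "one_two")
    )
    assert round(eff.estimate, 3) == 0.023
    assert eff.ci95[0] == pytest.approx(0.015, abs=0.001)
    assert eff.ci95[1] == pytest.approx(0.030, abs=0.001)
    assert eff.p < 0.001


def test_direct_effects_reproduce_published_rows(reported_system, diagram):
    age = direct_effect(reported_system, diagram, "age", "35-49")
    assert age.estimate == pytest.approx(0.148, abs=1e-12)
    assert age.ci95[0] == pytest.approx(0.112, abs=0.001)
    assert age.ci95[1] == pytest.approx(0.183, abs=0.001)

    rich = direct_effect(
        reported_system, diagram, "wealth", "richest",
        response="children", contrast="one_two",
    )
    assert rich.estimate == pytest.approx(0.383, abs=1e-12)


def test_reference_level_direct_effect_is_zero(reported_system, diagram):
    ref = direct_effect(reported_system, diagram, "wealth", "poorest")
    assert ref.estimate == 0.0 and ref.se == 0.0


def test_null_first_leg_gives_zero_product_and_b_scaled_se(diagram):
    table = pd.DataFrame(
        [
            {"equation": "screening", "contrast": "screened",
             "term": "children[one_two]", "estimate": 0.5, "se": 0.05},
            {"equation": "children", "contrast": "one_two",
             "term": "wealth[poorer]", "estimate": 0.0, "se": 0.02},
        ]
    )
    system = SystemFit.from_coefficient_table(table)
    eff = indirect_effect(system, diagram, _path("wealth", "poorer", "children", "one_two"))
    assert eff.estimate == 0.0
    assert eff.se == pytest.approx(0.5 * 0.02)


@pytest.mark.parametrize(
    "level, expected",
    [("poorer", 0.332), ("middle", 0.570), ("richer", 0.765), ("richest", 1.001)],
)
def test_wealth_per_row_totals_via_children_one_two(reported_system, diagram, level, expected):
    eff = total_effect(
        reported_system, diagram, "wealth", level,
        [_path("wealth", level, "children", "one_two")],
    )
    assert eff.estimate == pytest.approx(expected, abs=0.002)


def test_muslim_total_via_condom_and_children_three_four(reported_system, diagram):
    # 0.161 + 0.009 - 0.021 = 0.149
    eff = total_effect(
        reported_system, diagram, "religion", "muslim",
        [
            _path("religion", "muslim", "contraception", "condom"),
            _path("religion", "muslim", "children", "three_four"),
        ],
    )
    assert eff.estimate == pytest.approx(0.149, abs=0.002)


def test_schooling_total_via_sti_and_condom(reported_system, diagram):
    # -0.014 + 0.197 x 0.327 + 0.065 x 0.046 = 0.053
    eff = total_effect(
        reported_system, diagram, "schooling", None,
        [
            _path("schooling", None, "sti_awareness", "yes"),
            _path("schooling", None, "contraception", "condom"),
        ],
    )
    assert eff.estimate == pytest.approx(0.053, abs=0.002)


def test_total_with_no_paths_equals_direct(reported_system, diagram):
    tot = total_effect(reported_system, diagram, "age", "35-49", [])
    d = direct_effect(reported_system, diagram, "age", "35-49")
    assert tot.estimate == d.estimate
    assert tot.se == pytest.approx(d.se)


def test_total_effect_input_validation(reported_system, diagram):
    p = _path("wealth", "poorer", "children", "one_two")
    with pytest.raises(ValueError, match="duplicated"):
        total_effect(reported_system, diagram, "wealth", "poorer", [p, p])
    with pytest.raises(ValueError, match="share"):
        total_effect(
            reported_system, diagram, "wealth", "poorer",
            [_path("wealth", "middle", "children", "one_two")],
        )


@pytest.mark.parametrize(
    "estimate, expected_or",
    [
        (0.148, 1.16), (0.916, 2.50), (0.327, 1.39), (-0.209, 0.81),
        (0.169, 1.18), (0.125, 1.13), (0.187, 1.21), (0.0, 1.00),
    ],
)
def test_odds_ratio_transform(estimate, expected_or, reported_system, diagram):
    eff = direct_effect(reported_system, diagram, "age", "35-49")
    eff = type(eff)(
        eff.kind, eff.exposure, eff.exposure_level, eff.paths,
        estimate, eff.se, (estimate - 0.1, estimate + 0.1), eff.p,
    )
    orr = to_odds_ratio(eff)
    assert round(orr.odds_ratio, 2) == expected_or
    assert orr.ci95[0] == pytest.approx(np.exp(estimate - 0.1))
    assert np.log(orr.odds_ratio) == pytest.approx(estimate)  # round trip


# ---------------------------------------------------------------------------
# full-table reconstruction against the printed decomposition (+-0.002),
# excluding the two internally inconsistent published cells:
# schooling->contraception[others] indirect and the dependent "via STI" total.

PUBLISHED_INDIRECT = {
    ("contraception[condom]", "religion[muslim]"): 0.009,
    ("contraception[condom]", "religion[christian]"): -0.080,
    ("contraception[condom]", "religion[others]"): 0.023,
    ("contraception[condom]", "schooling"): 0.003,
    ("contraception[others]", "religion[muslim]"): -0.108,
    ("contraception[others]", "religion[christian]"): -0.131,
    ("contraception[others]", "religion[others]"): 0.005,
    ("children[one_two]", "wealth[poorer]"): 0.023,
    ("children[one_two]", "wealth[middle]"): 0.042,
    ("children[one_two]", "wealth[richer]"): 0.068,
    ("children[one_two]", "wealth[richest]"): 0.085,
    ("children[one_two]", "religion[muslim]"): -0.115,
    ("children[one_two]", "religion[christian]"): -0.088,
    ("children[one_two]", "religion[others]"): -0.007,
    ("children[three_four]", "wealth[poorer]"): -0.017,
    ("children[three_four]", "wealth[middle]"): -0.036,
    ("children[three_four]", "wealth[richer]"): -0.055,
    ("children[three_four]", "wealth[richest]"): -0.087,
    ("children[three_four]", "religion[muslim]"): -0.021,
    ("children[three_four]", "religion[christian]"): -0.024,
    ("children[three_four]", "religion[others]"): -0.010,
    ("children[more_than_four]", "wealth[poorer]"): -0.005,
    ("children[more_than_four]", "wealth[middle]"): -0.009,
    ("children[more_than_four]", "wealth[richer]"): -0.014,
    ("children[more_than_four]", "wealth[richest]"): -0.019,
    ("children[more_than_four]", "religion[muslim]"): 0.005,
    ("children[more_than_four]", "religion[christian]"): 0.002,
    ("children[more_than_four]", "religion[others]"): -0.003,
    ("sti_awareness[yes]", "schooling"): 0.064,
}

PUBLISHED_TOTALS = {
    ("children[one_two]", "wealth[poorer]", "children[one_two]"): 0.332,
    ("children[one_two]", "wealth[middle]", "children[one_two]"): 0.570,
    ("children[one_two]", "wealth[richer]", "children[one_two]"): 0.765,
    ("children[one_two]", "wealth[richest]", "children[one_two]"): 1.001,
    ("children[three_four]", "wealth[poorer]", "children[three_four]"): 0.292,
    ("children[three_four]", "wealth[middle]", "children[three_four]"): 0.492,
    ("children[three_four]", "wealth[richer]", "children[three_four]"): 0.643,
    ("children[three_four]", "wealth[richest]", "children[three_four]"): 0.829,
    ("children[more_than_four]", "wealth[poorer]", "children[more_than_four]"): 0.304,
    ("children[more_than_four]", "wealth[middle]", "children[more_than_four]"): 0.519,
    ("children[more_than_four]", "wealth[richer]", "children[more_than_four]"): 0.684,
    ("children[more_than_four]", "wealth[richest]", "children[more_than_four]"): 0.896,
    ("contraception[condom]", "religion[muslim]", "children[one_two]"): 0.056,
    ("contraception[condom]", "religion[muslim]", "children[three_four]"): 0.149,
    ("contraception[condom]", "religion[muslim]", "children[more_than_four]"): 0.175,
    ("contraception[condom]", "religion[christian]", "children[one_two]"): -0.153,
    ("contraception[condom]", "religion[christian]", "children[three_four]"): -0.089,
    ("contraception[condom]", "religion[christian]", "children[more_than_four]"): -0.062,
    ("contraception[condom]", "religion[others]", "children[one_two]"): 0.240,
    ("contraception[condom]", "religion[others]", "children[three_four]"): 0.237,
    ("contraception[condom]", "religion[others]", "children[more_than_four]"): 0.245,
    ("contraception[condom]", "schooling", "sti_awareness[yes]"): 0.053,
    ("contraception[others]", "religion[muslim]", "children[one_two]"): -0.061,
    ("contraception[others]", "religion[muslim]", "children[three_four]"): 0.033,
    ("contraception[others]", "religion[muslim]", "children[more_than_four]"): 0.058,
    ("contraception[others]", "religion[christian]", "children[one_two]"): -0.204,
    ("contraception[others]", "religion[christian]", "children[three_four]"): -0.140,
    ("contraception[others]", "religion[christian]", "children[more_than_four]"): -0.113,
    ("contraception[others]", "religion[others]", "children[one_two]"): 0.222,
    ("contraception[others]", "religion[others]", "children[three_four]"): 0.219,
    ("contraception[others]", "religion[others]", "children[more_than_four]"): 0.226,
}


@pytest.fixture(scope="module")
def reported_table(reported_system, diagram):
    return effect_table(reported_system, diagram, convention="per_row")


def test_reconstructs_every_published_indirect_effect(reported_table):
    rows = reported_table[reported_table["kind"] == "indirect"]
    lookup = {(r.block, r.row): r.estimate for r in rows.itertuples()}
    for key, printed in PUBLISHED_INDIRECT.items():
        assert lookup[key] == pytest.approx(printed, abs=0.002), key


def test_reconstructs_every_published_total_effect(reported_table):
    rows = reported_table[reported_table["kind"] == "total"]
    lookup = {}
    for r in rows.itertuples():
        other = r.via.split(" + ")[1] if " + " in r.via else r.via
        lookup[(r.block, r.row, other)] = r.estimate
    for key, printed in PUBLISHED_TOTALS.items():
        assert lookup[key] == pytest.approx(printed, abs=0.002), key


def test_table_structure_and_wealth_rows(reported_table, diagram):
    blocks = set(reported_table["block"])
    assert blocks == {
        "screening",
        "contraception[condom]", "contraception[others]",
        "children[one_two]", "children[three_four]", "children[more_than_four]",
        "sti_awareness[yes]",
    }
    poorer = reported_table[
        (reported_table["exposure"] == "wealth")
        & (reported_table["exposure_level"] == "poorer")
    ]
    assert (poorer["kind"] == "indirect").sum() == 3
    assert (poorer["kind"] == "total").sum() == 3


def test_no_mediator_diagram_yields_direct_only():
    from gsempath.model_spec import EquationSpec, VariableSpec, build_path_diagram

    d = build_path_diagram(
        [
            VariableSpec("y", "outcome", "bernoulli", ("0", "1"), "0"),
            VariableSpec("x", "covariate", "continuous"),
        ],
        [EquationSpec("y", ("x",), "bernoulli", "0")],
    )
    table = pd.DataFrame(
        [{"equation": "y", "contrast": "1", "term": "x", "estimate": 0.4, "se": 0.1},
         {"equation": "y", "contrast": "1", "term": "Intercept", "estimate": -1.0, "se": 0.1}]
    )
    system = SystemFit.from_coefficient_table(table)
    out = effect_table(system, d)
    assert set(out["kind"]) == {"direct"}


def test_additivity_and_reconstruction_identities(system_fit_20k, diagram):
    # on a refit system (full covariances): indirect rows are exact products of
    # the two direct coefficients, totals are exact sums, pre-rounding
    table = effect_table(system_fit_20k, diagram)
    directs = {
        (r.block, r.row): r.estimate
        for r in table[table["kind"] == "direct"].itertuples()
    }
    for r in table[table["kind"] == "indirect"].itertuples():
        a = directs[(r.block, r.row)]
        b = directs[("screening", r.block)]
        assert r.estimate == pytest.approx(a * b, abs=1e-12)
    for r in table[table["kind"] == "total"].itertuples():
        d = directs[("screening", r.row)]
        indirect_sum = 0.0
        for via in r.via.split(" + "):
            a = directs[(via, r.row)]
            b = directs[("screening", via)]
            indirect_sum += a * b
        assert r.estimate == pytest.approx(d + indirect_sum, abs=1e-12)


def test_grand_total_convention_sums_all_paths(reported_system, diagram):
    table = effect_table(reported_system, diagram, convention="grand_total")
    totals = table[(table["kind"] == "total") & (table["exposure"] == "wealth")
                   & (table["exposure_level"] == "poorer")]
    assert len(totals) == 1
    paths = [p for p in enumerate_mediation_paths(diagram, "wealth", "poorer")
             if not p.is_direct]
    expected = direct_effect(reported_system, diagram, "wealth", "poorer").estimate
    for p in paths:
        expected += indirect_effect(reported_system, diagram, p).estimate
    assert totals["estimate"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_odds_ratio_table_marks_references(reported_system, diagram):
    ors = odds_ratio_table(reported_system, diagram)
    age = ors[ors["term"] == "age[35-49]"]["odds_ratio"].iloc[0]
    assert round(age, 2) == 1.16
    refs = ors[ors["reference"]]
    assert (refs["odds_ratio"] == 1.0).all()
    assert "wealth[poorest]" in set(refs["term"])


def test_delta_method_se_matches_parametric_bootstrap(reported_system, diagram):
    # 10,000-draw parametric bootstrap of a*b vs first-order delta SE
    eff = indirect_effect(
        reported_system, diagram, _path("wealth", "poorer", "children", "one_two")
    )
    a, sa = 0.104, (0.123 - 0.084) / (2 * 1.959964)
    b, sb = 0.221, (0.280 - 0.162) / (2 * 1.959964)
    rng = np.random.default_rng(123)
    draws = rng.normal(a, sa, 10_000) * rng.normal(b, sb, 10_000)
    assert eff.se == pytest.approx(draws.std(ddof=1), rel=0.10)
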