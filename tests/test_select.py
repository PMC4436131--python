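"""Sequential cascade: DE statistics, filter rules, marker report."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crdmarkers import select, simulate
from crdmarkers.errors import ConfigError, DataError


def _matrix_and_design(rng, n_probes=20):
    design = simulate.generate_design(stages=("baseline", "rec14"), replicates=2)
    matrix = pd.DataFrame(
        rng.normal(size=(n_probes, len(design))),
        index=[f"p{i}" for i in range(n_probes)],
        columns=design["sample_id"],
    )
    return matrix, design


def test_de_identical_groups_null(rng):
    design = simulate.generate_design(stages=("baseline", "rec14"), replicates=2)
    base_ids = design[design["stage"] == "baseline"]["sample_id"]
    values = rng.normal(size=len(base_ids))
    matrix = pd.DataFrame(0.0, index=["p0"], columns=design["sample_id"])
    matrix.loc["p0", base_ids] = values
    # copy the baseline pattern into both rec14 protocol groups
    for protocol in ("CW", "CCW"):
        ids = design[(design["stage"] == "rec14") & (design["protocol"] == protocol)]["sample_id"]
        matrix.loc["p0", ids] = np.resize(values, len(ids))
    de = select.differential_expression(matrix, design, "CW")
    assert de.loc["p0", "fc"] == pytest.approx(1.0, abs=0.3)
    assert de.loc["p0", "p_value"] > 0.1


def test_two_group_anova_f_equals_t_squared(rng):
    matrix, design = _matrix_and_design(rng)
    de = select.differential_expression(matrix, design, "CW")
    base = matrix[design[design["stage"] == "baseline"]["sample_id"]].to_numpy()
    grp = matrix[
        design[(design["stage"] == "rec14") & (design["protocol"] == "CW")]["sample_id"]
    ].to_numpy()
    for i in range(len(matrix)):
        f_ref, p_ref = stats.f_oneway(base[i], grp[i])
        assert de["f_stat"].iloc[i] == pytest.approx(f_ref, abs=1e-10)
        assert de["p_value"].iloc[i] == pytest.approx(p_ref, abs=1e-10)


def test_de_planted_effect_detected(rng):
    matrix, design = _matrix_and_design(rng)
    matrix = matrix * 0.1
    ids = design[design["stage"] == "rec14"]["sample_id"]
    matrix.loc["p0", ids] += np.log(1.5)
    de = select.differential_expression(matrix, design, "CCW")
    assert de.loc["p0", "p_value"] < 0.001
    assert de.loc["p0", "fc"] == pytest.approx(1.5, rel=0.15)


def test_de_missing_group_rejected(rng):
    matrix, design = _matrix_and_design(rng)
    with pytest.raises(DataError):
        select.differential_expression(matrix, design[design["stage"] == "baseline"], "CW")


def test_intersect_de():
    de_a = pd.DataFrame({"p_value": [1e-4, 1e-4, 1e-4, 0.5]}, index=list("abcd"))
    de_b = pd.DataFrame({"p_value": [0.9, 1e-5, 1e-5, 1e-5]}, index=list("abcd"))
    assert select.intersect_de(de_a, de_b) == {"b", "c"}
    assert select.intersect_de(de_a.iloc[:1], de_b.iloc[3:]) == set()
    with pytest.raises(ConfigError):
        select.intersect_de(de_a, de_b, alpha=1.5)


@pytest.mark.parametrize(
    "fc_cw, fc_ccw, kept",
    [
        (1.25, 1.3, True),  # concordant up, beyond gate
        (1.25, 0.75, False),  # discordant directions
        (1.1, 1.1, False),  # inside the (0.8, 1.2) band
        (0.7, 0.75, True),  # concordant down
    ],
)
def test_fold_change_gate(fc_cw, fc_ccw, kept):
    result = select.fold_change_gate(
        pd.Series({"g": fc_cw}), pd.Series({"g": fc_ccw})
    )
    assert ("g" in result) is kept


def test_fold_change_gate_validates_bounds():
    with pytest.raises(ConfigError):
        select.fold_change_gate(pd.Series(dtype=float), pd.Series(dtype=float), 1.2, 0.8)


def _screens(rhythmic_probes_by_stage):
    screens = {}
    for stage in simulate.STAGES:
        flagged = rhythmic_probes_by_stage.get(stage, set())
        probes = sorted({"p1", "p2", "p3"} | flagged)
        screens[stage] = pd.DataFrame(
            {"rhythmic": [p in flagged for p in probes]}, index=probes
        )
    return screens


def test_exclude_rhythmic_any_condition_rule():
    annotation = {"p1": "geneA", "p2": "geneB", "p3": "geneC"}
    screens = _screens({"baseline": {"p1"}})
    kept = select.exclude_rhythmic({"geneA", "geneB"}, screens, annotation)
    assert kept == {"geneB"}  # rhythmic only at baseline is still excluded


def test_exclude_rhythmic_missing_condition_named():
    screens = _screens({})
    screens.pop("rec5")
    with pytest.raises(DataError, match="rec5"):
        select.exclude_rhythmic({"geneA"}, screens, {"p1": "geneA"})


def test_exclude_age_related_case_insensitive():
    assert select.exclude_age_related({"Cd36", "Tp53"}, {"TP53"}) == {"Cd36"}
    assert select.exclude_age_related(set(), {"TP53"}) == set()
    assert select.exclude_age_related({"Cd36"}, {"Abc1"}) == {"Cd36"}
    with pytest.warns(UserWarning):
        assert select.exclude_age_related({"Cd36"}, set()) == {"Cd36"}


def test_flag_blood_detectable_union_semantics():
    table = select.flag_blood_detectable(
        ["GeneA", "GeneB", "GeneC"], secreted_genes={"genea", "geneb"}, plasma_genes={"GENEB"}
    )
    flags = dict(zip(table["gene"], table["blood_detectable"]))
    assert flags == {"GeneA": True, "GeneB": True, "GeneC": False}


def test_marker_report_reference_panel_counts():
    """The shipped reference panel reproduces the published route counts."""
    panel = select.load_reference_panel()
    consensus = panel[panel["consensus"] == 1]["gene"]
    blood = panel[panel["blood"] == 1]["gene"]
    report, counts = select.build_marker_report(blood, consensus)
    assert counts == {"consensus_genes": 15, "blood_candidates": 9, "overlap": 5}
    assert len(report) == 19


@pytest.mark.parametrize(
    "blood, consensus, expected",
    [
        ({"a", "b", "c"}, {"d", "e"}, (2, 3, 0)),
        ({"a", "b"}, {"a", "b"}, (2, 2, 2)),
    ],
)
def test_marker_report_counts(blood, consensus, expected):
    _, counts = select.build_marker_report(blood, consensus)
    assert (counts["consensus_genes"], counts["blood_candidates"], counts["overlap"]) == (
        expected[0], expected[1], expected[2],
    )


def test_cascade_stages_are_nested(small_study):
    c = small_study.counts
    assert c["de_both"] <= min(c["de_cw"], c["de_ccw"])
    assert c["fc_pass"] <= c["de_both"]
    assert c["non_rhythmic"] <= c["fc_pass"]
    assert c["non_age"] <= c["non_rhythmic"]
    assert c["blood_candidates"] <= c["non_age"]


def test_cascade_recovers_planted_candidates(small_study):
    truth = small_study.truth
    planted = sorted(truth[truth["secreted"]]["gene"])
    assert small_study.candidates == planted
    ledger = small_study.ledger
    final = ledger[ledger["blood_candidate"]]
    # final flag implies the full conjunction of upstream filters
    assert final["de_both"].all()
    assert final["fc_gate"].all()
    assert (~final["rhythmic_any_condition"]).all()
    assert (~final["age_related"]).all()
    assert final["secreted_or_plasma"].all()


def test_exclusion_filters_commute(rng):
    screens = _screens({"shift6": {"p2"}})
    annotation = {"p1": "geneA", "p2": "geneB", "p3": "geneC"}
    for _ in range(10):
        genes = {g for g in ("geneA", "geneB", "geneC", "geneD") if rng.random() < 0.6}
        age = {g for g in ("geneA", "geneD") if rng.random() < 0.5} or {"zzz"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = select.exclude_age_related(
                select.exclude_rhythmic(genes, screens, annotation), age
            )
            b = select.exclude_rhythmic(
                select.exclude_age_related(genes, age), screens, annotation
            )
        assert a == b
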