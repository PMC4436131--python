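"""Generator correctness: design structure, planted effects, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from crdmarkers import rhythm, simulate
from crdmarkers.errors import ConfigError


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(), 120),  # 24 baseline + 2 protocols x 4 stages x 6 ZTs x 2
        (dict(stages=("baseline",), zts=(0,), replicates=1), 1),
        (dict(stages=("baseline",), zts=(0, 12), replicates=3), 6),
    ],
)
def test_design_sample_counts(kwargs, expected):
    assert len(simulate.generate_design(**kwargs)) == expected


def test_design_structure(paper_design):
    d = paper_design
    assert d["sample_id"].is_unique
    assert (d.loc[d["stage"] == "baseline", "protocol"] == "none").all()
    assert set(d.loc[d["stage"] != "baseline", "protocol"]) == {"CW", "CCW"}
    cells = d.groupby(["stage", "protocol", "zt"]).size()
    assert (cells[cells.index.get_level_values("stage") == "baseline"] == 4).all()
    assert (cells[cells.index.get_level_values("stage") != "baseline"] == 2).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(stages=()),
        dict(zts=()),
        dict(replicates=0),
        dict(stages=("baseline", "nonsense")),
    ],
)
def test_design_invalid_config(kwargs):
    with pytest.raises(ConfigError):
        simulate.generate_design(**kwargs)


def _one_gene_config(seed=0, **gene_overrides):
    row = {
        "gene": "g0", "archetype": "crd_responsive", "mesor": 8.0, "amplitude": 0.0,
        "acrophase": np.nan, "crd_log_fc": 0.0, "persistence": 1.0, "secreted": False,
    }
    row.update(gene_overrides)
    return simulate.GeneConfig(genes=pd.DataFrame([row]), noise_sd=0.2, seed=seed)


def test_seed_reproducibility():
    design = simulate.generate_design(stages=("baseline", "rec14"), replicates=2)
    config = _one_gene_config(seed=42, crd_log_fc=0.05)
    a = simulate.generate_expression(design, config)
    b = simulate.generate_expression(design, config)
    pd.testing.assert_frame_equal(a, b)
    c = simulate.generate_expression(design, simulate.with_seed(config, 43))
    assert not a.equals(c)


def test_zero_amplitude_expected_level_constant_across_zt(paper_design):
    config = _one_gene_config(amplitude=0.0)
    mu = simulate.expected_ln_levels(paper_design, config)
    base = mu.loc["g0", paper_design[paper_design["stage"] == "baseline"]["sample_id"]]
    assert base.nunique() == 1


def test_crd_fold_change_expectation():
    """Effect ln(1.5)/6 per shift with persistence 1 gives rec14/baseline FC 1.5.

    Verified against the Monte-Carlo mean of ~1,000 simulated animals per group.
    """
    design = simulate.generate_design(
        stages=("baseline", "rec14"), zts=(0,), replicates={"baseline": 1000, "rec14": 500}
    )
    config = _one_gene_config(seed=3, crd_log_fc=math.log(1.5) / 6, persistence=1.0)
    pm = simulate.generate_expression(design, config)
    ln_sample = np.log(pm.xs("sample", axis=1, level="channel")).mean(axis=0)
    is_rec = ln_sample.index.str.startswith("rec14")
    fc = math.exp(ln_sample[is_rec].mean() - ln_sample[~is_rec].mean())
    se = 0.2 * math.sqrt(1 / 1000 + 1 / 1000)  # noise_sd on ln scale
    assert abs(math.log(fc) - math.log(1.5)) < 3 * se


def test_null_gene_condition_means_balanced():
    """Null genes show no systematic condition differences (500 replicate sims)."""
    design = simulate.generate_design(stages=("baseline", "rec14"), zts=(0, 12), replicates=2)
    genes = pd.DataFrame(
        {
            "gene": [f"n{i}" for i in range(500)], "archetype": "null", "mesor": 8.0,
            "amplitude": 0.0, "acrophase": np.nan, "crd_log_fc": 0.0,
            "persistence": 0.0, "secreted": False,
        }
    )
    config = simulate.GeneConfig(genes=genes, noise_sd=0.2, seed=11)
    mu = simulate.expected_ln_levels(design, config)
    pm = simulate.generate_expression(design, config)
    ratios = np.log(pm.xs("sample", axis=1, level="channel"))
    ratios = ratios.groupby(level="probe_id").mean()
    is_rec = design["stage"].to_numpy() == "rec14"
    diff = ratios.loc[:, is_rec].mean(axis=1) - ratios.loc[:, ~is_rec].mean(axis=1)
    # per-gene SE of the difference: noise 0.2 per animal + spot noise 0.1/sqrt(3)
    per_sample_var = 0.2**2 + 0.1**2 / 3
    se = math.sqrt(per_sample_var * (1 / is_rec.sum() + 1 / (~is_rec).sum()))
    assert abs(diff.mean()) < 3 * se / math.sqrt(500)
    assert (mu.var(axis=1) == 0).all()


def test_generator_cosinor_consistency(paper_design):
    """Noise-free circadian genes are exactly recovered by the cosinor fit."""
    genes = pd.DataFrame(
        {
            "gene": ["c1", "c2"], "archetype": "circadian", "mesor": [8.0, 10.0],
            "amplitude": [1.0, 2.5], "acrophase": [12.0, 3.5], "crd_log_fc": 0.0,
            "persistence": 0.0, "secreted": False,
        }
    )
    config = simulate.GeneConfig(genes=genes, noise_sd=0.0, spot_noise_sd=0.0, seed=0)
    base = paper_design[paper_design["stage"] == "baseline"]
    mu = simulate.expected_ln_levels(base, config)
    for gene, mesor, amp, acro in [("c1", 8.0, 1.0, 12.0), ("c2", 10.0, 2.5, 3.5)]:
        fit = rhythm.cosinor_fit(base["zt"].to_numpy(float), mu.loc[gene].to_numpy())
        assert fit.mesor == pytest.approx(mesor, abs=1e-8)
        assert fit.amplitude == pytest.approx(amp, abs=1e-8)
        assert fit.acrophase == pytest.approx(acro, abs=1e-8)


def test_probe_matrix_long_roundtrip():
    design = simulate.generate_design(stages=("baseline",), zts=(0, 12), replicates=1)
    config = _one_gene_config(seed=5)
    pm = simulate.generate_expression(design, config)
    back = simulate.probe_matrix_from_long(simulate.probe_matrix_to_long(pm))
    pd.testing.assert_frame_equal(pm, back, check_names=False)


def test_serum_noiseless_peak_at_acrophase(paper_design):
    config = simulate.SerumConfig(
        name="x", rhythmic=True, mesor=10.0, amplitude=2.0, acrophase=12.0,
        noise_sd=0.0, n_per_cell=1,
    )
    series, sidecar = simulate.generate_serum(paper_design, config)
    base = series[series["stage"] == "baseline"]
    assert base.loc[base["value"].idxmax(), "zt"] == 12
    assert sidecar.empty


def test_serum_stage_shift_expectation():
    """A +18% planted recovery shift yields a mean ratio of 1.18 (MC check)."""
    design = simulate.generate_design(stages=("baseline", "rec14"), replicates=1)
    config = simulate.SerumConfig(
        name="x", rhythmic=False, mesor=100.0, amplitude=0.0,
        stage_shift={"rec14": 0.18}, noise_sd=10.0, n_per_cell=200, seed=9,
    )
    series, _ = simulate.generate_serum(design, config)
    means = series.groupby("stage")["value"].mean()
    n = (series["stage"] == "rec14").sum()
    se_ratio = 10.0 / 100.0 * math.sqrt(1 / n + 1 / (series["stage"] == "baseline").sum())
    assert means["rec14"] / means["baseline"] == pytest.approx(1.18, abs=3 * se_ratio)


def test_serum_outlier_sidecar_bookkeeping(paper_design):
    config = simulate.SerumConfig(
        name="x", mesor=10.0, amplitude=1.0, noise_sd=1.0, n_per_cell=2,
        outlier_count=1, outlier_magnitude=5.0, seed=2,
    )
    series, sidecar = simulate.generate_serum(paper_design, config)
    assert len(sidecar) == 1
    assert sidecar["sample_id"].iloc[0] in set(series["sample_id"])
    assert sidecar["injected_delta"].iloc[0] == pytest.approx(5.0)


@pytest.mark.parametrize(
    "bad",
    [
        dict(amplitude=-1.0),
        dict(persistence=1.5),
    ],
)
def test_gene_config_validation(bad):
    with pytest.raises(ConfigError):
        _one_gene_config(**bad)


def test_unknown_stage_in_design_rejected():
    design = simulate.generate_design(stages=("baseline",), zts=(0, 12), replicates=1)
    design.loc[0, "stage"] = "mystery"
    with pytest.raises(Exception, match="mystery"):
        simulate.expected_ln_levels(design, _one_gene_config())
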