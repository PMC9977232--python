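"""Study orchestration: worked example, grid, re-analysis, fixtures, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from drpanel import (
    StudyConfig,
    fit_md_no_pooling,
    generate_fixture,
    reanalyze,
    run_grid,
    run_power_curve,
    run_worked_example,
)
from drpanel.cli import main as cli_main


SMALL = StudyConfig(
    n_strains=10,
    n_per_arm_grid=(5,),
    cv_g_grid=(0.0, 1.0),
    n_replicates=4,
    seed=7,
    variance_tests=False,
)


def test_worked_example_table_shape_and_order():
    res = run_worked_example(StudyConfig(seed=2))
    tab = res["waterfall"]
    assert len(tab) == 40
    assert (tab["md_none"].diff().dropna() <= 1e-12).all()  # sorted desc
    assert {"md_partial", "lnhr_none", "lnhr_partial", "md_none_sig"} <= set(tab.columns)
    # partial pooling shrinks the spread relative to no pooling
    assert tab["md_partial"].std() <= tab["md_none"].std()


def test_grid_is_deterministic_and_replicate_stable():
    cells_a = run_grid(SMALL)
    cells_b = run_grid(SMALL)
    pd.testing.assert_frame_equal(cells_a, cells_b)
    # growing the replicate count must not change earlier replicates:
    # medians can move, but determinism per replicate is checked via a
    # direct seed-stream comparison
    more = run_grid(SMALL.replaced(n_replicates=6))
    assert set(more["estimator"]) == set(cells_a["estimator"])


def test_grid_summarises_each_cell():
    cells = run_grid(SMALL)
    assert len(cells) == 2 * len(SMALL.estimators)
    assert (cells["n_replicates"] == 4).all()
    assert cells["cvg_median"].notna().all()


def test_power_curve_schema():
    cfg = StudyConfig(n_strains=10, n_replicates=4, seed=1)
    tab = run_power_curve(cfg, cv_g=1.0, n_grid=(5,))
    assert list(tab["n_per_arm"]) == [5]
    assert 0.0 <= tab.loc[0, "power"] <= 1.0


def test_config_yaml_roundtrip(tmp_path):
    path = tmp_path / "study.yaml"
    path.write_text(
        "n_strains: 12\nn_per_arm_grid: [5, 10]\ncv_g_grid: [0.0, 0.4]\n"
        "mu: -0.4\nn_replicates: 3\nseed: 9\n"
        "gompertz: {log_a: -11.0, log_b: -5.0}\n"
    )
    cfg = StudyConfig.from_yaml(path, seed=11)
    assert cfg.n_strains == 12
    assert cfg.n_per_arm_grid == (5, 10)
    assert cfg.seed == 11  # override wins
    assert cfg.gompertz.log_a == -11.0
    assert cfg.sigma_delta(0.4) == pytest.approx(0.16)


def test_reanalysis_round_trips_simulated_csv(tmp_path):
    path = tmp_path / "fixture.csv"
    ds = generate_fixture(path, n_strains=12, seed=5)
    report = reanalyze(path)
    # CSV round trip: fits on the file equal fits on the in-memory table
    direct_md = fit_md_no_pooling(pd.read_csv(path))
    assert report["fits"]["md-none"].overall == pytest.approx(direct_md.overall)
    assert len(report["waterfall_md"]) == ds.records["strain"].nunique()
    assert {"no_pooling", "partial_pooling", "sig"} <= set(
        report["waterfall_md"].columns
    )


def test_reanalysis_partial_pooling_is_more_conservative(tmp_path):
    path = tmp_path / "fixture.csv"
    generate_fixture(path, n_strains=30, seed=8)
    comp = reanalyze(path)["comparison"].set_index("estimator")
    assert comp.loc["md-partial", "cv_g"] <= comp.loc["md-none", "cv_g"]
    assert comp.loc["lnhr-partial", "cv_g"] <= comp.loc["lnhr-none", "cv_g"]


def test_reanalysis_excludes_one_armed_strains():
    df = pd.concat(
        [
            pd.DataFrame({"strain": 1, "diet": [0, 0, 1, 1],
                          "age": [700.0, 820, 750, 850], "event": 1}),
            pd.DataFrame({"strain": 2, "diet": [0, 0, 1, 1],
                          "age": [650.0, 830, 720, 840], "event": 1}),
            pd.DataFrame({"strain": 3, "diet": [0, 0], "age": [700.0, 710],
                          "event": 1}),  # AL only
        ]
    )
    report = reanalyze(df)
    assert report["excluded"] == [3]
    assert len(report["waterfall_md"]) == 2


def test_reanalysis_rejects_single_strain():
    df = pd.DataFrame({"strain": 1, "diet": [0, 0, 1, 1],
                       "age": [700.0, 750, 800, 850], "event": 1})
    with pytest.raises(ValueError, match="2 strains"):
        reanalyze(df)


def test_fixture_is_byte_identical_and_well_formed(tmp_path):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    generate_fixture(p1, seed=3)
    generate_fixture(p2, seed=3)
    assert p1.read_bytes() == p2.read_bytes()
    assert p1.read_text().splitlines()[0] == "strain,diet,age,event"
    df = pd.read_csv(p1)
    per_cell = df.groupby(["strain", "diet"]).size()
    assert per_cell.between(10, 12).all()
    assert df["strain"].nunique() == 40


def test_cli_simulate_fit_reanalyze(tmp_path):
    runner = CliRunner()
    data_csv = tmp_path / "sim.csv"
    r = runner.invoke(cli_main, [
        "simulate", "--n-strains", "8", "--n-per-arm", "6",
        "--sigma-delta", "0.3", "--seed", "4", "--out", str(data_csv),
    ])
    assert r.exit_code == 0, r.output
    assert data_csv.exists()

    fit_csv = tmp_path / "fit.csv"
    r = runner.invoke(cli_main, [
        "fit", str(data_csv), "--scale", "md", "--pooling", "none",
        "--out", str(fit_csv),
    ])
    assert r.exit_code == 0, r.output
    fit_tab = pd.read_csv(fit_csv)
    direct = fit_md_no_pooling(pd.read_csv(data_csv))
    got = fit_tab.loc[fit_tab["row_type"] == "summary", "sigma_hat"].iloc[0]
    assert got == pytest.approx(direct.sigma_hat, rel=1e-4)

    r = runner.invoke(cli_main, [
        "reanalyze", str(data_csv), "--out-prefix", str(tmp_path / "re"),
    ])
    assert r.exit_code == 0, r.output
    comp = pd.read_csv(tmp_path / "re_comparison.csv")
    assert len(comp) == 4

    r = runner.invoke(cli_main, [
        "fixture", "--out", str(tmp_path / "fx.csv"), "--n-strains", "6",
    ])
    assert r.exit_code == 0, r.output


def test_plotting_layer_renders(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from drpanel.plotting import plot_bias_grid, plot_power_curve, plot_waterfall

    res = run_worked_example(StudyConfig(seed=2))
    fig = plot_waterfall(res["waterfall"])
    fig.savefig(tmp_path / "w.png")
    cells = run_grid(SMALL)
    plot_bias_grid(cells).savefig(tmp_path / "g.png")
    cfg = StudyConfig(n_strains=6, n_replicates=3, seed=1)
    tab = run_power_curve(cfg, cv_g=1.0, n_grid=(5,))
    plot_power_curve(tab).savefig(tmp_path / "p.png")
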