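"""Panel simulator: balance, determinism, effect structure, CSV I/O."""

import numpy as np
import pytest
from scipy import stats

from drpanel import (
    DesignSpec,
    EffectModel,
    GompertzParams,
    draw_strain_effects,
    fit_lnhr_no_pooling,
    read_dataset_csv,
    simulate_experiment,
    simulate_paired_experiments,
    survival,
    write_dataset_csv,
)


def test_zero_sigma_gives_zero_effects(rng):
    delta, alpha = draw_strain_effects(EffectModel(sigma_delta=0.0), 10, rng)
    assert np.all(delta == 0) and np.all(alpha == 0)


def test_strain_effect_sd_matches_parameter():
    rng = np.random.default_rng(42)
    delta, _ = draw_strain_effects(
        EffectModel(sigma_delta=0.5), 100_000, rng
    )
    assert 0.495 < delta.std(ddof=1) < 0.505


def test_effect_draws_reproducible():
    e = EffectModel(sigma_delta=0.3, sigma_alpha=0.1)
    d1 = draw_strain_effects(e, 20, np.random.default_rng(5))
    d2 = draw_strain_effects(e, 20, np.random.default_rng(5))
    for a, b in zip(d1, d2):
        np.testing.assert_array_equal(a, b)


def test_balanced_bookkeeping():
    design = DesignSpec(n_strains=40, n_per_strain_per_diet=5)
    data = simulate_experiment(design, EffectModel(), np.random.default_rng(0))
    df = data.records
    assert len(df) == 400
    counts = df.groupby(["strain", "diet"]).size()
    assert (counts == 5).all()
    assert df["event"].eq(1).all()
    assert set(df.columns) == {"strain", "diet", "age", "event"}


def test_dataset_bit_reproducible():
    design = DesignSpec(n_strains=6, n_per_strain_per_diet=4)
    e = EffectModel(sigma_delta=0.4, sigma_alpha=0.2)
    a = simulate_experiment(design, e, np.random.default_rng(11))
    b = simulate_experiment(design, e, np.random.default_rng(11))
    assert a.records.equals(b.records)


def test_strain_effects_length_checked():
    design = DesignSpec(n_strains=4, n_per_strain_per_diet=2)
    with pytest.raises(ValueError, match="n_strains"):
        simulate_experiment(
            design, EffectModel(), np.random.default_rng(0),
            strain_effects=(np.zeros(3), np.zeros(3)),
        )


def test_single_strain_dr_median_near_914():
    # one homogeneous strain, 400 per arm, mu = -0.5: the DR sample
    # median should sit near the analytic 914 days
    design = DesignSpec(n_strains=1, n_per_strain_per_diet=400)
    data = simulate_experiment(
        design, EffectModel(mu=-0.5), np.random.default_rng(2024)
    )
    dr = data.records.query("diet == 1")["age"]
    assert abs(dr.median() - 914) < 25  # ~ +-2 SE of a median at n=400


def test_null_arms_exchangeable():
    design = DesignSpec(n_strains=1, n_per_strain_per_diet=4000)
    data = simulate_experiment(
        design, EffectModel(mu=0.0), np.random.default_rng(31)
    )
    al = data.records.query("diet == 0")["age"]
    dr = data.records.query("diet == 1")["age"]
    assert stats.ks_2samp(al, dr).pvalue > 0.01


def test_pooled_marginal_matches_gompertz():
    # many strains, no strain variation: pooled AL ages follow the base
    # Gompertz law
    design = DesignSpec(n_strains=100, n_per_strain_per_diet=500)
    data = simulate_experiment(
        design, EffectModel(mu=-0.5), np.random.default_rng(8)
    )
    al = data.records.query("diet == 0")["age"].to_numpy()
    p = GompertzParams()
    res = stats.kstest(al, lambda x: 1 - np.asarray(survival(p, x)))
    assert res.statistic < 0.01


def test_paired_experiments_share_effects():
    design = DesignSpec(n_strains=12, n_per_strain_per_diet=3)
    e = EffectModel(sigma_delta=0.4, sigma_alpha=0.1)
    d1, d2 = simulate_paired_experiments(design, e, np.random.default_rng(9))
    np.testing.assert_array_equal(d1.true_delta, d2.true_delta)
    np.testing.assert_array_equal(d1.true_alpha, d2.true_alpha)
    assert not d1.records["age"].equals(d2.records["age"])


def test_paired_null_effects_uncorrelated():
    # no true strain variation => strain estimates across a pair carry no
    # shared signal; mean correlation over pairs ~ 0
    design = DesignSpec(n_strains=20, n_per_strain_per_diet=5)
    e = EffectModel(mu=-0.5, sigma_delta=0.0)
    rng = np.random.default_rng(17)
    cors = []
    for _ in range(500):
        d1, d2 = simulate_paired_experiments(design, e, rng)
        m1 = d1.records.groupby(["strain", "diet"])["age"].mean().unstack()
        m2 = d2.records.groupby(["strain", "diet"])["age"].mean().unstack()
        e1 = (m1[1] - m1[0]).to_numpy()
        e2 = (m2[1] - m2[0]).to_numpy()
        cors.append(np.corrcoef(e1, e2)[0, 1])
    assert abs(np.mean(cors)) < 0.05


def test_paired_strong_effects_highly_correlated():
    # large true variation, large n: no-pooling lnHRs replicate across
    # the pair with correlation > 0.8
    design = DesignSpec(n_strains=40, n_per_strain_per_diet=40)
    e = EffectModel(mu=-0.5, sigma_delta=0.5)
    rng = np.random.default_rng(23)
    cors = []
    for _ in range(5):
        d1, d2 = simulate_paired_experiments(design, e, rng)
        f1 = fit_lnhr_no_pooling(d1).strain_effects["estimate"].to_numpy()
        f2 = fit_lnhr_no_pooling(d2).strain_effects["estimate"].to_numpy()
        cors.append(np.corrcoef(f1, f2)[0, 1])
    assert np.mean(cors) > 0.8


def test_csv_roundtrip(tmp_path):
    design = DesignSpec(n_strains=5, n_per_strain_per_diet=3)
    data = simulate_experiment(design, EffectModel(), np.random.default_rng(6))
    path = tmp_path / "panel.csv"
    write_dataset_csv(data, path)
    header = path.read_text().splitlines()[0]
    assert header == "strain,diet,age,event"
    back = read_dataset_csv(path)
    assert back.records["strain"].tolist() == data.records["strain"].tolist()
    np.testing.assert_allclose(
        back.records["age"], data.records["age"], atol=1e-4
    )


def test_malformed_csv_names_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("strain,diet,age,event\n1,0,800,1\n1,2,810,1\n")
    with pytest.raises(ValueError, match="line 3"):
        read_dataset_csv(path)
    path.write_text("strain,diet,age,event\n1,0,-5,1\n")
    with pytest.raises(ValueError, match="age"):
        read_dataset_csv(path)
    path.write_text("strain,age\n1,800\n")
    with pytest.raises(ValueError, match="missing column"):
        read_dataset_csv(path)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        EffectModel(sigma_delta=-0.1)
    with pytest.raises(ValueError):
        DesignSpec(n_strains=0)
    with pytest.raises(ValueError):
        draw_strain_effects(EffectModel(), 0, np.random.default_rng(0))
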