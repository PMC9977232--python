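"""Replicated simulation studies, power analysis and CSV re-analysis.

This module turns the simulator and the four panel estimators into a
study-design tool:

* :func:`run_worked_example` — one simulated panel experiment analysed
  by all four estimators, with a waterfall table of per-strain effects.
* :func:`run_grid` — the bias/replicability grid: for each combination
  of animals-per-arm and true CV_G, replicate paired experiments are
  simulated and each estimator's CV_G bias, between-experiment
  replicability and variance-test power are summarised.
* :func:`run_power_curve` — power of the mixed-effects Cox variance
  test as a function of the per-arm sample size.
* :func:`reanalyze` — apply all four estimators to a user-supplied
  ``strain,diet,age,event`` CSV.
* :func:`generate_fixture` — a deterministic synthetic CSV emulating a
  multi-strain, two-diet mouse survival table.

Randomness follows a child-stream protocol: the master seed spawns an
independent stream per grid cell (keyed by the cell parameters, not the
grid order) and per replicate, so results for replicate k do not change
when the replicate count grows, and cells can be recomputed in
isolation.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .gompertz import GompertzParams
from .metrics import (
    StudyCell,
    bias_summary,
    power_estimate,
    replicability,
)
from .panels import ESTIMATORS, PanelFit, drop_incomplete_strains
from .simulate import (
    Dataset,
    DesignSpec,
    EffectModel,
    draw_strain_effects,
    simulate_experiment,
    simulate_paired_experiments,
    write_dataset_csv,
)

__all__ = [
    "StudyConfig",
    "run_worked_example",
    "run_grid",
    "run_power_curve",
    "reanalyze",
    "generate_fixture",
]

log = logging.getLogger("drpanel")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[drpanel] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

ALL_ESTIMATORS = ("md-none", "md-partial", "lnhr-none", "lnhr-partial")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a replicated simulation study.

    ``sigma_delta`` for each target CV_G is derived as
    ``cv_g * |mu|``, so the grid is stated on the unitless CV_G scale.
    """

    n_strains: int = 40
    n_per_arm_grid: tuple = (5, 10, 20, 40)
    cv_g_grid: tuple = (0.0, 0.2, 0.4, 1.0)
    mu: float = -0.5
    sigma_alpha: float = 0.0
    gompertz: GompertzParams = field(default_factory=GompertzParams)
    n_replicates: int = 1000
    alpha: float = 0.05
    seed: int = 1
    estimators: tuple = ALL_ESTIMATORS
    # skip the mixed-model LRT refits when a study only needs point
    # estimates (e.g. pure replicability runs); power is then NaN
    variance_tests: bool = True

    def __post_init__(self):
        if self.n_strains < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if any(n < 1 for n in self.n_per_arm_grid):
            raise ValueError("n_per_arm_grid entries must be >= 1")
        if any(c < 0 for c in self.cv_g_grid):
            raise ValueError("cv_g targets must be >= 0")
        unknown = set(self.estimators) - set(ALL_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")

    def sigma_delta(self, cv_g: float) -> float:
        return cv_g * abs(self.mu)

    def effect(self, cv_g: float) -> EffectModel:
        return EffectModel(
            mu=self.mu,
            sigma_delta=self.sigma_delta(cv_g),
            sigma_alpha=self.sigma_alpha,
        )

    def design(self, n_per_arm: int) -> DesignSpec:
        return DesignSpec(
            n_strains=self.n_strains,
            n_per_strain_per_diet=n_per_arm,
            gompertz=self.gompertz,
        )

    # -- YAML round trip ------------------------------------------------
    @classmethod
    def from_yaml(cls, path, **overrides) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        gomp = raw.pop("gompertz", None)
        cfg = {}
        for key in ("n_per_arm_grid", "cv_g_grid", "estimators"):
            if key in raw:
                cfg[key] = tuple(raw.pop(key))
        cfg.update(raw)
        if gomp is not None:
            cfg["gompertz"] = GompertzParams(**gomp)
        return cls(**cfg)

    def replaced(self, **kw) -> "StudyConfig":
        return replace(self, **kw)


def _cell_seed(config: StudyConfig, *key_parts: int) -> np.random.SeedSequence:
    """Independent stream per cell, keyed by cell parameters so that
    adding or reordering cells leaves other cells' draws unchanged."""
    return np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key_parts))


def _cvg_key(cv_g: float) -> int:
    return int(round(cv_g * 10**6))


# ---------------------------------------------------------------------
# worked example

def run_worked_example(
    config: StudyConfig | None = None,
    n_per_arm: int = 5,
    cv_g: float = 0.0,
) -> dict:
    """Simulate one panel experiment and analyse it four ways.

    Returns a dict with the simulated ``dataset``, the four
    :class:`PanelFit` objects under ``fits``, and a ``waterfall`` table
    sorted by the no-pooling MD estimate (descending), with
    significance stars for the per-strain no-pooling tests and the
    shrunken partial-pooling estimates alongside.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(_cell_seed(config, 0, n_per_arm, _cvg_key(cv_g)))
    data = simulate_experiment(
        config.design(n_per_arm), config.effect(cv_g), rng
    )
    fits = {name: ESTIMATORS[name](data) for name in config.estimators}

    base = fits.get("md-none") or next(iter(fits.values()))
    tab = base.strain_effects[["strain", "estimate", "p_value"]].rename(
        columns={"estimate": "md_none", "p_value": "md_none_p"}
    )
    tab["md_none_sig"] = np.where(tab["md_none_p"] < config.alpha, "*", "")
    for name, col in (
        ("md-partial", "md_partial"),
        ("lnhr-none", "lnhr_none"),
        ("lnhr-partial", "lnhr_partial"),
    ):
        if name in fits:
            other = fits[name].strain_effects.set_index("strain")["estimate"]
            tab[col] = tab["strain"].map(other)
    tab = tab.sort_values("md_none", ascending=False).reset_index(drop=True)
    return {"dataset": data, "fits": fits, "waterfall": tab}


# ---------------------------------------------------------------------
# bias / replicability / power grid

def _fit_safely(name: str, data: Dataset, variance_test: bool = True) -> PanelFit | None:
    try:
        return ESTIMATORS[name](data, variance_test=variance_test)
    except (RuntimeError, ValueError):
        return None


def run_grid(config: StudyConfig) -> pd.DataFrame:
    """Replicated paired-experiment study over the (n, CV_G) grid.

    For every cell, ``n_replicates`` pairs of experiments sharing
    strain effects are simulated; each selected estimator is applied to
    both members.  Per estimator the cell is summarised as a
    :class:`~drpanel.metrics.StudyCell`: median/IQR of the estimated
    CV_G (member one), mean between-pair correlation of strain-level
    estimates, and the proportion of significant variance tests
    (partial-pooling estimators only).  Cells with more than 20%
    failed fits are flagged in the output.
    """
    cells: list[dict] = []
    for n_per_arm in config.n_per_arm_grid:
        for cv in config.cv_g_grid:
            ss = _cell_seed(config, 1, n_per_arm, _cvg_key(cv))
            children = ss.spawn(config.n_replicates)
            per_est: dict[str, dict] = {
                name: {"cvg": [], "pairs": [], "pvals": [], "failed": 0,
                       "converged": 0}
                for name in config.estimators
            }
            for child in children:
                rng = np.random.default_rng(child)
                d1, d2 = simulate_paired_experiments(
                    config.design(n_per_arm), config.effect(cv), rng
                )
                for name in config.estimators:
                    f1 = _fit_safely(name, d1, variance_test=config.variance_tests)
                    f2 = _fit_safely(name, d2, variance_test=False)
                    if f1 is None or f2 is None:
                        per_est[name]["failed"] += 1
                        continue
                    # boundary fits (sigma_hat -> 0) are valid outcomes and
                    # are retained; only raised fits are dropped
                    if f1.converged and f2.converged:
                        per_est[name]["converged"] += 1
                    per_est[name]["cvg"].append(f1.cv_g)
                    per_est[name]["pairs"].append((f1, f2))
                    if f1.variance_test is not None and np.isfinite(
                        f1.variance_test[1]
                    ):
                        per_est[name]["pvals"].append(f1.variance_test[1])
            for name, acc in per_est.items():
                n_ok = acc["converged"]
                cvg = [c for c in acc["cvg"] if np.isfinite(c)]
                bs = bias_summary(cvg, cv) if cvg else None
                try:
                    rep = replicability(acc["pairs"])
                except ValueError:
                    rep = None
                power = (
                    power_estimate(acc["pvals"], config.alpha)
                    if acc["pvals"]
                    else np.nan
                )
                cell = StudyCell(
                    estimator=name,
                    n_per_arm=n_per_arm,
                    true_cv_g=cv,
                    cvg_median=bs.median if bs else np.nan,
                    cvg_iqr=bs.iqr if bs else np.nan,
                    cvg_bias=bs.bias if bs else np.nan,
                    replicability=rep.mean_correlation if rep else np.nan,
                    replicability_n_dropped=rep.n_dropped if rep else config.n_replicates,
                    power=power,
                    n_replicates=config.n_replicates,
                    n_converged=n_ok,
                )
                row = cell.as_row()
                row["flagged"] = acc["failed"] > 0.2 * config.n_replicates
                cells.append(row)
            log.info(
                "grid cell n=%d cv_g=%.3g done (%d replicates)",
                n_per_arm, cv, config.n_replicates,
            )
    return pd.DataFrame(cells)


# ---------------------------------------------------------------------
# power curve for the mixed-effects Cox variance test

def run_power_curve(
    config: StudyConfig,
    cv_g: float,
    n_grid: tuple | None = None,
) -> pd.DataFrame:
    """Power of the mixed-Cox variance LRT across per-arm sample sizes.

    Single (unpaired) experiments are simulated per replicate; power is
    the fraction of replicates with LRT p < alpha.  A binomial standard
    error accompanies each estimate.
    """
    n_grid = tuple(n_grid) if n_grid is not None else config.n_per_arm_grid
    rows = []
    for n_per_arm in n_grid:
        ss = _cell_seed(config, 2, n_per_arm, _cvg_key(cv_g))
        children = ss.spawn(config.n_replicates)
        pvals = []
        failed = 0
        for child in children:
            rng = np.random.default_rng(child)
            data = simulate_experiment(
                config.design(n_per_arm), config.effect(cv_g), rng
            )
            fit = _fit_safely("lnhr-partial", data)
            if fit is None or fit.variance_test is None:
                failed += 1
                continue
            pvals.append(fit.variance_test[1])
        power = power_estimate(pvals, config.alpha)
        rows.append(
            {
                "n_per_arm": n_per_arm,
                "true_cv_g": cv_g,
                "power": power,
                "binomial_se": float(
                    np.sqrt(power * (1 - power) / max(len(pvals), 1))
                ),
                "n_replicates": config.n_replicates,
                "n_converged": len(pvals),
                "flagged": failed > 0.2 * config.n_replicates,
            }
        )
        log.info("power point n=%d cv_g=%.3g: %.3f", n_per_arm, cv_g, power)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# re-analysis of user data

def reanalyze(data, alpha: float = 0.05) -> dict:
    """Apply all four estimators to a survival table.

    ``data`` may be a path to a ``strain,diet,age,event`` CSV, a
    DataFrame, or a :class:`Dataset`.  Strains missing a diet arm are
    excluded with a warning.  Returns a dict with the four ``fits``,
    a four-row ``comparison`` table (overall effect, sigma_hat, CV_G,
    variance LRT per estimator), MD- and lnHR-scale ``waterfall``
    tables, and the list of ``excluded`` strains.
    """
    if isinstance(data, (str,)) or hasattr(data, "__fspath__"):
        from .simulate import read_dataset_csv

        data = read_dataset_csv(data)
    df = data.records if isinstance(data, Dataset) else pd.DataFrame(data)
    df, excluded = drop_incomplete_strains(df)
    if excluded:
        log.warning("excluded strains missing a diet arm: %s", excluded)
    if df["strain"].nunique() < 2:
        raise ValueError(
            "re-analysis needs >= 2 strains with both diet arms; "
            f"got {df['strain'].nunique()}"
        )
    fits = {name: ESTIMATORS[name](df) for name in ALL_ESTIMATORS}
    comparison = pd.DataFrame(
        [
            {
                "estimator": name,
                "scale": f.scale,
                "pooling": f.pooling,
                "overall": f.overall,
                "overall_se": f.overall_se,
                "sigma_hat": f.sigma_hat,
                "cv_g": f.cv_g,
                "lrt_stat": f.variance_test[0] if f.variance_test else np.nan,
                "lrt_p": f.variance_test[1] if f.variance_test else np.nan,
                "n_flagged_strains": f.n_flagged,
            }
            for name, f in fits.items()
        ]
    )

    def waterfall(scale: str) -> pd.DataFrame:
        np_fit = fits[f"{scale}-none"]
        pp_fit = fits[f"{scale}-partial"]
        tab = np_fit.strain_effects[["strain", "estimate", "se", "p_value"]].rename(
            columns={"estimate": "no_pooling", "se": "no_pooling_se",
                     "p_value": "no_pooling_p"}
        )
        tab["sig"] = np.where(tab["no_pooling_p"] < alpha, "*", "")
        pp = pp_fit.strain_effects.set_index("strain")["estimate"]
        tab["partial_pooling"] = tab["strain"].map(pp)
        return tab.sort_values("no_pooling", ascending=False).reset_index(drop=True)

    return {
        "fits": fits,
        "comparison": comparison,
        "waterfall_md": waterfall("md"),
        "waterfall_lnhr": waterfall("lnhr"),
        "excluded": excluded,
    }


# ---------------------------------------------------------------------
# synthetic re-analysis fixture

def generate_fixture(
    path,
    n_strains: int = 40,
    n_range: tuple[int, int] = (10, 12),
    effect: EffectModel | None = None,
    gompertz: GompertzParams | None = None,
    seed: int = 20220826,
) -> Dataset:
    """Write a deterministic synthetic multi-strain survival CSV.

    Emulates a genetic-reference-panel mouse study with two diets and
    10-12 animals per strain per diet (the per-strain count varies to
    mimic realistic attrition); the default effect model has a
    protective overall effect with moderate among-strain variation in
    both the response and the baseline.  The file is byte-identical
    for a given seed.
    """
    from .gompertz import sample_death_times

    effect = effect or EffectModel(mu=-0.5, sigma_delta=0.25, sigma_alpha=0.1)
    gompertz = gompertz or GompertzParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    delta, alpha = draw_strain_effects(effect, n_strains, rng)
    lo, hi = n_range
    frames = []
    for j in range(n_strains):
        n_j = int(rng.integers(lo, hi + 1))
        al = sample_death_times(gompertz, n_j, shift=alpha[j], rng=rng)
        dr = sample_death_times(
            gompertz, n_j, shift=alpha[j] + effect.mu + delta[j], rng=rng
        )
        frames.append(
            pd.DataFrame(
                {
                    "strain": j + 1,
                    "diet": np.repeat([0, 1], n_j),
                    "age": np.concatenate([al, dr]),
                    "event": 1,
                }
            )
        )
    ds = Dataset(
        records=pd.concat(frames, ignore_index=True),
        true_delta=delta,
        true_alpha=alpha,
    )
    write_dataset_csv(ds, path)
    return ds
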