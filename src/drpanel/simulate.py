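"""Simulation of strain-by-diet lifespan panel experiments.

A genetic-reference-panel experiment exposes replicate animals from each
of several inbred strains to two diets: ad libitum (AL, diet = 0) and
dietary restriction (DR, diet = 1).  Death times follow a Gompertz
hazard; the DR effect for strain j is a proportional-hazards shift

    lnHR_j = mu + delta_j,        delta_j ~ N(0, sigma_delta^2),

so ``mu`` is the overall log hazard ratio of DR vs AL and
``sigma_delta`` the among-strain SD of the response.  An optional
strain-level baseline deviation ``alpha_j ~ N(0, sigma_alpha^2)``
(applied to both arms) models genetic variance in survival under AL;
by default it is switched off and survival under AL is homogeneous.

Datasets are plain tables with one row per animal and columns
``strain, diet, age, event`` (the same dialect used for re-analysis
input), plus the simulated true strain effects retained for
parameter-recovery checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gompertz import GompertzParams, sample_death_times

__all__ = [
    "EffectModel",
    "DesignSpec",
    "Dataset",
    "draw_strain_effects",
    "simulate_experiment",
    "simulate_paired_experiments",
    "read_dataset_csv",
    "write_dataset_csv",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ("strain", "diet", "age", "event")


@dataclass(frozen=True)
class EffectModel:
    """Distribution of the diet effect across strains.

    mu : overall log hazard ratio of DR vs AL (negative = protective).
    sigma_delta : among-strain SD of the diet effect (lnHR scale).
    sigma_alpha : among-strain SD of the AL baseline (lnHR scale);
        0 means homogeneous survival under AL.
    """

    mu: float = -0.5
    sigma_delta: float = 0.0
    sigma_alpha: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.sigma_delta < 0 or self.sigma_alpha < 0:
            raise ValueError("sigma_delta and sigma_alpha must be >= 0")


@dataclass(frozen=True)
class DesignSpec:
    """Balanced panel design: ``n_strains`` strains, ``n_per_strain_per_diet``
    animals in each diet arm of each strain."""

    n_strains: int = 40
    n_per_strain_per_diet: int = 5
    gompertz: GompertzParams = field(default_factory=GompertzParams)

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_per_strain_per_diet < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_records(self) -> int:
        return self.n_strains * 2 * self.n_per_strain_per_diet


@dataclass
class Dataset:
    """One simulated (or loaded) panel experiment.

    ``records`` has one row per animal with columns
    ``strain`` (int identifier), ``diet`` (0 = AL, 1 = DR),
    ``age`` (days), ``event`` (1 = death observed).  For simulated data
    the true strain-level deviations are kept for recovery tests.
    """

    records: pd.DataFrame
    true_delta: np.ndarray | None = None
    true_alpha: np.ndarray | None = None

    @property
    def strains(self) -> np.ndarray:
        return np.unique(self.records["strain"].to_numpy())

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def copy(self) -> "Dataset":
        return dataclasses.replace(self, records=self.records.copy())


def draw_strain_effects(
    effect: EffectModel, n_strains: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (delta, alpha): i.i.d. centred normal strain deviations.

    delta and alpha are mutually independent.  With a zero SD the
    corresponding vector is exactly zero.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    delta = rng.normal(0.0, effect.sigma_delta, size=n_strains) if effect.sigma_delta > 0 else np.zeros(n_strains)
    alpha = rng.normal(0.0, effect.sigma_alpha, size=n_strains) if effect.sigma_alpha > 0 else np.zeros(n_strains)
    return delta, alpha


def simulate_experiment(
    design: DesignSpec,
    effect: EffectModel,
    rng: np.random.Generator,
    strain_effects: tuple[np.ndarray, np.ndarray] | None = None,
) -> Dataset:
    """Simulate one balanced panel experiment.

    For strain j, AL animals die with hazard shift ``alpha_j`` and DR
    animals with shift ``alpha_j + mu + delta_j``.  All deaths are
    observed (event = 1).  ``strain_effects`` may be supplied to reuse a
    draw of (delta, alpha) across experiments, e.g. for paired
    replicability simulations.
    """
    if strain_effects is None:
        delta, alpha = draw_strain_effects(effect, design.n_strains, rng)
    else:
        delta, alpha = (np.asarray(v, dtype=float) for v in strain_effects)
        if len(delta) != design.n_strains or len(alpha) != design.n_strains:
            raise ValueError(
                f"strain_effects must have length n_strains={design.n_strains}"
            )

    n = design.n_per_strain_per_diet
    frames = []
    for j in range(design.n_strains):
        al_ages = sample_death_times(design.gompertz, n, shift=alpha[j], rng=rng)
        dr_ages = sample_death_times(
            design.gompertz, n, shift=alpha[j] + effect.mu + delta[j], rng=rng
        )
        frames.append(
            pd.DataFrame(
                {
                    "strain": j + 1,
                    "diet": np.repeat([0, 1], n),
                    "age": np.concatenate([al_ages, dr_ages]),
                    "event": 1,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return Dataset(records=records, true_delta=delta, true_alpha=alpha)


def simulate_paired_experiments(
    design: DesignSpec, effect: EffectModel, rng: np.random.Generator
) -> tuple[Dataset, Dataset]:
    """Two experiments on the same genotypes.

    One draw of (delta, alpha) is shared; death times are independent.
    This is the generative setup behind the between-experiment
    replicability metric.
    """
    shared = draw_strain_effects(effect, design.n_strains, rng)
    first = simulate_experiment(design, effect, rng, strain_effects=shared)
    second = simulate_experiment(design, effect, rng, strain_effects=shared)
    return first, second


def _validate_records(df: pd.DataFrame, source: str = "dataset") -> pd.DataFrame:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}; "
                         f"expected header {','.join(CSV_COLUMNS)}")
    df = df.loc[:, list(CSV_COLUMNS)].copy()
    for col, kind in (("diet", (0, 1)), ("event", (0, 1))):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~vals.isin(kind)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +2: header line and 0-based index
            raise ValueError(f"{source}: invalid {col} value at line {line}")
        df[col] = vals.astype(int)
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = ages.isna() | (ages <= 0)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{source}: invalid age at line {line} (must be positive)")
    df["age"] = ages.astype(float)
    return df


def read_dataset_csv(path) -> Dataset:
    """Read a ``strain,diet,age,event`` CSV into a :class:`Dataset`.

    Malformed rows raise ``ValueError`` naming the offending line.
    """
    df = pd.read_csv(path)
    return Dataset(records=_validate_records(df, source=str(path)))


def write_dataset_csv(dataset: Dataset, path) -> None:
    """Write the records table; ages with fixed 4-decimal formatting so
    the file is byte-identical across runs with the same seed."""
    dataset.records.to_csv(path, index=False, float_format="%.4f")
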