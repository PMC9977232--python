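"""Panel estimators of among-strain variance in the diet response.

Four estimators, crossed over two axes:

* **Scale** — mean difference in age at death (MD, days) or log hazard
  ratio (lnHR, dimensionless).
* **Pooling** — *no pooling* fits every strain separately and takes
  the SD of the per-strain estimates (which conflates sampling and
  biological variance), while *partial pooling* fits one mixed model
  whose strain-level effects are shrunken toward the overall effect and
  whose variance component estimates the among-strain SD directly.

The API follows the model/results convention: construct a
:class:`MeanDifferencePanel` or :class:`HazardRatioPanel` from a
dataset, call :meth:`fit`, and receive a :class:`PanelFit` carrying the
overall effect, the among-strain SD ``sigma_hat``, the unitless
``cv_g = sigma_hat / |overall|``, per-strain effects and the variance
likelihood-ratio test.

The linear mixed model is fitted with statsmodels (random intercept +
random diet slope, independent components, REML for the reported
variance, ML refits for the LRT).  The mixed-effects Cox model is the
package's own penalized-partial-likelihood implementation
(:mod:`drpanel.mixedcox`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import BETA_CAP, fit_cox
from .metrics import cv_g as _cv_g
from .mixedcox import fit_mixed_cox
from .simulate import Dataset

__all__ = [
    "PanelFit",
    "MeanDifferencePanel",
    "HazardRatioPanel",
    "fit_md_no_pooling",
    "fit_md_partial_pooling",
    "fit_lnhr_no_pooling",
    "fit_lnhr_partial_pooling",
    "drop_incomplete_strains",
    "ESTIMATORS",
]


@dataclass
class PanelFit:
    """One estimator's output on one panel dataset.

    ``strain_effects`` has one row per strain with columns ``strain``,
    ``estimate`` (on the analysis scale; shrunken values under partial
    pooling), ``se``, ``p_value``, ``p_holm`` and ``flagged``.  Partial
    pooling provides no per-strain test, so ``se``/``p_value`` are NaN
    there by design.
    """

    scale: str                  # "md" or "lnhr"
    pooling: str                # "none" or "partial"
    overall: float
    overall_se: float
    sigma_hat: float
    cv_g: float
    strain_effects: pd.DataFrame
    loglik: float | None = None
    variance_test: tuple[float, float] | None = None  # (LRT stat, p)
    converged: bool = True
    n_flagged: int = 0
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Panel fit: scale={self.scale}, pooling={self.pooling}",
            f"  strains: {len(self.strain_effects)}"
            + (f" ({self.n_flagged} flagged)" if self.n_flagged else ""),
            f"  overall effect: {self.overall:.4g} (se {self.overall_se:.4g})",
            f"  among-strain SD (sigma_hat): {self.sigma_hat:.4g}",
            f"  CV_G: {self.cv_g:.4g}",
        ]
        if self.variance_test is not None:
            stat, p = self.variance_test
            lines.append(f"  variance LRT: stat={stat:.4g}, p={p:.4g}")
        if self.loglik is not None:
            lines.append(f"  log-likelihood: {self.loglik:.6g}")
        if not self.converged:
            lines.append("  WARNING: fit did not converge cleanly")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per strain plus a trailing summary row."""
        rows = self.strain_effects.copy()
        rows.insert(0, "row_type", "strain")
        rows["scale"] = self.scale
        rows["pooling"] = self.pooling
        summary = pd.DataFrame(
            [
                {
                    "row_type": "summary",
                    "strain": "",
                    "scale": self.scale,
                    "pooling": self.pooling,
                    "estimate": self.overall,
                    "se": self.overall_se,
                    "sigma_hat": self.sigma_hat,
                    "cv_g": self.cv_g,
                    "lrt_stat": self.variance_test[0] if self.variance_test else np.nan,
                    "lrt_p": self.variance_test[1] if self.variance_test else np.nan,
                }
            ]
        )
        return pd.concat([rows, summary], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _as_records(data) -> pd.DataFrame:
    if isinstance(data, Dataset):
        return data.records
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError("expected a Dataset or records DataFrame")


def drop_incomplete_strains(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Remove strains that lack animals in one of the two diet arms."""
    arms = df.groupby("strain")["diet"].nunique()
    bad = arms[arms < 2].index.tolist()
    if bad:
        df = df[~df["strain"].isin(bad)].copy()
    return df, bad


def _holm(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


class _PanelModel:
    """Shared construction/validation for the two panel models."""

    def __init__(self, data):
        df = _as_records(data)
        required = {"strain", "diet", "age", "event"}
        if not required.issubset(df.columns):
            raise ValueError(f"records need columns {sorted(required)}")
        self.records = df.reset_index(drop=True)
        self.strains = np.unique(self.records["strain"].to_numpy())
        if len(self.strains) < 2:
            raise ValueError(
                "at least 2 strains are required to estimate among-strain "
                "variance (got "
                f"{len(self.strains)})"
            )
        arms = self.records.groupby("strain")["diet"].nunique()
        incomplete = arms[arms < 2].index.tolist()
        if incomplete:
            raise ValueError(
                f"strains {incomplete} lack one diet arm; drop them first "
                "(see drop_incomplete_strains)"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        return cls(df)

    @classmethod
    def from_csv(cls, path):
        from .simulate import read_dataset_csv

        return cls(read_dataset_csv(path))

    def _groups(self):
        codes = pd.Categorical(
            self.records["strain"], categories=self.strains
        ).codes.astype(int)
        return codes


class MeanDifferencePanel(_PanelModel):
    """Diet effect measured as the difference in mean age at death (days)."""

    def fit(
        self,
        pooling: str = "partial",
        boundary_mixture: bool = False,
        variance_test: bool = True,
    ) -> PanelFit:
        if pooling == "none":
            return self._fit_none()
        if pooling == "partial":
            return self._fit_partial(boundary_mixture, variance_test)
        raise ValueError("pooling must be 'none' or 'partial'")

    # -- no pooling: per-strain two-sample comparison ------------------
    def _fit_none(self) -> PanelFit:
        rows = []
        for strain, sub in self.records.groupby("strain", sort=True):
            al = sub.loc[sub["diet"] == 0, "age"].to_numpy()
            dr = sub.loc[sub["diet"] == 1, "age"].to_numpy()
            est = dr.mean() - al.mean()
            n0, n1 = len(al), len(dr)
            if n0 >= 2 and n1 >= 2:
                sp2 = ((n0 - 1) * al.var(ddof=1) + (n1 - 1) * dr.var(ddof=1)) / (
                    n0 + n1 - 2
                )
                se = np.sqrt(sp2 * (1 / n0 + 1 / n1))
                if se > 0:
                    t = est / se
                    p = 2 * stats.t.sf(abs(t), df=n0 + n1 - 2)
                else:
                    p = 0.0 if est != 0 else 1.0
                flagged = False
            else:
                se, p, flagged = np.nan, np.nan, True
            rows.append(
                {"strain": strain, "estimate": est, "se": se, "p_value": p,
                 "flagged": flagged}
            )
        tab = pd.DataFrame(rows)
        tab["p_holm"] = _holm(tab["p_value"].to_numpy())
        tab = tab[["strain", "estimate", "se", "p_value", "p_holm", "flagged"]]
        est = tab["estimate"].to_numpy()
        overall = float(np.mean(est))
        sigma_hat = float(np.std(est, ddof=1))
        se_ok = tab["se"].to_numpy()
        overall_se = float(
            np.sqrt(np.nansum(se_ok**2)) / len(est)
        )  # mean of independent per-strain estimates
        return PanelFit(
            scale="md",
            pooling="none",
            overall=overall,
            overall_se=overall_se,
            sigma_hat=sigma_hat,
            cv_g=_cv_g(sigma_hat, overall),
            strain_effects=tab,
            n_flagged=int(tab["flagged"].sum()),
        )

    # -- partial pooling: linear mixed model ---------------------------
    def _fit_partial(self, boundary_mixture: bool, variance_test_wanted: bool = True) -> PanelFit:
        from statsmodels.regression.mixed_linear_model import (
            MixedLM,
            MixedLMParams,
        )

        df = self.records
        endog = df["age"].to_numpy(dtype=float)
        # centre the diet indicator: with +-0.5 coding the random
        # intercept (strain level) and random slope (strain MD) are
        # orthogonal under balanced arms, so the slope BLUP is a pure
        # shrinkage of each strain's raw mean difference; the fixed
        # slope coefficient is unchanged by the shift
        diet_c = df["diet"].to_numpy(dtype=float) - 0.5
        exog = np.column_stack([np.ones(len(df)), diet_c])
        exog_re = exog
        groups = self._groups()

        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2)
        )

        def _fit(reml, re_cols):
            model = MixedLM(endog, exog, groups=groups, exog_re=exog_re[:, re_cols])
            kwargs = {"reml": reml}
            if len(re_cols) == 2:
                kwargs["free"] = free
            last_err = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for method in ("lbfgs", "bfgs", "cg", "powell"):
                    try:
                        res = model.fit(method=method, maxiter=500, **kwargs)
                    except Exception as err:  # singular fits, linalg failures
                        last_err = err
                        continue
                    if np.isfinite(res.llf):
                        return res
            raise RuntimeError(f"linear mixed model failed to fit: {last_err}")

        res = _fit(reml=True, re_cols=[0, 1])
        converged = bool(getattr(res, "converged", True))
        overall = float(res.fe_params[1])
        overall_se = float(res.bse_fe[1])
        sigma2_slope = float(np.asarray(res.cov_re)[1, 1])
        sigma_hat = float(np.sqrt(max(sigma2_slope, 0.0)))

        blups = res.random_effects
        rows = []
        for code, strain in enumerate(self.strains):
            dev = float(np.asarray(blups[code])[1])
            rows.append(
                {"strain": strain, "estimate": overall + dev, "se": np.nan,
                 "p_value": np.nan, "p_holm": np.nan, "flagged": False}
            )
        tab = pd.DataFrame(rows)

        # variance LRT: ML fits of slope+intercept vs intercept-only
        variance_test = None
        if variance_test_wanted:
            try:
                full_ml = _fit(reml=False, re_cols=[0, 1])
                null_ml = _fit(reml=False, re_cols=[0])
                stat = max(0.0, 2.0 * (full_ml.llf - null_ml.llf))
                if boundary_mixture:
                    p = 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
                else:
                    p = float(stats.chi2.sf(stat, 1))
                variance_test = (float(stat), p)
            except RuntimeError:
                variance_test = (np.nan, np.nan)
                converged = False

        return PanelFit(
            scale="md",
            pooling="partial",
            overall=overall,
            overall_se=overall_se,
            sigma_hat=sigma_hat,
            cv_g=_cv_g(sigma_hat, overall),
            strain_effects=tab,
            loglik=float(res.llf),
            variance_test=variance_test,
            converged=converged,
        )


class HazardRatioPanel(_PanelModel):
    """Diet effect measured as the log hazard ratio of DR vs AL."""

    def fit(
        self,
        pooling: str = "partial",
        boundary_mixture: bool = False,
        variance_test: bool = True,
    ) -> PanelFit:
        # the mixed-Cox variance test is a by-product of the outer
        # search, so variance_test=False has nothing to skip here
        del variance_test
        if pooling == "none":
            return self._fit_none()
        if pooling == "partial":
            return self._fit_partial(boundary_mixture)
        raise ValueError("pooling must be 'none' or 'partial'")

    # -- no pooling: per-strain Cox fits -------------------------------
    def _fit_none(self) -> PanelFit:
        rows = []
        for strain, sub in self.records.groupby("strain", sort=True):
            try:
                f = fit_cox(
                    sub["age"].to_numpy(),
                    sub["event"].to_numpy(),
                    sub["diet"].to_numpy(),
                )
                rows.append(
                    {"strain": strain, "estimate": f.lnhr, "se": f.se,
                     "p_value": f.p_value, "flagged": f.separated}
                )
            except ValueError:
                # no event in one arm: lnHR not estimable for this strain
                rows.append(
                    {"strain": strain, "estimate": np.nan, "se": np.nan,
                     "p_value": np.nan, "flagged": True}
                )
        tab = pd.DataFrame(rows)
        tab["p_holm"] = _holm(
            np.where(tab["flagged"], np.nan, tab["p_value"].to_numpy())
        )
        tab = tab[["strain", "estimate", "se", "p_value", "p_holm", "flagged"]]
        ok = ~tab["flagged"].to_numpy()
        est = tab.loc[ok, "estimate"].to_numpy()
        if len(est) < 2:
            raise ValueError("fewer than 2 strains with an estimable lnHR")
        overall = float(np.mean(est))
        sigma_hat = float(np.std(est, ddof=1))
        overall_se = float(
            np.sqrt(np.nansum(tab.loc[ok, "se"].to_numpy() ** 2)) / len(est)
        )
        return PanelFit(
            scale="lnhr",
            pooling="none",
            overall=overall,
            overall_se=overall_se,
            sigma_hat=sigma_hat,
            cv_g=_cv_g(sigma_hat, overall),
            strain_effects=tab,
            n_flagged=int(tab["flagged"].sum()),
            diagnostics={"n_excluded_from_sigma": int((~ok).sum())},
        )

    # -- partial pooling: mixed-effects Cox ----------------------------
    def _fit_partial(self, boundary_mixture: bool) -> PanelFit:
        df = self.records
        fit = fit_mixed_cox(
            df["age"].to_numpy(),
            df["event"].to_numpy(),
            df["diet"].to_numpy(),
            group=self._groups(),
            strains=self.strains,
            boundary_mixture=boundary_mixture,
        )
        tab = pd.DataFrame(
            {
                "strain": self.strains,
                "estimate": fit.lnhr_by_strain,
                "se": np.nan,
                "p_value": np.nan,
                "p_holm": np.nan,
                "flagged": False,
            }
        )
        return PanelFit(
            scale="lnhr",
            pooling="partial",
            overall=fit.overall,
            overall_se=fit.overall_se,
            sigma_hat=fit.sigma_hat,
            cv_g=_cv_g(fit.sigma_hat, fit.overall),
            strain_effects=tab,
            loglik=fit.integrated_loglik,
            variance_test=fit.variance_test,
            converged=fit.converged,
            diagnostics=fit.diagnostics,
        )


# ---------------------------------------------------------------------
# functional entry points

def fit_md_no_pooling(data, **kw) -> PanelFit:
    return MeanDifferencePanel(data).fit(pooling="none")


def fit_md_partial_pooling(data, boundary_mixture: bool = False,
                           variance_test: bool = True) -> PanelFit:
    return MeanDifferencePanel(data).fit(
        pooling="partial", boundary_mixture=boundary_mixture,
        variance_test=variance_test,
    )


def fit_lnhr_no_pooling(data, **kw) -> PanelFit:
    return HazardRatioPanel(data).fit(pooling="none")


def fit_lnhr_partial_pooling(data, boundary_mixture: bool = False,
                             variance_test: bool = True) -> PanelFit:
    return HazardRatioPanel(data).fit(
        pooling="partial", boundary_mixture=boundary_mixture,
        variance_test=variance_test,
    )


ESTIMATORS = {
    "md-none": fit_md_no_pooling,
    "md-partial": fit_md_partial_pooling,
    "lnhr-none": fit_lnhr_no_pooling,
    "lnhr-partial": fit_lnhr_partial_pooling,
}
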