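"""Longitudinal inference on fractal-dimension records.

Follow-up panels of implant patients are unbalanced — not every patient is
imaged at every one of the 0/3/6/12-month visits — so changes over time are
evaluated with mixed models: a linear mixed model with a per-patient random
intercept (default), or a GEE with exchangeable working correlation as an
alternative with the same fixed-effect structure.  Effects of time, jaw,
sex and age are reported as Wald chi-square tests, with pairwise contrasts
of each follow-up against baseline.  Independent groups (e.g. sexes) are
compared with a t-test.

The module follows the Model/Results idiom: build a
:class:`LongitudinalFdModel` from the FD table, call :meth:`fit`, and read
estimates, Wald contrasts and the summary table off the returned
:class:`LongitudinalFdResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDesignError, InputError

__all__ = [
    "WaldContrast",
    "TwoGroupTest",
    "LongitudinalFdModel",
    "LongitudinalFdResults",
    "two_group_test",
    "summarize",
    "validate_study",
]

_EFFECT_TERMS = {
    "time": "C(timepoint_months, Treatment(0))",
    "jaw": "C(jaw)",
    "sex": "C(sex)",
    "age": "age",
}


@dataclass(frozen=True)
class WaldContrast:
    """One Wald chi-square test on the fitted fixed effects."""

    label: str
    estimate: float
    wald_chi2: float
    df: int
    p_value: float
    p_holm: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "label": self.label, "estimate": self.estimate,
            "wald_chi2": self.wald_chi2, "df": self.df, "p": self.p_value,
            "p_holm": self.p_holm,
        }


@dataclass(frozen=True)
class TwoGroupTest:
    statistic: float
    p_value: float
    df: float
    variant: str


def validate_study(data: pd.DataFrame) -> pd.DataFrame:
    """Check the panel invariants: one row per (patient, timepoint), at
    least two timepoints per patient, fd_mean present and finite."""
    required = {"patient_id", "timepoint_months", "fd_mean"}
    missing = required - set(data.columns)
    if missing:
        raise InputError(f"FD table is missing columns: {sorted(missing)}")
    if data["fd_mean"].isna().any() or not np.isfinite(data["fd_mean"]).all():
        raise InputError("fd_mean contains missing or non-finite values")
    dup = data.duplicated(subset=["patient_id", "timepoint_months"])
    if dup.any():
        raise InputError("duplicate (patient_id, timepoint) rows in FD table")
    per_patient = data.groupby("patient_id")["timepoint_months"].nunique()
    if (per_patient < 2).any():
        bad = per_patient[per_patient < 2].index.tolist()
        raise InputError(f"patients with fewer than two timepoints: {bad}")
    return data


class LongitudinalFdModel:
    """Mixed model for FD change over time on an unbalanced panel.

    Parameters
    ----------
    data : DataFrame with columns patient_id, timepoint_months, fd_mean and
        the covariates named in ``fixed_effects``.
    fixed_effects : subset of {"time", "jaw", "sex", "age"}; time enters as
        a categorical with month 0 as the reference level, age as
        continuous.
    method : "lmm" for a linear mixed model with per-patient random
        intercept, "gee" for generalized estimating equations with
        exchangeable working correlation.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        fixed_effects: Sequence[str] = ("time", "jaw"),
        method: str = "lmm",
    ):
        bad = [e for e in fixed_effects if e not in _EFFECT_TERMS]
        if bad:
            raise InputError(f"unknown fixed effects: {bad}")
        if method not in ("lmm", "gee"):
            raise InputError("method must be 'lmm' or 'gee'")
        data = validate_study(pd.DataFrame(data))
        if "time" in fixed_effects and data["timepoint_months"].nunique() < 2:
            raise DegenerateDesignError(
                "a time effect needs at least two distinct timepoints"
            )
        self.data = data.reset_index(drop=True)
        self.fixed_effects = tuple(fixed_effects)
        self.method = method
        self.formula = "fd_mean ~ " + " + ".join(
            _EFFECT_TERMS[e] for e in self.fixed_effects
        )

    @classmethod
    def from_records(cls, records, **kwargs) -> "LongitudinalFdModel":
        """Build from an iterable of FdRecord objects (incomplete records,
        which have no mean FD, are dropped)."""
        rows = [r.to_dict() for r in records if r.complete]
        return cls(pd.DataFrame(rows), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LongitudinalFdModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "LongitudinalFdResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.method == "lmm":
                mod = smf.mixedlm(self.formula, self.data, groups=self.data["patient_id"])
                res = mod.fit(reml=True, method="lbfgs")
                converged = bool(res.converged)
                params = res.fe_params
                k = len(params)
                cov = pd.DataFrame(
                    np.asarray(res.cov_params())[:k, :k],
                    index=params.index, columns=params.index,
                )
                scale = float(res.scale)
                group_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
            else:
                mod = smf.gee(
                    self.formula, groups="patient_id", data=self.data,
                    cov_struct=sm.cov_struct.Exchangeable(),
                )
                res = mod.fit()
                converged = True
                params = res.params
                cov = pd.DataFrame(
                    np.asarray(res.cov_params()),
                    index=params.index, columns=params.index,
                )
                scale = float(res.scale)
                group_var = float("nan")
        return LongitudinalFdResults(
            model=self, _sm_result=res, params=params, cov_params=cov,
            converged=converged, scale=scale, group_var=group_var,
        )


class LongitudinalFdResults:
    """Fitted-model container: estimates, Wald tests, contrasts, summary."""

    def __init__(self, model, _sm_result, params, cov_params, converged, scale, group_var):
        self.model = model
        self._sm_result = _sm_result
        self.params = params
        self.cov_params = cov_params
        self.converged = converged
        self.scale = scale
        self.group_var = group_var
        if not converged:
            self.diagnostics = {
                "converged": False,
                "message": "optimizer did not converge; estimates are provisional",
            }
        else:
            self.diagnostics = {"converged": True}

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def _term_names(self, effect: str) -> list[str]:
        term = _EFFECT_TERMS[effect]
        if effect == "age":
            return [n for n in self.params.index if n == "age"]
        return [n for n in self.params.index if n.startswith(term + "[")]

    def wald_effect_test(self, effect: str) -> WaldContrast:
        """Joint Wald chi-square that all coefficients of one fixed effect
        are zero (df = number of coefficients)."""
        names = self._term_names(effect)
        if not names:
            raise InputError(f"effect {effect!r} is not in the fitted model")
        beta = self.params[names].to_numpy()
        v = self.cov_params.loc[names, names].to_numpy()
        chi2 = float(beta @ np.linalg.solve(v, beta))
        df = len(names)
        p = float(sps.chi2.sf(chi2, df))
        est = float(beta[0]) if df == 1 else float("nan")
        return WaldContrast(label=effect, estimate=est, wald_chi2=chi2, df=df, p_value=p)

    def time_contrasts(self) -> list[WaldContrast]:
        """Pairwise Wald tests of each follow-up month against baseline
        (month 0), Holm-adjusted p-values attached alongside the unadjusted
        ones."""
        names = self._term_names("time")
        if not names:
            raise InputError("the fitted model has no time effect")
        out = []
        for name in names:
            month = name.split("[T.")[1].rstrip("]")
            beta = float(self.params[name])
            se = float(np.sqrt(self.cov_params.loc[name, name]))
            chi2 = (beta / se) ** 2
            out.append(WaldContrast(
                label=f"month 0 vs month {month}", estimate=beta,
                wald_chi2=float(chi2), df=1, p_value=float(sps.chi2.sf(chi2, 1)),
            ))
        holm = multipletests([c.p_value for c in out], method="holm")[1]
        return [
            WaldContrast(label=c.label, estimate=c.estimate, wald_chi2=c.wald_chi2,
                         df=c.df, p_value=c.p_value, p_holm=float(ph))
            for c, ph in zip(out, holm)
        ]

    def effect_estimate(self, effect: str) -> float:
        """Point estimate of a single-coefficient effect (jaw, sex, age)."""
        names = self._term_names(effect)
        if len(names) != 1:
            raise InputError(f"effect {effect!r} has {len(names)} coefficients")
        return float(self.params[names[0]])

    def summary(self) -> str:
        lines = [
            f"Longitudinal FD model ({'linear mixed model' if self.model.method == 'lmm' else 'GEE, exchangeable'})",
            f"  observations: {len(self.model.data)}   patients: {self.model.data['patient_id'].nunique()}",
            f"  fixed effects: {', '.join(self.model.fixed_effects)}",
            f"  converged: {self.converged}",
            "",
            f"  {'coefficient':<42s} {'estimate':>10s} {'SE':>8s}",
        ]
        for name in self.params.index:
            lines.append(f"  {name:<42s} {self.params[name]:>10.4f} {self.bse[name]:>8.4f}")
        if np.isfinite(self.group_var):
            lines.append(f"  patient random-intercept variance: {self.group_var:.5f}")
        lines.append(f"  residual variance: {self.scale:.5f}")
        lines.append("")
        lines.append(f"  {'Wald contrast':<24s} {'chi2':>8s} {'df':>3s} {'p':>8s} {'p(Holm)':>8s}")
        if "time" in self.model.fixed_effects:
            for c in self.time_contrasts():
                lines.append(
                    f"  {c.label:<24s} {c.wald_chi2:>8.3f} {c.df:>3d} "
                    f"{c.p_value:>8.4f} {c.p_holm:>8.4f}"
                )
        for effect in self.model.fixed_effects:
            c = self.wald_effect_test(effect)
            lines.append(
                f"  {c.label:<24s} {c.wald_chi2:>8.3f} {c.df:>3d} {c.p_value:>8.4f} {'':>8s}"
            )
        return "\n".join(lines)

    def contrasts_frame(self) -> pd.DataFrame:
        rows = [c.to_dict() for c in self.time_contrasts()]
        rows += [self.wald_effect_test(e).to_dict() for e in self.model.fixed_effects]
        return pd.DataFrame(rows)


def two_group_test(
    values_a, values_b, *, variant: str = "welch"
) -> TwoGroupTest:
    """Two-sided t-test between independent groups.

    Welch (unequal variances) by default; ``variant='student'`` pools the
    variances.  Groups need at least two observations each and non-zero
    combined variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputError("groups contain non-finite values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return TwoGroupTest(statistic=0.0, p_value=1.0,
                                df=float(a.size + b.size - 2), variant=variant)
        raise InputError("degenerate groups: zero variance with unequal means")
    equal_var = variant == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return TwoGroupTest(
        statistic=float(res.statistic), p_value=float(res.pvalue), df=df,
        variant=variant,
    )


def _margin(values: pd.Series) -> dict:
    n = int(values.size)
    sd_undefined = n < 2
    return {
        "N": n,
        "mean": float(values.mean()),
        "SD": 0.0 if sd_undefined else float(values.std(ddof=1)),
        "min": float(values.min()),
        "max": float(values.max()),
        "sd_undefined": sd_undefined,
    }


def summarize(data: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table of fd_mean by sex, time and jaw with totals.

    One row per (factor, level) plus a Total row per factor; SD uses the
    n-1 denominator and is reported as 0 with ``sd_undefined=True`` for
    single-record margins.
    """
    if len(data) == 0:
        raise InputError("cannot summarize an empty FD table")
    rows = []
    factors = [
        ("sex", "Sex", {"female": "Women", "male": "Men"}),
        ("timepoint_months", "Time", {0: "0. Month", 3: "3. Month", 6: "6. Month", 12: "12. Month"}),
        ("jaw", "Jaw", {"maxilla": "Maxilla", "mandible": "Mandible"}),
    ]
    for col, factor_label, level_labels in factors:
        if col not in data.columns:
            continue
        for level, label in level_labels.items():
            sub = data.loc[data[col] == level, "fd_mean"]
            if sub.size == 0:
                continue
            rows.append({"factor": factor_label, "level": label, **_margin(sub)})
        rows.append({"factor": factor_label, "level": "Total", **_margin(data["fd_mean"])})
    return pd.DataFrame(rows)
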