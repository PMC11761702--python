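"""Longitudinal mixed-effects models for skilled-reaching learning curves.

The central model is a linear mixed-effects regression of a per-session
outcome (number of successful reaches, success rate, or mean stereotypy)
on log(day), stimulation group, and their interaction, with a random
intercept per animal:

    y_id = β0 + β1·log(d) + β2·G_i + β3·G_i·log(d) + b_i + ε_id,
    b_i ~ N(0, σ_a²),  ε_id ~ N(0, σ²),

where G_i = 1 for anodal tDCS and 0 for control. Days are coded on a
natural-log scale (day 1 = 0) to capture the saturating learning curve;
a stimulation effect that accumulates with practice appears as the
interaction β3. Missing sessions are handled by likelihood, so unbalanced
tables need no imputation.

The module follows the Model/Results idiom: build a
:class:`MixedLearningModel` from a tidy table, call :meth:`fit`, and read
coefficients, t/F statistics and p-values off the returned
:class:`LearningFitResults` (or print :meth:`~LearningFitResults.summary`).
t and F statistics are reported on the residual degrees of freedom
(n_obs − n_fixed); none of the reported p-values are corrected for
multiple comparisons, and fits across outcomes are exploratory companions
to a single planned primary contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

LEARNING_COLUMNS = ("animal_id", "day", "group", "paw", "successes", "attempts")


def validate_learning_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the animal × day learning table invariants.

    Required columns: animal_id, day (1-based), group (anodal/control),
    paw (left/right), successes, attempts; successes ≤ attempts; each
    animal in exactly one group.
    """
    missing = [c for c in LEARNING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"learning table lacks column(s): {', '.join(missing)}")
    if (table["day"] < 1).any():
        raise ValueError("day must be >= 1")
    if (table["successes"] > table["attempts"]).any():
        raise ValueError("successes must not exceed attempts")
    bad_group = set(table["group"]) - {"anodal", "control"}
    if bad_group:
        raise ValueError(f"unknown group label(s): {sorted(bad_group)}")
    n_groups = table.groupby("animal_id")["group"].nunique()
    if (n_groups > 1).any():
        raise ValueError("each animal must belong to exactly one group")
    return table


@dataclass
class LearningFitResults:
    """Results of a mixed-effects learning-curve fit.

    Wald t statistics are coefficient / SE on ``df_resid`` residual
    degrees of freedom; single-df F statistics are t². ``wrapped`` holds
    the underlying statsmodels MixedLMResults for diagnostics.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalues: pd.Series
    df_resid: int
    n_obs: int
    n_groups: int
    group_var: float  # random-intercept variance
    resid_var: float  # residual variance
    converged: bool
    model_desc: str = ""
    n_dropped: int = 0
    wrapped: object = field(default=None, repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided (1 − alpha) Wald confidence intervals on residual-df t."""
        tcrit = sps.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {
                "lower": self.params - tcrit * self.bse,
                "upper": self.params + tcrit * self.bse,
            }
        )

    def coef_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "F": self.fvalues,
                "p": self.pvalues,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Mixed-effects learning model: {self.model_desc}",
            f"n_obs={self.n_obs}  animals={self.n_groups}  "
            f"df_resid={self.df_resid}  converged={self.converged}",
            f"random-intercept var={self.group_var:.4g}  "
            f"residual var={self.resid_var:.4g}",
        ]
        if self.n_dropped:
            lines.append(f"rows dropped (missing/invalid response): {self.n_dropped}")
        lines.append(
            self.coef_table().to_string(float_format=lambda v: f"{v: .4g}")
        )
        lines.append("p-values are not corrected for multiple comparisons.")
        return "\n".join(lines)


class MixedLearningModel:
    """Linear mixed model with a per-animal random intercept.

    Parameters
    ----------
    data : DataFrame
        One row per animal × session (or trial) with the response and
        design columns already present.
    response : str
        Column holding the outcome.
    fixed : list of str
        Fixed-effect design columns (an intercept is always added).
    groups : str
        Column identifying the random-effect grouping factor (animal).
    re_formula : str or None
        Optional random-effects structure, e.g. ``"~logday"`` adds a
        random log-day slope; None keeps the random intercept only.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        fixed: list[str],
        groups: str = "animal_id",
        re_formula: str | None = None,
    ) -> None:
        cols = [response, groups, *fixed]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks column(s): {', '.join(missing)}")
        n0 = len(data)
        data = data.dropna(subset=[response]).copy()
        self.n_dropped = n0 - len(data)
        if self.n_dropped:
            logger.info("dropped %d rows with missing response", self.n_dropped)
        self.data = data
        self.response = response
        self.fixed = list(fixed)
        self.groups = groups
        self.re_formula = re_formula
        self.formula = f"{response} ~ {' + '.join(fixed) if fixed else '1'}"

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_learning_table(
        cls,
        table: pd.DataFrame,
        response: str = "successes",
        re_formula: str | None = None,
    ) -> "MixedLearningModel":
        """Build the log-day × group model from an animal × day table.

        ``response`` may be ``"successes"``, ``"rate"`` (successes /
        attempts; rows with zero attempts are dropped and counted), or any
        numeric column such as ``mean_stereotypy``.
        """
        table = validate_learning_table(table).copy()
        n_zero_attempts = 0
        if response == "rate":
            zero = table["attempts"] == 0
            n_zero_attempts = int(zero.sum())
            if n_zero_attempts:
                logger.info("dropping %d rows with zero attempts", n_zero_attempts)
                table = table.loc[~zero].copy()
            table["rate"] = table["successes"] / table["attempts"]
        table["logday"] = np.log(table["day"].astype(float))
        table["tdcs"] = (table["group"] == "anodal").astype(float)
        table["tdcs_x_logday"] = table["tdcs"] * table["logday"]
        model = cls(
            table,
            response=response,
            fixed=["logday", "tdcs", "tdcs_x_logday"],
            re_formula=re_formula,
        )
        model.n_dropped += n_zero_attempts
        return model

    @classmethod
    def from_trial_scores(
        cls,
        records: pd.DataFrame,
        group_by_animal: pd.Series | dict,
        *,
        paw: str | None = None,
        paw_by_animal: pd.Series | dict | None = None,
        success: bool | None = None,
        re_formula: str | None = None,
    ) -> "MixedLearningModel":
        """Per-trial stereotypy model: score ~ log(day) × tDCS, animal random.

        ``records`` is the per-trial stereotypy table (columns animal_id,
        day, score, success). ``paw`` optionally restricts to one
        paw-preference subset (requires ``paw_by_animal``); ``success``
        optionally stratifies into successful or unsuccessful trials.
        """
        df = records.copy()
        df["group"] = df["animal_id"].map(dict(group_by_animal))
        if df["group"].isna().any():
            raise ValueError("every animal needs a group assignment")
        if paw is not None:
            if paw_by_animal is None:
                raise ValueError("paw subsetting requires paw_by_animal")
            df["paw"] = df["animal_id"].map(dict(paw_by_animal))
            df = df.loc[df["paw"] == paw].copy()
        if success is not None:
            df = df.loc[df["success"] == success].copy()
        df["logday"] = np.log(df["day"].astype(float))
        df["tdcs"] = (df["group"] == "anodal").astype(float)
        df["tdcs_x_logday"] = df["tdcs"] * df["logday"]
        return cls(
            df,
            response="score",
            fixed=["logday", "tdcs", "tdcs_x_logday"],
            re_formula=re_formula,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, reml: bool = True) -> LearningFitResults:
        """Fit by (restricted) maximum likelihood.

        Non-convergence is flagged on the results object together with the
        optimizer diagnostics; there is no silent fallback to a simpler
        model.
        """
        endog = self.data[self.response].astype(float)
        exog = sm.add_constant(self.data[self.fixed].astype(float), has_constant="add")
        exog = exog.rename(columns={"const": "Intercept"})
        groups = self.data[self.groups]
        if self.re_formula is not None:
            model = sm.MixedLM.from_formula(
                f"{self.response} ~ {' + '.join(self.fixed)}",
                data=self.data,
                groups=groups,
                re_formula=self.re_formula,
            )
        else:
            model = sm.MixedLM(endog, exog, groups=groups)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml)
                converged = bool(getattr(res, "converged", True))
            except Exception as exc:  # singular fits at degenerate inputs
                logger.warning("MixedLM optimizer failed (%s); flagged", exc)
                res = model.fit(reml=reml, method="cg", maxiter=2000)
                converged = False
            names = (
                list(exog.columns)
                if self.re_formula is None
                else list(res.fe_params.index)
            )
            params = pd.Series(np.asarray(res.fe_params)[: len(names)], index=names)
            bse = pd.Series(np.asarray(res.bse_fe)[: len(names)], index=names)
        df_resid = max(int(len(endog) - len(names)), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = params / bse
        pvals = pd.Series(
            2 * sps.t.sf(np.abs(tvals), df_resid), index=names
        )
        return LearningFitResults(
            params=params,
            bse=bse,
            tvalues=tvals,
            pvalues=pvals,
            fvalues=tvals**2,
            df_resid=df_resid,
            n_obs=int(len(endog)),
            n_groups=int(groups.nunique()),
            group_var=float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0,
            resid_var=float(res.scale),
            converged=converged,
            model_desc=f"{self.formula} + (1|{self.groups})"
            if self.re_formula is None
            else f"{self.formula} + ({self.re_formula}|{self.groups})",
            n_dropped=self.n_dropped,
            wrapped=res,
        )

    def compare_random_slope(self) -> dict:
        """Likelihood-ratio comparison of random intercept vs + random slope.

        Both models are refitted by ML (not REML) so the likelihoods are
        comparable; the LRT df of 2 (slope variance + intercept-slope
        covariance) is conservative at the boundary.
        """
        base = MixedLearningModel(
            self.data, self.response, self.fixed, self.groups, None
        ).fit(reml=False)
        slope = MixedLearningModel(
            self.data, self.response, self.fixed, self.groups, "~logday"
        ).fit(reml=False)
        lr = 2 * (slope.wrapped.llf - base.wrapped.llf)
        return {
            "lr_stat": float(lr),
            "df": 2,
            "p": float(sps.chi2.sf(max(lr, 0.0), 2)),
            "base": base,
            "with_slope": slope,
        }


# ---------------------------------------------------------------------------
# Convenience fit functions (the pipeline's model surface)
# ---------------------------------------------------------------------------

def fit_success_model(table: pd.DataFrame, **kw) -> LearningFitResults:
    """Number of successful reaches ~ log(day) × tDCS + (1 | animal)."""
    _require_scale(table)
    return MixedLearningModel.from_learning_table(table, "successes", **kw).fit()


def fit_rate_model(table: pd.DataFrame, **kw) -> LearningFitResults:
    """Success rate (successes / attempts) ~ log(day) × tDCS + (1 | animal).

    Fitted as a linear mixed model on the ratio; rows with zero attempts
    are dropped and counted on the results object.
    """
    _require_scale(table)
    return MixedLearningModel.from_learning_table(table, "rate", **kw).fit()


def fit_stereotypy_model(
    records: pd.DataFrame,
    group_by_animal: pd.Series | dict,
    *,
    paw: str | None = None,
    paw_by_animal: pd.Series | dict | None = None,
    success: bool | None = None,
) -> LearningFitResults:
    """Per-trial stereotypy score ~ log(day) × tDCS + (1 | animal).

    Supports restriction to a paw-preference subset (left- and right-pawed
    animals behave differently enough that pooling them needs a 3-way
    interaction this model deliberately avoids) and stratification by
    trial success.
    """
    return MixedLearningModel.from_trial_scores(
        records,
        group_by_animal,
        paw=paw,
        paw_by_animal=paw_by_animal,
        success=success,
    ).fit()


def fit_mep_model(df: pd.DataFrame, design: str = "logdiff") -> LearningFitResults:
    """Mixed models for log MEP amplitudes with animal as a random effect.

    designs
    -------
    ``"side"``
        log amplitude ~ side (contra=1 vs ipsi=0). Columns: animal_id,
        hemisphere, log_value.
    ``"logdiff"``
        contra − ipsi log-difference ~ tDCS × training (trained vs
        untrained paw). Columns: animal_id, paw, hemisphere, group,
        log_value; the log-difference is computed here per animal × paw.
    ``"success"``
        log amplitude ~ success + tDCS. Columns: animal_id, group,
        success, log_value.
    """
    df = df.copy()
    if design == "side":
        df["side"] = (df["hemisphere"] == "contra").astype(float)
        model = MixedLearningModel(df, "log_value", ["side"])
    elif design == "logdiff":
        wide = (
            df.pivot_table(
                index=["animal_id", "paw", "group"],
                columns="hemisphere",
                values="log_value",
            )
            .reset_index()
        )
        if not {"contra", "ipsi"} <= set(wide.columns):
            raise ValueError("logdiff design needs contra and ipsi rows")
        wide["log_diff"] = wide["contra"] - wide["ipsi"]
        wide["tdcs"] = (wide["group"] == "anodal").astype(float)
        wide["trained"] = (wide["paw"] == "trained").astype(float)
        wide["tdcs_x_trained"] = wide["tdcs"] * wide["trained"]
        model = MixedLearningModel(
            wide, "log_diff", ["tdcs", "trained", "tdcs_x_trained"]
        )
    elif design == "success":
        df["tdcs"] = (df["group"] == "anodal").astype(float)
        model = MixedLearningModel(df, "log_value", ["success", "tdcs"])
    else:
        raise ValueError(f"unknown design {design!r}")
    return model.fit()


def success_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group × day mean and SEM of successes across animals.

    SEM is SD/√n over the animals present that day; days observed in a
    single animal get SEM NaN and a flag.
    """
    validate_learning_table(table)
    g = table.groupby(["group", "day"])["successes"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    out["single_animal"] = out["n"] < 2
    return out.drop(columns="sd")


def plot_learning_curves(table: pd.DataFrame, ax=None):
    """Mean ± SEM success curves per group on a log-scaled day axis."""
    import matplotlib.pyplot as plt

    summ = success_summary(table)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"anodal": "tab:red", "control": "tab:blue"}
    for grp, sub in summ.groupby("group"):
        ax.errorbar(
            sub["day"], sub["mean"], yerr=sub["sem"], label=grp,
            color=colors.get(grp), marker="o", capsize=2,
        )
    ax.set_xscale("log")
    ax.set_xlabel("training day (log scale)")
    ax.set_ylabel("successful reaches")
    ax.legend(frameon=False)
    return ax


def _require_scale(table: pd.DataFrame) -> None:
    groups = validate_learning_table(table).groupby("group")["animal_id"].nunique()
    if (groups < 2).any() or groups.size < 2:
        raise ValueError("need >= 2 animals per group")
    if table["day"].nunique() < 2:
        raise ValueError("need >= 2 training days")
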