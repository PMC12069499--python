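"""Cross-sectional parent-offspring regressions and the Wald parent-of-origin test.

The maternal (or paternal) effect on an offspring trait at one visit is the
OLS slope of the offspring trait on the z-scored parental trait, adjusted for
covariates.  The parent-of-origin contrast is the Wald statistic

    Z = (b_mat - b_pat) / sqrt(SE_mat^2 + SE_pat^2 - 2 cov(b_mat, b_pat))

with a two-sided normal p value, p = 2 * (1 - Phi(|Z|)).  When the maternal
and paternal models are fitted separately (the default) the covariance term is
taken as zero; a joint model (both parents as predictors) or a paired family
bootstrap can supply it instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import TrioCohort
from .transforms import apply_transform

__all__ = [
    "RegressionResult",
    "PoeResult",
    "SkipRecord",
    "poe_z",
    "fit_parent_model",
    "fit_midparent_model",
    "fit_joint_parent_model",
    "poe_scan",
    "DEFAULT_COVARIATES",
    "CARDIOMETABOLIC_COVARIATES",
]

#: anthropometric default: offspring age and sex
DEFAULT_COVARIATES = ("age", "sex")
#: cardiometabolic default: age, sex and BMI of both the offspring and the parent(s)
CARDIOMETABOLIC_COVARIATES = ("age", "sex", "bmi", "parent_age", "parent_bmi")

STRATA = ("all", "sons", "daughters")


@dataclass
class RegressionResult:
    """One fitted parent-offspring (or mid-parent) regression."""

    trait: str
    visit: str
    stratum: str
    parent: str  # mother | father | midparent
    beta: float
    se: float
    p_value: float
    n: int
    covariates: list[str] = field(default_factory=list)


@dataclass
class PoeResult:
    """The maternal-vs-paternal Wald contrast."""

    z: float
    p_value: float
    cov_used: float  # cov(b_maternal, b_paternal) that entered the variance
    cov_method: str  # zero | joint | bootstrap
    significant_nominal: bool
    significant_bonferroni: bool


@dataclass
class SkipRecord:
    """Explicit record of a model that could not be fitted."""

    trait: str
    visit: str
    stratum: str
    parent: str
    reason: str
    n: int = 0


def poe_z(
    b1: float,
    se1: float,
    b2: float,
    se2: float,
    cov: float = 0.0,
    alpha: float = 0.05,
    bonferroni_p: float = 0.001,
    cov_method: str = "zero",
) -> PoeResult:
    """Wald test of the maternal-paternal coefficient difference.

    ``b1``/``se1`` are the maternal coefficient and SE by convention, ``b2``/
    ``se2`` the paternal ones, and ``cov`` is cov(b1, b2), which enters the
    variance of the difference twice.  With separately fitted models pass
    ``cov=0``.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError(f"standard errors must be positive, got ({se1}, {se2})")
    var = se1**2 + se2**2 - 2.0 * cov
    if var <= 0:
        raise ValueError(
            f"variance of the coefficient difference is non-positive (cov={cov}); "
            "the supplied covariance is incompatible with the standard errors"
        )
    z = (b1 - b2) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return PoeResult(
        z=z,
        p_value=p,
        cov_used=cov,
        cov_method=cov_method,
        significant_nominal=p < alpha,
        significant_bonferroni=p <= bonferroni_p,
    )


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


def _family_frame(
    cohort: TrioCohort,
    trait: str,
    visit: str,
    stratum: str,
    transforms: dict[str, str] | None,
    bmi_trait: str,
    need_parents: Sequence[str],
    covariates: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-family analysis table with outcome, parental predictors and covariates.

    Returns the listwise-complete frame and the resolved covariate column
    names.  Parental predictors are transformed (per the registry) but not yet
    standardized; standardization happens on the complete-case sample in the
    fitting routine.
    """
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}, got {stratum!r}")
    tf = transforms or {}
    off = cohort.offspring_table(trait, visit)
    if off.empty:
        return off.assign(), []
    frame = pd.DataFrame(
        {"y": off["value"], "age": off["age"], "sex": (off["sex"] == "F").astype(float)}
    )
    if trait in tf and tf[trait] != "none":
        frame["y"] = apply_transform(frame["y"], tf[trait])

    for parent in need_parents:
        pv = cohort.parent_values(trait, parent)
        if trait in tf and tf[trait] != "none":
            pv = apply_transform(pv, tf[trait])
        frame[f"x_{parent}"] = pv.reindex(frame.index)

    cov_cols: list[str] = []
    for cov in covariates:
        if cov == "age":
            cov_cols.append("age")
        elif cov == "sex":
            if stratum == "all":
                cov_cols.append("sex")  # constant within a sex stratum, drop there
        elif cov == "bmi":
            if trait == bmi_trait:
                continue  # outcome is BMI itself: adjusting for it would be tautological
            bmi = cohort.offspring_table(bmi_trait, visit)["value"] if bmi_trait in cohort.trait_names else None
            if bmi is None:
                continue
            frame["bmi"] = bmi.reindex(frame.index)
            cov_cols.append("bmi")
        elif cov in ("parent_age", "parent_bmi"):
            for parent in need_parents:
                name = f"{parent}_{cov.removeprefix('parent_')}"
                if cov == "parent_age":
                    frame[name] = cohort.parent_ages(parent).reindex(frame.index)
                    cov_cols.append(name)
                else:
                    if trait == bmi_trait or bmi_trait not in cohort.trait_names:
                        continue
                    frame[name] = cohort.parent_values(bmi_trait, parent).reindex(frame.index)
                    cov_cols.append(name)
        else:
            raise ValueError(f"unknown covariate token {cov!r}")

    if stratum == "sons":
        frame = frame[frame["sex"] == 0.0]
    elif stratum == "daughters":
        frame = frame[frame["sex"] == 1.0]

    used = ["y"] + [f"x_{p}" for p in need_parents] + cov_cols
    frame = frame.dropna(subset=used)
    return frame, cov_cols


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, X).fit()


def _zscore_col(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ZeroDivisionError
    return (x - x.mean()) / sd


def fit_parent_model(
    cohort: TrioCohort,
    trait: str,
    parent: str,
    visit: str,
    stratum: str = "all",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transforms: dict[str, str] | None = None,
    bmi_trait: str = "bmi",
    standardize: bool = True,
    min_n: int = 30,
) -> RegressionResult | SkipRecord:
    """OLS of the (transformed) offspring trait on one parent's (transformed) trait.

    The parental predictor is z-scored on the analysis sample when
    ``standardize`` is true, so the slope is per parental SD.  Listwise
    deletion per model; returns a :class:`SkipRecord` (never silently drops)
    when the sample is too small or the design is rank deficient.
    """
    if parent not in ("mother", "father"):
        raise ValueError(f"parent must be mother or father, got {parent!r}")
    frame, cov_cols = _family_frame(
        cohort, trait, visit, stratum, transforms, bmi_trait, (parent,), covariates
    )
    xcol = f"x_{parent}"
    n = len(frame)
    k = 2 + len(cov_cols)
    if n < max(min_n, k + 2):
        return SkipRecord(trait, visit, stratum, parent, f"n={n} below floor", n)
    x = frame[xcol]
    if standardize:
        try:
            x = _zscore_col(x)
        except ZeroDivisionError:
            return SkipRecord(trait, visit, stratum, parent, "zero predictor variance", n)
    X = np.column_stack([np.ones(n), x.to_numpy()] + [frame[c].to_numpy() for c in cov_cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return SkipRecord(trait, visit, stratum, parent, "rank-deficient design", n)
    res = _ols(frame["y"].to_numpy(), X)
    return RegressionResult(
        trait=trait,
        visit=visit,
        stratum=stratum,
        parent=parent,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n=n,
        covariates=list(cov_cols),
    )


def fit_midparent_model(
    cohort: TrioCohort,
    trait: str,
    visit: str,
    stratum: str = "all",
    covariates: Sequence[str] = ("age", "sex", "parent_age"),
    transforms: dict[str, str] | None = None,
    bmi_trait: str = "bmi",
    standardize: bool = True,
    min_n: int = 30,
) -> RegressionResult | SkipRecord:
    """Heritability regression: offspring trait on the mid-parental mean.

    With ``standardize`` each parent is z-scored first and the predictor is the
    mean of the two z-scores (not re-standardized), so with equal parental
    contributions beta approaches the sum of the per-parent standardized
    slopes; trios missing either parent are excluded.
    """
    frame, cov_cols = _family_frame(
        cohort, trait, visit, stratum, transforms, bmi_trait, ("mother", "father"), covariates
    )
    n = len(frame)
    k = 2 + len(cov_cols)
    if n < max(min_n, k + 2):
        return SkipRecord(trait, visit, stratum, "midparent", f"n={n} below floor", n)
    xm, xf = frame["x_mother"], frame["x_father"]
    if standardize:
        try:
            xm, xf = _zscore_col(xm), _zscore_col(xf)
        except ZeroDivisionError:
            return SkipRecord(trait, visit, stratum, "midparent", "zero predictor variance", n)
    mid = (xm + xf) / 2.0
    X = np.column_stack([np.ones(n), mid.to_numpy()] + [frame[c].to_numpy() for c in cov_cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return SkipRecord(trait, visit, stratum, "midparent", "rank-deficient design", n)
    res = _ols(frame["y"].to_numpy(), X)
    return RegressionResult(
        trait=trait,
        visit=visit,
        stratum=stratum,
        parent="midparent",
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n=n,
        covariates=list(cov_cols),
    )


def fit_joint_parent_model(
    cohort: TrioCohort,
    trait: str,
    visit: str,
    stratum: str = "all",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transforms: dict[str, str] | None = None,
    bmi_trait: str = "bmi",
    min_n: int = 30,
):
    """Both parents in one OLS; returns (maternal, paternal results, cov(b_m, b_p)).

    The coefficient covariance comes from the fitted covariance matrix, which
    is what the Wald contrast of the difference uses.
    """
    frame, cov_cols = _family_frame(
        cohort, trait, visit, stratum, transforms, bmi_trait, ("mother", "father"), covariates
    )
    n = len(frame)
    k = 3 + len(cov_cols)
    if n < max(min_n, k + 2):
        return SkipRecord(trait, visit, stratum, "joint", f"n={n} below floor", n)
    try:
        xm = _zscore_col(frame["x_mother"])
        xf = _zscore_col(frame["x_father"])
    except ZeroDivisionError:
        return SkipRecord(trait, visit, stratum, "joint", "zero predictor variance", n)
    X = np.column_stack(
        [np.ones(n), xm.to_numpy(), xf.to_numpy()] + [frame[c].to_numpy() for c in cov_cols]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return SkipRecord(trait, visit, stratum, "joint", "rank-deficient design", n)
    res = _ols(frame["y"].to_numpy(), X)
    cov_mat = np.asarray(res.cov_params())
    res_m = RegressionResult(trait, visit, stratum, "mother", float(res.params[1]),
                             float(res.bse[1]), float(res.pvalues[1]), n, list(cov_cols))
    res_p = RegressionResult(trait, visit, stratum, "father", float(res.params[2]),
                             float(res.bse[2]), float(res.pvalues[2]), n, list(cov_cols))
    return res_m, res_p, float(cov_mat[1, 2])


def _bootstrap_cov(
    cohort: TrioCohort,
    trait: str,
    visit: str,
    stratum: str,
    covariates: Sequence[str],
    transforms: dict[str, str] | None,
    bmi_trait: str,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """cov(b_mat, b_pat) by paired resampling of whole trios."""
    frame, cov_cols = _family_frame(
        cohort, trait, visit, stratum, transforms, bmi_trait, ("mother", "father"), covariates
    )
    n = len(frame)
    pairs = np.empty((n_boot, 2))
    base = frame.reset_index(drop=True)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = base.iloc[idx]
        out = []
        for parent in ("mother", "father"):
            x = sub[f"x_{parent}"]
            sd = x.std(ddof=1)
            xz = (x - x.mean()) / sd
            X = np.column_stack([np.ones(n), xz.to_numpy()] + [sub[c].to_numpy() for c in cov_cols])
            beta, *_ = np.linalg.lstsq(X, sub["y"].to_numpy(), rcond=None)
            out.append(beta[1])
        pairs[b] = out
    return float(np.cov(pairs.T)[0, 1])


def poe_scan(
    cohort: TrioCohort,
    traits: Sequence[str],
    visits: Sequence[str] | None = None,
    strata: Sequence[str] = STRATA,
    cov_method: str = "zero",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transforms: dict[str, str] | None = None,
    bmi_trait: str = "bmi",
    alpha: float = 0.05,
    bonferroni_p: float = 0.001,
    min_n: int = 30,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """One maternal/paternal/Wald-Z row per trait x visit x stratum.

    Skipped cells appear with ``status`` explaining why instead of vanishing.
    """
    if cov_method not in ("zero", "joint", "bootstrap"):
        raise ValueError(f"unknown cov_method {cov_method!r}")
    rng = np.random.default_rng(seed)
    if visits is None:
        visits = cohort.visit_labels
    rows = []
    for trait in traits:
        for visit in visits:
            for stratum in strata:
                row: dict = {"trait": trait, "visit": visit, "stratum": stratum}
                res_m = fit_parent_model(
                    cohort, trait, "mother", visit, stratum, covariates, transforms,
                    bmi_trait, min_n=min_n,
                )
                res_p = fit_parent_model(
                    cohort, trait, "father", visit, stratum, covariates, transforms,
                    bmi_trait, min_n=min_n,
                )
                skip = next((r for r in (res_m, res_p) if isinstance(r, SkipRecord)), None)
                if skip is not None:
                    row.update(status=f"skipped: {skip.reason}")
                    rows.append(row)
                    continue
                cov = 0.0
                if cov_method == "joint":
                    joint = fit_joint_parent_model(
                        cohort, trait, visit, stratum, covariates, transforms, bmi_trait, min_n
                    )
                    if isinstance(joint, SkipRecord):
                        row.update(status=f"skipped: {joint.reason}")
                        rows.append(row)
                        continue
                    res_m, res_p, cov = joint
                elif cov_method == "bootstrap":
                    cov = _bootstrap_cov(
                        cohort, trait, visit, stratum, covariates, transforms, bmi_trait,
                        n_boot, rng,
                    )
                poe = poe_z(
                    res_m.beta, res_m.se, res_p.beta, res_p.se, cov,
                    alpha=alpha, bonferroni_p=bonferroni_p, cov_method=cov_method,
                )
                row.update(
                    status="ok",
                    beta_maternal=res_m.beta,
                    se_maternal=res_m.se,
                    p_maternal=res_m.p_value,
                    n_maternal=res_m.n,
                    beta_paternal=res_p.beta,
                    se_paternal=res_p.se,
                    p_paternal=res_p.p_value,
                    n_paternal=res_p.n,
                    z=poe.z,
                    p_poe=poe.p_value,
                    cov_used=poe.cov_used,
                    significant_nominal=poe.significant_nominal,
                    significant_bonferroni=poe.significant_bonferroni,
                )
                rows.append(row)
    columns = [
        "trait", "visit", "stratum", "status",
        "beta_maternal", "se_maternal", "p_maternal", "n_maternal",
        "beta_paternal", "se_paternal", "p_paternal", "n_paternal",
        "z", "p_poe", "cov_used", "significant_nominal", "significant_bonferroni",
    ]
    return pd.DataFrame(rows, columns=columns)
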