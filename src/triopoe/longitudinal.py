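"""Longitudinal parent-of-origin contrasts via mixed-effect regression.

Offspring trait measurements are stacked over visits and regressed jointly on
the z-scored maternal and paternal traits with a random intercept per family
absorbing the intra-family / inter-observation correlation.  Because both
parents sit in one model, the maternal-paternal Wald contrast can use the
actual coefficient covariance rather than assuming it zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import TrioCohort
from .cross_sectional import DEFAULT_COVARIATES, PoeResult, poe_z
from .transforms import apply_transform

__all__ = ["MixedModelResult", "fit_longitudinal_model", "longitudinal_poe_contrast"]


@dataclass
class MixedModelResult:
    """A fitted longitudinal model with its parental fixed effects and variances."""

    trait: str
    stratum: str
    fixed_effects: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    random_variances: dict[str, float]  # family, individual, residual
    n_obs: int
    n_families: int
    converged: bool
    parent_cov: float = 0.0  # cov(b_maternal, b_paternal) from the fit
    notes: list[str] = field(default_factory=list)


def _stack_frame(
    cohort: TrioCohort,
    trait: str,
    stratum: str,
    visits: Sequence[str] | None,
    covariates: Sequence[str],
    transforms: dict[str, str] | None,
    bmi_trait: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Long offspring table over visits with per-family parental predictors."""
    tf = transforms or {}
    if visits is None:
        visits = cohort.visit_labels
    parts = []
    for visit in visits:
        off = cohort.offspring_table(trait, visit)
        if off.empty:
            continue
        part = off.reset_index().assign(visit=visit)
        if "bmi" in covariates and trait != bmi_trait and bmi_trait in cohort.trait_names:
            bmi = cohort.offspring_table(bmi_trait, visit)["value"]
            part["bmi"] = bmi.reindex(part["family_id"]).to_numpy()
        parts.append(part)
    if not parts:
        return pd.DataFrame(), []
    frame = pd.concat(parts, ignore_index=True)
    if trait in tf and tf[trait] != "none":
        frame["value"] = apply_transform(frame["value"], tf[trait])
    frame["sex"] = (frame["sex"] == "F").astype(float)
    for parent in ("mother", "father"):
        pv = cohort.parent_values(trait, parent)
        if trait in tf and tf[trait] != "none":
            pv = apply_transform(pv, tf[trait])
        frame[f"x_{parent}"] = pv.reindex(frame["family_id"]).to_numpy()

    cov_cols: list[str] = []
    for cov in covariates:
        if cov == "age":
            cov_cols.append("age")
        elif cov == "sex":
            if stratum == "all":
                cov_cols.append("sex")
        elif cov == "bmi":
            if "bmi" in frame.columns:
                cov_cols.append("bmi")
        elif cov == "parent_age":
            for parent in ("mother", "father"):
                frame[f"{parent}_age"] = cohort.parent_ages(parent).reindex(frame["family_id"]).to_numpy()
                cov_cols.append(f"{parent}_age")
        elif cov == "parent_bmi":
            if trait == bmi_trait or bmi_trait not in cohort.trait_names:
                continue
            for parent in ("mother", "father"):
                frame[f"{parent}_bmi"] = cohort.parent_values(bmi_trait, parent).reindex(frame["family_id"]).to_numpy()
                cov_cols.append(f"{parent}_bmi")
        else:
            raise ValueError(f"unknown covariate token {cov!r}")

    if stratum == "sons":
        frame = frame[frame["sex"] == 0.0]
    elif stratum == "daughters":
        frame = frame[frame["sex"] == 1.0]
    used = ["value", "x_mother", "x_father"] + cov_cols
    frame = frame.dropna(subset=used).reset_index(drop=True)
    # standardize parents on the unique included families
    for parent in ("mother", "father"):
        per_fam = frame.drop_duplicates("family_id")[f"x_{parent}"]
        mu, sd = per_fam.mean(), per_fam.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero variance in {parent} predictor for trait {trait!r}")
        frame[f"x_{parent}"] = (frame[f"x_{parent}"] - mu) / sd
    return frame, cov_cols


def fit_longitudinal_model(
    cohort: TrioCohort,
    trait: str,
    stratum: str = "all",
    visits: Sequence[str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transforms: dict[str, str] | None = None,
    bmi_trait: str = "bmi",
    reml: bool = True,
    min_families: int = 30,
    allow_single_visit: bool = False,
) -> MixedModelResult:
    """Fit the visit-pooled model with both parental effects and a family intercept.

    REML by default (``reml=False`` for ML).  When every family contributes a
    single observation the family intercept is unidentifiable: its variance is
    pinned at 0 with a note and the fixed effects come from the equivalent OLS
    fit.  Non-convergence is flagged on the result, not raised.
    """
    frame, cov_cols = _stack_frame(cohort, trait, stratum, visits, covariates, transforms, bmi_trait)
    if frame.empty:
        raise ValueError(f"no offspring data for trait {trait!r}")
    n_visits = frame["visit"].nunique()
    if n_visits < 2 and not allow_single_visit:
        raise ValueError(
            f"longitudinal model needs >=2 visits with data, found {n_visits} "
            "(pass allow_single_visit=True to fit anyway)"
        )
    n_fam = frame["family_id"].nunique()
    if n_fam < min_families:
        raise ValueError(f"longitudinal model needs >= {min_families} families, found {n_fam}")

    names = ["intercept", "x_mother", "x_father"] + cov_cols
    X = np.column_stack(
        [np.ones(len(frame)), frame["x_mother"], frame["x_father"]]
        + [frame[c].to_numpy() for c in cov_cols]
    )
    y = frame["value"].to_numpy()
    notes: list[str] = []

    if len(frame) == n_fam:
        # one observation per family: the intercept variance is unidentifiable,
        # pin it at zero; the fixed effects are then exactly OLS
        res = sm.OLS(y, X).fit()
        notes.append("single observation per family: family variance pinned at 0")
        fixed = {nm: (float(b), float(s)) for nm, b, s in zip(names, res.params, res.bse)}
        cov_mat = np.asarray(res.cov_params())
        return MixedModelResult(
            trait=trait,
            stratum=stratum,
            fixed_effects=fixed,
            random_variances={"family": 0.0, "individual": 0.0,
                              "residual": float(res.mse_resid)},
            n_obs=len(frame),
            n_families=n_fam,
            converged=True,
            parent_cov=float(cov_mat[1, 2]),
            notes=notes,
        )

    groups = frame["family_id"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(reml=reml)
            converged = bool(getattr(res, "converged", True))
        except Exception as exc:  # pragma: no cover - rare optimizer failure
            notes.append(f"fit failed: {exc}")
            res = None
            converged = False
    for w in caught:
        if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
            notes.append(str(w.message))
    if res is None:
        return MixedModelResult(trait, stratum, {}, {}, len(frame), n_fam, False, notes=notes)

    fixed = {nm: (float(b), float(s)) for nm, b, s in zip(names, res.params[: len(names)], res.bse[: len(names)])}
    fam_var = float(np.asarray(res.cov_re)[0, 0])
    if fam_var < 0:
        fam_var = 0.0
        notes.append("negative family variance estimate pinned at 0")
    cov_mat = np.asarray(res.cov_params())
    return MixedModelResult(
        trait=trait,
        stratum=stratum,
        fixed_effects=fixed,
        # with one offspring per family the individual and family levels
        # coincide; the individual component is reported as 0
        random_variances={"family": fam_var, "individual": 0.0, "residual": float(res.scale)},
        n_obs=len(frame),
        n_families=n_fam,
        converged=converged,
        parent_cov=float(cov_mat[1, 2]),
        notes=notes,
    )


def longitudinal_poe_contrast(
    model: MixedModelResult, alpha: float = 0.05, bonferroni_p: float = 0.001
) -> PoeResult:
    """Wald Z for the maternal-paternal fixed-effect difference of a pooled fit.

    Uses the coefficient covariance from the joint fit, so the variance of the
    difference is var_m + var_p - 2 cov.
    """
    for term in ("x_mother", "x_father"):
        if term not in model.fixed_effects:
            raise ValueError(f"model has no {term} fixed effect; both parents are required")
    bm, sem = model.fixed_effects["x_mother"]
    bp, sep = model.fixed_effects["x_father"]
    return poe_z(
        bm, sem, bp, sep, cov=model.parent_cov,
        alpha=alpha, bonferroni_p=bonferroni_p, cov_method="joint",
    )
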