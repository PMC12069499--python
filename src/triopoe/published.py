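"""Published parent-effect coefficients from the Pune birth-cohort analyses.

The packaged table carries the published mother-child and father-child
regression coefficients (beta, SE), sample sizes, and the published Wald Z
and p for every trait x visit x stratum cell of the anthropometric and
cardiometabolic panels.  These printed estimates are inputs: re-applying the
Wald coefficient-difference formula with zero covariance to the (beta, SE)
pairs reproduces the published Z values, which is the package's arithmetic
verification surface (the underlying individual-level cohort data are not
public).

A handful of cells in the published table are flagged
``printed_z_inconsistent_with_coefficients``: for those, the published Z
matches its own published p value exactly but cannot be obtained from the
published coefficients under any covariance consistent with the printed SEs —
i.e. the printed beta or SE carries a typo.  They are retained, flagged, for
transparency.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .cross_sectional import poe_z

__all__ = ["load_published_coefficients", "reproduce_published_z"]


def load_published_coefficients() -> pd.DataFrame:
    """The packaged published-coefficients table as a DataFrame."""
    ref = resources.files("triopoe.data") / "published_parent_effects.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["note"] = df["note"].fillna("")
    return df


def reproduce_published_z(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every published Wald Z from the published (beta, SE) pairs.

    Adds ``z_computed`` (zero-covariance Wald statistic from the printed
    coefficients) and ``z_abs_diff`` columns.  Printed inputs are rounded to
    3 decimals, so agreement within ~0.05 is the expected resolution.
    """
    if table is None:
        table = load_published_coefficients()
    out = table.copy()
    out["z_computed"] = [
        poe_z(r.beta_maternal, r.se_maternal, r.beta_paternal, r.se_paternal).z
        for r in out.itertuples()
    ]
    out["z_abs_diff"] = (out["z_computed"] - out["z_published"]).abs()
    return out
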