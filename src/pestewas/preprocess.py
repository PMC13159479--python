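"""Probe filtering, per-feature winsorization, and covariate residualization.

The adjustment strategy is residualize-once-then-regress: a single design
matrix (age, sex, ancestry, smoking, study wave, cell composition, OP count —
deliberately *not* disease status, to avoid conditioning on a collider) is
removed from every probe, and all downstream statistics (robust correlation,
moderated regression, bump hunting) operate on the residual matrix.  The
exposure of interest is residualized against the same design before the
per-probe regressions, so each per-probe fit recovers the multiple-regression
exposure coefficient (Frisch–Waugh) and null test statistics stay calibrated
even though the copper and OP scores are strongly correlated.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_TYPES = ("cd8t", "cd4t", "nk", "bcell", "mono", "gran")
FLAG_TYPES = ("cross_reactive", "snp", "sex_chromosome", "non_cpg")
SMOKING_LEVELS = ("never", "former", "current")
WAVE_LEVELS = ("PEG1", "PEG2")

#: floor for the across-feature coefficient variance in the EB shrinkage fit
TAU2_FLOOR = 1e-8


def parse_flags(flags: str | float) -> frozenset:
    """Parse a ';'-separated QC flag field into a set of flag names."""
    if flags is None or (isinstance(flags, float) and np.isnan(flags)) or flags == "":
        return frozenset()
    parts = frozenset(str(flags).split(";"))
    unknown = parts - set(FLAG_TYPES)
    if unknown:
        raise ValueError(f"unknown QC flags: {sorted(unknown)}")
    return parts


def filter_probes(
    beta: pd.DataFrame, annot: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop probes carrying any QC flag (cross-reactive, SNP, sex chromosome,
    non-CpG) and report per-flag removal counts.

    Returns (filtered beta, filtered annotation, report).  The report counts
    a probe under every flag it carries; ``removed`` counts unique probes.
    """
    missing = beta.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"probes without annotation: {list(missing[:10])}")
    ann = annot.loc[beta.index]
    flag_sets = ann["flags"].map(parse_flags)
    report = {f: int(flag_sets.map(lambda s, f=f: f in s).sum()) for f in FLAG_TYPES}
    keep = flag_sets.map(len) == 0
    report["removed"] = int((~keep).sum())
    report["retained"] = int(keep.sum())
    return beta.loc[keep], ann.loc[keep], report


def winsorize(
    beta: pd.DataFrame, lower_q: float = 0.05, upper_q: float = 0.95
) -> pd.DataFrame:
    """Clamp each feature (row) to its [lower_q, upper_q] quantiles.

    Quantiles use linear interpolation of order statistics (the k-th order
    statistic of n values sits at quantile (k-1)/(n-1)), so the operation is
    idempotent and the post-winsorization row maximum equals the row's
    upper-quantile value exactly.
    """
    if not (0 <= lower_q < upper_q <= 1):
        raise ValueError("require 0 <= lower_q < upper_q <= 1")
    values = beta.to_numpy(float)
    lo = np.quantile(values, lower_q, axis=1, keepdims=True)
    hi = np.quantile(values, upper_q, axis=1, keepdims=True)
    return pd.DataFrame(
        np.clip(values, lo, hi), index=beta.index, columns=beta.columns
    )


def build_design(
    covariates: pd.DataFrame, drop_cell: str = "gran"
) -> tuple[np.ndarray, list[str]]:
    """Assemble the adjustment design matrix from a covariate table.

    Columns: intercept, age, sex (M=1), ancestry, smoking dummies
    (former/current vs never), wave (PEG2 vs PEG1), five of the six cell
    fractions (``drop_cell`` excluded — the fractions sum to one, so keeping
    all six would be exactly collinear with the intercept), and OP count.
    Disease status is intentionally absent.
    """
    if drop_cell not in CELL_TYPES:
        raise ValueError(f"drop_cell must be one of {CELL_TYPES}")
    cov = covariates
    for col in ("age", "sex", "ancestry", "smoking", "wave", "op_count", *CELL_TYPES):
        if col not in cov.columns:
            raise ValueError(f"covariate table lacks column {col!r}")
    bad_smoke = set(cov["smoking"]) - set(SMOKING_LEVELS)
    if bad_smoke:
        raise ValueError(f"smoking levels outside {SMOKING_LEVELS}: {sorted(bad_smoke)}")
    bad_wave = set(cov["wave"]) - set(WAVE_LEVELS)
    if bad_wave:
        raise ValueError(f"wave levels outside {WAVE_LEVELS}: {sorted(bad_wave)}")

    n = len(cov)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
    cols.append(("age", cov["age"].to_numpy(float)))
    cols.append(("sex_M", (cov["sex"] == "M").to_numpy(float)))
    cols.append(("ancestry", cov["ancestry"].to_numpy(float)))
    cols.append(("smoking_former", (cov["smoking"] == "former").to_numpy(float)))
    cols.append(("smoking_current", (cov["smoking"] == "current").to_numpy(float)))
    cols.append(("wave_PEG2", (cov["wave"] == "PEG2").to_numpy(float)))
    for cell in CELL_TYPES:
        if cell != drop_cell:
            cols.append((cell, cov[cell].to_numpy(float)))
    cols.append(("op_count", cov["op_count"].to_numpy(float)))

    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns whose removal restores full rank."""
    full = np.linalg.matrix_rank(X)
    out = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(names[j])
    return out


def adjusted_residual_df(covariates: pd.DataFrame, drop_cell: str = "gran") -> int:
    """Residual degrees of freedom left after covariate adjustment plus an
    exposure slope: n - design columns - 1 (for the moderated regression)."""
    X, _ = build_design(covariates, drop_cell=drop_cell)
    return X.shape[0] - X.shape[1] - 1


def residualize(
    beta: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "ols",
    drop_cell: str = "gran",
    return_coef: bool = False,
):
    """Produce the covariate-adjusted residual matrix.

    mode="ols"
        Per-feature least-squares residuals; exactly orthogonal to the design.
    mode="eb"
        Per-feature coefficients shrunk toward the across-feature mean
        coefficient vector, with per-covariate shrinkage strength set by the
        across-feature variance of the OLS coefficients net of their mean
        sampling variance (ridge-toward-prior; intercept never shrunk).
        Residuals are re-centered per feature after subtraction.
    """
    if mode not in ("ols", "eb"):
        raise ValueError("mode must be 'ols' or 'eb'")
    missing = [s for s in beta.columns if s not in covariates.index]
    if missing:
        raise ValueError(f"samples without covariates: {missing[:10]}")
    cov = covariates.loc[list(beta.columns)]
    X, _ = build_design(cov, drop_cell=drop_cell)
    Y = beta.to_numpy(float).T  # samples x features
    n, k = X.shape

    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)  # k x features
    if mode == "ols":
        resid = Y - X @ coef
        out = pd.DataFrame(resid.T, index=beta.index, columns=beta.columns)
        if return_coef:
            _, names = build_design(cov, drop_cell=drop_cell)
            return out, pd.DataFrame(coef.T, index=beta.index, columns=names)
        return out

    # Empirical-Bayes shrinkage toward the across-feature mean coefficients.
    resid0 = Y - X @ coef
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough samples for EB residualization")
    sigma2 = (resid0**2).sum(axis=0) / dof              # per-feature noise
    sigma2 = np.maximum(sigma2, 1e-300)
    XtX = X.T @ X
    a_jj = np.diag(np.linalg.inv(XtX))                  # unit sampling variance
    coef_var = sigma2[:, None] * a_jj[None, :]          # features x k
    beta_bar = coef.mean(axis=1)                        # k
    tau2 = coef.var(axis=1, ddof=1) - coef_var.mean(axis=0)
    tau2 = np.maximum(tau2, TAU2_FLOOR)
    prior_prec = 1.0 / tau2
    prior_prec[0] = 0.0                                 # intercept never shrunk

    XtY = X.T @ Y                                       # k x features
    n_feat = Y.shape[1]
    A = XtX[None, :, :] / sigma2[:, None, None] + np.diag(prior_prec)[None, :, :]
    rhs = (XtY / sigma2[None, :]).T + (prior_prec * beta_bar)[None, :]
    coef_eb = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]  # features x k
    resid = Y - X @ coef_eb.T
    resid -= resid.mean(axis=0, keepdims=True)          # intercept re-centering
    out = pd.DataFrame(resid.T, index=beta.index, columns=beta.columns)
    if return_coef:
        _, names = build_design(cov, drop_cell=drop_cell)
        return out, pd.DataFrame(coef_eb, index=beta.index, columns=names)
    return out


def residualize_exposure(
    covariates: pd.DataFrame,
    exposure: pd.Series | np.ndarray,
    sample_ids: Sequence | None = None,
    drop_cell: str = "gran",
) -> np.ndarray:
    """Residualize the exposure vector against the same adjustment design.

    Returns the exposure component orthogonal to the covariates; regressing
    the residual matrix on this vector yields the multiple-regression
    exposure coefficients (Frisch–Waugh–Lovell).
    """
    if isinstance(exposure, pd.Series):
        if sample_ids is None:
            sample_ids = list(exposure.index)
        x = exposure.loc[list(sample_ids)].to_numpy(float)
    else:
        x = np.asarray(exposure, float)
        if sample_ids is None:
            sample_ids = list(covariates.index)
    cov = covariates.loc[list(sample_ids)]
    X, _ = build_design(cov, drop_cell=drop_cell)
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ coef
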