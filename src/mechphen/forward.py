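"""Forward-genetics association models.

Per SNP and phenotype, a covariate-adjusted logistic regression of case
status on genotype, with the genotype coded additively (0/1/2 minor-allele
copies) or recessively (minor homozygote vs rest).  Reported statistics
are the Wald p-value and OR = exp(beta) with a 95% Wald CI for the
genotype term, which is what standard GWAS toolchains emit, so numbers
are directly comparable.

Recessive fits on rare homozygotes separate easily (e.g. every minor
homozygote a case); the default behaviour is to flag the result and leave
the p-value missing, with an optional Firth-type (Jeffreys-prior)
penalised fit as a fallback.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING

__all__ = ["fit_logistic", "or_filter", "firth_logistic"]

FORWARD_MODELS = ("additive", "recessive")
REVERSE_MODELS = ("rg1", "rg2")


def _design(
    dosages: np.ndarray,
    y: pd.Series,
    covariates: pd.DataFrame | None,
    coding: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Build (X, y, n_hzma) over complete cases; first X column after the
    intercept is the genotype term."""
    d = np.asarray(dosages, dtype=float)
    keep = d != MISSING
    d = d[keep]
    yv = np.asarray(y, dtype=float)[keep]
    n_hzma = int((d == 2).sum())
    if coding == "recessive":
        g = (d == 2).astype(float)
    elif coding == "additive":
        g = d
    else:
        raise ValueError(f"unknown genotype coding {coding!r}")
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = covariates.loc[np.asarray(y.index)[keep]]
        cat_cols = [
            c for c in cov.columns if not np.issubdtype(cov[c].dtype, np.number)
        ]
        num = pd.get_dummies(cov, columns=cat_cols, drop_first=True, dtype=float)
        for c in num.columns:
            col = num[c].to_numpy(dtype=float)
            if np.ptp(col) > 0:  # single-level covariates are dropped
                cols.append(col)
    X = np.column_stack(cols)
    return X, yv, n_hzma


def firth_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-prior penalised logistic regression (Firth).

    Newton iterations on the modified score U*(b) = X'(y - p + h(1/2 - p))
    where h are hat-matrix diagonals; estimates stay finite under complete
    separation.  Returns (beta, covariance).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, cov, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        # step-halving for stability
        while np.abs(step).max() > 5.0:
            step *= 0.5
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov


def fit_logistic(
    dosages: np.ndarray,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    coding: str = "additive",
    snp_id: str = "",
    gene_id: str = "",
    phenotype_id: str = "",
    firth: bool = False,
) -> dict:
    """Fit one SNP x phenotype logistic association.

    ``y`` is a boolean case/control Series indexed by subject id;
    ``covariates`` (optional) is indexed the same way with columns such as
    age (continuous), gender and dataset (categorical, dummy-coded,
    single-level columns dropped).  Returns a result row (dict) with OR,
    Wald 95% CI and p for the genotype term; non-convergence or separation
    is flagged and leaves the p-value missing unless ``firth`` is set.
    """
    X, yv, n_hzma = _design(dosages, y, covariates, coding)
    n_case = int(yv.sum())
    n_control = int(len(yv) - n_case)
    row = {
        "snp_id": snp_id,
        "gene_id": gene_id,
        "phenotype_id": phenotype_id,
        "model": coding,
        "OR": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p": np.nan,
        "n_case": n_case,
        "n_control": n_control,
        "n_hzma": n_hzma,
        "flag": "",
    }
    if n_case == 0 or n_control == 0:
        row["flag"] = "no_case_or_control"
        return row
    if np.ptp(X[:, 1]) == 0:
        row["flag"] = "monomorphic_in_sample"
        return row

    import statsmodels.api as sm

    beta = cov = None
    flag = ""
    with np.errstate(all="ignore"):
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = sm.GLM(yv, X, family=sm.families.Binomial()).fit(maxiter=100)
            beta, cov = res.params, res.cov_params()
            if (
                not np.all(np.isfinite(beta))
                or not np.all(np.isfinite(np.diag(cov)))
                or np.abs(beta[1]) > 15
                or np.sqrt(cov[1, 1]) > 50
            ):
                flag = "separation"
        except Exception:
            flag = "non_convergence"
    if flag:
        if firth:
            beta, cov = firth_logistic(X, yv)
            flag += ",firth"
        else:
            row["flag"] = flag
            return row
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    z = b / se if se > 0 else np.nan
    row.update(
        OR=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.959963984540054 * se)),
        ci_high=float(np.exp(b + 1.959963984540054 * se)),
        p=float(2 * stats.norm.sf(abs(z))),
        flag=flag,
    )
    return row


def or_filter(results: pd.DataFrame) -> pd.DataFrame:
    """Keep forward-model rows with OR strictly > 1 (risk direction).

    Reverse-genetics rows (models rg1/rg2, which carry no OR) pass through
    untouched.  OR exactly 1 is excluded (strict inequality).
    """
    is_forward = results["model"].isin(FORWARD_MODELS)
    keep = ~is_forward | (results["OR"] > 1)
    return results.loc[keep].reset_index(drop=True)
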