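"""Carrier association tests, AFP dichotomization and p-value handling.

Each core ROH region is treated as a binary marker (carrier /
non-carrier) and tested against disease status (Fisher's exact test)
or against the quantitative age-of-first-phrase (AFP) phenotype
(ordinary least squares with covariates, or logistic regression on the
k-means early/late split).  Multiple testing is handled by Bonferroni
correction over the number of regions tested; evidence across cohorts
is combined with Stouffer's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import CarrierMatrix, SampleTable

__all__ = [
    "AssocResult", "DichotomyResult", "fisher_carrier_test",
    "fisher_exact_two_sided", "quantitative_trait_regression",
    "logistic_trait_regression", "kmeans_dichotomize", "bonferroni",
    "stouffer_combine", "compare_distributions",
]


@dataclass
class AssocResult:
    """One region's test result."""

    region: object
    test: str                      # "fisher" | "linear" | "logistic"
    effect: float                  # odds ratio or coefficient
    se: float = float("nan")
    p: float = float("nan")
    p_bonferroni: float = float("nan")
    n_used: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")


@dataclass
class DichotomyResult:
    """Exact 1-D 2-means split of AFP values."""

    cutoff: float                  # months; early < cutoff <= late
    labels: np.ndarray             # 0 = early, 1 = late (NaN input -> -1)
    cluster_means: tuple


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Probability-mass rule: sum hypergeometric probabilities of all
    tables (with the observed margins) no more likely than the observed
    one.  Degenerate margins give p = 1.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_carrier_test(matrix: CarrierMatrix, sample: SampleTable) -> list:
    """Fisher's exact test of carrier status x case/control per region.

    The odds ratio is ad/bc with a Haldane-Anscombe 0.5 added to every
    cell when any cell is zero.  Empty carrier or status margins are
    flagged with p = 1 and an undefined OR.
    """
    status = sample.aligned_to(matrix.sample_ids).status_array()
    is_case = status == 1
    is_ctrl = status == 0
    out = []
    for r in range(matrix.n_regions):
        col = matrix.incidence[:, r].astype(bool)
        a = int((col & is_case).sum())          # carrier cases
        b = int((~col & is_case).sum())
        c = int((col & is_ctrl).sum())          # carrier controls
        d = int((~col & is_ctrl).sum())
        flags = []
        if (a + c) == 0 or (b + d) == 0 or (a + b) == 0 or (c + d) == 0:
            p = 1.0
            orat = float("nan")
            flags.append("empty_margin")
        else:
            p = fisher_exact_two_sided(a, b, c, d)
            if min(a, b, c, d) == 0:
                orat = ((a + .5) * (d + .5)) / ((b + .5) * (c + .5))
                flags.append("haldane_correction")
            else:
                orat = (a * d) / (b * c)
        out.append(AssocResult(matrix.regions[r], "fisher", float(orat),
                               p=p, n_used=a + b + c + d, flags=flags))
    return out


def _design(sample: SampleTable, carrier: np.ndarray,
            covariates: Sequence[str]):
    df = sample.table.copy()
    df["carrier"] = carrier
    cols = ["carrier"] + list(covariates)
    return df, cols


def quantitative_trait_regression(matrix: CarrierMatrix, sample: SampleTable,
                                  covariates: Sequence[str] = ()) -> list:
    """OLS of AFP (months) on carrier status plus covariates, per region.

    Rows with a missing phenotype or covariate are listwise-deleted; the
    number of complete cases used is reported.  A constant carrier
    column is flagged as collinear and skipped.
    """
    sample = sample.aligned_to(matrix.sample_ids)
    out = []
    for r in range(matrix.n_regions):
        carrier = matrix.incidence[:, r].astype(float)
        df, cols = _design(sample, carrier, covariates)
        sub = df[["afp_months"] + cols].dropna()
        n = len(sub)
        if n < len(cols) + 2:
            out.append(AssocResult(matrix.regions[r], "linear", float("nan"),
                                   n_used=n, flags=["insufficient_n"]))
            continue
        if sub["carrier"].nunique() < 2:
            out.append(AssocResult(matrix.regions[r], "linear", float("nan"),
                                   n_used=n, flags=["collinear_carrier"]))
            continue
        X = sm.add_constant(sub[cols].to_numpy(dtype=float))
        fit = sm.OLS(sub["afp_months"].to_numpy(dtype=float), X).fit()
        out.append(AssocResult(matrix.regions[r], "linear",
                               float(fit.params[1]), se=float(fit.bse[1]),
                               p=float(fit.pvalues[1]), n_used=n))
    return out


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Newton iterations on the modified score U(b) + X' (h * (0.5 - mu));
    returns (coefficients, standard errors).  Used as the fallback when
    the ML fit separates.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w   # hat-matrix diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, np.sqrt(np.diag(cov))


def logistic_trait_regression(matrix: CarrierMatrix, sample: SampleTable,
                              dichotomy: DichotomyResult,
                              covariates: Sequence[str] = ()) -> list:
    """Logistic regression of late/early AFP on carrier status per region.

    Wald p-values from the ML fit; on perfect separation (non-converged
    or exploding estimates) the fit falls back to Firth's penalised
    likelihood and the result is flagged.
    """
    sample = sample.aligned_to(matrix.sample_ids)
    labels = np.asarray(dichotomy.labels, dtype=float)
    labels[labels < 0] = np.nan
    out = []
    for r in range(matrix.n_regions):
        carrier = matrix.incidence[:, r].astype(float)
        df, cols = _design(sample, carrier, covariates)
        df["late"] = labels
        sub = df[["late"] + cols].dropna()
        n = len(sub)
        y = sub["late"].to_numpy(dtype=float)
        if n < len(cols) + 2 or len(np.unique(y)) < 2:
            out.append(AssocResult(matrix.regions[r], "logistic", float("nan"),
                                   n_used=n, flags=["insufficient_n"]))
            continue
        if sub["carrier"].nunique() < 2:
            out.append(AssocResult(matrix.regions[r], "logistic", float("nan"),
                                   n_used=n, flags=["collinear_carrier"]))
            continue
        X = sm.add_constant(sub[cols].to_numpy(dtype=float))
        flags = []
        try:
            import warnings
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")   # separation warns before we flag it
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = fit.params, fit.bse
            separated = (not fit.mle_retvals.get("converged", True)) or \
                np.any(np.abs(beta) > 15) or np.any(~np.isfinite(se))
        except Exception:
            separated = True
        if separated:
            beta, se = _firth_logistic(X, y)
            flags.append("firth_fallback")
        z = beta[1] / se[1]
        out.append(AssocResult(matrix.regions[r], "logistic", float(beta[1]),
                               se=float(se[1]),
                               p=float(2 * stats.norm.sf(abs(z))),
                               n_used=n, flags=flags))
    return out


def kmeans_dichotomize(values, seed: int = 0) -> DichotomyResult:
    """Exact one-dimensional 2-means split of AFP values.

    Optimal 1-D clusters are contiguous in sorted order, so every sorted
    split point is evaluated and the split minimising the within-cluster
    sum of squares is taken — no random initialisation is involved (the
    ``seed`` argument is accepted for interface symmetry).  The cutoff
    is the midpoint between the largest early and smallest late value.
    """
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    x = np.sort(vals[finite])
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct values to dichotomize")
    best = (np.inf, 1)
    csum = np.cumsum(x)
    csq = np.cumsum(x ** 2)
    total_sum, total_sq, n = csum[-1], csq[-1], len(x)
    for k in range(1, n):            # early cluster = x[:k]
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = total_sum - s1, total_sq - q1
        wss = (q1 - s1 ** 2 / k) + (q2 - s2 ** 2 / (n - k))
        if wss < best[0] - 1e-12:
            best = (wss, k)
    k = best[1]
    # place the boundary at the last index whose value equals x[k-1]
    while k < n and x[k] == x[k - 1]:
        k += 1
    cutoff = (x[k - 1] + x[k]) / 2.0 if k < n else x[-1]
    labels = np.full(len(vals), -1, dtype=int)
    labels[finite] = (vals[finite] >= cutoff).astype(int)
    early = vals[finite][vals[finite] < cutoff]
    late = vals[finite][vals[finite] >= cutoff]
    return DichotomyResult(float(cutoff), labels,
                           (float(early.mean()), float(late.mean())))


def bonferroni(p_raw, alpha: float = 0.05):
    """Bonferroni correction: p_corr = min(1, p * N); threshold alpha / N."""
    p = np.asarray(p_raw, dtype=float)
    n = len(p)
    if n == 0:
        return np.array([]), float("nan")
    return np.minimum(1.0, p * n), alpha / n


def stouffer_combine(p_list, weights=None, one_sided: bool = True):
    """Stouffer's combined z and p.

    z_i = Phi^{-1}(1 - p_i); combined z = sum(w_i z_i) / sqrt(sum(w_i^2));
    combined p = 1 - Phi(z).  Default weights are equal; pass sample
    sizes to obtain the sqrt(n)-weighted ("z trend") variant via
    ``weights=np.sqrt(n_list)``.
    """
    p = np.asarray(p_list, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    if not one_sided:
        p = p / 2.0
    z = stats.norm.isf(p)
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    z_comb = float((w * z).sum() / np.sqrt((w ** 2).sum()))
    return z_comb, float(stats.norm.sf(z_comb))


def compare_distributions(values_a, values_b):
    """Two-sided Mann-Whitney U with tie correction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
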