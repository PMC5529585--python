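"""Cohort-level statistics relating reading skill to segmentation measures.

Pipeline: z-transform the three reading scores, extract a composite reading
score as the first principal component of their correlation matrix, then
test each of the eight task outcomes (acuity limit, knee k, asymptote t,
slope s, for the motion and form tasks) against the composite with
semi-partial Spearman correlations controlling gender and non-verbal IQ.
Raw p-values are adjusted with the Benjamini-Hochberg step-up procedure
over the eight-test family (FDR 0.05) and each correlation is converted to
a Cohen's d effect size via d = 2r / sqrt(1 - r^2).

The semi-partial correlation removes the covariates from the *predictor*
(the reading composite), so it asks whether reading ability explains any
additional variance beyond gender and IQ; residualising the outcome
instead is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .curvefit import CurveFitError, fit_two_limb

__all__ = [
    "PcaResult",
    "CorrelationTest",
    "CohortAnalysis",
    "StatsError",
    "z_transform",
    "pca_composite",
    "variance_explained",
    "semipartial_spearman",
    "bh_adjust",
    "cohens_d_from_r",
    "analyze_cohort",
]

OUTCOMES = ("acuity", "k", "t", "s")
TASKS = ("motion", "form")


class StatsError(ValueError):
    """Degenerate input to a statistical routine."""


def z_transform(scores) -> np.ndarray:
    """Standardise to sample mean 0 and sample SD 1 (divisor n - 1)."""
    x = np.asarray(scores, dtype=float)
    if len(np.unique(x)) < 2:
        raise StatsError("z-transform undefined for constant input")
    return (x - x.mean()) / x.std(ddof=1)


@dataclass
class PcaResult:
    """PCA of the three reading scores' correlation matrix."""

    eigenvalues: np.ndarray
    loadings: np.ndarray
    component_scores: np.ndarray
    variance_explained: np.ndarray


def variance_explained(eigenvalues) -> np.ndarray:
    """Proportion of total variance carried by each component."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < -1e-9):
        raise StatsError("eigenvalues must be non-negative")
    return ev / ev.sum()


def pca_composite(scores) -> PcaResult:
    """First-principal-component composite of three reading scores.

    ``scores`` is an (n, 3) array (columns NART, TOWRE-SWE, TOWRE-PDE; any
    three positively keyed reading measures work). The eigendecomposition
    is of the 3x3 correlation matrix; component loadings are
    sqrt(lambda_1) * v_1 and the composite is oriented so that higher
    scores mean better reading (positive correlation with the mean
    z-score).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise StatsError("scores must be an (n, 3) array")
    if X.shape[0] < 4:
        raise StatsError("need at least 4 participants for PCA")
    Z = np.column_stack([z_transform(X[:, j]) for j in range(3)])
    corr = np.corrcoef(Z, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise StatsError("correlation matrix is undefined (rank-deficient input)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    v1 = eigvecs[:, 0]
    composite = Z @ v1
    if np.corrcoef(composite, Z.mean(axis=1))[0, 1] < 0:
        v1 = -v1
        composite = -composite
        eigvecs[:, 0] = v1
    loadings = np.sqrt(np.maximum(eigvals[0], 0.0)) * v1
    return PcaResult(
        eigenvalues=eigvals,
        loadings=loadings,
        component_scores=composite,
        variance_explained=variance_explained(eigvals),
    )


def _residualise(target: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(target)), covariates])
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ beta


def semipartial_spearman(
    outcome,
    predictor,
    covariates,
    *,
    residualize: str = "predictor",
    p_method: str = "t",
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Semi-partial Spearman correlation controlling for covariates.

    All variables are rank-transformed first; the covariates are regressed
    out of the ranked ``predictor`` (or ``outcome``, if requested) by least
    squares and the residuals are correlated with the other ranked
    variable. Two-sided p-values come from the t approximation with
    df = n - 2 - n_covariates, or from a permutation test of the
    residualised variable.

    Returns ``(r_s, p)``.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(y):
        C = C.T
    n = len(y)
    n_cov = C.shape[1]
    if len(x) != n or C.shape[0] != n:
        raise StatsError("outcome, predictor and covariates must share length")
    if n <= n_cov + 2:
        raise StatsError("too few complete cases for the semi-partial correlation")
    for arr, name in ((y, "outcome"), (x, "predictor")):
        if len(np.unique(arr)) < 2:
            raise StatsError(f"{name} ranks are degenerate (constant)")

    ry = sps.rankdata(y)
    rx = sps.rankdata(x)
    rC = np.column_stack([sps.rankdata(C[:, j]) for j in range(n_cov)])
    if residualize == "predictor":
        resid, other = _residualise(rx, rC), ry
    elif residualize == "outcome":
        resid, other = _residualise(ry, rC), rx
    else:
        raise StatsError("residualize must be 'predictor' or 'outcome'")
    if np.allclose(resid, 0.0):
        raise StatsError("residualised variable is degenerate")

    r = float(np.corrcoef(resid, other)[0, 1])
    if p_method == "t":
        df = n - 2 - n_cov
        denom = max(1.0 - r * r, np.finfo(float).tiny)
        tval = r * np.sqrt(df / denom)
        p = float(2.0 * sps.t.sf(abs(tval), df))
    elif p_method == "permutation":
        if rng is None:
            rng = np.random.default_rng()
        count = 0
        for _ in range(n_permutations):
            rp = float(np.corrcoef(rng.permutation(resid), other)[0, 1])
            if abs(rp) >= abs(r):
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise StatsError("p_method must be 't' or 'permutation'")
    return r, min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Equivalent to sorting ascending and taking
    p_adj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1. The family is
    the full set of supplied p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def cohens_d_from_r(r: float) -> float:
    """Cohen's d from a correlation: d = 2r / sqrt(1 - r^2)."""
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise StatsError("|r| must be < 1 for a finite d")
    return float(2.0 * r / np.sqrt(1.0 - r * r))


@dataclass
class CorrelationTest:
    """One of the eight semi-partial tests."""

    task: str
    outcome: str
    r_s: float
    p_raw: float
    p_adjusted: float
    d: float


@dataclass
class CohortAnalysis:
    """Full statistical analysis of one cohort."""

    table: pd.DataFrame
    pca: PcaResult
    n_participants: int
    n_excluded: int
    fit_errors: list

    def summary_json(self) -> dict:
        return dict(
            n_participants=self.n_participants,
            n_excluded=self.n_excluded,
            eigenvalues=[float(v) for v in self.pca.eigenvalues],
            loadings=[float(v) for v in self.pca.loadings],
            variance_explained=[float(v) for v in self.pca.variance_explained],
        )


def analyze_cohort(
    cohort,
    *,
    residualize: str = "predictor",
    p_method: str = "t",
    log_space_fit: bool = False,
    alpha: float = 0.05,
) -> CohortAnalysis:
    """Run the full eight-test analysis on a cohort.

    Fits the two-limbed function to every participant's motion and form
    curves, computes the PCA reading composite, and tests each of the eight
    outcomes (acuity, k, t, s per task) against the composite with
    semi-partial Spearman correlations controlling gender and IQ,
    BH-adjusted across the eight-test family. Participants whose curve fit
    fails are excluded from all tests (their errors are reported).
    """
    records = list(cohort.records)
    fit_errors = []
    per_participant = []
    for rec in records:
        row = {}
        failed = False
        for task in TASKS:
            out = rec.task(task)
            row[(task, "acuity")] = out.acuity
            try:
                fit = fit_two_limb(out.curve, log_space=log_space_fit)
            except CurveFitError as exc:
                fit_errors.append((rec.id, task, str(exc)))
                failed = True
                break
            row[(task, "k")] = fit.k
            row[(task, "t")] = fit.t
            row[(task, "s")] = fit.s
        if not failed:
            per_participant.append((rec, row))

    if len(per_participant) < 8:
        raise StatsError("need at least 8 complete records after exclusions")

    kept = [rec for rec, _ in per_participant]
    reading = np.array([rec.reading_raw for rec in kept])
    pca = pca_composite(reading)
    composite = pca.component_scores
    covariates = np.column_stack(
        [[rec.gender for rec in kept], [rec.iq for rec in kept]]
    )

    rows = []
    for task in TASKS:
        for outcome in OUTCOMES:
            values = np.array([row[(task, outcome)] for _, row in per_participant])
            r, p = semipartial_spearman(
                values, composite, covariates,
                residualize=residualize, p_method=p_method,
            )
            rows.append(dict(task=task, outcome=outcome, r_s=r, p_raw=p, d=cohens_d_from_r(r)))
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] <= alpha
    table = table[["task", "outcome", "r_s", "p_raw", "p_adjusted", "d", "significant"]]
    return CohortAnalysis(
        table=table,
        pca=pca,
        n_participants=len(kept),
        n_excluded=len(records) - len(kept),
        fit_errors=fit_errors,
    )
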