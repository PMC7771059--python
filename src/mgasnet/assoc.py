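"""Univariate association stage.

Three steps feed the gene-based combination: a one-way ANOVA screen of
traits across diagnostic groups, per-SNP-per-trait linear regression with
covariate adjustment (additive genetic model), and the trait correlation
matrix that encodes the dependence among the per-trait tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "PhenotypeScreenResult",
    "PValueMatrix",
    "TraitCorrelation",
    "phenotype_screen",
    "snp_qt_regression",
    "trait_correlation",
]


@dataclass
class PhenotypeScreenResult:
    table: pd.DataFrame  # trait, F, p, passed
    alpha: float

    @property
    def passed_traits(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "trait"])


@dataclass
class PValueMatrix:
    snps: list[str]
    traits: list[str]
    p: np.ndarray        # SNP x trait, in (0, 1]
    beta: np.ndarray     # SNP x trait
    n_used: np.ndarray   # SNP x trait sample counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.snps, columns=self.traits)

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.snps, columns=self.traits)


@dataclass
class TraitCorrelation:
    traits: list[str]
    R_T: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R_T, index=self.traits, columns=self.traits)


def phenotype_screen(
    phenotypes: pd.DataFrame, diagnosis: pd.Series, alpha: float = 0.05
) -> PhenotypeScreenResult:
    """One-way ANOVA of each trait across diagnostic groups.

    A trait passes the screen iff its ANOVA p-value is below ``alpha``;
    only passing traits are carried into the genetic association stage.
    """
    diagnosis = diagnosis.loc[phenotypes.index]
    groups = {g: idx for g, idx in phenotypes.groupby(diagnosis, observed=True).groups.items()}
    if len(groups) < 2:
        raise ValueError("phenotype screen needs at least 2 diagnostic groups")
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"diagnostic group {g!r} has fewer than 2 samples")
    rows = []
    for trait in phenotypes.columns:
        x = phenotypes[trait]
        if np.ptp(x.to_numpy()) == 0:
            raise ValueError(f"trait {trait!r} is constant across all samples")
        F, p = stats.f_oneway(*(x.loc[idx].to_numpy() for idx in groups.values()))
        rows.append((trait, float(F), float(p), bool(p < alpha)))
    table = pd.DataFrame(rows, columns=["trait", "F", "p", "passed"])
    return PhenotypeScreenResult(table=table, alpha=alpha)


def _ols_pair(g: np.ndarray, y: np.ndarray, C: np.ndarray) -> tuple[float, float, int]:
    """Full OLS of y on [1, C, g]; returns (beta_g, p, n). Used on the
    slow path (missing data) — the fast path residualizes once."""
    n = len(y)
    X = np.column_stack([np.ones(n), C, g])
    XtX = X.T @ X
    try:
        coef = np.linalg.solve(XtX, X.T @ y)
    except np.linalg.LinAlgError:
        return 0.0, 1.0, n
    resid = y - X @ coef
    df = n - X.shape[1]
    if df <= 0:
        return 0.0, 1.0, n
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[-1, -1])
    if se == 0:
        return float(coef[-1]), 0.0 if coef[-1] != 0 else 1.0, n
    t = coef[-1] / se
    return float(coef[-1]), float(2 * stats.t.sf(abs(t), df)), n


def snp_qt_regression(
    genotypes: np.ndarray,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    snp_ids: list[str] | None = None,
) -> PValueMatrix:
    """OLS of each trait on each SNP dosage with covariates and intercept.

    Implemented by Frisch-Waugh residualization: traits and dosages are
    residualized on [1, covariates] once, then each SNP-trait pair reduces
    to a simple regression whose t-test (with the full-model degrees of
    freedom) is identical to the dosage coefficient test of the full OLS.

    Monomorphic SNPs get beta 0 and p 1 (with a logged count) so the
    matrix shape is stable downstream. Pairs with missing values fall back
    to per-pair listwise deletion.
    """
    G = np.asarray(genotypes, dtype=float)
    Y = phenotypes.to_numpy(dtype=float)
    C = covariates.to_numpy(dtype=float)
    if not (G.shape[0] == Y.shape[0] == C.shape[0]):
        raise ValueError("genotypes, phenotypes and covariates must share samples")
    n, n_snps = G.shape
    n_traits = Y.shape[1]
    snp_ids = snp_ids if snp_ids is not None else [f"SNP{i + 1}" for i in range(n_snps)]
    traits = list(phenotypes.columns)

    has_missing = np.isnan(G).any() or np.isnan(Y).any() or np.isnan(C).any()
    df = n - C.shape[1] - 2  # intercept + covariates + dosage
    if df <= 0:
        raise ValueError("not enough samples for the covariate model")

    p = np.ones((n_snps, n_traits))
    beta = np.zeros((n_snps, n_traits))
    n_used = np.full((n_snps, n_traits), n, dtype=int)

    if not has_missing:
        X = np.column_stack([np.ones(n), C])
        Q, _ = np.linalg.qr(X)
        My = Y - Q @ (Q.T @ Y)
        Mg = G - Q @ (Q.T @ G)
        gg = np.einsum("ij,ij->j", Mg, Mg)
        mono = gg <= 1e-12
        if mono.any():
            log.warning("%d monomorphic SNP(s): p recorded as 1", int(mono.sum()))
        gg_safe = np.where(mono, 1.0, gg)
        A = Mg.T @ My                              # SNP x trait cross products
        yy = np.einsum("ij,ij->j", My, My)
        beta = A / gg_safe[:, None]
        sse = np.maximum(yy[None, :] - A**2 / gg_safe[:, None], 0.0)
        se = np.sqrt(sse / df / gg_safe[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2 * stats.t.sf(np.abs(t), df)
        beta[mono, :] = 0.0
        p[mono, :] = 1.0
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        return PValueMatrix(snp_ids, traits, p, beta, n_used)

    for j in range(n_snps):
        for k in range(n_traits):
            mask = ~(np.isnan(G[:, j]) | np.isnan(Y[:, k]) | np.isnan(C).any(axis=1))
            g, y = G[mask, j], Y[mask, k]
            n_used[j, k] = mask.sum()
            if g.std() == 0:
                log.warning("monomorphic SNP %s after deletion: p=1", snp_ids[j])
                continue
            beta[j, k], p[j, k], _ = _ols_pair(g, y, C[mask])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return PValueMatrix(snp_ids, traits, p, beta, n_used)


def trait_correlation(phenotypes: pd.DataFrame) -> TraitCorrelation:
    """Pearson correlation matrix of the traits, clipped to PSD."""
    Y = phenotypes.to_numpy(dtype=float)
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 samples for trait correlation")
    if (Y.std(axis=0) == 0).any():
        bad = [c for c, s in zip(phenotypes.columns, Y.std(axis=0)) if s == 0]
        raise ValueError(f"constant trait(s): {bad}")
    R = np.corrcoef(Y, rowvar=False)
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-10:
        log.warning("trait correlation projected to nearest PSD (min eig %.3g)", w.min())
        w = np.clip(w, 0.0, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return TraitCorrelation(list(phenotypes.columns), R)
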