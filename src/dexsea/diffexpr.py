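"""Per-gene two-factor differential expression.

Each gene is fitted with the linear model

    y = b0 + b1 * tissue + b2 * genotype

by ordinary least squares, with tissue coded blood=0 / cerebellum=1 and
genotype coded wildtype=0 / transgenic=1, so a positive genotype coefficient
means up-regulation in transgenic animals. Two-sided p-values come from the
t distribution with n_samples - 3 residual degrees of freedom. The false
discovery rate is estimated with Storey-Tibshirani q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Raised when the sample design cannot support the model."""


@dataclass
class QValueFit:
    """Storey-Tibshirani q-value fit."""

    pi0: float
    lambda_grid: np.ndarray
    q_values: np.ndarray


def _design_matrix(design: SampleDesign) -> np.ndarray:
    tissue = (design.table["tissue"] == "cerebellum").to_numpy(dtype=float)
    geno = (design.table["genotype"] == "transgenic").to_numpy(dtype=float)
    if len(np.unique(tissue)) < 2:
        raise DesignError("tissue factor has a single level")
    if len(np.unique(geno)) < 2:
        raise DesignError("genotype factor has a single level")
    return np.column_stack([np.ones_like(tissue), tissue, geno])


def fit_gene_models(matrix: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Fit the tissue+genotype model to every gene.

    Returns a DataFrame indexed by gene with columns genotype_effect, t, p,
    q, signed_fold_change, tissue_effect, tissue_p. The result is
    deterministic and invariant to a joint permutation of sample columns and
    design rows. Genes with a numerically exact fit (residual variance below
    1e-12) get p = 1 when the coefficient is also ~0, else p = 0, with a
    warning.
    """
    if matrix.scale != "log2":
        raise ValueError("fit_gene_models expects a log2-scale matrix")
    design = design.aligned_to(matrix.sample_ids)
    X = _design_matrix(design)
    n_samples = X.shape[0]
    df_resid = n_samples - 3
    if df_resid <= 0:
        raise DesignError(f"need more than 3 samples, got {n_samples}")

    Y = matrix.values  # genes x samples
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x 3
    resid = Y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df_resid

    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    exact = sigma2 < 1e-12
    if exact.any():
        logger.warning(
            "fit_gene_models: %d gene(s) with ~zero residual variance; "
            "p set to 0/1 by coefficient magnitude", int(exact.sum())
        )

    def coef_p(k: int) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[:, k] / se[:, k]
        p = 2.0 * stats.t.sf(np.abs(t), df_resid)
        degenerate_p = np.where(np.abs(beta[:, k]) < 1e-12, 1.0, 0.0)
        p = np.where(exact, degenerate_p, p)
        t = np.where(exact, np.where(np.abs(beta[:, k]) < 1e-12, 0.0, np.inf), t)
        return t, p

    t_geno, p_geno = coef_p(2)
    _, p_tissue = coef_p(1)

    # Signed fold change from per-genotype linear-scale means.
    lin = np.power(2.0, Y)
    geno = X[:, 2].astype(bool)
    mean_tg = lin[:, geno].mean(axis=1)
    mean_wt = lin[:, ~geno].mean(axis=1)
    sfc = np.array(
        [signed_fold_change(a, b) for a, b in zip(mean_tg, mean_wt)]
    )

    qfit = storey_qvalues(p_geno)
    return pd.DataFrame(
        {
            "genotype_effect": beta[:, 2],
            "t": t_geno,
            "p": p_geno,
            "q": qfit.q_values,
            "signed_fold_change": sfc,
            "tissue_effect": beta[:, 1],
            "tissue_p": p_tissue,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    t = (mean_a - mean_b) / sqrt(va/na + vb/nb), with Welch-Satterthwaite
    degrees of freedom. Two zero-variance groups give t=0, p=1 when means
    are equal, else p=0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    denom2 = va / na + vb / nb
    if denom2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        logger.warning("welch_t_test: zero variance in both groups with "
                       "unequal means; p = 0")
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(denom2)
    df = denom2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def signed_fold_change(transgenic_mean_linear: float, wildtype_mean_linear: float) -> float:
    """Signed linear-scale fold change; negative means down in transgenic.

    Always >= 1 in magnitude: transgenic/wildtype if transgenic >= wildtype,
    else -(wildtype/transgenic).
    """
    if transgenic_mean_linear <= 0 or wildtype_mean_linear <= 0:
        raise ValueError("fold change requires positive linear-scale means")
    if transgenic_mean_linear >= wildtype_mean_linear:
        return float(transgenic_mean_linear / wildtype_mean_linear)
    return float(-(wildtype_mean_linear / transgenic_mean_linear))


def storey_qvalues(
    p_values: np.ndarray,
    pi0: float | None = None,
    lambda_grid: np.ndarray | None = None,
) -> QValueFit:
    """Storey-Tibshirani q-values.

    pi0 (the fraction of true nulls) is estimated by fitting a cubic
    smoother to pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over
    lambda in {0, 0.05, ..., 0.90} and evaluating it at lambda = 0.90,
    clipped to (0, 1]. For fewer than 100 tests the smoother is unstable and
    pi0 falls back to 1 (the Benjamini-Hochberg limit) with a warning. Pass
    ``pi0`` explicitly to override the estimate.

    q_i = min over thresholds t >= p_(i) of pi0 * m * t / #{p <= t},
    enforced monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.9001, 0.05)

    if pi0 is None:
        if m < 100:
            logger.warning(
                "storey_qvalues: only %d tests; pi0 smoother unstable, "
                "falling back to pi0 = 1", m,
            )
            pi0 = 1.0
        else:
            pi0_lambda = np.array(
                [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambda_grid]
            )
            coeffs = np.polynomial.polynomial.polyfit(lambda_grid, pi0_lambda, 3)
            pi0 = float(np.polynomial.polynomial.polyval(0.90, coeffs))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    # min over t >= p_(i) of pi0*m*t / #{p <= t}; candidate thresholds are
    # the observed p-values (the ratio is increasing between them).
    raw = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueFit(pi0=float(pi0), lambda_grid=lambda_grid, q_values=q)


def tissue_nonspecific_fraction(
    de: pd.DataFrame, alpha_genotype: float = 0.01, alpha_tissue: float = 0.05
) -> tuple[int, int, float]:
    """Among genotype-significant genes, count those with no significant
    blood-vs-brain difference.

    Returns (count_significant, count_tissue_flat, fraction); fraction is 0
    when nothing is significant.
    """
    if not (0 < alpha_genotype <= 1 and 0 < alpha_tissue <= 1):
        raise ValueError("alpha thresholds must be in (0, 1]")
    sig = de[de["p"] < alpha_genotype]
    n_sig = len(sig)
    n_flat = int((sig["tissue_p"] >= alpha_tissue).sum())
    frac = n_flat / n_sig if n_sig else 0.0
    return n_sig, n_flat, frac
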