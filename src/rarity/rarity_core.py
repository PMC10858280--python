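"""The block-wise heritability estimator.

For each genotype block G_k (n samples x p_k standardized columns) and a
standardized trait y, ordinary least squares gives fitted values
ŷ = G_k (G_k'G_k)^{-1} G_k' y and the block variance explained
R²_k = ŷ'ŷ / y'y.  The per-block heritability estimate is the adjusted R²,

    R̄²_k = 1 − (1 − R²_k)(n − 1)/(n − p_k − 1),

and total heritability is the sum over the K blocks, ĥ² = Σ_k R̄²_k —
valid when between-block correlation has been removed by LD pruning.  The
sampling variance of a squared multiple correlation (Algina's asymptotic
form),

    Var(R²_k) = 4 R²_k (1 − R²_k)² (n − p_k − 1)² / ((n² − 1)(n + 3)),

propagates through the adjustment factor to Wald 95% intervals per block
and, summing variances across (approximately uncorrelated) blocks, for ĥ².
Negative adjusted R² values are retained — truncation at zero would bias
the sum upward under the null.

Since y and every design column are standardized to mean 0, no intercept
is fitted and the degrees of freedom are n − p_k − 1 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import qr

from .blocks import BlockSet
from .phenotype_prep import PhenotypeVector

log = logging.getLogger(__name__)

Z975 = 1.96  # conventional two-sided 95% normal quantile


@dataclass
class BlockEstimate:
    label: str
    p_k: int
    r2: float
    adj_r2: float
    var_r2: float
    var_adj_r2: float
    ci95: tuple
    f_stat: float
    p_value: float


@dataclass
class HeritabilityResult:
    h2: float
    var_h2: float
    ci95: tuple
    n: int
    K: int
    blocks: list
    construct: str = "custom"
    samples: list | None = None

    def se(self) -> float:
        return float(np.sqrt(self.var_h2))

    def to_dict(self) -> dict:
        return {
            "h2": self.h2,
            "var_h2": self.var_h2,
            "se": self.se(),
            "ci95": list(self.ci95),
            "n": self.n,
            "K": self.K,
            "construct": self.construct,
        }


def r2_sampling_variance(r2: float, n: int, p_k: int) -> float:
    """Asymptotic Var(R²) for an n-sample, p_k-predictor OLS fit."""
    return 4.0 * r2 * (1.0 - r2) ** 2 * (n - p_k - 1) ** 2 / ((n * n - 1.0) * (n + 3.0))


def adjusted_r2(r2: float, n: int, p_k: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - p_k - 1.0)


def fit_block(G_k: np.ndarray, y, label: str = "block") -> BlockEstimate:
    """OLS fit of one block; returns R², adjusted R², variances, CI, F-test.

    ``G_k`` is an n x p_k standardized design and ``y`` a standardized
    trait (PhenotypeVector or array).  The fit uses a pivoted QR
    factorization; if the design is rank-deficient the dependent columns
    are dropped and the effective predictor count replaces p_k (with a
    warning).  The F statistic tests R² > 0 on (p_k, n − p_k − 1) df.
    """
    yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    G_k = np.asarray(G_k, dtype=float)
    if G_k.ndim == 1:
        G_k = G_k[:, None]
    n, p = G_k.shape
    if yv.shape != (n,):
        raise ValueError(f"block {label}: y has length {yv.size}, expected {n}")
    if p >= n - 2:
        raise ValueError(
            f"block {label}: p_k={p} >= n-2={n - 2}; OLS needs p_k < n - 2"
        )
    Q, R, _ = qr(G_k, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = (diag.max() if diag.size else 0.0) * max(n, p) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p:
        log.warning("block %s: rank-deficient design (rank %d < p_k %d); "
                    "dependent columns dropped", label, rank, p)
        p = rank
    coef = Q[:, :rank].T @ yv
    yty = float(yv @ yv)
    r2 = float(coef @ coef) / yty
    r2 = min(max(r2, 0.0), 1.0)
    adj = adjusted_r2(r2, n, p)
    var_r2 = r2_sampling_variance(r2, n, p)
    factor = ((n - 1.0) / (n - p - 1.0)) ** 2
    var_adj = factor * var_r2
    half = Z975 * np.sqrt(var_adj)
    df2 = n - p - 1
    if r2 >= 1.0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = (r2 / p) / ((1.0 - r2) / df2)
        p_value = float(stats.f.sf(f_stat, p, df2))
    return BlockEstimate(
        label=label, p_k=p, r2=r2, adj_r2=adj,
        var_r2=var_r2, var_adj_r2=var_adj,
        ci95=(adj - half, adj + half),
        f_stat=float(f_stat), p_value=p_value,
    )


def estimate_h2(blockset: BlockSet, y) -> HeritabilityResult:
    """Sum per-block adjusted R² over a BlockSet into a total ĥ² with CI.

    Blocks are fitted independently (any execution order yields the same
    result); variance of the sum is the sum of per-block variances, which
    assumes between-block correlation was removed by LD pruning upstream.
    """
    yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    if isinstance(y, PhenotypeVector) and y.state != "standardized":
        log.warning("phenotype state is %r, not 'standardized'", y.state)
    ests = []
    for b in blockset.blocks:
        try:
            ests.append(fit_block(blockset.design[:, b.columns], yv, label=b.label))
        except ValueError as err:
            raise ValueError(f"block {b.label}: {err}") from err
    h2 = float(sum(e.adj_r2 for e in ests))
    var_h2 = float(sum(e.var_adj_r2 for e in ests))
    half = Z975 * np.sqrt(var_h2)
    return HeritabilityResult(
        h2=h2, var_h2=var_h2, ci95=(h2 - half, h2 + half),
        n=int(blockset.design.shape[0]), K=len(ests), blocks=ests,
        construct=blockset.construct,
        samples=list(blockset.samples) if blockset.samples else None,
    )


def gene_significance(results, n_genes: int | None = None, alpha: float = 0.05):
    """Bonferroni gene-level significance table from per-gene estimates.

    ``results`` is a list of BlockEstimate (one per gene).  The threshold
    is ``alpha / n_genes`` (strict <), with ``n_genes`` defaulting to the
    number of results.  Returns a DataFrame sorted by p-value with the
    threshold attached in ``.attrs['threshold']`` (3 significant digits in
    the reported column).
    """
    import pandas as pd

    if n_genes is None:
        n_genes = len(results)
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    threshold = alpha / n_genes
    tab = pd.DataFrame(
        {
            "gene": [e.label for e in results],
            "p_k": [e.p_k for e in results],
            "h2_gene": [e.adj_r2 for e in results],
            "f_stat": [e.f_stat for e in results],
            "p_value": [e.p_value for e in results],
        }
    )
    tab["significant"] = tab["p_value"] < threshold
    tab = tab.sort_values("p_value", kind="stable").reset_index(drop=True)
    tab.attrs["threshold"] = float(f"{threshold:.3g}")
    tab.attrs["n_genes"] = int(n_genes)
    return tab


def compare_estimates(a: HeritabilityResult, b: HeritabilityResult):
    """Two-sample z-test for a difference in heritability between strata.

    Valid only for disjoint sample strata (checked when both results carry
    sample ids).  Returns (z, two-sided normal p).
    """
    if a.samples is not None and b.samples is not None:
        overlap = set(a.samples) & set(b.samples)
        if overlap:
            raise ValueError(
                f"strata share {len(overlap)} sample(s); comparison requires "
                "disjoint strata"
            )
    denom = np.sqrt(a.var_h2 + b.var_h2)
    if denom == 0:
        raise ValueError("both estimates have zero variance")
    z = (a.h2 - b.h2) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
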