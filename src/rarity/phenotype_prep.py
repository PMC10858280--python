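"""Phenotype preparation: medication adjustment, winsorization, rank-based
inverse-normal transform, covariate residualization, standardization.

The estimator consumes one standardized trait per sample.  Preparation runs
in a fixed order: winsorize (optional) -> mean-impute missing values ->
Blom inverse-normal transform -> OLS residualization on covariates (age,
sex, genetic PCs, ...) -> standardize to mean 0 / variance 1.  Medication
effects on biomarkers are undone first with the conventional published
corrections (e.g. statin users' LDL divided by 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats


@dataclass
class PhenotypeVector:
    """One trait aligned to the genotype sample order."""

    samples: list
    y: np.ndarray
    state: str = "raw"
    trait: str | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.samples),):
            raise ValueError("y must have one value per sample")


@dataclass(frozen=True)
class MedicationRule:
    action: str  # divide | add | exclude_sample
    value: float = 0.0

    def __post_init__(self):
        if self.action not in ("divide", "add", "exclude_sample"):
            raise ValueError(f"unknown medication action {self.action!r}")
        if self.action == "divide" and self.value <= 0:
            raise ValueError("divide rule requires a positive divisor")


@dataclass
class MedicationRules:
    """trait name -> correction applied to samples flagged as medicated."""

    rules: dict = field(default_factory=dict)

    def for_trait(self, trait: str) -> MedicationRule:
        key = str(trait).lower()
        if key not in self.rules:
            raise KeyError(
                f"no medication rule for trait {trait!r}; "
                f"known: {', '.join(sorted(self.rules))}"
            )
        return self.rules[key]


#: Shipped defaults: statins attenuate lipids by known multiplicative
#: factors; blood-pressure medication is corrected additively; samples on
#: glucose-lowering drugs are excluded outright.
DEFAULT_MEDICATION_RULES = MedicationRules(rules={
    "ldl": MedicationRule("divide", 0.7),
    "apob": MedicationRule("divide", 0.7),
    "cholesterol": MedicationRule("divide", 0.8),
    "apoa1": MedicationRule("divide", 1.06),
    "hdl": MedicationRule("divide", 1.05),
    "dbp": MedicationRule("add", 10.0),
    "sbp": MedicationRule("add", 15.0),
    "glucose": MedicationRule("exclude_sample"),
    "hba1c": MedicationRule("exclude_sample"),
})


def adjust_for_medication(
    y: PhenotypeVector,
    flags,
    rules: MedicationRules | None = None,
) -> PhenotypeVector:
    """Undo medication effects for flagged samples.

    ``flags`` is a boolean array aligned to ``y.samples`` marking samples on
    the medication relevant to ``y.trait``.  divide/add rules modify flagged
    values; an ``exclude_sample`` rule removes flagged samples entirely.
    """
    rules = rules or DEFAULT_MEDICATION_RULES
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (len(y.samples),):
        raise ValueError("flags must align with samples")
    if y.trait is None:
        raise ValueError("PhenotypeVector.trait must be set to look up a rule")
    rule = rules.for_trait(y.trait)
    if rule.action == "exclude_sample":
        keep = ~flags
        return PhenotypeVector(
            samples=[s for s, k in zip(y.samples, keep) if k],
            y=y.y[keep], state=y.state, trait=y.trait,
        )
    out = y.y.copy()
    if rule.action == "divide":
        out[flags] = out[flags] / rule.value
    else:
        out[flags] = out[flags] + rule.value
    return replace(y, y=out)


def inverse_normal(values: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse-normal transform, Blom offset by default.

    Maps value with (average, for ties) rank r among n to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``; with offset 3/8 this is
    the Blom transform whose output closely resembles a standard normal.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def _residualize(y: np.ndarray, covariates) -> np.ndarray:
    import pandas as pd

    C = pd.DataFrame(covariates)
    names = list(C.columns)
    X = np.column_stack([np.ones(y.size), C.to_numpy(dtype=float)])
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means[None, :], X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns via pivoted QR on the covariates
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
        bad_names = [("intercept" if j == 0 else names[j - 1]) for j in bad]
        raise ValueError(f"collinear covariate column(s): {', '.join(bad_names)}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def standardize(y: np.ndarray) -> np.ndarray:
    sd = y.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant phenotype")
    return (y - y.mean()) / sd


def prepare(
    y: PhenotypeVector,
    covariates=None,
    winsor_limits: tuple[float, float] | None = None,
) -> PhenotypeVector:
    """Full preparation pipeline; returns a standardized PhenotypeVector.

    ``winsor_limits`` are value bounds (lo, hi) clipped before anything
    else.  Missing trait values are mean-imputed.  ``covariates`` is an
    optional table (DataFrame or 2-D array) aligned to the samples; the
    inverse-normal trait is residualized on it (with intercept) before
    final standardization, so the output is exactly orthogonal to every
    covariate column.
    """
    vals = y.y.copy()
    if winsor_limits is not None:
        lo, hi = winsor_limits
        if lo > hi:
            raise ValueError("winsor_limits must satisfy lo <= hi")
        vals = np.clip(vals, lo, hi)
    missing = np.isnan(vals)
    if missing.all():
        raise ValueError("phenotype is entirely missing")
    if missing.any():
        vals[missing] = vals[~missing].mean()
    if np.unique(vals).size == 1:
        raise ValueError("constant phenotype")
    z = inverse_normal(vals)
    if covariates is not None:
        z = _residualize(z, covariates)
    z = standardize(z)
    return PhenotypeVector(samples=list(y.samples), y=z,
                           state="standardized", trait=y.trait)
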