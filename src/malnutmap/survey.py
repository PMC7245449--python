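"""Design-based estimation for stratified, clustered, weighted survey data.

Point estimates are Horvitz-Thompson ratio estimates; standard errors come
from Taylor linearization with the with-replacement approximation at the
first stage (PSU totals within strata).  Confidence intervals for proportions
are Wald intervals on the logit scale, back-transformed so they stay inside
[0, 1].  Tests of association between categorical variables use the weighted
Pearson chi-square with the Rao-Scott second-order (Satterthwaite)
correction, referenced to an F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "PrevalenceEstimate",
    "RaoScottResult",
    "weighted_prevalence",
    "weighted_total",
    "rao_scott_chi2",
    "two_way_prevalence_table",
]


class EstimationError(ValueError):
    """Raised when a design-based estimate is undefined (e.g. empty domain)."""


@dataclass
class SurveyDesign:
    """Stratum, PSU and design-weight assignment, one entry per record."""

    strata: np.ndarray
    psus: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.psus = np.asarray(self.psus)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.weights)
        if len(self.strata) != n or len(self.psus) != n:
            raise ValueError("strata, psus and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("design weights must be strictly positive")
        # PSU labels are only meaningful within a stratum
        self._cluster = pd.MultiIndex.from_arrays(
            [self.strata, self.psus]
        ).to_flat_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(
            strata=df["stratum_id"].to_numpy(),
            psus=df["psu_id"].to_numpy(),
            weights=df["design_weight"].to_numpy(),
        )

    @property
    def n_psus(self) -> int:
        return len(set(self._cluster))

    @property
    def n_strata(self) -> int:
        return len(set(self.strata.tolist()))

    @property
    def degrees_of_freedom(self) -> int:
        """Design df: number of PSUs minus number of strata."""
        return self.n_psus - self.n_strata


@dataclass(frozen=True)
class PrevalenceEstimate:
    domain: str
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_valid: int
    weighted_total: float
    single_psu_strata: int = 0  # strata with one PSU: SE unreliable if > 0


def _linearized_covariance(
    scores: np.ndarray, design: SurveyDesign
) -> tuple[np.ndarray, int]:
    """Stratified with-replacement covariance of a total of linearized scores.

    ``scores`` is (n_records, k).  Returns (k, k) covariance and the number of
    single-PSU strata (which contribute nothing to the variance and make the
    SE an underestimate).
    """
    df = pd.DataFrame(scores)
    df["_stratum"] = design.strata
    df["_psu"] = design._cluster
    psu_totals = df.groupby(["_stratum", "_psu"], sort=False).sum()
    k = scores.shape[1]
    V = np.zeros((k, k))
    single = 0
    for _, block in psu_totals.groupby(level=0, sort=False):
        z = block.to_numpy()
        n_h = z.shape[0]
        if n_h < 2:
            single += 1
            continue
        dev = z - z.mean(axis=0, keepdims=True)
        V += (n_h / (n_h - 1)) * dev.T @ dev
    return V, single


def weighted_prevalence(
    y: Sequence,
    design: SurveyDesign,
    domain: Optional[Sequence] = None,
    label: str = "",
    alpha: float = 0.05,
) -> PrevalenceEstimate:
    """Survey-weighted prevalence with Taylor-linearized SE and logit CI.

    ``y`` is a 0/1 (or boolean) outcome per record, NaN allowed for records
    without a valid measurement; ``domain`` restricts estimation to a
    subpopulation while keeping the full design for variance estimation, the
    standard subdomain treatment.
    """
    y = np.asarray(y, dtype=float)
    d = np.ones(len(y), dtype=bool) if domain is None else np.asarray(domain, dtype=bool)
    valid = d & ~np.isnan(y)
    if not valid.any():
        raise EstimationError(f"no valid records in domain {label!r}")

    w = design.weights
    wd = np.where(valid, w, 0.0)
    W = wd.sum()
    yv = np.where(valid, y, 0.0)
    p_hat = float((wd * yv).sum() / W)
    total = float((wd * yv).sum())

    # linearized score for the ratio p = sum(w y)/sum(w) over the domain
    scores = (wd * (yv - p_hat) / W)[:, None]
    V, single = _linearized_covariance(scores, design)
    se = float(np.sqrt(max(V[0, 0], 0.0)))

    df_des = max(design.degrees_of_freedom, 1)
    tcrit = float(stats.t.ppf(1 - alpha / 2, df_des))
    if p_hat <= 0.0 or p_hat >= 1.0 or se == 0.0:
        lo = hi = p_hat
    else:
        logit = np.log(p_hat / (1 - p_hat))
        se_logit = se / (p_hat * (1 - p_hat))
        lo = float(1 / (1 + np.exp(-(logit - tcrit * se_logit))))
        hi = float(1 / (1 + np.exp(-(logit + tcrit * se_logit))))
    return PrevalenceEstimate(
        domain=label,
        p_hat=p_hat,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_valid=int(valid.sum()),
        weighted_total=total,
        single_psu_strata=single,
    )


def weighted_total(
    y: Sequence, design: SurveyDesign, domain: Optional[Sequence] = None
) -> float:
    """Extrapolated population total: sum of weights over valid positives."""
    y = np.asarray(y, dtype=float)
    d = np.ones(len(y), dtype=bool) if domain is None else np.asarray(domain, dtype=bool)
    valid = d & ~np.isnan(y)
    return float((design.weights * np.where(valid, y, 0.0)).sum())


@dataclass(frozen=True)
class RaoScottResult:
    statistic: float          # second-order corrected F statistic
    df: tuple                 # (numerator df, denominator df)
    p_value: float
    pearson_chi2: float       # uncorrected weighted Pearson X^2
    eigenvalues: np.ndarray   # generalized design effects
    design_df: int


def _independence_jacobian(p: np.ndarray, R: int, C: int) -> np.ndarray:
    """Jacobian of the independence residuals h_rc = p_rc - p_r. p_.c,
    r < R-1, c < C-1, with respect to the full cell-probability vector."""
    P = p.reshape(R, C)
    prow = P.sum(axis=1)
    pcol = P.sum(axis=0)
    H = np.zeros(((R - 1) * (C - 1), R * C))
    k = 0
    for r in range(R - 1):
        for c in range(C - 1):
            for a in range(R):
                for b in range(C):
                    v = 0.0
                    if a == r and b == c:
                        v += 1.0
                    if a == r:
                        v -= pcol[c]
                    if b == c:
                        v -= prow[r]
                    H[k, a * C + b] = v
            k += 1
    return H


def rao_scott_chi2(
    row_var: Sequence, col_var: Sequence, design: SurveyDesign
) -> RaoScottResult:
    """Weighted Pearson chi-square test of independence with the Rao-Scott
    second-order correction, referenced to F(d0, d0 * design_df)."""
    rows = pd.Categorical(np.asarray(row_var))
    cols = pd.Categorical(np.asarray(col_var))
    R, C = len(rows.categories), len(cols.categories)
    if R < 2 or C < 2:
        raise EstimationError("both variables need at least 2 observed levels")

    n = len(rows.codes)
    w = design.weights
    W = w.sum()
    # cell indicator matrix, one column per (row, col) cell
    E = np.zeros((n, R * C))
    E[np.arange(n), rows.codes * C + cols.codes] = 1.0
    p = (w[:, None] * E).sum(axis=0) / W
    P = p.reshape(R, C)
    prow, pcol = P.sum(axis=1), P.sum(axis=0)
    if np.any(prow == 0) or np.any(pcol == 0):
        raise EstimationError("degenerate table: a margin is entirely zero")

    expected = np.outer(prow, pcol)
    X2 = float(n * ((P - expected) ** 2 / expected).sum())

    scores = w[:, None] * (E - p) / W
    V, _ = _linearized_covariance(scores, design)
    V0 = (np.diag(p) - np.outer(p, p)) / n

    H = _independence_jacobian(p, R, C)
    A = H @ V0 @ H.T
    B = H @ V @ H.T
    lam = np.real(np.linalg.eigvals(np.linalg.solve(A, B)))
    lam = np.clip(lam, 0.0, None)

    sum_lam = lam.sum()
    sum_lam2 = (lam**2).sum()
    if X2 == 0.0 or sum_lam <= 0:
        df_des = max(design.degrees_of_freedom, 1)
        return RaoScottResult(0.0, ((R - 1) * (C - 1), df_des), 1.0, X2, lam, df_des)

    d0 = sum_lam**2 / sum_lam2  # Satterthwaite numerator df
    Fstat = X2 / sum_lam
    df_des = max(design.degrees_of_freedom, 1)
    p_value = float(stats.f.sf(Fstat, d0, d0 * df_des))
    return RaoScottResult(float(Fstat), (float(d0), float(d0 * df_des)), p_value, X2, lam, df_des)


def two_way_prevalence_table(
    df: pd.DataFrame,
    covariate: str,
    outcome: str,
    design: SurveyDesign,
    missing_label: str = "Missing",
) -> pd.DataFrame:
    """Weighted column-proportion table: distribution of a covariate within
    each outcome level, with logit-scale CIs per cell.

    Records with a missing covariate form an explicit ``Missing`` category;
    records with a missing outcome are dropped from all columns.
    """
    cov = df[covariate].astype(object).where(df[covariate].notna(), missing_label)
    out = df[outcome]
    rows = []
    for level in (True, False):
        in_level = (out == level) & out.notna()
        if not in_level.any():
            continue
        for cat in pd.unique(cov):
            est = weighted_prevalence(
                (cov == cat).astype(float),
                design,
                domain=in_level.to_numpy(),
                label=f"{outcome}={level}|{covariate}={cat}",
            )
            rows.append(
                {
                    "outcome_level": level,
                    "category": cat,
                    "proportion": est.p_hat,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n": est.n_valid,
                }
            )
    return pd.DataFrame(rows)
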