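"""Cohort-level statistics: group tests, partial rank correlations, FDR.

This layer mirrors how a dimensional-psychopathology cohort is analysed
once the per-subject normalized locus-coeruleus volume (``lc_norm``) is on
file: an independent-samples t-test between the healthy-control (HC) and
patient (PT) groups with a Cohen's d effect size, then two-tailed Spearman
correlations of ``lc_norm`` against six questionnaire scales (MASQ general
distress / anhedonic depression / anxious arousal; ATQ effortful-control
activation / attentional / inhibitory subscales), controlling for age and
for sex separately by rank residualization, with Benjamini-Hochberg FDR
correction across the six scales per covariate set.

Design notes
------------
* The group comparison defaults to the Welch (unequal-variance) t-test with
  Welch-Satterthwaite fractional df; demographic-table style replication
  uses the pooled variant with integer df.  Cohen's d always uses the
  pooled SD.
* Partial Spearman is the standard rank-residual construction: rank every
  variable (average ranks on ties), residualize the x- and y-ranks on the
  covariate ranks by least squares, and correlate the residuals; the
  two-tailed p comes from the t approximation with df = n - 2 - k.
* Missing data are handled complete-case per test, with the per-test n
  reported.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, SchemaError

#: questionnaire scales correlated with lc_norm (FDR family per covariate set)
SCALE_COLUMNS = [
    "masq_general_distress",
    "masq_anhedonic_depression",
    "masq_anxious_arousal",
    "atq_activation",
    "atq_attentional",
    "atq_inhibitory",
]

REQUIRED_COLUMNS = ["subject_id", "group", "age", "sex", "lc_norm"] + SCALE_COLUMNS


@dataclass
class StatResult:
    """One test's outcome: statistic, df, two-tailed p, effect size.

    ``effect`` is Cohen's d for mean comparisons and Spearman rho for rank
    correlations.  ``p_fdr`` is filled only when the test belongs to a
    multiplicity-corrected family.
    """

    statistic: float
    df: float
    p: float
    effect: float
    method: str
    n: int | tuple | None = None
    p_fdr: float | None = None
    mean_a: float | None = None
    mean_b: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_group(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise InsufficientDataError(f"group {name} needs n >= 2, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"group {name} contains non-finite values")
    return x


def _t_result(m1, v1, n1, m2, v2, n2, variant: str) -> StatResult:
    """Shared t machinery from first/second moments of the two groups."""
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = m1 - m2
    if variant == "pooled":
        df = float(n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(se2)
        if se2 == 0.0:
            df = float(n1 + n2 - 2)
        else:
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    if se == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    d = diff / np.sqrt(sp2) if sp2 > 0 else 0.0
    return StatResult(statistic=float(t), df=float(df), p=float(p),
                      effect=float(d), method=f"t_{variant}",
                      n=(int(n1), int(n2)), mean_a=float(m1), mean_b=float(m2))


def two_sample_t(a, b, variant: str = "welch") -> StatResult:
    """Two-tailed independent-samples t-test with Cohen's d (pooled SD)."""
    a = _validate_group(a, "a")
    b = _validate_group(b, "b")
    return _t_result(a.mean(), a.var(ddof=1), a.size,
                     b.mean(), b.var(ddof=1), b.size, variant)


def t_from_summary(m1: float, s1: float, n1: int,
                   m2: float, s2: float, n2: int,
                   variant: str = "pooled") -> StatResult:
    """Same test as :func:`two_sample_t`, from printed means/SDs/ns."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("summary SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2")
    return _t_result(m1, s1 ** 2, n1, m2, s2 ** 2, n2, variant)


def binary_t_from_counts(k1: int, n1: int, k2: int, n2: int) -> StatResult:
    """Pooled t-test on 0/1 indicator vectors expanded from counts.

    Fully determined by the printed counts (no rounding loss), which is how
    categorical demographic rows tested "by t-test" are reproduced exactly.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n")
        if n < 2:
            raise InsufficientDataError("each group needs n >= 2")
    a = np.concatenate([np.ones(k1), np.zeros(n1 - k1)])
    b = np.concatenate([np.ones(k2), np.zeros(n2 - k2)])
    return two_sample_t(a, b, variant="pooled")


def chi_square_2x2(a: int, b: int, c: int, d: int) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    table = np.asarray([[a, b], [c, d]], dtype=np.float64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateDataError("2x2 table has a zero margin")
    n = table.sum()
    expected = np.outer(rows, cols) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    # phi coefficient as the effect size for a 2x2 table
    phi = float(np.sign(a * d - b * c) * np.sqrt(chi2 / n))
    return StatResult(statistic=chi2, df=1.0, p=p, effect=phi,
                      method="chi2_2x2", n=int(n))


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(y.size), covs])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def spearman_partial(x, y, covariates: Sequence = ()) -> StatResult:
    """Two-tailed (partial) Spearman rank correlation.

    With no covariates this is the ordinary Spearman rho (p from the t
    approximation, df = n-2).  With covariates, all variables are rank
    transformed, the x- and y-ranks are residualized on the covariate ranks
    by least squares, and the residuals are correlated; df = n - 2 - k.
    Rows with any missing value are dropped (complete cases).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    covs = [np.asarray(c, dtype=np.float64) for c in covariates]
    if y.size != x.size or any(c.size != x.size for c in covs):
        raise ValueError("all inputs must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    for c in covs:
        keep &= np.isfinite(c)
    x, y = x[keep], y[keep]
    covs = [c[keep] for c in covs]
    n = x.size
    k = len(covs)
    if n < 4 + k:
        raise InsufficientDataError(f"need at least {4 + k} complete cases, got {n}")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateDataError("constant variable after ranking")
    if k:
        rc = np.column_stack([_rank(c) for c in covs])
        rx = _residualize(rx, rc)
        ry = _residualize(ry, rc)
        if np.allclose(rx, 0) or np.allclose(ry, 0):
            raise DegenerateDataError("rank residuals are identically zero")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = float(n - 2 - k)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    method = "spearman" if k == 0 else f"spearman_partial_{k}cov"
    return StatResult(statistic=rho * np.sqrt(df / max(1.0 - rho ** 2, 1e-300)),
                      df=df, p=p, effect=rho, method=method, n=n)


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    adjusted(i) = min_{j >= i} p_(j) * m / j over the sorted p-values,
    clipped at 1, returned in the input order.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


# -------------------------------------------------------------- cohort table

def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError("cohort table missing required columns: "
                          + ", ".join(missing))
    bad = set(df["group"].unique()) - {"HC", "PT"}
    if bad:
        raise SchemaError(f"group labels must be HC/PT, found {sorted(bad)}")
    return df


def load_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def _encode_sex(s: pd.Series) -> np.ndarray:
    if s.dtype == object:
        return s.map({"M": 1.0, "F": 0.0}).to_numpy(dtype=np.float64)
    return s.to_numpy(dtype=np.float64)


@dataclass
class CohortReport:
    """Structured output of :func:`run_cohort_analysis`."""

    group_test: StatResult
    correlations: Dict[str, Dict[str, StatResult]]  # covariate -> scale -> result

    def to_dict(self) -> dict:
        return {
            "group_test": self.group_test.to_dict(),
            "correlations": {
                cov: {scale: r.to_dict() for scale, r in res.items()}
                for cov, res in self.correlations.items()
            },
        }

    def to_text(self) -> str:
        lines: List[str] = []
        g = self.group_test
        lines.append("Group comparison of lc_norm (PT vs HC)")
        lines.append(
            f"  t({g.df:.1f}) = {g.statistic:.3f}, p = {g.p:.4f}, "
            f"Cohen's d = {g.effect:.3f}, n = {g.n}"
        )
        for cov, res in self.correlations.items():
            lines.append(f"Spearman correlations with lc_norm, controlling {cov}")
            for scale, r in res.items():
                lines.append(
                    f"  {scale:28s} rho = {r.effect:+.3f}  p = {r.p:.4f}"
                    f"  p_fdr = {r.p_fdr:.4f}  (n = {r.n})"
                )
        return "\n".join(lines)


def run_cohort_analysis(table: pd.DataFrame, t_variant: str = "welch",
                        covariate_sets: Sequence[str] = ("age", "sex"),
                        ) -> CohortReport:
    """Full dimensional analysis of a cohort table.

    1. t-test (default Welch) of ``lc_norm``, patients vs controls, with
       Cohen's d (pooled SD).
    2. Partial Spearman correlations of ``lc_norm`` with the six scales,
       controlling each covariate in ``covariate_sets`` separately,
       BH-FDR corrected across the six scales within each covariate set.
    """
    df = validate_cohort(table)
    pt = df.loc[df["group"] == "PT", "lc_norm"].dropna().to_numpy()
    hc = df.loc[df["group"] == "HC", "lc_norm"].dropna().to_numpy()
    if pt.size < 2 or hc.size < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    group_test = two_sample_t(pt, hc, variant=t_variant)

    correlations: Dict[str, Dict[str, StatResult]] = {}
    lc = df["lc_norm"].to_numpy(dtype=np.float64)
    for cov_name in covariate_sets:
        if cov_name == "sex":
            cov = _encode_sex(df["sex"])
        else:
            cov = df[cov_name].to_numpy(dtype=np.float64)
        results = {
            scale: spearman_partial(lc, df[scale].to_numpy(dtype=np.float64),
                                    covariates=[cov])
            for scale in SCALE_COLUMNS
        }
        adj = fdr_bh([results[s].p for s in SCALE_COLUMNS])
        for s, q in zip(SCALE_COLUMNS, adj):
            results[s].p_fdr = float(q)
        correlations[cov_name] = results
    return CohortReport(group_test=group_test, correlations=correlations)
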