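"""Associations between brain-age attenuation and clinical change.

Clinical change over the trial is a delta (T0 minus T18, so a decrease is
positive).  Continuous deltas are tested with Pearson correlation, ordinal
food-frequency items with Kendall's tau-b, and two-level items with an
independent t-test.  Multiple comparisons are corrected with the
Benjamini-Hochberg FDR separately within each biomarker category
(anthropometry, liver, glycemic, lipids, imaging); food-frequency items
are reported uncorrected by default.  Both sides of an association can be
residualized on covariates (age, sex) first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BIOMARKER_CATEGORIES",
    "ClinicalTable",
    "AssociationResult",
    "delta",
    "percent_change",
    "pearson_test",
    "kendall_test",
    "independent_ttest",
    "residualize",
    "fdr_bh",
    "chi_square_gof",
    "hippocampal_occupancy",
    "run_association_suite",
]

#: the five pre-selected biomarker families used as FDR correction units;
#: "ffq" marks food-frequency items, which sit outside the FDR families
BIOMARKER_CATEGORIES = ("anthropometry", "liver", "glycemic", "lipids",
                        "imaging")


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    category: str
    stat_type: str  # "pearson_r" | "kendall_tau" | "t"
    statistic: float
    p: float
    q: float | None
    n: int

    @property
    def significant(self) -> bool | None:
        return None if self.q is None else bool(self.q <= 0.05)


@dataclass
class ClinicalTable:
    """Per-subject clinical variables with category tags.

    ``data`` holds one row per subject (index = subject id) and one column
    per variable; ``categories`` maps each variable to a biomarker
    category or "ffq"; ``ordinal`` and ``binary`` name the variables to be
    tested with Kendall's tau-b and the t-test respectively.
    """

    data: pd.DataFrame
    categories: dict[str, str]
    ordinal: frozenset = frozenset()
    binary: frozenset = frozenset()

    def __post_init__(self) -> None:
        allowed = set(BIOMARKER_CATEGORIES) | {"ffq"}
        for var, cat in self.categories.items():
            if cat not in allowed:
                raise ValueError(
                    f"unknown category {cat!r} for variable {var!r}"
                )
            if var not in self.data.columns:
                raise ValueError(f"variable {var!r} not in table")
        self.ordinal = frozenset(self.ordinal)
        self.binary = frozenset(self.binary)


def delta(value_t0, value_t18) -> np.ndarray:
    """Change over the trial: T0 minus T18 (a decrease is positive)."""
    t0 = np.asarray(value_t0, dtype=float)
    t18 = np.asarray(value_t18, dtype=float)
    if t0.shape != t18.shape:
        raise ValueError("T0/T18 shapes differ")
    return t0 - t18


def percent_change(value_t0, value_t18) -> np.ndarray:
    """100 * (T18 - T0) / T0; negative = reduction from baseline."""
    t0 = np.asarray(value_t0, dtype=float)
    t18 = np.asarray(value_t18, dtype=float)
    if np.any(t0 == 0):
        raise ValueError("zero baseline value")
    return 100.0 * (t18 - t0) / t0


def pearson_test(x, y) -> dict[str, float]:
    """Pearson r with the two-sided t-transform p (n - 2 df)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(x)}


def kendall_test(x, y) -> dict[str, float]:
    """Kendall's tau-b (tie-corrected).  Exact p by enumeration for small
    untied samples, normal approximation otherwise."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("all-tied input")
    no_ties = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    method = "exact" if (len(x) <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return {"tau": float(res.statistic), "p": float(res.pvalue),
            "n": len(x)}


def independent_ttest(
    group_a, group_b, equal_var: bool = True
) -> dict[str, float]:
    """Two-sample t-test, pooled variance by default (Welch optional)."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "n": len(a) + len(b)}


def residualize(y, covariates) -> np.ndarray:
    """OLS residuals of y on covariates plus an intercept."""
    y = np.asarray(y, dtype=float).ravel()
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != len(y):
        raise ValueError("covariate rows must match y length")
    if len(y) <= C.shape[1] + 1:
        raise ValueError("too few observations for the covariate design")
    X = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def fdr_bh(pvalues, alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return {"q": p, "reject": np.zeros(0, dtype=bool)}
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    # rejection by the adjusted p, consistent with q <= alpha
    return {"q": q, "reject": q <= alpha}


def chi_square_gof(counts, expected=None) -> dict[str, float]:
    """Chi-square goodness of fit against uniform (or given) expectations."""
    obs = np.asarray(counts, dtype=float).ravel()
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("counts must be nonnegative with positive total")
    if expected is None:
        expected = np.full(obs.shape, obs.sum() / obs.size)
    expected = np.asarray(expected, dtype=float).ravel()
    if np.any(expected <= 0):
        raise ValueError("expected cell counts must be positive")
    res = stats.chisquare(obs, expected)
    return {"x2": float(res.statistic), "p": float(res.pvalue),
            "df": obs.size - 1}


def hippocampal_occupancy(
    hipp_left, ilv_left, hipp_right, ilv_right
) -> np.ndarray:
    """Hippocampal occupancy score: h / (h + inferior-lateral-ventricle
    volume) per hemisphere, averaged across hemispheres.  All volumes in
    the same units; hippocampal volumes must be positive (a zero ventricle
    gives the boundary value 1)."""
    hl = np.asarray(hipp_left, dtype=float)
    vl = np.asarray(ilv_left, dtype=float)
    hr = np.asarray(hipp_right, dtype=float)
    vr = np.asarray(ilv_right, dtype=float)
    if np.any(hl <= 0) or np.any(hr <= 0):
        raise ValueError("hippocampal volumes must be positive")
    if np.any(vl < 0) or np.any(vr < 0):
        raise ValueError("ventricle volumes must be nonnegative")
    return (hl / (hl + vl) + hr / (hr + vr)) / 2.0


def run_association_suite(
    attenuation,
    clinical: ClinicalTable,
    covariates=None,
    alpha: float = 0.05,
    include_ffq_in_fdr: bool = False,
    equal_var: bool = True,
) -> list[AssociationResult]:
    """Test every clinical variable against brain-age attenuation.

    Continuous variables -> Pearson; ``clinical.ordinal`` -> Kendall
    tau-b; ``clinical.binary`` -> independent t-test over the two levels.
    Missing values are handled pairwise-complete per variable with the n
    used logged per test.  If ``covariates`` is given (subjects x
    covariates, aligned with the table), both the attenuation and each
    continuous variable are residualized on them first.  BH-FDR is applied
    within each biomarker category; "ffq" items are left uncorrected
    unless ``include_ffq_in_fdr``.
    """
    att = np.asarray(attenuation, dtype=float).ravel()
    if len(att) != len(clinical.data):
        raise ValueError("attenuation length must match the clinical table")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != len(att):
            raise ValueError("covariate rows must match subject count")

    raw: list[AssociationResult] = []
    for var, cat in clinical.categories.items():
        vals = clinical.data[var].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(att)
        if cov is not None:
            ok &= np.all(np.isfinite(cov), axis=1)
        n_dropped = int(len(vals) - ok.sum())
        if n_dropped:
            logger.info("%s: dropped %d subjects with missing values",
                        var, n_dropped)
        v, a = vals[ok], att[ok]
        if var in clinical.binary:
            levels = np.unique(v)
            if len(levels) != 2:
                raise ValueError(f"{var!r} is not two-level")
            res = independent_ttest(
                a[v == levels[0]], a[v == levels[1]], equal_var=equal_var
            )
            raw.append(AssociationResult(var, cat, "t", res["t"],
                                         res["p"], None, res["n"]))
        elif var in clinical.ordinal:
            res = kendall_test(v, a)
            raw.append(AssociationResult(var, cat, "kendall_tau",
                                         res["tau"], res["p"], None,
                                         res["n"]))
        else:
            if cov is not None:
                a_r = residualize(a, cov[ok])
                v_r = residualize(v, cov[ok])
            else:
                a_r, v_r = a, v
            res = pearson_test(v_r, a_r)
            raw.append(AssociationResult(var, cat, "pearson_r", res["r"],
                                         res["p"], None, res["n"]))

    # BH within each category family
    out: list[AssociationResult] = []
    families: dict[str, list[int]] = {}
    for i, r in enumerate(raw):
        if r.category == "ffq" and not include_ffq_in_fdr:
            continue
        families.setdefault(r.category, []).append(i)
    qmap: dict[int, float] = {}
    for idx in families.values():
        q = fdr_bh([raw[i].p for i in idx], alpha=alpha)["q"]
        qmap.update(dict(zip(idx, q)))
    for i, r in enumerate(raw):
        out.append(AssociationResult(
            r.variable, r.category, r.stat_type, r.statistic, r.p,
            float(qmap[i]) if i in qmap else None, r.n,
        ))
    return out
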