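"""Group-comparison statistics for cohort summary tables.

Covers the statistics used in demographic and outcome tables: Welch's
unequal-variance t test computed from summary data (mean, SD, n), Pearson
chi-square tests of independence on contingency tables, per-group frequency
tallies with printed-style percentages, Benjamini-Hochberg FDR adjustment,
and a one-way MANCOVA (Wilks' lambda via hypothesis/error cross-product
matrices, Rao's F approximation) with per-response post hoc ANCOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import SubjectRecord

__all__ = [
    "GroupSummary",
    "welch_t",
    "pooled_t",
    "chi_square",
    "tally",
    "bh_adjust",
    "mancova_wilks",
    "MancovaResult",
    "AncovaResult",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (mean, sd, n) of one variable in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Welch's t and Welch-Satterthwaite df for a - b from summary data.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b); fractional df.  Raises if
    both groups have zero variance (t undefined unless means differ, in
    which case it is infinite and still reported as an error).
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df)


def pooled_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Student's pooled-variance t (df = n_a + n_b - 2); for completeness."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    return float(t), float(df)


def t_pvalue(t: float, df: float) -> float:
    """Two-sided p from the t reference distribution."""
    return float(2.0 * stats.t.sf(abs(t), df))


def chi_square(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df for an r x c contingency table
    (expected counts from the margins, no continuity correction)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.size == 0:
        raise ValueError("contingency table must be 2-dimensional and non-empty")
    if (tab < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    if tab.sum() <= 0:
        raise ValueError("contingency table total must be > 0")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    res = stats.chi2_contingency(tab, correction=False)
    return float(res.statistic), int(res.dof)


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10.0**decimals
    return np.floor(x * factor + 0.5) / factor


def tally(subjects: list[SubjectRecord], field: str) -> pd.DataFrame:
    """Per-group counts and percentages of subjects endorsing each label.

    ``field`` is 'affects' or 'concern_types'.  A subject counts once per
    label no matter how many of their concerns repeat it.  Percentages are
    of the group n, rounded half-up to 1 decimal as in printed tables.
    """
    if field not in ("affects", "concern_types"):
        raise ValueError(f"field must be 'affects' or 'concern_types', got '{field}'")
    group_n: dict[str, int] = {}
    counts: dict[tuple[str, str], int] = {}
    labels_seen: list[str] = []
    for s in subjects:
        group_n[s.group] = group_n.get(s.group, 0) + 1
        endorsed: set[str] = set()
        for c in s.concerns:
            if field == "affects":
                endorsed.update(a.label for a in c.affects)
            else:
                endorsed.update(c.concern_types)
        for lab in endorsed:
            if lab not in labels_seen:
                labels_seen.append(lab)
            counts[(s.group, lab)] = counts.get((s.group, lab), 0) + 1
    rows = []
    for lab in labels_seen:
        for grp, n in group_n.items():
            cnt = counts.get((grp, lab), 0)
            rows.append(
                {
                    "label": lab,
                    "group": grp,
                    "count": cnt,
                    "n": n,
                    "percent": _round_half_up(100.0 * cnt / n, 1),
                }
            )
    return pd.DataFrame(rows, columns=["label", "group", "count", "n", "percent"])


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# MANCOVA


@dataclass
class AncovaResult:
    response: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    cohen_f: float


@dataclass
class MancovaResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float
    n: int
    responses: list[str]
    posthoc: list[AncovaResult]


def _design(group, covariates, n):
    """Full and reduced (no group) design matrices with intercept."""
    g = np.asarray(group)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    dummy = (g == levels[1]).astype(float).reshape(-1, 1)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    dropped = []
    for i, cov in enumerate(covariates):
        c = np.asarray(cov, dtype=float).reshape(-1, 1)
        name = f"covariate_{i}"
        if np.ptp(c) == 0:
            dropped.append(name)  # constant: collinear with the intercept
            continue
        cols.append(c)
        names.append(name)
    X_red = np.hstack(cols)
    X_full = np.hstack(cols + [dummy])
    names_full = names + ["group"]
    r = np.linalg.matrix_rank(X_full)
    if r < X_full.shape[1]:
        # identify a collinear column by leave-one-out rank
        bad = [
            names_full[j]
            for j in range(X_full.shape[1])
            if np.linalg.matrix_rank(np.delete(X_full, j, axis=1)) == r
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X_full, X_red, dropped


def _resid_crossprod(Y, X):
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R


def mancova_wilks(
    responses,
    group,
    covariates=(),
    response_names: list[str] | None = None,
    posthoc: bool = True,
) -> MancovaResult:
    """One-way MANCOVA: Wilks' lambda for the group effect after covariates.

    E is the residual cross-product matrix of the full model (intercept +
    covariates + group); H is the extra cross-product explained by group
    over the covariate-only model.  Lambda = det(E) / det(E + H), converted
    to an F statistic by Rao's approximation (exact for a 2-level factor).
    Post hoc per-response ANCOVA F tests (with partial eta^2 and Cohen's f)
    are attached when ``posthoc`` is true.
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n, p = Y.shape
    names = response_names or [f"y{j}" for j in range(p)]
    X_full, X_red, _dropped = _design(group, covariates, n)
    q = X_full.shape[1] - 1  # non-intercept predictors incl. group
    if n <= p + q + 1:
        raise ValueError(
            f"n={n} too small for p={p} responses and {q} predictors"
        )

    E = _resid_crossprod(Y, X_full)
    E_red = _resid_crossprod(Y, X_red)
    H = E_red - E

    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0:
        raise ValueError("error cross-product matrix is singular; collinear responses?")
    lam = float(np.exp(logdet_E - np.linalg.slogdet(E + H)[1]))

    nu_h = 1.0  # 2-level factor
    nu_e = float(n - X_full.shape[1])
    # Rao's F approximation (exact when min(p, nu_h) <= 2)
    s = 1.0
    if p**2 + nu_h**2 - 5 > 0:
        s = np.sqrt((p**2 * nu_h**2 - 4) / (p**2 + nu_h**2 - 5))
    df1 = p * nu_h
    df2 = s * (nu_e - (p - nu_h + 1) / 2.0) - (p * nu_h - 2) / 2.0
    lam_s = lam ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))

    post = []
    if posthoc:
        for j in range(p):
            ss_e = float(E[j, j])
            ss_h = float(H[j, j])
            d2 = int(nu_e)
            Fj = (ss_h / nu_h) / (ss_e / d2)
            eta = ss_h / (ss_h + ss_e)
            post.append(
                AncovaResult(
                    response=names[j],
                    F=float(Fj),
                    df1=int(nu_h),
                    df2=d2,
                    p=float(stats.f.sf(Fj, nu_h, d2)),
                    partial_eta_sq=float(eta),
                    cohen_f=float(np.sqrt(eta / (1 - eta))) if eta < 1 else float("inf"),
                )
            )

    return MancovaResult(
        wilks_lambda=lam,
        F=float(F),
        df1=float(df1),
        df2=float(df2),
        p=pval,
        n=n,
        responses=names,
        posthoc=post,
    )
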