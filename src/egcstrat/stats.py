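"""Cohort statistics: contingency tests, rank tests, multiple-testing
correction, and disease-free-survival models.

Conventions match small-cohort clinical genomics reporting:

* 2x2 tables use Fisher's exact test when any expected count is below 5 and
  the Pearson chi-square (no continuity correction) otherwise.
* The two-sided Fisher p-value follows the point-probability rule: the sum of
  hypergeometric probabilities, margins fixed, of every table at most as
  probable as the observed one.
* Rank comparisons are two-sided Wilcoxon rank-sum (Mann-Whitney U) tests,
  exact for small untied samples, normal approximation with tie correction
  otherwise; families of p-values are corrected with Benjamini-Hochberg.
* Survival uses Cox proportional-hazards partial likelihood with Breslow tie
  handling, Wald confidence intervals, and a scaled-Schoenfeld-residual test
  of the proportional-hazards assumption; group curves are Kaplan-Meier with
  log-rank tests.

Disease-free survival (DFS) is time from surgery to recurrence or death from
any cause, whichever occurs first.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests


class TestMethod(str, Enum):
    __test__ = False  # API class, not a pytest item

    FISHER_EXACT = "fisher_exact"
    PEARSON_CHI2 = "pearson_chi2"
    MANN_WHITNEY = "mann_whitney"
    WILCOXON_RANK_SUM = "wilcoxon_rank_sum"
    T_TEST = "t_test"
    LOGRANK = "logrank"


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: method, statistic (when defined), p-value, and an
    optional BH-adjusted p."""

    __test__ = False  # API class, not a pytest item

    method: TestMethod
    statistic: float | None
    p_value: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b (row 1) and c, d (row 2); rows = groups, columns = levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        """Expected counts under independence with fixed margins."""
        m = self.as_array()
        return np.outer(m.sum(axis=1), m.sum(axis=0)) / m.sum()


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox PH fit for one covariate (one level vs reference)."""

    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    schoenfeld_p: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.hazard_ratio <= self.ci_high:
            raise ValueError(
                f"{self.covariate}: HR {self.hazard_ratio} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


def fisher_exact_2x2(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test by the point-probability rule."""
    if t.total == 0:
        raise ValueError("all-zero table cannot be tested")
    odds, p = st.fisher_exact(t.as_array(), alternative="two-sided")
    return TestResult(TestMethod.FISHER_EXACT, None, float(min(p, 1.0)))


def pearson_chi2_2x2(t: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    Uses the closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); any zero margin
    is rejected (the statistic is undefined there).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("chi-square undefined for a table with a zero margin")
    n = t.total
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(st.chi2.sf(stat, df=1))
    return TestResult(TestMethod.PEARSON_CHI2, float(stat), p)


def choose_test(t: ContingencyTable2x2) -> TestMethod:
    """Operational "as appropriate" rule: Fisher's exact test iff any
    expected count under independence is below 5, else Pearson chi-square."""
    if t.total == 0:
        raise ValueError("all-zero table")
    if float(t.expected().min()) < 5.0:
        return TestMethod.FISHER_EXACT
    return TestMethod.PEARSON_CHI2


def test_2x2(t: ContingencyTable2x2) -> TestResult:
    """Run the test chosen by :func:`choose_test` on the table."""
    if choose_test(t) is TestMethod.FISHER_EXACT:
        return fisher_exact_2x2(t)
    return pearson_chi2_2x2(t)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact: bool | None = None
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``exact=None`` (auto) uses exact enumeration when both samples have at
    most 10 observations and there are no ties, else the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if exact is None:
        pooled = np.concatenate([x, y])
        exact = x.size <= 10 and y.size <= 10 and np.unique(pooled).size == pooled.size
    res = st.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        TestMethod.WILCOXON_RANK_SUM, float(res.statistic), float(min(res.pvalue, 1.0))
    )


def t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample pooled-variance Student's t test (two-sided)."""
    res = st.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=True)
    return TestResult(TestMethod.T_TEST, float(res.statistic), float(res.pvalue))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Order-equivariant: permuting the input permutes the output identically.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# Clinical records and survival
# ---------------------------------------------------------------------------

class Kodama(str, Enum):
    PEN_A = "pen_a"
    PEN_B = "pen_b"
    UNKNOWN = "unknown"


#: Documented clinical-table schema (TSV header names and per-column types).
CLINICAL_COLUMNS = {
    "patient_id": str,
    "kodama": str,          # pen_a | pen_b | unknown
    "age": float,           # years
    "sex": str,             # F | M
    "location": str,        # upper_middle | lower
    "lauren": str,          # intestinal | diffuse_mixed
    "grade": str,           # g1_g2 | g3
    "pn_status": str,       # pn0 | pn_pos
    "ln_ratio": float,      # involved / examined nodes, in [0, 1]
    "lvi": bool,            # lymphovascular invasion
    "tumor_size": float,    # cm
    "dfs_time": float,      # months
    "event": bool,          # recurrence or death from any cause
}


@dataclass(frozen=True)
class ClinicalRecord:
    """Covariates plus disease-free-survival outcome for one patient."""

    patient_id: str
    kodama: Kodama
    age: float
    sex: str
    location: str
    lauren: str
    grade: str
    pn_status: str
    ln_ratio: float
    lvi: bool
    tumor_size: float
    dfs_time: float
    event: bool

    def __post_init__(self) -> None:
        if self.dfs_time < 0:
            raise ValueError(f"dfs_time must be >= 0, got {self.dfs_time}")
        if not 0.0 <= self.ln_ratio <= 1.0:
            raise ValueError(f"ln_ratio must be in [0, 1], got {self.ln_ratio}")


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Records -> DataFrame with the documented column schema."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "kodama": r.kodama.value,
                "age": r.age,
                "sex": r.sex,
                "location": r.location,
                "lauren": r.lauren,
                "grade": r.grade,
                "pn_status": r.pn_status,
                "ln_ratio": r.ln_ratio,
                "lvi": r.lvi,
                "tumor_size": r.tumor_size,
                "dfs_time": r.dfs_time,
                "event": r.event,
            }
            for r in records
        ],
        columns=list(CLINICAL_COLUMNS),
    )


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV, coercing the documented column types."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical column(s): {', '.join(missing)}")
    for col, typ in CLINICAL_COLUMNS.items():
        if typ is bool:
            df[col] = df[col].astype(str).str.lower().isin({"true", "1", "yes"})
        elif typ is float:
            df[col] = df[col].astype(float)
        else:
            df[col] = df[col].astype(str)
    return df


def _design_column(
    df: pd.DataFrame, covariate: str, reference_level: str | None
) -> tuple[pd.Series, str]:
    """Numeric design column for one covariate; categorical covariates are
    coded 0/1 against the reference level (two-level only)."""
    col = df[covariate]
    if pd.api.types.is_numeric_dtype(col) and col.dtype != bool:
        return col.astype(float), covariate
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    if len(levels) > 2:
        raise ValueError(
            f"covariate {covariate!r} has {len(levels)} levels; univariate "
            "coding supports two (dichotomize first)"
        )
    if reference_level is None:
        reference_level = levels[0]
    elif str(reference_level) not in levels:
        raise ValueError(
            f"reference level {reference_level!r} not a level of {covariate!r}"
        )
    other = [l for l in levels if l != str(reference_level)][0]
    return (col.astype(str) == other).astype(float), f"{covariate}:{other}"


def cox_univariate(
    records: pd.DataFrame | Sequence[ClinicalRecord],
    covariate: str,
    reference_level: str | None = None,
    time_col: str = "dfs_time",
    event_col: str = "event",
    ties: str = "breslow",
) -> CoxFit:
    """Univariate Cox proportional-hazards fit for one covariate.

    Continuous covariates enter as-is; two-level categoricals are coded
    against ``reference_level`` (default: the lexicographically first level).
    Ties are handled by the Breslow approximation by default; ``ties="efron"``
    switches to Efron (fit via statsmodels, without the Schoenfeld test).
    Reports the Wald hazard ratio, 95% CI and p, plus the scaled-Schoenfeld-
    residual proportional-hazards test p-value.
    """
    df = records if isinstance(records, pd.DataFrame) else clinical_to_frame(records)
    n_events = int(df[event_col].astype(bool).sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")
    design, name = _design_column(df, covariate, reference_level)
    if design.nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    times = df[time_col].astype(float)
    events = df[event_col].astype(bool)

    if ties == "efron":
        import statsmodels.duration.hazard_regression as hr

        model = hr.PHReg(times.to_numpy(), design.to_numpy()[:, None],
                         status=events.to_numpy().astype(int), ties="efron")
        res = model.fit()
        hrat = float(np.exp(res.params[0]))
        lo, hi = np.exp(res.conf_int()[0])
        return CoxFit(name, hrat, float(lo), float(hi),
                      float(res.pvalues[0]), float("nan"), len(df), n_events)
    if ties != "breslow":
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")

    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    fit_df = pd.DataFrame({"T": times, "E": events, name: design})
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="T", event_col="E", robust=False)
    summary = cph.summary.loc[name]
    try:
        ph = proportional_hazard_test(cph, fit_df, time_transform="rank")
        schoenfeld_p = float(np.atleast_1d(ph.p_value)[0])
    except Exception:  # degenerate residuals on tiny/boundary fits
        schoenfeld_p = float("nan")
    return CoxFit(
        covariate=name,
        hazard_ratio=float(summary["exp(coef)"]),
        ci_low=float(summary["exp(coef) lower 95%"]),
        ci_high=float(summary["exp(coef) upper 95%"]),
        p_value=float(summary["p"]),
        schoenfeld_p=schoenfeld_p,
        n=len(fit_df),
        n_events=n_events,
    )


@dataclass(frozen=True)
class KmCurve:
    """Kaplan-Meier estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int


def km_logrank(
    records: pd.DataFrame | Sequence[ClinicalRecord],
    groups: Mapping[str, str] | str,
    time_col: str = "dfs_time",
    event_col: str = "event",
) -> tuple[list[KmCurve], TestResult]:
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    ``groups`` is either a clinical column name or a patient_id -> label map;
    patients absent from the map are excluded. Needs >= 2 groups and >= 1
    event overall. Groups with all-censored records are estimated without
    error (flat curves).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = records if isinstance(records, pd.DataFrame) else clinical_to_frame(records)
    if isinstance(groups, str):
        labels = df[groups].astype(str)
        sub = df
    else:
        sub = df[df["patient_id"].isin(groups)].copy()
        labels = sub["patient_id"].map(lambda p: str(groups[p]))
    if labels.nunique() < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if int(sub[event_col].astype(bool).sum()) < 1:
        raise ValueError("log-rank needs >= 1 event overall")
    curves = []
    for g in sorted(labels.unique()):
        mask = (labels == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col].to_numpy()[mask], sub[event_col].astype(bool).to_numpy()[mask])
        curves.append(
            KmCurve(
                group=g,
                times=kmf.survival_function_.index.to_numpy(dtype=float),
                survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
                n=int(mask.sum()),
                n_events=int(sub[event_col].astype(bool).to_numpy()[mask].sum()),
            )
        )
    lr = multivariate_logrank_test(
        sub[time_col].to_numpy(),
        labels.to_numpy(),
        sub[event_col].astype(bool).to_numpy(),
    )
    return curves, TestResult(
        TestMethod.LOGRANK, float(lr.test_statistic), float(lr.p_value)
    )


def write_test_table(
    rows: Iterable[tuple[str, TestResult]], path: str | Path
) -> None:
    """Write (comparison, TestResult) pairs as a tidy TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["comparison", "method", "statistic", "p_value", "p_adjusted"])
        for name, r in rows:
            writer.writerow([
                name,
                r.method.value,
                "" if r.statistic is None else f"{r.statistic:.6g}",
                f"{r.p_value:.6g}",
                "" if r.p_adjusted is None else f"{r.p_adjusted:.6g}",
            ])
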