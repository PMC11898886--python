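"""Variance-gated two-sample testing across biomarker panels.

For each biomarker and each group pair, an F-test on the sample variances
decides between the pooled-variance Student t-test (variances compatible)
and Welch's t-test (variances not compatible).  Raw two-sided p-values are
reported without multiple-testing adjustment; a comparison is called
*significant* at p <= 0.05 and *borderline* for 0.05 < p < 0.10.

Statistics are computed from explicit formulas with scipy distributions
supplying the reference CDFs, so each piece is separately checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import GROUPS, PanelDefinition, default_panel

#: Group pairs in the reporting order of the comparison table.
PAIRS: tuple[tuple[str, str], ...] = (
    ("localized", "healthy"),
    ("metastatic", "healthy"),
    ("localized", "metastatic"),
)

PAIR_LABELS: dict[tuple[str, str], str] = {
    ("localized", "healthy"): "localized-vs-control",
    ("metastatic", "healthy"): "metastatic-vs-control",
    ("localized", "metastatic"): "localized-vs-metastatic",
}

F_GATE_ALPHA = 0.05  # two-sided level of the variance gate


@dataclass(frozen=True)
class TestResult:
    biomarker: str
    pair: str
    f_stat: float
    f_p: float
    variance_equal: bool
    test_used: str  # "student" | "welch"
    t_stat: float
    df: float
    p_value: float
    call: str  # "significant" | "borderline" | "ns"


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"{name}: need a 1-D sample of length >= 2")
    if np.var(v, ddof=1) == 0.0:
        raise ValueError(f"{name}: degenerate (zero) sample variance")
    return v


def f_variance_test(x, y) -> tuple[float, float, bool]:
    """Two-sided F-test of equal variances.

    F = s_x^2 / s_y^2 with n-1 denominators; the two-sided p-value is twice
    the smaller tail of F_{n_x-1, n_y-1}, capped at 1.  ``variance_equal``
    is True when the test does not reject at the 0.05 gate level.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    f = np.var(x, ddof=1) / np.var(y, ddof=1)
    dfn, dfd = x.size - 1, y.size - 1
    p = 2.0 * min(sps.f.cdf(f, dfn, dfd), sps.f.sf(f, dfn, dfd))
    p = min(p, 1.0)
    return float(f), float(p), bool(p > F_GATE_ALPHA)


def two_sample_t(x, y, equal_var: bool) -> tuple[float, float, float]:
    """Two-sided two-sample t-test.

    Pooled-variance Student form (df = n_x + n_y - 2) when ``equal_var``,
    otherwise Welch's statistic with Welch–Satterthwaite degrees of freedom.
    Returns (t, df, p).
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    nx, ny = x.size, y.size
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    diff = x.mean() - y.mean()
    if equal_var:
        df = nx + ny - 2
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def classify_call(p_value: float) -> str:
    """Significance call: <= 0.05 significant, (0.05, 0.10) borderline, else ns."""
    if p_value <= 0.05:
        return "significant"
    if p_value < 0.10:
        return "borderline"
    return "ns"


def gated_test(x, y, biomarker: str = "", pair: str = "") -> TestResult:
    """F-gate then Student/Welch on one biomarker and group pair."""
    f, f_p, equal = f_variance_test(x, y)
    t, df, p = two_sample_t(x, y, equal_var=equal)
    return TestResult(
        biomarker=biomarker,
        pair=pair,
        f_stat=f,
        f_p=f_p,
        variance_equal=equal,
        test_used="student" if equal else "welch",
        t_stat=t,
        df=df,
        p_value=p,
        call=classify_call(p),
    )


def compare_groups(
    table: pd.DataFrame, panel: PanelDefinition | None = None
) -> list[TestResult]:
    """All biomarkers x the three group pairs (localized-vs-control,
    metastatic-vs-control, localized-vs-metastatic).

    Returns len(panel) * 3 results in biomarker-major order.  Raw p-values;
    no multiplicity adjustment.
    """
    panel = panel if panel is not None else default_panel()
    missing = [g for g in GROUPS if g not in set(table["group"])]
    if missing:
        raise ValueError(f"groups absent from table: {missing}")
    by_group = {g: table[table["group"] == g] for g in GROUPS}
    results = []
    for protease, col in zip(panel.proteases, panel.columns):
        for pair in PAIRS:
            a = by_group[pair[0]][col].to_numpy(float)
            b = by_group[pair[1]][col].to_numpy(float)
            results.append(
                gated_test(a, b, biomarker=protease, pair=PAIR_LABELS[pair])
            )
    return results


def comparison_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tidy frame ``biomarker,pair,f_p,test_used,t_stat,df,p_value,call``."""
    frame = pd.DataFrame([asdict(r) for r in results])
    return frame[
        ["biomarker", "pair", "f_p", "test_used", "t_stat", "df", "p_value", "call"]
    ]
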