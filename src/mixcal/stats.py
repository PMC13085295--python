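"""Figures of merit and statistical validation tests.

Everything a QC chemometrician reports after building a calibration:
per-sample recovery percentages with Dixon Q outlier screening, mean/RSD
summaries, predicted-vs-nominal regression diagnostics, the elliptical
joint confidence region (EJCR) for (slope, intercept), one-sample t
against the 100% reference recovery, pooled two-sample t and variance-F
comparison against an official method, distribution critical values, and
a molar-mass/titration-equivalence utility for the pharmacopeial back
titration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RecoverySummary", "RegressionDiagnostics", "EjcrResult", "ComparisonResult",
    "QTestResult", "recovery_percent", "summarize_recoveries", "dixon_q_test",
    "regression_diagnostics", "ejcr", "one_sample_t_vs_reference",
    "compare_with_official", "critical_value", "molar_mass", "titration_equivalent",
]

# Dixon r10 (gap/range) critical values, n = 3..10, at 95% confidence
# (the classical analytical-chemistry Q table) and at the stricter 99% level.
_Q_CRITICAL = {
    0.05: {3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468, 9: 0.437, 10: 0.412},
    0.01: {3: 0.988, 4: 0.889, 5: 0.780, 6: 0.698, 7: 0.637, 8: 0.590, 9: 0.555, 10: 0.527},
}

# IUPAC 2021 standard atomic weights (conventional values), g/mol.
_ATOMIC_WEIGHTS = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011,
    "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180, "Na": 22.990, "Mg": 24.305,
    "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.098, "Ca": 40.078, "Fe": 55.845, "Cu": 63.546, "Zn": 65.38,
    "Br": 79.904, "I": 126.90, "Ag": 107.87, "Ba": 137.33, "Pt": 195.08,
}


@dataclass
class QTestResult:
    sorted_values: list[float]
    q_statistic: float
    q_critical: float
    rejected_value: float | None = None
    rejected_index: int | None = None  # index into the original list


@dataclass
class RecoverySummary:
    component: str
    recoveries_percent: list[float]
    rejected_indices: list[int]
    mean_percent: float
    rsd_percent: float
    rmsep: float | None = None
    n_used: int = 0


@dataclass
class RegressionDiagnostics:
    slope: float
    intercept: float
    r: float
    rmsec: float


@dataclass
class EjcrResult:
    slope: float
    intercept: float
    s2: float
    n: int
    f_crit: float
    contains_ideal: bool
    ellipse_boundary: np.ndarray = field(repr=False, default=None)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: int | tuple[int, int]
    critical: float
    alpha: float
    significant: bool


def recovery_percent(predicted: float, nominal: float) -> float:
    """Recovery % = 100 * predicted / nominal."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return 100.0 * predicted / nominal


def dixon_q_test(values, alpha: float = 0.05) -> QTestResult:
    """Dixon Q (r10, gap/range) outlier test for 3 <= n <= 10.

    Both extremes are considered and the more extreme (larger q) tail is
    tested; at most one value is rejected per pass.
    """
    vals = [float(v) for v in values]
    n = len(vals)
    if not 3 <= n <= 10:
        raise ValueError(f"Dixon Q is tabulated for 3 <= n <= 10, got n={n}")
    if alpha not in _Q_CRITICAL:
        raise ValueError(f"no Q table at alpha={alpha}; available: {sorted(_Q_CRITICAL)}")
    order = np.argsort(vals, kind="stable")
    s = np.asarray(vals)[order]
    rng = s[-1] - s[0]
    crit = _Q_CRITICAL[alpha][n]
    if rng == 0:
        return QTestResult(list(s), 0.0, crit)
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    if q_high >= q_low:
        q, suspect, idx = q_high, s[-1], int(order[-1])
    else:
        q, suspect, idx = q_low, s[0], int(order[0])
    if q > crit:
        return QTestResult(list(s), float(q), crit, float(suspect), idx)
    return QTestResult(list(s), float(q), crit)


def summarize_recoveries(recoveries, apply_q: bool = False, alpha: float = 0.05,
                         component: str = "", sequential: bool = False,
                         rmsep: float | None = None) -> RecoverySummary:
    """Mean and RSD of recovery percentages, with optional Dixon Q
    rejection (single pass by default; ``sequential`` repeats until no
    further rejection while n stays in the tabulated range)."""
    vals = [float(v) for v in recoveries]
    if len(vals) < 2:
        raise ValueError("need at least 2 recoveries")
    rejected: list[int] = []
    if apply_q:
        if len(vals) < 3:
            raise ValueError("Q rejection needs at least 3 values")
        live = list(range(len(vals)))
        while len(live) >= 3:
            res = dixon_q_test([vals[i] for i in live], alpha=alpha)
            if res.rejected_index is None:
                break
            rejected.append(live.pop(res.rejected_index))
            if not sequential:
                break
        kept = [vals[i] for i in sorted(live)]
    else:
        kept = vals
    arr = np.asarray(kept)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else float("inf")
    return RecoverySummary(component, vals, sorted(rejected), mean, rsd, rmsep, len(kept))


def regression_diagnostics(predicted, nominal) -> RegressionDiagnostics:
    """OLS of predicted on nominal plus Pearson r and the RMSE."""
    y = np.asarray(predicted, float)
    x = np.asarray(nominal, float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("nominal values are all equal")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    rmsec = float(np.sqrt(np.mean((y - x) ** 2)))
    return RegressionDiagnostics(float(slope), float(intercept), r, rmsec)


def ejcr(predicted, nominal, alpha: float = 0.05, n_boundary: int = 360) -> EjcrResult:
    """Elliptical joint confidence region for (intercept, slope).

    From the OLS fit of predicted vs nominal, the 100(1-alpha)% region is
    ``{beta : (beta - b)' X'X (beta - b) <= 2 s^2 F(alpha; 2, n-2)}`` with
    ``X = [1, nominal]``.  The model is unbiased at this confidence when
    the ideal point (intercept 0, slope 1) lies inside.
    """
    y = np.asarray(predicted, float)
    xn = np.asarray(nominal, float)
    n = y.size
    if n < 3:
        raise ValueError("EJCR needs at least 3 points")
    X = np.column_stack([np.ones(n), xn])
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    s2 = float(resid @ resid) / (n - 2)
    f_crit = float(sps.f.ppf(1 - alpha, 2, n - 2))
    XtX = X.T @ X
    ideal = np.array([0.0, 1.0])
    d = ideal - b
    contains = float(d @ XtX @ d) <= 2 * s2 * f_crit + 1e-15
    # parametric boundary: (beta - b)' XtX (beta - b) = c  via eigendecomposition
    c = 2 * s2 * f_crit
    evals, evecs = np.linalg.eigh(XtX)
    theta = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
    radii = np.sqrt(np.maximum(c, 0) / np.maximum(evals, 1e-300))
    boundary = b[:, None] + (evecs * radii) @ np.vstack([np.cos(theta), np.sin(theta)])
    return EjcrResult(float(b[1]), float(b[0]), s2, n, f_crit, bool(contains), boundary.T)


def one_sample_t_vs_reference(values, reference: float = 100.0,
                              alpha: float = 0.05) -> ComparisonResult:
    """Student t of the mean recovery against a reference value (100%)."""
    v = np.asarray(values, float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    t = (v.mean() - reference) / (sd / np.sqrt(n))
    df = n - 1
    crit = critical_value("t_two_sided", alpha, df)
    return ComparisonResult("one_sample_t_vs_100", float(t), df, crit, alpha, abs(t) > crit)


def compare_with_official(model_values, official_values, alpha: float = 0.05
                          ) -> tuple[ComparisonResult, ComparisonResult]:
    """Pooled-variance two-sample t and variance-ratio F against an
    official method (larger variance in the F numerator)."""
    a = np.asarray(model_values, float)
    b = np.asarray(official_values, float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df_t = n1 + n2 - 2
    t_crit = critical_value("t_two_sided", alpha, df_t)
    if v1 >= v2:
        f, df_f = (v1 / v2 if v2 > 0 else np.inf), (n1 - 1, n2 - 1)
    else:
        f, df_f = v2 / v1, (n2 - 1, n1 - 1)
    f_crit = critical_value("F_upper", alpha, df_f)
    return (
        ComparisonResult("two_sample_t", float(t), df_t, t_crit, alpha, abs(t) > t_crit),
        ComparisonResult("variance_F", float(f), df_f, f_crit, alpha, f > f_crit),
    )


def critical_value(kind: str, alpha: float, df) -> float:
    """Tabulated critical value: two-sided Student t or upper-tail F."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if kind == "t_two_sided":
        df = int(df)
        if df < 1:
            raise ValueError("df must be >= 1")
        return float(sps.t.ppf(1 - alpha / 2, df))
    if kind == "F_upper":
        dfn, dfd = (int(df[0]), int(df[1]))
        if dfn < 1 or dfd < 1:
            raise ValueError("df must be >= 1")
        return float(sps.f.ppf(1 - alpha, dfn, dfd))
    raise ValueError(f"unknown kind {kind!r}")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(formula: str) -> float:
    """Molar mass (g/mol) of a Hill-style formula such as ``C18H26BrNO``."""
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula at {formula[pos:]!r}")
        pos = m.end()
        sym, count = m.group(1), int(m.group(2) or 1)
        if sym not in _ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element symbol {sym!r}")
        total += _ATOMIC_WEIGHTS[sym] * count
    if pos != len(formula) or total == 0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return total


def titration_equivalent(formula: str, titrant_molarity: float = 0.1,
                         volume_mL: float = 1.0, stoichiometry: int = 1) -> float:
    """Analyte mass (mg) equivalent to a titrant volume: for the
    potentiometric back titration, 1.0 mL of 0.1 M NaOH corresponds to
    35.23 mg of dextromethorphan hydrobromide (C18H26BrNO)."""
    return titrant_molarity * volume_mL * molar_mass(formula) / stoichiometry
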