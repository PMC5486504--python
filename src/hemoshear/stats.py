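"""The cohort statistics pipeline.

The procedure mirrors the standard SPSS-style analysis of a two-group
hemodynamic cohort:

1. every continuous variable is gated per group through a normality test
   (one-sample Kolmogorov–Smirnov against a normal with estimated moments,
   using Lilliefors-corrected critical values — plain KS with estimated
   parameters is anti-conservative);
2. if both groups pass (p >= 0.05) the groups are compared with the
   independent-samples t test (equal variances by default) and described
   as mean +/- SD; otherwise with the Mann–Whitney U test and described as
   median and quartiles (exact enumeration for small untied samples,
   tie-corrected normal approximation with continuity correction
   otherwise);
3. Spearman rank correlations relate hemodynamic to morphological factors;
4. metrics that reach two-sided p < 0.05 in the univariate screen enter a
   backward stepwise binary logistic regression (removal at p > 0.10) for
   rupture.

No multiple-testing correction is applied across metrics, matching the
source procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "StatResult",
    "LogisticModelResult",
    "DegenerateSampleError",
    "test_normality",
    "compare_groups",
    "spearman_matrix",
    "univariate_screen",
    "backward_stepwise_logistic",
    "build_comparison_tables",
    "HEMODYNAMIC_PARAMS",
]

#: canonical row order of the comparison tables
HEMODYNAMIC_PARAMS = ["MWSS", "PWSS", "LSAR", "HWSS", "MP_ratio", "HP_ratio"]

NORMALITY_GATE_P = 0.05
SCREEN_P = 0.05
REMOVAL_P = 0.10


class DegenerateSampleError(ValueError):
    """Sample is constant or too small for the requested test."""


@dataclass(frozen=True)
class StatResult:
    """One two-group comparison: test choice, statistic, p, descriptives."""

    parameter: str
    groups: tuple[str, str]
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p_two_sided: float
    descriptives: tuple[dict, dict]  # per group, style matching test_used

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class LogisticModelResult:
    """Backward-stepwise logistic fit with its full removal trace."""

    retained: tuple[str, ...]
    coefficients: dict  # name -> coefficient (incl. "const")
    p_values: dict
    trace: tuple[tuple[int, str, float], ...]  # (step, removed, its p)
    separation_flagged: bool = False


def test_normality(x) -> float:
    """Two-sided p for departure from normality (Lilliefors-corrected KS).

    The gate used downstream treats ``p >= 0.05`` as compatible with
    normality.  Raises for constant or tiny samples.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise DegenerateSampleError("need n >= 4 for the normality test")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample has no defined normality test")
    _, p = lilliefors(x, dist="norm")
    return float(p)


def _descriptives(x, style: str) -> dict:
    x = np.asarray(x, dtype=float)
    if style == "mean_sd":
        return {"n": len(x), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": len(x), "median": float(med), "q1": float(q1), "q3": float(q3)}


def _mann_whitney(a, b) -> tuple[float, float]:
    """U statistic of the first sample and two-sided p.

    Exact enumeration when min(n1, n2) <= 8 with no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if min(len(a), len(b)) <= 8 and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    a,
    b,
    parameter: str = "",
    groups: tuple[str, str] = ("a", "b"),
    force_test: str | None = None,
    equal_var: bool = True,
) -> StatResult:
    """Normality-gated two-group comparison.

    Both groups must pass the normality gate for the t test; otherwise the
    Mann–Whitney U test is used.  ``force_test`` ("t" / "mann_whitney")
    overrides the gate.  Identical samples give statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise DegenerateSampleError("need n >= 3 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constants: no difference by definition
        return StatResult(
            parameter, groups, "t", 0.0, 1.0,
            (_descriptives(a, "mean_sd"), _descriptives(b, "mean_sd")),
        )
    if force_test is None:
        try:
            use_t = test_normality(a) >= NORMALITY_GATE_P and test_normality(b) >= NORMALITY_GATE_P
        except DegenerateSampleError:
            use_t = False
    else:
        use_t = force_test == "t"
    if use_t:
        if np.array_equal(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        return StatResult(
            parameter, groups, "t", float(stat), float(p),
            (_descriptives(a, "mean_sd"), _descriptives(b, "mean_sd")),
        )
    stat, p = _mann_whitney(a, b)
    return StatResult(
        parameter, groups, "mann_whitney", stat, min(p, 1.0),
        (_descriptives(a, "quartiles"), _descriptives(b, "quartiles")),
    )


def spearman_matrix(
    frame: pd.DataFrame,
    hemodynamic: Sequence[str],
    morphology: Sequence[str],
) -> pd.DataFrame:
    """Spearman rank correlation (tie-corrected) of each hemodynamic
    parameter against each morphology parameter.

    Returns a long-format frame with columns hemodynamic, morphology, r, p;
    constant columns yield NaN with a flag rather than an error.
    """
    if len(frame) < 5:
        raise DegenerateSampleError("need n >= 5 for rank correlations")
    rows = []
    for hcol in hemodynamic:
        for mcol in morphology:
            x, y = frame[hcol].to_numpy(float), frame[mcol].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"hemodynamic": hcol, "morphology": mcol,
                     "r": math.nan, "p": math.nan, "undefined": True}
                )
                continue
            r, p = sps.spearmanr(x, y)
            rows.append(
                {"hemodynamic": hcol, "morphology": mcol,
                 "r": float(r), "p": float(p), "undefined": False}
            )
    return pd.DataFrame(rows)


def univariate_screen(
    frame: pd.DataFrame,
    candidates: Sequence[str],
    label_col: str = "ruptured",
    alpha: float = SCREEN_P,
) -> list[str]:
    """Candidates whose two-group comparison reaches p < ``alpha``."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate parameters to screen")
    y = frame[label_col].to_numpy()
    out = []
    for c in candidates:
        a = frame.loc[y == 1, c].to_numpy(float)
        b = frame.loc[y == 0, c].to_numpy(float)
        try:
            res = compare_groups(a, b, parameter=c)
        except DegenerateSampleError:
            continue
        if res.p_two_sided < alpha:
            out.append(c)
    return out


def backward_stepwise_logistic(
    frame: pd.DataFrame,
    params: Sequence[str],
    label_col: str = "ruptured",
    removal_p: float = REMOVAL_P,
) -> LogisticModelResult:
    """Backward stepwise binary logistic regression.

    Fits the full model on ``params``, then repeatedly removes the
    least-significant parameter while its Wald p exceeds ``removal_p``;
    the removal trace reconstructs the final model.  Complete separation
    is flagged instead of raising.
    """
    if not params:
        raise ValueError("need at least one screened parameter")
    y = frame[label_col].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    current = list(params)
    trace: list[tuple[int, str, float]] = []
    step = 0
    flagged = False
    while True:
        X = sm.add_constant(frame[current].to_numpy(float))
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            pvals = dict(zip(["const"] + current, fit.pvalues))
            coefs = dict(zip(["const"] + current, fit.params))
            if not np.all(np.isfinite(fit.bse)):
                raise np.linalg.LinAlgError("non-finite standard errors")
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            flagged = True
            coefs = {k: math.nan for k in ["const"] + current}
            pvals = {k: math.nan for k in ["const"] + current}
            break
        worst = max(current, key=lambda c: pvals[c])
        if pvals[worst] > removal_p:
            step += 1
            trace.append((step, worst, float(pvals[worst])))
            current.remove(worst)
            if not current:
                coefs, pvals = {}, {}
                break
        else:
            break
    return LogisticModelResult(
        retained=tuple(current),
        coefficients=coefs,
        p_values=pvals,
        trace=tuple(trace),
        separation_flagged=flagged,
    )


def build_comparison_tables(
    frame: pd.DataFrame,
    params: Sequence[str] = tuple(HEMODYNAMIC_PARAMS),
) -> dict[str, pd.DataFrame]:
    """The four standard comparison tables.

    ``overall``: ruptured vs unruptured; ``by_neck``: narrow vs wide;
    ``narrow`` / ``wide``: ruptured vs unruptured within each stratum.
    Stratified tables whose strata are empty are skipped (key absent).
    """
    tables: dict[str, pd.DataFrame] = {}

    def _table(sub: pd.DataFrame, split_col: str, split_vals: tuple[str, str]):
        ga = sub[sub[split_col] == split_vals[0]]
        gb = sub[sub[split_col] == split_vals[1]]
        if len(ga) < 3 or len(gb) < 3:
            return None
        rows = []
        for pname in params:
            res = compare_groups(
                ga[pname].to_numpy(float), gb[pname].to_numpy(float),
                parameter=pname, groups=split_vals,
            )
            da, db = res.descriptives
            rows.append(
                {
                    "parameter": pname,
                    "test": res.test_used,
                    f"{split_vals[0]}_desc": _fmt_desc(da),
                    f"{split_vals[1]}_desc": _fmt_desc(db),
                    "statistic": res.statistic,
                    "p": res.p_two_sided,
                }
            )
        return pd.DataFrame(rows)

    t = _table(frame, "rupture_label", ("ruptured", "unruptured"))
    if t is not None:
        tables["overall"] = t
    t = _table(frame, "neck_category", ("narrow", "wide"))
    if t is not None:
        tables["by_neck"] = t
    for cat in ("narrow", "wide"):
        sub = frame[frame["neck_category"] == cat]
        t = _table(sub, "rupture_label", ("ruptured", "unruptured"))
        if t is not None:
            tables[cat] = t
    return tables


def _fmt_desc(d: dict) -> str:
    if "mean" in d:
        return f"{d['mean']:.3g} ± {d['sd']:.3g}"
    return f"{d['median']:.3g} ({d['q1']:.3g}–{d['q3']:.3g})"
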