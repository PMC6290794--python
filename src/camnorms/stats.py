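"""Group comparisons: Cohen's d with CI, odds ratios, exact and t tests.

This layer reproduces the study's comparison surface: per measure and per
domain, T-scores are contrasted between an exposed and a reference group
(pooled-SD Cohen's d with a normal-approximation CI and a pooled two-sided
t-test), and impairment flags are contrasted as odds ratios (2x2 point
estimate -- identical to a single-predictor logistic regression -- with a
Wald CI and an optional profile-likelihood CI).  Tests are two-sided and no
multiplicity adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .measures import DOMAIN_MEMBERS, MEASURE_NAMES

_Z = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContinuousComparison:
    """Two-group contrast of a continuous score (group 1 vs reference group 0)."""

    n1: int
    mean1: float
    sd1: float
    n0: int
    mean0: float
    sd0: float
    d: float
    d_ci: tuple[float, float]
    p: float


@dataclass(frozen=True)
class BinaryComparison:
    """2x2 impairment contrast: a/b exposed impaired/unimpaired, c/d reference."""

    a: int
    b: int
    c: int
    d: int
    or_: float
    or_ci: tuple[float, float]
    p: float
    ci_method: str = "wald"
    continuity_corrected: bool = False


@dataclass(frozen=True)
class TTestResult:
    diff: float
    t: float
    df: float
    p: float


def cohens_d(mean1, sd1, n1, mean0, sd0, n0) -> ContinuousComparison:
    """Pooled-SD Cohen's d of group 1 vs group 0, with 95% CI and pooled t-test p.

    d = (mean1 - mean0) / s_p with s_p^2 = ((n1-1) sd1^2 + (n0-1) sd0^2)/(n1+n0-2);
    CI = d +/- 1.96 * sqrt((n1+n0)/(n1 n0) + d^2 / (2 (n1+n0))).
    """
    n1, n0 = int(n1), int(n0)
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need n >= 2 per group, got n1={n1}, n0={n0}")
    if sd1 <= 0 or sd0 <= 0:
        raise ValueError("group SDs must be > 0")
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n0 - 1) * sd0**2) / (n1 + n0 - 2))
    d = (mean1 - mean0) / sp
    se_d = np.sqrt((n1 + n0) / (n1 * n0) + d**2 / (2 * (n1 + n0)))
    t = student_t(stats1=(mean1, sd1, n1), stats0=(mean0, sd0, n0))
    return ContinuousComparison(
        n1=n1, mean1=float(mean1), sd1=float(sd1),
        n0=n0, mean0=float(mean0), sd0=float(sd0),
        d=float(d), d_ci=(float(d - _Z * se_d), float(d + _Z * se_d)), p=t.p,
    )


def cohens_d_from_values(x1, x0) -> ContinuousComparison:
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    return cohens_d(
        x1.mean(), x1.std(ddof=1), x1.size, x0.mean(), x0.std(ddof=1), x0.size
    )


def _profile_or_ci(a, b, c, d, level=0.95):
    """Profile-likelihood CI for the odds ratio of a 2x2 table.

    Profiles the binomial log-likelihood over the log odds ratio psi
    (nuisance: reference log-odds), inverting the deviance at the
    chi-squared(1) quantile.
    """
    n1, n0 = a + b, c + d

    def negll(eta, psi):
        # group log-odds: reference eta, exposed eta + psi
        return -(
            a * (eta + psi) - n1 * np.logaddexp(0.0, eta + psi)
            + c * eta - n0 * np.logaddexp(0.0, eta)
        )

    def profile(psi):
        res = optimize.minimize_scalar(negll, args=(psi,), bounds=(-20, 20), method="bounded")
        return -res.fun

    psi_hat = np.log((a / b) / (c / d))
    l_max = profile(psi_hat)
    crit = stats.chi2.ppf(level, 1) / 2.0

    def root(psi):
        return (l_max - profile(psi)) - crit

    lo = optimize.brentq(root, psi_hat - 10, psi_hat)
    hi = optimize.brentq(root, psi_hat, psi_hat + 10)
    return float(np.exp(lo)), float(np.exp(hi))


def odds_ratio(a, b, c, d, ci: str = "wald") -> BinaryComparison:
    """Odds ratio (a/b)/(c/d) of exposure group vs reference with 95% CI.

    The point estimate equals the MLE of a single-binary-predictor logistic
    regression.  ``ci`` is ``"wald"`` (log-OR normal approximation) or
    ``"profile"`` (profile-likelihood deviance inversion).  When any cell is
    zero but no margin is zero, the Haldane-Anscombe 0.5 correction is
    applied to estimate and CI (flagged on the result); a zero margin leaves
    the OR undefined and raises.  ``p`` is the two-sided Wald test on the
    log odds ratio.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be >= 0")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("a zero margin leaves the odds ratio undefined")
    corrected = bool(np.any(cells == 0))
    w = cells + 0.5 if corrected else cells
    or_ = (w[0] / w[1]) / (w[2] / w[3])
    se = np.sqrt((1.0 / w).sum())
    log_or = np.log(or_)
    if ci == "wald":
        ci_bounds = (float(np.exp(log_or - _Z * se)), float(np.exp(log_or + _Z * se)))
    elif ci == "profile":
        ci_bounds = _profile_or_ci(*(w.tolist()))
    else:
        raise ValueError(f"ci must be 'wald' or 'profile', got {ci!r}")
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return BinaryComparison(
        a=int(a), b=int(b), c=int(c), d=int(d),
        or_=float(or_), or_ci=ci_bounds, p=p,
        ci_method=ci, continuity_corrected=corrected,
    )


def fisher_exact(a, b, c, d) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be >= 0")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def student_t(x1=None, x0=None, stats1=None, stats0=None) -> TTestResult:
    """Pooled-variance two-sided t-test from raw values or (mean, sd, n) summaries."""
    if (x1 is None) != (x0 is None) or (stats1 is None) != (stats0 is None):
        raise ValueError("provide both groups as values or both as summaries")
    if x1 is not None:
        x1 = np.asarray(x1, dtype=float)
        x0 = np.asarray(x0, dtype=float)
        stats1 = (x1.mean(), x1.std(ddof=1), x1.size)
        stats0 = (x0.mean(), x0.std(ddof=1), x0.size)
    elif stats1 is None:
        raise ValueError("provide raw values or summaries")
    mean1, sd1, n1 = stats1
    mean0, sd0, n0 = stats0
    if n1 < 2 or n0 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 == 0 and sd0 == 0:
        if mean1 == mean0:
            return TTestResult(diff=0.0, t=0.0, df=float(n1 + n0 - 2), p=1.0)
        raise ValueError("degenerate zero variance with unequal means")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean0, sd0, n0, equal_var=True
    )
    return TTestResult(
        diff=float(mean1 - mean0), t=float(t), df=float(n1 + n0 - 2), p=float(p)
    )


# --- cohort-level comparison layer ---------------------------------------

#: name -> (exposed label, reference label, row-mask factory)
STRATIFIERS = {
    "hiv_status": ("hiv_pos", "hiv_neg",
                   lambda df: df["group"] == "hiv_pos",
                   lambda df: df["group"] == "hiv_neg"),
    "art_status": ("cart", "naive",
                   lambda df: (df["group"] == "hiv_pos") & (df["on_cart"] == True),  # noqa: E712
                   lambda df: (df["group"] == "hiv_pos") & (df["on_cart"] == False)),  # noqa: E712
    "cd4_350": ("cd4>=350", "cd4<350",
                lambda df: (df["group"] == "hiv_pos") & (df["cd4"] >= 350),
                lambda df: (df["group"] == "hiv_pos") & (df["cd4"] < 350)),
    "vl_detectable": ("undetectable", "detectable",
                      lambda df: (df["group"] == "hiv_pos") & (df["vl_detectable"] == False),  # noqa: E712
                      lambda df: (df["group"] == "hiv_pos") & (df["vl_detectable"] == True)),  # noqa: E712
    "genotype": ("AG", "non_AG_or_AG_plus",
                 lambda df: (df["group"] == "hiv_pos") & (df["genotype"] == "AG"),
                 lambda df: (df["group"] == "hiv_pos") & (df["genotype"].isin(["non_AG", "AG_plus"]))),
}


def _as_boolean(col: pd.Series) -> pd.Series:
    """Coerce an impairment flag column to nullable boolean.

    Tolerates CSV round trips, where True/False come back as strings.
    """
    if col.dtype == object:
        col = col.map(
            {True: True, False: False, "True": True, "False": False,
             "true": True, "false": False}
        )
    return col.astype("boolean")


@dataclass
class ComparisonReport:
    """Per-measure/domain group contrasts for one stratifier."""

    stratifier: str
    exposed_label: str
    reference_label: str
    continuous: pd.DataFrame  # T-score contrasts (Cohen's d layout)
    binary: pd.DataFrame      # impairment contrasts (odds-ratio layout)


def compare_cohort(
    scored: pd.DataFrame,
    stratifier: str = "hiv_status",
    min_n: int = 2,
    or_ci: str = "wald",
) -> ComparisonReport:
    """Contrast T-scores and impairment between the stratifier's two groups.

    Built-in stratifiers: hiv_status, art_status, cd4_350 (>=350 vs <350),
    vl_detectable (undetectable vs detectable), genotype (AG vs the rest).
    Measures with fewer than ``min_n`` scored subjects in either stratum are
    skipped.  No multiple-testing correction is applied.
    """
    if stratifier not in STRATIFIERS:
        raise KeyError(
            f"unknown stratifier {stratifier!r}; valid: {', '.join(STRATIFIERS)}"
        )
    label1, label0, mask1_fn, mask0_fn = STRATIFIERS[stratifier]
    required = {
        "art_status": ["on_cart"], "cd4_350": ["cd4"],
        "vl_detectable": ["vl_detectable"], "genotype": ["genotype"],
    }.get(stratifier, [])
    for col in required:
        if col not in scored.columns:
            raise KeyError(f"stratifier {stratifier!r} needs column {col!r}")
    m1, m0 = mask1_fn(scored), mask0_fn(scored)
    targets = [m for m in MEASURE_NAMES if f"t_{m}" in scored.columns]
    targets += [d for d in DOMAIN_MEMBERS if f"t_{d}" in scored.columns]
    cont_rows, bin_rows = [], []
    for name in targets:
        t1 = scored.loc[m1, f"t_{name}"].dropna()
        t0 = scored.loc[m0, f"t_{name}"].dropna()
        if len(t1) < min_n or len(t0) < min_n:
            continue
        cc = cohens_d_from_values(t1, t0)
        cont_rows.append(
            {"measure": name, "n1": cc.n1, "mean1": cc.mean1, "sd1": cc.sd1,
             "n0": cc.n0, "mean0": cc.mean0, "sd0": cc.sd0, "d": cc.d,
             "d_ci_low": cc.d_ci[0], "d_ci_high": cc.d_ci[1], "p": cc.p}
        )
        flags = _as_boolean(scored[f"impaired_{name}"])
        i1 = flags[m1].dropna().astype(bool)
        i0 = flags[m0].dropna().astype(bool)
        a, b = int(i1.sum()), int((~i1).sum())
        c, d = int(i0.sum()), int((~i0).sum())
        try:
            bc = odds_ratio(a, b, c, d, ci=or_ci)
        except ValueError:
            continue
        bin_rows.append(
            {"measure": name, "a": a, "b": b, "c": c, "d": d,
             "pct1": 100.0 * a / (a + b), "pct0": 100.0 * c / (c + d),
             "or": bc.or_, "or_ci_low": bc.or_ci[0], "or_ci_high": bc.or_ci[1],
             "p": bc.p, "fisher_p": fisher_exact(a, b, c, d)}
        )
    return ComparisonReport(
        stratifier=stratifier,
        exposed_label=label1,
        reference_label=label0,
        continuous=pd.DataFrame(cont_rows),
        binary=pd.DataFrame(bin_rows),
    )
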