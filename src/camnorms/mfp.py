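"""Multivariable fractional polynomial (MFP) demographic-correction model.

Scaled scores are regressed on age, education and gender with a Gaussian
linear model in which each continuous covariate may enter through a
fractional polynomial (FP) transform drawn from the canonical power set
{-2, -1, -0.5, 0, 0.5, 1, 2, 3} (0 denoting the natural log).  An FP1
function uses one power, an FP2 two (a repeated power p contributing
``x^p`` and ``x^p * ln x``).  Covariates are first shifted/rescaled to
``t = (x + shift)/scale`` with ``t > 0``; for education in years the
convention yields ``(edu + 1)/10`` and for age in years ``age/100``.

Function selection follows the Royston-Sauerbrei closed testing procedure
per continuous covariate at level ``alpha``: best FP2 is compared against
the null (4 df), against linear (3 df) and against best FP1 (2 df) using
deviance differences ``n * ln(RSS_reduced / RSS_full)`` referred to
chi-squared.  Gender (male indicator) always enters linearly and is always
retained.  Covariates are cycled, most significant first, until selections
stabilize.

Usage follows the familiar model/results split::

    res = MFPModel(ss, demographics_frame).fit(alpha=0.05)
    res.summary()
    coefs = res.to_norm_coefficients("wcst_errors")
    report = res.bootstrap_stability(K=1000, seed=7)
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .measures import TestMeasure, get_measure
from .norms import NormCoefficients

POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_OBS_PER_CANDIDATE_TERM = 10


class MFPError(ValueError):
    pass


class SingularFitError(MFPError):
    """The design matrix is rank deficient (collinear covariates)."""


class UnsupportedShapeError(MFPError):
    """A non-linear selected FP shape cannot be emitted as linear norm coefficients."""


@dataclass(frozen=True)
class Demographics:
    """One subject's demographic covariates (age and education in years)."""

    age: float
    education: float
    male: int

    def __post_init__(self) -> None:
        if self.education < 0:
            raise ValueError(f"education must be >= 0, got {self.education}")
        if self.male not in (0, 1):
            raise ValueError(f"male must be 0 or 1, got {self.male}")


@dataclass(frozen=True)
class FPTerm:
    """One fractional polynomial term: ((x + shift)/scale)^power (0 = ln)."""

    variable: str
    power: float
    shift: float = 0.0
    scale: float = 1.0
    repeated: bool = False  # second term of a repeated-power pair: t^p * ln t

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def label(self) -> str:
        p = "ln" if self.power == 0 else f"^{self.power:g}"
        rep = "*ln" if self.repeated else ""
        return f"{self.variable}{p}{rep}"


def fp_transform(x, term: FPTerm):
    """Evaluate a fractional polynomial term at x (power 0 means natural log)."""
    x = np.asarray(x, dtype=float)
    t = (x + term.shift) / term.scale
    if np.any(t <= 0):
        raise MFPError(
            f"{term.variable}: x + shift must be > 0 for fractional polynomial "
            f"transforms (shift={term.shift})"
        )
    if term.power == 0:
        base = np.log(t)
    else:
        base = t ** term.power
    if term.repeated:
        base = base * np.log(t)
    return base


def default_shift_scale(x) -> tuple[float, float]:
    """Positivity shift and power-of-ten scale for a covariate.

    shift = 1 - floor(min(x)) when min(x) <= 0, else 0; scale = the power of
    ten nearest (on log scale) to the observed range.  For education 0-20
    this gives (edu + 1)/10 and for age 18-64 it gives age/100.
    """
    x = np.asarray(x, dtype=float)
    xmin, xmax = float(np.min(x)), float(np.max(x))
    shift = 1.0 - math.floor(xmin) if xmin <= 0 else 0.0
    rng = (xmax + shift) - (xmin + shift)
    scale = 10.0 ** round(math.log10(rng)) if rng > 0 else 1.0
    return shift, scale


def _fp_columns(t: np.ndarray, logt: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Design columns for an FP power tuple (repeats use the t^p * ln t convention)."""
    cols = []
    prev = None
    for p in powers:
        base = logt if p == 0 else t ** p
        if prev is not None and p == prev:
            base = cols[-1] * logt
        cols.append(base)
        prev = p
    return np.column_stack(cols)


@dataclass
class _Covariate:
    name: str
    x: np.ndarray
    shift: float
    scale: float
    t: np.ndarray = field(init=False)
    logt: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t = (self.x + self.shift) / self.scale
        if np.any(self.t <= 0):
            raise MFPError(f"{self.name}: x + shift must be > 0 (shift={self.shift})")
        self.logt = np.log(self.t)

    def columns(self, powers: tuple[float, ...]) -> np.ndarray:
        return _fp_columns(self.t, self.logt, powers)

    def terms(self, powers: tuple[float, ...]) -> tuple[FPTerm, ...]:
        out = []
        prev = None
        for p in powers:
            out.append(
                FPTerm(self.name, p, self.shift, self.scale, repeated=(prev == p))
            )
            prev = p
        return tuple(out)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError("design matrix is rank deficient (collinear covariates)")
    if res.size:
        return float(res[0])
    r = y - X @ beta
    return float(r @ r)


class MFPModel:
    """Gaussian MFP model of scaled scores on demographic covariates.

    Parameters
    ----------
    endog : array-like
        Response (scaled scores, 1-19 scale).
    exog : pandas.DataFrame
        Covariates; continuous columns are FP candidates, binary columns
        enter linearly and are always retained.
    continuous, binary : sequence of str
        Column roles; default continuous ``("education", "age")`` and binary
        ``("male",)``.
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        continuous: tuple[str, ...] = ("education", "age"),
        binary: tuple[str, ...] = ("male",),
        powers: tuple[float, ...] = POWERS,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(exog)
        missing = [c for c in (*continuous, *binary) if c not in exog.columns]
        if missing:
            raise MFPError(f"exog is missing columns {missing}")
        if len(exog) != self.endog.size:
            raise MFPError("endog and exog lengths differ")
        self.exog = exog.reset_index(drop=True)
        self.continuous = tuple(continuous)
        self.binary = tuple(binary)
        self.powers = tuple(powers)
        n_candidate_terms = 2 * len(self.continuous) + len(self.binary)
        self.nobs = self.endog.size
        if self.nobs < _OBS_PER_CANDIDATE_TERM * n_candidate_terms:
            raise MFPError(
                f"need at least {_OBS_PER_CANDIDATE_TERM * n_candidate_terms} "
                f"observations for {n_candidate_terms} candidate terms, got {self.nobs}"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str, *,
        continuous: tuple[str, ...] = ("education", "age"),
        binary: tuple[str, ...] = ("male",), **kwargs
    ) -> "MFPModel":
        return cls(df[response].to_numpy(), df, continuous=continuous,
                   binary=binary, **kwargs)

    # -- internal ----------------------------------------------------------

    def _prepare(self) -> dict[str, _Covariate]:
        covs = {}
        for name in self.continuous:
            x = self.exog[name].to_numpy(dtype=float)
            shift, scale = default_shift_scale(x)
            covs[name] = _Covariate(name, x, shift, scale)
        return covs

    def _binary_block(self) -> np.ndarray:
        if not self.binary:
            return np.empty((self.nobs, 0))
        return self.exog[list(self.binary)].to_numpy(dtype=float)

    def _design(self, covs, selection, override=None):
        """(X, names) for the current selection; ``override=(name, powers)``
        swaps one covariate's function (powers=None drops it)."""
        blocks = [np.ones((self.nobs, 1))]
        names = ["const"]
        for name in self.continuous:
            powers = selection[name]
            if override is not None and name == override[0]:
                powers = override[1]
            if powers is None:
                continue
            blocks.append(covs[name].columns(powers))
            names.extend(t.label for t in covs[name].terms(powers))
        bin_block = self._binary_block()
        if bin_block.shape[1]:
            blocks.append(bin_block)
            names.extend(self.binary)
        return np.hstack(blocks), names

    def _fsp(self, name, covs, selection, alpha):
        """Closed-test function selection for one covariate."""
        n = self.nobs

        def rss_for(powers):
            X, _ = self._design(covs, selection, override=(name, powers))
            return _rss(X, self.endog)

        rss_null = rss_for(None)
        rss_lin = rss_for((1.0,))
        fp1 = min(((rss_for((p,)), (p,)) for p in self.powers), key=lambda z: z[0])
        fp2 = min(
            (
                (rss_for(pp), pp)
                for pp in itertools.combinations_with_replacement(self.powers, 2)
            ),
            key=lambda z: z[0],
        )

        def dev_stat(rss_reduced, rss_full):
            return max(n * math.log(rss_reduced / rss_full), 0.0)

        if stats.chi2.sf(dev_stat(rss_null, fp2[0]), 4) > alpha:
            return None
        if stats.chi2.sf(dev_stat(rss_lin, fp2[0]), 3) > alpha:
            return (1.0,)
        if stats.chi2.sf(dev_stat(fp1[0], fp2[0]), 2) > alpha:
            return fp1[1]
        return fp2[1]

    def _visit_order(self, covs) -> list[str]:
        """Continuous covariates ordered most significant first (full linear fit)."""
        selection = {name: (1.0,) for name in self.continuous}
        X, names = self._design(covs, selection)
        beta, _, rank, _ = np.linalg.lstsq(X, self.endog, rcond=None)
        if rank < X.shape[1]:
            raise SingularFitError("design matrix is rank deficient (collinear covariates)")
        resid = self.endog - X @ beta
        df = self.nobs - X.shape[1]
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        pvals = {}
        for name in self.continuous:
            j = names.index(f"{name}^1")
            tstat = beta[j] / se[j]
            pvals[name] = 2 * stats.t.sf(abs(tstat), df)
        return sorted(self.continuous, key=lambda nm: pvals[nm])

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        alpha: float = 0.05,
        forced_linear: tuple[str, ...] = (),
        max_cycles: int = 5,
    ) -> "MFPResults":
        """Run function selection and return the fitted model.

        ``forced_linear`` lists continuous covariates that bypass selection
        and always enter linearly.
        """
        covs = self._prepare()
        order = self._visit_order(covs)
        selection: dict[str, tuple[float, ...] | None] = {
            name: (1.0,) for name in self.continuous
        }
        for _ in range(max_cycles):
            changed = False
            for name in order:
                if name in forced_linear:
                    new = (1.0,)
                else:
                    new = self._fsp(name, covs, selection, alpha)
                if new != selection[name]:
                    selection[name] = new
                    changed = True
            if not changed:
                break

        X, names = self._design(covs, selection)
        beta, _, rank, _ = np.linalg.lstsq(X, self.endog, rcond=None)
        if rank < X.shape[1]:
            raise SingularFitError("design matrix is rank deficient (collinear covariates)")
        resid = self.endog - X @ beta
        rss = float(resid @ resid)
        df_resid = self.nobs - X.shape[1]
        resid_sd = math.sqrt(rss / df_resid)
        cov_params = rss / df_resid * np.linalg.inv(X.T @ X)
        llf = -0.5 * self.nobs * (math.log(2 * math.pi * rss / self.nobs) + 1)
        terms = {
            name: (covs[name].terms(selection[name]) if selection[name] else None)
            for name in self.continuous
        }
        return MFPResults(
            model=self,
            alpha=alpha,
            selection=dict(selection),
            terms=terms,
            covariates={name: (covs[name].shift, covs[name].scale) for name in self.continuous},
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov_params)), index=names),
            resid=resid,
            resid_sd=resid_sd,
            df_resid=df_resid,
            llf=llf,
        )


@dataclass
class MFPResults:
    """Fit results: selected FP shapes, coefficients, dispersion, diagnostics."""

    model: MFPModel
    alpha: float
    selection: dict[str, tuple[float, ...] | None]
    terms: dict[str, tuple[FPTerm, ...] | None]
    covariates: dict[str, tuple[float, float]]  # name -> (shift, scale)
    params: pd.Series
    bse: pd.Series
    resid: np.ndarray
    resid_sd: float
    df_resid: int
    llf: float

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        """Predicted scaled score for new demographic data."""
        pred = np.full(len(exog), self.params["const"], dtype=float)
        for name, terms in self.terms.items():
            if terms is None:
                continue
            for term in terms:
                pred += self.params[term.label] * fp_transform(
                    exog[name].to_numpy(dtype=float), term
                )
        for name in self.model.binary:
            pred += self.params[name] * exog[name].to_numpy(dtype=float)
        return pred

    def t_scores(self, exog: pd.DataFrame | None = None, endog=None) -> np.ndarray:
        """Demographically corrected T-scores (mean 50, SD 10 on the fitting sample)."""
        if exog is None:
            return 50.0 + 10.0 * self.resid / self.resid_sd
        y = np.asarray(endog, dtype=float)
        return 50.0 + 10.0 * (y - self.predict(exog)) / self.resid_sd

    def canonical_coefficients(self) -> dict[str, float]:
        """Coefficients re-expressed on the canonical (edu+1)/10, age/100 basis.

        Requires every selected continuous shape to be linear (a dropped
        covariate contributes a zero coefficient); a non-linear shape raises
        :class:`UnsupportedShapeError` -- use :meth:`predict` instead.
        """
        canonical = {"education": (1.0, 10.0), "age": (0.0, 100.0)}
        slopes = {}
        b0 = float(self.params["const"])
        for name in self.model.continuous:
            sel = self.selection[name]
            if sel is None:
                slopes[name] = 0.0
                continue
            if sel != (1.0,):
                raise UnsupportedShapeError(
                    f"{name}: selected powers {sel} are not linear; linear norm "
                    "coefficients cannot represent this shape (use predict())"
                )
            shift, scale = self.covariates[name]
            beta = float(self.params[f"{name}^1"])
            c_shift, c_scale = canonical.get(name, (shift, scale))
            slope = beta * c_scale / scale  # coefficient on (x + c_shift)/c_scale
            b0 += beta * shift / scale - slope * c_shift / c_scale
            slopes[name] = slope
        return {
            "const": b0,
            "education": slopes.get("education", 0.0),
            "age": slopes.get("age", 0.0),
            "male": float(self.params.get("male", 0.0)),
            "resid_sd": self.resid_sd,
        }

    def to_norm_coefficients(self, measure: TestMeasure | str) -> NormCoefficients:
        """Emit linear T-score formula coefficients for ``measure``."""
        if isinstance(measure, str):
            measure = get_measure(measure)
        c = self.canonical_coefficients()
        return NormCoefficients(
            measure,
            b0=c["const"],
            b_edu=c["education"],
            b_age=c["age"],
            b_male=c["male"],
            resid_sd=c["resid_sd"],
        )

    def bootstrap_stability(self, K: int = 1000, seed: int | None = None) -> "StabilityReport":
        """Bootstrap the whole selection-and-fit procedure K times.

        Subjects are resampled with replacement; each replicate reruns the
        closed-test selection.  Deterministic given ``seed`` (replicate r
        uses an independent derived stream).
        """
        if K < 1:
            raise MFPError("K must be >= 1")
        children = np.random.SeedSequence(seed).spawn(K)
        counts: dict[str, dict[str, int]] = {n: {} for n in self.model.continuous}
        coef_rows = []
        n_failed = 0
        y = self.model.endog
        exog = self.model.exog
        for child in children:
            rng = np.random.default_rng(child)
            idx = rng.integers(0, self.nobs, self.nobs)
            try:
                res = MFPModel(
                    y[idx],
                    exog.iloc[idx],
                    continuous=self.model.continuous,
                    binary=self.model.binary,
                    powers=self.model.powers,
                ).fit(alpha=self.alpha)
            except (SingularFitError, MFPError):
                n_failed += 1
                continue
            for name in self.model.continuous:
                key = _powers_key(res.selection[name])
                counts[name][key] = counts[name].get(key, 0) + 1
            if all(
                res.selection[n] in (None, (1.0,)) for n in self.model.continuous
            ):
                coef_rows.append(res.canonical_coefficients())
        n_ok = K - n_failed
        freqs = {
            name: {k: v / n_ok for k, v in sorted(cnt.items())}
            for name, cnt in counts.items()
        } if n_ok else {name: {} for name in counts}
        coef_df = pd.DataFrame(coef_rows)
        if len(coef_df):
            coef_summary = coef_df.agg(["mean"]).T
            coef_summary["p2.5"] = coef_df.quantile(0.025)
            coef_summary["p97.5"] = coef_df.quantile(0.975)
        else:
            coef_summary = pd.DataFrame(columns=["mean", "p2.5", "p97.5"])
        return StabilityReport(
            K=K,
            n_failed=n_failed,
            power_frequencies=freqs,
            coef_summary=coef_summary,
            n_linear_replicates=len(coef_df),
        )

    def summary(self) -> str:
        lines = [
            "MFP demographic-correction model (Gaussian)",
            f"  nobs: {self.nobs}   df_resid: {self.df_resid}   "
            f"resid SD: {self.resid_sd:.4f}   loglik: {self.llf:.2f}",
            f"  selection alpha: {self.alpha}",
            "  selected shapes:",
        ]
        for name in self.model.continuous:
            sel = self.selection[name]
            shape = "dropped" if sel is None else (
                "linear" if sel == (1.0,) else f"FP powers {sel}"
            )
            shift, scale = self.covariates[name]
            lines.append(f"    {name:<12} {shape}   [t = (x + {shift:g})/{scale:g}]")
        for name in self.model.binary:
            lines.append(f"    {name:<12} linear (always retained)")
        lines.append("  coefficients (estimate, SE):")
        for label in self.params.index:
            lines.append(
                f"    {label:<16} {self.params[label]: .4f}  ({self.bse[label]:.4f})"
            )
        return "\n".join(lines)


def _powers_key(sel: tuple[float, ...] | None) -> str:
    if sel is None:
        return "dropped"
    return ",".join(f"{p:g}" for p in sel)


@dataclass
class StabilityReport:
    """Bootstrap stability of MFP function selection and coefficients."""

    K: int
    n_failed: int
    power_frequencies: dict[str, dict[str, float]]
    coef_summary: pd.DataFrame
    n_linear_replicates: int

    def summary(self) -> str:
        lines = [f"Bootstrap stability report (K={self.K}, failed fits: {self.n_failed})"]
        for name, freqs in self.power_frequencies.items():
            pretty = ", ".join(f"{k}: {v:.1%}" for k, v in freqs.items())
            lines.append(f"  {name}: {pretty}")
        lines.append(
            f"  coefficient summary over {self.n_linear_replicates} linear replicates:"
        )
        lines.append(self.coef_summary.to_string())
        return "\n".join(lines)


def fit_mfp(
    y,
    demographics,
    alpha: float = 0.05,
    **kwargs,
) -> MFPResults:
    """Convenience wrapper: fit the MFP model on scaled scores.

    ``demographics`` may be a DataFrame with age/education/male columns or a
    sequence of :class:`Demographics`.
    """
    if not isinstance(demographics, pd.DataFrame):
        demographics = pd.DataFrame(
            [{"age": d.age, "education": d.education, "male": d.male} for d in demographics]
        )
    return MFPModel(y, demographics).fit(alpha=alpha, **kwargs)
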