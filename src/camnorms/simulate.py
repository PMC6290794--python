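"""Synthetic two-group cohort generator.

Emulates the statistical structure of the study population behind the
built-in norms: a seronegative normative group and an HIV-positive group
with their own demographic distributions (age and education as truncated
normals, gender as Bernoulli), demographic gradients on every test score
(inherited from a generative norm set), within-subject correlation across
the seven measures through a single shared factor, group effects expressed
as target Cohen's d on the T-score scale, and HIV covariates (CD4,
viral load, treatment status, viral genotype class) for the positive group.

Generation inverts the scoring pipeline: expected scaled score from the
generative coefficients, plus correlated Gaussian noise, plus the group
shift ``d * resid_sd`` for positives, rounded and clamped to the table's SS
range, then mapped to a raw value drawn uniformly within the SS bin.
Scoring the generated cohort with the generative norms therefore recovers
the configured effects (up to rounding attenuation and sampling error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cameroon import builtin_cameroon_norms
from .mfp import Demographics
from .norms import NormSet
from .scaled import round_half_away
from .scoring import RawRecord

_Z75 = stats.norm.ppf(0.75)  # 0.6745: quartile z used to solve log-normal spread


@dataclass(frozen=True)
class GroupDemographics:
    """Truncated-normal age/education and Bernoulli gender for one group."""

    age_mean: float
    age_sd: float
    edu_mean: float
    edu_sd: float
    male_p: float
    age_range: tuple[float, float] = (18.0, 64.0)
    edu_range: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_p <= 1.0:
            raise ValueError(f"male_p must be in [0, 1], got {self.male_p}")
        if self.age_sd <= 0 or self.edu_sd <= 0:
            raise ValueError("age_sd and edu_sd must be > 0")


@dataclass(frozen=True)
class HIVCovariateSpec:
    """Distributional targets for HIV covariates in the positive group."""

    cd4_median: float = 407.0
    cd4_iqr: tuple[float, float] = (246.0, 574.0)
    p_detectable: float = 0.433
    log10_vl_mean: float = 4.59
    log10_vl_sd: float = 1.28
    p_cart: float = 0.551
    genotype_probs: dict[str, float] = field(
        default_factory=lambda: {"AG": 0.59, "AG_plus": 0.149, "non_AG": 0.261}
    )

    def __post_init__(self) -> None:
        for p in (self.p_detectable, self.p_cart, *self.genotype_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.genotype_probs.values()) - 1.0) > 1e-6:
            raise ValueError("genotype class probabilities must sum to 1")

    def cd4_lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln CD4, least-squares matched to the median and IQR."""
        q = np.log([self.cd4_iqr[0], self.cd4_median, self.cd4_iqr[1]])
        z = np.array([-_Z75, 0.0, _Z75])
        sigma = float((q[2] - q[0]) / (2 * _Z75))
        mu = float(q.mean())
        return mu, sigma


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic two-group cohort."""

    n_neg: int
    n_pos: int
    neg: GroupDemographics
    pos: GroupDemographics
    norms: NormSet
    effects: dict[str, float] = field(default_factory=dict)
    hiv: HIVCovariateSpec = field(default_factory=HIVCovariateSpec)
    shared_factor_loading: float = 0.4
    genotype_effects: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_neg <= 0 or self.n_pos <= 0:
            raise ValueError("group sizes must be > 0")
        valid = set(self.norms.measure_names)
        for d in (self.effects, self.genotype_effects or {}):
            unknown = sorted(set(d) - valid)
            if unknown:
                raise ValueError(
                    f"effects specified for unknown measures {unknown}; "
                    f"valid: {', '.join(sorted(valid))}"
                )
        if not 0.0 <= self.shared_factor_loading < 1.0:
            raise ValueError("shared_factor_loading must be in [0, 1)")


def default_cameroon_spec(norms: NormSet | None = None) -> CohortSpec:
    """CohortSpec matching the study cohort behind the built-in norms.

    Group sizes 395/347; age 34.6 +/- 10.5 vs 37.9 +/- 9.38; education
    12.4 +/- 4.23 vs 9.65 +/- 3.78 years; male 34.7% vs 22.2%; group effects
    are the published T-score Cohen's d per measure; CD4 median 407
    (IQR 246-574), 43.3% detectable viral load with log10 VL 4.59 +/- 1.28,
    55.1% on cART; genotype classes AG 59% / AG-plus 14.9% / non-AG 26.1%.
    """
    return CohortSpec(
        n_neg=395,
        n_pos=347,
        neg=GroupDemographics(34.6, 10.5, 12.4, 4.23, 0.347),
        pos=GroupDemographics(37.9, 9.38, 9.65, 3.78, 0.222),
        norms=norms if norms is not None else builtin_cameroon_norms(),
        effects={
            "ctt2_time": -0.21,
            "hct_errors": -0.17,
            "stroop_correct": -0.04,
            "wcst_errors": -0.39,
            "category_fluency": -0.01,
            "action_fluency": -0.16,
            "letter_fluency": -0.07,
        },
        hiv=HIVCovariateSpec(),
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_group(rng, demo: GroupDemographics, n: int) -> pd.DataFrame:
    age = _truncated_normal(rng, demo.age_mean, demo.age_sd, *demo.age_range, n)
    edu = np.clip(
        round_half_away(
            _truncated_normal(rng, demo.edu_mean, demo.edu_sd, *demo.edu_range, n)
        ),
        demo.edu_range[0],
        demo.edu_range[1],
    )
    male = (rng.random(n) < demo.male_p).astype(int)
    return pd.DataFrame({"age": age, "education": edu, "male": male})


def _draw_scores(rng, spec: CohortSpec, demo: pd.DataFrame, group: str,
                 genotype: np.ndarray | None) -> pd.DataFrame:
    n = len(demo)
    lam = spec.shared_factor_loading
    factor = rng.standard_normal(n)
    raw = {}
    for name in spec.norms.measure_names:
        coef = spec.norms.coefficients[name]
        table = spec.norms.ss_tables[name]
        mu = coef.predict_ss(
            demo["age"].to_numpy(), demo["education"].to_numpy(), demo["male"].to_numpy()
        )
        eps = rng.standard_normal(n)
        noise = coef.resid_sd * (lam * factor + math.sqrt(1.0 - lam * lam) * eps)
        ss_cont = mu + noise
        if group == "hiv_pos":
            ss_cont = ss_cont + spec.effects.get(name, 0.0) * coef.resid_sd
            if spec.genotype_effects and genotype is not None:
                # effect defined as AG minus (AG_plus u non_AG)
                d_gen = spec.genotype_effects.get(name, 0.0)
                ss_cont = ss_cont - d_gen * coef.resid_sd * (genotype != "AG")
        ss = np.clip(round_half_away(ss_cont), table.ss_min, table.ss_max).astype(int)
        # invert to a raw value uniformly within the SS bin
        bounds = np.array([table.bin_bounds(s) for s in range(table.ss_min, table.ss_max + 1)])
        lo = bounds[ss - table.ss_min, 0]
        hi = bounds[ss - table.ss_min, 1]
        raw[name] = rng.integers(lo, hi + 1)
    return pd.DataFrame(raw)


def _draw_hiv_covariates(rng, hiv: HIVCovariateSpec, n: int) -> pd.DataFrame:
    mu, sigma = hiv.cd4_lognormal_params()
    cd4 = np.exp(rng.normal(mu, sigma, n)).round().astype(int)
    detectable = rng.random(n) < hiv.p_detectable
    log10_vl = np.where(
        detectable, rng.normal(hiv.log10_vl_mean, hiv.log10_vl_sd, n), np.nan
    )
    on_cart = rng.random(n) < hiv.p_cart
    classes = list(hiv.genotype_probs)
    genotype = rng.choice(classes, size=n, p=[hiv.genotype_probs[c] for c in classes])
    return pd.DataFrame(
        {
            "cd4": cd4,
            "vl_detectable": detectable,
            "log10_vl": log10_vl,
            "on_cart": on_cart,
            "genotype": genotype,
        }
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None, as_frame: bool = True):
    """Draw a full two-group cohort; deterministic given ``seed``.

    Returns a wide cohort DataFrame (ready for :func:`camnorms.scoring.score_frame`)
    or, with ``as_frame=False``, a list of :class:`~camnorms.scoring.RawRecord`.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for group, n, gdemo in (
        ("hiv_neg", spec.n_neg, spec.neg),
        ("hiv_pos", spec.n_pos, spec.pos),
    ):
        demo = _draw_group(rng, gdemo, n)
        if group == "hiv_pos":
            cov = _draw_hiv_covariates(rng, spec.hiv, n)
            genotype = cov["genotype"].to_numpy()
        else:
            cov = None
            genotype = None
        scores = _draw_scores(rng, spec, demo, group, genotype)
        prefix = "neg" if group == "hiv_neg" else "pos"
        frame = pd.concat([demo, scores], axis=1)
        frame.insert(0, "group", group)
        frame.insert(0, "subject_id", [f"{prefix}{i:05d}" for i in range(n)])
        if cov is not None:
            frame = pd.concat([frame, cov], axis=1)
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    if as_frame:
        return df
    return frame_to_records(df)


def generate_normative_sample(
    spec: CohortSpec, seed: int | None = None, n: int | None = None, as_frame: bool = True
):
    """Draw only the seronegative normative group (optionally resized to ``n``)."""
    if n is not None:
        spec = replace(spec, n_neg=n)
    rng = np.random.default_rng(seed)
    demo = _draw_group(rng, spec.neg, spec.n_neg)
    scores = _draw_scores(rng, spec, demo, "hiv_neg", None)
    df = pd.concat([demo, scores], axis=1)
    df.insert(0, "group", "hiv_neg")
    df.insert(0, "subject_id", [f"neg{i:05d}" for i in range(spec.n_neg)])
    if as_frame:
        return df
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[RawRecord]:
    """Convert a wide cohort DataFrame into RawRecord objects."""
    from .measures import MEASURE_NAMES

    cov_cols = [c for c in ("cd4", "vl_detectable", "log10_vl", "on_cart", "genotype")
                if c in df.columns]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        raw = {m: d[m] for m in MEASURE_NAMES if m in d and np.isfinite(d[m])}
        covariates = {c: d[c] for c in cov_cols} if d["group"] == "hiv_pos" and cov_cols else None
        records.append(
            RawRecord(
                subject_id=str(d["subject_id"]),
                group=d["group"],
                demographics=Demographics(
                    age=float(d["age"]), education=float(d["education"]), male=int(d["male"])
                ),
                raw=raw,
                covariates=covariates,
            )
        )
    return records
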