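"""Linear mixed-effects modeling of the synergy-control -> adaptability link.

The maximal model for each synergy k regresses a coordination-variability
response (DP, or the DP x NJI product) on the speed-normalized PA_kRMS, the
walking-speed factor ("Trial"), their interaction, and random intercepts and
PA_kRMS slopes for both participants and trials:

    response ~ PA + Trial + PA:Trial + (PA | Participant) + (PA | Trial)

Backward stepwise elimination simplifies the maximal model: random terms first
(REML likelihood-ratio tests, slopes before the matching intercepts), then
fixed terms (ML likelihood-ratio tests, interaction before main effects, the
fixed intercept never removed).  Fitting is backed by statsmodels MixedLM;
participant-only random structures use a correlated intercept+slope block,
while models that also carry trial random terms are fit as independent
variance components within a single group (crossed random effects), which
drops the intercept-slope correlation for those structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coordination import DPRecord
from .posture import PARMSRecord
from .smoothness import NJIRecord

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ModelFitError",
    "assemble_dataset",
    "fit_mixed",
    "stepwise_eliminate",
    "compare_models",
    "model_indices",
    "bonferroni_gate",
    "lrt",
]

FIXED_TERMS = ("PA", "Trial", "PA:Trial")
RANDOM_TERMS = (
    "participant_intercept",
    "participant_slope",
    "trial_intercept",
    "trial_slope",
)


class ModelFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model candidate: response, PA covariate, fixed and random terms.

    The fixed intercept is always present.  A random slope requires the
    matching random intercept (hierarchy of the grouping structure).
    """

    response: str
    pa: str
    fixed_terms: tuple[str, ...] = FIXED_TERMS
    random_terms: tuple[str, ...] = RANDOM_TERMS
    k: int | None = None
    # parametrize participant random effects as independent variance
    # components (no intercept-slope correlation); used during random-term
    # elimination so every candidate in a chain is nested in the previous one
    vc_only: bool = False

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random_terms:
            if t not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")
        for grp in ("participant", "trial"):
            if f"{grp}_slope" in self.random_terms and f"{grp}_intercept" not in self.random_terms:
                raise ValueError(f"{grp} random slope requires the {grp} random intercept")
        object.__setattr__(self, "fixed_terms", tuple(dict.fromkeys(self.fixed_terms)))
        object.__setattr__(self, "random_terms", tuple(dict.fromkeys(self.random_terms)))

    def drop_fixed(self, term: str) -> "ModelSpec":
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))

    def drop_random(self, term: str) -> "ModelSpec":
        return replace(self, random_terms=tuple(t for t in self.random_terms if t != term))

    def formula(self) -> str:
        parts = ["1"]
        if "PA" in self.fixed_terms:
            parts.append("pa")
        if "Trial" in self.fixed_terms:
            parts.append("C(trial)")
        if "PA:Trial" in self.fixed_terms:
            parts.append("pa:C(trial)")
        return "y ~ " + " + ".join(parts)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.response == other.response
            and self.pa == other.pa
            and self.vc_only == other.vc_only
            and set(self.fixed_terms) <= set(other.fixed_terms)
            and set(self.random_terms) <= set(other.random_terms)
        )


@dataclass
class FittedModel:
    """One REML+ML mixed-model fit with variance components and fit indices."""

    spec: ModelSpec
    n: int
    fe_params: pd.Series
    fe_bse: pd.Series
    fe_pvalues: pd.Series
    vcomps: dict[str, float]
    resid_var: float
    llf_reml: float
    llf_ml: float
    df: int
    singular: bool
    converged: bool
    _frame: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    _res_reml: object = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf_ml + 2.0 * self.df

    @property
    def bic(self) -> float:
        return -2.0 * self.llf_ml + self.df * np.log(self.n)

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf_ml

    @property
    def icc(self) -> float:
        """Intraclass correlation: participant-intercept variance share."""
        v = self.vcomps.get("participant_intercept", 0.0)
        denom = v + self.resid_var
        return float(np.clip(v / denom, 0.0, 1.0)) if denom > 0 else 0.0

    def row_fingerprint(self) -> int:
        return int(pd.util.hash_pandas_object(self._frame[["subject", "trial", "y"]]).sum())


def _working_frame(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject", "trial", spec.response, spec.pa):
        if col not in data.columns:
            raise ValueError(f"data is missing required column {col!r}")
    wf = pd.DataFrame(
        {
            "subject": data["subject"].astype(str),
            "trial": data["trial"].astype(str),
            "pa": data[spec.pa].astype(float),
            "y": data[spec.response].astype(float),
        }
    ).reset_index(drop=True)
    if not np.isfinite(wf["y"]).all() or not np.isfinite(wf["pa"]).all():
        raise ValueError("response/covariate contain non-finite values")
    if wf["y"].std() == 0:
        raise ModelFitError("response is constant; nothing to model")
    wf["one"] = 1
    return wf


def _uses_vc(spec: ModelSpec) -> bool:
    return spec.vc_only or bool(
        {"trial_intercept", "trial_slope"} & set(spec.random_terms)
    )


def _count_df(spec: ModelSpec, n_fe: int) -> int:
    rt = set(spec.random_terms)
    n_re = 0
    if _uses_vc(spec):
        # independent variance components, one parameter each
        n_re = len(rt)
    else:
        if "participant_slope" in rt:
            n_re = 3  # intercept var, slope var, covariance
        elif "participant_intercept" in rt:
            n_re = 1
    return n_fe + n_re + 1  # + residual variance


def _fit_with_retries(model, reml: bool):
    """Fit with two optimizers and keep the better likelihood.

    Gradient-based L-BFGS occasionally converges to a spurious point on
    variance-component models, so a direction-set (Powell) fit is always run
    as well; further fallbacks cover singular-Hessian failures at variance
    boundaries.
    """
    best = None
    last_exc: Exception | None = None
    for method in (["bfgs"], ["powell"], ["lbfgs"], ["nm"], ["cg"]):
        try:
            res = model.fit(reml=reml, method=method, maxiter=300)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
            best = res
        if method == ["powell"] and best is not None:
            break  # two successful fits are enough
    if best is None:
        raise ModelFitError(f"mixed-model optimization failed: {last_exc}") from last_exc
    return best


def _fit_one(spec: ModelSpec, wf: pd.DataFrame, reml: bool):
    formula = spec.formula()
    rt = set(spec.random_terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not rt:
            res = sm.OLS.from_formula(formula, data=wf).fit()
            return res, "ols"
        if _uses_vc(spec):
            vc = {}
            if "participant_intercept" in rt:
                vc["participant_intercept"] = "0 + C(subject)"
            if "participant_slope" in rt:
                vc["participant_slope"] = "0 + C(subject):pa"
            if "trial_intercept" in rt:
                vc["trial_intercept"] = "0 + C(trial)"
            if "trial_slope" in rt:
                vc["trial_slope"] = "0 + C(trial):pa"
            model = sm.MixedLM.from_formula(
                formula, data=wf, groups="one", vc_formula=vc, re_formula="0"
            )
            return _fit_with_retries(model, reml), "vc"
        re_formula = "1 + pa" if "participant_slope" in rt else "1"
        model = sm.MixedLM.from_formula(
            formula, data=wf, groups="subject", re_formula=re_formula
        )
        return _fit_with_retries(model, reml), "re"


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one model by REML (reported estimates) and ML (for LRT/AIC/BIC).

    Singular or non-converged fits are flagged, not silently accepted; a fit
    that produces non-finite estimates raises :class:`ModelFitError`.
    """
    wf = _working_frame(spec, data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _extract_fit(spec, wf)


def _extract_fit(spec: ModelSpec, wf: pd.DataFrame) -> FittedModel:
    res_reml, kind = _fit_one(spec, wf, reml=True)
    res_ml, _ = _fit_one(spec, wf, reml=False)
    y_var = float(wf["y"].var())
    tol = 1e-6 * y_var
    vcomps: dict[str, float] = {}
    singular = False
    converged = True
    if kind == "ols":
        fe = res_reml.params
        bse = res_reml.bse
        pvals = res_reml.pvalues
        resid_var = float(res_reml.mse_resid)
        llf_reml = float(res_reml.llf)
        llf_ml = float(res_ml.llf)
    else:
        fe = res_reml.fe_params
        bse = res_reml.bse_fe
        pvals = pd.Series(
            2 * stats.norm.sf(np.abs(fe / bse)), index=fe.index, dtype=float
        )
        resid_var = float(res_reml.scale)
        llf_reml = float(res_reml.llf)
        llf_ml = float(res_ml.llf)
        converged = bool(getattr(res_reml, "converged", True))
        if kind == "re":
            cov = np.asarray(res_reml.cov_re)
            vcomps["participant_intercept"] = float(cov[0, 0])
            if cov.shape[0] > 1:
                vcomps["participant_slope"] = float(cov[1, 1])
                vcomps["participant_int_slope_cov"] = float(cov[0, 1])
                denom = np.sqrt(cov[0, 0] * cov[1, 1])
                if denom <= 0 or abs(cov[0, 1]) / denom > 0.999:
                    singular = True
            if cov[0, 0] < tol or (cov.shape[0] > 1 and cov[1, 1] < tol):
                singular = True
        else:  # variance components, crossed
            names = list(res_reml.model.exog_vc.names)
            for name, v in zip(names, np.asarray(res_reml.vcomp) * 1.0):
                vcomps[name] = float(v)
            if any(v < tol for v in vcomps.values()):
                singular = True
    if not (np.isfinite(fe).all() and np.isfinite(llf_reml) and np.isfinite(llf_ml)):
        raise ModelFitError(f"non-finite estimates for {spec}")
    n_fe = len(fe)
    return FittedModel(
        spec=spec,
        n=len(wf),
        fe_params=fe,
        fe_bse=bse,
        fe_pvalues=pvals,
        vcomps=vcomps,
        resid_var=resid_var,
        llf_reml=llf_reml,
        llf_ml=llf_ml,
        df=_count_df(spec, n_fe),
        singular=singular,
        converged=converged,
        _frame=wf,
        _res_reml=res_reml,
    )


def lrt(full: FittedModel, reduced: FittedModel, reml: bool = False) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model against the full model.

    Returns (chi-square, df difference, p).  REML likelihoods are only valid
    for comparing random structures with identical fixed effects.
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError("models are not nested")
    ll_f = full.llf_reml if reml else full.llf_ml
    ll_r = reduced.llf_reml if reml else reduced.llf_ml
    chi2 = max(0.0, 2.0 * (ll_f - ll_r))
    df = full.df - reduced.df
    if df <= 0:
        return chi2, df, 1.0 if chi2 < 1e-9 else float("nan")
    return chi2, df, float(stats.chi2.sf(chi2, df))


_TERM_PREFIX = {
    "PA": ("pa",),
    "Trial": ("C(trial)[",),
    "PA:Trial": ("pa:C(trial)[",),
}


def _term_coef_names(fe_index, term: str) -> list[str]:
    if term == "PA":
        return [c for c in fe_index if c == "pa"]
    prefixes = _TERM_PREFIX[term]
    return [c for c in fe_index if any(c.startswith(p) for p in prefixes)]


def wald_f_test(model: FittedModel, term: str) -> tuple[float, int, int, float]:
    """Wald F-test of one fixed term with a between-within denominator df.

    The denominator degrees of freedom are approximated as
    ``n - p_fixed - (n_subjects - 1)`` (a small-sample stand-in for a
    Satterthwaite approximation); the test uses the REML fixed-effect
    covariance of the full fit.
    """
    names = _term_coef_names(model.fe_params.index, term)
    if not names:
        raise ValueError(f"term {term!r} has no coefficients in the fit")
    res = model._res_reml
    idx = [list(model.fe_params.index).index(c) for c in names]
    beta = model.fe_params.to_numpy()[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    q = len(idx)
    try:
        stat = float(beta @ np.linalg.solve(cov, beta)) / q
    except np.linalg.LinAlgError:
        return float("nan"), q, 0, float("nan")
    n_subjects = model._frame["subject"].nunique()
    den_df = max(1, model.n - len(model.fe_params) - (n_subjects - 1))
    p = float(stats.f.sf(stat, q, den_df))
    return stat, q, den_df, p


class _FitCache:
    def __init__(self, data: pd.DataFrame):
        self.data = data
        self._cache: dict[ModelSpec, FittedModel | None] = {}

    def get(self, spec: ModelSpec) -> FittedModel | None:
        """Fitted model, or None when the optimizer fails outright."""
        if spec not in self._cache:
            try:
                self._cache[spec] = fit_mixed(spec, self.data)
            except ModelFitError:
                self._cache[spec] = None
        return self._cache[spec]


def _random_candidates(spec: ModelSpec) -> list[str]:
    """Removable random terms; slopes must go before their intercepts."""
    out = []
    rt = set(spec.random_terms)
    for grp in ("trial", "participant"):
        if f"{grp}_slope" in rt:
            out.append(f"{grp}_slope")
        elif f"{grp}_intercept" in rt:
            out.append(f"{grp}_intercept")
    return out


def _fixed_candidates(spec: ModelSpec) -> list[str]:
    """Removable fixed terms respecting marginality; intercept never removed."""
    ft = set(spec.fixed_terms)
    if "PA:Trial" in ft:
        return ["PA:Trial"]
    return [t for t in ("PA", "Trial") if t in ft]


def stepwise_eliminate(
    maximal: ModelSpec,
    data: pd.DataFrame,
    alpha_random: float = 0.05,
    alpha_fixed: float = 0.05,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Backward elimination from the maximal model.

    Random terms are tested first with REML likelihood-ratio tests (slope
    before intercept within a grouping); fixed terms follow with ML
    likelihood-ratio tests (interaction before main effects).  At each step
    the least significant candidate with p above the threshold is removed.
    Returns the reduced spec and the elimination log.
    """
    cache = _FitCache(data)
    spec = maximal
    # crossed maximal models are parametrized with independent variance
    # components; keep that parametrization for the whole random phase so
    # successive candidates stay nested
    random_phase_vc = _uses_vc(maximal)
    if random_phase_vc:
        spec = replace(spec, vc_only=True)
    log: list[dict] = []

    # --- random terms: REML likelihood-ratio tests ---
    while True:
        cands = _random_candidates(spec)
        if not cands:
            break
        full = cache.get(spec)
        if full is None:
            # unfittable structure: simplify by removing the first candidate
            term = cands[0]
            log.append(
                dict(phase="random", term=term, stat=np.nan, df=np.nan, p=np.nan, removed=True)
            )
            spec = spec.drop_random(term)
            continue
        results = []
        for term in cands:
            reduced = cache.get(spec.drop_random(term))
            if reduced is None:
                continue
            chi2, df, p = lrt(full, reduced, reml=True)
            results.append((term, chi2, df, p))
        if not results:
            break
        term, stat, df, p = max(results, key=lambda r: (r[3], -r[1]))
        remove = p > alpha_random
        log.append(dict(phase="random", term=term, stat=stat, df=df, p=p, removed=remove))
        if not remove:
            break
        spec = spec.drop_random(term)

    if random_phase_vc:
        # reporting parametrization: correlated participant block
        spec = replace(spec, vc_only=False)

    # --- fixed terms: Wald F-tests with small-sample denominator df ---
    while True:
        cands = _fixed_candidates(spec)
        if not cands:
            break
        full = cache.get(spec)
        if full is None:
            term = cands[0]
            log.append(
                dict(phase="fixed", term=term, stat=np.nan, df=np.nan, p=np.nan, removed=True)
            )
            spec = spec.drop_fixed(term)
            continue
        results = []
        for term in cands:
            fstat, q, den, p = wald_f_test(full, term)
            if np.isfinite(p):
                results.append((term, fstat, q, p))
        if not results:
            break
        term, stat, df, p = max(results, key=lambda r: (r[3], -r[1]))
        remove = p > alpha_fixed
        log.append(dict(phase="fixed", term=term, stat=stat, df=df, p=p, removed=remove))
        if not remove:
            break
        spec = spec.drop_fixed(term)
    return spec, pd.DataFrame(log)


def compare_models(
    models: Sequence[FittedModel], baseline_index: int = 0
) -> pd.DataFrame:
    """Goodness-of-fit comparison table against a baseline model.

    All models must be fit on identical rows.  Chi-square LRTs are reported
    for nested pairs only; non-nested pairs get information criteria alone.
    """
    if not models:
        raise ValueError("no models to compare")
    base = models[baseline_index]
    fp = base.row_fingerprint()
    for m in models:
        if m.row_fingerprint() != fp or m.n != base.n:
            raise ValueError("models were fit on different rows; cannot compare")
    rows = []
    for i, m in enumerate(models):
        chi2 = p = df_diff = np.nan
        if i != baseline_index:
            if m.spec == base.spec:
                chi2, df_diff, p = 0.0, 0, 1.0
            elif base.spec.is_nested_in(m.spec):
                chi2, df_diff, p = lrt(m, base)
            elif m.spec.is_nested_in(base.spec):
                chi2, df_diff, p = lrt(base, m)
        rows.append(
            dict(
                model=f"{m.spec.response} ~ {m.spec.pa}",
                k=m.spec.k,
                df=m.df,
                AIC=m.aic,
                BIC=m.bic,
                logLik=m.llf_ml,
                deviance=m.deviance,
                chisq=chi2,
                df_diff=df_diff,
                p=p,
                singular=m.singular,
            )
        )
    return pd.DataFrame(rows)


def model_indices(model: FittedModel, null_model: FittedModel) -> dict[str, float]:
    """Final-model report indices: ICC, McFadden pseudo-R2 (fixed and total).

    ``null_model`` must share the random structure and rows of ``model`` but
    carry no fixed covariates.  The "total" variant uses a fixed-intercept-only
    OLS null with no random terms (recorded in the output metadata).
    """
    if null_model.row_fingerprint() != model.row_fingerprint():
        raise ValueError("null model was fit on different rows")
    if null_model.spec.fixed_terms:
        raise ValueError("null model must have no fixed covariates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols_null = sm.OLS.from_formula("y ~ 1", data=model._frame).fit()
    return dict(
        icc=model.icc,
        pseudo_r2_fixed=1.0 - model.llf_ml / null_model.llf_ml,
        pseudo_r2_total=1.0 - model.llf_ml / float(ols_null.llf),
        aic=model.aic,
        bic=model.bic,
        loglik_reml=model.llf_reml,
        loglik_ml=model.llf_ml,
        total_null="fixed-intercept-only OLS without random terms",
    )


def bonferroni_gate(p_values: Iterable[float], alpha: float = 0.007) -> np.ndarray:
    """Significance decisions at the Bonferroni-corrected level (strict <)."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha


def assemble_dataset(
    pa_records: Iterable[PARMSRecord],
    dp_records: Iterable[DPRecord],
    nji_records: Iterable[NJIRecord],
) -> pd.DataFrame:
    """Join per-trial statistics into the long modeling table.

    One row per subject x speed with columns ``PA{k}_RMS_norm`` for every
    available k, ``DP``, ``NJI`` and ``DPxNJI``; the ``trial`` column is the
    speed as an ordered categorical factor.
    """
    pa_list = list(pa_records)
    dp_list = list(dp_records)
    nji_list = list(nji_records)
    pa_df = pd.DataFrame(
        [
            dict(subject=r.subject, speed=r.speed, k=r.k, value=r.pa_rms_norm)
            for r in pa_list
        ]
    )
    if pa_df.duplicated(["subject", "speed", "k"]).any():
        raise ValueError("duplicate (subject, speed, k) PA records")
    wide = pa_df.pivot(index=["subject", "speed"], columns="k", values="value")
    wide.columns = [f"PA{int(k)}_RMS_norm" for k in wide.columns]

    def _keyed(records, attr):
        out = {}
        for r in records:
            key = (r.subject, r.speed)
            if key in out:
                raise ValueError(f"duplicate (subject, speed) record {key}")
            out[key] = getattr(r, attr)
        return out

    dp_map = _keyed(dp_list, "trial_dp")
    nji_map = _keyed(nji_list, "nji")
    missing = [k for k in wide.index if k not in dp_map or k not in nji_map]
    if missing:
        raise ValueError(f"missing DP/NJI cells for: {missing}")
    table = wide.reset_index()
    table["DP"] = [dp_map[k] for k in wide.index]
    table["NJI"] = [nji_map[k] for k in wide.index]
    table["DPxNJI"] = table["DP"] * table["NJI"]
    speeds = sorted(table["speed"].unique())
    table["trial"] = pd.Categorical(
        [f"{s:g}" for s in table["speed"]],
        categories=[f"{s:g}" for s in speeds],
        ordered=True,
    )
    return table.sort_values(["subject", "speed"]).reset_index(drop=True)
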