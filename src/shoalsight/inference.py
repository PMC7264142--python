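"""Multimodel inference: AICc weighting, full model averaging, repeatability.

The statistical recipe is the standard information-theoretic one for
behavioural data with modest sample-size-to-parameter ratios:

* candidate set = every subset of the main effects (optionally with terms
  forced into all models, e.g. an interaction of interest);
* each model scored by AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1);
* Akaike weight w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2);
* relative importance of a term = sum of the weights of the models that
  contain it, over the complete candidate set;
* *full* model averaging over the smallest weight-descending subset whose
  cumulative weight reaches 95% (weights renormalized): a term absent
  from a model contributes beta = 0, which shrinks weakly supported
  effects towards zero; the unconditional SE folds in between-model
  variance (Burnham & Anderson's revised estimator).

Mixed-model estimation itself is delegated: gaussian models with random
intercepts for fish nested in group go to statsmodels' MixedLM (fitted by
ML so that AICc is comparable across fixed-effect subsets); binomial and
negative-binomial families are fit as fixed-effects GLMs (statsmodels has
no maximum-likelihood GLMM) and the result records that the requested
random structure was not honoured.

Repeatability R = sigma2_id / (sigma2_id + sigma2_group + sigma2_resid)
comes from the fitted variance components, with a seeded parametric
bootstrap CI and a boundary-corrected likelihood-ratio test of the
individual-identity intercept.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FittedModel",
    "CandidateSet",
    "AveragingResult",
    "RepeatabilityResult",
    "standardize",
    "aicc",
    "fit_model",
    "all_subsets",
    "weights_and_ri",
    "full_model_average",
    "cooks_filter",
    "repeatability",
    "spearman",
]


def standardize(
    df: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Scale columns to mean 0, SD 1; returns the frame and (mean, sd) map."""
    out = df.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        m, s = float(np.mean(x)), float(np.std(x, ddof=0))
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {col!r} has zero or undefined SD")
        out[col] = (x - m) / s
        params[col] = (m, s)
    return out, params


def aicc(loglik: float, k_params: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k_params + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k_params + 1}")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


@dataclass(frozen=True)
class ModelSpec:
    """One model: response, fixed terms, family, optional nested random effects.

    ``random`` maps role -> column: ``{"group": ..., "individual": ...}``
    for fish-within-group intercepts (gaussian only), or ``{}`` for none.
    ``transform`` applies to the response before fitting.
    """

    response: str
    fixed: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()  # "a:b" terms, forced into the model
    random: dict = field(default_factory=dict)
    family: str = "gaussian"
    transform: str = "none"  # none | log10 | sqrt

    def formula(self) -> str:
        terms = list(self.fixed) + list(self.interactions)
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"

    def term_names(self) -> tuple[str, ...]:
        return tuple(self.fixed) + tuple(self.interactions)


@dataclass
class FittedModel:
    spec: ModelSpec
    loglik: float
    k_params: int
    n: int
    params: pd.Series
    bse: pd.Series
    converged: bool
    random_effects_honoured: bool
    vc: dict = field(default_factory=dict)  # variance components, gaussian LMM
    result: object = None  # underlying statsmodels result

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k_params, self.n)


def _fit_mixedlm(model):
    """ML fit with a fallback across optimizers.

    Variance components on the zero boundary can leave one optimizer with a
    singular Hessian or a non-finite log-likelihood (lbfgs in particular
    reports llf = inf at an exact zero); such fits are rejected and the next
    optimizer tried.
    """
    last: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "cg"):
        try:
            res = model.fit(reml=False, method=method, maxiter=500)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
            continue
        if np.isfinite(res.llf):
            return res
        last = ValueError(f"non-finite log-likelihood from {method}")
    raise last


def _transform_response(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.transform == "none":
        return df
    out = df.copy()
    y = out[spec.response].to_numpy(dtype=float)
    if spec.transform == "log10":
        if np.any(y <= 0):
            raise ValueError("log10 transform needs a strictly positive response")
        out[spec.response] = np.log10(y)
    elif spec.transform == "sqrt":
        if np.any(y < 0):
            raise ValueError("sqrt transform needs a non-negative response")
        out[spec.response] = np.sqrt(y)
    else:
        raise ValueError(f"unknown transform {spec.transform!r}")
    return out


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one candidate model; see the module docstring for the contract."""
    df = _transform_response(data.dropna(subset=[spec.response, *spec.fixed]), spec)
    n = len(df)
    formula = spec.formula()
    honoured = True
    vc: dict = {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.family == "gaussian" and spec.random:
            group_col = spec.random.get("group")
            id_col = spec.random.get("individual")
            if group_col and id_col:
                model = smf.mixedlm(
                    formula, df, groups=df[group_col], re_formula="1",
                    vc_formula={"individual": f"0 + C({id_col})"},
                )
            elif group_col or id_col:
                model = smf.mixedlm(formula, df, groups=df[group_col or id_col])
            else:
                raise ValueError("random must name 'group' and/or 'individual'")
            res = _fit_mixedlm(model)
            k = len(res.fe_params) + res.k_re * (res.k_re + 1) // 2 + len(res.vcomp) + 1
            vc = {"group": float(res.cov_re.iloc[0, 0]) if res.k_re else 0.0,
                  "resid": float(res.scale)}
            for name, val in zip(model.exog_vc.names, np.atleast_1d(res.vcomp)):
                vc[name] = float(val)
            fitted = FittedModel(spec, float(res.llf), k, n, res.fe_params,
                                 res.bse_fe, bool(res.converged), True, vc, res)
        elif spec.family == "gaussian":
            res = smf.ols(formula, df).fit()
            k = len(res.params) + 1  # + residual variance
            fitted = FittedModel(spec, float(res.llf), k, n, res.params, res.bse,
                                 True, True, {"resid": float(res.scale)}, res)
        elif spec.family == "binomial":
            honoured = not spec.random
            res = smf.glm(formula, df, family=sm.families.Binomial()).fit()
            fitted = FittedModel(spec, float(res.llf), len(res.params), n,
                                 res.params, res.bse, bool(res.converged),
                                 honoured, {}, res)
        elif spec.family == "negative-binomial":
            honoured = not spec.random
            # ML dispersion via the discrete NegativeBinomial model
            from statsmodels.discrete.discrete_model import NegativeBinomial

            y, X = _design(formula, df)
            res = NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            params = res.params.drop(labels=["alpha"], errors="ignore")
            bse = res.bse.drop(labels=["alpha"], errors="ignore")
            fitted = FittedModel(spec, float(res.llf), len(res.params), n,
                                 params, bse, bool(res.mle_retvals.get("converged", True)),
                                 honoured, {}, res)
        else:
            raise ValueError(f"unknown family {spec.family!r}")
    return fitted


def _design(formula: str, df: pd.DataFrame):
    import patsy  # statsmodels' formula backend

    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    return y.iloc[:, 0], X


def all_subsets(
    base: ModelSpec, data: pd.DataFrame, always: tuple[str, ...] = ()
) -> "CandidateSet":
    """Fit all 2^k subsets of the main effects (``always`` terms in every model)."""
    models = []
    k = len(base.fixed)
    for r in range(k + 1):
        for combo in itertools.combinations(base.fixed, r):
            spec = ModelSpec(
                response=base.response,
                fixed=tuple(always) + combo,
                interactions=base.interactions,
                random=base.random,
                family=base.family,
                transform=base.transform,
            )
            try:
                fm = fit_model(spec, data)
            except Exception as exc:  # noqa: BLE001 - non-convergence is data-dependent
                import logging

                logging.getLogger("shoalsight").warning(
                    "candidate %s failed (%s); excluded", spec.formula(), exc
                )
                continue
            # keep any fit with a finite ML solution: mixed models whose
            # group variance sits on the zero boundary often report a false
            # "not converged" flag while the likelihood is perfectly usable
            if np.isfinite(fm.loglik):
                models.append(fm)
    return CandidateSet(models)


class CandidateSet:
    """Fitted candidate models with AICc ranking and Akaike weights."""

    def __init__(self, models: list[FittedModel]):
        if not models:
            raise ValueError("empty candidate set")
        self.models = sorted(models, key=lambda m: m.aicc)
        a = np.array([m.aicc for m in self.models])
        self.delta = a - a.min()
        w = np.exp(-self.delta / 2.0)
        self.weights = w / w.sum()

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "formula": [m.spec.formula() for m in self.models],
                "k": [m.k_params for m in self.models],
                "loglik": [m.loglik for m in self.models],
                "aicc": [m.aicc for m in self.models],
                "delta": self.delta,
                "weight": self.weights,
            }
        )


def weights_and_ri(candidates: CandidateSet) -> tuple[np.ndarray, dict[str, float]]:
    """Akaike weights and per-term relative importance over the complete set."""
    terms: dict[str, float] = {}
    for m, w in zip(candidates.models, candidates.weights):
        for t in m.spec.term_names():
            terms[t] = terms.get(t, 0.0) + float(w)
    return candidates.weights, terms


@dataclass
class AveragingResult:
    estimates: pd.DataFrame  # term, estimate, se, ci_lo, ci_hi, ri
    subset_size: int
    subset_cumweight: float


def full_model_average(
    candidates: CandidateSet,
    ci_level: float = 0.95,
    cumulative_weight: float = 0.95,
) -> AveragingResult:
    """Full (zero-substitution) model averaging over the 95% cumulative set.

    Every term seen in any candidate gets a weighted-average estimate with
    beta = 0 in models that omit it; the SE is Burnham-Anderson's
    unconditional estimator sqrt(sum w (se^2 + (b - b_bar)^2)).  RI always
    uses the complete candidate set.
    """
    _, ri = weights_and_ri(candidates)
    cum = np.cumsum(candidates.weights)
    m_keep = int(np.searchsorted(cum, cumulative_weight) + 1)
    m_keep = min(m_keep, len(candidates.models))
    sub = candidates.models[:m_keep]
    w = candidates.weights[:m_keep]
    w = w / w.sum()

    all_terms = sorted({t for m in sub for t in m.params.index if t != "Intercept"})
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2.0)
    rows = []
    for term in all_terms:
        betas = np.array([float(m.params.get(term, 0.0)) for m in sub])
        ses = np.array([float(m.bse.get(term, 0.0)) for m in sub])
        est = float(np.sum(w * betas))
        se = float(np.sqrt(np.sum(w * (ses**2 + (betas - est) ** 2))))
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "ci_lo": est - z * se,
                "ci_hi": est + z * se,
                "ri": float(ri.get(term, 0.0)),
            }
        )
    return AveragingResult(pd.DataFrame(rows), m_keep, float(cum[m_keep - 1]))


def cooks_filter(
    spec: ModelSpec, data: pd.DataFrame, factor: float = 6.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with Cook's distance > ``factor`` x mean Cook's distance.

    Influence is computed on the OLS fit of the model's fixed-effects
    design (mixed-model influence measures are not available in the
    delegated tooling); the caller refits on the kept rows.
    """
    df = _transform_response(data.dropna(subset=[spec.response, *spec.fixed]), spec)
    res = smf.ols(spec.formula(), df).fit()
    cooks = res.get_influence().cooks_distance[0]
    cutoff = factor * float(np.mean(cooks))
    keep = cooks <= cutoff
    if not keep.any():
        raise ValueError("Cook's filter removed every observation")
    return df.loc[keep], df.loc[~keep]


@dataclass
class RepeatabilityResult:
    R: float
    ci: tuple[float, float]
    p_lrt: float
    vc: dict


def repeatability(
    data: pd.DataFrame,
    response: str,
    individual: str,
    group: str | None = None,
    fixed: tuple[str, ...] = (),
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RepeatabilityResult:
    """Individual-level repeatability from nested variance components.

    R = sigma2_id / (sigma2_id + sigma2_group + sigma2_resid); the group
    component enters the denominator when a group column is given.  The CI
    is a seeded parametric bootstrap (simulate from the fitted components,
    refit, take percentiles); p is a boundary-corrected LRT (0.5 chi2_1)
    of the individual intercept.
    """
    spec = ModelSpec(response=response, fixed=fixed,
                     random=({"group": group, "individual": individual}
                             if group else {"individual": individual}))
    full = fit_model(spec, data)
    s_id = full.vc.get("individual", full.vc.get("group", 0.0)) if group else full.vc.get("group", 0.0)
    s_grp = full.vc.get("group", 0.0) if group else 0.0
    s_res = full.vc.get("resid", np.nan)
    denom = s_id + s_grp + s_res
    R = float(max(0.0, s_id) / denom) if denom > 0 else 0.0

    # LRT against the model without the individual intercept
    if group:
        null_spec = ModelSpec(response=response, fixed=fixed, random={"group": group})
        null_fit = fit_model(null_spec, data)
    else:
        null_spec = ModelSpec(response=response, fixed=fixed, random={})
        null_fit = fit_model(null_spec, data)
    lr = max(0.0, 2.0 * (full.loglik - null_fit.loglik))
    p = 0.5 * scipy.stats.chi2.sf(lr, df=1) if lr > 0 else 1.0

    rng = np.random.default_rng(seed)
    df = data.dropna(subset=[response]).copy()
    ids = df[individual].to_numpy()
    uniq_ids = pd.unique(ids)
    grps = df[group].to_numpy() if group else None
    uniq_grps = pd.unique(grps) if group else []
    mu = float(df[response].mean())
    boots = []
    for _ in range(n_boot):
        y = np.full(len(df), mu)
        bid = dict(zip(uniq_ids, rng.normal(0.0, np.sqrt(max(s_id, 0.0)), len(uniq_ids))))
        y += np.vectorize(bid.get)(ids)
        if group:
            bg = dict(zip(uniq_grps, rng.normal(0.0, np.sqrt(max(s_grp, 0.0)), len(uniq_grps))))
            y += np.vectorize(bg.get)(grps)
        y += rng.normal(0.0, np.sqrt(s_res), len(df))
        bdf = df.copy()
        bdf[response] = y
        try:
            bfit = fit_model(ModelSpec(response=response, random=spec.random), bdf)
        except Exception:  # noqa: BLE001
            continue
        b_id = bfit.vc.get("individual", 0.0) if group else bfit.vc.get("group", 0.0)
        b_grp = bfit.vc.get("group", 0.0) if group else 0.0
        b_res = bfit.vc.get("resid", np.nan)
        d = b_id + b_grp + b_res
        if d > 0:
            boots.append(max(0.0, b_id) / d)
    if boots:
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        ci = (float(min(lo, R)), float(max(hi, R)))
    else:
        ci = (R, R)
    return RepeatabilityResult(R=R, ci=ci, p_lrt=float(p),
                               vc={"individual": s_id, "group": s_grp, "resid": s_res})


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("Spearman correlation needs at least 4 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    r, p = scipy.stats.spearmanr(x, y)
    return float(r), float(p)
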