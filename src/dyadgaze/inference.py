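"""Mixed-effects inference on congruency-conditioned saccadic reaction times.

The analysis models a power-transformed SRT as a function of gaze-point
congruency with nested random intercepts::

    f(SRT) ~ congruency + (1 | pair / subject) + (1 | trial)

fitted by maximum likelihood (ML, not REML — the likelihood-ratio model
comparison requires ML).  The transformation ``f`` is selected by a
profile-likelihood Box-Cox scan and snapped to an interpretable family
(log10 / square root / identity) when the estimate is close enough.

Model comparison against the random-effects-only null uses the
chi-square likelihood-ratio test, chi2 = 2 * (logLik_full - logLik_null).
The evidence ratio exp(delta logLik) is reported alongside; note that a
chi-square statistic and the likelihood ratio itself are different
numbers (ratio = exp(chi2 / 2)) even though both are sometimes quoted
as "times better".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformSpec",
    "SrtModelResult",
    "InsufficientDataError",
    "select_transform",
    "apply_transform",
    "fit_srt_model",
    "likelihood_ratio_test",
]


class InsufficientDataError(ValueError):
    """Raised when a stratum lacks the structure needed for the model."""


@dataclass(frozen=True)
class TransformSpec:
    """Chosen power transformation for positive response data."""

    family: str  # 'log10' | 'sqrt' | 'identity' | 'power'
    lmbda: float  # Box-Cox lambda-hat from the profile likelihood
    snap_radius: float = 0.25
    grid: tuple[float, float, int] = (-2.0, 2.0, 401)

    def __call__(self, x):
        return apply_transform(x, self)


def apply_transform(x, spec: TransformSpec):
    x = np.asarray(x, dtype=float)
    if spec.family == "log10":
        return np.log10(x)
    if spec.family == "sqrt":
        return np.sqrt(x)
    if spec.family == "identity":
        return x
    if spec.family == "power":
        return (x ** spec.lmbda - 1.0) / spec.lmbda
    raise ValueError(f"unknown transform family {spec.family!r}")


def select_transform(values, snap_radius: float = 0.25,
                     grid=(-2.0, 2.0, 401)) -> TransformSpec:
    """Box-Cox profile-likelihood selection of a power transformation.

    Scans lambda over a uniform grid, takes the maximising lambda-hat,
    and snaps it to the nearest of {0 -> log10, 0.5 -> sqrt,
    1 -> identity} when within ``snap_radius``; otherwise the raw power
    transform with lambda-hat is kept.
    """
    x = np.asarray(values, dtype=float)
    n_bad = int(np.sum(~(x > 0)))
    if n_bad:
        raise ValueError(f"Box-Cox requires positive data; {n_bad} value(s) are <= 0")
    if len(x) < 10:
        raise ValueError("need at least 10 observations to select a transform")
    lo, hi, n = grid
    lambdas = np.linspace(lo, hi, int(n))
    llf = np.array([stats.boxcox_llf(l, x) for l in lambdas])
    lmbda = float(lambdas[int(np.argmax(llf))])
    anchors = {0.0: "log10", 0.5: "sqrt", 1.0: "identity"}
    nearest = min(anchors, key=lambda a: abs(lmbda - a))
    if abs(lmbda - nearest) <= snap_radius:
        family = anchors[nearest]
    else:
        family = "power"
    return TransformSpec(family=family, lmbda=lmbda, snap_radius=snap_radius,
                         grid=(lo, hi, int(n)))


@dataclass
class SrtModelResult:
    """Fitted mixed-model summary for one stratum."""

    stratum: str
    transform: TransformSpec
    b: float  # congruency fixed effect, transformed scale (incongruent - congruent)
    se: float
    t: float
    p: float
    df_method: str
    llf_full: float
    llf_null: float
    chi2: float
    lrt_df: int
    lrt_p: float
    evidence_ratio: float  # exp(delta logLik); exp(chi2 / 2)
    n_obs: int
    n_pairs: int
    random_structure: str  # which rung of the simplification ladder converged
    converged: bool
    descriptives: dict = field(default_factory=dict)  # raw-scale ms, per class
    vc_estimates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "transform"}
        d["transform"] = {"family": self.transform.family, "lambda": self.transform.lmbda}
        return d


#: simplification ladder mirrored in output metadata.  The saturated
#: model has crossed random intercepts (pair, subject nested in pair via
#: unique subject codes, and trial shared across pairs), expressed in
#: statsmodels' single-group variance-component form; the fallbacks drop
#: the trial term, then the pair level.  Each entry is
#: (name, groups, re_formula, vc_formula).
_LADDER = [
    ("pair/subject + trial", "_one", "0",
     {"pair": "0 + C(pair)", "subject": "0 + C(subject)", "trial": "0 + C(trial)"}),
    ("pair/subject", "pair", "1", {"subject": "0 + C(subject)"}),
    ("subject", "subject", "1", None),
]


def _fit_ok(res) -> bool:
    return bool(res.converged) and np.isfinite(res.llf) and np.all(np.isfinite(res.bse_fe))


def _fit_one(formula: str, df: pd.DataFrame, rung):
    import statsmodels.formula.api as smf

    name, groups, re_formula, vc = rung
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, groups=groups, re_formula=re_formula,
                            vc_formula=vc, data=df)
        res = None
        for method in ("lbfgs", "powell"):
            try:
                res = model.fit(reml=False, method=method)
            except Exception:  # noqa: BLE001 - optimizer/linalg failures
                continue
            if _fit_ok(res):
                break
    if res is None:
        raise RuntimeError(f"{name}: optimizer failed")
    return res


def _fit_mixedlm(formula: str, df: pd.DataFrame):
    """Fit through the convergence ladder; returns (result, structure_name)."""
    last_err = None
    for rung in _LADDER:
        try:
            res = _fit_one(formula, df, rung)
            if _fit_ok(res):
                return res, rung[0]
            last_err = RuntimeError(f"{rung[0]}: did not converge")
        except Exception as exc:  # noqa: BLE001 - statsmodels raises many types
            last_err = exc
    raise RuntimeError(f"all random-effect structures failed: {last_err}")


def fit_srt_model(table: pd.DataFrame, stratum: str = "all",
                  transform: str | TransformSpec = "auto",
                  anchor_structure: str | None = None) -> SrtModelResult:
    """Fit the congruency model on a screened analysis table.

    Parameters
    ----------
    table : DataFrame
        Columns ``pair, subject, trial, congruency, overt_attention,
        srt_ms`` (+ optional ``exclusion``, dropped unless 'none').
    stratum : {'all', 'overt', 'not_overt'}
        Optional restriction on responder overt attention.
    transform : 'auto' | 'sqrt' | 'log10' | 'identity' | TransformSpec
        'auto' runs Box-Cox selection on the stratum's SRTs.
    anchor_structure : str, optional
        Force a specific rung of the random-structure ladder (used to
        fit null and full models on the same structure).
    """
    df = table.copy()
    if "exclusion" in df.columns:
        df = df[df["exclusion"] == "none"]
    df = df[df["congruency"].isin(["congruent", "incongruent"])]
    df = df[np.isfinite(df["srt_ms"].astype(float))]
    if stratum == "overt":
        df = df[df["overt_attention"].astype(bool)]
    elif stratum == "not_overt":
        df = df[~df["overt_attention"].astype(bool)]
    elif stratum != "all":
        raise ValueError("stratum must be all|overt|not_overt")
    df = df.reset_index(drop=True)

    if df["congruency"].nunique() < 2:
        raise InsufficientDataError(f"stratum {stratum!r} has < 2 congruency levels")
    if df["pair"].nunique() < 2:
        raise InsufficientDataError(f"stratum {stratum!r} has < 2 pairs")

    if isinstance(transform, TransformSpec):
        tspec = transform
    elif transform == "auto":
        if len(df) < 10:
            raise InsufficientDataError(
                f"stratum {stratum!r} has {len(df)} rows; too few for Box-Cox selection")
        tspec = select_transform(df["srt_ms"].to_numpy(dtype=float))
    else:
        tspec = TransformSpec(family=transform, lmbda={"log10": 0.0, "sqrt": 0.5,
                                                       "identity": 1.0}[transform])
    df["y"] = apply_transform(df["srt_ms"].to_numpy(dtype=float), tspec)
    # code congruency so that b > 0 means incongruent slower
    df["congruency"] = pd.Categorical(df["congruency"],
                                      categories=["congruent", "incongruent"])
    df["_one"] = 1

    if float(np.var(df["y"].to_numpy())) < 1e-14:
        # degenerate: identical responses everywhere; no effect estimable
        return _degenerate_result(df, stratum, tspec)

    full, structure = _fit_full_null(df, "y ~ congruency", anchor_structure)
    null, _ = _fit_full_null(df, "y ~ 1", structure)

    b = float(full.fe_params.iloc[1])
    se = float(full.bse_fe.iloc[1])
    tval = b / se
    # Wald t with a residual-df approximation (observations minus fixed
    # effects minus random-intercept levels); statsmodels has no
    # Satterthwaite df, and the flag records that
    n_levels = df["pair"].nunique() + df["subject"].nunique()
    dof = max(len(df) - 2 - n_levels, 2)
    p = float(2 * stats.t.sf(abs(tval), dof))
    chi2, lrt_df, lrt_p, ev = likelihood_ratio_test(null, full)

    desc = {}
    for cls, g in df.groupby("congruency", observed=True):
        desc[str(cls)] = {"mean_ms": float(g["srt_ms"].mean()),
                          "sd_ms": float(g["srt_ms"].std(ddof=1)),
                          "n": int(len(g))}
    vc = {}
    try:
        names = list(full.model.exog_vc.names)
        vc = {n: float(v) for n, v in zip(names, np.atleast_1d(full.vcomp))}
    except Exception:
        vc = {f"vc{i}": float(v) for i, v in enumerate(np.atleast_1d(full.vcomp))}
    vc["residual"] = float(full.scale)
    if structure != "pair/subject + trial":
        try:
            vc["group_intercept"] = float(np.asarray(full.cov_re)[0, 0])
        except Exception:
            pass
    return SrtModelResult(
        stratum=stratum, transform=tspec, b=b, se=se, t=tval, p=p,
        df_method=f"wald-t(resid-df={dof})",
        llf_full=float(full.llf), llf_null=float(null.llf),
        chi2=chi2, lrt_df=lrt_df, lrt_p=lrt_p, evidence_ratio=ev,
        n_obs=int(len(df)), n_pairs=int(df["pair"].nunique()),
        random_structure=structure, converged=bool(full.converged),
        descriptives=desc, vc_estimates=vc,
    )


def _fit_full_null(df, formula, anchor_structure):
    if anchor_structure is None:
        return _fit_mixedlm(formula, df)
    for rung in _LADDER:
        if rung[0] == anchor_structure:
            return _fit_one(formula, df, rung), rung[0]
    raise ValueError(f"unknown random structure {anchor_structure!r}")


def _degenerate_result(df, stratum, tspec) -> "SrtModelResult":
    desc = {str(cls): {"mean_ms": float(g["srt_ms"].mean()),
                       "sd_ms": float(g["srt_ms"].std(ddof=1)),
                       "n": int(len(g))}
            for cls, g in df.groupby("congruency", observed=True)}
    return SrtModelResult(
        stratum=stratum, transform=tspec, b=0.0, se=0.0, t=0.0, p=1.0,
        df_method="degenerate(zero-variance)", llf_full=np.nan, llf_null=np.nan,
        chi2=0.0, lrt_df=1, lrt_p=1.0, evidence_ratio=1.0,
        n_obs=int(len(df)), n_pairs=int(df["pair"].nunique()),
        random_structure="none", converged=True, descriptives=desc)


def likelihood_ratio_test(null_fit, full_fit) -> tuple[float, int, float, float]:
    """Chi-square LRT of nested ML fits on identical rows.

    Returns ``(chi2, df, p, evidence_ratio)`` where
    ``chi2 = 2 * (logLik_full - logLik_null)``, ``df`` is the fixed-
    parameter difference, and ``evidence_ratio = exp(delta logLik)`` is
    the likelihood ratio itself.
    """
    if int(null_fit.nobs) != int(full_fit.nobs):
        raise ValueError("models were fitted on different row counts; refusing LRT")
    delta = float(full_fit.llf - null_fit.llf)
    chi2 = 2.0 * delta
    df = int(len(full_fit.fe_params) - len(null_fit.fe_params))
    if df == 0:
        p = 1.0 if chi2 <= 0 else float(stats.chi2.sf(chi2, 1))
    else:
        p = float(stats.chi2.sf(max(chi2, 0.0), df)) if chi2 > 0 else 1.0
    return chi2, df, p, float(np.exp(delta))
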