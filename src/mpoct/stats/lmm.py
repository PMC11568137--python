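"""Random-intercept linear mixed models for the structure/function table.

Thin, opinionated wrapper around ``statsmodels`` MixedLM: fixed terms are
named biomarkers of the analysis table, the random part is always a
per-patient intercept, and fits expose exactly the quantities the
downstream analysis needs (Wald CIs, variance components, log-likelihood,
BIC with k = fixed effects + 2 variance parameters).

Covariates are standardized internally before optimization — the raw
um/nl/deg scales are badly conditioned for MixedLM — and every reported
quantity is transformed back to the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

#: canonical main-effect order; also the design-column naming
MAIN_TERMS = ("device", "run", "age", "eccentricity", "onl", "ez",
              "drusen", "hrf", "sdd")

#: candidate two-way interactions considered by the global model
ALLOWED_INTERACTIONS = (
    ("ez", "onl"),
    ("sdd", "drusen"),
    ("eccentricity", "drusen"),
    ("eccentricity", "sdd"),
    ("eccentricity", "ez"),
    ("eccentricity", "onl"),
    ("onl", "drusen"),
)

_TERM_SOURCE = {
    "device": lambda t: (t["device"] == "MAIA").astype(float),
    "run": lambda t: (t["run"] == 2).astype(float),
    "age": lambda t: t["age"].astype(float),
    "eccentricity": lambda t: t["eccentricity_deg"].astype(float),
    "onl": lambda t: t["onl_um"].astype(float),
    "ez": lambda t: t["ez_um"].astype(float),
    "drusen": lambda t: t["drusen_nl"].astype(float),
    "hrf": lambda t: t["hrf_nl"].astype(float),
    "sdd": lambda t: t["sdd_nl"].astype(float),
}


class SingularDesignError(ValueError):
    """Raised when the fixed-effect design is rank deficient."""


class ModelSpecError(ValueError):
    pass


def _canon_interaction(pair) -> tuple[str, str]:
    pair = tuple(pair)
    if pair in ALLOWED_INTERACTIONS:
        return pair
    if pair[::-1] in ALLOWED_INTERACTIONS:
        return pair[::-1]
    raise ModelSpecError(f"interaction {pair} not among the candidate set")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model.

    ``allow_nonmarginal`` permits an interaction without its eccentricity
    main effect, matching the published final-model parameterization in
    which eccentricity enters only through the thickness interactions.
    """

    mains: tuple[str, ...] = MAIN_TERMS
    interactions: tuple[tuple[str, str], ...] = ALLOWED_INTERACTIONS
    reml: bool = False
    allow_nonmarginal: bool = False

    def __post_init__(self) -> None:
        mains = tuple(m for m in MAIN_TERMS if m in self.mains)
        if len(mains) != len(self.mains):
            unknown = set(self.mains) - set(MAIN_TERMS)
            raise ModelSpecError(f"unknown main terms: {sorted(unknown)}")
        inters = tuple(_canon_interaction(p) for p in self.interactions)
        inters = tuple(p for p in ALLOWED_INTERACTIONS if p in inters)
        object.__setattr__(self, "mains", mains)
        object.__setattr__(self, "interactions", inters)
        if not self.allow_nonmarginal:
            for a, b in inters:
                if a not in mains or b not in mains:
                    raise ModelSpecError(
                        f"interaction {a}x{b} requires both main effects")

    @classmethod
    def global_model(cls, reml: bool = False) -> "ModelSpec":
        return cls(mains=MAIN_TERMS, interactions=ALLOWED_INTERACTIONS, reml=reml)

    @classmethod
    def final_model(cls, reml: bool = True,
                    eccentricity_main: bool = False) -> "ModelSpec":
        """The selected structure: device, drusen, HRF, ONL, EZ and the two
        thickness-by-eccentricity interactions."""
        mains = ["device", "onl", "ez", "drusen", "hrf"]
        if eccentricity_main:
            mains.insert(1, "eccentricity")
        return cls(mains=tuple(m for m in MAIN_TERMS if m in mains),
                   interactions=(("eccentricity", "ez"), ("eccentricity", "onl")),
                   reml=reml, allow_nonmarginal=not eccentricity_main)

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.mains + tuple(f"{a}:{b}" for a, b in self.interactions)

    def key(self) -> str:
        return "+".join(self.term_names) if self.term_names else "1"

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.mains) + len(self.interactions)


def design_matrix(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Fixed-effect design (with intercept) on the original scales."""
    cols = {"intercept": np.ones(len(table))}
    base = {m: _TERM_SOURCE[m](table) for m in MAIN_TERMS
            if m in spec.mains or any(m in p for p in spec.interactions)}
    for m in spec.mains:
        cols[m] = base[m]
    for a, b in spec.interactions:
        cols[f"{a}:{b}"] = base[a] * base[b]
    return pd.DataFrame(cols, index=table.index)


@dataclass
class ModelFit:
    """Everything reported about one fitted mixed model."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame          # columns: lower, upper
    pvalues: pd.Series
    cov_params: pd.DataFrame        # fixed effects only
    var_random: float
    var_resid: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    design: pd.DataFrame = field(repr=False)

    @property
    def k_params(self) -> int:
        return len(self.params) + 2

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.n_obs)

    def fixed_predictor(self) -> np.ndarray:
        return np.asarray(self.design) @ self.params.values

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "ci_lower": self.conf_int["lower"],
            "ci_upper": self.conf_int["upper"], "p": self.pvalues,
        })


def _prepare(table: pd.DataFrame, spec: ModelSpec):
    needed = ["pws_db", "patient_id"]
    t = table
    if "included" in t.columns:
        t = t[t["included"].astype(bool)]
    X = design_matrix(t, spec)
    mask = X.notna().all(axis=1) & t["pws_db"].notna()
    t = t[mask]
    X = X[mask]
    if t["patient_id"].nunique() < 2:
        raise ValueError("need records from >= 2 patients")
    return t, X


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a random-intercept LMM by ML or REML (per ``spec.reml``).

    Raises :class:`SingularDesignError` for constant covariates or a rank
    deficient design. Wald (large-sample z) confidence intervals.
    """
    t, X = _prepare(table, spec)
    Xv = np.asarray(X, dtype=float)
    sds = Xv[:, 1:].std(axis=0)
    if np.any(sds == 0):
        bad = [X.columns[i + 1] for i in np.flatnonzero(sds == 0)]
        raise SingularDesignError(f"constant covariate(s): {bad}")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise SingularDesignError("fixed-effect design is rank deficient")

    means = Xv[:, 1:].mean(axis=0)
    Z = Xv.copy()
    Z[:, 1:] = (Z[:, 1:] - means) / sds

    endog = np.asarray(t["pws_db"], dtype=float)
    groups = np.asarray(t["patient_id"])
    model = MixedLM(endog, Z, groups=groups)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for method in ("powell", "lbfgs", "cg", "bfgs"):
            try:
                cand = model.fit(reml=spec.reml, method=method, maxiter=500)
            except Exception:
                continue
            # some optimizers report success on degenerate solutions
            if not np.isfinite(cand.llf):
                continue
            if fit is None or (cand.converged and not fit.converged) or (
                    cand.converged == fit.converged and cand.llf > fit.llf + 1e-8):
                fit = cand
            if fit.converged:
                break
    if fit is None:
        raise RuntimeError("mixed-model optimization failed for all methods")

    # map standardized-scale estimates back to the original scale
    p = Z.shape[1]
    A = np.eye(p)
    for j in range(1, p):
        A[j, j] = 1.0 / sds[j - 1]
        A[0, j] = -means[j - 1] / sds[j - 1]
    beta_z = np.asarray(fit.fe_params)
    cov_z = np.asarray(fit.cov_params())[:p, :p]
    beta = A @ beta_z
    cov = A @ cov_z @ A.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    zcrit = norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * norm.sf(np.abs(zval))

    # the REML criterion includes log|X' V^-1 X|, so column standardization
    # shifts it by sum(log sd); report the raw-scale value
    llf = float(fit.llf) - (float(np.sum(np.log(sds))) if spec.reml else 0.0)

    names = list(X.columns)
    params = pd.Series(beta, index=names)
    return ModelFit(
        spec=spec,
        params=params,
        bse=pd.Series(se, index=names),
        conf_int=pd.DataFrame({"lower": beta - zcrit * se,
                               "upper": beta + zcrit * se}, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        var_random=float(np.asarray(fit.cov_re)[0, 0]),
        var_resid=float(fit.scale),
        llf=llf,
        n_obs=len(t),
        n_groups=int(pd.Series(groups).nunique()),
        converged=bool(fit.converged),
        design=X,
    )
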