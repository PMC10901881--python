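"""Linear mixed models for epoch-level reaction times.

The analysis model family predicts the epoch-level median RT from group
(active vs sham tACS), session (1-3, treatment coded, reference 1),
trial type (hpt vs lpt, reference hpt), epoch (numeric 1-4) and optional
covariates (age, MoCA), with a by-participant random intercept and a
by-participant random slope for epoch (``~ 1 + epoch | participant``).
Estimation is maximum likelihood throughout, so Akaike information
criteria are comparable across fixed-effect structures; the best model
is the minimum-AIC candidate, supplemented by likelihood-ratio tests for
nested pairs.

Coefficients are reported with Wald t-distribution confidence intervals
and p values (residual-style degrees of freedom: rows minus fixed
parameters), standardized betas obtained by refitting on a standardized
dataset (response and numeric predictors z-scored, categorical dummies
untouched), and Nakagawa-Schielzeth marginal/conditional R-squared.
Fitting itself is delegated to statsmodels' MixedLM.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

RESPONSE = "median_rt_ms"
GROUP_COL = "participant_id"

#: term -> formula fragment with the study's treatment coding
_TERM_FRAGMENTS = {
    "group": "C(group, Treatment('sham'))",
    "session": "C(session)",
    "trial_type": "C(trial_type, Treatment('hpt'))",
    "epoch": "epoch",
    "age": "age",
    "moca": "moca",
}
NUMERIC_TERMS = ("epoch", "age", "moca")

_RENAMES = [
    (re.compile(r"C\(group, Treatment\('sham'\)\)\[T\.active\]"), "group_active"),
    (re.compile(r"C\(session\)\[T\.(\d+)\]"), r"session\1"),
    (re.compile(r"C\(trial_type, Treatment\('hpt'\)\)\[T\.lpt\]"), "trial_type_lpt"),
    (re.compile(r"^Intercept$"), "intercept"),
]


class FitError(RuntimeError):
    """Raised when a mixed model cannot be fitted or did not converge."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a set of fixed-effect terms.

    ``terms`` uses the vocabulary group, session, trial_type, epoch, age,
    moca and ':'-joined interactions thereof (e.g. ``group:session``).
    Lower-order terms of every interaction are added automatically
    (marginality).  The random structure — intercept and epoch slope per
    participant — is fixed across the family.
    """

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        closed = self.with_marginality(self.terms)
        object.__setattr__(self, "terms", closed)
        for term in closed:
            for factor in term.split(":"):
                if factor not in _TERM_FRAGMENTS:
                    raise ValueError(f"unknown model term factor: {factor!r}")

    @staticmethod
    def with_marginality(terms: tuple[str, ...]) -> tuple[str, ...]:
        out: list[str] = []

        def add(t: str) -> None:
            factors = t.split(":")
            if len(factors) > 1:
                for f in factors:
                    add(f)
            if t not in out:
                out.append(t)

        for t in terms:
            add(t)
        return tuple(out)

    @property
    def formula(self) -> str:
        rhs = " + ".join(
            ":".join(_TERM_FRAGMENTS[f] for f in term.split(":"))
            for term in self.terms
        )
        return f"{RESPONSE} ~ {rhs}"

    @property
    def variables(self) -> set[str]:
        return {f for term in self.terms for f in term.split(":")}

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


#: the study's selected model: RT ~ group*session + trial_type + epoch*session
SELECTED_MODEL = ModelSpec(
    "group*session + trial_type + epoch*session",
    ("group:session", "trial_type", "epoch:session"),
)


def default_model_family() -> list[ModelSpec]:
    """The candidate family searched by the study's selection procedure."""
    return [
        ModelSpec("main effects", ("group", "session", "trial_type", "epoch")),
        ModelSpec(
            "group*session + trial_type + epoch",
            ("group:session", "trial_type", "epoch"),
        ),
        SELECTED_MODEL,
        ModelSpec(
            "group*session + trial_type*session + epoch*session",
            ("group:session", "trial_type:session", "epoch:session"),
        ),
        ModelSpec(
            "group*session*trial_type + epoch*session",
            ("group:session:trial_type", "epoch:session"),
        ),
    ]


@dataclass(frozen=True)
class CoefficientEstimate:
    name: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    n: int
    std_beta: float | None = None
    std_ci_low: float | None = None
    std_ci_high: float | None = None


@dataclass
class ModelFit:
    """A fitted mixed model in reporting form."""

    spec: ModelSpec
    coefficients: dict[str, CoefficientEstimate]
    aic: float
    loglik: float
    n_params: int
    n_obs: int
    n_groups: int
    converged: bool
    marginal_r2: float
    conditional_r2: float
    cov_re: np.ndarray
    residual_var: float
    fe_cov: pd.DataFrame = field(repr=False, default=None)

    def __getitem__(self, name: str) -> CoefficientEstimate:
        return self.coefficients[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.coefficients.values()])

    def to_table(self) -> str:
        """Publication-style text table (Predictor / N / Beta / CI / p)."""
        lines = [
            f"Model: {self.spec.formula}",
            f"{'Predictor':<28}{'N':>5}{'Beta':>9}{'95% CI':>18}"
            f"{'Std.Beta':>10}{'Std.CI':>18}{'p':>8}",
        ]
        for c in self.coefficients.values():
            ci = f"[{c.ci_low:.2f}, {c.ci_high:.2f}]"
            if c.std_beta is None:
                sb, sci = "", ""
            else:
                sb = f"{c.std_beta:.2f}"
                sci = f"[{c.std_ci_low:.2f}, {c.std_ci_high:.2f}]"
            p = "<0.001" if c.p < 0.001 else f"{c.p:.3f}"
            lines.append(
                f"{c.name:<28}{c.n:>5}{c.beta:>9.2f}{ci:>18}{sb:>10}{sci:>18}{p:>8}"
            )
        lines.append(
            f"AIC (ML) = {self.aic:.1f}; logLik = {self.loglik:.1f}; "
            f"conditional R2 = {self.conditional_r2:.2f}; "
            f"marginal R2 = {self.marginal_r2:.2f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "formula": self.spec.formula,
            "terms": list(self.spec.terms),
            "coefficients": {k: v.__dict__ for k, v in self.coefficients.items()},
            "aic": self.aic,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
        }


def _rename(name: str) -> str:
    parts = name.split(":")
    out = []
    for part in parts:
        for pat, repl in _RENAMES:
            part = pat.sub(repl, part)
        out.append(part)
    return ":".join(out)


def _prepare(aggregates: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = {RESPONSE, GROUP_COL} | spec.variables
    missing = cols - set(aggregates.columns)
    if missing:
        raise ValueError(f"modelling table lacks columns: {sorted(missing)}")
    df = aggregates.dropna(subset=[RESPONSE]).copy()
    n_dropped = len(aggregates) - len(df)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with missing response", stacklevel=3)
    if df[GROUP_COL].nunique() < 2:
        raise FitError("random effects unidentifiable with fewer than 2 participants")
    return df


def _raw_fit(df: pd.DataFrame, spec: ModelSpec):
    """Fit by ML, retrying optimizers until convergence."""
    model = smf.mixedlm(spec.formula, df, groups=df[GROUP_COL], re_formula="~epoch")
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise FitError(
            f"rank-deficient fixed-effect matrix (rank {rank} < "
            f"{model.exog.shape[1]} columns) for {spec.formula}"
        )
    last_exc: Exception | None = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                res = model.fit(reml=False, method=method, maxiter=2000)
            if res.converged:
                return res
        except (ConvergenceWarning, np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    # accept a non-warning fit even if a singular boundary was hit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, maxiter=2000)
    if res.converged:
        return res
    raise FitError(f"mixed model did not converge for {spec.formula}: {last_exc}")


def _n_params(res) -> int:
    model = res.model
    k_re = model.k_re * (model.k_re + 1) // 2
    return len(res.fe_params) + k_re + model.k_vc + 1  # +1 residual variance


def _aic(res) -> float:
    return float(-2.0 * res.llf + 2.0 * _n_params(res))


def r_squared(res) -> tuple[float, float]:
    """Nakagawa-Schielzeth (marginal, conditional) R-squared.

    marginal = var(fixed) / (var(fixed) + var(random) + var(residual));
    conditional adds the random-effect variance to the numerator.  The
    random-effect variance averages z' S z over the design rows, with S
    the estimated random-effect covariance (intercept + epoch slope).
    """
    fixed = res.model.exog @ res.fe_params
    var_f = float(np.var(fixed))
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    z = res.model.exog_re
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
    var_e = float(res.scale)
    total = var_f + var_r + var_e
    return var_f / total, (var_f + var_r) / total


def standardized_refit(
    aggregates: pd.DataFrame, spec: ModelSpec
) -> dict[str, tuple[float, float, float]]:
    """Refit on the standardized dataset; return std betas with CIs.

    The response and every numeric predictor are centred and scaled to
    unit SD; categorical predictors stay untouched, so their std betas
    are in response-SD units.
    """
    df = _prepare(aggregates, spec)
    for col in (RESPONSE,) + tuple(v for v in NUMERIC_TERMS if v in spec.variables):
        sd = df[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize zero-variance column {col!r}")
        df[col] = (df[col] - df[col].mean()) / sd
    res = _raw_fit(df, spec)
    df_resid = len(df) - len(res.fe_params)
    tcrit = sps.t.ppf(0.975, df_resid)
    out = {}
    for raw_name, beta in res.fe_params.items():
        se = res.bse_fe[raw_name]
        out[_rename(raw_name)] = (
            float(beta),
            float(beta - tcrit * se),
            float(beta + tcrit * se),
        )
    return out


def fit_model(
    aggregates: pd.DataFrame, spec: ModelSpec, *, standardize: bool = True
) -> ModelFit:
    """Fit one candidate by ML and assemble the full report."""
    df = _prepare(aggregates, spec)
    res = _raw_fit(df, spec)
    n_obs = len(df)
    p_fixed = len(res.fe_params)
    df_resid = n_obs - p_fixed
    tcrit = sps.t.ppf(0.975, df_resid)

    std = standardized_refit(aggregates, spec) if standardize else {}

    exog = res.model.exog
    coefficients: dict[str, CoefficientEstimate] = {}
    for j, (raw_name, beta) in enumerate(res.fe_params.items()):
        se = float(res.bse_fe[raw_name])
        tval = beta / se
        name = _rename(raw_name)
        sb = std.get(name)
        coefficients[name] = CoefficientEstimate(
            name=name,
            beta=float(beta),
            se=se,
            ci_low=float(beta - tcrit * se),
            ci_high=float(beta + tcrit * se),
            t=float(tval),
            df=df_resid,
            p=float(2.0 * sps.t.sf(abs(tval), df_resid)),
            n=int(np.sum(exog[:, j] != 0)),
            std_beta=None if sb is None else sb[0],
            std_ci_low=None if sb is None else sb[1],
            std_ci_high=None if sb is None else sb[2],
        )

    marg, cond = r_squared(res)
    fe_names = [_rename(n) for n in res.fe_params.index]
    fe_cov = pd.DataFrame(
        np.asarray(res.cov_params())[: p_fixed, : p_fixed],
        index=fe_names,
        columns=fe_names,
    )
    return ModelFit(
        spec=spec,
        coefficients=coefficients,
        aic=_aic(res),
        loglik=float(res.llf),
        n_params=_n_params(res),
        n_obs=n_obs,
        n_groups=int(res.model.n_groups),
        converged=bool(res.converged),
        marginal_r2=marg,
        conditional_r2=cond,
        cov_re=np.atleast_2d(np.asarray(res.cov_re)),
        residual_var=float(res.scale),
        fe_cov=fe_cov,
    )


@dataclass
class LikelihoodRatioTest:
    smaller: str
    larger: str
    statistic: float
    df: int
    p: float


@dataclass
class ModelComparison:
    """Result of the minimum-AIC model search."""

    fits: list[ModelFit]
    lr_tests: list[LikelihoodRatioTest]
    selected: ModelFit

    def aic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.spec.name for f in self.fits],
                "n_params": [f.n_params for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
            }
        ).sort_values("aic", ignore_index=True)


def compare_models(
    aggregates: pd.DataFrame, specs: list[ModelSpec]
) -> ModelComparison:
    """Fit all candidates on identical rows; select by minimum AIC.

    Likelihood-ratio chi-squared tests are reported for every nested
    pair.  Ties in AIC break by fewer parameters, then input order.
    Candidates are fitted on the intersection of complete rows across
    all specs; differing row subsets are a hard error by construction.
    """
    if len(specs) < 2:
        raise ValueError("need at least two candidate models")
    all_vars = {v for s in specs for v in s.variables}
    rows = aggregates.dropna(subset=[RESPONSE] + sorted(all_vars & set(aggregates.columns)))
    fits = [fit_model(rows, spec, standardize=False) for spec in specs]
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("candidates were fitted on differing row subsets")

    lr_tests = []
    for i, small in enumerate(fits):
        for j, large in enumerate(fits):
            if i == j or not small.spec.is_nested_in(large.spec):
                continue
            if set(small.spec.terms) == set(large.spec.terms):
                continue
            stat = max(0.0, 2.0 * (large.loglik - small.loglik))
            ddf = large.n_params - small.n_params
            lr_tests.append(
                LikelihoodRatioTest(
                    smaller=small.spec.name,
                    larger=large.spec.name,
                    statistic=stat,
                    df=ddf,
                    p=float(sps.chi2.sf(stat, ddf)) if ddf > 0 else np.nan,
                )
            )

    selected = min(enumerate(fits), key=lambda kv: (kv[1].aic, kv[1].n_params, kv[0]))[1]
    return ModelComparison(fits=fits, lr_tests=lr_tests, selected=selected)
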