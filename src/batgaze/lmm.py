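"""Linear mixed-effects models of inter-pulse intervals.

Both published model structures are linear mixed models with *nested
random intercepts* and a small fixed-effects design:

* approach model — post-IPI ~ condition + calls-to-turn + interaction,
  random intercepts for bat / bat:condition / bat:condition:day /
  bat:condition:day:trial;
* days model — post-IPI ~ condition + day-number + interaction, same
  nesting.

Condition enters the fixed part as a *numeric* code (the single printed
"Condition" coefficient implies numeric coding); both one-based
{Straight=1, Right=2, Left=3} and zero-based {0, 1, 2} codings are
supported, and :func:`per_condition_slopes` cross-checks whichever coding
is chosen against derived per-condition slopes.

The solver is a profiled restricted-maximum-likelihood (REML) estimator
specialised to nested random intercepts.  Because every random effect is
an intercept over an indicator column, the marginal covariance is
``sigma^2 (I + Z Gamma Z')`` and the Woodbury identity reduces each
likelihood evaluation to one sparse factorization of the small matrix
``Gamma^{-1} + Z'Z`` — which makes fitting at tens of thousands of rows
take seconds rather than minutes.  The general-purpose ``statsmodels``
``MixedLM`` fits the identical model and serves as an independent
cross-check on small data in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .geometry import Condition

__all__ = [
    "NestedMixedLM", "LMMResult", "IPIApproachModel", "IPIDaysModel",
    "per_condition_slopes", "simulate_ipi_dataset",
    "CONDITION_CODES_ONE_BASED", "CONDITION_CODES_ZERO_BASED",
]

CONDITION_CODES_ONE_BASED = {"STRAIGHT": 1.0, "RIGHT_TURN": 2.0, "LEFT_TURN": 3.0}
CONDITION_CODES_ZERO_BASED = {"STRAIGHT": 0.0, "RIGHT_TURN": 1.0, "LEFT_TURN": 2.0}


# ---------------------------------------------------------------------------
# Generic nested-random-intercept solver
# ---------------------------------------------------------------------------

class NestedMixedLM:
    """Linear mixed model with nested random intercepts.

    Parameters
    ----------
    endog : (n,) response vector.
    exog : (n, p) fixed-effects design matrix (include the intercept).
    groups : list of (n,) label arrays, coarsest first; level ``l`` is
        nested by keying each label on all labels up to ``l`` (so passing
        ``[bat, condition, day, trial]`` yields bat, bat:condition,
        bat:condition:day and bat:condition:day:trial intercepts).
    exog_names, group_names : optional labels for reporting.
    """

    def __init__(self, endog, exog, groups, exog_names=None, group_names=None):
        self.y = np.asarray(endog, float)
        self.X = np.atleast_2d(np.asarray(exog, float))
        if self.X.shape[0] != len(self.y):
            raise ValueError("endog/exog length mismatch")
        self.n, self.p = self.X.shape
        self.exog_names = list(exog_names) if exog_names is not None else \
            [f"x{j}" for j in range(self.p)]
        self.group_names = list(group_names) if group_names is not None else \
            [f"level{l}" for l in range(len(groups))]
        self._build_z(groups)

    def _build_z(self, groups):
        cols = []
        self.level_sizes = []
        combined = None
        for g in groups:
            g = np.asarray(g)
            if len(g) != self.n:
                raise ValueError("group label length mismatch")
            key = g.astype(str) if combined is None else \
                np.char.add(np.char.add(combined, "/"), g.astype(str))
            combined = key
            _, codes = np.unique(key, return_inverse=True)
            cols.append(codes)
            self.level_sizes.append(int(codes.max()) + 1)
        data, rows, colidx = [], [], []
        offset = 0
        for codes, k in zip(cols, self.level_sizes):
            rows.append(np.arange(self.n))
            colidx.append(codes + offset)
            data.append(np.ones(self.n))
            offset += k
        self.k_total = offset
        self.Z = sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(colidx))),
            shape=(self.n, self.k_total))
        self.ZtZ = (self.Z.T @ self.Z).tocsc()
        A = np.column_stack([self.X, self.y])
        self.ZtA = self.Z.T @ A
        self.AtA = A.T @ A
        self._col_level = np.concatenate([
            np.full(k, l) for l, k in enumerate(self.level_sizes)])

    def _profiled(self, log_gamma, reml=True):
        """Return (-2 log-lik up to a constant, beta, sigma2, XtWiX_inv)."""
        gamma = np.exp(np.clip(log_gamma, -30.0, 30.0))
        ginv = 1.0 / gamma[self._col_level]
        M = (self.ZtZ + sparse.diags(ginv)).tocsc()
        lu = splu(M)
        logdet_M = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        logdet_W = logdet_M + float(np.sum(np.array(self.level_sizes) * np.log(gamma)))
        MinvZtA = lu.solve(self.ZtA)
        Q = self.AtA - self.ZtA.T @ MinvZtA        # A' W^-1 A
        XtWX = Q[:self.p, :self.p]
        XtWy = Q[:self.p, self.p]
        ytWy = Q[self.p, self.p]
        try:
            cf = np.linalg.cholesky(XtWX)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(float(ytWy - beta @ XtWy), 1e-12)
        if reml:
            dof = self.n - self.p
            sigma2 = rss / dof
            crit = dof * np.log(sigma2) + logdet_W + 2.0 * np.sum(np.log(np.diag(cf)))
        else:
            sigma2 = rss / self.n
            crit = self.n * np.log(sigma2) + logdet_W
        return float(crit), beta, float(sigma2), XtWX

    def fit(self, reml: bool = True, start_log_gamma=None) -> "LMMResult":
        L = len(self.level_sizes)
        x0 = np.full(L, np.log(0.05)) if start_log_gamma is None \
            else np.asarray(start_log_gamma, float)
        res = optimize.minimize(
            lambda lg: self._profiled(lg, reml)[0], x0, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 2000})
        crit, beta, sigma2, XtWX = self._profiled(res.x, reml)
        if beta is None:
            raise RuntimeError("mixed-model fit failed to converge: " + str(res))
        gamma = np.exp(res.x)
        vc = gamma * sigma2
        singular = gamma < 1e-8
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        bse = np.sqrt(np.diag(cov_beta))
        z = beta / bse
        pvals = 2.0 * norm.sf(np.abs(z))
        ci_lo = beta - 1.96 * bse
        ci_hi = beta + 1.96 * bse
        return LMMResult(
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            conf_int_low=pd.Series(ci_lo, index=self.exog_names),
            conf_int_high=pd.Series(ci_hi, index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names,
                                    columns=self.exog_names),
            variance_components=pd.Series(
                np.concatenate([[sigma2], vc]),
                index=["residual"] + self.group_names),
            singular_components=pd.Series(
                np.concatenate([[False], singular]),
                index=["residual"] + self.group_names),
            n_observations=self.n,
            converged=bool(res.success),
            criterion=float(crit),
            reml=reml,
            model=self,
        )


@dataclass
class LMMResult:
    """Fitted mixed-model results: estimates, uncertainty, variances."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int_low: pd.Series
    conf_int_high: pd.Series
    cov_params: pd.DataFrame
    variance_components: pd.Series
    singular_components: pd.Series
    n_observations: int
    converged: bool
    criterion: float
    reml: bool
    model: NestedMixedLM | None = None
    condition_codes: dict | None = None
    covariate_name: str | None = None

    def summary(self) -> str:
        lines = ["Linear mixed-effects model (nested random intercepts, "
                 + ("REML" if self.reml else "ML") + ")",
                 f"Observations: {self.n_observations}", "",
                 f"{'Predictor':<28}{'Estimate':>10}{'CI':>20}{'p':>10}"]
        for name in self.params.index:
            ci = f"{self.conf_int_low[name]:.2f} - {self.conf_int_high[name]:.2f}"
            lines.append(f"{name:<28}{self.params[name]:>10.2f}{ci:>20}"
                         f"{self.pvalues[name]:>10.3g}")
        lines += ["", f"{'Random effects':<28}{'Variance':>10}"]
        for name, v in self.variance_components.items():
            flag = "  (singular, reported 0)" if self.singular_components[name] else ""
            shown = 0.0 if self.singular_components[name] else v
            lines.append(f"{name:<28}{shown:>10.2f}{flag}")
        return "\n".join(lines)

    def derived_slopes(self, sign: float = 1.0) -> pd.Series:
        """Per-condition slope of post-IPI vs the covariate.

        ``slope(c) = covariate + interaction * code(c)``, multiplied by
        ``sign`` (use -1 to express a calls-*to*-turn coefficient as change
        per call *while approaching*).
        """
        if self.condition_codes is None:
            raise ValueError("result carries no condition coding")
        cov = self.params[self.covariate_name]
        inter = self.params[f"condition:{self.covariate_name}"]
        return pd.Series({c: sign * (cov + inter * code)
                          for c, code in self.condition_codes.items()})

    def derived_slope_se(self) -> pd.Series:
        """Standard error of each derived per-condition slope."""
        cn, it = self.covariate_name, f"condition:{self.covariate_name}"
        v_c = self.cov_params.loc[cn, cn]
        v_i = self.cov_params.loc[it, it]
        cv = self.cov_params.loc[cn, it]
        return pd.Series({c: float(np.sqrt(v_c + code ** 2 * v_i + 2 * code * cv))
                          for c, code in self.condition_codes.items()})


# ---------------------------------------------------------------------------
# The two published model structures
# ---------------------------------------------------------------------------

def _prep(data: pd.DataFrame, covariate: str, coding: dict) -> tuple:
    cond = data["condition"].map(lambda c: c.value if isinstance(c, Condition) else str(c))
    codes = cond.map(coding).to_numpy(float)
    if np.any(~np.isfinite(codes)):
        raise ValueError("condition column contains values outside the coding")
    cov = data[covariate].to_numpy(float)
    X = np.column_stack([np.ones(len(data)), codes, cov, codes * cov])
    names = ["intercept", "condition", covariate, f"condition:{covariate}"]
    groups = [data["bat"].to_numpy(), cond.to_numpy(),
              data["day"].to_numpy(), data["trial"].to_numpy()]
    gnames = ["bat", "condition", "day", "trial"]
    return X, names, groups, gnames


class _IPIModelBase:
    covariate: str = ""
    default_coding: dict = {}

    def __init__(self, data: pd.DataFrame, condition_coding: dict | str | None = None):
        """``data`` rows are single calls from successful flights emitted
        before the turn, with columns ``post_ipi_ms``, ``condition``,
        the covariate, ``bat``, ``day``, ``trial``."""
        if condition_coding in (None, "default"):
            coding = dict(self.default_coding)
        elif condition_coding == "one_based":
            coding = dict(CONDITION_CODES_ONE_BASED)
        elif condition_coding == "zero_based":
            coding = dict(CONDITION_CODES_ZERO_BASED)
        else:
            coding = dict(condition_coding)
        self.condition_coding = coding
        self.data = data
        X, names, groups, gnames = _prep(data, self.covariate, coding)
        self._lmm = NestedMixedLM(data["post_ipi_ms"].to_numpy(float), X,
                                  groups, exog_names=names, group_names=gnames)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw):
        return cls(data, **kw)

    def fit(self, reml: bool = True) -> LMMResult:
        res = self._lmm.fit(reml=reml)
        res.condition_codes = self.condition_coding
        res.covariate_name = self.covariate
        return res


class IPIApproachModel(_IPIModelBase):
    """Post-IPI as the bat approaches the turn.

    Fixed effects: condition (numeric code, one-based by default),
    number of calls remaining before the turn, and their interaction;
    nested random intercepts bat / condition / day / trial.  The derived
    per-condition slope *while approaching* is minus (covariate +
    interaction x code), since calls-to-turn counts down.
    """

    covariate = "calls_to_turn"
    default_coding = CONDITION_CODES_ONE_BASED


class IPIDaysModel(_IPIModelBase):
    """Post-IPI over consecutive experimental days within each condition.

    Fixed effects: condition (zero-based numeric code by default), day
    number, and their interaction; same nested random intercepts.
    """

    covariate = "day_number"
    default_coding = CONDITION_CODES_ZERO_BASED


def per_condition_slopes(covariate_coef: float, interaction_coef: float,
                         coding: dict, sign: float = 1.0) -> pd.Series:
    """Internal-consistency cross-check utility.

    Reconstructs the three per-condition slopes implied by a fitted (or
    published) covariate coefficient and condition-interaction coefficient
    under a numeric condition coding: ``sign * (covariate + interaction *
    code)``.  With ``sign=-1`` a calls-to-turn coefficient becomes change
    per call while approaching.
    """
    return pd.Series({c: sign * (covariate_coef + interaction_coef * code)
                      for c, code in coding.items()})


# ---------------------------------------------------------------------------
# Generative simulation (the models' own data-generating process)
# ---------------------------------------------------------------------------

def simulate_ipi_dataset(structure: str = "approach",
                         coeffs=(33.17, -1.53, -0.19, 0.11),
                         variances=(141.56, 20.74, 6.28, 3.14, 4.72),
                         n_bats: int = 4, n_days: int = 7, n_trials: int = 14,
                         mean_calls: int = 35, seed: int = 0,
                         coding: dict | None = None) -> pd.DataFrame:
    """Simulate call-level IPI data exactly from one model structure.

    ``coeffs`` are (intercept, condition, covariate, interaction);
    ``variances`` are (residual, bat, condition, day, trial).  The default
    sizes give roughly 40 000 rows.  Setting every variance to zero yields
    a noiseless dataset, the exact generative inverse of the fixed effects.
    """
    if structure not in ("approach", "days"):
        raise ValueError("structure must be 'approach' or 'days'")
    coding = coding or (CONDITION_CODES_ONE_BASED if structure == "approach"
                        else CONDITION_CODES_ZERO_BASED)
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3 = coeffs
    s2_res, s2_bat, s2_cond, s2_day, s2_trial = variances
    rows = []
    conds = list(coding.keys())
    for b in range(n_bats):
        u_bat = rng.normal(0, np.sqrt(s2_bat))
        for cond in conds:
            code = coding[cond]
            u_cond = rng.normal(0, np.sqrt(s2_cond))
            for day in range(1, n_days + 1):
                u_day = rng.normal(0, np.sqrt(s2_day))
                for trial in range(1, n_trials + 1):
                    u_trial = rng.normal(0, np.sqrt(s2_trial))
                    n_calls = max(5, int(rng.poisson(mean_calls)))
                    for k in range(n_calls):
                        x = (n_calls - 1 - k) if structure == "approach" else day
                        mu = b0 + b1 * code + b2 * x + b3 * code * x
                        rows.append((
                            f"bat{b+1}", cond, day, f"{cond}-d{day}-t{trial}",
                            x, mu + u_bat + u_cond + u_day + u_trial
                            + rng.normal(0, np.sqrt(s2_res))))
    cov = "calls_to_turn" if structure == "approach" else "day_number"
    return pd.DataFrame(rows, columns=["bat", "condition", "day", "trial",
                                       cov, "post_ipi_ms"])
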