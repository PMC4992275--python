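"""The five analysis models, as Model objects with oracle-verifiable fits.

Model 1: unconditional logistic regression of D on E, unmatched design.
Model 2: as 1 but adjusting for C.
Model 3: unconditional logistic regression of D on E, matched design.
Model 4: as 3 but adjusting for C.
Model 5: conditional logistic regression on the 1:1 matched pairs.

Both likelihoods are implemented here with Newton-Raphson iterations rather
than delegated, because these fits are the measuring instrument of the whole
simulation study: the test suite checks them against closed forms (the 2x2
``ln(ad/bc)`` estimate with Woolf standard error; the matched-pairs
discordant ratio ``ln(n10/n01)``) and against an independent general-purpose
fitter.

In a 1:1 pair-conditional likelihood any covariate that is constant within
every pair contributes nothing; exact matching makes C such a covariate, so
model 5 "adjusting for C" drops C with a diagnostic flag instead of chasing
an inestimable parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .sampling import CaseControlSample

__all__ = [
    "EstimationError",
    "BinaryLogit",
    "MatchedPairLogit",
    "LogitResults",
    "EstimateResult",
    "fit_unconditional",
    "fit_conditional",
    "fit_model",
    "MODEL_DESCRIPTIONS",
]

MODEL_DESCRIPTIONS = {
    1: "unconditional logistic, unmatched, unadjusted",
    2: "unconditional logistic, unmatched, adjusted for C",
    3: "unconditional logistic, matched, unadjusted",
    4: "unconditional logistic, matched, adjusted for C",
    5: "conditional logistic, matched pairs",
}

_GTOL = 1e-8
_MAXITER = 100
_SEPARATION_BOUND = 15.0  # |log-odds| beyond this with no convergence => separation


class EstimationError(ValueError):
    """Degenerate input for which no estimate exists."""


@dataclass
class LogitResults:
    """Fit results: point estimates, model-based standard errors, diagnostics."""

    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    nobs: int
    exog_names: tuple[str, ...]
    flags: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> tuple[float, float]:
        i = self.exog_names.index(name)
        return float(self.params[i]), float(self.bse[i])

    def summary(self) -> str:
        lines = [
            f"{'term':>12} {'coef':>12} {'std err':>12} {'odds ratio':>12}",
            "-" * 52,
        ]
        for name, b, s in zip(self.exog_names, self.params, self.bse):
            lines.append(f"{name:>12} {b:>12.4f} {s:>12.4f} {np.exp(b):>12.4f}")
        lines.append("-" * 52)
        lines.append(
            f"n = {self.nobs}, log-likelihood = {self.llf:.4f}, "
            f"converged = {self.converged}"
        )
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _newton(
    loglike, score, hessian, k: int, maxiter: int = _MAXITER, gtol: float = _GTOL
):
    """Newton-Raphson with step halving from beta = 0."""
    beta = np.zeros(k)
    ll = loglike(beta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        g = score(beta)
        if np.max(np.abs(g)) < gtol:
            converged = True
            break
        h = hessian(beta)
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError:
            return beta, ll, False, it, None
        # halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_cand = loglike(cand)
            if ll_cand >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = loglike(beta)
    h = hessian(beta)
    return beta, ll, converged, it, h


def _finish(beta, ll, converged, n_iter, hess, nobs, names, flags):
    if hess is None:
        bse = np.full(len(beta), np.nan)
        flags = flags + ("singular_information",)
    else:
        try:
            cov = np.linalg.inv(-hess)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(len(beta), np.nan)
            flags = flags + ("singular_information",)
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        # the likelihood is maximized (or flat) at an effectively infinite
        # log-odds ratio: no finite MLE exists, whatever the gradient says
        flags = flags + ("separation",)
        converged = False
    return LogitResults(
        params=beta,
        bse=bse,
        llf=float(ll),
        converged=bool(converged),
        n_iter=n_iter,
        nobs=int(nobs),
        exog_names=tuple(names),
        flags=tuple(flags),
    )


class BinaryLogit:
    """Maximum-likelihood logistic regression of a binary outcome.

    Parameters
    ----------
    endog : array of 0/1 outcomes.
    exog : design matrix (an intercept column is prepended automatically).
    exog_names : names for the columns of ``exog``.
    """

    def __init__(self, endog, exog, exog_names=None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.shape[0] != X.shape[0] or y.shape[0] == 0:
            raise EstimationError("empty or misaligned data")
        if not np.isin(y, (0.0, 1.0)).all():
            raise EstimationError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise EstimationError("outcome is constant; likelihood unbounded")
        names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
        constant = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
        if constant:
            raise EstimationError(
                f"constant predictor column(s): {', '.join(constant)}"
            )
        self.endog = y
        self.exog = np.column_stack([np.ones(len(y)), X])
        self.exog_names = ["intercept", *names]

    def loglike(self, beta) -> float:
        eta = self.exog @ beta
        # numerically stable: log expit(+-eta)
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def score(self, beta) -> np.ndarray:
        mu = expit(self.exog @ beta)
        return self.exog.T @ (self.endog - mu)

    def hessian(self, beta) -> np.ndarray:
        mu = expit(self.exog @ beta)
        w = mu * (1.0 - mu)
        return -(self.exog.T * w) @ self.exog

    def fit(self, maxiter: int = _MAXITER, gtol: float = _GTOL) -> LogitResults:
        beta, ll, conv, it, h = _newton(
            self.loglike, self.score, self.hessian, self.exog.shape[1], maxiter, gtol
        )
        return _finish(beta, ll, conv, it, h, len(self.endog), self.exog_names, ())


class MatchedPairLogit:
    """Conditional logistic regression for 1:1 matched pairs.

    The pair-conditional likelihood is

        prod_pairs  exp(eta_case) / (exp(eta_case) + exp(eta_control)),

    with ``eta`` the linear predictor without intercept; only the within-pair
    covariate differences ``d = x_case - x_control`` enter.  Covariates
    constant within every pair are dropped and flagged.  With E as the single
    covariate the maximizer is the classical discordant-pair closed form
    ``ln(n10/n01)`` with standard error ``sqrt(1/n10 + 1/n01)``.
    """

    def __init__(self, case_exog, control_exog, exog_names=None):
        xc = np.asarray(case_exog, dtype=float)
        x0 = np.asarray(control_exog, dtype=float)
        if xc.ndim == 1:
            xc, x0 = xc[:, None], x0[:, None]
        if xc.shape != x0.shape or xc.shape[0] == 0:
            raise EstimationError("empty or misaligned pair data")
        names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(xc.shape[1])
        ]
        diffs = xc - x0
        keep = [j for j in range(diffs.shape[1]) if np.ptp(diffs[:, j]) != 0
                or diffs[0, j] != 0]
        self.dropped = tuple(names[j] for j in range(diffs.shape[1]) if j not in keep)
        if not keep:
            raise EstimationError(
                "no covariate varies within pairs; conditional likelihood is flat"
            )
        self.diffs = diffs[:, keep]
        self.exog_names = [names[j] for j in keep]
        self.n_pairs = diffs.shape[0]
        # pairs whose covariate differences are all zero contribute a constant
        # factor 1/2; only "informative" (discordant-in-predictor) pairs count
        self.informative = np.any(self.diffs != 0, axis=1)

    def loglike(self, beta) -> float:
        eta = self.diffs @ beta
        return float(-np.sum(np.logaddexp(0.0, -eta)))

    def score(self, beta) -> np.ndarray:
        p = expit(-(self.diffs @ beta))
        return self.diffs.T @ p

    def hessian(self, beta) -> np.ndarray:
        eta = self.diffs @ beta
        w = expit(eta) * expit(-eta)
        return -(self.diffs.T * w) @ self.diffs

    def fit(self, maxiter: int = _MAXITER, gtol: float = _GTOL) -> LogitResults:
        if not self.informative.any():
            raise EstimationError("all pairs concordant; conditional likelihood flat")
        flags = tuple(f"dropped_constant_within_pair:{n}" for n in self.dropped)
        beta, ll, conv, it, h = _newton(
            self.loglike, self.score, self.hessian, self.diffs.shape[1], maxiter, gtol
        )
        res = _finish(beta, ll, conv, it, h, self.n_pairs, self.exog_names, flags)
        if not conv and np.max(np.abs(beta)) > _SEPARATION_BOUND:
            # e.g. every discordant pair has the case exposed: estimate infinite
            res.flags = tuple(set(res.flags) | {"infinite_estimate"})
        return res


@dataclass(frozen=True)
class EstimateResult:
    """One model's estimate of the exposure log-odds ratio on one sample."""

    model_id: int
    beta_hat: float
    se_model: float
    converged: bool
    n_used: int
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def description(self) -> str:
        return MODEL_DESCRIPTIONS[self.model_id]


def _failed(model_id: int, n_used: int, *notes: str) -> EstimateResult:
    return EstimateResult(model_id, float("nan"), float("nan"), False, n_used, tuple(notes))


def fit_unconditional(sample: CaseControlSample, adjust_for_C: bool) -> EstimateResult:
    """Models 1-4: ordinary logistic fit of D on E (and C when adjusting)."""
    df = sample.data
    if len(df) == 0:
        raise EstimationError("empty sample")
    if adjust_for_C and "C" not in df.columns:
        raise EstimationError("C is not an observed column in this sample")
    model_id = {("unmatched", False): 1, ("unmatched", True): 2,
                ("matched", False): 3, ("matched", True): 4}[
        (sample.design, adjust_for_C)]
    names = ["E", "C"] if adjust_for_C else ["E"]
    try:
        res = BinaryLogit(df["D"], df[names], exog_names=names).fit()
    except EstimationError as exc:
        return _failed(model_id, len(df), str(exc))
    beta, se = res["E"]
    return EstimateResult(model_id, beta, se, res.converged, res.nobs, res.flags)


def fit_conditional(sample: CaseControlSample, adjust_for_C: bool = True) -> EstimateResult:
    """Model 5: 1:1 pair-conditional logistic fit.

    C is constant within every exactly matched pair, so requesting adjustment
    for C only adds a diagnostic flag; the estimate cannot and does not
    depend on it.
    """
    if sample.design != "matched":
        raise EstimationError("conditional fit requires a matched sample")
    df = sample.data
    names = ["E", "C"] if (adjust_for_C and "C" in df.columns) else ["E"]
    cases = df[df["role"] == "case"].sort_values("pair_id")
    controls = df[df["role"] == "control"].sort_values("pair_id")
    if not (cases["pair_id"].to_numpy() == controls["pair_id"].to_numpy()).all():
        raise EstimationError("invalid pair structure")
    try:
        model = MatchedPairLogit(cases[names], controls[names], exog_names=names)
        res = model.fit()
    except EstimationError as exc:
        return _failed(5, len(cases), str(exc))
    beta, se = res["E"]
    n_used = int(model.informative.sum())
    return EstimateResult(5, beta, se, res.converged, n_used, res.flags)


def fit_model(
    model_id: int,
    unmatched: CaseControlSample | None = None,
    matched: CaseControlSample | None = None,
) -> EstimateResult:
    """Dispatch one of the five paper models to the right design and fitter."""
    if model_id in (1, 2):
        if unmatched is None:
            raise EstimationError(f"model {model_id} needs an unmatched sample")
        return fit_unconditional(unmatched, adjust_for_C=(model_id == 2))
    if model_id in (3, 4):
        if matched is None:
            raise EstimationError(f"model {model_id} needs a matched sample")
        return fit_unconditional(matched, adjust_for_C=(model_id == 4))
    if model_id == 5:
        if matched is None:
            raise EstimationError("model 5 needs a matched sample")
        return fit_conditional(matched)
    raise EstimationError(f"unknown model id {model_id}")
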