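"""Hierarchical type-II maximum-likelihood fitting.

Subject-level parameters (raw scale) are given independent Gaussian
population priors whose hyperparameters are estimated by empirical Bayes:
an EM loop alternates subject-level MAP estimation (E-step, multi-start
quasi-Newton) with closed-form hyperparameter updates from the Laplace
approximation of each subject's posterior (M-step),

    mean_j  <-  average_i m_ij
    var_j   <-  average_i (m_ij^2 + [H_i^{-1}]_jj) - mean_j^2

where m_i is subject i's posterior mode and H_i the Hessian of the negative
log posterior there.  Convergence is monitored on the Laplace approximation
of the marginal log likelihood.  Model comparison uses the integrated BIC,

    iBIC = -2 * LML + 2 k ln(N_obs),

with LML the Monte-Carlo marginal log likelihood (per subject, the log of
the mean likelihood over parameter draws from the fitted population prior,
1000 draws by default), k the number of free parameters (each contributing a
mean and a variance hyperparameter, hence the factor 2), and N_obs the total
number of observed choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .models import ModelSpec, ParameterVector, sequence_log_likelihood_batch
from .task import SubjectDataset

VARIANCE_FLOOR = 1e-6
_LOG_2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Optimization or EM failure carrying diagnostic state."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class PopulationPrior:
    """Independent Gaussians over a model's raw-scale parameters."""

    model: ModelSpec
    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        k = self.model.n_params
        self.mean = np.asarray(self.mean, dtype=float).reshape(k)
        self.variance = np.maximum(
            np.asarray(self.variance, dtype=float).reshape(k), VARIANCE_FLOOR
        )

    def logpdf(self, raw: np.ndarray) -> float:
        z2 = (np.asarray(raw) - self.mean) ** 2 / self.variance
        return float(
            -0.5 * np.sum(z2 + np.log(self.variance) + _LOG_2PI)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(
            self.mean, np.sqrt(self.variance), size=(n, self.model.n_params)
        )

    @classmethod
    def default(cls, model: ModelSpec) -> "PopulationPrior":
        """Diffuse initialization: raw means 0, variances 4."""
        k = model.n_params
        return cls(model, np.zeros(k), np.full(k, 4.0))


@dataclass
class SubjectFit:
    """Laplace summary of one subject's posterior."""

    subject_id: str
    map_raw: np.ndarray
    hessian: np.ndarray
    log_posterior_at_mode: float
    converged: bool = True
    message: str = ""

    def map_natural(self, model: ModelSpec) -> np.ndarray:
        return model.to_natural(self.map_raw)

    def posterior_variance(self) -> np.ndarray:
        """Diagonal of the inverse Hessian (Laplace posterior variances)."""
        return np.diag(np.linalg.inv(self.hessian)).copy()

    def laplace_evidence(self, k: int) -> float:
        """Laplace approximation of this subject's log marginal likelihood."""
        sign, logdet = np.linalg.slogdet(self.hessian)
        return self.log_posterior_at_mode + 0.5 * (k * _LOG_2PI - logdet)


@dataclass
class FitResult:
    """Outcome of one hierarchical fit of one model."""

    model_name: str
    prior: PopulationPrior
    subjects: list[SubjectFit]
    lml: float
    ibic: float
    em_trace: list[float] = field(default_factory=list)
    n_obs: int = 0
    converged: bool = True

    def map_table(self):
        """Per-subject MAP estimates on the natural scale as a DataFrame."""
        import pandas as pd

        model = self.prior.model
        rows = []
        for fit in self.subjects:
            row = {"subject": fit.subject_id}
            row.update(zip(model.slot_names, fit.map_natural(model)))
            rows.append(row)
        return pd.DataFrame(rows)


def compute_ibic(lml: float, n_free_params: int, n_obs: int) -> float:
    """Integrated BIC: -2*LML plus 2 hyperparameters per free parameter."""
    if n_free_params > 0 and n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    penalty = 2.0 * n_free_params * (np.log(n_obs) if n_free_params else 0.0)
    return float(-2.0 * lml + penalty)


def _neg_log_posterior(raw, data, model, prior):
    natural = model.to_natural(raw[None, :])
    ll = sequence_log_likelihood_batch(data, model, natural)[0]
    return -(ll + prior.logpdf(raw))


def _fd_hessian(f, x, step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = x.size
    h = np.eye(k) * step
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        fp = f(x + h[i])
        fm = f(x - h[i])
        hess[i, i] = (fp - 2.0 * f0 + fm) / step**2
        for j in range(i + 1, k):
            fpp = f(x + h[i] + h[j])
            fpm = f(x + h[i] - h[j])
            fmp = f(x - h[i] + h[j])
            fmm = f(x - h[i] - h[j])
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return hess


def _regularize(hess: np.ndarray) -> np.ndarray:
    """Add ridge until positive definite (starting at 1e-6)."""
    ridge = 1e-6
    eye = np.eye(hess.shape[0])
    for _ in range(40):
        try:
            np.linalg.cholesky(hess + ridge * eye)
            return hess + ridge * eye
        except np.linalg.LinAlgError:
            ridge *= 10.0
    raise FitError("Hessian could not be regularized to positive definite")


def map_estimate(
    data: SubjectDataset,
    model: ModelSpec,
    prior: PopulationPrior,
    n_restarts: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> SubjectFit:
    """Posterior mode of one subject's raw parameters, with curvature.

    Maximizes log likelihood + log prior by L-BFGS from the prior mean,
    ``n_restarts - 1`` draws from the prior, and any ``extra_starts`` (used
    by the EM loop to warm-start from the previous iteration's mode).
    """
    k = model.n_params
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(data) == 0:
        # likelihood is constant; the posterior is the prior
        hess = _regularize(np.diag(1.0 / prior.variance))
        return SubjectFit(
            data.subject_id, prior.mean.copy(), hess, prior.logpdf(prior.mean)
        )

    def nlp(raw):
        return _neg_log_posterior(raw, data, model, prior)

    starts = [prior.mean.copy()]
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    if n_restarts > len(starts):
        starts.extend(prior.sample(n_restarts - len(starts), rng))

    best = None
    n_ok = 0
    for x0 in starts:
        res = minimize(nlp, x0, method="L-BFGS-B")
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError(f"all {len(starts)} starts failed for {data.subject_id}")
    hess = _regularize(_fd_hessian(nlp, best.x))
    return SubjectFit(
        data.subject_id,
        best.x.copy(),
        hess,
        -float(best.fun),
        converged=n_ok > 0,
        message="" if best.success else str(best.message),
    )


def marginal_log_likelihood_mc(
    cohort: Sequence[SubjectDataset],
    model: ModelSpec,
    prior: PopulationPrior,
    n_samples: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo marginal log likelihood under a population prior.

    Per subject: draw ``n_samples`` raw parameter vectors from the prior,
    evaluate the choice-sequence likelihood at each, and take the log of the
    sample mean likelihood (log-sum-exp); sum over subjects.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    total = 0.0
    for data in cohort:
        raws = prior.sample(n_samples, rng)
        naturals = model.to_natural(raws)
        lls = sequence_log_likelihood_batch(data, model, naturals)
        total += float(logsumexp(lls) - np.log(n_samples))
    return total


def _laplace_lml(subjects: Sequence[SubjectFit], k: int) -> float:
    return float(sum(s.laplace_evidence(k) for s in subjects))


def em_fit(
    cohort: Sequence[SubjectDataset],
    model: ModelSpec,
    init: PopulationPrior | None = None,
    max_iter: int = 200,
    tol: float = 1e-2,
    seed: int = 0,
    n_restarts: int = 5,
    mc_samples: int = 1000,
    divergence_slack: float = 1e-2,
) -> FitResult:
    """Empirical-Bayes EM over a cohort.

    E-step: MAP estimate per subject under the current prior.  M-step:
    moment-match the prior to the Laplace posteriors.  Stops when the
    Laplace-approximate marginal log likelihood changes by less than ``tol``
    per subject or after ``max_iter`` iterations; aborts if it decreases by
    more than ``divergence_slack`` per subject for three consecutive
    iterations.  The reported
    ``lml``/``ibic`` come from the Monte-Carlo estimator at the converged
    prior with a reporting seed derived from ``seed``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must contain at least one subject")
    k = model.n_params
    # tol and slack are per subject: the Laplace lml (and its approximation
    # error, which makes the trace oscillate at the fixed point) scales with
    # cohort size, so an absolute threshold would never be met at large n
    tol = tol * len(cohort)
    divergence_slack = divergence_slack * len(cohort)
    prior = init if init is not None else PopulationPrior.default(model)
    prior = PopulationPrior(model, prior.mean.copy(), prior.variance.copy())
    n_obs = sum(len(d) for d in cohort)
    mc_seed = _reporting_seed(seed)

    trace: list[float] = []
    subjects: list[SubjectFit] = []
    if max_iter < 1:
        lml = marginal_log_likelihood_mc(cohort, model, prior, mc_samples, mc_seed)
        return FitResult(
            model.name, prior, [], lml, compute_ibic(lml, k, max(n_obs, 1)),
            [lml], n_obs,
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    # fixed standard-normal restart offsets per subject, mapped through the
    # current prior each iteration: keeps the E-step a deterministic function
    # of the prior, so the Laplace lml trace is not jittered by fresh draws
    offsets = rng.standard_normal((len(cohort), max(n_restarts - 1, 0), k))
    warm: list[np.ndarray] = [None] * len(cohort)  # type: ignore[list-item]
    n_decreasing = 0
    converged = False
    for it in range(max_iter):
        sd = np.sqrt(prior.variance)
        subjects = []
        for i, data in enumerate(cohort):
            extra = list(prior.mean + sd * offsets[i])
            if warm[i] is not None:
                extra.insert(0, warm[i])
            subjects.append(
                map_estimate(
                    data, model, prior, n_restarts=0, rng=rng,
                    extra_starts=extra,
                )
            )
            warm[i] = subjects[-1].map_raw
        lml_laplace = _laplace_lml(subjects, k)
        if trace and lml_laplace < trace[-1] - divergence_slack:
            n_decreasing += 1
            if n_decreasing >= 3:
                raise FitError(
                    f"EM diverging for {model.name} "
                    f"(lml decreasing 3 iterations)",
                    trace + [lml_laplace],
                )
        else:
            n_decreasing = 0
        done = bool(trace) and abs(lml_laplace - trace[-1]) < tol
        trace.append(lml_laplace)
        if done:
            converged = True
            break
        # M-step: moment-match the Laplace posteriors
        modes = np.array([s.map_raw for s in subjects])
        post_var = np.array([s.posterior_variance() for s in subjects])
        mean = modes.mean(axis=0)
        var = (modes**2 + post_var).mean(axis=0) - mean**2
        prior = PopulationPrior(model, mean, var)

    if not converged and max_iter > 1:
        warnings.warn(
            f"EM for {model.name} stopped at max_iter={max_iter} "
            "without meeting tol",
            stacklevel=2,
        )
    lml = marginal_log_likelihood_mc(cohort, model, prior, mc_samples, mc_seed)
    return FitResult(
        model.name,
        prior,
        subjects,
        lml,
        compute_ibic(lml, k, n_obs),
        trace,
        n_obs,
        converged=converged or max_iter == 1,
    )


def _reporting_seed(seed: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=(999,)).generate_state(1)[0]
        % (2**31)
    )
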