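"""Tumor-type-parallelized latent Dirichlet allocation (PLDA).

The generative model: each signature k has a distribution ``phi_k`` over the
96 mutation types, drawn from ``Dirichlet(beta)``.  Each sample s of tumor
type l draws activities ``theta_ls ~ Dirichlet(alpha_l)``; every one of its
``n_ls`` mutations picks a signature ``z ~ Categorical(theta_ls)`` and then a
mutation type ``v ~ Categorical(phi_z)``.  Unlike plain LDA there is one
concentration vector ``alpha_l`` per tumor type, so the prior encodes which
signatures tend to be active in which cancers and all tumor types can be
analyzed jointly.

Inference is mean-field variational Bayes with coordinate ascent:

* ``q(theta_ls) = Dirichlet(gamma_ls)``,
* ``q(phi_k) = Dirichlet(lambda_k)``,
* ``q(z)``: factorized responsibilities.

Mutations of the same type within a sample are exchangeable, so
responsibilities are stored once per (sample, mutation type) and weighted by
the observed count — mathematically identical to per-mutation updates at a
fraction of the cost.  Hyperparameters ``alpha_l`` and ``beta`` are estimated
by Minka's inverse-digamma fixed-point iteration for Dirichlet
concentrations, safeguarded so the corresponding ELBO terms never decrease.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import digamma, gammaln, xlogy, zeta

from .catalog import ActivityMatrix, MutationCatalog, SignatureSet, write_activities, write_signature_set
from .sbs96 import N_TYPES

logger = logging.getLogger(__name__)

_PHI_FLOOR = 1e-12
_ALPHA_FLOOR = 1e-10


class NumericalError(RuntimeError):
    """Raised when an update or bound evaluates to a non-finite value."""


@dataclass(frozen=True)
class Hyperparameters:
    """Dirichlet concentrations: one K-vector ``alpha_l`` per tumor type and a
    shared 96-vector ``beta`` for the signature prior."""

    alpha: np.ndarray  # (L, K)
    beta: np.ndarray   # (96,)

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if a.ndim != 2:
            raise ValueError("alpha must be an (L, K) matrix")
        if b.shape == ():  # scalar broadcast convenience
            b = np.full(N_TYPES, float(b))
            object.__setattr__(self, "beta", b)
        if b.shape != (N_TYPES,):
            raise ValueError(f"beta must be a scalar or a {N_TYPES}-vector")
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("all hyperparameters must be strictly positive")
        object.__setattr__(self, "alpha", a)

    @property
    def K(self) -> int:
        return self.alpha.shape[1]

    @classmethod
    def default(cls, L: int, K: int, alpha0: float | None = None, beta0: float = 0.1):
        """Weakly informative defaults: alpha uniform at 1/K, beta symmetric 0.1."""
        if alpha0 is None:
            alpha0 = 1.0 / K
        return cls(alpha=np.full((L, K), alpha0), beta=np.full(N_TYPES, beta0))


@dataclass(frozen=True)
class VariationalState:
    """Mean-field variational parameters.

    ``gamma``: (N, K) Dirichlet parameters of q(theta) per sample.
    ``lam``:   (K, 96) Dirichlet parameters of q(phi) per signature.
    ``resp``:  (N, 96, K) responsibilities, normalized over the last axis;
    entries at zero-count cells are kept normalized but carry no weight.
    """

    gamma: np.ndarray
    lam: np.ndarray
    resp: np.ndarray

    @property
    def K(self) -> int:
        return self.gamma.shape[1]


@dataclass(frozen=True)
class ElboReport:
    """ELBO total with its per-tumor-type decomposition (nats).

    ``total == per_type.sum() + signature_term`` by construction: the
    document-level terms (theta prior, z terms, q(theta) entropy) split over
    tumor types while the signature prior/posterior terms are shared.
    """

    total: float
    per_type: np.ndarray  # (L,)
    signature_term: float


@dataclass(frozen=True)
class FitResult:
    K: int
    elbo: float
    theta: ActivityMatrix
    phi: SignatureSet
    hyper: Hyperparameters
    n_iterations: int
    converged: bool
    seed: int
    elbo_per_type: np.ndarray | None = None

    def save(self, out_dir, label: str = "fit") -> None:
        """Serialize theta/phi as TSV plus a JSON sidecar with
        hyperparameters, ELBO and run metadata."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_activities(self.theta, out / f"{label}_theta.tsv")
        write_signature_set(self.phi, out / f"{label}_phi.tsv")
        sidecar = {
            "K": self.K,
            "elbo": self.elbo,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
            "alpha": self.hyper.alpha.tolist(),
            "beta": self.hyper.beta.tolist(),
        }
        (out / f"{label}_model.json").write_text(json.dumps(sidecar, indent=1))


# -- expectations --------------------------------------------------------------


def _elog_dirichlet(params: np.ndarray) -> np.ndarray:
    """E[log p] under Dirichlet(params), row-wise."""
    return digamma(params) - digamma(params.sum(axis=-1, keepdims=True))


def expected_activity(alpha_l: np.ndarray) -> np.ndarray:
    """Expected signature activity under ``Dirichlet(alpha_l)``:
    ``E[theta_k] = alpha_k / sum(alpha)``."""
    a = np.asarray(alpha_l, dtype=float)
    if a.ndim != 1 or (a <= 0).any():
        raise ValueError("alpha_l must be a vector of positive reals")
    return a / a.sum()


# -- coordinate updates --------------------------------------------------------


#: Concentration of the Dirichlet that randomizes initial responsibilities.
#: A sparse draw (< 1) breaks the near-uniform symmetry that traps coordinate
#: ascent in poor local optima at the true number of signatures.
_INIT_CONCENTRATION = 0.1


def init_state(catalog: MutationCatalog, K: int, hyper: Hyperparameters, seed: int) -> VariationalState:
    """Seeded initialization: responsibilities drawn from a sparse symmetric
    Dirichlet per (sample, mutation type) cell, then gamma/lambda derived by
    one update pass.  Deterministic given the seed."""
    if K < 1:
        raise ValueError("K must be at least 1")
    rng = np.random.default_rng(seed)
    if K == 1:
        resp = np.ones((catalog.n_samples, N_TYPES, 1))
    else:
        resp = rng.dirichlet(
            np.full(K, _INIT_CONCENTRATION), size=(catalog.n_samples, N_TYPES)
        )
    state = VariationalState(
        gamma=np.ones((catalog.n_samples, K)), lam=np.ones((K, N_TYPES)), resp=resp
    )
    state = update_gamma(state, catalog, hyper)
    return update_lambda(state, catalog, hyper)


def update_responsibilities(state: VariationalState, catalog: MutationCatalog) -> VariationalState:
    """Softmax responsibility update:
    ``r_nvk ∝ exp(E[log theta_nk] + E[log phi_kv])``."""
    return _update_resp_from_elog(state, _elog_dirichlet(state.lam))


def _update_resp_from_elog(state: VariationalState, elog_phi: np.ndarray) -> VariationalState:
    elog_theta = _elog_dirichlet(state.gamma)  # (N, K)
    if not (np.isfinite(elog_theta).all() and np.isfinite(elog_phi).all()):
        raise NumericalError("non-finite digamma input in responsibility update")
    log_r = elog_theta[:, None, :] + elog_phi.T[None, :, :]  # (N, V, K)
    log_r -= log_r.max(axis=2, keepdims=True)
    r = np.exp(log_r)
    r /= r.sum(axis=2, keepdims=True)
    return replace(state, resp=r)


def update_gamma(state: VariationalState, catalog: MutationCatalog, hyper: Hyperparameters) -> VariationalState:
    """``gamma_nk = alpha_{l(n),k} + sum_v M_nv r_nvk``."""
    gamma = hyper.alpha[catalog.type_index] + np.einsum(
        "nv,nvk->nk", catalog.counts.astype(float), state.resp
    )
    return replace(state, gamma=gamma)


def update_lambda(state: VariationalState, catalog: MutationCatalog, hyper: Hyperparameters) -> VariationalState:
    """``lambda_kv = beta_v + sum_n M_nv r_nvk``."""
    lam = hyper.beta[None, :] + np.einsum(
        "nv,nvk->kv", catalog.counts.astype(float), state.resp
    )
    return replace(state, lam=lam)


# -- hyperparameter fixed points -----------------------------------------------


def _trigamma(x):
    # psi'(x) = zeta(2, x); calling zeta directly avoids polygamma overhead
    return zeta(2.0, x)


def _inverse_digamma(y: np.ndarray) -> np.ndarray:
    """Solve ``digamma(x) = y`` by Newton iteration from Minka's initializer."""
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):  # unused branch of the where
        x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y + np.euler_gamma))
    for _ in range(5):
        x = np.maximum(x - (digamma(x) - y) / _trigamma(x), _ALPHA_FLOOR)
    return x


def dirichlet_fixed_point(alpha0, sum_psi, sum_psi_total, n_obs, *, tol=1e-12, max_iter=1000):
    """Minka's fixed-point iteration for a Dirichlet concentration vector.

    Maximizes ``sum_s [lgamma(sum a) - sum_k lgamma(a_k)
    + sum_k (a_k - 1) (psi(g_sk) - psi(sum g_s))]`` over ``a`` given the
    sufficient statistics ``sum_psi[k] = sum_s psi(g_sk)`` and
    ``sum_psi_total = sum_s psi(sum_j g_sj)`` from ``n_obs`` observations.
    The stationarity condition is ``psi(a_k) - psi(sum a) = mean_s
    E[log p_sk]``; each sweep solves it for ``a_k`` at the current ``sum a``
    through the inverse digamma, which converges monotonically (Minka's
    Dirichlet-estimation iteration).  Entries are clamped to at least 1e-10.
    """
    alpha = np.array(alpha0, dtype=float)
    mean_elogp = (np.asarray(sum_psi, dtype=float) - sum_psi_total) / n_obs
    for _ in range(max_iter):
        new = _inverse_digamma(digamma(alpha.sum()) + mean_elogp)
        delta = np.max(np.abs(new - alpha) / np.maximum(alpha, _ALPHA_FLOOR))
        alpha = new
        if delta < tol:
            break
    else:
        logger.debug("Dirichlet fixed point still moving after %d iterations", max_iter)
    return alpha


def _dirichlet_objective(alpha, sum_psi, sum_psi_total, n_obs):
    """The alpha-dependent ELBO terms at the given sufficient statistics.

    Equals ``sum_s E[log Dirichlet(theta_s; alpha)]`` up to the
    alpha-independent ``-psi`` pieces, since ``sum_s sum_k (a_k - 1)
    (psi(g_sk) - psi(sum g_s)) = sum_k (a_k - 1) sum_psi[k]
    - (sum a - K) sum_psi_total``.
    """
    a = np.asarray(alpha, dtype=float)
    return (
        n_obs * (gammaln(a.sum(axis=-1)) - gammaln(a).sum(axis=-1))
        + ((a - 1) * sum_psi).sum(axis=-1)
        - (a.sum(axis=-1) - a.shape[-1]) * sum_psi_total
    )


def update_alpha(hyper: Hyperparameters, state: VariationalState, catalog: MutationCatalog, l: int, *, inner_max_iter: int = 1000) -> Hyperparameters:
    """Re-estimate ``alpha_l`` from the gamma statistics of tumor type ``l``.

    The fixed point is safeguarded: if the iterate does not improve the
    alpha-dependent ELBO terms, the previous value is kept.
    """
    rows = catalog.samples_of_type(l)
    if rows.size == 0:
        raise ValueError(f"tumor type index {l} has no samples")
    if rows.size == 1:
        logger.debug("tumor type %r has a single sample; alpha_l weakly identified", l)
    g = state.gamma[rows]
    sum_psi = digamma(g).sum(axis=0)
    sum_psi_total = float(digamma(g.sum(axis=1)).sum())
    old = hyper.alpha[l]
    new = dirichlet_fixed_point(old, sum_psi, sum_psi_total, rows.size, max_iter=inner_max_iter)
    if _dirichlet_objective(new, sum_psi, sum_psi_total, rows.size) < _dirichlet_objective(
        old, sum_psi, sum_psi_total, rows.size
    ):
        logger.warning("alpha fixed point decreased the bound for type %d; keeping previous", l)
        new = old
    alpha = hyper.alpha.copy()
    alpha[l] = new
    return replace(hyper, alpha=alpha)


def update_beta(hyper: Hyperparameters, state: VariationalState, mode: str = "scalar", *, inner_max_iter: int = 1000) -> Hyperparameters:
    """Re-estimate the signature prior ``beta`` from the lambda statistics,
    pooled over the K signature-level Dirichlets.

    ``mode='scalar'`` (default) constrains all ``beta_v`` equal, matching a
    single symmetric prior node; ``mode='vector'`` estimates one value per
    mutation-type context.
    """
    lam = state.lam
    K = lam.shape[0]
    sum_psi = digamma(lam).sum(axis=0)  # (V,)
    sum_psi_total = float(digamma(lam.sum(axis=1)).sum())
    old = hyper.beta
    if mode == "vector":
        new = dirichlet_fixed_point(old, sum_psi, sum_psi_total, K, max_iter=inner_max_iter)
    elif mode == "scalar":
        # symmetric constraint: psi(b) = psi(V b) + mean of E[log phi_kv]
        b = float(old[0])
        mean_elog = float(sum_psi.sum() - N_TYPES * sum_psi_total) / (K * N_TYPES)
        for _ in range(inner_max_iter):
            nb = float(_inverse_digamma(digamma(N_TYPES * b) + mean_elog))
            done = abs(nb - b) / b < 1e-8
            b = nb
            if done:
                break
        new = np.full(N_TYPES, b)
    else:
        raise ValueError(f"unknown beta mode {mode!r}")
    if _dirichlet_objective(new, sum_psi, sum_psi_total, K) < _dirichlet_objective(
        old, sum_psi, sum_psi_total, K
    ):
        logger.warning("beta fixed point decreased the bound; keeping previous value")
        new = old
    return replace(hyper, beta=new)


# -- evidence lower bound ------------------------------------------------------


def _dirichlet_logpdf_terms(params_prior, elog):
    """E[log Dirichlet(x; prior)] rows, with x's E[log] given."""
    return (
        gammaln(params_prior.sum(axis=-1))
        - gammaln(params_prior).sum(axis=-1)
        + ((params_prior - 1) * elog).sum(axis=-1)
    )


def elbo(state: VariationalState, catalog: MutationCatalog, hyper: Hyperparameters) -> ElboReport:
    """Mean-field evidence lower bound in nats.

    Document-level terms (theta prior, expected z/v log-likelihood, q
    entropies) are accumulated per tumor type; the shared signature prior and
    q(phi) entropy form the signature term.  The multinomial coefficient of
    the observed counts is omitted, as is conventional for token-exchangeable
    models; this constant offset cancels in all model-selection comparisons.
    """
    elog_theta = _elog_dirichlet(state.gamma)  # (N, K)
    elog_phi = _elog_dirichlet(state.lam)      # (K, V)
    M = catalog.counts.astype(float)
    r = state.resp

    # expected z assignment + emission log-likelihood, minus q(z) entropy
    cell = np.einsum("nvk,nk->nv", r, elog_theta) + np.einsum("nvk,kv->nv", r, elog_phi)
    cell -= xlogy(r, r).sum(axis=2)
    per_sample = (M * cell).sum(axis=1)

    per_sample += _dirichlet_logpdf_terms(hyper.alpha[catalog.type_index], elog_theta)
    per_sample -= _dirichlet_logpdf_terms(state.gamma, elog_theta)  # -E[log q(theta)]

    per_type = np.zeros(catalog.L)
    np.add.at(per_type, catalog.type_index, per_sample)

    signature_term = float(
        _dirichlet_logpdf_terms(hyper.beta[None, :], elog_phi).sum()
        - _dirichlet_logpdf_terms(state.lam, elog_phi).sum()
    )
    total = float(per_type.sum() + signature_term)
    if not np.isfinite(total):
        for name, value in [("per-type", per_type), ("signature", signature_term)]:
            if not np.isfinite(value).all():
                raise NumericalError(f"non-finite ELBO {name} term")
        raise NumericalError("non-finite ELBO")
    return ElboReport(total=total, per_type=per_type, signature_term=signature_term)


# -- fitting -------------------------------------------------------------------


def _check_fittable(catalog: MutationCatalog):
    if catalog.n_samples == 0:
        raise ValueError("cannot fit an empty catalog")
    if (catalog.n_mutations == 0).any():
        bad = [catalog.sample_ids[i] for i in np.flatnonzero(catalog.n_mutations == 0)]
        raise ValueError(
            f"samples with zero mutations must be filtered before fitting: {bad}"
        )


def _finish(catalog, K, state, hyper, elbo_report, n_iter, converged, seed, phi_override=None):
    theta_values = state.gamma / state.gamma.sum(axis=1, keepdims=True)
    names = tuple(f"Signature_{k + 1}" for k in range(K))
    theta = ActivityMatrix(
        sample_ids=catalog.sample_ids,
        tumor_types=catalog.sample_tumor_types(),
        signature_names=phi_override.names if phi_override is not None else names,
        values=theta_values,
    )
    if phi_override is not None:
        phi = phi_override
    else:
        phi = SignatureSet(names=names, probs=state.lam / state.lam.sum(axis=1, keepdims=True))
    return FitResult(
        K=K,
        elbo=elbo_report.total,
        theta=theta,
        phi=phi,
        hyper=hyper,
        n_iterations=n_iter,
        converged=converged,
        seed=seed,
        elbo_per_type=elbo_report.per_type,
    )


def _tempered_responsibilities(state, elog_phi, temperature):
    """Responsibility update with the log-responsibilities divided by a
    temperature; temperature 1 is the exact mean-field update."""
    elog_theta = _elog_dirichlet(state.gamma)
    if not (np.isfinite(elog_theta).all() and np.isfinite(elog_phi).all()):
        raise NumericalError("non-finite digamma input in responsibility update")
    log_r = (elog_theta[:, None, :] + elog_phi.T[None, :, :]) / temperature
    log_r -= log_r.max(axis=2, keepdims=True)
    r = np.exp(log_r)
    r /= r.sum(axis=2, keepdims=True)
    return replace(state, resp=r)


def fit(
    catalog: MutationCatalog,
    K: int,
    hyper_init: Hyperparameters | None = None,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    estimate_hyperparameters: bool = True,
    warmup: int = 5,
    beta_mode: str = "scalar",
    n_pilots: int = 16,
    pilot_sweeps: int = 12,
    anneal_start: float = 4.0,
    n_refine: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit PLDA by coordinate-ascent variational Bayes.

    Coordinate ascent on this model is highly multimodal, so each call
    screens ``n_pilots`` random starts (sub-seeded deterministically from
    ``seed``) with short deterministically annealed runs: for
    ``pilot_sweeps`` sweeps the responsibility softmax is tempered, cooling
    linearly from ``anneal_start`` to 1, which delays hard component
    assignments.  The ``n_refine`` best pilot states are then run to
    convergence — alternating responsibility/gamma/lambda updates with
    safeguarded hyperparameter fixed-point steps (the latter starting after
    ``warmup`` sweeps) until the relative ELBO change drops below ``tol`` or
    ``max_iter`` sweeps elapse — and the best converged bound wins.  Fully
    deterministic given ``seed``.  Posterior means are returned:
    ``theta = gamma`` row-normalized and ``phi = lambda`` row-normalized.
    """
    _check_fittable(catalog)
    if K < 1:
        raise ValueError("K must be at least 1")
    if anneal_start < 1 or pilot_sweeps < 0 or n_pilots < 1 or n_refine < 1:
        raise ValueError("pilot/annealing parameters must be positive (anneal_start >= 1)")
    hyper0 = hyper_init if hyper_init is not None else Hyperparameters.default(catalog.L, K)
    if hyper0.alpha.shape != (catalog.L, K):
        raise ValueError(
            f"hyper_init.alpha has shape {hyper0.alpha.shape}, expected {(catalog.L, K)}"
        )

    def pilot(sub_seed):
        state = init_state(catalog, K, hyper0, sub_seed)
        for it in range(1, pilot_sweeps + 1):
            temperature = 1.0 + (anneal_start - 1.0) * max(0.0, 1.0 - it / pilot_sweeps)
            state = _tempered_responsibilities(state, _elog_dirichlet(state.lam), temperature)
            state = update_gamma(state, catalog, hyper0)
            state = update_lambda(state, catalog, hyper0)
        return elbo(state, catalog, hyper0).total, state

    def refine(state):
        hyper = hyper0
        prev = -np.inf
        report = elbo(state, catalog, hyper)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            state = update_responsibilities(state, catalog)
            state = update_gamma(state, catalog, hyper)
            state = update_lambda(state, catalog, hyper)
            if estimate_hyperparameters and it > warmup:
                # warm-started every sweep, so a small inner budget suffices
                for l in range(catalog.L):
                    hyper = update_alpha(hyper, state, catalog, l, inner_max_iter=50)
                hyper = update_beta(hyper, state, mode=beta_mode, inner_max_iter=50)
            report = elbo(state, catalog, hyper)
            logger.debug("sweep %d: elbo=%.6f", it, report.total)
            if it > warmup + 1 and prev > -np.inf and abs(report.total - prev) <= tol * abs(report.total):
                converged = True
                break
            prev = report.total
        if not converged:
            logger.info("fit(K=%d, seed=%d) stopped at max_iter=%d without convergence", K, seed, max_iter)
        return state, hyper, report, it, converged

    if K == 1:
        candidates = [init_state(catalog, K, hyper0, seed)]
    else:
        rng = np.random.default_rng(seed)
        sub_seeds = [int(rng.integers(0, 2**31)) for _ in range(n_pilots)]
        scored = sorted((pilot(s) for s in sub_seeds), key=lambda se: -se[0])
        candidates = [state for _, state in scored[:n_refine]]

    best = None
    for cand in candidates:
        outcome = refine(cand)
        if best is None or outcome[2].total > best[2].total:
            best = outcome
    state, hyper, report, it, converged = best
    return _finish(catalog, K, state, hyper, report, it, converged, seed)


def fit_fixed_signatures(
    catalog: MutationCatalog,
    phi_fixed: SignatureSet,
    hyper_init: Hyperparameters | None = None,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    estimate_hyperparameters: bool = True,
    warmup: int = 5,
    seed: int = 0,
) -> FitResult:
    """Re-estimate activities with the signature distributions held fixed.

    Responsibilities use ``log phi_kv`` in place of the variational
    expectation ``psi(lambda_kv) - psi(sum lambda)``; only theta (and alpha)
    are learned.  Signatures containing zeros are floored at 1e-12 and
    renormalized so responsibilities cannot underflow.  The reported bound is
    the conditional ELBO given phi (theta prior + expected likelihood +
    entropies); it omits the signature-prior term, which is constant here.
    """
    _check_fittable(catalog)
    probs = np.maximum(phi_fixed.probs, _PHI_FLOOR)
    probs /= probs.sum(axis=1, keepdims=True)
    phi = SignatureSet(names=phi_fixed.names, probs=probs)
    K = phi.K
    log_phi = np.log(probs)
    hyper = hyper_init if hyper_init is not None else Hyperparameters.default(catalog.L, K)
    if hyper.alpha.shape != (catalog.L, K):
        raise ValueError("hyper_init.alpha does not match (L, K) of the fixed signatures")

    state = init_state(catalog, K, hyper, seed)

    def conditional_elbo(state):
        elog_theta = _elog_dirichlet(state.gamma)
        M = catalog.counts.astype(float)
        cell = np.einsum("nvk,nk->nv", state.resp, elog_theta)
        cell += np.einsum("nvk,kv->nv", state.resp, log_phi)
        cell -= xlogy(state.resp, state.resp).sum(axis=2)
        per_sample = (M * cell).sum(axis=1)
        per_sample += _dirichlet_logpdf_terms(hyper.alpha[catalog.type_index], elog_theta)
        per_sample -= _dirichlet_logpdf_terms(state.gamma, elog_theta)
        per_type = np.zeros(catalog.L)
        np.add.at(per_type, catalog.type_index, per_sample)
        total = float(per_type.sum())
        if not np.isfinite(total):
            raise NumericalError("non-finite conditional ELBO")
        return ElboReport(total=total, per_type=per_type, signature_term=0.0)

    prev = -np.inf
    report = conditional_elbo(state)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        state = _update_resp_from_elog(state, log_phi)
        state = update_gamma(state, catalog, hyper)
        if estimate_hyperparameters and it > warmup:
            for l in range(catalog.L):
                hyper = update_alpha(hyper, state, catalog, l)
        report = conditional_elbo(state)
        if prev > -np.inf and abs(report.total - prev) <= tol * abs(report.total):
            if not estimate_hyperparameters or it > warmup + 1:
                converged = True
                break
        prev = report.total
    return _finish(catalog, K, state, hyper, report, it, converged, seed, phi_override=phi)
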