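"""EM estimation for the covariate-dependent continuous-time HMM.

The E-step needs, for every inter-visit interval, the expected time spent
in each state and the expected number of jumps along each allowed edge,
conditioned on the states at the interval's two ends.  Both reduce to the
integral

    I(E) = int_0^delta expm(u Q) E expm((delta - u) Q) du

for indicator matrices E, which is the (1, 2) block of
``expm(delta * [[Q, E], [0, Q]])`` (the Van Loan construction) and equals
the Frechet derivative of the matrix exponential at ``delta Q`` in
direction ``delta E``.  For endpoint-weight matrices ``W`` the full M x M
table of weighted integrals is obtained in one call as

    C = int_0^delta expm(u Q^T) W expm((delta - u) Q^T) du
      = expm_frechet(delta Q^T, delta W),

with ``C[i, i]`` the expected dwell in state ``i`` and
``Q[i, j] * C[i, j]`` the expected jump count on edge ``(i, j)``.  When
the generator's spectrum is well separated a spectral decomposition gives
the same table from two small matrix products per interval; the Frechet
route remains the fallback for (near-)defective generators, e.g. an
intercept-only model whose states share an exit rate.

The M-step updates pi in closed form, the per-edge log-linear coefficients
by damped Newton-Raphson (the expected complete-data objective is concave
per edge), and — only when the observation model is not frozen — the
Gaussian emission parameters by posterior-weighted moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import expm_frechet

from .model import (
    BetaParams,
    CovariateVector,
    EmissionParams,
    GeneratorMatrix,
    InitialDistribution,
    ModelParams,
    PatientRecord,
    TransitionStructure,
    ValidationError,
    VARIANCE_FLOOR,
    RATE_FLOOR,
    DEFAULT_CLIP_RANGE,
    build_generator,
    emission_loglik_matrix,
    transition_matrix,
)

__all__ = [
    "SufficientStats",
    "FitResult",
    "viterbi_decode",
    "posterior_smoothing",
    "expected_markov_stats",
    "accumulate_stats",
    "update_initial_probs",
    "update_generator_closed_form",
    "update_beta_newton",
    "fit_em",
    "held_out_loglik",
    "initialize_params",
]

_LOG_ZERO = -1e30


def _logsumexp(a: np.ndarray, axis: int | None = None):
    """Minimal log-sum-exp (scipy's adds substantial per-call overhead)."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(under="ignore"):
        out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out if axis is not None else float(out)

# spectral fast path: smallest admissible pairwise eigenvalue gap (relative)
# and largest admissible eigenvector condition number
_EVD_MIN_GAP = 1e-6
_EVD_MAX_COND = 1e8


# ---------------------------------------------------------------------------
# Sufficient statistics container
# ---------------------------------------------------------------------------


@dataclass
class SufficientStats:
    """Expected Markov-jump statistics accumulated over a cohort.

    ``dwell``/``jumps`` are cohort totals; ``per_patient_dwell`` /
    ``per_patient_jumps`` keep the per-patient breakdown needed by the
    covariate (Newton) update, aligned with ``covariates``.
    """

    dwell: np.ndarray              # (M,) expected years in each state
    jumps: np.ndarray              # (n_edges,) expected transition counts
    start_post: np.ndarray         # (M,) summed first-visit posteriors
    obs_post: list                 # per patient (T, M) posteriors / indicators
    per_patient_dwell: np.ndarray  # (N, M)
    per_patient_jumps: np.ndarray  # (N, n_edges)
    covariates: np.ndarray         # (N, L)
    loglik: float = 0.0


@dataclass
class FitResult:
    """Outcome of an EM fit."""

    params: ModelParams
    loglik_trace: np.ndarray
    decoded: dict[str, np.ndarray]
    converged: bool
    n_iter: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# Per-generator workspace: transition matrices + weighted count integrals
# ---------------------------------------------------------------------------


class _GeneratorWorkspace:
    """Caches spectral data and interval quantities for one generator."""

    def __init__(self, q: np.ndarray):
        self.q = q
        self._a_cache: dict[float, np.ndarray] = {}
        self._hard_cache: dict[tuple[float, int, int], np.ndarray] = {}
        self.use_evd = False
        try:
            lam, u = np.linalg.eig(q)
            scale = max(1.0, float(np.max(np.abs(lam))))
            gaps = np.abs(lam[:, None] - lam[None, :])
            np.fill_diagonal(gaps, np.inf)
            if np.min(gaps) > _EVD_MIN_GAP * scale and np.linalg.cond(u) < _EVD_MAX_COND:
                self.lam = lam
                self.u = u
                self.uinv = np.linalg.inv(u)
                self.use_evd = True
        except np.linalg.LinAlgError:
            pass

    def trans(self, delta: float) -> np.ndarray:
        a = self._a_cache.get(delta)
        if a is None:
            if self.use_evd:
                a = (self.u * np.exp(self.lam * delta)) @ self.uinv
                a = np.maximum(a.real, 0.0)
                a /= a.sum(axis=1, keepdims=True)
            else:
                a = transition_matrix(GeneratorMatrix(self.q), delta)
            self._a_cache[delta] = a
        return a

    def _phi(self, delta: float) -> np.ndarray:
        """Divided-difference kernel G[a,b] = (e^{la d} - e^{lb d})/(la - lb)."""
        lam = self.lam
        e = np.exp(lam * delta)
        diff = lam[:, None] - lam[None, :]
        np.fill_diagonal(diff, 1.0)  # placeholder, diagonal overwritten
        g = (e[:, None] - e[None, :]) / diff
        np.fill_diagonal(g, delta * e)
        return g

    def weighted_counts(self, delta: float, w: np.ndarray) -> np.ndarray:
        """C[i,j] = sum_{s,e} W[s,e] * I(E_ij)[s,e] for weight matrix W."""
        if self.use_evd:
            h = (self.u.T @ w @ self.uinv.T) * self._phi(delta)
            c = (self.uinv.T @ h @ self.u.T).real
        else:
            c = expm_frechet(delta * self.q.T, delta * w, compute_expm=False)
        return np.maximum(c, 0.0)

    def hard_counts(self, delta: float, s: int, e: int) -> np.ndarray:
        """Counts conditioned on endpoints (s, e), 0-based, cached."""
        key = (delta, s, e)
        c = self._hard_cache.get(key)
        if c is None:
            a = self.trans(delta)
            if a[s, e] <= 0:
                raise ValidationError(
                    f"endpoint pair ({s + 1},{e + 1}) has zero probability at delta={delta}"
                )
            w = np.zeros_like(self.q)
            w[s, e] = 1.0 / a[s, e]
            c = self.weighted_counts(delta, w)
            self._hard_cache[key] = c
        return c

    # -- batched forms over many intervals (the hot path of the E-step) ----

    def trans_batch(self, deltas: np.ndarray) -> np.ndarray:
        """(n, M, M) stack of transition matrices for a delta vector."""
        if self.use_evd:
            e = np.exp(np.multiply.outer(deltas, self.lam))   # (n, M)
            a = np.einsum("ab,nb,bc->nac", self.u, e, self.uinv)
            a = np.maximum(a.real, 0.0)
            a /= a.sum(axis=2, keepdims=True)
            return a
        return np.stack([self.trans(float(d)) for d in deltas])

    def _phi_batch(self, deltas: np.ndarray) -> np.ndarray:
        lam = self.lam
        e = np.exp(np.multiply.outer(deltas, lam))            # (n, M)
        diff = lam[:, None] - lam[None, :]
        np.fill_diagonal(diff, 1.0)
        g = (e[:, :, None] - e[:, None, :]) / diff[None, :, :]
        idx = np.arange(lam.size)
        g[:, idx, idx] = deltas[:, None] * e
        return g

    def hard_counts_batch(self, deltas: np.ndarray, starts: np.ndarray,
                          ends: np.ndarray, a_batch: np.ndarray) -> np.ndarray:
        """(n, M, M) weighted-count tables for endpoint-conditioned
        intervals; `starts`/`ends` are 0-based Viterbi endpoints."""
        if not self.use_evd:
            out = np.empty((deltas.size, *self.q.shape))
            for n, (d, s, e) in enumerate(zip(deltas, starts, ends)):
                out[n] = self.hard_counts(float(d), int(s), int(e))
            return out
        denom = a_batch[np.arange(deltas.size), starts, ends]
        if np.any(denom <= 0):
            bad = int(np.argmax(denom <= 0))
            raise ValidationError(
                f"endpoint pair ({starts[bad] + 1},{ends[bad] + 1}) has zero "
                f"probability at delta={deltas[bad]}")
        # (U^T e_s e_e^T Uinv^T)[a,b] = U[s,a] * Uinv[b,e]
        p = (self.u[starts][:, :, None] * self.uinv.T[ends][:, None, :]
             / denom[:, None, None])
        h = p * self._phi_batch(deltas)
        c = np.einsum("ai,nab,jb->nij", self.uinv, h, self.u).real
        return np.maximum(c, 0.0)

    def soft_counts_batch(self, deltas: np.ndarray, w_batch: np.ndarray) -> np.ndarray:
        """(n, M, M) count tables for endpoint-weight matrices W."""
        if not self.use_evd:
            out = np.empty_like(w_batch)
            for n, (d, w) in enumerate(zip(deltas, w_batch)):
                out[n] = self.weighted_counts(float(d), w)
            return out
        h = np.einsum("sa,nse,be->nab", self.u, w_batch, self.uinv)
        h = h * self._phi_batch(deltas)
        c = np.einsum("ai,nab,jb->nij", self.uinv, h, self.u).real
        return np.maximum(c, 0.0)


def expected_markov_stats(
    start: int,
    end: int,
    delta: float,
    q: GeneratorMatrix,
    structure: TransitionStructure | None = None,
) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
    """Endpoint-conditioned expected dwell times and jump counts.

    Given that the process is in ``start`` at time 0 and ``end`` at time
    ``delta`` (both 1-based), returns the expected time spent in each state
    (sums to ``delta``) and the expected number of jumps on each edge.

    Raises :class:`ValidationError` when the endpoint pair has zero
    probability under ``expm(delta Q)``.
    """
    m = q.n_states
    if not (1 <= start <= m and 1 <= end <= m):
        raise ValidationError("start/end outside state range")
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    ws = _GeneratorWorkspace(q.rates)
    c = ws.hard_counts(float(delta), start - 1, end - 1)
    dwell = np.diag(c).copy()
    if structure is None:
        edges = [(i + 1, j + 1) for i in range(m) for j in range(m) if i != j and q.rates[i, j] > 0]
    else:
        edges = list(structure.edges)
    jumps = {(i, j): float(q.rates[i - 1, j - 1] * c[i - 1, j - 1]) for i, j in edges}
    return dwell, jumps


# ---------------------------------------------------------------------------
# Decoding and smoothing
# ---------------------------------------------------------------------------


def _interval_log_transitions(record: PatientRecord, params: ModelParams,
                              ws: _GeneratorWorkspace) -> np.ndarray:
    """(T-1, M, M) stack of log A(delta_t) for the record's intervals."""
    deltas = np.diff(record.times)
    mats = np.empty((deltas.size, params.structure.n_states, params.structure.n_states))
    for t, d in enumerate(deltas):
        a = ws.trans(float(d))
        with np.errstate(divide="ignore"):
            mats[t] = np.where(a > 0, np.log(np.maximum(a, 1e-300)), _LOG_ZERO)
    return mats


def _workspace_for(record: PatientRecord, params: ModelParams,
                   cache: dict | None = None) -> _GeneratorWorkspace:
    key = record.covariates.values.tobytes()
    if cache is not None and key in cache:
        return cache[key]
    q = params.generator_for(record.covariates)
    ws = _GeneratorWorkspace(q.rates)
    if cache is not None:
        cache[key] = ws
    return ws


def viterbi_decode(record: PatientRecord, params: ModelParams,
                   _cache: dict | None = None) -> np.ndarray:
    """Most probable hidden state sequence for one patient (1-based).

    Ties are broken toward the lower state index (``argmax`` keeps the
    first maximizer).
    """
    if record.n_features != params.emissions.n_features:
        raise ValidationError("record feature count != emission model")
    em = emission_loglik_matrix(record.features, params.emissions)
    with np.errstate(divide="ignore"):
        logpi = np.where(params.initial.probs > 0,
                         np.log(np.maximum(params.initial.probs, 1e-300)), _LOG_ZERO)
    if record.n_visits == 1:
        la = np.zeros((0, logpi.size, logpi.size))
    else:
        ws = _workspace_for(record, params, _cache)
        la = _interval_log_transitions(record, params, ws)
    states, _ = _viterbi_forward(logpi, em, la)
    return states + 1


def posterior_smoothing(record: PatientRecord, params: ModelParams,
                        _cache: dict | None = None
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward-backward smoothing for one patient.

    Returns the (T, M) visit-state posteriors, the (T-1, M, M) pairwise
    posteriors of consecutive visit states, and the observed-data
    log-likelihood of the record.  All recursions run in log space.
    """
    if record.n_features != params.emissions.n_features:
        raise ValidationError("record feature count != emission model")
    em = emission_loglik_matrix(record.features, params.emissions)
    with np.errstate(divide="ignore"):
        logpi = np.where(params.initial.probs > 0,
                         np.log(np.maximum(params.initial.probs, 1e-300)), _LOG_ZERO)
    if record.n_visits == 1:
        la = np.zeros((0, logpi.size, logpi.size))
    else:
        ws = _workspace_for(record, params, _cache)
        la = _interval_log_transitions(record, params, ws)
    post, pair, ll = _smooth(logpi, em, la)
    if not np.isfinite(ll):
        raise ValidationError(f"patient {record.patient_id}: non-finite log-likelihood")
    return post, pair, ll


def _viterbi_forward(logpi: np.ndarray, em: np.ndarray,
                     la: np.ndarray) -> tuple[np.ndarray, float]:
    """Viterbi path (0-based) and forward log-likelihood from precomputed
    emission and interval log-transition stacks."""
    t_n = em.shape[0]
    m = logpi.size
    if t_n == 1:
        la0 = logpi + em[0]
        return np.array([int(np.argmax(la0))]), _logsumexp(la0)
    score = logpi + em[0]
    alpha = logpi + em[0]
    back = np.zeros((t_n - 1, m), dtype=np.intp)
    for t in range(1, t_n):
        cand = score[:, None] + la[t - 1]
        back[t - 1] = np.argmax(cand, axis=0)
        score = cand[back[t - 1], np.arange(m)] + em[t]
        alpha = _logsumexp(alpha[:, None] + la[t - 1], axis=0) + em[t]
    states = np.empty(t_n, dtype=np.intp)
    states[-1] = int(np.argmax(score))
    for t in range(t_n - 2, -1, -1):
        states[t] = back[t, states[t + 1]]
    return states, float(_logsumexp(alpha))


def _smooth(logpi: np.ndarray, em: np.ndarray,
            la: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward-backward posteriors and log-likelihood from precomputed
    emission and interval log-transition stacks."""
    t_n = em.shape[0]
    m = logpi.size
    if t_n == 1:
        la0 = logpi + em[0]
        ll = _logsumexp(la0)
        post = np.exp(la0 - ll)[None, :]
        return post, np.zeros((0, m, m)), ll
    alpha = np.empty((t_n, m))
    alpha[0] = logpi + em[0]
    for t in range(1, t_n):
        alpha[t] = _logsumexp(alpha[t - 1][:, None] + la[t - 1], axis=0) + em[t]
    ll = float(_logsumexp(alpha[-1]))
    beta = np.empty((t_n, m))
    beta[-1] = 0.0
    for t in range(t_n - 2, -1, -1):
        beta[t] = _logsumexp(la[t] + (em[t + 1] + beta[t + 1])[None, :], axis=1)
    post = np.exp(alpha + beta - ll)
    post /= post.sum(axis=1, keepdims=True)
    pair = np.empty((t_n - 1, m, m))
    for t in range(t_n - 1):
        p = np.exp(alpha[t][:, None] + la[t] + (em[t + 1] + beta[t + 1])[None, :] - ll)
        pair[t] = p / p.sum()
    return post, pair, ll


# ---------------------------------------------------------------------------
# E-step accumulation
# ---------------------------------------------------------------------------


def accumulate_stats(cohort: Sequence[PatientRecord], params: ModelParams,
                     mode: Literal["hard", "soft"] = "hard") -> SufficientStats:
    """Expected (or Viterbi-conditioned) sufficient statistics for a cohort.

    ``hard`` conditions every interval on its decoded Viterbi endpoints;
    ``soft`` weights all endpoint pairs by the pairwise smoothing
    posteriors.  Patients with a single visit contribute only to the
    initial distribution, the emission posteriors and the log-likelihood.
    """
    if mode not in ("hard", "soft"):
        raise ValidationError(f"mode must be 'hard' or 'soft', got {mode!r}")
    structure = params.structure
    m = structure.n_states
    rows, cols = structure.edge_arrays()
    n = len(cohort)
    l_dim = cohort[0].covariates.n_covariates if n else 0
    stats = SufficientStats(
        dwell=np.zeros(m),
        jumps=np.zeros(structure.n_edges),
        start_post=np.zeros(m),
        obs_post=[None] * n,
        per_patient_dwell=np.zeros((n, m)),
        per_patient_jumps=np.zeros((n, structure.n_edges)),
        covariates=np.zeros((n, l_dim)),
    )
    # group patients sharing a covariate vector: one generator (and one
    # spectral decomposition) per distinct Z
    groups: dict[bytes, list[int]] = {}
    for idx, rec in enumerate(cohort):
        stats.covariates[idx] = rec.covariates.values
        groups.setdefault(rec.covariates.values.tobytes(), []).append(idx)
    total_ll = 0.0
    with np.errstate(divide="ignore"):
        logpi = np.where(params.initial.probs > 0,
                         np.log(np.maximum(params.initial.probs, 1e-300)), _LOG_ZERO)
    for members in groups.values():
        ws = _GeneratorWorkspace(
            params.generator_for(cohort[members[0]].covariates).rates)
        # flatten all intervals of the group
        deltas, owner = [], []
        for idx in members:
            d = np.diff(cohort[idx].times)
            deltas.append(d)
            owner.append(np.full(d.size, idx, dtype=np.intp))
        deltas = (np.concatenate(deltas) if deltas else np.zeros(0))
        owner = (np.concatenate(owner) if owner else np.zeros(0, dtype=np.intp))
        a_all = ws.trans_batch(deltas) if deltas.size else np.zeros((0, m, m))
        with np.errstate(divide="ignore"):
            la_all = np.where(a_all > 0,
                              np.log(np.maximum(a_all, 1e-300)), _LOG_ZERO)
        # per-patient dynamic programs on slices of the shared stacks
        pos = 0
        starts = np.empty(deltas.size, dtype=np.intp)
        ends = np.empty(deltas.size, dtype=np.intp)
        w_soft = (np.empty((deltas.size, m, m)) if mode == "soft" else None)
        for idx in members:
            rec = cohort[idx]
            t_n = rec.n_visits
            la = la_all[pos:pos + t_n - 1]
            em = emission_loglik_matrix(rec.features, params.emissions)
            if mode == "hard":
                path0, ll = _viterbi_forward(logpi, em, la)
                post = np.zeros((t_n, m))
                post[np.arange(t_n), path0] = 1.0
                starts[pos:pos + t_n - 1] = path0[:-1]
                ends[pos:pos + t_n - 1] = path0[1:]
            else:
                post, pair, ll = _smooth(logpi, em, la)
                a_slice = a_all[pos:pos + t_n - 1]
                w = np.zeros_like(pair)
                mask = (pair > 0) & (a_slice > 0)
                w[mask] = pair[mask] / a_slice[mask]
                w_soft[pos:pos + t_n - 1] = w
            if not np.isfinite(ll):
                raise ValidationError(
                    f"patient {rec.patient_id}: non-finite log-likelihood")
            total_ll += ll
            stats.obs_post[idx] = post
            stats.start_post += post[0]
            pos += t_n - 1
        if deltas.size:
            if mode == "hard":
                c_all = ws.hard_counts_batch(deltas, starts, ends, a_all)
            else:
                c_all = ws.soft_counts_batch(deltas, w_soft)
            idx_m = np.arange(m)
            np.add.at(stats.per_patient_dwell, owner, c_all[:, idx_m, idx_m])
            np.add.at(stats.per_patient_jumps, owner,
                      ws.q[rows, cols] * c_all[:, rows, cols])
    stats.dwell = stats.per_patient_dwell.sum(axis=0)
    stats.jumps = stats.per_patient_jumps.sum(axis=0)
    stats.loglik = total_ll
    return stats


# ---------------------------------------------------------------------------
# M-step updates
# ---------------------------------------------------------------------------


def update_initial_probs(stats: SufficientStats) -> InitialDistribution:
    """Normalize the summed first-visit posteriors into pi."""
    total = stats.start_post.sum()
    if np.any(stats.start_post < 0) or total <= 0:
        raise ValidationError("start_post must be non-negative with positive total")
    return InitialDistribution(stats.start_post / total)


def update_generator_closed_form(
    stats: SufficientStats,
    structure: TransitionStructure,
    rate_floor: float = RATE_FLOOR,
) -> GeneratorMatrix:
    """Covariate-free maximum-likelihood generator: jumps / dwell per edge.

    When an edge has no expected jumps (or its source state no dwell) the
    rate is set to ``rate_floor`` instead of 0, keeping the generator's
    support intact for the next E-step.
    """
    m = structure.n_states
    q = np.zeros((m, m))
    for k, (i, j) in enumerate(structure.edges):
        d = stats.dwell[i - 1]
        nij = stats.jumps[k]
        q[i - 1, j - 1] = nij / d if (d > 0 and nij > 0) else rate_floor
    q[np.arange(m), np.arange(m)] = -q.sum(axis=1)
    return GeneratorMatrix(q)


def _normalize_patient_stats(
    stats_per_patient,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a cohort SufficientStats or an iterable of (stats, Z) pairs."""
    if isinstance(stats_per_patient, SufficientStats):
        s = stats_per_patient
        return s.per_patient_dwell, s.per_patient_jumps, s.covariates
    dwell, jumps, zs = [], [], []
    for s, z in stats_per_patient:
        dwell.append(np.asarray(s.dwell, dtype=float))
        jumps.append(np.asarray(s.jumps, dtype=float))
        zs.append(z.values if isinstance(z, CovariateVector) else np.asarray(z, dtype=float))
    return np.stack(dwell), np.stack(jumps), np.stack(zs)


def beta_objective(bmat: np.ndarray, dwell: np.ndarray, jumps: np.ndarray,
                   zs: np.ndarray, structure: TransitionStructure,
                   clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE) -> float:
    """Expected complete-data transition log-likelihood (up to constants).

    sum_n sum_(i,j) [ jumps_n,ij * (beta_ij . Z_n) - dwell_n,i * exp(beta_ij . Z_n) ].
    """
    total = 0.0
    for k, (i, _) in enumerate(structure.edges):
        eta = np.clip(zs @ bmat[k], clip_range[0], clip_range[1])
        total += float(np.sum(jumps[:, k] * eta - dwell[:, i - 1] * np.exp(eta)))
    return total


def update_beta_newton(
    stats_per_patient,
    beta0: BetaParams,
    structure: TransitionStructure,
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE,
    grad_tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 1e-8,
) -> BetaParams:
    """Maximize the expected transition log-likelihood over beta.

    The objective separates across edges; each edge's block is concave, so
    a damped Newton iteration (step-halving line search, at most 20
    halvings, ridge-regularized near-singular Hessians, gradient-ascent
    fallback) converges when the gradient infinity-norm drops below
    ``grad_tol``.
    """
    dwell, jumps, zs = _normalize_patient_stats(stats_per_patient)
    bmat = beta0.matrix(structure).copy()
    lo, hi = clip_range
    for k, (i, _) in enumerate(structure.edges):
        d_i = dwell[:, i - 1]
        n_k = jumps[:, k]
        if n_k.sum() == 0 and d_i.sum() == 0:
            continue  # edge carries no information; keep initialization

        def obj(b):
            eta = np.clip(zs @ b, lo, hi)
            return float(np.sum(n_k * eta - d_i * np.exp(eta)))

        b = bmat[k]
        f = obj(b)
        for _ in range(max_iter):
            eta = np.clip(zs @ b, lo, hi)
            r = d_i * np.exp(eta)
            grad = zs.T @ (n_k - r)
            if np.max(np.abs(grad)) < grad_tol:
                break
            hess = -(zs.T * r) @ zs
            try:
                step = np.linalg.solve(-hess + ridge * np.eye(b.size), grad)
            except np.linalg.LinAlgError:
                step = grad
            improved = False
            t = 1.0
            for _ in range(20):
                cand = b + t * step
                fc = obj(cand)
                if fc > f:
                    b, f = cand, fc
                    improved = True
                    break
                t *= 0.5
            if not improved:
                # gradient ascent with line search as a last resort
                t = 1.0 / max(1.0, float(np.max(np.abs(grad))))
                for _ in range(30):
                    cand = b + t * grad
                    fc = obj(cand)
                    if fc > f:
                        b, f = cand, fc
                        improved = True
                        break
                    t *= 0.5
            if not improved:
                break
        bmat[k] = b
    return BetaParams.from_matrix(bmat, structure)


def _update_emissions(cohort: Sequence[PatientRecord],
                      stats: SufficientStats,
                      emissions: EmissionParams) -> EmissionParams:
    """Posterior-weighted Gaussian moments per state-feature, NaN-aware."""
    m, k = emissions.n_states, emissions.n_features
    wsum = np.zeros((m, k))
    wx = np.zeros((m, k))
    wx2 = np.zeros((m, k))
    for rec, post in zip(cohort, stats.obs_post):
        x = rec.features
        obs = ~np.isnan(x)
        x0 = np.where(obs, x, 0.0)
        for s in range(m):
            w = post[:, s][:, None] * obs
            wsum[s] += w.sum(axis=0)
            wx[s] += (post[:, s][:, None] * x0 * obs).sum(axis=0)
            wx2[s] += (post[:, s][:, None] * x0**2 * obs).sum(axis=0)
    means = np.where(wsum > 0, wx / np.maximum(wsum, 1e-300), emissions.means)
    var = np.where(
        wsum > 0,
        wx2 / np.maximum(wsum, 1e-300) - means**2,
        emissions.variances,
    )
    return EmissionParams(means, np.maximum(var, VARIANCE_FLOOR), frozen=False)


# ---------------------------------------------------------------------------
# Outer EM loop
# ---------------------------------------------------------------------------


def fit_em(
    cohort: Sequence[PatientRecord],
    init: ModelParams,
    mode: Literal["hard", "soft"] = "hard",
    freeze_emissions: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    newton_kwargs: dict | None = None,
) -> FitResult:
    """Alternate E-step statistics with pi / beta (/ emission) updates.

    The trace records the observed-data log-likelihood of the parameters
    entering each iteration; in ``soft`` mode it is non-decreasing up to
    numerical noise.  Convergence is declared when the relative
    log-likelihood change drops below ``tol``.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    params = init
    trace: list[float] = []
    converged = False
    nk = newton_kwargs or {}
    for it in range(max_iter):
        stats = accumulate_stats(cohort, params, mode)
        trace.append(stats.loglik)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
        new_pi = update_initial_probs(stats)
        new_beta = update_beta_newton(stats, params.beta, params.structure,
                                      params.clip_range, **nk)
        new_em = (params.emissions if (freeze_emissions or params.emissions.frozen)
                  else _update_emissions(cohort, stats, params.emissions))
        params = ModelParams(params.structure, new_beta, new_em, new_pi, params.clip_range)
    cache: dict = {}
    decoded = {rec.patient_id: viterbi_decode(rec, params, cache) for rec in cohort}
    return FitResult(
        params=params,
        loglik_trace=np.asarray(trace),
        decoded=decoded,
        converged=converged,
        n_iter=len(trace),
        seed=seed,
    )


def held_out_loglik(cohort: Sequence[PatientRecord], params: ModelParams) -> float:
    """Observed-data log-likelihood of a held-out cohort (0 when empty)."""
    cache: dict = {}
    return float(sum(posterior_smoothing(rec, params, cache)[2] for rec in cohort))


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _uniform_initial(m: int) -> InitialDistribution:
    return InitialDistribution(np.full(m, 1.0 / m))


def initialize_params(
    cohort: Sequence[PatientRecord],
    structure: TransitionStructure,
    emissions: EmissionParams,
    strategy: Literal["random", "two_step"] = "random",
    n_restarts: int = 5,
    short_iters: int = 10,
    seed: int = 0,
    mode: Literal["hard", "soft"] = "hard",
    initial: InitialDistribution | None = None,
) -> ModelParams:
    """Multi-restart / per-covariate initialization of the transition model.

    ``random`` draws each restart's coefficients from a standard normal,
    runs a short EM burn-in, and keeps the candidate with the highest
    log-likelihood.  ``two_step`` fits one single-covariate model per
    covariate (that covariate plus the intercept) and assembles the full
    coefficient matrix from the per-covariate fits, averaging intercepts —
    appropriate when the covariates are close to mutually independent.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    l_dim = cohort[0].covariates.n_covariates
    pi0 = initial if initial is not None else _uniform_initial(structure.n_states)
    rng = np.random.default_rng(seed)
    if strategy == "random":
        best: tuple[float, ModelParams] | None = None
        for _ in range(max(1, n_restarts)):
            bmat = rng.standard_normal((structure.n_edges, l_dim))
            cand = ModelParams(structure, BetaParams.from_matrix(bmat, structure),
                               emissions, pi0)
            fit = fit_em(cohort, cand, mode=mode, freeze_emissions=True,
                         max_iter=max(1, short_iters), tol=0.0)
            ll = float(fit.loglik_trace[-1])
            if best is None or ll > best[0]:
                best = (ll, fit.params)
        return best[1]
    if strategy == "two_step":
        labels = cohort[0].covariates.labels
        per_cov: dict[int, np.ndarray] = {}
        intercepts = []
        for c in range(l_dim - 1):
            sub = [
                PatientRecord(
                    rec.patient_id, rec.times, rec.features,
                    CovariateVector(
                        np.array([rec.covariates.values[c], 1.0]),
                        (labels[c], labels[-1]),
                    ),
                )
                for rec in cohort
            ]
            bmat = np.zeros((structure.n_edges, 2))
            cand = ModelParams(structure, BetaParams.from_matrix(bmat, structure),
                               emissions, pi0)
            fit = fit_em(sub, cand, mode=mode, freeze_emissions=True,
                         max_iter=max(1, short_iters), tol=0.0)
            fitted = fit.params.beta.matrix(structure)
            per_cov[c] = fitted[:, 0]
            intercepts.append(fitted[:, 1])
        full = np.zeros((structure.n_edges, l_dim))
        for c, col in per_cov.items():
            full[:, c] = col
        if intercepts:
            full[:, -1] = np.mean(np.stack(intercepts), axis=0)
        return ModelParams(structure, BetaParams.from_matrix(full, structure),
                           emissions, pi0)
    raise ValidationError(f"unknown initialization strategy {strategy!r}")
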