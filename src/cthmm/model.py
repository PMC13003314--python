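"""Core model objects for covariate-dependent continuous-time hidden Markov models.

The disease course of a patient is a Markov jump process on states
``1..M`` whose generator matrix ``Q`` is patient specific: each allowed
rate is log-linear in a static covariate vector ``Z``,

    log Q_ij = beta_ij . Z,

with the last coordinate of ``Z`` fixed to 1 so that the intercept is part
of the coefficient vector.  Observations are made at irregular visit
times; at a visit the K clinical features are conditionally independent
Gaussians given the hidden state.  Interval transition probabilities are
``A(delta) = expm(delta * Q)``.

State indices are 1-based in every user-facing structure (edges, decoded
sequences, serialized JSON) and 0-based only inside numerical kernels.
Missing feature values are ``NaN`` in memory and ``"NA"`` in files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ValidationError",
    "TransitionStructure",
    "CovariateVector",
    "BetaParams",
    "GeneratorMatrix",
    "EmissionParams",
    "InitialDistribution",
    "PatientRecord",
    "ModelParams",
    "allowed_edges",
    "build_generator",
    "transition_matrix",
    "emission_loglik",
    "emission_loglik_matrix",
    "DEFAULT_CLIP_RANGE",
    "VARIANCE_FLOOR",
    "RATE_FLOOR",
]

#: Linear predictor beta.Z is clipped to this range before exponentiation so
#: transient Newton overshoots cannot overflow/underflow the rates.
DEFAULT_CLIP_RANGE = (-30.0, 10.0)

#: Per-state, per-feature emission variances never drop below this floor.
VARIANCE_FLOOR = 1e-6

#: Rate assigned by the closed-form generator update when an edge has no
#: expected jumps (or a state no expected dwell).
RATE_FLOOR = 1e-10

SCHEMA_VERSION = "1.0"


class ValidationError(ValueError):
    """Raised when inputs violate a documented model contract."""


# ---------------------------------------------------------------------------
# Transition structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionStructure:
    """Allowed directed transitions of a forward-progression state graph.

    Parameters
    ----------
    n_states
        Number of hidden states M (>= 2).
    max_hop
        Largest allowed forward jump ``j - i``.
    edges
        Lexicographically sorted tuple of allowed ``(i, j)`` pairs, 1-based.
    """

    n_states: int
    max_hop: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValidationError(f"n_states must be >= 2, got {self.n_states}")
        if not self.edges:
            raise ValidationError("edge list is empty")
        seen = set()
        for i, j in self.edges:
            if not (1 <= i <= self.n_states and 1 <= j <= self.n_states):
                raise ValidationError(f"edge ({i},{j}) outside 1..{self.n_states}")
            if i == j:
                raise ValidationError(f"self-edge ({i},{j}) not allowed")
            if (i, j) in seen:
                raise ValidationError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
        if tuple(sorted(self.edges)) != self.edges:
            raise ValidationError("edges must be sorted lexicographically")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_index(self) -> dict[tuple[int, int], int]:
        """Map each 1-based edge to its position in the edge list."""
        return {e: k for k, e in enumerate(self.edges)}

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based (row, col) index arrays of the allowed edges."""
        rows = np.array([i - 1 for i, _ in self.edges], dtype=np.intp)
        cols = np.array([j - 1 for _, j in self.edges], dtype=np.intp)
        return rows, cols


def allowed_edges(n_states: int, max_hop: int) -> TransitionStructure:
    """Enumerate forward transitions reachable within ``max_hop`` states.

    The default progression graph permits ``i -> j`` for ``i < j <= i + max_hop``;
    with 9 states and a two-hop limit this yields the 15 transition pairs of
    the Huntington's disease staging model.

    Examples
    --------
    >>> allowed_edges(9, 2).n_edges
    15
    """
    if not isinstance(n_states, (int, np.integer)) or not isinstance(max_hop, (int, np.integer)):
        raise ValidationError("n_states and max_hop must be integers")
    if n_states < 2:
        raise ValidationError(f"n_states must be >= 2, got {n_states}")
    if not (1 <= max_hop < n_states):
        raise ValidationError(f"max_hop must satisfy 1 <= max_hop < n_states, got {max_hop}")
    edges = tuple(
        (i, j)
        for i in range(1, n_states + 1)
        for j in range(i + 1, min(i + max_hop, n_states) + 1)
    )
    return TransitionStructure(int(n_states), int(max_hop), edges)


# ---------------------------------------------------------------------------
# Covariates and coefficients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateVector:
    """Static per-patient covariates with a trailing intercept coordinate."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("covariate vector must be 1-D and non-empty")
        if len(self.labels) != values.size:
            raise ValidationError("labels length must match values length")
        if not np.all(np.isfinite(values)):
            raise ValidationError("covariate values must be finite")
        if values[-1] != 1.0:
            raise ValidationError("last covariate coordinate must be the intercept 1")

    @property
    def n_covariates(self) -> int:
        return self.values.size


@dataclass
class BetaParams:
    """Per-edge coefficient vectors of the log-linear rate model."""

    coefficients: dict[tuple[int, int], np.ndarray]

    def __post_init__(self) -> None:
        coeffs = {tuple(e): np.asarray(v, dtype=float) for e, v in self.coefficients.items()}
        lengths = {v.size for v in coeffs.values()}
        if not coeffs:
            raise ValidationError("beta has no edges")
        if len(lengths) != 1:
            raise ValidationError(f"coefficient vectors differ in length: {sorted(lengths)}")
        for e, v in coeffs.items():
            if v.ndim != 1 or not np.all(np.isfinite(v)):
                raise ValidationError(f"coefficients for edge {e} must be finite 1-D")
        self.coefficients = coeffs

    @property
    def n_covariates(self) -> int:
        return next(iter(self.coefficients.values())).size

    def matrix(self, structure: TransitionStructure) -> np.ndarray:
        """Stack coefficients into an (n_edges, L) array in structure order."""
        missing = [e for e in structure.edges if e not in self.coefficients]
        if missing:
            raise ValidationError(f"beta missing edges {missing}")
        return np.stack([self.coefficients[e] for e in structure.edges])

    @classmethod
    def from_matrix(cls, mat: np.ndarray, structure: TransitionStructure) -> "BetaParams":
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] != structure.n_edges:
            raise ValidationError("coefficient matrix row count != number of edges")
        return cls({e: mat[k].copy() for k, e in enumerate(structure.edges)})

    @classmethod
    def constant(cls, structure: TransitionStructure, values: Sequence[float]) -> "BetaParams":
        """Same coefficient vector on every allowed edge."""
        v = np.asarray(values, dtype=float)
        return cls({e: v.copy() for e in structure.edges})


@dataclass(frozen=True)
class GeneratorMatrix:
    """Rate matrix Q of the Markov jump process: rows sum to zero."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", q)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValidationError("generator must be square")
        off = q - np.diag(np.diag(q))
        if np.any(off < -1e-12):
            raise ValidationError("off-diagonal rates must be non-negative")
        if np.max(np.abs(q.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(q))):
            raise ValidationError("generator rows must sum to zero")

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]


def build_generator(
    beta: BetaParams,
    z: CovariateVector,
    structure: TransitionStructure,
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE,
) -> GeneratorMatrix:
    """Assemble the patient-specific generator Q(beta, Z).

    Each allowed rate is ``exp(beta_ij . Z)`` with the linear predictor
    clipped to ``clip_range``; disallowed off-diagonals are zero and the
    diagonal is minus the row sum, so the final state of a forward
    structure is absorbing.
    """
    bmat = beta.matrix(structure)
    if bmat.shape[1] != z.n_covariates:
        raise ValidationError(
            f"beta has {bmat.shape[1]} covariates but Z has {z.n_covariates}"
        )
    eta = np.clip(bmat @ z.values, clip_range[0], clip_range[1])
    rates = np.exp(eta)
    m = structure.n_states
    q = np.zeros((m, m))
    rows, cols = structure.edge_arrays()
    q[rows, cols] = rates
    q[np.arange(m), np.arange(m)] = -q.sum(axis=1)
    return GeneratorMatrix(q)


def transition_matrix(q: GeneratorMatrix, delta: float) -> np.ndarray:
    """Interval transition probabilities ``A(delta) = expm(delta * Q)``.

    Uses scaling-and-squaring, which is robust to the defective spectra
    that forward generators with tied exit rates produce.  Tiny negative
    entries from round-off are clipped to zero and rows renormalized; a
    row-sum error above 1e-8 raises instead of being papered over.
    """
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    a = expm(float(delta) * q.rates)
    neg = a < 0
    if np.any(neg):
        if np.min(a) < -1e-8:
            raise ValidationError(f"expm produced entry {np.min(a):.3e} < -1e-8")
        a = np.where(neg, 0.0, a)
    row_sums = a.sum(axis=1)
    if np.max(np.abs(row_sums - 1.0)) > 1e-8:
        raise ValidationError("transition matrix rows deviate from 1 by > 1e-8")
    return a / row_sums[:, None]


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------


@dataclass
class EmissionParams:
    """Per-state Gaussian observation model over K features.

    ``frozen`` marks an emission model imported from a prior staging study
    and held fixed during EM, so that fitting only re-estimates the
    transition model on top of established disease states.
    """

    means: np.ndarray
    variances: np.ndarray
    frozen: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.means.shape != self.variances.shape or self.means.ndim != 2:
            raise ValidationError("means and variances must be equal-shape 2-D arrays")
        if np.any(self.variances < VARIANCE_FLOOR):
            raise ValidationError(f"variances must be >= {VARIANCE_FLOOR}")
        if not (np.all(np.isfinite(self.means)) and np.all(np.isfinite(self.variances))):
            raise ValidationError("emission parameters must be finite")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def emission_loglik(x: np.ndarray, state: int, emissions: EmissionParams) -> float:
    """Gaussian log-density of one feature row under a given state.

    Missing features (NaN) contribute nothing; an all-missing row returns 0
    by the empty-product convention.  ``state`` is 1-based.
    """
    if not 1 <= state <= emissions.n_states:
        raise ValidationError(f"state {state} outside 1..{emissions.n_states}")
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    if not np.any(obs):
        return 0.0
    mu = emissions.means[state - 1, obs]
    var = emissions.variances[state - 1, obs]
    resid = x[obs] - mu
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * var) + resid**2 / var))


def emission_loglik_matrix(features: np.ndarray, emissions: EmissionParams) -> np.ndarray:
    """(T, M) matrix of per-visit emission log-likelihoods, NaN-aware."""
    x = np.asarray(features, dtype=float)
    obs = ~np.isnan(x)
    x0 = np.where(obs, x, 0.0)
    mu = emissions.means  # (M, K)
    var = emissions.variances
    # residual^2 term only where observed
    resid2 = (x0[:, None, :] - mu[None, :, :]) ** 2 / var[None, :, :]
    lognorm = np.log(2.0 * np.pi * var)[None, :, :]
    contrib = -0.5 * (lognorm + resid2)
    return np.where(obs[:, None, :], contrib, 0.0).sum(axis=2)


# ---------------------------------------------------------------------------
# Initial distribution, patients, parameter bundle
# ---------------------------------------------------------------------------


@dataclass
class InitialDistribution:
    """Distribution pi over the hidden state at a patient's first visit."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        self.probs = p
        if p.ndim != 1 or np.any(p < 0):
            raise ValidationError("pi must be a non-negative vector")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(f"pi must sum to 1 within 1e-12, got {p.sum()!r}")

    @property
    def n_states(self) -> int:
        return self.probs.size


@dataclass
class PatientRecord:
    """One patient's longitudinal observations and static covariates."""

    patient_id: str
    times: np.ndarray
    features: np.ndarray
    covariates: CovariateVector

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.features, dtype=float)
        self.times = t
        self.features = x
        if t.ndim != 1 or t.size < 1:
            raise ValidationError(f"patient {self.patient_id}: needs >= 1 visit")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"patient {self.patient_id}: times must strictly increase")
        if not np.all(np.isfinite(t)):
            raise ValidationError(f"patient {self.patient_id}: non-finite visit time")
        if x.ndim != 2 or x.shape[0] != t.size:
            raise ValidationError(
                f"patient {self.patient_id}: features must be T x K with T = {t.size}"
            )

    @property
    def n_visits(self) -> int:
        return self.times.size

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class ModelParams:
    """Full parameter bundle Theta = (structure, beta, emissions, pi)."""

    structure: TransitionStructure
    beta: BetaParams
    emissions: EmissionParams
    initial: InitialDistribution
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE

    def __post_init__(self) -> None:
        m = self.structure.n_states
        if self.emissions.n_states != m:
            raise ValidationError("emission model state count != structure")
        if self.initial.n_states != m:
            raise ValidationError("pi length != number of states")
        self.beta.matrix(self.structure)  # validates edge coverage
        self.clip_range = (float(self.clip_range[0]), float(self.clip_range[1]))

    @property
    def covariate_labels(self) -> tuple[str, ...] | None:
        return getattr(self, "_covariate_labels", None)

    def generator_for(self, z: CovariateVector) -> GeneratorMatrix:
        return build_generator(self.beta, z, self.structure, self.clip_range)

    # -- serialization ------------------------------------------------------

    def to_dict(self, covariate_labels: Sequence[str] | None = None) -> dict:
        return {
            "version": SCHEMA_VERSION,
            "n_states": self.structure.n_states,
            "max_hop": self.structure.max_hop,
            "edges": [list(e) for e in self.structure.edges],
            "beta": {
                f"{i}->{j}": self.beta.coefficients[(i, j)].tolist()
                for i, j in self.structure.edges
            },
            "covariate_labels": list(covariate_labels) if covariate_labels else None,
            "means": self.emissions.means.tolist(),
            "variances": self.emissions.variances.tolist(),
            "frozen": bool(self.emissions.frozen),
            "pi": self.initial.probs.tolist(),
            "clip_range": list(self.clip_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        structure = TransitionStructure(
            int(d["n_states"]), int(d["max_hop"]), tuple(tuple(e) for e in d["edges"])
        )
        beta = BetaParams(
            {tuple(map(int, k.split("->"))): np.asarray(v) for k, v in d["beta"].items()}
        )
        emissions = EmissionParams(
            np.asarray(d["means"]), np.asarray(d["variances"]), bool(d["frozen"])
        )
        initial = InitialDistribution(np.asarray(d["pi"]))
        params = cls(structure, beta, emissions, initial, tuple(d.get("clip_range", DEFAULT_CLIP_RANGE)))
        if d.get("covariate_labels"):
            params._covariate_labels = tuple(d["covariate_labels"])
        return params

    def to_json(self, path, covariate_labels: Sequence[str] | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(covariate_labels), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
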