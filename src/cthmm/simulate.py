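"""Synthetic clinico-genomic cohorts for the progression model.

Stands in for the access-restricted observational data: each simulated
patient has static genetic covariates (SNP dosages, a scaled CAG repeat
length, or custom draws), a latent forward Markov-jump trajectory through
the disease states generated by the Gillespie algorithm under the
patient's own log-linear generator, roughly annual visit times with
jittered gaps, and Gaussian clinical features emitted from the state
occupied at each visit.

The defaults mirror the study conditions the model targets: 9 disease
states with forward transitions up to two hops, 9 clinical features,
between 4 and 14 visits per patient at approximately annual intervals,
SNP dosages in {0, 1, 2}, and CAG repeat lengths on [40, 50] affinely
rescaled as (CAG - 40) / 10 before entering the rate model.  Patients
enter the cohort spread across early-to-middle disease states, as in
observational registries that enroll at any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

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
    allowed_edges,
    build_generator,
)

__all__ = [
    "CovariateSpec",
    "VisitSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "default_emissions",
    "default_config",
    "sample_covariates",
    "simulate_path",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate column.

    ``snp_dosage`` draws Binomial(2, maf); ``scaled_cag`` draws an integer
    CAG repeat length uniformly on ``cag_range`` and rescales it by
    ``(cag - cag_range[0]) / cag_scale``; ``binary`` draws Bernoulli(p);
    ``custom`` draws N(0, 1).  ``missing_rate`` masks that fraction of
    values, which are later mean-imputed before generator evaluation.
    """

    name: str
    kind: Literal["snp_dosage", "scaled_cag", "binary", "custom"] = "snp_dosage"
    maf: float = 0.3
    p: float = 0.5
    cag_range: tuple[int, int] = (40, 50)
    cag_scale: float = 10.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "snp_dosage" and not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"MAF must be in (0, 0.5], got {self.maf}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.kind == "scaled_cag" and self.cag_range[0] >= self.cag_range[1]:
            raise ValidationError("cag_range must be (low, high) with low < high")


@dataclass(frozen=True)
class VisitSpec:
    """Visit schedule: count range and jittered inter-visit gaps (years).

    Gaps are Gamma distributed with mean ``mean_gap`` and shape
    ``gap_shape`` (strictly positive, coefficient of variation
    ``1/sqrt(shape)``), mimicking approximately annual study visits.
    """

    min_visits: int = 4
    max_visits: int = 14
    mean_gap: float = 1.0
    gap_shape: float = 4.0
    jitter: bool = True

    def __post_init__(self) -> None:
        if self.min_visits < 1 or self.max_visits < self.min_visits:
            raise ValidationError("need 1 <= min_visits <= max_visits")
        if self.mean_gap <= 0 or self.gap_shape <= 0:
            raise ValidationError("gaps must be positive")


@dataclass
class SimulationConfig:
    n_patients: int
    structure: TransitionStructure
    true_beta: BetaParams
    true_emissions: EmissionParams
    covariate_spec: tuple[CovariateSpec, ...]
    visit_spec: VisitSpec = field(default_factory=VisitSpec)
    initial_probs: np.ndarray | None = None
    feature_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        self.covariate_spec = tuple(self.covariate_spec)
        if self.initial_probs is not None:
            p = np.asarray(self.initial_probs, dtype=float)
            if p.size != self.structure.n_states or np.any(p < 0):
                raise ValidationError("initial_probs must be a length-M non-negative vector")
            self.initial_probs = p / p.sum()


@dataclass
class SyntheticCohort:
    """Simulated records plus the latent ground truth behind them."""

    records: list[PatientRecord]
    true_paths: list[dict]  # per patient: jump_times, jump_states, visit_states
    config: SimulationConfig

    def true_params(self) -> ModelParams:
        cfg = self.config
        pi = cfg.initial_probs
        if pi is None:
            pi = _default_initial(cfg.structure.n_states)
        return ModelParams(cfg.structure, cfg.true_beta, cfg.true_emissions,
                           InitialDistribution(pi))


# ---------------------------------------------------------------------------
# Defaults emulating the study conditions
# ---------------------------------------------------------------------------


def _default_initial(m: int) -> np.ndarray:
    """Enrollment spread over all transient states, front-loaded.

    Observational registries enroll at any stage; weighting early states
    more (and the absorbing end-stage not at all) balances the expected
    number of traversals per allowed transition, so every edge of the
    forward graph is estimable from a cohort of a few hundred patients.
    The weights were chosen to maximize the minimum per-edge event count
    under the default rates.
    """
    w = np.concatenate([[3.5, 2.0, 1.4], np.ones(max(m - 5, 0)), [0.9]])[: m - 1]
    if m >= 7:
        w[4:-1] = 0.85
    p = np.concatenate([w, [0.0]])
    return p / p.sum()


def default_emissions(n_states: int = 9, n_features: int = 9,
                      separation: float = 1.0, variance: float = 0.25) -> EmissionParams:
    """Well-separated Gaussian observation model: feature means increase
    with disease state (severity drift), shared variance."""
    grid = separation * np.arange(n_states, dtype=float)[:, None]
    offsets = 0.1 * np.arange(n_features, dtype=float)[None, :]
    return EmissionParams(grid + offsets, np.full((n_states, n_features), variance),
                          frozen=True)


def default_config(n_patients: int = 300, seed: int = 0) -> SimulationConfig:
    """Study-scale defaults: 9 states, hop-2 forward edges, one SNP and a
    scaled CAG covariate, annual jittered visits, 4-14 visits/patient.

    Intercept rates of 0.4/yr (adjacent) and 0.2/yr (two-hop) give the
    slow multi-year staging typical of neurodegenerative progression; the
    CAG coefficient of +1 makes longer repeats accelerate every allowed
    transition, the SNP coefficient +0.5 a moderate modifier.
    """
    structure = allowed_edges(9, 2)
    bmat = np.zeros((structure.n_edges, 3))  # columns: snp, cag, intercept
    for k, (i, j) in enumerate(structure.edges):
        bmat[k, 2] = np.log(0.4) if j - i == 1 else np.log(0.2)
        bmat[k, 0] = 0.5
        bmat[k, 1] = 1.0
    return SimulationConfig(
        n_patients=n_patients,
        structure=structure,
        true_beta=BetaParams.from_matrix(bmat, structure),
        true_emissions=default_emissions(),
        covariate_spec=(
            CovariateSpec("snp1", kind="snp_dosage", maf=0.3),
            CovariateSpec("cag", kind="scaled_cag"),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Covariate sampling
# ---------------------------------------------------------------------------


def sample_covariates(spec: Sequence[CovariateSpec], n: int,
                      seed: int | np.random.Generator = 0) -> tuple[np.ndarray, list[str]]:
    """Draw the (n, L) covariate matrix, intercept appended last.

    Missing values (per ``missing_rate``) are NaN; callers impute before
    building generators.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = []
    labels = []
    for cs in spec:
        if cs.kind == "snp_dosage":
            col = rng.binomial(2, cs.maf, size=n).astype(float)
        elif cs.kind == "scaled_cag":
            cag = rng.integers(cs.cag_range[0], cs.cag_range[1] + 1, size=n)
            col = (cag - cs.cag_range[0]) / cs.cag_scale
        elif cs.kind == "binary":
            col = rng.binomial(1, cs.p, size=n).astype(float)
        elif cs.kind == "custom":
            col = rng.standard_normal(n)
        else:  # pragma: no cover
            raise ValidationError(f"unknown covariate kind {cs.kind!r}")
        if cs.missing_rate > 0:
            col = col.copy()
            col[rng.random(n) < cs.missing_rate] = np.nan
        cols.append(col)
        labels.append(cs.name)
    cols.append(np.ones(n))
    labels.append("intercept")
    return np.column_stack(cols), labels


def _mean_impute(mat: np.ndarray) -> np.ndarray:
    out = mat.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        miss = np.isnan(col)
        if miss.any():
            col[miss] = np.nanmean(col) if not miss.all() else 0.0
    return out


# ---------------------------------------------------------------------------
# Path and cohort simulation
# ---------------------------------------------------------------------------


def simulate_path(q: GeneratorMatrix, start: int, horizon: float,
                  seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie simulation of one trajectory from ``start`` (1-based).

    Returns ``(jump_times, states)`` where ``states[k]`` is occupied from
    ``jump_times[k]`` to ``jump_times[k+1]`` (or ``horizon``);
    ``jump_times[0] = 0``.  Holding times are Exponential(-Q_ss), the next
    state drawn proportionally to the outgoing rates; absorbing states end
    the path.
    """
    if horizon < 0:
        raise ValidationError("horizon must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = q.rates
    m = q.n_states
    times = [0.0]
    states = [start]
    t, s = 0.0, start - 1
    while True:
        exit_rate = -rates[s, s]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= horizon:
            break
        probs = rates[s].copy()
        probs[s] = 0.0
        probs = probs / probs.sum()
        s = int(rng.choice(m, p=probs))
        times.append(t)
        states.append(s + 1)
    return np.asarray(times), np.asarray(states, dtype=np.intp)


def state_at(jump_times: np.ndarray, states: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """State occupied at time(s) t given a jump trajectory."""
    idx = np.searchsorted(jump_times, np.atleast_1d(t), side="right") - 1
    return states[np.maximum(idx, 0)]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full generative pass: covariates, latent paths, visits, features."""
    rng = np.random.default_rng(config.seed)
    cov_rng, path_rng, visit_rng, noise_rng = rng.spawn(4)
    n = config.n_patients
    m = config.structure.n_states
    k_feat = config.true_emissions.n_features
    pi = config.initial_probs if config.initial_probs is not None else _default_initial(m)

    raw_cov, labels = sample_covariates(config.covariate_spec, n, cov_rng)
    imputed = _mean_impute(raw_cov)
    vs = config.visit_spec
    records: list[PatientRecord] = []
    truths: list[dict] = []
    for idx in range(n):
        z = CovariateVector(imputed[idx], tuple(labels))
        q = build_generator(config.true_beta, z, config.structure)
        n_visits = int(visit_rng.integers(vs.min_visits, vs.max_visits + 1))
        if vs.jitter:
            gaps = visit_rng.gamma(vs.gap_shape, vs.mean_gap / vs.gap_shape,
                                   size=n_visits - 1)
        else:
            gaps = np.full(n_visits - 1, vs.mean_gap)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        start = int(path_rng.choice(m, p=pi)) + 1
        horizon = float(times[-1]) + 1e-9
        jump_times, jump_states = simulate_path(q, start, horizon, path_rng)
        visit_states = state_at(jump_times, jump_states, times)
        features = (config.true_emissions.means[visit_states - 1]
                    + noise_rng.standard_normal((n_visits, k_feat))
                    * np.sqrt(config.true_emissions.variances[visit_states - 1]))
        if config.feature_missing_rate > 0:
            mask = noise_rng.random(features.shape) < config.feature_missing_rate
            features = np.where(mask, np.nan, features)
        records.append(PatientRecord(f"P{idx:05d}", times, features, z))
        truths.append({
            "patient_id": f"P{idx:05d}",
            "jump_times": jump_times.tolist(),
            "jump_states": jump_states.tolist(),
            "visit_states": visit_states.tolist(),
            "raw_covariates": raw_cov[idx].tolist(),
        })
    return SyntheticCohort(records, truths, config)
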