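"""Tabular / VCF input handling, cohort and SNP filters, run configuration.

File conventions: UTF-8 TSV with a header row, ``NA`` for missing values,
visit times in decimal years.  The observation table is long-format
(``patient_id``, ``time_years``, one column per clinical feature); the
covariate table has one row per patient (``patient_id`` plus one column
per covariate, intercept NOT stored — it is appended on read).

Filter conventions, recorded in each report:

* SNP filter — keep SNPs with empirical MAF strictly above ``maf_min``
  (MAF = min(p, 1-p) with p = mean dosage / 2 over non-missing calls) and
  per-SNP call rate of at least ``call_rate_min`` (a call-rate reading of
  the "missing value threshold": 0.7 means at most 30% missing calls).
* Cohort filter — keep patients with at least ``min_visits`` visits and
  CAG repeat length inside the inclusive ``cag_range``.

Remaining missing dosages after filtering are mean-imputed before model
fitting; imputation values are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    CovariateVector,
    ModelParams,
    PatientRecord,
    ValidationError,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "vcf_to_dosage",
    "filter_snps",
    "filter_cohort",
    "RunConfig",
    "write_bootstrap_tsv",
    "write_decoded_paths",
]

logger = logging.getLogger("cthmm")

NA = "NA"


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


def write_cohort(records: Sequence[PatientRecord], obs_path, cov_path) -> None:
    """Write the long-format observation TSV and the covariate TSV."""
    if not records:
        raise ValidationError("no records to write")
    k = records[0].n_features
    obs_rows = []
    for rec in records:
        for t in range(rec.n_visits):
            row = {"patient_id": rec.patient_id, "time_years": rec.times[t]}
            for f in range(k):
                row[f"f{f + 1}"] = rec.features[t, f]
            obs_rows.append(row)
    pd.DataFrame(obs_rows).to_csv(obs_path, sep="\t", index=False, na_rep=NA,
                                  float_format="%.10g")
    labels = records[0].covariates.labels[:-1]  # intercept not stored
    cov_rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id}
        for c, lab in enumerate(labels):
            row[lab] = rec.covariates.values[c]
        cov_rows.append(row)
    pd.DataFrame(cov_rows).to_csv(cov_path, sep="\t", index=False, na_rep=NA,
                                  float_format="%.10g")


def read_cohort(obs_path, cov_path) -> list[PatientRecord]:
    """Parse the two cohort tables into records, visits sorted by time.

    Every observation patient must appear in the covariate table; exact
    duplicate (patient, time) rows are an error.  The intercept column is
    appended to the covariates.
    """
    obs = pd.read_csv(obs_path, sep="\t", na_values=[NA], dtype={"patient_id": str})
    cov = pd.read_csv(cov_path, sep="\t", na_values=[NA], dtype={"patient_id": str})
    for name, frame, required in (("observation", obs, ("patient_id", "time_years")),
                                  ("covariate", cov, ("patient_id",))):
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"{name} table missing columns {missing}")
    feat_cols = [c for c in obs.columns if c not in ("patient_id", "time_years")]
    if not feat_cols:
        raise ValidationError("observation table has no feature columns")
    if obs["time_years"].isna().any() or not np.all(np.isfinite(obs["time_years"])):
        raise ValidationError("times must parse as finite reals")
    cov_labels = [c for c in cov.columns if c != "patient_id"]
    cov = cov.set_index("patient_id")
    if cov.index.duplicated().any():
        dups = cov.index[cov.index.duplicated()].tolist()
        raise ValidationError(f"duplicate covariate rows for patients {dups}")
    records = []
    for pid, grp in obs.groupby("patient_id", sort=True):
        if pid not in cov.index:
            raise ValidationError(f"patient {pid!r} has observations but no covariates")
        grp = grp.sort_values("time_years")
        times = grp["time_years"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"patient {pid!r}: duplicate or tied visit times")
        feats = grp[feat_cols].to_numpy(dtype=float)
        zvals = np.concatenate([cov.loc[pid, cov_labels].to_numpy(dtype=float), [1.0]])
        if np.any(np.isnan(zvals)):
            raise ValidationError(
                f"patient {pid!r}: missing covariate value; impute before reading"
            )
        z = CovariateVector(zvals, tuple(cov_labels) + ("intercept",))
        records.append(PatientRecord(str(pid), times, feats, z))
    return records


# ---------------------------------------------------------------------------
# VCF dosages
# ---------------------------------------------------------------------------


def vcf_to_dosage(vcf_path, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Additive allele dosages (0/1/2, NaN when uncalled) per sample.

    Returns a samples x SNPs DataFrame for the requested variant IDs;
    raises listing any requested ID absent from the file.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    wanted = list(snp_ids)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    found: dict[str, np.ndarray] = {}
    for var in vcf:
        if var.ID in wanted and var.ID not in found:
            gts = var.genotypes  # [allele0, allele1, phased]
            dosage = np.empty(len(samples))
            for s, gt in enumerate(gts):
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                dosage[s] = sum(1 for a in alleles if a > 0) if len(alleles) == 2 else np.nan
            found[var.ID] = dosage
    missing = [s for s in wanted if s not in found]
    if missing:
        raise ValidationError(f"variant IDs not found in VCF: {missing}")
    return pd.DataFrame({s: found[s] for s in wanted}, index=samples)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_snps(dosages: pd.DataFrame, maf_min: float = 0.05,
                call_rate_min: float = 0.7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNP columns with MAF <= ``maf_min`` or call rate < ``call_rate_min``.

    MAF uses non-missing calls only.  Returns the kept columns and a
    per-SNP report (maf, call_rate, kept, reason).
    """
    rows = []
    keep = []
    for col in dosages.columns:
        vals = dosages[col].to_numpy(dtype=float)
        called = ~np.isnan(vals)
        call_rate = called.mean() if vals.size else 0.0
        if called.any():
            p = vals[called].mean() / 2.0
            maf = min(p, 1.0 - p)
        else:
            maf = 0.0
        reasons = []
        if maf <= maf_min:
            reasons.append(f"MAF {maf:.4g} <= {maf_min}")
        if call_rate < call_rate_min:
            reasons.append(f"call rate {call_rate:.4g} < {call_rate_min}")
        kept = not reasons
        if kept:
            keep.append(col)
        rows.append({"snp": col, "maf": maf, "call_rate": call_rate,
                     "kept": kept, "reason": "; ".join(reasons)})
    report = pd.DataFrame(rows)
    logger.info("filter_snps kept %d/%d SNPs (maf_min=%g strict, call_rate_min=%g)",
                len(keep), dosages.shape[1], maf_min, call_rate_min)
    return dosages[keep], report


def filter_cohort(records: Sequence[PatientRecord], min_visits: int = 4,
                  cag_range: tuple[float, float] = (40.0, 50.0),
                  cag_label: str = "cag_repeats",
                  ) -> tuple[list[PatientRecord], dict]:
    """Keep patients with enough visits and CAG inside the inclusive range.

    Patients lacking the CAG covariate are only subject to the visit rule.
    The report gives per-rule exclusion counts.
    """
    kept = []
    n_few, n_cag = 0, 0
    for rec in records:
        ok = True
        if rec.n_visits < min_visits:
            n_few += 1
            ok = False
        if cag_label in rec.covariates.labels:
            cag = rec.covariates.values[rec.covariates.labels.index(cag_label)]
            if not (cag_range[0] <= cag <= cag_range[1]):
                n_cag += 1
                ok = False
        if ok:
            kept.append(rec)
    report = {
        "n_input": len(records),
        "n_kept": len(kept),
        "excluded_too_few_visits": n_few,
        "excluded_cag_out_of_range": n_cag,
        "min_visits": min_visits,
        "cag_range": list(cag_range),
    }
    logger.info("filter_cohort kept %d/%d patients", len(kept), len(records))
    return kept, report


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration for the command-line workflows."""

    n_states: int = 9
    max_hop: int = 2
    mode: str = "hard"
    freeze_emissions: bool = True
    tol: float = 1e-6
    max_iter: int = 200
    init_strategy: str = "random"
    n_restarts: int = 5
    short_iters: int = 10
    bootstrap_B: int = 100
    bootstrap_level: float = 0.95
    train_frac: float = 0.8
    maf_min: float = 0.05
    call_rate_min: float = 0.7
    min_visits: int = 4
    cag_range: tuple[float, float] = (40.0, 50.0)
    effect_threshold: float = 2.0
    display_threshold: float = 0.005
    n_patients: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValidationError(f"mode must be hard|soft, got {self.mode!r}")
        if self.init_strategy not in ("random", "two_step"):
            raise ValidationError(f"init_strategy must be random|two_step")
        for name, val, lo, hi in (
            ("tol", self.tol, 0.0, np.inf),
            ("bootstrap_level", self.bootstrap_level, 0.0, 1.0),
            ("train_frac", self.train_frac, 0.0, 1.0),
            ("maf_min", self.maf_min, 0.0, 0.5),
            ("call_rate_min", self.call_rate_min, 0.0, 1.0),
        ):
            if not (lo <= val <= hi):
                raise ValidationError(f"{name}={val} outside [{lo}, {hi}]")
        if self.n_states < 2 or not (1 <= self.max_hop < self.n_states):
            raise ValidationError("invalid n_states/max_hop")
        self.cag_range = (float(self.cag_range[0]), float(self.cag_range[1]))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load YAML or JSON; unknown keys are rejected by name."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValidationError("config must be a mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------


def write_bootstrap_tsv(calls, path) -> None:
    """Effect-call table: edge, covariate, beta_hat, ci bounds, call."""
    rows = [{
        "from_state": c.edge[0], "to_state": c.edge[1], "covariate": c.covariate,
        "beta_hat": c.beta_hat, "ci_lower": c.ci[0], "ci_upper": c.ci[1],
        "call": c.call,
    } for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_decoded_paths(decoded: dict[str, np.ndarray],
                        records: Sequence[PatientRecord], path) -> None:
    """Per-visit Viterbi states: patient_id, visit_index, time, state."""
    by_id = {r.patient_id: r for r in records}
    rows = []
    for pid, states in decoded.items():
        rec = by_id[pid]
        for t, s in enumerate(states):
            rows.append({"patient_id": pid, "visit_index": t,
                         "time": rec.times[t], "state": int(s)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def fit_result_to_dict(fit) -> dict:
    """JSON-serializable FitResult (decoded paths written separately)."""
    return {
        "params": fit.params.to_dict(),
        "loglik_trace": [float(x) for x in fit.loglik_trace],
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "seed": fit.seed,
    }
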