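"""Synthetic cohorts of correlated node time series with planted structure.

The generator emulates the design of a task fMRI connectivity study of
children with reading difficulty: 24 participants each completing two runs
under three word-pair presentation modalities (visual-visual VV,
auditory-visual AV, auditory-auditory AA), with ~200 time points per run
extracted from a 43-node reading network (an optional larger
"outside network" is just a different node count).

Each subject x modality gets a planted block (community) correlation
matrix: node pairs inside a module correlate at ``within_r`` and pairs in
different modules at ``between_r``, with both levels drawn per subject so
that cohort members genuinely differ in how modular their connectivity is.
Time series are i.i.d. Gaussian draws from that matrix (zero-lag
correlation is the only statistic the downstream analysis consumes; an
optional AR(1) knob adds temporal smoothness without changing the
stationary zero-lag structure, for robustness checks only).

The participant-level outcome (a standardized pseudo-word decoding
efficiency score, PDE) is a linear function of the *true* network metrics
of the noiseless planted structure plus Gaussian noise, so parameter
recovery through the full pipeline is checkable against ground truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import (
    CorrelationMatrix,
    RunTimeSeries,
    mcc_threshold,
    run_file_name,
    significance_threshold,
    write_timeseries_matrix,
)
from .metrics import compute_metrics

logger = logging.getLogger(__name__)

MODALITIES = ("VV", "AV", "AA")

# Nuisance-variable ranges emulating the study cohort: ages 7y10m-13y8m in
# months, task accuracy .51-.85, response latency 900-1863 ms.
AGE_RANGE_MONTHS = (94.0, 164.0)
ACCURACY_RANGE = (0.51, 0.85)
LATENCY_RANGE_MS = (900.0, 1863.0)

# Default planted link: a positive association between crossmodal (AV)
# modularity and decoding skill, the kind of segregation-skill relationship
# the pipeline is built to detect.  The weight is sized so that, against
# the default outcome noise SD of 5 PDE points and the true-metric spread
# of the default cohort (~0.06), the planted linear model explains roughly
# half of the outcome variance.
DEFAULT_OUTCOME_BETAS: dict[tuple[str, str], float] = {("AV", "modularity"): 80.0}


@dataclass
class SynthConfig:
    """Study-design parameters of a synthetic cohort.

    ``within_r`` and ``between_r`` may be single correlations or
    ``(low, high)`` ranges; ranges are drawn uniformly per subject x
    modality, which is what creates between-subject metric variance.
    ``outcome_betas`` maps ``(modality, metric)`` to a linear weight on the
    true (noiseless-structure) metric value.
    """

    n_subjects: int = 24
    n_nodes: int = 43
    n_timepoints: int = 202
    n_runs_per_modality: int = 2
    modalities: tuple[str, ...] = MODALITIES
    n_modules: int = 4
    within_r: float | tuple[float, float] = (0.30, 0.55)
    between_r: float | tuple[float, float] = (0.12, 0.38)
    edge_jitter_sd: float = 0.08
    outcome_betas: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_BETAS)
    )
    outcome_intercept: float = 90.5
    outcome_noise_sd: float = 5.0
    true_metric_scheme: str = "significance"
    true_metric_alpha: float = 0.05
    ar1_phi: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_modules <= self.n_nodes:
            raise ValueError("n_modules must be in [1, n_nodes]")
        for name in ("within_r", "between_r"):
            v = getattr(self, name)
            lo, hi = (v, v) if np.isscalar(v) else v
            if not (-1 < lo <= hi < 1):
                raise ValueError(f"{name} must lie in (-1, 1)")
        whi = self.within_r if np.isscalar(self.within_r) else self.within_r[1]
        blo = self.between_r if np.isscalar(self.between_r) else self.between_r[0]
        if blo > whi:
            raise ValueError("between_r must not exceed within_r")
        self.outcome_betas = {tuple(k): float(v) for k, v in dict(self.outcome_betas).items()}


@dataclass
class GroundTruth:
    """Exactly what was used to generate a cohort.

    Sufficient to recompute every subject's expected outcome: the module
    assignment, the per subject x modality generating correlations (with
    any PSD shrinkage applied), the true metric values of the noiseless
    structure, and the outcome model.
    """

    module_assignment: list[int]
    generating_correlations: dict
    true_metrics: pd.DataFrame
    outcome_betas: dict
    outcome_intercept: float
    outcome_noise_sd: float
    nuisance_ranges: dict
    seed: int

    def expected_outcome(self, subject_id: str) -> float:
        """Noise-free outcome implied by the planted linear model."""
        tm = self.true_metrics
        total = self.outcome_intercept
        for (modality, metric), beta in self.outcome_betas.items():
            row = tm[(tm.subject_id == subject_id) & (tm.modality == modality)]
            total += beta * float(row[metric].iloc[0])
        return total

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "module_assignment": [int(m) for m in self.module_assignment],
            "generating_correlations": self.generating_correlations,
            "true_metrics": self.true_metrics.to_dict(orient="records"),
            "outcome_betas": {f"{m}:{k}": v for (m, k), v in self.outcome_betas.items()},
            "outcome_intercept": self.outcome_intercept,
            "outcome_noise_sd": self.outcome_noise_sd,
            "nuisance_ranges": self.nuisance_ranges,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        doc = yaml.safe_load(Path(path).read_text())
        betas = {tuple(k.split(":")): v for k, v in doc["outcome_betas"].items()}
        return cls(
            module_assignment=doc["module_assignment"],
            generating_correlations=doc["generating_correlations"],
            true_metrics=pd.DataFrame(doc["true_metrics"]),
            outcome_betas=betas,
            outcome_intercept=doc["outcome_intercept"],
            outcome_noise_sd=doc["outcome_noise_sd"],
            nuisance_ranges=doc["nuisance_ranges"],
            seed=doc["seed"],
        )


@dataclass
class Cohort:
    runs: list[RunTimeSeries]
    subjects: pd.DataFrame
    truth: GroundTruth


def default_module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal blocks, e.g. four anatomical node groups."""
    return np.sort(np.arange(n_nodes) % n_modules)


def _psd_repair(cov: np.ndarray, max_shrinkage: float, context: str) -> tuple[np.ndarray, float]:
    """Shrink toward the identity by the smallest amount that restores PSD."""
    emin = float(np.linalg.eigvalsh(cov)[0])
    if emin >= 0:
        return cov, 0.0
    shrinkage = (1e-10 - emin) / (1.0 - emin)
    if shrinkage > max_shrinkage:
        raise ValueError(f"covariance not PSD within maximum shrinkage: {context}")
    cov = (1.0 - shrinkage) * cov + shrinkage * np.eye(cov.shape[0])
    logger.info("%s: applied shrinkage %.4g toward identity", context, shrinkage)
    return cov, shrinkage


def planted_covariance(
    n_nodes: int,
    module_assignment: Sequence[int],
    within_r: float,
    between_r: float,
    max_shrinkage: float = 0.99,
) -> tuple[np.ndarray, float]:
    """Block correlation matrix with a PSD guarantee.

    Entry (i, j) is ``within_r`` when i and j share a module, else
    ``between_r``, with unit diagonal.  If the implied matrix is not
    positive semi-definite it is shrunk toward the identity,
    ``(1 - lam) C + lam I``, with the smallest ``lam`` that restores PSD;
    the applied shrinkage is returned so callers can record it.
    """
    if not (-1 < between_r <= within_r < 1):
        raise ValueError("require -1 < between_r <= within_r < 1")
    assignment = np.asarray(module_assignment)
    if assignment.shape != (n_nodes,):
        raise ValueError("module_assignment must have one entry per node")
    same = assignment[:, None] == assignment[None, :]
    cov = np.where(same, within_r, between_r)
    np.fill_diagonal(cov, 1.0)
    return _psd_repair(
        cov,
        max_shrinkage,
        f"planted_covariance(within_r={within_r}, between_r={between_r}, "
        f"n_modules={len(np.unique(assignment))})",
    )


def jittered_covariance(
    cov: np.ndarray,
    jitter_sd: float,
    seed: int,
    max_shrinkage: float = 0.99,
) -> tuple[np.ndarray, float]:
    """Add pairwise heterogeneity around the block levels.

    Real functional connectivity is not block-constant: individual node
    pairs scatter around their community-level coupling.  Symmetric
    Gaussian jitter (clipped to keep correlations in (-0.95, 0.95)) is
    added to every off-diagonal entry, followed by the same PSD repair as
    the base matrix.  With ``jitter_sd = 0`` the input is returned as is.
    """
    if jitter_sd == 0:
        return cov, 0.0
    n = cov.shape[0]
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    noise = np.zeros((n, n))
    noise[iu, ju] = rng.normal(0.0, jitter_sd, size=iu.size)
    noise += noise.T
    out = np.clip(cov + noise, -0.95, 0.95)
    np.fill_diagonal(out, 1.0)
    return _psd_repair(out, max_shrinkage, f"jittered_covariance(sd={jitter_sd})")


def sample_run(
    cov: np.ndarray,
    n_timepoints: int,
    seed: int,
    subject_id: str = "s00",
    modality: str = "VV",
    run_index: int = 1,
    ar1_phi: float = 0.0,
) -> RunTimeSeries:
    """Draw one run of multivariate-normal node time series.

    Draws are i.i.d. across time from N(0, cov); with ``ar1_phi`` nonzero
    the innovations are blended into a stationary AR(1) whose zero-lag
    covariance is still ``cov``.
    """
    cov = np.asarray(cov, dtype=float)
    n_nodes = cov.shape[0]
    if n_timepoints < n_nodes + 3:
        warnings.warn(
            "n_timepoints < n_nodes + 3: correlation significance downstream "
            "will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        np.zeros(n_nodes), cov, size=n_timepoints, method="eigh"
    )  # time x nodes
    if ar1_phi:
        phi = float(ar1_phi)
        scale = np.sqrt(1.0 - phi**2)
        out = np.empty_like(draws)
        out[0] = draws[0]
        for t in range(1, n_timepoints):
            out[t] = phi * out[t - 1] + scale * draws[t]
        draws = out
    return RunTimeSeries(
        subject_id=subject_id, modality=modality, run_index=run_index, data=draws.T
    )


def subseed(master_seed: int, *parts: int) -> int:
    """Deterministic per-(subject, modality, run) sub-seed below 2**31."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % (2**31))


def _draw_level(rng: np.random.Generator, value: float | tuple[float, float]) -> float:
    if np.isscalar(value):
        return float(value)
    lo, hi = value
    return float(rng.uniform(lo, hi))


def true_structure_metrics(
    cov: np.ndarray, config: SynthConfig, seed: int
) -> dict[str, float]:
    """Network metrics of the noiseless planted correlation structure.

    The planted matrix is binarized with the same rule the pipeline applies
    to empirical correlations (default: the significance threshold at the
    configured run length), then the three graph measures are computed.
    """
    corr = CorrelationMatrix(cov.copy(), n_timepoints=config.n_timepoints)
    if config.true_metric_scheme == "significance":
        net = significance_threshold(corr, alpha=config.true_metric_alpha)
    elif config.true_metric_scheme == "mcc":
        net = mcc_threshold(corr)
    else:
        raise ValueError(f"unknown true_metric_scheme: {config.true_metric_scheme!r}")
    if net.adjacency.sum() == 0:
        # noiseless structure below the significance boundary everywhere:
        # no edges, hence no community structure and zero efficiency
        logger.info("true_structure_metrics: edgeless noiseless graph; metrics set to 0")
        return {"modularity": 0.0, "transitivity": 0.0, "global_efficiency": 0.0}
    return compute_metrics(net, seed=seed)


def generate_cohort(config: SynthConfig) -> Cohort:
    """One full synthetic cohort: runs, subject table, and ground truth."""
    assignment = default_module_assignment(config.n_nodes, config.n_modules)
    level_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 901)))
    nuisance_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 902)))
    noise_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 903)))

    subject_ids = [f"s{i:02d}" for i in range(config.n_subjects)]
    runs: list[RunTimeSeries] = []
    gen_corr: dict = {}
    true_rows = []
    for si, sid in enumerate(subject_ids):
        gen_corr[sid] = {}
        for mi, modality in enumerate(config.modalities):
            w = _draw_level(level_rng, config.within_r)
            b = min(_draw_level(level_rng, config.between_r), w)
            cov, shrink = planted_covariance(config.n_nodes, assignment, w, b)
            jitter_seed = subseed(config.seed, 800, si, mi)
            cov, jshrink = jittered_covariance(cov, config.edge_jitter_sd, jitter_seed)
            gen_corr[sid][modality] = {
                "within_r": round(w, 10),
                "between_r": round(b, 10),
                "shrinkage": round(shrink + jshrink, 10),
                "jitter_sd": config.edge_jitter_sd,
                "jitter_seed": jitter_seed,
            }
            tm = true_structure_metrics(cov, config, seed=subseed(config.seed, 700, si, mi))
            true_rows.append({"subject_id": sid, "modality": modality, **tm})
            for run_index in range(1, config.n_runs_per_modality + 1):
                runs.append(
                    sample_run(
                        cov,
                        config.n_timepoints,
                        seed=subseed(config.seed, si, mi, run_index),
                        subject_id=sid,
                        modality=modality,
                        run_index=run_index,
                        ar1_phi=config.ar1_phi,
                    )
                )
    true_metrics = pd.DataFrame(true_rows)

    truth = GroundTruth(
        module_assignment=list(assignment),
        generating_correlations=gen_corr,
        true_metrics=true_metrics,
        outcome_betas=dict(config.outcome_betas),
        outcome_intercept=config.outcome_intercept,
        outcome_noise_sd=config.outcome_noise_sd,
        nuisance_ranges={
            "age_months": list(AGE_RANGE_MONTHS),
            "accuracy": list(ACCURACY_RANGE),
            "latency_ms": list(LATENCY_RANGE_MS),
        },
        seed=config.seed,
    )

    pde = []
    for sid in subject_ids:
        mu = truth.expected_outcome(sid)
        pde.append(mu + noise_rng.normal(0.0, config.outcome_noise_sd))
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age_months": nuisance_rng.uniform(*AGE_RANGE_MONTHS, size=config.n_subjects),
            "accuracy": nuisance_rng.uniform(*ACCURACY_RANGE, size=config.n_subjects),
            "latency_ms": nuisance_rng.uniform(*LATENCY_RANGE_MS, size=config.n_subjects),
            "pde": pde,
        }
    )
    return Cohort(runs=runs, subjects=subjects, truth=truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write runs as tab-separated matrices plus subject CSV and truth YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for run in cohort.runs:
        write_timeseries_matrix(
            ts_dir / run_file_name(run.subject_id, run.modality, run.run_index), run.data
        )
    cohort.subjects.to_csv(out_dir / "subjects.csv", index=False)
    cohort.truth.to_yaml(out_dir / "ground_truth.yaml")


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "age_months", "accuracy", "latency_ms", "pde"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return df
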