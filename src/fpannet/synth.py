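"""Synthetic cohorts with planted tree-topology effects.

The generator produces multichannel Gaussian "BOLD-like" time series whose
population covariance is organized around a spanning-tree backbone: region
pairs joined by a backbone edge correlate strongly, all other pairs weakly.
Each subject's backbone is a convex blend between the two reference
topologies — star-like (centralized) at blend 0 and line-like
(decentralized) at blend 1 — so the tree metrics the pipeline estimates
(diameter, leaf fraction, kappa, hierarchy) have a known ground truth and a
known direction of group difference.  A symptom score is tied linearly to
each subject's realized blend, making metric-score correlations recoverable
by construction.

Defaults emulate the study conditions of a two-group child cohort: 69
controls vs 119 patients, 166 usable volumes of 16 FPAN regions, a
gender imbalance and a verbal-IQ gap between groups, and symptom scores
separating the groups by roughly three control standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import TimeSeriesPanel, write_timeseries_tsv
from .trees import SpanningTree, make_tree

__all__ = [
    "CovariateModel",
    "SyntheticCohortSpec",
    "backbone_covariance",
    "blend_covariance",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]

_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class CovariateModel:
    """Group-wise covariate distributions for the synthetic cohort.

    Gender is Bernoulli (1 = male), continuous covariates are Gaussian.
    Defaults reproduce the demographic profile of the emulated cohort:
    balanced gender in controls vs male-dominated patients, and a verbal-IQ
    advantage for controls.
    """

    gender_p_tdc: float = 0.478
    gender_p_adhd: float = 0.748
    viq_mean_tdc: float = 112.6
    viq_mean_adhd: float = 107.1
    viq_sd: float = 14.0
    piq_mean_tdc: float = 107.5
    piq_mean_adhd: float = 103.9
    piq_sd: float = 15.2
    age_mean: float = 10.2
    age_sd: float = 1.85
    handedness_mean_tdc: float = 0.568
    handedness_mean_adhd: float = 0.645
    handedness_sd: float = 0.29


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full parameterization of a simulated two-group cohort.

    ``backbone_blend_*`` set each group's mean position on the star (0) to
    line (1) backbone continuum; individual subjects scatter around the
    group mean with ``blend_sd`` (truncated to [0, 1]).  ``symptom_link``
    is the slope of the symptom score in the realized blend, on top of a
    group baseline, so a group with a more line-like backbone also carries
    higher scores.
    """

    n_tdc: int = 69
    n_adhd: int = 119
    n_timepoints: int = 166
    n_regions: int = 16
    backbone_blend_tdc: float = 0.2
    backbone_blend_adhd: float = 0.8
    blend_sd: float = 0.15
    edge_r_strong: float = 0.6
    edge_r_weak: float = 0.1
    noise_sd: float = 0.5
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    symptom_baseline_tdc: float = 43.0
    symptom_baseline_adhd: float = 62.0
    symptom_link: float = 13.0
    symptom_noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tdc < 2 or self.n_adhd < 2:
            raise ValueError("group sizes must be >= 2")
        for b in (self.backbone_blend_tdc, self.backbone_blend_adhd):
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"backbone blend {b} outside [0, 1]")
        if not abs(self.edge_r_strong) < 1 or not abs(self.edge_r_weak) < 1:
            raise ValueError("edge correlations must have magnitude < 1")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")


def _repair_positive_definite(cov: np.ndarray) -> np.ndarray:
    """Project to the nearest positive-definite correlation-like matrix.

    Eigenvalues are clipped at a small floor (1e-6) and the diagonal is
    re-standardized to 1, so planted edge correlations survive approximately.
    """
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    # repair only when genuinely non-positive-definite, so the projection
    # is idempotent: re-repairing an already repaired matrix is a no-op
    if w.min() > 1e-10:
        return cov
    w = np.clip(w, _EIG_FLOOR, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    if np.linalg.eigvalsh(repaired).min() <= 0:
        raise RuntimeError("positive-definite repair failed")
    return repaired


def backbone_covariance(
    tree: SpanningTree, edge_r_strong: float, edge_r_weak: float
) -> np.ndarray:
    """Unit-diagonal covariance with strong tree-edge and weak off-edge entries.

    The raw template (``edge_r_strong`` on backbone edges, ``edge_r_weak``
    elsewhere) need not be positive definite — a star hub correlated 0.6
    with 15 mutually weakly-correlated leaves is not — so the template is
    repaired by eigenvalue clipping and diagonal re-standardization.  The
    ordering strong > weak survives the repair, which is what the
    backbone-recovery guarantees rely on.
    """
    if not abs(edge_r_strong) < 1:
        raise ValueError("edge_r_strong must have magnitude < 1")
    if not abs(edge_r_weak) < abs(edge_r_strong) and edge_r_strong != 0:
        raise ValueError("edge_r_weak must be weaker than edge_r_strong")
    n = tree.n_nodes
    cov = np.full((n, n), float(edge_r_weak))
    np.fill_diagonal(cov, 1.0)
    for i, j in tree.edges:
        cov[i, j] = cov[j, i] = float(edge_r_strong)
    return _repair_positive_definite(cov)


def blend_covariance(cov_a: np.ndarray, cov_b: np.ndarray, blend: float) -> np.ndarray:
    """Convex combination ``(1-blend)*cov_a + blend*cov_b``, kept positive definite."""
    if not 0.0 <= blend <= 1.0:
        raise ValueError(f"blend {blend} outside [0, 1]")
    cov_a = np.asarray(cov_a, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    if cov_a.shape != cov_b.shape:
        raise ValueError("covariance matrices must be conformable")
    mixed = (1.0 - blend) * cov_a + blend * cov_b
    # A convex mix of positive-definite matrices is positive definite, but
    # repair defensively in case the inputs were only borderline.
    return _repair_positive_definite(mixed)


def simulate_subject(
    cov: np.ndarray, n_timepoints: int, noise_sd: float, seed
) -> np.ndarray:
    """Draw a T x N Gaussian time series with the given channel covariance.

    Rows are i.i.d. zero-mean multivariate normal draws; independent white
    observation noise of standard deviation ``noise_sd`` is added per
    channel.  ``seed`` may be an int or a numpy SeedSequence/Generator.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    if n_timepoints < n:
        import warnings

        warnings.warn(
            f"T={n_timepoints} < N={n}: sample correlations will be rank deficient",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_timepoints, n)) @ chol.T
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal((n_timepoints, n))
    return data


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(spec: SyntheticCohortSpec):
    """Simulate a full two-group cohort with planted topology differences.

    Returns
    -------
    panels : list of TimeSeriesPanel
        One T x N time-series panel per subject.
    cohort : pandas.DataFrame
        One row per subject: subject_id, group, gender, age, handedness,
        viq, piq, adhd_index.
    truth : pandas.DataFrame
        Ground-truth per-subject realized backbone blends, for recovery
        testing.
    """
    rng = np.random.default_rng(spec.seed)
    star = make_tree("star", spec.n_regions)
    path = make_tree("path", spec.n_regions)
    cov_star = backbone_covariance(star, spec.edge_r_strong, spec.edge_r_weak)
    cov_path = backbone_covariance(path, spec.edge_r_strong, spec.edge_r_weak)

    cm = spec.covariate_model
    panels: list[TimeSeriesPanel] = []
    cohort_rows = []
    truth_rows = []
    groups = [("TDC", spec.n_tdc), ("ADHD", spec.n_adhd)]
    for group, n_group in groups:
        if group == "TDC":
            blend_mean = spec.backbone_blend_tdc
            gender_p, viq_mean = cm.gender_p_tdc, cm.viq_mean_tdc
            piq_mean, hand_mean = cm.piq_mean_tdc, cm.handedness_mean_tdc
            baseline = spec.symptom_baseline_tdc
        else:
            blend_mean = spec.backbone_blend_adhd
            gender_p, viq_mean = cm.gender_p_adhd, cm.viq_mean_adhd
            piq_mean, hand_mean = cm.piq_mean_adhd, cm.handedness_mean_adhd
            baseline = spec.symptom_baseline_adhd
        blends = _truncated_normal(rng, blend_mean, spec.blend_sd, 0.0, 1.0, n_group)
        for k in range(n_group):
            sid = f"{group.lower()}{k + 1:03d}"
            blend = float(blends[k])
            cov = blend_covariance(cov_star, cov_path, blend)
            data = simulate_subject(cov, spec.n_timepoints, spec.noise_sd, rng)
            panels.append(
                TimeSeriesPanel(
                    subject_id=sid,
                    data=data,
                    roi_names=[f"roi{i:02d}" for i in range(spec.n_regions)],
                )
            )
            cohort_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "gender": int(rng.random() < gender_p),
                    "age": float(rng.normal(cm.age_mean, cm.age_sd)),
                    "handedness": float(
                        np.clip(rng.normal(hand_mean, cm.handedness_sd), 0.0, 1.0)
                    ),
                    "viq": float(rng.normal(viq_mean, cm.viq_sd)),
                    "piq": float(rng.normal(piq_mean, cm.piq_sd)),
                    "adhd_index": float(
                        baseline
                        + spec.symptom_link * blend
                        + rng.normal(0.0, spec.symptom_noise_sd)
                    ),
                }
            )
            truth_rows.append({"subject_id": sid, "group": group, "blend": blend})
    cohort = pd.DataFrame(cohort_rows)
    truth = pd.DataFrame(truth_rows)
    return panels, cohort, truth


def write_cohort(panels, cohort: pd.DataFrame, truth: pd.DataFrame, out_dir) -> None:
    """Write a simulated cohort: one time-series TSV per subject + tables."""
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for panel in panels:
        write_timeseries_tsv(panel, ts_dir / f"{panel.subject_id}.tsv")
    cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
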