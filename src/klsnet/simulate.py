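"""Synthetic cohorts with planted group effects and outcome coupling.

Two generators cover the pipeline end to end with no external data:

* :func:`simulate_roi_samples` draws per-region voxel intensities
  (Gaussian per region) for every subject; planted region pairs get a
  group-conditional mean shift in the second region, so the KLS of that
  pair differs between patients and controls after network construction.
* :func:`simulate_connectivity_direct` skips the voxel level and draws
  KLS matrices directly as logit-normal entries in (0, 1) with planted
  group mean shifts on chosen edges — fast fixtures for the statistics
  and prediction stages.

Patient overall survival is a linear combination of the planted connection
values plus age/sex confounding and Gaussian noise, truncated below at
1 month. Cohort sizes, ages, and sex ratios default to the studied cohort
(78 patients vs 60 controls; ages ~64 +/- 10 vs ~61 +/- 10 years; ~83%
male). Regeneration from the same (config, seed) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .features import edge_name, feature_table
from .group_stats import SubjectFeatureTable
from .kls_network import ConnectivityMatrix, estimate_pdf, kls, select_bandwidth
from .roi_extraction import ROISampleSet
from .survival_model import PatientRecord

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_roi_samples",
    "simulate_connectivity_direct",
    "build_all_networks",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort generator."""

    n_patients: int = 78
    n_controls: int = 60
    n_regions: int = 90
    voxels_per_region: int = 200
    region_mean_range: tuple[float, float] = (0.8, 1.2)
    region_sd_range: tuple[float, float] = (0.05, 0.15)
    #: (region_i, region_j, effect size d) — patient-group shift per edge
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    #: survival coefficient per planted edge, keyed by (i, j)
    outcome_betas: dict[tuple[int, int], float] = field(default_factory=dict)
    survival_intercept: float = 16.0
    survival_noise_sd: float = 6.0
    #: direct mode only: when set, overrides survival_noise_sd so the
    #: population correlation between the planted-edge signal and the
    #: (untruncated) outcome equals this value
    outcome_target_r: float | None = None
    age_beta: float = -0.1
    sex_beta: float = 0.0
    patient_age: tuple[float, float] = (63.9, 10.05)
    control_age: tuple[float, float] = (61.33, 10.28)
    p_male: float = 0.83
    # direct-matrix mode
    edge_mean_range: tuple[float, float] = (0.25, 0.75)
    logit_sd: float = 0.5
    #: "d" = effect sizes in sd units; "raw" = absolute KLS-scale shifts
    effect_scale: str = "d"
    seed: int = 0

    def __post_init__(self) -> None:
        for i, j, d in self.planted_edges:
            if not (1 <= i <= self.n_regions and 1 <= j <= self.n_regions and i != j):
                raise ValueError(f"planted edge ({i}, {j}) is not a valid region pair")
            if not np.isfinite(d):
                raise ValueError("effect sizes must be finite")
        for i, j in self.outcome_betas:
            if edge_name(i, j) not in {edge_name(a, b) for a, b, _ in self.planted_edges}:
                raise ValueError(f"outcome beta on unplanted edge ({i}, {j})")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        d["outcome_betas"] = {edge_name(i, j): b for (i, j), b in self.outcome_betas.items()}
        return d


@dataclass
class SyntheticCohort:
    """Generated subjects plus the ground truth that produced them."""

    config: SimulationConfig
    subject_ids: list[str]
    groups: np.ndarray
    ages: np.ndarray
    sexes: np.ndarray
    survival: np.ndarray  # NaN for controls
    roi_sets: dict[str, ROISampleSet] | None = None
    matrices: dict[str, ConnectivityMatrix] | None = None

    @property
    def patient_ids(self) -> list[str]:
        return [s for s, g in zip(self.subject_ids, self.groups) if g == "patient"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in zip(self.subject_ids, self.groups) if g == "control"]

    def _covariate(self, name: str, ids: list[str]) -> np.ndarray:
        idx = [self.subject_ids.index(s) for s in ids]
        return getattr(self, name)[idx]

    def patients_table(self) -> SubjectFeatureTable:
        mats = [self.matrices[s] for s in self.patient_ids]
        return feature_table(
            mats, "patient", self._covariate("ages", self.patient_ids),
            self._covariate("sexes", self.patient_ids),
        )

    def controls_table(self) -> SubjectFeatureTable:
        mats = [self.matrices[s] for s in self.control_ids]
        return feature_table(
            mats, "control", self._covariate("ages", self.control_ids),
            self._covariate("sexes", self.control_ids),
        )

    def patient_records(self) -> list[PatientRecord]:
        tab = self.patients_table()
        surv = self._covariate("survival", self.patient_ids)
        return [
            PatientRecord(
                subject_id=sid,
                connection_features=tab.features.iloc[k],
                age=float(tab.age[k]),
                sex=float(tab.sex[k]),
                overall_survival=float(surv[k]),
            )
            for k, sid in enumerate(self.patient_ids)
        ]

    def cohort_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.groups,
                "age": self.ages,
                "sex": np.where(self.sexes > 0, "M", "F"),
                "overall_survival_months": self.survival,
            }
        )

    def ground_truth_frame(self) -> pd.DataFrame:
        betas = {edge_name(i, j): b for (i, j), b in self.config.outcome_betas.items()}
        rows = [
            (i, j, d, betas.get(edge_name(i, j), 0.0))
            for i, j, d in self.config.planted_edges
        ]
        return pd.DataFrame(rows, columns=["region_i", "region_j", "effect_size", "beta"])

    def write(self, outdir) -> None:
        """Serialize cohort table, ground truth, and per-subject data."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort_frame().to_csv(out / "cohort.tsv", sep="\t", index=False)
        self.ground_truth_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        if self.matrices is not None:
            for sid, m in self.matrices.items():
                m.to_tsv(out / f"{sid}.klsnet.tsv")
        if self.roi_sets is not None:
            for sid, r in self.roi_sets.items():
                r.to_tsv(out / f"{sid}.roisamples.tsv")


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_patients + cfg.n_controls
    groups = np.array(["patient"] * cfg.n_patients + ["control"] * cfg.n_controls, dtype=object)
    ages = np.concatenate(
        [
            rng.normal(cfg.patient_age[0], cfg.patient_age[1], cfg.n_patients),
            rng.normal(cfg.control_age[0], cfg.control_age[1], cfg.n_controls),
        ]
    )
    sexes = (rng.random(n) < cfg.p_male).astype(float)
    ids = [f"pat{k+1:03d}" for k in range(cfg.n_patients)] + [
        f"con{k+1:03d}" for k in range(cfg.n_controls)
    ]
    return ids, groups, ages, sexes


def _survival(
    cfg, rng, edge_values: np.ndarray, betas: np.ndarray, base: np.ndarray, age, sex,
    noise_sd: float | None = None,
):
    """Linear outcome over centered planted-edge values, truncated at 1 month."""
    signal = (edge_values - base) @ betas if betas.size else 0.0
    if noise_sd is None:
        noise_sd = cfg.survival_noise_sd
    y = (
        cfg.survival_intercept
        + signal
        + cfg.age_beta * (age - np.mean(age))
        + cfg.sex_beta * sex
        + rng.normal(0.0, noise_sd, len(age))
    )
    return np.maximum(y, 1.0)


def _pair_kls(x1: np.ndarray, x2: np.ndarray) -> float:
    """KLS of two samples with the shared-grid rule used by build_network."""
    h1, h2 = select_bandwidth(x1), select_bandwidth(x2)
    h = max(h1, h2)
    lo = min(x1.min(), x2.min()) - 3.0 * h
    hi = max(x1.max(), x2.max()) + 3.0 * h
    grid = np.linspace(lo, hi, 512)
    p = estimate_pdf(x1, grid=grid, bandwidth=h1)
    q = estimate_pdf(x2, grid=grid, bandwidth=h2)
    return kls(p, q)


def simulate_roi_samples(cfg: SimulationConfig) -> SyntheticCohort:
    """Voxel-level cohort: Gaussian region intensities with planted shifts.

    Patients get region j of each planted edge (i, j, d) shifted by
    ``d * sigma_j`` (shifts on a region accumulate over edges). Survival is
    coupled to the patients' KLS values of the planted edges.
    """
    if cfg.outcome_target_r is not None:
        raise ValueError("outcome_target_r is only available in direct-matrix mode")
    rng = np.random.default_rng(cfg.seed)
    ids, groups, ages, sexes = _draw_covariates(cfg, rng)
    mu = rng.uniform(*cfg.region_mean_range, cfg.n_regions)
    sd = rng.uniform(*cfg.region_sd_range, cfg.n_regions)
    shift = np.zeros(cfg.n_regions)
    for i, j, d in cfg.planted_edges:
        shift[j - 1] += d * sd[j - 1]
    roi_sets: dict[str, ROISampleSet] = {}
    beta_edges = sorted(cfg.outcome_betas, key=lambda e: edge_name(*e))
    betas = np.array([cfg.outcome_betas[e] for e in beta_edges])
    kls_values = np.zeros((len(ids), len(beta_edges)))
    for k, (sid, grp) in enumerate(zip(ids, groups)):
        mu_k = mu + shift if grp == "patient" else mu
        samples = {
            r + 1: rng.normal(mu_k[r], sd[r], cfg.voxels_per_region)
            for r in range(cfg.n_regions)
        }
        roi_sets[sid] = ROISampleSet(subject_id=sid, samples=samples)
        for e_idx, (i, j) in enumerate(beta_edges):
            kls_values[k, e_idx] = _pair_kls(samples[i], samples[j])
    survival = np.full(len(ids), np.nan)
    is_pat = groups == "patient"
    if is_pat.any():
        base = kls_values[is_pat].mean(axis=0) if betas.size else np.zeros(0)
        survival[is_pat] = _survival(
            cfg, rng, kls_values[is_pat], betas, base, ages[is_pat], sexes[is_pat]
        )
    return SyntheticCohort(
        config=cfg, subject_ids=ids, groups=groups, ages=ages, sexes=sexes,
        survival=survival, roi_sets=roi_sets,
    )


def _logitnormal_moments(mu: float, s: float) -> tuple[float, float]:
    """Mean and sd of sigmoid(N(mu, s^2)) by Gauss-Hermite quadrature."""
    vals = expit(mu + s * np.sqrt(2.0) * _GH_NODES)
    m1 = float(np.dot(_GH_WEIGHTS, vals) / np.sqrt(np.pi))
    m2 = float(np.dot(_GH_WEIGHTS, vals**2) / np.sqrt(np.pi))
    return m1, float(np.sqrt(max(m2 - m1 * m1, 0.0)))


def _solve_logit_shift(mu: float, s: float, raw_shift: float) -> float:
    """Logit-scale offset whose raw-scale mean shift equals ``raw_shift``."""
    base, _ = _logitnormal_moments(mu, s)
    target = float(np.clip(base + raw_shift, 1e-4, 1.0 - 1e-4))
    return brentq(lambda d: _logitnormal_moments(mu + d, s)[0] - target, -40.0, 40.0)


def simulate_connectivity_direct(cfg: SimulationConfig) -> SyntheticCohort:
    """Matrix-level cohort: logit-normal KLS edges with planted mean shifts.

    With ``effect_scale="d"`` the patient-vs-control raw-scale mean
    difference on a planted edge is ``d`` times the edge's raw-scale sd;
    with ``"raw"`` it is the stated shift itself.
    """
    rng = np.random.default_rng(cfg.seed)
    ids, groups, ages, sexes = _draw_covariates(cfg, rng)
    r = cfg.n_regions
    iu, ju = np.triu_indices(r, k=1)
    n_edges = iu.size
    base_raw = rng.uniform(*cfg.edge_mean_range, n_edges)
    mu_e = logit(base_raw)
    edge_index = {(int(iu[k]) + 1, int(ju[k]) + 1): k for k in range(n_edges)}
    delta = np.zeros(n_edges)
    for i, j, d in cfg.planted_edges:
        k = edge_index[(min(i, j), max(i, j))]
        if cfg.effect_scale == "d":
            _, raw_sd = _logitnormal_moments(mu_e[k], cfg.logit_sd)
            raw_shift = d * raw_sd
        elif cfg.effect_scale == "raw":
            raw_shift = d
        else:
            raise ValueError("effect_scale must be 'd' or 'raw'")
        delta[k] += _solve_logit_shift(mu_e[k], cfg.logit_sd, raw_shift)
    region_ids = list(range(1, r + 1))
    matrices: dict[str, ConnectivityMatrix] = {}
    beta_edges = sorted(cfg.outcome_betas, key=lambda e: edge_name(*e))
    betas = np.array([cfg.outcome_betas[e] for e in beta_edges])
    beta_cols = [edge_index[(min(i, j), max(i, j))] for i, j in beta_edges]
    edge_vals = np.zeros((len(ids), len(beta_edges)))
    for k, (sid, grp) in enumerate(zip(ids, groups)):
        mu_k = mu_e + delta if grp == "patient" else mu_e
        vals = expit(rng.normal(mu_k, cfg.logit_sd))
        w = np.zeros((r, r))
        w[iu, ju] = vals
        w = w + w.T
        matrices[sid] = ConnectivityMatrix(
            region_ids=region_ids, weights=w, subject_id=sid,
            meta={"subject_id": sid, "generator": "direct", "seed": cfg.seed},
        )
        if beta_cols:
            edge_vals[k] = vals[beta_cols]
    survival = np.full(len(ids), np.nan)
    is_pat = groups == "patient"
    if is_pat.any():
        moments = [_logitnormal_moments(mu_e[c] + delta[c], cfg.logit_sd) for c in beta_cols]
        base = np.array([m[0] for m in moments])
        noise_sd = None
        if cfg.outcome_target_r is not None:
            # edges are independent, so signal variance sums analytically
            sig_var = float(np.sum((betas * np.array([m[1] for m in moments])) ** 2))
            r = cfg.outcome_target_r
            if not 0 < r < 1 or sig_var == 0:
                raise ValueError("outcome_target_r needs 0 < r < 1 and coupled edges")
            noise_sd = float(np.sqrt(sig_var * (1.0 / r**2 - 1.0)))
        survival[is_pat] = _survival(
            cfg, rng, edge_vals[is_pat], betas, base, ages[is_pat], sexes[is_pat],
            noise_sd=noise_sd,
        )
    return SyntheticCohort(
        config=cfg, subject_ids=ids, groups=groups, ages=ages, sexes=sexes,
        survival=survival, matrices=matrices,
    )


def build_all_networks(cohort: SyntheticCohort, **kwargs) -> SyntheticCohort:
    """Fill ``cohort.matrices`` from its ROI samples via KLS construction."""
    from .kls_network import build_network

    if cohort.roi_sets is None:
        raise ValueError("cohort has no ROI samples")
    cohort.matrices = {
        sid: build_network(rois, **kwargs) for sid, rois in cohort.roi_sets.items()
    }
    return cohort
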