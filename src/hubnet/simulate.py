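"""Synthetic connectome cohorts with planted brain-behavior structure.

The study design this generator emulates has no public data, so every
downstream stage is exercised on simulated cohorts carrying the same
statistical structure:

- a fixed "true" backbone of region pairs that are connected in nearly
  every subject, against a background of rare spurious edges;
- one hub region whose FA-weighted nodal degree tracks a latent
  phonological-awareness trait, at a calibrated partial correlation;
- behavioral scores in which the latent trait drives three phonological
  tasks and (through them) character reading, so that phonological
  awareness fully mediates the degree-reading association when the planted
  direct path is zero;
- a sex effect on the latent trait, reading-history ratios that split the
  cohort into good and poor readers at the 0.36 threshold, and age/IQ
  covariates in realistic young-adult ranges.

Generative model per cohort: a symmetric true-edge mask is drawn at the
target backbone density; each subject realizes each edge as a Bernoulli
(presence probability high for true edges, low for others); present edges
get a shifted-Poisson streamline count and an FA value
``fa_base + hub_loading * PA_latent`` (hub-incident edges only) plus
Gaussian noise, truncated to [0.05, 0.95].  Observed task scores are noisy
affine transforms of the latent trait; reading is generated from the
latent trait and (optionally) the standardized hub degree; rapid-naming
times are pure noise, matching a design in which naming speed shows no
nodal-degree association.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .atlas import LEFT_MTG_INDEX
from .behavior import BehavioralRecord
from .connectome import SubjectConnectome


class ConfigurationError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


# Whole-sample score distributions the behavioral tasks are scaled to
# (means/SDs in raw task units, typical of undergraduate cohorts).
TASK_SCALES = {
    "phoneme_deletion": (14.2, 1.8, 0.0, 16.0),
    "spoonerism1": (12.7, 3.1, 0.0, 16.0),
    "spoonerism2": (14.6, 1.6, 0.0, 16.0),
}
READING_SCALE = (83.5, 14.3, 0.0, 150.0)
RAN_SCALES = {
    "ran_digits": (9.6, 1.7),
    "ran_objects": (21.4, 2.7),
    "ran_colors": (23.5, 3.1),
}
AGE_SCALE = (18.06, 0.45, 17.0, 19.0)
IQ_SCALE = (56.8, 2.4, 40.0, 60.0)


@dataclass
class CohortConfig:
    """Study-design constants and planted effect sizes for one cohort.

    Defaults reproduce the emulated design: 37 good and 28 poor readers on
    a 90-region parcellation, a true backbone at 22% pair density, a hub at
    the left middle temporal gyrus, a planted hub-trait partial correlation
    of 0.56 (via ``hub_loading``; calibrated when left ``None``), a
    standardized mediated effect of 0.56 * 0.604 ~ 0.338 on reading with a
    zero direct path, and a standardized sex effect of 0.300 on the trait.
    """

    n_good: int = 37
    n_poor: int = 28
    n_regions: int = 90
    true_backbone_density: float = 0.22
    p_edge_true: float = 0.95
    p_edge_false: float = 0.05
    count_scale: float = 50.0
    hub_index: int = LEFT_MTG_INDEX
    hub_loading: float | None = None  # calibrated to a_path when None
    fa_base: float = 0.45
    fa_noise_sd: float = 0.10
    a_path: float = 0.56  # target hub-degree <-> trait partial correlation
    b_path: float = 0.604  # standardized trait -> reading path
    c_prime: float = 0.0  # standardized direct hub-degree -> reading path
    sex_effect_pa: float = 0.300  # standardized sex -> trait effect
    arhq_shift: float = 0.15  # width of the group bands around 0.36
    task_noise_sd: float = 0.30  # task noise relative to unit-variance trait
    p_female: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "true_backbone_density": self.true_backbone_density,
            "p_edge_true": self.p_edge_true,
            "p_edge_false": self.p_edge_false,
            "p_female": self.p_female,
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if self.n_good + self.n_poor < 10:
            raise ConfigurationError("cohort must have at least 10 subjects")
        if not 0 <= self.hub_index < self.n_regions:
            raise ConfigurationError("hub_index out of range")
        for name in ("count_scale", "fa_noise_sd", "task_noise_sd", "arhq_shift"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not 0.05 <= self.fa_base <= 0.95:
            raise ConfigurationError("fa_base must lie in [0.05, 0.95]")
        if not abs(self.a_path) < 1:
            raise ConfigurationError("a_path must lie strictly inside (-1, 1)")
        if self.b_path**2 + self.c_prime**2 > 1:
            raise ConfigurationError(
                "b_path^2 + c_prime^2 must not exceed 1 (reading is standardized)"
            )

    @property
    def n_subjects(self) -> int:
        return self.n_good + self.n_poor


def _latent_trait(rng: np.random.Generator, sex: np.ndarray, cfg: CohortConfig):
    """Latent phonological trait with a planted *standardized* sex effect."""
    beta = cfg.sex_effect_pa
    pq = cfg.p_female * (1 - cfg.p_female)
    if abs(beta) >= 1 or pq == 0:
        delta = 0.0 if pq == 0 else np.sign(beta) * 1e6
    else:
        delta = beta / (np.sqrt(pq) * np.sqrt(1 - beta**2))
    raw = rng.standard_normal(sex.size) + delta * sex
    return (raw - raw.mean()) / raw.std(ddof=1)


def true_edge_mask(config: CohortConfig) -> np.ndarray:
    """The cohort's planted backbone, as an upper-triangle boolean vector.

    Drawn from a sub-seed of the cohort seed (not the main generation
    stream), so callers can recover the ground-truth edge set of any
    generated cohort without replaying the generator.
    """
    rng = np.random.default_rng((config.seed * 1000003 + 7) % 2**31)
    n_pairs = config.n_regions * (config.n_regions - 1) // 2
    return rng.random(n_pairs) < config.true_backbone_density


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectConnectome], list[BehavioralRecord]]:
    """Generate one synthetic cohort of connectomes and behavioral records.

    Deterministic for a fixed config (the seed lives on the config).  Good
    readers occupy the first ``n_good`` slots; group membership is encoded
    only through the reading-history ratio, so the downstream classifier is
    genuinely exercised.
    """
    cfg = config
    if cfg.hub_loading is None:
        cfg = replace(cfg, hub_loading=calibrate_hub_loading(cfg.a_path, cfg))
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    nr = cfg.n_regions
    iu = np.triu_indices(nr, 1)
    n_pairs = iu[0].size

    # --- behavioral latents and covariates ---------------------------------
    sex = (rng.random(n) < cfg.p_female).astype(int)
    latent = _latent_trait(rng, sex, cfg)
    age = np.clip(rng.normal(*AGE_SCALE[:2], n), *AGE_SCALE[2:])
    iq = np.clip(rng.normal(*IQ_SCALE[:2], n), *IQ_SCALE[2:])

    # --- connectomes -------------------------------------------------------
    true_mask = true_edge_mask(cfg)
    p_present = np.where(true_mask, cfg.p_edge_true, cfg.p_edge_false)
    present = rng.random((n, n_pairs)) < p_present
    counts = np.where(present, 1 + rng.poisson(cfg.count_scale, (n, n_pairs)), 0)
    touches_hub = (iu[0] == cfg.hub_index) | (iu[1] == cfg.hub_index)
    fa = (
        cfg.fa_base
        + cfg.hub_loading * latent[:, None] * touches_hub[None, :]
        + rng.normal(0.0, cfg.fa_noise_sd, (n, n_pairs))
    )
    fa = np.where(present, np.clip(fa, 0.05, 0.95), 0.0)

    # Hub degree over true hub-incident edges, for the planted direct path.
    hub_cols = true_mask & touches_hub
    deg = fa[:, hub_cols].sum(axis=1)
    deg_sd = deg.std(ddof=1)
    deg_z = (deg - deg.mean()) / deg_sd if deg_sd > 0 else np.zeros(n)

    # --- observed behavior -------------------------------------------------
    tau = cfg.task_noise_sd
    scale_z = np.sqrt(1 + tau**2)
    task_scores = {}
    for task, (mean, sd, lo, hi) in TASK_SCALES.items():
        obs_z = (latent + tau * rng.standard_normal(n)) / scale_z
        task_scores[task] = np.clip(mean + sd * obs_z, lo, hi)

    resid_sd = np.sqrt(max(0.0, 1 - cfg.b_path**2 - cfg.c_prime**2))
    reading_z = (
        cfg.b_path * latent
        + cfg.c_prime * deg_z
        + resid_sd * rng.standard_normal(n)
    )
    mean, sd, lo, hi = READING_SCALE
    reading = np.clip(mean + sd * reading_z, lo, hi)

    ran_times = {
        task: np.clip(rng.normal(mean, sd_t, n), 3.0, None)
        for task, (mean, sd_t) in RAN_SCALES.items()
    }

    # Reading-history ratio: bands just below / above the 0.36 threshold.
    shift = max(cfg.arhq_shift, 1e-3)
    arhq = np.empty(n)
    arhq[: cfg.n_good] = 0.36 - rng.uniform(0.01, shift, cfg.n_good)
    arhq[cfg.n_good:] = 0.36 + rng.uniform(0.005, shift, cfg.n_poor)
    arhq = np.clip(arhq, 0.0, 1.0)

    # --- assemble ----------------------------------------------------------
    connectomes: list[SubjectConnectome] = []
    records: list[BehavioralRecord] = []
    for i in range(n):
        cm = np.zeros((nr, nr), dtype=int)
        fm = np.zeros((nr, nr))
        cm[iu], fm[iu] = counts[i], fa[i]
        cm += cm.T
        fm += fm.T
        sid = f"S{i + 1:03d}"
        connectomes.append(SubjectConnectome(sid, cm, fm))
        records.append(
            BehavioralRecord(
                subject_id=sid,
                sex=int(sex[i]),
                age=float(age[i]),
                raven_iq=float(iq[i]),
                arhq=float(arhq[i]),
                phoneme_deletion=float(task_scores["phoneme_deletion"][i]),
                spoonerism1=float(task_scores["spoonerism1"][i]),
                spoonerism2=float(task_scores["spoonerism2"][i]),
                ran_digits=float(ran_times["ran_digits"][i]),
                ran_objects=float(ran_times["ran_objects"][i]),
                ran_colors=float(ran_times["ran_colors"][i]),
                character_reading=float(reading[i]),
            )
        )
    return connectomes, records


def _hub_partial_r(
    loading: float, cfg: CohortConfig, n: int, seed: int
) -> float:
    """Partial r between hub degree and the observed trait composite.

    Fast reduced simulation used by the calibrator: only hub-incident true
    edges are realized (the only ones entering the hub's backbone degree),
    and the behavioral side is reduced to the three-task composite plus
    the sex/age/IQ covariates that get partialled out.
    """
    rng = np.random.default_rng(seed)
    sex = (rng.random(n) < cfg.p_female).astype(int)
    latent = _latent_trait(rng, sex, cfg)
    # Expected number of true hub-incident edges under the design density.
    k_hub = max(int(round((cfg.n_regions - 1) * cfg.true_backbone_density)), 1)
    present = rng.random((n, k_hub)) < cfg.p_edge_true
    fa = (
        cfg.fa_base
        + loading * latent[:, None]
        + rng.normal(0.0, cfg.fa_noise_sd, (n, k_hub))
    )
    deg = np.where(present, np.clip(fa, 0.05, 0.95), 0.0).sum(axis=1)

    # Observed composite exactly as generate_cohort builds it, including the
    # task score ceilings, which attenuate the composite-trait correlation.
    tau = cfg.task_noise_sd
    scale_z = np.sqrt(1 + tau**2)
    task_z = []
    for mean, sd, lo, hi in TASK_SCALES.values():
        obs = np.clip(
            mean + sd * (latent + tau * rng.standard_normal(n)) / scale_z, lo, hi
        )
        task_z.append((obs - obs.mean()) / obs.std(ddof=1))
    comp = np.mean(task_z, axis=0)
    age = rng.normal(*AGE_SCALE[:2], n)
    iq = rng.normal(*IQ_SCALE[:2], n)
    design = np.column_stack([np.ones(n), sex, age, iq])
    coef_d, *_ = np.linalg.lstsq(design, deg, rcond=None)
    coef_c, *_ = np.linalg.lstsq(design, comp, rcond=None)
    rd, rc = deg - design @ coef_d, comp - design @ coef_c
    return float(np.corrcoef(rd, rc)[0, 1])


def calibrate_hub_loading(
    target_partial_r: float,
    config: CohortConfig,
    n_subjects: int = 50000,
    tol: float = 0.006,
    max_loading: float = 5.0,
) -> float:
    """Hub FA loading that realizes a target hub-trait partial correlation.

    Bisects the loading against a large-n reduced simulation (fixed seed,
    so the objective is a smooth deterministic function of the loading)
    until the realized partial r is within ``tol`` of the target.  Raises
    :class:`CalibrationError` when the target is unattainable: FA
    truncation caps the achievable signal, and task/edge noise caps the
    achievable correlation.
    """
    if not abs(target_partial_r) < 1:
        raise CalibrationError("target partial r must lie inside (-1, 1)")
    if target_partial_r == 0:
        return 0.0
    sign = np.sign(target_partial_r)
    target = abs(target_partial_r)
    seed = (config.seed * 7919 + 13) % (2**31)
    f = lambda lam: _hub_partial_r(lam, config, n_subjects, seed)

    lo, hi = 0.0, 0.02
    f_hi = f(hi)
    while f_hi < target:
        hi *= 2
        if hi > max_loading:
            raise CalibrationError(
                f"partial r {target_partial_r} unattainable: realized at most "
                f"{f_hi:.3f} with loading {hi / 2:g}"
            )
        f_hi = f(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target) <= tol * 0.5:
            return float(sign * mid)
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return float(sign * 0.5 * (lo + hi))
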