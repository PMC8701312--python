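"""Synthetic cohort, behavior, and expression generators.

Every downstream stage of the pipeline is exercised on data from this
module: an icosphere standing in for the registered cortical template,
two-timepoint thickness maps with age-related thinning and (optionally)
spatially clustered group differences in the thinning rate, group-skewed
RBS-R item responses with missingness, and a genes-by-samples expression
matrix containing genes whose spatial profile tracks a planted effect map.

The generative model for thickness at vertex ``v`` of subject ``i``::

    signal_T1(i, v) = baseline_ct + subject_offset_i + age_slope * (age_i - mean_age)
    CT_T1(i, v)     = signal_T1(i, v) + eps1(i, v)
    CT_T2(i, v)     = signal_T1(i, v)
                      + isi_i * (thinning_rate_td + sign_c * group_rate_delta
                                 * 1[i in ASD] * 1[v in planted cluster c])
                      + eps2(i, v)

with independent measurement noise ``eps`` at each timepoint
(sd = ``noise_sd``).  Ground truth (cluster labels, true rate delta, planted
gene identities) travels on a separate ``truth`` channel that analysis
stages never receive.

One master seed feeds a named sub-stream per component, so changing, say,
the behavioral draw cannot perturb the thickness maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import Cohort, SubjectRecord, GeneSet, N_RBSR_ITEMS, RBSR_ITEM_MAX
from .mesh import SurfaceMesh

_STREAMS = {"mesh": 0, "thickness": 1, "behavior": 2, "expression": 3, "demographics": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one simulation component."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


# ---------------------------------------------------------------------------
# Configuration


#: Synthetic item->factor partition of the 43 RBS-R items.  The published
#: four-factor assignment is not reproduced here; this partition only has to
#: respect the factor sizes implied by the subscale score ranges.
DEFAULT_FACTOR_MAP: dict[int, str] = {
    **{i: "F1" for i in range(1, 19)},    # persistent
    **{i: "F2" for i in range(19, 25)},   # stereotyped
    **{i: "F3" for i in range(25, 33)},   # self-injurious
    **{i: "F4" for i in range(33, 44)},   # compulsive
}

#: Per-item mean severities per group and factor, calibrated so the expected
#: subscale totals sit near the observed cohort means (ASD total ~25, TD ~2).
DEFAULT_FACTOR_ITEM_MEANS = {
    "ASD": {"F1": 0.94, "F2": 0.51, "F3": 0.11, "F4": 0.40},
    "TD": {"F1": 0.088, "F2": 0.050, "F3": 0.006, "F4": 0.015},
}


@dataclass
class RbsrSimConfig:
    """Truncated negative-binomial item responses with a subject severity factor."""

    factor_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_FACTOR_MAP))
    factor_item_means: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_FACTOR_ITEM_MEANS.items()})
    subject_dispersion: float = 1.2   # gamma shape of the subject severity multiplier
    t2_innovation: float = 0.25      # sd of the multiplicative T1->T2 severity drift
    missing_rate: float = 0.01       # per-item MCAR probability, capped per subject
    max_missing: int = 3


@dataclass
class ExpressionSimConfig:
    n_genes: int = 1000
    n_samples: int = 150
    n_planted: int = 40
    planted_correlation: float = 0.7


@dataclass
class SimulationConfig:
    """Study-shaped defaults: n = 33 ASD + 37 TD scanned twice ~2 years apart."""

    seed: int = 0
    n_asd: int = 33
    n_td: int = 37
    mesh_subdivisions: int = 4        # 2562 vertices
    mesh_radius: float = 100.0        # mm; spherical-template convention
    baseline_ct: float = 2.7          # mm
    thinning_rate_td: float = -0.035  # mm/year
    group_rate_delta: float = 0.0     # mm/year added to ASD rate inside planted clusters
    planted_clusters: tuple = ()      # (seed_vertex, radius_mm, sign) triples
    subject_sd: float = 0.12          # mm, between-subject baseline spread
    noise_sd: float = 0.05            # mm, per-timepoint measurement noise
    age_slope: float = -0.02          # mm/year cross-sectional age effect
    age_range: tuple = (11.0, 18.0)   # years at T1
    isi_mean: float = 2.07            # years
    isi_sd: float = 0.24
    sex_male_fraction: float = 0.81
    fsiq_mean: dict = field(default_factory=lambda: {"ASD": 101.38, "TD": 107.07})
    fsiq_sd: dict = field(default_factory=lambda: {"ASD": 13.19, "TD": 11.52})
    rbsr: RbsrSimConfig = field(default_factory=RbsrSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)

    def validate(self, mesh: SurfaceMesh) -> None:
        for sd in (self.subject_sd, self.noise_sd, self.isi_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        diameter = np.pi * self.mesh_radius  # half great circle: max geodesic distance
        for seed_vertex, radius, _sign in self.planted_clusters:
            if not 0 <= seed_vertex < mesh.n_vertices:
                raise ValueError(f"planted cluster seed {seed_vertex} not on mesh")
            if radius > diameter:
                raise ValueError(f"planted cluster radius {radius} mm exceeds mesh diameter")


@dataclass
class SyntheticCohort:
    mesh: SurfaceMesh
    ct_t1: np.ndarray          # (n_subjects, n_vertices) mm
    ct_t2: np.ndarray
    subjects: Cohort
    truth: dict                # write-only for analysis stages

    @property
    def isi(self) -> np.ndarray:
        return np.array([s.isi for s in self.subjects])


# ---------------------------------------------------------------------------
# Mesh


def make_icosphere(subdivisions: int = 4, radius: float = 100.0) -> SurfaceMesh:
    """Closed 2-sphere template with 10 * 4**s + 2 vertices."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       mesh_id=f"icosphere-s{subdivisions}-r{radius:g}")
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Cohort simulation


def planted_label_map(mesh: SurfaceMesh, planted_clusters) -> np.ndarray:
    """Integer label per vertex: 0 outside, c>=1 inside planted cluster c."""
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    for c, (seed_vertex, radius, _sign) in enumerate(planted_clusters, start=1):
        labels[mesh.geodesic_ball(int(seed_vertex), float(radius))] = c
    return labels


def simulate_cohort(config: SimulationConfig, mesh: SurfaceMesh | None = None) -> SyntheticCohort:
    """Draw a two-timepoint synthetic cohort under ``config``.

    Identical seeds give bit-identical cohorts; with ``group_rate_delta=0``
    the thickness law is exchangeable across diagnostic groups.
    """
    if mesh is None:
        mesh = make_icosphere(config.mesh_subdivisions, config.mesh_radius)
    config.validate(mesh)
    n = config.n_asd + config.n_td
    V = mesh.n_vertices

    rng_demo = substream(config.seed, "demographics")
    groups = np.array(["ASD"] * config.n_asd + ["TD"] * config.n_td)
    sexes = np.where(rng_demo.random(n) < config.sex_male_fraction, "male", "female")
    ages = rng_demo.uniform(*config.age_range, size=n)
    isi = np.clip(rng_demo.normal(config.isi_mean, config.isi_sd, size=n), 0.5, None)
    fsiq = np.array([rng_demo.normal(config.fsiq_mean[g], config.fsiq_sd[g]) for g in groups])
    handed = np.where(rng_demo.random(n) < 0.9, "right", "left")

    rng_ct = substream(config.seed, "thickness")
    subject_offset = rng_ct.normal(0.0, config.subject_sd, size=n)
    labels = planted_label_map(mesh, config.planted_clusters)
    # per-vertex rate delta applied to ASD subjects
    delta_map = np.zeros(V)
    for c, (_seed, _radius, sign) in enumerate(config.planted_clusters, start=1):
        delta_map[labels == c] = float(sign) * config.group_rate_delta

    is_asd = (groups == "ASD").astype(float)
    signal_t1 = (config.baseline_ct + subject_offset[:, None]
                 + config.age_slope * (ages - ages.mean())[:, None]) * np.ones((1, V))
    rate = config.thinning_rate_td + is_asd[:, None] * delta_map[None, :]
    eps1 = rng_ct.normal(0.0, config.noise_sd, size=(n, V)) if config.noise_sd > 0 else 0.0
    eps2 = rng_ct.normal(0.0, config.noise_sd, size=(n, V)) if config.noise_sd > 0 else 0.0
    ct_t1 = signal_t1 + eps1
    ct_t2 = signal_t1 + isi[:, None] * rate + eps2

    rbsr_t1, rbsr_t2 = _simulate_rbsr(config, groups)

    subjects = Cohort([
        SubjectRecord(
            subject_id=f"sub-{i + 1:03d}", group=groups[i], sex=sexes[i],
            age_t1=float(ages[i]), isi=float(isi[i]), fsiq=float(fsiq[i]),
            handedness=handed[i], rbsr_items_t1=rbsr_t1[i], rbsr_items_t2=rbsr_t2[i])
        for i in range(n)
    ])
    truth = {
        "planted_labels": labels,
        "group_rate_delta": config.group_rate_delta,
        "planted_clusters": tuple(config.planted_clusters),
        "delta_map": delta_map,
    }
    return SyntheticCohort(mesh=mesh, ct_t1=ct_t1, ct_t2=ct_t2, subjects=subjects, truth=truth)


def _simulate_rbsr(config: SimulationConfig, groups: np.ndarray):
    """Item responses: Poisson-gamma counts truncated at the item maximum."""
    rb = config.rbsr
    rng = substream(config.seed, "behavior")
    n = len(groups)
    item_factors = [rb.factor_map[i] for i in range(1, N_RBSR_ITEMS + 1)]

    severity = rng.gamma(rb.subject_dispersion, 1.0 / rb.subject_dispersion, size=n)
    drift = np.exp(rng.normal(0.0, rb.t2_innovation, size=n))
    t1 = np.empty((n, N_RBSR_ITEMS))
    t2 = np.empty((n, N_RBSR_ITEMS))
    for i in range(n):
        mu = np.array([rb.factor_item_means[groups[i]][f] for f in item_factors])
        t1[i] = np.minimum(rng.poisson(mu * severity[i]), RBSR_ITEM_MAX)
        t2[i] = np.minimum(rng.poisson(mu * severity[i] * drift[i]), RBSR_ITEM_MAX)
    for items in (t1, t2):
        miss = rng.random(items.shape) < rb.missing_rate
        # cap missingness at the configured per-subject maximum
        for i in range(n):
            idx = np.flatnonzero(miss[i])
            if len(idx) > rb.max_missing:
                idx = rng.choice(idx, size=rb.max_missing, replace=False)
            items[i, idx] = np.nan
    return t1, t2


# ---------------------------------------------------------------------------
# Expression simulation


def simulate_expression(mesh: SurfaceMesh, effect_map: np.ndarray,
                        config: ExpressionSimConfig, seed: int = 0):
    """Genes-by-samples matrix with ``n_planted`` genes tracking ``effect_map``.

    Samples sit at randomly chosen mesh vertices.  A planted gene's profile
    is ``effect_map`` at the sample vertices plus Gaussian noise scaled so the
    expected Pearson correlation equals ``planted_correlation`` (exactly the
    map when the configured correlation is 1).  Remaining genes are iid
    noise.  Returns ``(ExpressionMatrix, planted_gene_ids)``.
    """
    from .decoding import ExpressionMatrix

    if config.n_planted > config.n_genes:
        raise ValueError("n_planted exceeds n_genes")
    if config.n_samples < 3:
        raise ValueError("need at least 3 samples for spatial correlation")
    rho = config.planted_correlation
    if not 0 < rho <= 1:
        raise ValueError("planted_correlation must be in (0, 1]")

    rng = substream(seed, "expression")
    effect = np.asarray(effect_map, dtype=np.float64).ravel()
    sample_vertices = rng.choice(mesh.n_vertices, size=config.n_samples, replace=False)
    profile = effect[sample_vertices]
    sd_e = profile.std()
    if sd_e == 0:
        raise ValueError("effect map is constant at the sampled vertices")

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    planted_idx = rng.choice(config.n_genes, size=config.n_planted, replace=False)
    values = rng.normal(0.0, 1.0, size=(config.n_genes, config.n_samples))
    noise_sd = sd_e * np.sqrt(1.0 / rho**2 - 1.0)
    planted_noise = (rng.normal(0.0, noise_sd, size=(config.n_planted, config.n_samples))
                     if noise_sd > 0 else 0.0)
    values[planted_idx] = profile[None, :] + planted_noise

    expr = ExpressionMatrix(genes=genes, values=values, sample_vertices=sample_vertices,
                            mesh_id=mesh.mesh_id)
    return expr, [genes[i] for i in planted_idx]


def planted_gene_set(planted_ids, n_in_set: int, n_extra: int,
                     all_genes, seed: int = 0, name: str = "planted") -> GeneSet:
    """A gene set holding ``n_in_set`` planted genes plus ``n_extra`` decoys."""
    rng = np.random.default_rng(seed)
    members = list(rng.choice(planted_ids, size=n_in_set, replace=False))
    decoys = [g for g in all_genes if g not in set(planted_ids)]
    members += list(rng.choice(decoys, size=n_extra, replace=False))
    return GeneSet(name, tuple(members), annotation="synthetic planted set")
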