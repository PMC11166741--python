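"""Synthetic neonatal cortical cohorts on icosphere meshes.

The generator emulates the structure of third-trimester preterm MRI cohorts:
two-hemisphere icosphere surfaces carrying per-vertex morphometric features
(cortical thickness, sulcal depth, GM/WM intensity ratio) that grow linearly
with postmenstrual age (PMA), with smooth spatial variation of the growth
rate, additive/multiplicative acquisition-site effects, clinical risk factors
that delay effective brain maturation, longitudinal repeat scans, and
neurodevelopmental outcome scores loaded on the maturation delay.  Every
latent quantity (the per-subject maturation shift in weeks) is returned as
ground truth so recovery can be tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

HEMI_LEFT = 0
HEMI_RIGHT = 1

FEATURE_NAMES = ("thickness", "sulcal_depth", "gmwm_ratio")

_MAX_LEVEL = 7  # resource guard: level 7 is 163,842 vertices per hemisphere


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated one- or two-hemisphere icosphere.

    Vertex ordering is parent-first within each hemisphere: the vertices of
    subdivision level L-1 occupy the first 10*4^(L-1)+2 indices of a level-L
    hemisphere, so a coarser icosphere's vertex i coincides with the finer
    icosphere's vertex i (per hemisphere).  Hemispheres are stored left block
    first, then right.
    """

    coordinates: np.ndarray  # (n_vertices, 3) float, mm
    faces: np.ndarray  # (n_faces, 3) int
    hemisphere_label: np.ndarray  # (n_vertices,) int8, 0=left 1=right
    level: int

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def n_hemispheres(self) -> int:
        return int(self.hemisphere_label.max()) + 1

    def hemisphere_slices(self) -> list[slice]:
        """Contiguous vertex-index slice per hemisphere (left first)."""
        out = []
        for h in range(self.n_hemispheres):
            idx = np.flatnonzero(self.hemisphere_label == h)
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out

    def unit_positions(self) -> np.ndarray:
        """Per-hemisphere centered, unit-normalized vertex positions."""
        pos = np.empty_like(self.coordinates)
        for sl in self.hemisphere_slices():
            block = self.coordinates[sl]
            centered = block - block.mean(axis=0)
            pos[sl] = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        return pos


def vertices_per_hemisphere(level: int) -> int:
    return 10 * 4**level + 2


def faces_per_hemisphere(level: int) -> int:
    return 20 * 4**level


def edges_per_hemisphere(level: int) -> int:
    return 30 * 4**level


def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One icosphere subdivision; parent vertices keep their indices and
    edge midpoints are appended in first-encounter order (deterministic)."""
    verts = list(verts)
    midpoint: dict[tuple[int, int], int] = {}

    def mid(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in midpoint:
            m = (verts[a] + verts[b]) / 2.0
            m /= np.linalg.norm(m)
            midpoint[key] = len(verts)
            verts.append(m)
        return midpoint[key]

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for i, (a, b, c) in enumerate(faces):
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces[4 * i : 4 * i + 4] = [
            [a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca],
        ]
    return np.asarray(verts), new_faces


def make_icosphere(level: int, hemispheres: int = 2) -> SurfaceMesh:
    """Build a one- or two-hemisphere unit icosphere.

    The left hemisphere is a unit sphere centered at (-1.1, 0, 0); the right
    hemisphere is its mirror image (x negated) centered at (+1.1, 0, 0), so
    the two components are disjoint.  Vertex ordering is parent-first per
    hemisphere (see :class:`SurfaceMesh`).
    """
    if level < 0 or int(level) != level:
        raise ValueError("level must be a non-negative integer")
    if level > _MAX_LEVEL:
        raise ValueError(f"level {level} > {_MAX_LEVEL} refused (resource guard)")
    if hemispheres not in (1, 2):
        raise ValueError("hemispheres must be 1 or 2")

    verts, faces = _base_icosahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)

    n = len(verts)
    left = verts + np.array([-1.1, 0.0, 0.0])
    if hemispheres == 1:
        coords = left
        all_faces = faces
        hemi = np.zeros(n, dtype=np.int8)
    else:
        right = verts * np.array([-1.0, 1.0, 1.0]) + np.array([1.1, 0.0, 0.0])
        coords = np.vstack([left, right])
        # mirroring flips orientation; reverse winding to keep normals outward
        all_faces = np.vstack([faces, faces[:, ::-1] + n])
        hemi = np.concatenate([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    return SurfaceMesh(coords, all_faces, hemi, int(level))


def mesh_adjacency(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Sparse binary symmetric adjacency derived from the faces."""
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n = mesh.n_vertices
    a = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    a = a + a.T
    a.data[:] = 1.0
    a = a.tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    return a


# --------------------------------------------------------------------------
# cohort records and feature maps
# --------------------------------------------------------------------------


@dataclass
class ScanRecord:
    """Metadata for one MRI scan."""

    scan_id: str
    subject_id: str
    site_id: str
    sex: str  # "M" / "F"
    ga_birth: float  # weeks
    birthweight: float  # grams
    pma_scan: float  # weeks
    clinical_flags: dict[str, int] = field(default_factory=dict)
    outcome_scores: dict[str, float] | None = None
    true_maturation_shift: float | None = None  # weeks; simulation only

    def __post_init__(self) -> None:
        if self.pma_scan < self.ga_birth:
            raise ValueError(
                f"pma_scan {self.pma_scan} < ga_birth {self.ga_birth} "
                f"for scan {self.scan_id}"
            )
        for name, wk in (("ga_birth", self.ga_birth), ("pma_scan", self.pma_scan)):
            if not 20.0 <= wk <= 50.0:
                raise ValueError(f"{name}={wk} outside [20, 50] weeks")


@dataclass
class FeatureMap:
    """Per-vertex morphometric features for one scan.

    Columns are ordered (thickness mm, sulcal_depth mm, gmwm_ratio)."""

    scan_id: str
    values: np.ndarray  # (n_vertices, 3)
    mesh_level: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError("values must be (n_vertices, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values in scan {self.scan_id}")
        if np.any(self.values[:, 0] <= 0):
            raise ValueError(f"non-positive thickness in scan {self.scan_id}")
        if np.any(self.values[:, 2] <= 0):
            raise ValueError(f"non-positive GM/WM ratio in scan {self.scan_id}")


@dataclass(frozen=True)
class FeatureParams:
    """Linear developmental model of one feature: value = baseline(v) +
    slope(v) * (pma - shift - 26) + site effects + noise."""

    baseline: float
    baseline_amplitude: float  # spatial variation of the baseline
    slope: float  # per week
    slope_amplitude: float  # spatial variation of the slope
    noise_sd: float  # vertexwise residual SD


@dataclass(frozen=True)
class SiteParams:
    """Additive location and multiplicative scale effect of one site,
    per feature (length-3 tuples, feature order as FEATURE_NAMES)."""

    location: tuple[float, float, float]
    scale: float


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate a preterm cohort scanned twice during the third
    trimester at two acquisition sites: gestational age at birth
    28.2 +/- 1.9 weeks, birthweight 1080 +/- ~310 g, first scan at PMA
    31.4 +/- 1.9 weeks, ~30% of subjects rescanned 4-5 weeks later, and
    binary postnatal clinical factors at their observed prevalences, each
    delaying effective brain maturation by w_j weeks.  Outcome scores
    (Bayley-III-like; population mean ~100) load negatively on the total
    maturation delay.
    """

    n_subjects: int = 129
    repeat_scan_fraction: float = 0.3
    mesh_level: int = 3
    site_probs: dict[str, float] = field(
        default_factory=lambda: {"site_1p5T": 0.43, "site_3T": 0.57}
    )
    male_prob: float = 0.54
    ga_birth_mean: float = 28.2
    ga_birth_sd: float = 1.9
    birthweight_slope: float = 100.0  # g per GA week
    birthweight_mean: float = 1080.0
    birthweight_resid_sd: float = 240.0
    pma_scan1_mean: float = 31.4
    pma_scan1_sd: float = 1.9
    repeat_gap_weeks: tuple[float, float] = (4.0, 5.0)
    flag_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "postnatal_steroids": 0.14,
            "chronic_lung_disease": 0.279,
            "hypotension": 0.589,
            "infection": 0.542,
            "pda": 0.504,
            "nec": 0.039,
        }
    )
    flag_effect_weeks: dict[str, float] = field(
        default_factory=lambda: {
            "postnatal_steroids": 0.8,
            "chronic_lung_disease": 0.6,
            "hypotension": 0.25,
            "infection": 0.25,
            "pda": 0.2,
            "nec": 0.5,
        }
    )
    subject_shift_sd: float = 0.5  # weeks, subject random effect
    features: dict[str, FeatureParams] = field(
        default_factory=lambda: {
            "thickness": FeatureParams(1.2, 0.10, 0.04, 0.02, 0.20),
            "sulcal_depth": FeatureParams(2.0, 0.50, 0.35, 0.15, 1.50),
            "gmwm_ratio": FeatureParams(1.10, 0.05, -0.012, 0.006, 0.08),
        }
    )
    site_effects: dict[str, SiteParams] = field(
        default_factory=lambda: {
            "site_1p5T": SiteParams((0.05, 0.3, 0.02), 1.15),
            "site_3T": SiteParams((0.0, 0.0, 0.0), 1.0),
        }
    )
    outcome_fraction: float = 0.295  # 38/129 follow-up
    outcomes: dict[str, tuple[float, float, float]] = field(
        # name -> (intercept, loading lambda on -shift, residual SD)
        default_factory=lambda: {
            "cognitive": (103.0, 9.0, 13.0),
            "language": (92.6, 6.0, 13.0),
            "motor": (93.7, 2.0, 13.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in {**self.site_probs, **self.flag_prevalence}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name} outside [0, 1]: {p}")
        for frac in (self.repeat_scan_fraction, self.outcome_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        sds = [self.ga_birth_sd, self.pma_scan1_sd, self.subject_shift_sd]
        if any(s < 0 for s in sds):
            raise ValueError("SDs must be non-negative")
        if abs(sum(self.site_probs.values()) - 1.0) > 1e-9:
            raise ValueError("site probabilities must sum to 1")

    def expected_shift(self) -> float:
        """Population mean of the maturation shift (weeks)."""
        return sum(
            self.flag_effect_weeks.get(k, 0.0) * p
            for k, p in self.flag_prevalence.items()
        )

    def shift_sd(self) -> float:
        """Population SD of the maturation shift (weeks)."""
        var = self.subject_shift_sd**2
        for k, p in self.flag_prevalence.items():
            var += self.flag_effect_weeks.get(k, 0.0) ** 2 * p * (1 - p)
        return float(np.sqrt(var))

    def noise_floor_mae(self) -> float:
        """Irreducible MAE (weeks) of any feature-based age predictor.

        Features depend on PMA only through (pma - shift); the shift itself
        is invisible to the predictor, so the best achievable absolute error
        is E|shift - E shift| = sqrt(2/pi) * SD(shift) under normality.
        """
        return float(np.sqrt(2.0 / np.pi) * self.shift_sd())

    def with_(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def spatially_structured(cls, **kwargs) -> "SimulationConfig":
        """Variant with low per-vertex signal-to-noise: vertexwise distractor
        noise is quadrupled so that only predictors exploiting the spatial
        smoothness of the growth pattern can average it away."""
        cfg = cls(**kwargs)
        cfg.features = {
            k: dataclasses.replace(v, noise_sd=4.0 * v.noise_sd)
            for k, v in cfg.features.items()
        }
        return cfg


@dataclass
class Cohort:
    """A simulated cohort: shared mesh, scan records, aligned feature maps."""

    mesh: SurfaceMesh
    records: list[ScanRecord]
    feature_maps: list[FeatureMap]
    config: SimulationConfig

    @property
    def n_scans(self) -> int:
        return len(self.records)

    def feature_array(self) -> np.ndarray:
        """(n_scans, n_vertices, 3) stacked feature values."""
        return np.stack([fm.values for fm in self.feature_maps])

    def metadata(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "scan_id": r.scan_id,
                "subject_id": r.subject_id,
                "site_id": r.site_id,
                "sex": r.sex,
                "ga_birth": r.ga_birth,
                "birthweight": r.birthweight,
                "pma_scan": r.pma_scan,
                "true_maturation_shift": r.true_maturation_shift,
            }
            row.update(r.clinical_flags)
            if r.outcome_scores:
                row.update(r.outcome_scores)
            rows.append(row)
        return pd.DataFrame(rows)


def _spatial_pattern(unit_pos: np.ndarray, kind: int) -> np.ndarray:
    """Smooth, seed-free, zero-mean spatial pattern from low-order real
    spherical harmonics of the unit-sphere vertex positions; unit SD."""
    x, y, z = unit_pos[:, 0], unit_pos[:, 1], unit_pos[:, 2]
    if kind == 0:
        p = z  # Y_1,0
    elif kind == 1:
        p = x * y * np.sqrt(15.0 / 4.0)  # ~Y_2,-2
    else:
        p = (x**2 - y**2) * np.sqrt(15.0 / 16.0) + 0.5 * z  # mixed order 1+2
    p = p - p.mean()
    sd = p.std()
    return p / sd if sd > 0 else p


def simulate_cohort(config: SimulationConfig, mesh: SurfaceMesh | None = None) -> Cohort:
    """Generate a reproducible synthetic cohort.

    Per-vertex feature value for scan s at vertex v:

        baseline_f + b_f * pattern_b(v)
        + (slope_f + a_f * pattern_a(v)) * (pma_s - shift_subj - 26)
        + site_location_f + site_scale * noise_sd_f * eps_{svf}

    where shift_subj = sum_j w_j flag_j + subject random effect (weeks) is
    the ground-truth maturation delay, shared across a subject's scans.
    """
    rng = np.random.default_rng(config.seed)
    if mesh is None:
        mesh = make_icosphere(config.mesh_level, hemispheres=2)
    elif mesh.level != config.mesh_level:
        raise ValueError("mesh level does not match config.mesh_level")
    unit_pos = mesh.unit_positions()

    n = config.n_subjects
    sites = list(config.site_probs)
    site_p = np.array([config.site_probs[s] for s in sites])
    subj_site = rng.choice(len(sites), size=n, p=site_p)
    subj_sex = np.where(rng.random(n) < config.male_prob, "M", "F")
    ga = rng.normal(config.ga_birth_mean, config.ga_birth_sd, size=n)
    ga = np.clip(ga, 23.0, 42.0)
    bw = (
        config.birthweight_mean
        + config.birthweight_slope * (ga - config.ga_birth_mean)
        + rng.normal(0.0, config.birthweight_resid_sd, size=n)
    )
    bw = np.maximum(bw, 350.0)

    flags = {
        k: (rng.random(n) < p).astype(int) for k, p in config.flag_prevalence.items()
    }
    shift = rng.normal(0.0, config.subject_shift_sd, size=n)
    for k, f in flags.items():
        shift = shift + config.flag_effect_weeks.get(k, 0.0) * f

    pma1 = rng.normal(config.pma_scan1_mean, config.pma_scan1_sd, size=n)
    pma1 = np.maximum(pma1, ga + 0.3)
    pma1 = np.clip(pma1, 26.0, 45.0)
    has_repeat = rng.random(n) < config.repeat_scan_fraction
    gap = rng.uniform(*config.repeat_gap_weeks, size=n)
    pma2 = np.minimum(pma1 + gap, 49.5)

    fp = [config.features[f] for f in FEATURE_NAMES]
    patt_a = np.stack([_spatial_pattern(unit_pos, i) for i in range(3)], axis=1)
    patt_b = np.stack([_spatial_pattern(unit_pos, (i + 1) % 3) for i in range(3)], axis=1)
    baseline = np.array([p.baseline for p in fp]) + patt_b * np.array(
        [p.baseline_amplitude for p in fp]
    )
    slope_v = np.array([p.slope for p in fp]) + patt_a * np.array(
        [p.slope_amplitude for p in fp]
    )
    noise_sd = np.array([p.noise_sd for p in fp])

    records: list[ScanRecord] = []
    feature_maps: list[FeatureMap] = []
    for i in range(n):
        subject_id = f"sub-{i:04d}"
        site = sites[subj_site[i]]
        se = config.site_effects[site]
        occasions = [pma1[i]] + ([pma2[i]] if has_repeat[i] else [])
        for occ, pma in enumerate(occasions, start=1):
            scan_id = f"{subject_id}_scan-{occ}"
            age_arg = pma - shift[i] - 26.0
            eps = rng.standard_normal((mesh.n_vertices, 3))
            values = (
                baseline
                + slope_v * age_arg
                + np.asarray(se.location)
                + se.scale * noise_sd * eps
            )
            # positivity guards for thickness and GM/WM ratio; at the default
            # noise levels these never bind (>5 sigma), but heavy-noise
            # variants must still produce valid maps
            values[:, 0] = np.maximum(values[:, 0], 0.05)
            values[:, 2] = np.maximum(values[:, 2], 0.05)
            records.append(
                ScanRecord(
                    scan_id=scan_id,
                    subject_id=subject_id,
                    site_id=site,
                    sex=str(subj_sex[i]),
                    ga_birth=float(ga[i]),
                    birthweight=float(bw[i]),
                    pma_scan=float(pma),
                    clinical_flags={k: int(v[i]) for k, v in flags.items()},
                    true_maturation_shift=float(shift[i]),
                )
            )
            feature_maps.append(FeatureMap(scan_id, values, mesh.level))
    return Cohort(mesh, records, feature_maps, config)


def simulate_outcomes(
    records: list[ScanRecord],
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assign outcome scores to a random subset of subjects.

    score = intercept - lambda * (shift - E[shift]) + N(0, residual SD); the
    shift is centered at its population expectation so the score mean equals
    the configured intercept.  Only ``outcome_fraction`` of subjects receive
    scores (emulating partial follow-up); scores are written back onto the
    records and returned as a subject-level table.
    """
    if any(r.true_maturation_shift is None for r in records):
        raise ValueError("records must carry true_maturation_shift")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    subjects: dict[str, float] = {}
    for r in records:
        subjects.setdefault(r.subject_id, r.true_maturation_shift)
    subj_ids = sorted(subjects)
    followed = rng.random(len(subj_ids)) < config.outcome_fraction
    e_shift = config.expected_shift()

    rows = []
    scores_by_subject: dict[str, dict[str, float]] = {}
    for sid, keep in zip(subj_ids, followed):
        if not keep:
            continue
        shift = subjects[sid]
        scores = {}
        for name, (intercept, lam, resid_sd) in config.outcomes.items():
            scores[name] = float(
                intercept - lam * (shift - e_shift) + rng.normal(0.0, resid_sd)
            )
        scores_by_subject[sid] = scores
        rows.append({"subject_id": sid, **scores})
    for r in records:
        if r.subject_id in scores_by_subject:
            r.outcome_scores = dict(scores_by_subject[r.subject_id])
    return pd.DataFrame(rows)
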