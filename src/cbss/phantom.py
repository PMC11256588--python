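"""Synthetic digital head phantoms for the CSF pseudodiffusivity pipeline.

Each phantom subject is a procedural head on the acquisition grid: an
ellipsoidal brain with a subarachnoid CSF shell, a two-voxel cortical
gray-matter ribbon carrying a sulcus/cistern atlas, a white-matter core,
two lateral-ventricle blobs joined through a narrow midline
third-ventricle channel (so the distance-zone fine mapping has a
junction to anchor on) and a small fourth ventricle. Low-b diffusion
signals are generated from the single-compartment isotropic decay
S(b) = S(0) exp(-b D*) with a per-region true pseudodiffusivity, plus
optional Gaussian or Rician (magnitude) noise. Covariates with planted
region-on-covariate effects let the downstream statistics be checked
against a known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import ANAT, GmAtlas, RegionDef, VENTRICLE_REGIONS
from .grid import AcquisitionScheme, DiffusionSeries, VoxelGrid, default_low_b_scheme
from .parcellation import nearest_label_assign

__all__ = [
    "PlantedEffect", "PhantomSpec", "PhantomSubject",
    "generate_subject", "generate_cohort",
    "PHANTOM_ATLAS_REGIONS", "REGION_DSTAR_DEFAULT",
]

#: Sulcus/cistern atlas painted on the phantom's GM ribbon: four
#: bilateral pairs, two sulci (superior octants) and two cisterns
#: (inferior octants).
PHANTOM_ATLAS_REGIONS: dict[int, RegionDef] = {
    101: RegionDef(101, "central_sulcus_left", "left", "sulcus", "central_sulcus"),
    102: RegionDef(102, "central_sulcus_right", "right", "sulcus", "central_sulcus"),
    103: RegionDef(103, "parietooccipital_sulcus_left", "left", "sulcus", "parietooccipital_sulcus"),
    104: RegionDef(104, "parietooccipital_sulcus_right", "right", "sulcus", "parietooccipital_sulcus"),
    105: RegionDef(105, "suprasellar_cistern_left", "left", "cistern", "suprasellar_cistern"),
    106: RegionDef(106, "suprasellar_cistern_right", "right", "cistern", "suprasellar_cistern"),
    107: RegionDef(107, "prepontine_cistern_left", "left", "cistern", "prepontine_cistern"),
    108: RegionDef(108, "prepontine_cistern_right", "right", "cistern", "prepontine_cistern"),
}

#: Ground-truth pseudodiffusivity per merged region (mm^2/s). Cisterns
#: and the third/fourth ventricles run fast, cortical sulci slow,
#: mirroring the regional ordering low-b imaging reports in vivo.
REGION_DSTAR_DEFAULT: dict[str, float] = {
    "central_sulcus": 2.4e-3,
    "parietooccipital_sulcus": 2.2e-3,
    "suprasellar_cistern": 5.5e-3,
    "prepontine_cistern": 6.5e-3,
    "lateral_ventricle": 4.0e-3,
    "third_ventricle": 6.0e-3,
    "fourth_ventricle": 5.0e-3,
}

#: population mean/sd/loading-on-latent-cognition of each cognitive score
_COGNITION_POP = {
    "mmse": (26.0, 3.0, 0.80),
    "moca": (20.0, 5.0, 0.85),
    "stm": (10.0, 3.0, 0.75),
    "ltm": (9.0, 3.0, 0.75),
    "tmta": (60.0, 20.0, -0.60),
}
_AGE_POP = (68.0, 9.0)
_EDUCATION_POP = (12.0, 3.0)
_MALE_FRACTION = 0.383


@dataclass(frozen=True)
class PlantedEffect:
    """A known effect of one covariate on one region's true D*.

    The subject's regional D* is ``base * (1 + rel_sd * u)`` with
    ``u = slope * z_cov + sqrt(1 - slope^2) * e`` and ``e ~ N(0, 1)``,
    so the standardized regression slope of regional D* on the
    covariate's z-score is ``slope`` by construction.
    """

    region: str
    covariate: str
    slope: float
    rel_sd: float = 0.1

    def __post_init__(self) -> None:
        if not -1.0 <= self.slope <= 1.0:
            raise ValueError("planted standardized slope must lie in [-1, 1]")
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a synthetic cohort; same spec + seed give
    bit-identical outputs."""

    shape: tuple[int, int, int] = (24, 34, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    s0: float = 1000.0
    region_dstar: dict[str, float] = field(default_factory=lambda: dict(REGION_DSTAR_DEFAULT))
    tissue_adc: float = 0.8e-3  # parenchymal decay, slower than any CSF region
    noise_model: str = "rician"  # none | gaussian | rician
    sigma: float = 0.02  # noise sd as a fraction of s0
    n_b0: int = 5
    b_max: float = 200.0
    cohort_size: int = 1
    planted_effects: tuple[PlantedEffect, ...] = ()
    region_rel_sd: float = 0.1  # between-subject D* variation without a planted effect
    cbf_coupling_base: float = 0.4
    cbf_age_coupling: float = 0.0  # slope of the MPD-CBF coupling on z(age)
    third_gradient_per_mm: float = 0.0  # fractional D* change per mm along the third ventricle
    jitter: bool = True  # per-subject geometric jitter (topology preserved)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(
                f"grid {self.shape} too small: need at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if any(d <= 0 for d in self.region_dstar.values()):
            raise ValueError("all region pseudodiffusivities must be positive")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.cohort_size < 1:
            raise ValueError("cohort size must be at least 1")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for eff in self.planted_effects:
            if eff.region not in self.region_dstar:
                raise ValueError(f"planted effect targets unknown region {eff.region!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))

    @property
    def scheme(self) -> AcquisitionScheme:
        return default_low_b_scheme(n_b0=self.n_b0, b_max=self.b_max)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_effects"] = [asdict(e) for e in self.planted_effects]
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "PhantomSpec":
        payload = json.loads(Path(path).read_text())
        payload["planted_effects"] = tuple(
            PlantedEffect(**e) for e in payload.get("planted_effects", ()))
        for key in ("shape", "spacing"):
            payload[key] = tuple(payload[key])
        return PhantomSpec(**payload)


@dataclass(frozen=True)
class PhantomSubject:
    """One synthetic subject: maps, signals and covariates with truth."""

    subject_id: str
    anat: VoxelGrid  # anatomical segmentation (aseg-style codes)
    atlas: GmAtlas
    free_water: VoxelGrid
    cfa: VoxelGrid
    series: DiffusionSeries
    cbf: VoxelGrid
    covariates: dict[str, float]
    true_dstar: dict[str, float]  # merged region -> this subject's D*
    true_dstar_map: VoxelGrid  # per-voxel generating D* (NaN outside CSF)


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    rho2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return rho2 <= 1.0


def _make_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Procedural head geometry; returns (anat labels, atlas labels)."""
    shape = spec.shape
    c = (np.asarray(shape, float) - 1.0) / 2.0
    semi = 0.44 * np.asarray(shape, float)
    if spec.jitter:
        semi = semi + rng.uniform(-0.3, 0.3, size=3)
        c = c + rng.uniform(-0.3, 0.3, size=3)

    head = _ellipsoid(shape, c, semi)
    inner1 = _ellipsoid(shape, c, np.maximum(semi - 1.4, 0.5))
    inner2 = _ellipsoid(shape, c, np.maximum(semi - 3.4, 0.5))
    sas = head & ~inner1
    gm = inner1 & ~inner2
    core = inner2

    core_semi = np.maximum(semi - 3.4, 0.5)
    idx = np.indices(shape, dtype=float)
    x, y, z = idx

    lat_dx = 0.50 * core_semi[0]
    lat_center_y = c[1] + 0.35 * core_semi[1]
    lat_semi = np.array([0.32 * core_semi[0], 0.45 * core_semi[1], 0.50 * core_semi[2]])
    if spec.jitter:
        lat_semi = lat_semi * (1.0 + rng.uniform(-0.08, 0.08, size=3))
    lat_left = _ellipsoid(shape, np.array([c[0] - lat_dx, lat_center_y, c[2] + 0.1 * core_semi[2]]), lat_semi) & core
    lat_right = _ellipsoid(shape, np.array([c[0] + lat_dx, lat_center_y, c[2] + 0.1 * core_semi[2]]), lat_semi) & core

    # midline third-ventricle channel: runs posterior from under the
    # lateral blobs so a 3-voxel dilation of either blob reaches it
    chan = (
        (np.abs(x - c[0]) <= 0.6)
        & (y >= c[1] - core_semi[1] + 0.5)
        & (y <= c[1] + 0.15 * core_semi[1])
        & (np.abs(z - c[2]) <= 1.2)
    ) & core & ~lat_left & ~lat_right

    fourth = _ellipsoid(
        shape,
        np.array([c[0], c[1] - 0.55 * core_semi[1], c[2] - 0.55 * core_semi[2]]),
        np.array([0.20 * core_semi[0], 0.18 * core_semi[1], 0.25 * core_semi[2]]),
    ) & core & ~chan & ~lat_left & ~lat_right

    anat = np.zeros(shape, dtype=np.int16)
    left = x < c[0]
    anat[core & left] = ANAT.LEFT_WM
    anat[core & ~left] = ANAT.RIGHT_WM
    anat[gm & left] = ANAT.LEFT_GM
    anat[gm & ~left] = ANAT.RIGHT_GM
    anat[sas] = ANAT.SUBARACHNOID
    anat[lat_left] = ANAT.LEFT_LATERAL_VENTRICLE
    anat[lat_right] = ANAT.RIGHT_LATERAL_VENTRICLE
    anat[chan] = ANAT.THIRD_VENTRICLE
    anat[fourth] = ANAT.FOURTH_VENTRICLE

    # atlas octants on the GM ribbon: sulci above the equator, cisterns below
    atlas = np.zeros(shape, dtype=np.int16)
    gm_mask = np.isin(anat, (ANAT.LEFT_GM, ANAT.RIGHT_GM))
    sup = z >= c[2]
    ant = y >= c[1]
    atlas[gm_mask & sup & ant & left] = 101
    atlas[gm_mask & sup & ant & ~left] = 102
    atlas[gm_mask & sup & ~ant & left] = 103
    atlas[gm_mask & sup & ~ant & ~left] = 104
    atlas[gm_mask & ~sup & ant & left] = 105
    atlas[gm_mask & ~sup & ant & ~left] = 106
    atlas[gm_mask & ~sup & ~ant & left] = 107
    atlas[gm_mask & ~sup & ~ant & ~left] = 108
    return anat, atlas


def _covariates(spec: PhantomSpec, rng: np.random.Generator) -> dict[str, float]:
    age = rng.normal(*_AGE_POP)
    sex = float(rng.uniform() < _MALE_FRACTION)
    education = float(np.clip(np.round(rng.normal(*_EDUCATION_POP)), 5, 22))
    g = rng.normal()
    cov = {"age": float(age), "sex": sex, "education": education}
    for name, (mu, sd, w) in _COGNITION_POP.items():
        e = rng.normal()
        cov[name] = float(mu + sd * (w * g + np.sqrt(1.0 - w ** 2) * e))
    return cov


def _population_z(name: str, value: float) -> float:
    """Z-score a covariate against its generating population moments."""
    if name == "age":
        mu, sd = _AGE_POP
    elif name == "education":
        mu, sd = _EDUCATION_POP
    elif name in _COGNITION_POP:
        mu, sd, _ = _COGNITION_POP[name]
    else:
        raise ValueError(f"no population moments for covariate {name!r}")
    return (value - mu) / sd


def _subject_dstar(spec: PhantomSpec, cov: dict[str, float], rng: np.random.Generator) -> dict[str, float]:
    effects = {eff.region: eff for eff in spec.planted_effects}
    out = {}
    for region in sorted(spec.region_dstar):
        base = spec.region_dstar[region]
        e = rng.normal()
        if region in effects:
            eff = effects[region]
            zc = _population_z(eff.covariate, cov[eff.covariate])
            u = eff.slope * zc + np.sqrt(1.0 - eff.slope ** 2) * e
            rel = eff.rel_sd
        else:
            u = e
            rel = spec.region_rel_sd
        out[region] = float(base * max(1.0 + rel * u, 0.2))
    return out


def _third_ventricle_gradient(anat: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Multiplicative D* factor along the third ventricle (1 at its start)."""
    from .finemap import find_third_ventricle_start  # local: avoid import cycle

    lat = np.isin(anat, (ANAT.LEFT_LATERAL_VENTRICLE, ANAT.RIGHT_LATERAL_VENTRICLE))
    third = anat == ANAT.THIRD_VENTRICLE
    factor = np.ones(anat.shape)
    if spec.third_gradient_per_mm == 0 or not lat.any() or not third.any():
        return factor
    seed = find_third_ventricle_start(lat, third)
    dist = ndimage.distance_transform_edt(~seed, sampling=spec.spacing)
    factor[third] = np.maximum(1.0 + spec.third_gradient_per_mm * dist[third], 0.1)
    return factor


def generate_subject(spec: PhantomSpec, subject_index: int = 0) -> PhantomSubject:
    """Generate one phantom subject deterministically from (spec, index)."""
    streams = np.random.SeedSequence(spec.seed, spawn_key=(int(subject_index),)).spawn(5)
    rng_cov, rng_geom, rng_tissue, rng_noise, rng_cbf = (np.random.default_rng(s) for s in streams)

    cov = _covariates(spec, rng_cov)
    anat, atlas_labels = _make_geometry(spec, rng_geom)
    dstar_by_region = _subject_dstar(spec, cov, rng_cov)

    csf_like = np.isin(anat, (
        ANAT.SUBARACHNOID, ANAT.LEFT_LATERAL_VENTRICLE, ANAT.RIGHT_LATERAL_VENTRICLE,
        ANAT.THIRD_VENTRICLE, ANAT.FOURTH_VENTRICLE))
    gm_mask = np.isin(anat, (ANAT.LEFT_GM, ANAT.RIGHT_GM))
    wm_mask = np.isin(anat, (ANAT.LEFT_WM, ANAT.RIGHT_WM))
    head = csf_like | gm_mask | wm_mask

    # tissue-property maps
    fw = np.zeros(spec.shape)
    fw[csf_like] = 0.96 + 0.03 * rng_tissue.uniform(size=int(csf_like.sum()))
    fw[gm_mask] = 0.12 + 0.06 * rng_tissue.uniform(size=int(gm_mask.sum()))
    # WM free water kept at zero so CSF + WM fractions close to <= 1
    # even where the two-class split assigns a WM fraction of one
    fw[wm_mask] = 0.0
    cfa = np.zeros(spec.shape)
    cfa[wm_mask] = 0.60 + 0.15 * rng_tissue.uniform(size=int(wm_mask.sum()))
    cfa[gm_mask] = 0.12 + 0.06 * rng_tissue.uniform(size=int(gm_mask.sum()))
    cfa[csf_like] = 0.02 * rng_tissue.uniform(size=int(csf_like.sum()))

    # per-voxel generating D*: ventricles by their own region, the
    # subarachnoid shell by its nearest gray-matter atlas label
    dstar_map = np.full(spec.shape, np.nan)
    for code, region in VENTRICLE_REGIONS.items():
        vox = anat == code
        if vox.any():
            dstar_map[vox] = dstar_by_region[region.merged_name]
    sas_idx = np.argwhere(anat == ANAT.SUBARACHNOID)
    if sas_idx.size:
        codes = nearest_label_assign(sas_idx, atlas_labels, spec.spacing)
        merged = np.array([PHANTOM_ATLAS_REGIONS[int(cd)].merged_name for cd in codes])
        vals = np.array([dstar_by_region[m] for m in merged])
        dstar_map[tuple(sas_idx.T)] = vals
    dstar_map[csf_like] *= _third_ventricle_gradient(anat, spec)[csf_like]

    # signals: mono-exponential decay, parenchyma decays slower
    scheme = spec.scheme
    decay_d = np.zeros(spec.shape)
    decay_d[csf_like] = dstar_map[csf_like]
    decay_d[gm_mask | wm_mask] = spec.tissue_adc
    signal = np.zeros(spec.shape + (scheme.n_volumes,))
    signal[head] = spec.s0 * np.exp(-np.outer(decay_d[head], scheme.bvals))
    if spec.noise_model == "gaussian" and spec.sigma > 0:
        signal = signal + spec.sigma * spec.s0 * rng_noise.standard_normal(signal.shape)
    elif spec.noise_model == "rician" and spec.sigma > 0:
        n1 = rng_noise.standard_normal(signal.shape)
        n2 = rng_noise.standard_normal(signal.shape)
        s = spec.sigma * spec.s0
        signal = np.sqrt((signal + s * n1) ** 2 + (s * n2) ** 2)

    # CBF: regional values coupled to the subject's D* profile with an
    # age-modulated gain, painted on the GM ribbon
    base_cbf = float(np.clip(rng_cbf.normal(48.7, 14.0), 20.0, 90.0))
    atlas_merged = sorted({r.merged_name for r in PHANTOM_ATLAS_REGIONS.values()})
    profile = np.array([dstar_by_region[m] for m in atlas_merged])
    s_profile = (profile - profile.mean()) / (profile.std() if profile.std() > 0 else 1.0)
    gain = 8.0 * (spec.cbf_coupling_base + spec.cbf_age_coupling * _population_z("age", cov["age"]))
    regional_cbf = {
        m: float(base_cbf + gain * s_profile[i] + rng_cbf.normal(0.0, 2.0))
        for i, m in enumerate(atlas_merged)
    }
    cbf = np.zeros(spec.shape)
    for code, region in PHANTOM_ATLAS_REGIONS.items():
        vox = atlas_labels == code
        if vox.any():
            cbf[vox] = regional_cbf[region.merged_name] + rng_cbf.normal(0.0, 2.0, size=int(vox.sum()))
    cbf[wm_mask] = 0.4 * base_cbf + rng_cbf.normal(0.0, 2.0, size=int(wm_mask.sum()))

    grid = VoxelGrid(anat, spec.spacing)
    atlas = GmAtlas(grid.like(atlas_labels), dict(PHANTOM_ATLAS_REGIONS))
    return PhantomSubject(
        subject_id=f"sub-{subject_index:03d}",
        anat=grid,
        atlas=atlas,
        free_water=grid.like(fw),
        cfa=grid.like(cfa),
        series=DiffusionSeries(signal, scheme, spec.spacing),
        cbf=grid.like(cbf),
        covariates=cov,
        true_dstar=dstar_by_region,
        true_dstar_map=grid.like(dstar_map),
    )


def generate_cohort(spec: PhantomSpec) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate the full cohort plus its covariate table."""
    subjects = [generate_subject(spec, i) for i in range(spec.cohort_size)]
    table = pd.DataFrame(
        [{"subject": s.subject_id, **s.covariates} for s in subjects]
    ).set_index("subject")
    return subjects, table
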