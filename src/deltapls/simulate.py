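"""Synthetic longitudinal cohorts with known planted effects.

Generates demographics, masked parameter maps and symptom tables that mimic
the structure of a sport-concussion imaging study: a large control cohort
imaged once and a concussed cohort imaged at acute injury (ACU), return to
play (RTP) and one year post-RTP (YR1), with session-dependent attrition.
Every map is a sum of a modality baseline, demographic offsets (sex, age,
history of concussion), a subject-level random intercept, optional planted
group and sex-by-group effects in known regions, and spatially smooth
Gaussian noise.  The ground truth (regions, amplitudes, dropout pattern) is
returned alongside the data so downstream inference can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .io import (
    SESSIONS,
    MaskGeometry,
    ParameterMap,
    SubjectRecord,
    write_mask,
    write_stat_map,
)
from .clinical import SYMPTOM_ITEMS

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SPORTS = ("hockey", "rugby", "football", "soccer", "basketball", "volleyball")


@lru_cache(maxsize=32)
def _smoothing_norm(dims: tuple[int, ...], sigma_vox: tuple[float, ...]) -> float:
    """L2 norm of the periodic Gaussian smoothing kernel on this grid.

    Dividing a smoothed white-noise field by this factor restores unit
    variance exactly (circular boundary), so noise amplitude is controlled
    by ``noise_sd`` alone regardless of the smoothing scale.
    """
    impulse = np.zeros(dims)
    impulse[tuple(0 for _ in dims)] = 1.0
    kernel = gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
    return float(np.sqrt((kernel ** 2).sum()))


def smooth_gaussian_field(
    dims: tuple[int, int, int],
    voxel_size: float | np.ndarray,
    fwhm: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with Gaussian-shaped
    spatial autocorrelation of the given FWHM (mm).

    ``fwhm=0`` yields i.i.d. standard normal noise.  Smoothing uses
    periodic boundaries so the field is stationary; the field is rescaled
    by the kernel norm so the marginal variance stays 1 after smoothing.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    noise = rng.standard_normal(dims)
    if fwhm == 0:
        return noise
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    sigma_vox = tuple(fwhm * _FWHM_TO_SIGMA / voxel_size)
    smoothed = gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    return smoothed / _smoothing_norm(tuple(dims), sigma_vox)


def sphere_mask(
    dims: tuple[int, int, int], center: tuple[float, float, float], radius: float
) -> np.ndarray:
    """Boolean sphere (in voxel units) used to define effect regions."""
    grid = np.indices(dims).astype(float)
    d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius ** 2


def ellipsoid_mask(
    dims: tuple[int, int, int], radii_frac: tuple[float, float, float]
) -> np.ndarray:
    """Centered ellipsoid covering ``radii_frac`` of each half-dimension."""
    grid = np.indices(dims).astype(float)
    d2 = sum(
        ((grid[a] - (dims[a] - 1) / 2.0) / (radii_frac[a] * dims[a] / 2.0)) ** 2
        for a in range(3)
    )
    return d2 <= 1.0


@dataclass
class EffectSpec:
    """A planted effect: a spatial region plus a per-session amplitude.

    Amplitudes are expressed in units of the modality noise SD, so an
    amplitude of 1.0 plants an effect equal to one noise standard
    deviation in every modality.
    """

    center: tuple[float, float, float]
    radius: float
    amplitudes: dict[str, float]  # session -> amplitude (noise-SD units)

    def region(self, dims: tuple[int, int, int]) -> np.ndarray:
        return sphere_mask(dims, self.center, self.radius)


@dataclass
class ModalityParams:
    """Baseline level and demographic offsets for one parameter map type."""

    baseline: float
    noise_sd: float
    sex_offset: float = 0.0        # added for females (sex=1)
    age_slope: float = 0.0         # per year relative to age 20
    hoc_offset: float = 0.0
    intercept_sd: float = 0.0      # subject-level random intercept SD
    clip: tuple[float, float] | None = None


# Subject random intercepts model residual inter-subject variability left
# after demographic matching and control-referencing; they are kept at 20%
# of the voxel noise SD so that no single common mode dominates the
# session-level sampling noise (a requirement for the nominal calibration
# of the downstream significance procedures).
DEFAULT_MODALITIES: dict[str, ModalityParams] = {
    # CBF in ml/100 g/min: baseline gray-matter perfusion with a modest
    # female elevation and a slow decline with age.
    "CBF": ModalityParams(baseline=55.0, noise_sd=5.0, sex_offset=4.0,
                          age_slope=-0.4, hoc_offset=-1.0, intercept_sd=1.0),
    # FA dimensionless in [0, 1].
    "FA": ModalityParams(baseline=0.45, noise_sd=0.025, sex_offset=-0.01,
                         age_slope=0.001, hoc_offset=-0.003,
                         intercept_sd=0.005, clip=(0.0, 1.0)),
    # MD on a 1e-3 mm^2/s scale.
    "MD": ModalityParams(baseline=0.80, noise_sd=0.02, sex_offset=0.005,
                         age_slope=-0.0005, hoc_offset=0.002,
                         intercept_sd=0.004),
}

# Session retention mirrors the study cohort: of 61 concussed athletes,
# 53 were scanned at ACU, 51 at RTP and 32 at 1YR.
DEFAULT_DROPOUT = {"ACU": 8 / 61, "RTP": 10 / 61, "YR1": 29 / 61}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator."""

    n_control: int = 167
    n_concussed: int = 61
    dims: tuple[int, int, int] = (24, 28, 24)
    voxel_size: float = 3.0
    mask: np.ndarray | None = None          # defaults to a ~1,900-voxel ellipsoid
    noise_fwhm: float = 6.0                 # mm, matches the smoothing scale
    modalities: tuple[str, ...] = ("CBF", "FA", "MD")
    modality_params: dict[str, ModalityParams] = field(
        default_factory=lambda: dict(DEFAULT_MODALITIES)
    )
    main_effect: EffectSpec | None = None
    sex_effect: EffectSpec | None = None
    dropout_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DROPOUT)
    )
    age_mean: float = 20.3
    age_sd: float = 2.0
    age_range: tuple[float, float] = (17.0, 28.0)
    # concussed athletes span a narrower, younger range so that every
    # athlete has a viable matched subgroup under the ±2-year caliper
    age_range_concussed: tuple[float, float] = (18.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_concussed <= 0:
            raise ValueError("cohort sizes must be positive")
        for s, p in self.dropout_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability for {s} outside [0,1]")
        if self.mask is None:
            self.mask = ellipsoid_mask(self.dims, (0.62, 0.62, 0.62))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.dims):
            raise ValueError("mask shape does not match grid dims")
        for eff in (self.main_effect, self.sex_effect):
            if eff is not None:
                region = eff.region(self.dims)
                if not (region & self.mask).any():
                    raise ValueError("effect region lies outside the analysis mask")

    def geometry(self) -> MaskGeometry:
        return MaskGeometry(
            mask=self.mask,
            voxel_size=np.full(3, self.voxel_size),
            origin=np.zeros(3),
        )


def default_effects(config: SimulationConfig) -> SimulationConfig:
    """Attach the default planted effects (used by the demo pipeline):

    a concussion main effect in one spherical region (negative, deepening
    over sessions, as seen for perfusion) and a sex-by-concussion effect
    in a second disjoint sphere, peaking at RTP.
    """
    dx, dy, dz = config.dims
    main = EffectSpec(
        center=(dx * 0.32, dy * 0.5, dz * 0.5), radius=4.2,
        amplitudes={"ACU": -0.4, "RTP": -0.7, "YR1": -1.0},
    )
    sex = EffectSpec(
        center=(dx * 0.68, dy * 0.5, dz * 0.5), radius=3.3,
        amplitudes={"ACU": 0.5, "RTP": 0.8, "YR1": 0.5},
    )
    return replace(config, main_effect=main, sex_effect=sex)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort, reproducible from (config, seed)."""

    config: SimulationConfig
    main_region: np.ndarray | None        # in-mask boolean vector
    sex_region: np.ndarray | None
    main_amplitudes: dict[str, dict[str, float]]  # modality -> session -> map units
    sex_amplitudes: dict[str, dict[str, float]]   # female-minus-male contrast
    intercepts: pd.DataFrame              # subject x modality
    retained: pd.DataFrame                # concussed subject x session (bool)


def _draw_ages(
    rng: np.random.Generator, n: int, cfg: SimulationConfig,
    age_range: tuple[float, float],
) -> np.ndarray:
    lo = (age_range[0] - cfg.age_mean) / cfg.age_sd
    hi = (age_range[1] - cfg.age_mean) / cfg.age_sd
    ages = truncnorm.rvs(lo, hi, loc=cfg.age_mean, scale=cfg.age_sd,
                         size=n, random_state=rng)
    return np.round(ages)


def _draw_subjects(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[SubjectRecord]:
    records = []
    n = cfg.n_control + cfg.n_concussed
    ages = np.concatenate([
        _draw_ages(rng, cfg.n_control, cfg, cfg.age_range),
        _draw_ages(rng, cfg.n_concussed, cfg, cfg.age_range_concussed),
    ])
    sexes = rng.integers(0, 2, size=n)
    hocs = rng.integers(0, 2, size=n)
    for i in range(n):
        concussed = i >= cfg.n_control
        hoc = int(hocs[i])
        records.append(
            SubjectRecord(
                subject_id=f"{'CONC' if concussed else 'CTRL'}{i:04d}",
                group="concussed" if concussed else "control",
                sex=int(sexes[i]),
                age=float(ages[i]),
                hoc=hoc,
                n_prior_concussions=int(1 + rng.poisson(0.8)) if hoc else 0,
                months_since_last=float(rng.uniform(6, 60)) if hoc else None,
                sport=str(rng.choice(SPORTS)),
                days_to_rtp=int(rng.lognormal(np.log(14), 0.5)) if concussed else None,
            )
        )
    return records


def _symptom_items(
    rng: np.random.Generator, elevated: bool
) -> np.ndarray:
    """One 22-item SCAT rating vector (0-6 per item)."""
    if elevated:
        present = rng.random(22) < 0.6
        ratings = rng.integers(1, 5, size=22)
    else:
        present = rng.random(22) < 0.12
        ratings = rng.integers(1, 3, size=22)
    return np.where(present, ratings, 0)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], list[ParameterMap], pd.DataFrame, SyntheticTruth]:
    """Generate one full synthetic cohort.

    Controls receive a single CONTROL-session map per modality; concussed
    athletes receive ACU/RTP/YR1 maps subject to Bernoulli dropout at the
    configured per-session rates (missing completely at random).  Symptom
    tables cover baseline (all athletes) plus ACU and RTP for concussed
    athletes, with ACU ratings elevated.
    """
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry()
    mask = config.mask
    records = _draw_subjects(rng, config)

    main_region = None
    sex_region = None
    if config.main_effect is not None:
        main_region = config.main_effect.region(config.dims)[mask]
    if config.sex_effect is not None:
        sex_region = config.sex_effect.region(config.dims)[mask]

    concussed = [r for r in records if r.group == "concussed"]
    retained = pd.DataFrame(
        {s: rng.random(len(concussed)) >= config.dropout_probs.get(s, 0.0)
         for s in SESSIONS},
        index=[r.subject_id for r in concussed],
    )

    intercepts = pd.DataFrame(
        {m: rng.standard_normal(len(records))
         * config.modality_params[m].intercept_sd
         for m in config.modalities},
        index=[r.subject_id for r in records],
    )

    maps: list[ParameterMap] = []
    for rec in records:
        sessions = ["CONTROL"] if rec.group == "control" else [
            s for s in SESSIONS if retained.loc[rec.subject_id, s]
        ]
        for modality in config.modalities:
            par = config.modality_params[modality]
            base = (
                par.baseline
                + par.sex_offset * rec.sex
                + par.age_slope * (rec.age - 20.0)
                + par.hoc_offset * rec.hoc
                + intercepts.loc[rec.subject_id, modality]
            )
            for session in sessions:
                field3d = smooth_gaussian_field(
                    config.dims, config.voxel_size, config.noise_fwhm, rng
                )
                values = base + par.noise_sd * field3d[mask]
                if rec.group == "concussed":
                    if config.main_effect is not None:
                        amp = config.main_effect.amplitudes.get(session, 0.0)
                        values = values + amp * par.noise_sd * main_region
                    if config.sex_effect is not None:
                        amp = config.sex_effect.amplitudes.get(session, 0.0)
                        sign = 0.5 if rec.sex == 1 else -0.5
                        values = values + sign * amp * par.noise_sd * sex_region
                if par.clip is not None:
                    values = np.clip(values, *par.clip)
                maps.append(ParameterMap(rec.subject_id, session, modality,
                                         values, geometry))

    symptom_rows = []
    for rec in records:
        sessions = ["baseline"] if rec.group == "control" else [
            "baseline", "ACU", "RTP"
        ]
        for session in sessions:
            items = _symptom_items(rng, elevated=(session == "ACU"))
            row = {"subject_id": rec.subject_id, "session": session}
            row.update({name: int(v) for name, v in zip(SYMPTOM_ITEMS, items)})
            symptom_rows.append(row)
    symptoms = pd.DataFrame(symptom_rows)

    def _amps(effect: EffectSpec | None) -> dict[str, dict[str, float]]:
        if effect is None:
            return {m: {s: 0.0 for s in SESSIONS} for m in config.modalities}
        return {
            m: {s: effect.amplitudes.get(s, 0.0)
                * config.modality_params[m].noise_sd for s in SESSIONS}
            for m in config.modalities
        }

    truth = SyntheticTruth(
        config=config,
        main_region=main_region,
        sex_region=sex_region,
        main_amplitudes=_amps(config.main_effect),
        sex_amplitudes=_amps(config.sex_effect),
        intercepts=intercepts,
        retained=retained,
    )
    return records, maps, symptoms, truth


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Tabulate the true planted contrasts per modality and session.

    ``main_contrast`` is the concussed-minus-reference group difference in
    the main-effect region; ``sex_contrast`` is the female-minus-male
    difference among concussed athletes in the sex-effect region (both in
    map units, zero outside the regions by construction).
    """
    rows = []
    for m, per_session in truth.main_amplitudes.items():
        for s in SESSIONS:
            rows.append({
                "modality": m,
                "session": s,
                "main_contrast": per_session[s],
                "sex_contrast": truth.sex_amplitudes[m][s],
                "main_region_voxels": (
                    0 if truth.main_region is None else int(truth.main_region.sum())
                ),
                "sex_region_voxels": (
                    0 if truth.sex_region is None else int(truth.sex_region.sum())
                ),
            })
    return pd.DataFrame(rows)


def write_cohort(
    records: list[SubjectRecord],
    maps: list[ParameterMap],
    geometry: MaskGeometry,
    out_dir: str | Path,
) -> Path:
    """Write the manifest + NIfTI layout that :func:`deltapls.io.read_cohort`
    reads back.  Returns the manifest path."""
    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    write_mask(geometry, out_dir / "mask.nii.gz")
    by_id = {r.subject_id: r for r in records}
    rows = []
    for pm in maps:
        rec = by_id[pm.subject_id]
        fname = f"{pm.subject_id}_{pm.session}_{pm.modality}.nii.gz"
        write_stat_map(pm.values, geometry, vol_dir / fname)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group, "sex": rec.sex,
            "age": rec.age, "hoc": rec.hoc,
            "n_prior": rec.n_prior_concussions,
            "months_since_last": rec.months_since_last, "sport": rec.sport,
            "days_to_rtp": rec.days_to_rtp, "session": pm.session,
            "modality": pm.modality, "volume_path": fname,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
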