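"""Synthetic organoid-cohort generation.

Generates patient cohorts of organoid (PDO) morphometric records — and
optionally rendered bright-field-like images — with the statistical
structure the downstream classification/voting analysis assumes:

* two culture platforms differing in within-patient size dispersion
  (arrayed/bioprinted "Eba" organoids are uniform, conventional dome-grown
  "Std" organoids are heterogeneous: area CV defaults 0.18 vs 0.71),
* organoid scale around 200 µm diameter,
* two patient classes (High-/Low-CEA, split at 2.5 ng/mL serum CEA) whose
  morphology differs by a tunable standardized effect size,
* per-patient random effects so organoids from one patient are correlated,
* batch tags (training / validation / external) for the three-tier
  evaluation protocol.

The feature model is driven by a single latent discriminant z per organoid:

    z = ±Δ/2 + u_patient + e,   u ~ N(0, σ_p²),  e ~ N(0, 1 − σ_p²)

with the sign set by the patient's class and Δ the standardized
between-class shift (``class_effect``).  The marginal per-class
distribution of z is N(±Δ/2, 1), so the 1-D equal-variance Bayes accuracy
of the z > 0 rule is Φ(Δ/2) — ``calibrate_separation`` inverts this to hit
a requested single-organoid accuracy.  Log-area is an affine function of z
(hence log-normal with the configured mean diameter and platform CV);
circularity is a noisy monotone function of z, so it carries class signal
but no information beyond z; perimeter is the deterministic identity
P = sqrt(4πA/C).  Area alone therefore attains exactly the calibrated
Bayes accuracy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .morphometrics import MorphFeatures

__all__ = [
    "GeneratorConfig",
    "PatientProfile",
    "PDORecord",
    "LabeledImage",
    "Cohort",
    "generate_cohort",
    "calibrate_separation",
    "render_pdo_image",
    "records_to_frame",
    "write_feature_csv",
    "read_feature_csv",
    "write_image_set",
]

# Platform defaults: area coefficient of variation at day 21.
PLATFORM_AREA_CV = {"Eba": 0.18, "Std": 0.71}

# Serum CEA class boundary (ng/mL), the clinical High/Low-CEA benchmark.
CEA_THRESHOLD_NG_ML = 2.5

# Exact header of the feature-library CSV.
FEATURE_CSV_COLUMNS = [
    "patient_id",
    "platform",
    "batch",
    "pdo_id",
    "area_um2",
    "perimeter_um",
    "circularity",
    "cea_class",
]

BATCH_TAGS = ("training", "validation", "external")

# Baseline circularity and its within-class noise, per platform.  Arrayed
# organoids are near-spherical; dome-grown ones are more irregular.
_CIRC_BASE = {"Eba": 0.93, "Std": 0.78}
_CIRC_SD = {"Eba": 0.02, "Std": 0.08}
# Slope of circularity on the latent discriminant (per standardized unit).
_CIRC_SLOPE = -0.03

# Patient random-effect SD as a fraction of the between-class shift.
_PATIENT_EFFECT_FRACTION = 0.25


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for one synthetic cohort.

    Parameters
    ----------
    n_high_patients, n_low_patients
        Number of High-/Low-CEA patients.
    pdos_per_patient_per_batch
        Organoids generated per patient in each batch.
    batches
        Batch tags drawn from ``("training", "validation", "external")``.
    platform
        ``"Eba"`` (uniform, arrayed) or ``"Std"`` (heterogeneous, dome).
    mean_diameter
        Mean organoid diameter in µm (default 200).
    area_cv
        Coefficient of variation of organoid area; platform default if None.
    class_effect
        Standardized shift Δ of the latent discriminant between classes.
        Default 0 (no separation).
    target_single_pdo_accuracy
        If set (in (0.5, 1)), overrides ``class_effect`` with the Δ that
        makes the single-organoid Bayes accuracy equal this value.
    pixel_size
        µm per pixel for rendered images (default 2).
    noise_sd
        Gaussian intensity noise SD for rendered images (8-bit units).
    roughness
        Relative amplitude of boundary irregularity of rendered organoids.
    seed
        Seed of the single generator all randomness flows from.
    """

    n_high_patients: int = 3
    n_low_patients: int = 2
    pdos_per_patient_per_batch: int = 49
    batches: tuple[str, ...] = ("training",)
    platform: str = "Eba"
    mean_diameter: float = 200.0
    area_cv: float | None = None
    class_effect: float = 0.0
    target_single_pdo_accuracy: float | None = None
    pixel_size: float = 2.0
    noise_sd: float = 8.0
    roughness: float = 0.0
    seed: int = 0
    patient_id_start: int = 1

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_AREA_CV:
            raise ConfigurationError(f"unknown platform {self.platform!r}")
        if self.n_high_patients < 1 or self.n_low_patients < 1:
            raise ConfigurationError("patient counts must be >= 1")
        if self.pdos_per_patient_per_batch < 1:
            raise ConfigurationError("pdos_per_patient_per_batch must be >= 1")
        if not self.batches:
            raise ConfigurationError("at least one batch tag required")
        for tag in self.batches:
            if tag not in BATCH_TAGS:
                raise ConfigurationError(f"unknown batch tag {tag!r}")
        if self.area_cv is not None and not self.area_cv > 0:
            raise ConfigurationError("area_cv must be > 0")
        if self.mean_diameter <= 0:
            raise ConfigurationError("mean_diameter must be > 0")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.target_single_pdo_accuracy is not None and not (
            0.5 < self.target_single_pdo_accuracy < 1.0
        ):
            raise ConfigurationError(
                "target_single_pdo_accuracy must lie in (0.5, 1)"
            )
        if self.class_effect < 0:
            raise ConfigurationError("class_effect must be >= 0")
        # normalise batches to a tuple so configs hash/compare cleanly
        object.__setattr__(self, "batches", tuple(self.batches))

    @property
    def effective_area_cv(self) -> float:
        return self.area_cv if self.area_cv is not None else PLATFORM_AREA_CV[self.platform]

    @property
    def effective_class_effect(self) -> float:
        if self.target_single_pdo_accuracy is not None:
            return calibrate_separation(self.target_single_pdo_accuracy)
        return self.class_effect

    @property
    def mean_area(self) -> float:
        """Mean cross-sectional area in µm² implied by the mean diameter."""
        return np.pi * (self.mean_diameter / 2.0) ** 2


@dataclass(frozen=True)
class PatientProfile:
    """One synthetic patient: serum CEA level, class, and random effect."""

    patient_id: str
    serum_cea: float  # ng/mL
    cea_class: str  # "High" | "Low"
    offset: float  # standardized per-patient shift of the discriminant

    def __post_init__(self) -> None:
        expected = "High" if self.serum_cea > CEA_THRESHOLD_NG_ML else "Low"
        if self.cea_class != expected:
            raise ValueError(
                f"cea_class {self.cea_class!r} inconsistent with serum CEA "
                f"{self.serum_cea} ng/mL (threshold {CEA_THRESHOLD_NG_ML})"
            )


@dataclass(frozen=True)
class PDORecord:
    """One organoid of the data library."""

    patient_id: str
    platform: str
    batch: str
    pdo_id: str
    features: MorphFeatures
    cea_class: str
    image_path: str | None = None


@dataclass(frozen=True)
class LabeledImage:
    """A rendered grayscale organoid image with analytic ground truth.

    ``raster`` is a row-major uint8 grid, origin top-left, dark object on a
    light background (bright-field convention).  ``ground_truth`` carries
    the shape parameters and the analytic area/perimeter of the noiseless
    boundary polygon.
    """

    raster: np.ndarray
    pixel_size: float
    ground_truth: dict

    def __post_init__(self) -> None:
        if self.raster.size == 0:
            raise ValueError("raster must be non-empty")


class Cohort:
    """A generated cohort: sequence of :class:`PDORecord` plus profiles."""

    def __init__(self, records: list[PDORecord], profiles: list[PatientProfile], config: GeneratorConfig):
        self.records = records
        self.profiles = profiles
        self.config = config

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def calibrate_separation(target_accuracy: float, dispersion: float = 1.0) -> float:
    """Standardized mean shift Δ whose Bayes accuracy is ``target_accuracy``.

    For two equal-variance Gaussians N(±Δ/2, σ²) the optimal (midpoint)
    rule classifies correctly with probability Φ(Δ/2σ); solving for the
    shift gives Δ = 2 σ Φ⁻¹(target).  With the default ``dispersion`` of 1
    the returned shift is in standardized units.

    Raises
    ------
    ValueError
        if ``target_accuracy`` is outside [0.5, 1) — accuracies below
        chance are meaningless for a Bayes rule and 1 is unattainable.
    """
    if not 0.5 <= target_accuracy < 1.0:
        raise ValueError("target_accuracy must lie in [0.5, 1)")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    return 2.0 * dispersion * float(norm.ppf(target_accuracy))


def _patient_profiles(config: GeneratorConfig, rng: np.random.Generator) -> list[PatientProfile]:
    delta = config.effective_class_effect
    sigma_p = _PATIENT_EFFECT_FRACTION * delta
    profiles: list[PatientProfile] = []
    for cls, count, prefix in (
        ("High", config.n_high_patients, "CEA_hi"),
        ("Low", config.n_low_patients, "CEA_lo"),
    ):
        for i in range(count):
            if cls == "High":
                # right-skewed serum levels above the clinical threshold
                cea = CEA_THRESHOLD_NG_ML * (1.5 + rng.lognormal(1.0, 0.6))
            else:
                cea = rng.uniform(0.3, 0.9) * CEA_THRESHOLD_NG_ML
            offset = rng.normal(0.0, sigma_p) if sigma_p > 0 else 0.0
            profiles.append(
                PatientProfile(
                    patient_id=f"{prefix}-{i + config.patient_id_start:02d}",
                    serum_cea=float(cea),
                    cea_class=cls,
                    offset=float(offset),
                )
            )
    return profiles


def _features_from_latent(
    z: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> list[MorphFeatures]:
    cv = config.effective_area_cv
    sigma_ln = np.sqrt(np.log1p(cv**2))
    mu_ln = np.log(config.mean_area) - 0.5 * sigma_ln**2
    area = np.exp(mu_ln + sigma_ln * z)
    base = _CIRC_BASE[config.platform]
    circ = base + _CIRC_SLOPE * z + rng.normal(0.0, _CIRC_SD[config.platform], size=z.shape)
    circ = np.clip(circ, 0.15, 1.0)
    perimeter = np.sqrt(4.0 * np.pi * area / circ)
    return [
        MorphFeatures(area=float(a), perimeter=float(p), circularity=float(c))
        for a, p, c in zip(area, perimeter, circ)
    ]


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the full cohort of organoid records for ``config``.

    Returns ``n_patients × len(batches) × pdos_per_patient_per_batch``
    records.  Identical config and seed yield identical output.
    """
    rng = np.random.default_rng(config.seed)
    profiles = _patient_profiles(config, rng)
    delta = config.effective_class_effect
    sigma_p = _PATIENT_EFFECT_FRACTION * delta
    # split the unit marginal variance between patient and organoid level
    sigma_w = float(np.sqrt(max(1.0 - sigma_p**2, 0.05)))

    records: list[PDORecord] = []
    n = config.pdos_per_patient_per_batch
    for profile in profiles:
        sign = 1.0 if profile.cea_class == "High" else -1.0
        for batch in config.batches:
            z = sign * delta / 2.0 + profile.offset + rng.normal(0.0, sigma_w, size=n)
            feats = _features_from_latent(z, config, rng)
            for k, f in enumerate(feats):
                records.append(
                    PDORecord(
                        patient_id=profile.patient_id,
                        platform=config.platform,
                        batch=batch,
                        pdo_id=f"{profile.patient_id}_{batch}_{k + 1:03d}",
                        features=f,
                        cea_class=profile.cea_class,
                    )
                )
    return Cohort(records, profiles, config)


# ---------------------------------------------------------------------------
# image rendering

def _boundary_polygon(
    r0: float,
    aspect: float,
    angle: float,
    roughness: float,
    rng: np.random.Generator,
    n_vertices: int = 720,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Closed boundary polygon (µm, object-centred) of one organoid.

    An ellipse of equal-area radius ``r0`` and axis ratio ``aspect``,
    optionally modulated by smooth low-order harmonic roughness.
    """
    a = r0 * np.sqrt(aspect)
    b = r0 / np.sqrt(aspect)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = a * np.cos(theta)
    y = b * np.sin(theta)
    if roughness > 0:
        modulation = np.zeros_like(theta)
        for order in (3, 4, 5, 7):
            amp = rng.normal(0.0, roughness / 2.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            modulation += amp * np.cos(order * theta + phase)
        scale = 1.0 + modulation
        x, y = x * scale, y * scale
    ca, sa = np.cos(angle), np.sin(angle)
    xr = ca * x - sa * y
    yr = sa * x + ca * y
    # shoelace area and polygonal perimeter of the noiseless boundary
    area = 0.5 * abs(np.dot(xr, np.roll(yr, -1)) - np.dot(yr, np.roll(xr, -1)))
    perim = float(np.sum(np.hypot(np.diff(np.r_[xr, xr[0]]), np.diff(np.r_[yr, yr[0]]))))
    truth = {"semi_axes_um": (float(a), float(b)), "angle_rad": float(angle),
             "area_um2": float(area), "perimeter_um": perim}
    return xr, yr, truth


def render_pdo_image(record: PDORecord, config: GeneratorConfig) -> LabeledImage:
    """Render one organoid as a dark object on a light noisy background.

    Deterministic given ``config.seed`` and the record's ``pdo_id``.  The
    canvas is auto-sized to 1.7× the object's bounding diameter.  The
    ground truth carries the analytic area and perimeter of the noiseless
    boundary polygon, which differ from the record's sampled features only
    through the roughness modulation.
    """
    rng = np.random.default_rng([config.seed, zlib.crc32(record.pdo_id.encode())])
    r0 = float(np.sqrt(record.features.area / np.pi))
    aspect = float(np.exp(abs(rng.normal(0.0, 0.05))))
    angle = float(rng.uniform(0.0, np.pi))
    x, y, truth = _boundary_polygon(r0, aspect, angle, config.roughness, rng)

    extent = max(np.ptp(x), np.ptp(y))
    side = int(np.ceil(1.7 * extent / config.pixel_size))
    side = max(side, 32)
    half = side * config.pixel_size / 2.0
    if extent >= 2.0 * half:
        raise ValueError("organoid larger than canvas")

    # µm -> pixel coordinates (origin top-left, row-major)
    cols = (x + half) / config.pixel_size
    rows = (y + half) / config.pixel_size

    from skimage.draw import polygon as draw_polygon

    raster = np.full((side, side), 200.0)
    rr, cc = draw_polygon(rows, cols, shape=raster.shape)
    raster[rr, cc] = 60.0
    if config.noise_sd > 0:
        raster += rng.normal(0.0, config.noise_sd, size=raster.shape)
    raster = np.clip(raster, 0, 255).astype(np.uint8)

    truth = dict(truth)
    truth.update(center_px=(side / 2.0, side / 2.0), roughness=config.roughness,
                 pdo_id=record.pdo_id)
    return LabeledImage(raster=raster, pixel_size=config.pixel_size, ground_truth=truth)


# ---------------------------------------------------------------------------
# I/O

def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "platform": r.platform,
            "batch": r.batch,
            "pdo_id": r.pdo_id,
            "area_um2": r.features.area,
            "perimeter_um": r.features.perimeter,
            "circularity": r.features.circularity,
            "cea_class": r.cea_class,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PDORecord]:
    missing = set(FEATURE_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return [
        PDORecord(
            patient_id=str(row.patient_id),
            platform=str(row.platform),
            batch=str(row.batch),
            pdo_id=str(row.pdo_id),
            features=MorphFeatures(
                area=float(row.area_um2),
                perimeter=float(row.perimeter_um),
                circularity=float(row.circularity),
            ),
            cea_class=str(row.cea_class),
        )
        for row in frame.itertuples(index=False)
    ]


def write_feature_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(FEATURE_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"feature library {path} missing columns: {sorted(missing)}")
    return frame


def write_image_set(cohort: Cohort, out_dir, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Render and write every organoid as 8-bit PNG plus a ground-truth CSV."""
    from PIL import Image

    config = config or cohort.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in cohort:
        img = render_pdo_image(record, config)
        path = out_dir / f"{record.pdo_id}.png"
        Image.fromarray(img.raster, mode="L").save(path)
        rows.append(
            {
                "pdo_id": record.pdo_id,
                "image": path.name,
                "pixel_size_um": img.pixel_size,
                "truth_area_um2": img.ground_truth["area_um2"],
                "truth_perimeter_um": img.ground_truth["perimeter_um"],
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return truth
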