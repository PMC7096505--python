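"""Synthetic FT-IR tissue cohorts with full ground truth.

Emulates a 42-patient breast-carcinoma imaging study: each patient contributes
one absorbance cube whose pixels belong to contiguous histologic regions
(epithelium, fibroblast, myofibroblast, collagen, blood, necrosis, plus a
background class), and whose collagen pixels are a within-tumor mixture of two
collagen phenotypes ("ECM3" vs "non-ECM3") that differ spectrally only inside
the 872–1320 cm⁻¹ fingerprint window.  Alongside the cubes the generator
produces a clinical table (grade, size, nodal/receptor status, a gene-expression
surrogate linearly coupled to the true ECM3 pixel fraction, and survival times
whose hazard is raised for ECM3 × grade-III patients) and the exact ground
truth needed for parameter-recovery tests.

The spatial layout is produced by randomized multi-seed region growing; it is
deliberately non-anatomical — blobs, not tumor morphology — which is sufficient
to exercise per-pixel classification and score aggregation.  Phenotype
assignment within collagen is i.i.d. per pixel by default; optional Markov
smoothing passes add spatial correlation but no downstream statistic depends
on it.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hyperio import COHORT_COLUMNS, HyperspectralCube, WavenumberAxis

#: Histologic classes a pixel can carry in the truth raster, in code order.
TRUE_CLASS_NAMES = [
    "background",
    "epithelium",
    "fibroblast",
    "myofibroblast",
    "collagen_nonECM3",
    "collagen_ECM3",
    "blood",
    "necrosis",
]
TRUE_CODE = {name: i for i, name in enumerate(TRUE_CLASS_NAMES)}

#: Classes the histology classifier distinguishes (collagen phenotypes merged).
TISSUE_CLASS_NAMES = [
    "epithelium", "fibroblast", "myofibroblast", "collagen", "blood", "necrosis",
]

AMIDE_I = 1656.0       # cm⁻¹, protein amide I band — present in every class
SNR_NOISE_BAND = 1826.0  # cm⁻¹, kept signal-free (noise reference)
ECM3_WINDOW = (872.0, 1320.0)  # cm⁻¹, the only region where phenotypes differ


class SpectrumSpecError(ValueError):
    """Invalid class-spectrum specification."""


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class ClassSpectrumSpec:
    """Gaussian-peak template for one histologic class.

    ``peaks`` is a list of (center cm⁻¹, amplitude a.u., sigma cm⁻¹);
    ``baseline_coeffs`` are polynomial coefficients (low order, ascending) in
    the axis coordinate normalized to [-1, 1].
    """

    class_name: str
    peaks: tuple[tuple[float, float, float], ...]
    baseline_coeffs: tuple[float, ...] = ()

    def __post_init__(self):
        for c, a, s in self.peaks:
            if s <= 0:
                raise SpectrumSpecError(f"{self.class_name}: peak width {s} <= 0")
            if abs(c - SNR_NOISE_BAND) < 30.0 and a != 0:
                raise SpectrumSpecError(
                    f"{self.class_name}: peak at {c} contaminates the "
                    f"{SNR_NOISE_BAND} noise-reference band")


def make_class_spectrum(spec: ClassSpectrumSpec, axis: WavenumberAxis) -> np.ndarray:
    """Evaluate a class template: sum of Gaussian peaks plus smooth baseline."""
    if len(axis) == 0:
        raise ValueError("empty wavenumber axis")
    v = axis.values
    y = np.zeros_like(v)
    for c, a, s in spec.peaks:
        y += a * np.exp(-0.5 * ((v - c) / s) ** 2)
    if spec.baseline_coeffs:
        t = 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0
        y += np.polynomial.polynomial.polyval(t, np.asarray(spec.baseline_coeffs))
    return y


def default_class_specs(ecm3_contrast: float = 1.0) -> dict[str, ClassSpectrumSpec]:
    """Template library for all tissue classes.

    Band positions follow typical FFPE breast-tissue FT-IR assignments:
    amide I 1656, amide II 1546, CH bending 1452, amide III ~1236, nucleic-acid
    / carbohydrate 1080, collagen carbohydrate 1032.  The two collagen
    phenotypes share every peak outside 872–1320 cm⁻¹; inside the window the
    ECM3 phenotype shifts amplitude between the amide III and carbohydrate
    bands, scaled by ``ecm3_contrast`` (0 → identical phenotypes, a null
    cohort).
    """
    c = float(ecm3_contrast)
    collagen_common = (
        (1656.0, 0.80, 18.0),
        (1546.0, 0.42, 16.0),
        (1452.0, 0.12, 10.0),
        (1400.0, 0.10, 10.0),
        (1338.0, 0.08, 8.0),
    )
    collagen_window_non = (
        (1236.0, 0.32, 14.0),
        (1204.0, 0.12, 10.0),
        (1080.0, 0.26, 16.0),
        (1032.0, 0.30, 12.0),
        (920.0, 0.06, 10.0),
    )
    collagen_window_ecm3 = (
        (1236.0, 0.32 + 0.10 * c, 14.0),
        (1204.0, 0.12 + 0.08 * c, 10.0),
        (1080.0, 0.26 - 0.06 * c, 16.0),
        (1032.0, 0.30 + 0.08 * c, 12.0),
        (920.0, 0.06 + 0.04 * c, 10.0),
    )
    specs = {
        "epithelium": ClassSpectrumSpec("epithelium", (
            (1656.0, 0.90, 18.0), (1546.0, 0.50, 16.0), (1452.0, 0.10, 10.0),
            (1236.0, 0.40, 12.0), (1120.0, 0.15, 10.0), (1080.0, 0.45, 14.0),
            (968.0, 0.10, 8.0),
        )),
        "fibroblast": ClassSpectrumSpec("fibroblast", (
            (1656.0, 0.85, 18.0), (1546.0, 0.46, 16.0), (1452.0, 0.14, 10.0),
            (1236.0, 0.28, 12.0), (1080.0, 0.30, 14.0),
        )),
        "myofibroblast": ClassSpectrumSpec("myofibroblast", (
            (1656.0, 0.88, 18.0), (1546.0, 0.48, 16.0), (1452.0, 0.13, 10.0),
            (1236.0, 0.34, 12.0), (1080.0, 0.34, 14.0), (1032.0, 0.12, 12.0),
        )),
        "collagen_nonECM3": ClassSpectrumSpec(
            "collagen_nonECM3", collagen_common + collagen_window_non),
        "collagen_ECM3": ClassSpectrumSpec(
            "collagen_ECM3", collagen_common + collagen_window_ecm3),
        "blood": ClassSpectrumSpec("blood", (
            (1656.0, 0.95, 16.0), (1546.0, 0.55, 14.0), (1396.0, 0.18, 10.0),
            (1236.0, 0.10, 12.0), (1080.0, 0.12, 14.0),
        )),
        "necrosis": ClassSpectrumSpec("necrosis", (
            (1656.0, 0.55, 22.0), (1546.0, 0.30, 20.0), (1236.0, 0.15, 16.0),
            (1080.0, 0.15, 18.0),
        )),
    }
    return specs


@dataclass(frozen=True)
class SynthCohortConfig:
    """Generating conditions for a synthetic imaging cohort.

    Defaults mirror the study design: 22 ECM3 + 20 non-ECM3 patients, a
    750–2000 cm⁻¹ axis at 2 cm⁻¹ point spacing, within-tumor mixing of
    collagen phenotypes with per-group true-fraction intervals straddling the
    ~0.35 patient-level cutoff, a gene-expression surrogate that is an affine
    function of the true ECM3 pixel fraction on the mean-log2 scale, and
    exponential survival whose log-hazard is raised for ECM3 × grade-III.
    """

    n_ecm3: int = 22
    n_non_ecm3: int = 20
    image_shape: tuple[int, int] = (32, 32)
    axis_spec: tuple[float, float, float] = (750.0, 2000.0, 2.0)  # min, max, step
    ecm3_fraction_range_pos: tuple[float, float] = (0.4, 0.9)
    ecm3_fraction_range_neg: tuple[float, float] = (0.0, 0.3)
    noise_sd: float = 0.01             # absorbance a.u., i.i.d. per band
    baseline_drift_amp: float = 0.02   # max |low-order polynomial drift|, a.u.
    scale_range: tuple[float, float] = (0.8, 1.2)  # thickness/scattering jitter
    ecm3_contrast: float = 1.0         # scales the phenotype spectral difference
    gene_intercept: float = 8.2        # mean log2 expression at fraction 0
    gene_slope: float = 7.7            # log2 units per unit true fraction
    gene_noise_sd: float = 0.8
    hazard_baseline_rate: float = 0.006          # events / month
    log_hr_ecm3_gradeIII: float = 1.1            # extra log hazard, ECM3 & grade III
    followup_months: float = 120.0               # administrative censoring
    smoothing_passes: int = 0          # Markov smoothing of phenotype labels
    seed: int = 0

    def __post_init__(self):
        for name in ("ecm3_fraction_range_pos", "ecm3_fraction_range_neg"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"{name}=({lo}, {hi}) must be ordered within [0, 1]")
        if self.n_ecm3 + self.n_non_ecm3 < 4:
            raise ConfigError("need at least 4 patients in total")
        lo, hi, step = self.axis_spec
        if step <= 0 or abs((hi - lo) / step - round((hi - lo) / step)) > 1e-9:
            raise ConfigError("axis step must be positive and divide the range")
        if self.scale_range[0] > self.scale_range[1] or self.scale_range[0] <= 0:
            raise ConfigError("scale_range must be ordered and positive")

    @property
    def axis(self) -> WavenumberAxis:
        lo, hi, step = self.axis_spec
        return WavenumberAxis.from_range(lo, hi, step)


@dataclass
class PatientTruth:
    """Exact generating state for one patient."""

    patient_id: str
    group: str                      # "ECM3" / "non-ECM3"
    true_fraction: float            # generating Bernoulli rate for ECM3 collagen
    class_map: np.ndarray           # H×W int codes into TRUE_CLASS_NAMES

    @property
    def realized_fraction(self) -> float:
        """ECM3 collagen pixels / all collagen pixels, computed from the map."""
        n_ecm3 = int(np.sum(self.class_map == TRUE_CODE["collagen_ECM3"]))
        n_all = n_ecm3 + int(np.sum(self.class_map == TRUE_CODE["collagen_nonECM3"]))
        return n_ecm3 / n_all if n_all else float("nan")


@dataclass
class CohortGroundTruth:
    config: SynthCohortConfig
    patients: list[PatientTruth] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": [p.patient_id for p in self.patients],
            "group": [p.group for p in self.patients],
            "true_fraction": [p.true_fraction for p in self.patients],
            "realized_fraction": [p.realized_fraction for p in self.patients],
        })


# Region-growing seed multiplicities; collagen gets the largest share so each
# tumor yields a few hundred collagen pixels at the default 32×32 frame.
_REGION_SEEDS = [
    ("epithelium", 3),
    ("fibroblast", 2),
    ("myofibroblast", 2),
    ("collagen", 4),
    ("blood", 2),
    ("necrosis", 2),
    ("background", 2),
]


def _grow_regions(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Randomized multi-source flood fill: contiguous blob per seed.

    Returns an H×W raster of region class names (collagen not yet split into
    phenotypes).  Every seeded class is guaranteed at least one pixel.
    """
    H, W = shape
    n_seeds = sum(k for _, k in _REGION_SEEDS)
    if H * W < n_seeds:
        raise ConfigError(
            f"image {shape} too small to host all {n_seeds} class seeds")
    labels = np.full((H, W), -1, dtype=int)
    class_of_seed: list[str] = []
    for name, k in _REGION_SEEDS:
        class_of_seed.extend([name] * k)

    flat = rng.choice(H * W, size=n_seeds, replace=False)
    heap: list[tuple[float, int, int, int]] = []
    for s, f in enumerate(flat):
        r, c = divmod(int(f), W)
        labels[r, c] = s  # seeds are fixed so every class keeps ≥ 1 pixel
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and labels[rr, cc] == -1:
                heapq.heappush(heap, (rng.random(), rr, cc, s))
    while heap:
        _, r, c, s = heapq.heappop(heap)
        if labels[r, c] != -1:
            continue
        labels[r, c] = s
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and labels[rr, cc] == -1:
                heapq.heappush(heap, (rng.random(), rr, cc, s))

    names = np.array(class_of_seed, dtype=object)
    return names[labels]


def _smooth_phenotype(ecm3: np.ndarray, collagen: np.ndarray, passes: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Majority-vote Markov smoothing of the ECM3 mask within collagen pixels."""
    out = ecm3.copy()
    H, W = out.shape
    for _ in range(passes):
        padded = np.pad(out.astype(int), 1)
        votes = (padded[:-2, 1:-1] + padded[2:, 1:-1]
                 + padded[1:-1, :-2] + padded[1:-1, 2:])
        neigh = np.pad(collagen.astype(int), 1)
        denom = (neigh[:-2, 1:-1] + neigh[2:, 1:-1]
                 + neigh[1:-1, :-2] + neigh[1:-1, 2:])
        flip = collagen & (denom > 0)
        out = np.where(flip, votes * 2 > denom, out) & collagen
    return out


def generate_tissue_image(config: SynthCohortConfig, group: str,
                          true_fraction: float,
                          rng: np.random.Generator,
                          patient_id: str = "P0") -> tuple[HyperspectralCube, PatientTruth]:
    """Generate one patient's absorbance cube plus its exact ground truth.

    Pixel model: ``scale · template + polynomial drift + N(0, noise_sd)`` with
    scale drawn per pixel from ``scale_range`` and the drift a random
    quadratic bounded by ``baseline_drift_amp``.  Collagen pixels carry the
    ECM3 template independently with probability ``true_fraction``.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError(f"true_fraction {true_fraction} outside [0, 1]")
    axis = config.axis
    specs = default_class_specs(config.ecm3_contrast)
    templates = {name: make_class_spectrum(spec, axis)
                 for name, spec in specs.items()}
    templates["background"] = np.zeros(len(axis))

    region = _grow_regions(config.image_shape, rng)
    collagen = region == "collagen"
    ecm3_px = np.zeros(region.shape, dtype=bool)
    ecm3_px[collagen] = rng.random(int(collagen.sum())) < true_fraction
    if config.smoothing_passes:
        ecm3_px = _smooth_phenotype(ecm3_px, collagen, config.smoothing_passes, rng)

    class_map = np.empty(region.shape, dtype=int)
    for name in ("background", "epithelium", "fibroblast", "myofibroblast",
                 "blood", "necrosis"):
        class_map[region == name] = TRUE_CODE[name]
    class_map[collagen & ~ecm3_px] = TRUE_CODE["collagen_nonECM3"]
    class_map[collagen & ecm3_px] = TRUE_CODE["collagen_ECM3"]

    H, W = config.image_shape
    B = len(axis)
    template_stack = np.stack([templates[n] for n in TRUE_CLASS_NAMES])
    base = template_stack[class_map.ravel()]            # (H·W, B)

    scale = rng.uniform(*config.scale_range, size=(H * W, 1))
    # random bounded quadratic drift per pixel on t ∈ [-1, 1]
    t = np.linspace(-1.0, 1.0, B)
    coeffs = rng.uniform(-1.0, 1.0, size=(H * W, 3))
    norm = np.abs(coeffs).sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    amp = config.baseline_drift_amp * rng.random((H * W, 1))
    drift = (coeffs / norm * amp) @ np.vstack([np.ones_like(t), t, t * t])
    noise = rng.normal(0.0, config.noise_sd, size=(H * W, B)) \
        if config.noise_sd > 0 else 0.0

    data = (scale * base + drift + noise).reshape(H, W, B)
    cube = HyperspectralCube(data=data, axis=axis)
    truth = PatientTruth(patient_id=patient_id, group=group,
                         true_fraction=float(true_fraction), class_map=class_map)
    return cube, truth


# Clinical covariate frequencies per group (ECM3, non-ECM3): sampling
# probabilities of the first level of each two-level characteristic.
_COVARIATE_P = {
    "size_class": (("<2cm", ">=2cm"), (0.67, 0.55)),
    "nodal_status": (("N0", "N+"), (0.20, 0.35)),
    "er_status": (("negative", "positive"), (0.09, 0.15)),
    "pgr_status": (("negative", "positive"), (0.09, 0.40)),
    "her2_status": (("positive", "negative"), (0.27, 0.15)),
}


def _clinical_rows(config: SynthCohortConfig, groups: list[str],
                   fractions: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical table given per-patient group labels and true ECM3 fractions."""
    n = len(groups)
    rows: dict[str, list] = {c: [] for c in COHORT_COLUMNS}
    is_ecm3 = np.array([g == "ECM3" for g in groups])

    grade = np.where(rng.random(n) < 0.5, "I-II", "III")
    expr = (config.gene_intercept + config.gene_slope * fractions
            + (rng.normal(0.0, config.gene_noise_sd, n)
               if config.gene_noise_sd > 0 else 0.0))
    interaction = is_ecm3 & (grade == "III")
    rate = config.hazard_baseline_rate * np.exp(
        config.log_hr_ecm3_gradeIII * interaction)
    raw_time = rng.exponential(1.0 / rate)
    event = raw_time <= config.followup_months
    time = np.minimum(raw_time, config.followup_months)

    for i in range(n):
        rows["patient_id"].append(f"P{i:03d}")
        rows["ecm_class"].append(groups[i])
        rows["grade"].append(grade[i])
        for col, (levels, probs) in _COVARIATE_P.items():
            p = probs[0] if is_ecm3[i] else probs[1]
            rows[col].append(levels[0] if rng.random() < p else levels[1])
        rows["mean_log2_expr"].append(float(expr[i]))
        rows["survival_months"].append(float(time[i]))
        rows["event"].append(int(event[i]))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def generate_cohort_table(config: SynthCohortConfig
                          ) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Cohort table + truth only (no imaging) — cheap path for statistics tests.

    True fractions are drawn exactly as in :func:`generate_cohort`; the truth
    carries empty class maps.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    groups = ["ECM3"] * config.n_ecm3 + ["non-ECM3"] * config.n_non_ecm3
    lo_p, hi_p = config.ecm3_fraction_range_pos
    lo_n, hi_n = config.ecm3_fraction_range_neg
    fractions = np.array([
        rng.uniform(lo_p, hi_p) if g == "ECM3" else rng.uniform(lo_n, hi_n)
        for g in groups])
    table = _clinical_rows(config, groups, fractions, rng)
    truth = CohortGroundTruth(config=config, patients=[
        PatientTruth(patient_id=f"P{i:03d}", group=groups[i],
                     true_fraction=float(fractions[i]),
                     class_map=np.empty((0, 0), dtype=int))
        for i in range(len(groups))])
    return table, truth


def generate_cohort(config: SynthCohortConfig
                    ) -> tuple[list[HyperspectralCube], pd.DataFrame, CohortGroundTruth]:
    """Generate the full imaging cohort: cubes, clinical table and ground truth."""
    if config.ecm3_fraction_range_pos[0] > config.ecm3_fraction_range_pos[1]:
        raise ConfigError("degenerate positive fraction interval")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    groups = ["ECM3"] * config.n_ecm3 + ["non-ECM3"] * config.n_non_ecm3
    lo_p, hi_p = config.ecm3_fraction_range_pos
    lo_n, hi_n = config.ecm3_fraction_range_neg
    fractions = np.array([
        rng.uniform(lo_p, hi_p) if g == "ECM3" else rng.uniform(lo_n, hi_n)
        for g in groups])
    table = _clinical_rows(config, groups, fractions, rng)

    cubes: list[HyperspectralCube] = []
    truth = CohortGroundTruth(config=config)
    for i, g in enumerate(groups):
        cube, pt = generate_tissue_image(config, g, float(fractions[i]), rng,
                                         patient_id=f"P{i:03d}")
        cubes.append(cube)
        truth.patients.append(pt)
    return cubes, table, truth


def null_config(config: SynthCohortConfig) -> SynthCohortConfig:
    """A copy of ``config`` with zero spectral difference between phenotypes."""
    return replace(config, ecm3_contrast=0.0)
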