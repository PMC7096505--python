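"""End-to-end orchestration: simulate → preprocess → segment → train → score → stats.

A single :class:`RunConfig` (YAML on disk) drives the whole chain.  All
randomness flows from one root seed through named substreams (cohort,
histology training, cross-validation folds, ROC bootstrap), so each stage is
independently reproducible and an identical config + seed yields a
bit-identical run report.

``simulate_cohort`` produces the synthetic imaging data; ``analyze_cohort``
consumes it (either in memory or reloaded from disk) and produces the run
report: cohort summary, chosen hyperparameters, out-of-fold AUC with CI, IR
score table and cutoff, sensitivity/specificity against the gene-expression
labels, the expression association fit, and ECM×grade survival statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortstats, ecm3disc, histoseg, irscore, specprep
from .hyperio import HyperspectralCube, read_cohort_table, read_envi, \
    write_cohort_table, write_envi
from .specprep import PreprocessConfig
from .synthcohort import (SynthCohortConfig, TRUE_CLASS_NAMES, TRUE_CODE,
                          generate_cohort, generate_tissue_image)

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("cohort", "histology", "cv", "roc")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    synth: SynthCohortConfig = field(default_factory=SynthCohortConfig)
    prep: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_histology_training_images: int = 4
    histology_training_fraction: float = 0.5  # ECM3 share in training collagen
    n_components: int = 20
    cv_folds: int = 5
    pca_before_cv: bool = False          # PCA once on all rows before CV
    n_bootstrap: int = 2000
    group_test: str = "welch_t"
    fit_orientation: str = "ir_on_expr"
    seed: int = 0
    mode: str = "simulate"            # simulate | analyze
    output_dir: str | None = None

    def stage_seeds(self) -> dict[str, int]:
        """Named integer substream seeds derived from the root seed."""
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STAGE_NAMES))
        return {name: int(ss.generate_state(1)[0] % (2 ** 31))
                for name, ss in zip(_STAGE_NAMES, children)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        prep = d.pop("prep", {})

        def _tuplify(obj):
            if isinstance(obj, list):
                return tuple(_tuplify(v) for v in obj)
            return obj

        synth = {k: _tuplify(v) for k, v in synth.items()}
        prep = {k: _tuplify(v) for k, v in prep.items()}
        return cls(synth=SynthCohortConfig(**synth),
                   prep=PreprocessConfig(**prep), **d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_run_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


# --------------------------------------------------------------------------
# Stage 1: simulation
# --------------------------------------------------------------------------

@dataclass
class SimulatedData:
    cubes: list[HyperspectralCube]
    cohort: pd.DataFrame
    truth_maps: list[np.ndarray]          # per-patient H×W true class codes
    true_fractions: list[float]
    train_cubes: list[HyperspectralCube]
    train_maps: list[np.ndarray]


def simulate_cohort(config: RunConfig) -> SimulatedData:
    """Generate the patient cohort plus dedicated histology-training images."""
    seeds = config.stage_seeds()
    synth = replace(config.synth, seed=seeds["cohort"])
    try:
        cubes, cohort, truth = generate_cohort(synth)
    except Exception as exc:
        raise StageError(f"simulate/cohort: {exc}") from exc

    rng = np.random.default_rng(np.random.SeedSequence(seeds["histology"]))
    train_cubes, train_maps = [], []
    for i in range(config.n_histology_training_images):
        cube, pt = generate_tissue_image(
            synth, "training", config.histology_training_fraction, rng,
            patient_id=f"T{i:02d}")
        train_cubes.append(cube)
        train_maps.append(pt.class_map)
    # the operative truth is the realized per-map pixel fraction (the
    # generating Bernoulli rate differs from it by binomial sampling)
    return SimulatedData(cubes=cubes, cohort=cohort,
                         truth_maps=[p.class_map for p in truth.patients],
                         true_fractions=[p.realized_fraction
                                         for p in truth.patients],
                         train_cubes=train_cubes, train_maps=train_maps)


def save_simulation(sim: SimulatedData, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort_table(sim.cohort, out_dir / "cohort.csv")
    np.savetxt(out_dir / "true_fractions.csv", np.asarray(sim.true_fractions),
               header="true_fraction", comments="# ")
    for i, (cube, tmap) in enumerate(zip(sim.cubes, sim.truth_maps)):
        write_envi(cube, out_dir / f"P{i:03d}")
        np.savetxt(out_dir / f"P{i:03d}_truth.csv", tmap, fmt="%d",
                   delimiter=",")
    for i, (cube, tmap) in enumerate(zip(sim.train_cubes, sim.train_maps)):
        write_envi(cube, out_dir / f"T{i:02d}")
        np.savetxt(out_dir / f"T{i:02d}_truth.csv", tmap, fmt="%d",
                   delimiter=",")
    return out_dir


def load_simulation(in_dir) -> SimulatedData:
    in_dir = Path(in_dir)
    cohort = read_cohort_table(in_dir / "cohort.csv")
    fractions = np.atleast_1d(
        np.loadtxt(in_dir / "true_fractions.csv", comments="#")).tolist()
    cubes, truth_maps = [], []
    for i in range(len(cohort)):
        cubes.append(read_envi(in_dir / f"P{i:03d}.hdr"))
        truth_maps.append(np.loadtxt(in_dir / f"P{i:03d}_truth.csv",
                                     delimiter=",", dtype=int))
    train_cubes, train_maps = [], []
    for path in sorted(in_dir.glob("T*.hdr")):
        train_cubes.append(read_envi(path))
        train_maps.append(np.loadtxt(path.with_name(path.stem + "_truth.csv"),
                                     delimiter=",", dtype=int))
    return SimulatedData(cubes=cubes, cohort=cohort, truth_maps=truth_maps,
                         true_fractions=fractions, train_cubes=train_cubes,
                         train_maps=train_maps)


# --------------------------------------------------------------------------
# Stage 2-3: preprocessing + histology segmentation
# --------------------------------------------------------------------------

def _merged_tissue_label(code: int) -> str:
    name = TRUE_CLASS_NAMES[code]
    return "collagen" if name.startswith("collagen") else name


def train_histology_from_truth(train_cubes: list[HyperspectralCube],
                               train_maps: list[np.ndarray],
                               prep: PreprocessConfig) -> histoseg.HistologyModel:
    """Train the Gaussian-Bayes histology classifier on labeled synthetic pixels.

    Collagen phenotypes are merged into one 'collagen' training class;
    background pixels are excluded (they are gated by the amide-I floor at
    prediction time).
    """
    X_all, labels_all = [], []
    for cube, tmap in zip(train_cubes, train_maps):
        processed, _ = specprep.preprocess_cube(cube, prep)
        flat = processed.flat_spectra()
        valid = processed.valid_mask.reshape(-1)
        codes = tmap.reshape(-1)
        tissue = valid & (codes != TRUE_CODE["background"])
        X, flagged = histoseg.compute_metrics(flat[tissue], cube.axis)
        ok = ~flagged & np.all(np.isfinite(X), axis=1)
        X_all.append(X[ok])
        labels_all.extend(_merged_tissue_label(c)
                          for c, keep in zip(codes[tissue], ok) if keep)
    return histoseg.train_histology_classifier(
        np.vstack(X_all), np.array(labels_all))


def collagen_pixel_spectra(cube: HyperspectralCube, prep: PreprocessConfig,
                           model: histoseg.HistologyModel
                           ) -> tuple[np.ndarray, histoseg.TissueClassMap, dict, np.ndarray]:
    """Preprocess one cube, segment it, and return its cleaned collagen spectra
    on the training window: (spectra, class map, clean log, coords)."""
    processed, manifest = specprep.preprocess_cube(cube, prep)
    class_map = histoseg.classify_pixels(processed, model)
    spectra, coords = histoseg.extract_class_spectra(processed, class_map,
                                                     "collagen")
    if spectra.shape[0] == 0:
        return spectra, class_map, {"n_input": 0, "n_kept": 0}, coords
    window, _ = specprep.subset_range(spectra, cube.axis, *prep.train_range)
    keep, clean_log = specprep.clean_pixels(window, prep.clean_min,
                                            prep.clean_max)
    return window[keep], class_map, clean_log, coords[keep]


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------

def analyze_cohort(config: RunConfig, sim: SimulatedData) -> dict:
    """Run segmentation, discriminant training, scoring and statistics."""
    seeds = config.stage_seeds()
    prep = config.prep
    cohort = sim.cohort.copy()

    try:
        model = train_histology_from_truth(sim.train_cubes, sim.train_maps, prep)
    except Exception as exc:
        raise StageError(f"analyze/histology-training: {exc}") from exc

    patient_ids = cohort["patient_id"].tolist()
    labels_by_pid = dict(zip(patient_ids, cohort["ecm_class"]))
    pixel_sets: dict[str, np.ndarray] = {}
    seg_accuracy = []
    for pid, cube, tmap in zip(patient_ids, sim.cubes, sim.truth_maps):
        try:
            window, class_map, _, _ = collagen_pixel_spectra(cube, prep, model)
        except Exception as exc:
            raise StageError(f"analyze/segment[{pid}]: {exc}") from exc
        pixel_sets[pid] = window
        if tmap.size:
            merged_truth = np.array(
                [_merged_tissue_label(c) for c in tmap.reshape(-1)])
            pred = np.array([class_map.class_names[i]
                             for i in class_map.labels.reshape(-1)])
            seg_accuracy.append(float(np.mean(pred == merged_truth)))

    try:
        matrix, labels, kept_ids = ecm3disc.build_training_matrix(
            pixel_sets, labels_by_pid)
        # cap the PC count for small cohorts (rank limit is rows − 1)
        n_comp = min(config.n_components, matrix.shape[0] - 1)
        cv = ecm3disc.cross_validate(
            matrix, labels, k=config.cv_folds, seed=seeds["cv"],
            n_components=n_comp, pca_before_cv=config.pca_before_cv)
        roc = ecm3disc.roc_curve(cv.oof_posterior, labels,
                                 n_boot=config.n_bootstrap, seed=seeds["roc"])
        final_pca = ecm3disc.fit_pca(matrix, n_comp)
        final_model = ecm3disc.fit_rlda(final_pca.transform(matrix), labels,
                                        *cv.chosen)
    except Exception as exc:
        raise StageError(f"analyze/train: {exc}") from exc

    n_collagen, n_ecm3 = [], []
    for pid in kept_ids:
        px_labels, _ = ecm3disc.predict_pixels(final_pca, final_model,
                                               pixel_sets[pid])
        n_collagen.append(int(px_labels.size))
        n_ecm3.append(int(px_labels.sum()))
    scores = np.array([e / c for e, c in zip(n_ecm3, n_collagen)])
    kept_labels = np.array([labels_by_pid[pid] for pid in kept_ids])

    try:
        cutoff, cutoff_info = irscore.find_cutoff(scores, kept_labels)
        strat = irscore.stratify(scores, cutoff, kept_labels)
        score_table = irscore.ir_score_table(kept_ids, n_collagen, n_ecm3,
                                             cutoff)
    except Exception as exc:
        raise StageError(f"analyze/score: {exc}") from exc

    try:
        tstat, tp_p = cohortstats.compare_groups(scores, kept_labels,
                                                 config.group_test)
        kept = cohort.set_index("patient_id").loc[kept_ids]
        assoc = cohortstats.linear_fit(kept["mean_log2_expr"].to_numpy(),
                                       scores, config.fit_orientation)
        chars = cohortstats.characteristics_table(cohort)
        kept = kept.assign(ir_call=np.where(strat.calls, "ECM3", "non-ECM3"))
        surv = cohortstats.survival_by_ecm_and_grade(kept.reset_index(),
                                                     ecm_column="ir_call")
    except Exception as exc:
        raise StageError(f"analyze/stats: {exc}") from exc

    truth_by_pid = dict(zip(patient_ids, sim.true_fractions))
    true_fracs = np.array([truth_by_pid[pid] for pid in kept_ids])
    score_truth_r = float(np.corrcoef(scores, true_fracs)[0, 1]) \
        if np.ptp(true_fracs) > 0 else float("nan")

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohort": {
            "n_patients": len(patient_ids),
            "n_ecm3": int((cohort["ecm_class"] == "ECM3").sum()),
            "n_non_ecm3": int((cohort["ecm_class"] == "non-ECM3").sum()),
            "n_analyzed": len(kept_ids),
        },
        "segmentation": {
            "mean_pixel_accuracy": (float(np.mean(seg_accuracy))
                                    if seg_accuracy else None),
        },
        "discriminant": {
            "chosen_gamma": cv.chosen[0],
            "chosen_delta": cv.chosen[1],
            "cv_loss": float(cv.cv_loss[cv.chosen_index]),
            "oof_auc": roc.auc,
            "oof_auc_ci": list(roc.auc_ci),
            "n_nonzero_weights": int(np.count_nonzero(final_model.w)),
        },
        "ir_score": {
            "cutoff": cutoff,
            "cutoff_method": cutoff_info["method"],
            "sensitivity_pct": strat.sensitivity_pct,
            "specificity_pct": strat.specificity_pct,
            "sensitivity": f"{strat.tp}/{strat.tp + strat.fn}",
            "specificity": f"{strat.tn}/{strat.tn + strat.fp}",
            "confusion": {"tp": strat.tp, "fn": strat.fn,
                          "tn": strat.tn, "fp": strat.fp},
            "score_vs_truth_pearson_r": score_truth_r,
            "scores": {pid: float(s) for pid, s in zip(kept_ids, scores)},
        },
        "group_comparison": {"test": config.group_test,
                             "statistic": tstat, "p": tp_p},
        "association": {
            "orientation": assoc.orientation,
            "slope": assoc.slope, "slope_se": assoc.slope_se,
            "slope_t": assoc.slope_t, "slope_p": assoc.slope_p,
            "intercept": assoc.intercept, "intercept_se": assoc.intercept_se,
            "r_squared": assoc.r_squared,
        },
        "survival": {
            "logrank_chi2": surv["logrank_chi2"],
            "logrank_df": surv["logrank_df"],
            "logrank_p": surv["logrank_p"],
            "gradeIII_logrank_p": surv.get("gradeIII_logrank_p"),
        },
    }

    if config.output_dir:
        _write_artifacts(config, report, score_table, chars, cohort, surv)
    return report


def run_end_to_end(config: RunConfig) -> dict:
    """Simulate and analyze in one pass."""
    return analyze_cohort(config, simulate_cohort(config))


def _write_artifacts(config: RunConfig, report: dict,
                     score_table: pd.DataFrame, chars: pd.DataFrame,
                     cohort: pd.DataFrame, surv: dict) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report["config_hash"], "seed": report["seed"]}
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    for name, df in (("ir_scores", score_table), ("characteristics", chars)):
        with open(out / f"{name}.csv", "w") as fh:
            fh.write(f"# {json.dumps(stamp)}\n")
            df.to_csv(fh, index=False)
    write_cohort_table(cohort, out / "cohort.csv")
    save_run_config(config, out / "run_config.yaml")
    try:
        _plot_km(surv, out / "km_curves.png")
    except Exception as exc:  # plotting is best-effort provenance, not data
        logger.warning("KM plot failed: %s", exc)


def _plot_km(surv: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    styles = {"ECM3 GIII": ("k", "-"), "non-ECM3 GIII": ("k", ":"),
              "ECM3 GI-II": ("0.6", "-"), "non-ECM3 GI-II": ("0.6", ":")}
    for name, fit in surv["km_fits"].items():
        color, ls = styles.get(name, ("C0", "-"))
        ax.step(fit.event_times, fit.survival, where="post", color=color,
                linestyle=ls, label=name)
    ax.set_xlabel("months")
    ax.set_ylabel("disease-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    ax.set_title(f"log-rank p = {surv['logrank_p']:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_classified_map(class_map: histoseg.TissueClassMap,
                          ecm3_mask: np.ndarray) -> np.ndarray:
    """RGB render: grey tissue classes, ECM3 collagen red, non-ECM3 blue."""
    greys = {"background": 0.0, "epithelium": 0.75, "fibroblast": 0.55,
             "myofibroblast": 0.45, "blood": 0.35, "necrosis": 0.25,
             "collagen": 0.6}
    H, W = class_map.labels.shape
    img = np.zeros((H, W, 3))
    for i, name in enumerate(class_map.class_names):
        img[class_map.labels == i] = greys.get(name, 0.5)
    collagen = class_map.mask("collagen")
    img[collagen & ecm3_mask] = (0.85, 0.1, 0.1)
    img[collagen & ~ecm3_mask] = (0.1, 0.2, 0.85)
    return img
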