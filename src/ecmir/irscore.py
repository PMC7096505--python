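"""Patient-level IR score: aggregation, cutoff selection, dichotomization.

The IR score of a tumor is the fraction of its collagen-classified pixels that
the spectral discriminant calls ECM3.  The cohort-level cutoff on the score is
the posterior-0.5 point of a logistic regression of the gene-expression labels
on the score (−β₀/β₁); under complete separation, the midpoint between the
highest negative and lowest positive score is used instead.  A score exactly
at the cutoff is called positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)


class UndefinedScoreError(ValueError):
    """Patient has no collagen pixels; the IR score is undefined."""


def compute_ir_score(n_ecm3: int, n_collagen: int) -> float:
    """Exact count ratio n_ecm3 / n_collagen as a float."""
    if n_collagen < 1:
        raise UndefinedScoreError("zero collagen pixels: IR score undefined")
    if not 0 <= n_ecm3 <= n_collagen:
        raise ValueError("ECM3 pixel count outside [0, n_collagen]")
    return n_ecm3 / n_collagen


def score_from_pixel_labels(pixel_labels: np.ndarray) -> float:
    """IR score from a boolean per-pixel ECM3 call array for one patient."""
    labels = np.asarray(pixel_labels, dtype=bool)
    return compute_ir_score(int(labels.sum()), int(labels.size))


def find_cutoff(scores: np.ndarray, labels: np.ndarray,
                positive: str = "ECM3") -> tuple[float, dict]:
    """Score cutoff from a logistic model P(positive) = σ(β₀ + β₁·score).

    Returns (cutoff, info).  The cutoff is −β₀/β₁ (posterior 0.5).  Complete
    separation (detected by MLE weight blow-up or a statsmodels separation
    error) falls back to the midpoint between max(negative scores) and
    min(positive scores).  A non-positive β₁ falls back to the Youden point of
    the score ROC, with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive).astype(float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    def _midpoint() -> float:
        return float((scores[y == 0].max() + scores[y == 1].min()) / 2.0)

    if scores[y == 0].max() < scores[y == 1].min():
        # complete separation: the logistic MLE diverges, the posterior-0.5
        # point degenerates to anywhere inside the gap; take its midpoint
        cutoff = _midpoint()
        logger.info("find_cutoff: scores completely separated; midpoint rule "
                    "gives %.4f", cutoff)
        return cutoff, {"method": "midpoint_separation"}

    X = sm.add_constant(scores)
    try:
        import warnings
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # quasi-separation stalls the MLE; the fallbacks below handle it
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta0, beta1 = fit.params
    except (PerfectSeparationError, np.linalg.LinAlgError):
        cutoff = _midpoint()
        logger.info("find_cutoff: complete separation; midpoint rule gives %.4f",
                    cutoff)
        return cutoff, {"method": "midpoint_separation"}

    if abs(beta1) > 1e4 or abs(beta0) > 1e6:
        # diverging MLE — the classes are (quasi-)separated on the score
        cutoff = _midpoint()
        logger.info("find_cutoff: diverging logistic fit (|β₁|=%.3g); midpoint "
                    "rule gives %.4f", abs(beta1), cutoff)
        return cutoff, {"method": "midpoint_separation"}

    if beta1 <= 0:
        logger.warning("find_cutoff: non-positive slope β₁=%.3g; falling back "
                       "to the Youden point of the score ROC", beta1)
        from .ecm3disc import roc_curve
        roc = roc_curve(scores, np.asarray(labels), positive=positive,
                        n_boot=10, seed=0)
        return float(roc.optimal_threshold), {"method": "youden_fallback",
                                              "beta": (float(beta0), float(beta1))}

    cutoff = float(-beta0 / beta1)
    return cutoff, {"method": "logistic",
                    "beta": (float(beta0), float(beta1))}


@dataclass
class StratificationResult:
    calls: np.ndarray               # boolean positive calls
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: Fraction
    specificity: Fraction

    @property
    def sensitivity_pct(self) -> int:
        return round(100 * float(self.sensitivity))

    @property
    def specificity_pct(self) -> int:
        return round(100 * float(self.specificity))


def stratify(scores: np.ndarray, cutoff: float, labels: np.ndarray,
             positive: str = "ECM3") -> StratificationResult:
    """Dichotomize at the cutoff (score ≥ cutoff → positive) and score it.

    Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP), kept as exact
    fractions; rounded integer percentages via the ``*_pct`` properties.
    """
    if np.isnan(cutoff):
        raise ValueError("cutoff must not be NaN")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(labels) == positive
    calls = scores >= cutoff
    tp = int(np.sum(calls & truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))
    fp = int(np.sum(calls & ~truth))
    sens = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
    spec = Fraction(tn, tn + fp) if tn + fp else Fraction(0)
    return StratificationResult(calls=calls, tp=tp, fn=fn, tn=tn, fp=fp,
                                sensitivity=sens, specificity=spec)


def ir_score_table(patient_ids: list[str], n_collagen: np.ndarray,
                   n_ecm3: np.ndarray, cutoff: float) -> pd.DataFrame:
    """Per-patient score table with the cohort cutoff and dichotomized call."""
    scores = np.array([compute_ir_score(int(e), int(c))
                       for e, c in zip(n_ecm3, n_collagen)])
    return pd.DataFrame({
        "patient_id": patient_ids,
        "n_collagen_pixels": np.asarray(n_collagen, dtype=int),
        "n_ecm3_pixels": np.asarray(n_ecm3, dtype=int),
        "ir_score": scores,
        "cutoff": cutoff,
        "call": np.where(scores >= cutoff, "ECM3", "non-ECM3"),
    })
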