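"""Relative response factors (RRFs) and homologue-based RRF prediction.

The internal-standard method expresses each calibration injection as a
relative response factor

    RRF = (A_analyte / A_IS) / (m_analyte / m_IS)

where ``A`` are peak responses and ``m`` masses.  Congeners with an authentic
standard are quantified with their own RRF.  Congeners without a standard
(most of the 837 possible OH-PCBs) are quantified with a *predicted* RRF
derived from the calibrated congeners of the same homologue (chlorine
count):

* per-homologue estimate: geometric mean (GM) of the standard-level GM RRFs
  of that homologue, with a seeded percentile-bootstrap 95% interval obtained
  by resampling standards (not injections) within the homologue;
* cross-homologue fallback: a weighted least-squares regression of ln(RRF)
  on the chlorine count, used for homologues absent from (or sparse in) the
  calibration set, with a bootstrap interval from resampling standards
  globally.

Injections of the same standard are repeated measures, so they are pooled
into one standard-level GM before any resampling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .peak_tables import AnalyteID, CalibrationReplicate

__all__ = [
    "RRFObservation",
    "HomologueEstimate",
    "PredictedRRF",
    "ResponseModel",
    "compute_rrfs",
    "fit_response_model",
    "predict_rrf",
]

logger = logging.getLogger(__name__)

_MAX_CL = 10


@dataclass(frozen=True)
class RRFObservation:
    """RRF of one standard in one replicate injection."""

    analyte: AnalyteID
    rrf: float
    replicate_index: int

    def __post_init__(self) -> None:
        if self.rrf <= 0:
            raise ValueError(f"{self.analyte.label}: RRF must be > 0")


@dataclass(frozen=True)
class HomologueEstimate:
    n_cl: int
    estimate: float
    ci_low: float
    ci_high: float
    n_standards: int
    estimator: str  # "gm" | "regression"
    fallback_estimate: float | None = None


@dataclass(frozen=True)
class PredictedRRF:
    estimate: float
    ci_low: float
    ci_high: float
    estimator: str
    n_standards: int
    wide_ci: bool = False


def compute_rrfs(
    calibration: Iterable[CalibrationReplicate],
    is_response: float,
    is_mass: float,
) -> list[RRFObservation]:
    """Per-replicate RRFs from a calibration table.

    Standards with a nonpositive response are excluded with a warning rather
    than aborting the calibration.
    """
    if is_response <= 0 or is_mass <= 0:
        raise ValueError("internal-standard response and mass must be > 0")
    out: list[RRFObservation] = []
    dropped = []
    for rec in calibration:
        if rec.response <= 0:
            dropped.append((rec.analyte.label, rec.replicate_index))
            continue
        rrf = (rec.response / is_response) / (rec.standard_mass_ng / is_mass)
        out.append(RRFObservation(rec.analyte, rrf, rec.replicate_index))
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} calibration replicate(s) with nonpositive "
            f"response (e.g. {dropped[:3]})",
            stacklevel=2,
        )
        logger.warning("calibration replicates excluded: %s", dropped)
    return out


def _expanded_quantiles(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile-bootstrap quantiles with the small-sample expansion.

    The plain 2.5/97.5 percentile interval undercovers badly when only a
    handful of standards are resampled; widening the quantiles to
    Phi(-sqrt(n/(n-1)) * t(1-alpha/2, n-1)) (Hesterberg's expanded
    percentile interval) restores near-nominal coverage.
    """
    if n < 2:
        return 2.5, 97.5
    z = np.sqrt(n / (n - 1)) * stats.t.ppf(1 - alpha / 2, n - 1)
    a = float(stats.norm.cdf(-z))
    return 100 * a, 100 * (1 - a)


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on x; returns (intercept, slope)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    if sxx <= 0:
        return float(my), 0.0
    slope = (w * (x - mx) * (y - my)).sum() / sxx
    return float(my - slope * mx), float(slope)


def _boot_lines(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised WLS over bootstrap resamples (rows of ``idx``)."""
    X, Y, W = x[idx], y[idx], w[idx]
    sw = W.sum(axis=1)
    mx = (W * X).sum(axis=1) / sw
    my = (W * Y).sum(axis=1) / sw
    dx = X - mx[:, None]
    sxx = (W * dx**2).sum(axis=1)
    sxy = (W * dx * (Y - my[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    intercept = my - slope * mx
    return intercept, slope


@dataclass
class ResponseModel:
    """Fitted per-homologue RRF model with bootstrap uncertainty."""

    per_homologue: dict[int, HomologueEstimate]
    per_analyte: dict[str, float]
    regression_intercept: float
    regression_slope: float
    regression_boot: np.ndarray  # (B, 2) intercept/slope resamples
    bootstrap_B: int
    seed: int
    min_standards_gm: int = 3

    def predict(self, n_cl: int) -> PredictedRRF:
        return predict_rrf(self, n_cl)

    def analyte_rrf(self, label: str) -> float | None:
        return self.per_analyte.get(label)

    def to_json(self, path=None) -> str:
        payload = {
            "per_homologue": {
                str(k): asdict(v) for k, v in sorted(self.per_homologue.items())
            },
            "per_analyte": dict(sorted(self.per_analyte.items())),
            "regression": {
                "intercept": self.regression_intercept,
                "slope": self.regression_slope,
            },
            "regression_boot": self.regression_boot.tolist(),
            "bootstrap_B": self.bootstrap_B,
            "seed": self.seed,
            "min_standards_gm": self.min_standards_gm,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ResponseModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        per_hom = {
            int(k): HomologueEstimate(**v) for k, v in payload["per_homologue"].items()
        }
        return cls(
            per_homologue=per_hom,
            per_analyte=payload["per_analyte"],
            regression_intercept=payload["regression"]["intercept"],
            regression_slope=payload["regression"]["slope"],
            regression_boot=np.asarray(payload["regression_boot"], dtype=float),
            bootstrap_B=payload["bootstrap_B"],
            seed=payload["seed"],
            min_standards_gm=payload.get("min_standards_gm", 3),
        )


def fit_response_model(
    rrfs: Sequence[RRFObservation],
    B: int = 2000,
    seed: int = 0,
    min_standards_gm: int = 3,
) -> ResponseModel:
    """Fit the per-homologue RRF model from replicate RRF observations.

    Parameters
    ----------
    rrfs
        Per-replicate observations from :func:`compute_rrfs`.
    B
        Number of bootstrap resamples for the percentile intervals.
    seed
        Seed of the bootstrap random stream; fixed seed gives identical
        intervals across runs.
    min_standards_gm
        Homologues with fewer standards than this keep their GM estimate but
        are additionally annotated with the regression fallback.
    """
    rrfs = list(rrfs)
    if not rrfs:
        raise ValueError("no RRF observations")
    rng = np.random.default_rng(seed)

    # Pool injections: standard-level GM per analyte.
    by_analyte: dict[str, list[float]] = {}
    n_cl_of: dict[str, int] = {}
    for obs in rrfs:
        by_analyte.setdefault(obs.analyte.label, []).append(obs.rrf)
        n_cl_of[obs.analyte.label] = obs.analyte.n_cl
    labels = sorted(by_analyte)
    std_gm = {lab: float(np.exp(np.mean(np.log(by_analyte[lab])))) for lab in labels}
    std_w = {lab: float(len(by_analyte[lab])) for lab in labels}

    # Cross-homologue regression of ln(RRF) on chlorine count, weighted by the
    # number of replicate injections behind each standard.
    x = np.array([n_cl_of[lab] for lab in labels], dtype=float)
    y = np.log([std_gm[lab] for lab in labels])
    w = np.array([std_w[lab] for lab in labels])
    intercept, slope = _wls_line(x, y, w)
    if np.unique(x).size < 2:
        logger.warning(
            "single homologue in calibration; regression fallback degenerates "
            "to the global geometric mean"
        )

    # Per-homologue GM estimates with percentile bootstrap over standards.
    per_homologue: dict[int, HomologueEstimate] = {}
    for n_cl in sorted({n_cl_of[lab] for lab in labels}):
        vals = np.log([std_gm[lab] for lab in labels if n_cl_of[lab] == n_cl])
        est = float(np.exp(vals.mean()))
        n_std = vals.size
        idx = rng.integers(0, n_std, size=(B, n_std))
        boots = np.exp(vals[idx].mean(axis=1))
        lo, hi = np.percentile(boots, _expanded_quantiles(n_std))
        fallback = float(np.exp(intercept + slope * n_cl))
        per_homologue[n_cl] = HomologueEstimate(
            n_cl=n_cl,
            estimate=est,
            ci_low=float(min(lo, est)),
            ci_high=float(max(hi, est)),
            n_standards=int(n_std),
            estimator="gm",
            fallback_estimate=fallback if n_std < min_standards_gm else None,
        )
        if n_std < min_standards_gm:
            logger.info(
                "homologue %d: only %d standard(s); regression fallback %.4g "
                "recorded alongside GM %.4g",
                n_cl,
                n_std,
                fallback,
                est,
            )

    boot_idx = rng.integers(0, len(labels), size=(B, len(labels)))
    boot_a, boot_b = _boot_lines(x, y, w, boot_idx)
    return ResponseModel(
        per_homologue=per_homologue,
        per_analyte=std_gm,
        regression_intercept=intercept,
        regression_slope=slope,
        regression_boot=np.column_stack([boot_a, boot_b]),
        bootstrap_B=B,
        seed=seed,
        min_standards_gm=min_standards_gm,
    )


def predict_rrf(model: ResponseModel, n_cl: int) -> PredictedRRF:
    """Predicted RRF (with 95% interval) for a homologue.

    Homologues represented in the calibration return their GM entry; absent
    homologues fall back to the ln-linear regression, flagged ``wide_ci``.
    """
    if not 0 <= n_cl <= _MAX_CL:
        raise ValueError(f"n_cl {n_cl} outside 0-{_MAX_CL}")
    entry = model.per_homologue.get(n_cl)
    if entry is not None:
        return PredictedRRF(
            estimate=entry.estimate,
            ci_low=entry.ci_low,
            ci_high=entry.ci_high,
            estimator=entry.estimator,
            n_standards=entry.n_standards,
        )
    est = float(np.exp(model.regression_intercept + model.regression_slope * n_cl))
    boots = np.exp(model.regression_boot[:, 0] + model.regression_boot[:, 1] * n_cl)
    n_std = sum(e.n_standards for e in model.per_homologue.values())
    lo, hi = np.percentile(boots, _expanded_quantiles(n_std))
    logger.info("homologue %d absent from calibration; regression RRF %.4g", n_cl, est)
    return PredictedRRF(
        estimate=est,
        ci_low=float(min(lo, est)),
        ci_high=float(max(hi, est)),
        estimator="regression",
        n_standards=0,
        wide_ci=True,
    )
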