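"""Mass quantification, recovery correction, and LOQ censoring.

Masses come from the internal-standard method,

    mass = (A_analyte / A_IS) * m_IS / RRF,

are corrected by the recovery of the surrogate standard with the nearest
chlorine count, converted to concentration (ng/g dry weight for sediments,
ng/sample for Aroclor mixtures), and censored against a limit of
quantification (LOQ) derived from method blanks:

* known congeners: LOQ = mean + t(0.95, n-1) * s of the blank masses (the
  upper end of a 95% one-sided bound with the standard deviation itself,
  not the standard error);
* unknown OH-PCBs: one LOQ per matrix, the same upper bound applied to the
  log of the positive known OH-PCB LOQs, i.e.
  exp(mean(ln L) + t(0.95, n-1) * sd(ln L)).

A concentration strictly below its LOQ is recorded as zero and flagged
censored; a value exactly at the LOQ is retained.  Blanks are used only for
the LOQ — masses are never blank-subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .peak_tables import (
    IS_FOR_FAMILY,
    AnalyteID,
    SampleRun,
    parse_analyte_id,
    parse_surrogate_label,
)
from .response_model import ResponseModel, predict_rrf

__all__ = [
    "QuantificationError",
    "LOQTable",
    "RecoveryTable",
    "ConcentrationTable",
    "quantify_mass",
    "recovery_correct",
    "loq_known",
    "loq_unknown",
    "censor",
    "build_loq_table",
    "compute_recoveries",
    "concentrations",
    "CONCENTRATION_COLUMNS",
]

logger = logging.getLogger(__name__)

RECOVERY_FLAG_RANGE = (0.25, 2.0)

CONCENTRATION_COLUMNS = [
    "sample_id",
    "site",
    "matrix",
    "analyte",
    "family",
    "n_cl",
    "rrt",
    "concentration",
    "units",
    "censored",
    "loq",
    "recovery",
    "rrf_estimator",
]


class QuantificationError(ValueError):
    """Inputs that make a quantification step impossible."""


def quantify_mass(
    response: float, is_response: float, is_mass: float, rrf: float
) -> float:
    """Analyte mass (ng) by the internal-standard method."""
    if rrf <= 0:
        raise QuantificationError("RRF must be > 0")
    if is_response <= 0 or is_mass <= 0:
        raise QuantificationError("internal-standard response and mass must be > 0")
    if response <= 0:
        raise QuantificationError("peak response must be > 0")
    return (response / is_response) * is_mass / rrf


def recovery_correct(
    mass_ng: float, analyte: AnalyteID, recoveries: Mapping[int, float]
) -> float:
    """Divide a mass by the recovery of the surrogate with the nearest #Cl.

    ``recoveries`` maps surrogate chlorine count to recovery fraction for the
    analyte's family in the analyte's sample.  Ties in |#Cl difference| go to
    the lower-chlorinated surrogate.
    """
    if not recoveries:
        raise QuantificationError(f"{analyte.label}: no surrogate recoveries")
    n_cl = min(sorted(recoveries), key=lambda s: (abs(s - analyte.n_cl), s))
    recovery = recoveries[n_cl]
    if recovery <= 0:
        raise QuantificationError(
            f"{analyte.label}: surrogate Cl{n_cl} recovery {recovery} <= 0"
        )
    return mass_ng / recovery


def loq_known(blank_masses: Iterable[float], alpha: float = 0.05) -> float:
    """LOQ of a calibrated congener from its method-blank masses (ng).

    mean + t(1-alpha, n-1) * sd, the upper end of the blank distribution's
    95% bound (the sd is not divided by sqrt(n)).
    """
    vals = np.asarray(list(blank_masses), dtype=float)
    if vals.size < 2:
        raise QuantificationError(
            "need >=2 blank values for an LOQ; supply a configured fallback "
            "LOQ for this analyte instead"
        )
    t = stats.t.ppf(1 - alpha, df=vals.size - 1)
    return float(vals.mean() + t * vals.std(ddof=1))


def loq_unknown(known_loqs: Iterable[float], alpha: float = 0.05) -> float:
    """Matrix-wide LOQ for OH-PCBs without standards.

    The same one-sided upper bound applied to ln of the positive known
    OH-PCB LOQs: exp(mean(ln L) + t(1-alpha, n-1) * sd(ln L)).  Always at
    least the geometric mean of the inputs.
    """
    vals = np.asarray(list(known_loqs), dtype=float)
    if vals.size < 2:
        raise QuantificationError("need >=2 known LOQs to derive the unknown LOQ")
    if np.any(vals <= 0):
        raise QuantificationError("known LOQs must all be positive")
    logs = np.log(vals)
    t = stats.t.ppf(1 - alpha, df=vals.size - 1)
    return float(np.exp(logs.mean() + t * logs.std(ddof=1)))


def censor(
    concentration: float, loq: float, boundary: str = "below"
) -> tuple[float, bool]:
    """Apply LOQ censoring: a value below the LOQ becomes zero.

    Returns ``(value, censored)``.  With the default ``boundary="below"``
    only values strictly below the LOQ are censored — a value exactly at the
    LOQ is retained, and an LOQ of zero retains everything.  The alternate
    policy ``"at-or-below"`` also censors the boundary value.
    """
    if concentration < 0:
        raise QuantificationError("negative concentration")
    if loq < 0:
        raise QuantificationError("negative LOQ")
    if boundary not in ("below", "at-or-below"):
        raise QuantificationError(f"unknown censoring boundary {boundary!r}")
    is_below = concentration < loq if boundary == "below" else concentration <= loq
    if is_below:
        return 0.0, True
    return float(concentration), False


@dataclass
class LOQTable:
    """Per-analyte LOQs for knowns plus one unknown-congener LOQ, per matrix."""

    known: dict[str, float]
    unknown_loq: float
    matrix: str
    units: str
    alpha: float = 0.05
    n_blanks: int = 0

    def loq_for(self, analyte: AnalyteID) -> float:
        if analyte.kind == "unknown-OHPCB":
            return self.unknown_loq
        return self.known.get(analyte.label, 0.0)


def build_loq_table(
    blanks: pd.DataFrame,
    matrix: str,
    alpha: float = 0.05,
    blank_sample_mass_g: float = 1.0,
) -> LOQTable:
    """LOQ table from a tidy blank-mass frame (blank_id, analyte, mass_ng).

    Analytes absent from a given blank contribute a zero mass to that blank.
    Sediment LOQs are expressed per gram using ``blank_sample_mass_g`` (the
    matrix-equivalent mass carried through each blank); Aroclor LOQs stay in
    ng/sample.  The unknown-congener LOQ uses only the positive LOQs of known
    OH-PCBs; if fewer than two exist it is set to zero with a warning.
    """
    if matrix not in ("sediment", "aroclor"):
        raise QuantificationError(f"unknown matrix {matrix!r}")
    if blanks.empty:
        raise QuantificationError("no blank rows; cannot derive LOQs")
    wide = blanks.pivot_table(
        index="analyte", columns="blank_id", values="mass_ng", fill_value=0.0
    )
    n_blanks = wide.shape[1]
    scale = blank_sample_mass_g if matrix == "sediment" else 1.0
    units = "ng/g" if matrix == "sediment" else "ng/sample"
    known: dict[str, float] = {}
    known_oh_loqs: list[float] = []
    for label, row in wide.iterrows():
        analyte = parse_analyte_id(label)
        loq = loq_known(row.to_numpy(), alpha=alpha) / scale
        loq = max(loq, 0.0)
        if analyte.kind == "unknown-OHPCB":
            continue  # unknowns get the matrix-wide LOQ below
        known[analyte.label] = loq
        if analyte.kind == "known-OHPCB" and loq > 0:
            known_oh_loqs.append(loq)
    if len(known_oh_loqs) >= 2:
        unknown = loq_unknown(known_oh_loqs, alpha=alpha)
    else:
        unknown = 0.0
        logger.warning(
            "fewer than two positive known OH-PCB LOQs in %s blanks; "
            "unknown-congener LOQ set to 0",
            matrix,
        )
    return LOQTable(
        known=known,
        unknown_loq=unknown,
        matrix=matrix,
        units=units,
        alpha=alpha,
        n_blanks=n_blanks,
    )


@dataclass
class RecoveryTable:
    """Surrogate recoveries per (sample, family, surrogate #Cl)."""

    entries: dict[tuple[str, str, int], float] = field(default_factory=dict)
    flagged: list[tuple[str, str, int, float]] = field(default_factory=list)

    def for_sample(self, sample_id: str, family: str) -> dict[int, float]:
        return {
            n_cl: rec
            for (sid, fam, n_cl), rec in self.entries.items()
            if sid == sample_id and fam == family
        }


def compute_recoveries(
    sample: SampleRun,
    is_mass_ng: float = 25.0,
    surrogate_rrf: float = 1.0,
) -> RecoveryTable:
    """Surrogate recoveries of one sample from its surrogate responses.

    The isotope-labelled surrogates are taken to have unit RRF against their
    family's internal standard (they are calibrated separately from the
    analytes), so recovery = measured surrogate mass / spiked mass.
    Recoveries outside [0.25, 2.0] are flagged and logged, never capped.
    """
    table = RecoveryTable()
    for label, response in sample.surrogate_responses.items():
        family, n_cl = parse_surrogate_label(label)
        is_label = IS_FOR_FAMILY[family]
        is_response = sample.internal_standard_responses.get(is_label)
        if is_response is None:
            raise QuantificationError(
                f"sample {sample.sample_id}: internal standard {is_label} missing"
            )
        measured = quantify_mass(response, is_response, is_mass_ng, surrogate_rrf)
        recovery = measured / sample.spiked_surrogate_mass_ng
        table.entries[(sample.sample_id, family, n_cl)] = recovery
        if not RECOVERY_FLAG_RANGE[0] <= recovery <= RECOVERY_FLAG_RANGE[1]:
            table.flagged.append((sample.sample_id, family, n_cl, recovery))
            logger.warning(
                "sample %s: %s surrogate Cl%d recovery %.2f outside %s",
                sample.sample_id,
                family,
                n_cl,
                recovery,
                RECOVERY_FLAG_RANGE,
            )
    return table


@dataclass
class ConcentrationTable:
    """Censored, recovery-corrected congener x sample concentrations."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CONCENTRATION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise QuantificationError(f"concentration table missing columns {missing}")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=CONCENTRATION_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        frame = pd.read_csv(path)
        frame["censored"] = frame["censored"].astype(bool)
        return cls(frame)

    def totals(self, family: str) -> pd.Series:
        sub = self.frame[self.frame["family"] == family]
        return sub.groupby("sample_id")["concentration"].sum()


def concentrations(
    sample: SampleRun,
    model: ResponseModel,
    loqs: LOQTable,
    recoveries: RecoveryTable | None = None,
    is_mass_ng: float = 25.0,
    censor_boundary: str = "below",
) -> ConcentrationTable:
    """Quantify one sample end to end.

    Knowns use their own calibration RRF; unknowns use the homologue
    prediction.  Injections are averaged before quantification.  Zero is by
    definition censored (a non-detect), so ``concentration == 0`` iff
    ``censored``.
    """
    if loqs.matrix != sample.matrix:
        raise QuantificationError(
            f"sample {sample.sample_id} matrix {sample.matrix!r} does not match "
            f"LOQ table matrix {loqs.matrix!r}"
        )
    if recoveries is None:
        recoveries = compute_recoveries(sample, is_mass_ng=is_mass_ng)
    rec_by_family = {
        fam: recoveries.for_sample(sample.sample_id, fam) for fam in ("OHPCB", "PCB")
    }

    by_analyte: dict[AnalyteID, list[float]] = {}
    for peak in sample.peaks:
        by_analyte.setdefault(peak.analyte, []).append(peak.response)

    rows = []
    n_censored = 0
    for analyte in sorted(by_analyte, key=lambda a: (a.family, a.n_cl, a.label)):
        family = analyte.family
        is_label = IS_FOR_FAMILY[family]
        is_response = sample.internal_standard_responses.get(is_label)
        if is_response is None:
            raise QuantificationError(
                f"sample {sample.sample_id}: internal standard {is_label} missing"
            )
        response = float(np.mean(by_analyte[analyte]))
        own_rrf = model.analyte_rrf(analyte.label)
        if analyte.kind != "unknown-OHPCB" and own_rrf is not None:
            rrf, estimator = own_rrf, "standard"
        else:
            pred = predict_rrf(model, analyte.n_cl)
            rrf, estimator = pred.estimate, pred.estimator
            if analyte.kind != "unknown-OHPCB":
                logger.warning(
                    "known analyte %s has no calibration standard; homologue "
                    "RRF used",
                    analyte.label,
                )
        if response > 0:
            mass = quantify_mass(response, is_response, is_mass_ng, rrf)
            fam_recs = rec_by_family[family]
            corrected = recovery_correct(mass, analyte, fam_recs)
            rec_ncl = min(
                sorted(fam_recs), key=lambda s: (abs(s - analyte.n_cl), s)
            )
            recovery_used = fam_recs[rec_ncl]
            conc = (
                corrected / sample.sample_mass_g
                if sample.matrix == "sediment"
                else corrected
            )
        else:
            conc, recovery_used = 0.0, float("nan")
        loq = loqs.loq_for(analyte)
        value, censored = censor(conc, loq, boundary=censor_boundary)
        censored = censored or value == 0.0
        if censored:
            value = 0.0
            n_censored += 1
        rows.append(
            {
                "sample_id": sample.sample_id,
                "site": sample.site,
                "matrix": sample.matrix,
                "analyte": analyte.label,
                "family": family,
                "n_cl": analyte.n_cl,
                "rrt": analyte.rrt if analyte.rrt is not None else np.nan,
                "concentration": value,
                "units": loqs.units,
                "censored": censored,
                "loq": loq,
                "recovery": recovery_used,
                "rrf_estimator": estimator,
            }
        )
    logger.info(
        "sample %s: %d peaks quantified, %d censored to zero",
        sample.sample_id,
        len(rows),
        n_censored,
    )
    return ConcentrationTable(pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS))
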