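"""Data model and CSV readers/writers for congener-specific peak tables.

Analytes are PCB and mono-hydroxylated PCB (OH-PCB) chromatographic peaks.
Known congeners carry EPA/BZ congener numbers ("PCB52", "4-OH-PCB52",
"4'-OH-PCB18"); OH-PCB peaks without an authentic standard are identified
only by their homologue (chlorine count) and relative retention time and are
written in the ``<n_cl>@<rrt>`` grammar, e.g. ``2@1.232``.  Coeluting
congeners form a single analyte ("PCB20 + PCB28").

CSV schemas
-----------
calibration : analyte, standard_mass_ng, response, replicate
sample      : sample_id, site, matrix, sample_mass_g, analyte, n_cl, rrt,
              response, injection
blank       : blank_id, analyte, mass_ng

In the sample schema, rows whose analyte is an internal-standard label
(``d5-PCB30``, ``PCB204``) populate ``SampleRun.internal_standard_responses``
and rows with a surrogate label (``SURR-<family>-Cl<n>``) populate
``SampleRun.surrogate_responses``; all other rows are analyte peaks.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AnalyteID",
    "PeakRecord",
    "SampleRun",
    "CalibrationReplicate",
    "AnalyteParseError",
    "PeakTableError",
    "parse_analyte_id",
    "format_analyte_id",
    "congener_n_cl",
    "canonical_order",
    "read_peak_table",
    "read_calibration_table",
    "read_sample_table",
    "read_blank_table",
    "write_calibration_table",
    "write_sample_table",
    "write_blank_table",
    "surrogate_label",
    "parse_surrogate_label",
    "IS_LABELS",
    "IS_FOR_FAMILY",
]


class PeakTableError(ValueError):
    """Malformed tabular input (missing column, bad cell, duplicate key)."""


class AnalyteParseError(PeakTableError):
    """An analyte label does not follow any recognised grammar."""


# Internal standards: one is the quantification reference for each family.
IS_LABELS = ("d5-PCB30", "PCB204")
IS_FOR_FAMILY = {"OHPCB": "d5-PCB30", "PCB": "PCB204"}

# BZ (EPA) congener-number ranges per homologue (#Cl).
_HOMOLOGUE_BOUNDS = (
    (1, 3, 1),
    (4, 15, 2),
    (16, 39, 3),
    (40, 81, 4),
    (82, 127, 5),
    (128, 169, 6),
    (170, 193, 7),
    (194, 205, 8),
    (206, 208, 9),
    (209, 209, 10),
)

_UNKNOWN_RE = re.compile(r"(\d{1,2})@(\d+(?:\.\d+)?)")
_OHPCB_RE = re.compile(r"(\d+)('?)-OH-PCB(\d+)")
_PCB_RE = re.compile(r"PCB\s*(\d+)")
_SURR_RE = re.compile(r"SURR-(OHPCB|PCB)-Cl(\d+)")


def congener_n_cl(number: int) -> int:
    """Chlorine count of a PCB congener from its EPA/BZ number (1-209)."""
    for lo, hi, n_cl in _HOMOLOGUE_BOUNDS:
        if lo <= number <= hi:
            return n_cl
    raise AnalyteParseError(f"congener number {number} outside 1-209")


@dataclass(frozen=True)
class AnalyteID:
    """One chromatographic peak identity (possibly several coeluting congeners).

    kind is one of ``known-PCB``, ``known-OHPCB``, ``unknown-OHPCB``.  For
    unknown OH-PCBs the relative retention time (vs. the retention-time
    internal standard) is part of the identity; for knowns it is optional
    elution metadata used by :func:`canonical_order`.
    """

    kind: str
    label: str
    n_cl: int
    rrt: float | None = None
    coeluters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("known-PCB", "known-OHPCB", "unknown-OHPCB"):
            raise AnalyteParseError(f"unknown analyte kind {self.kind!r}")
        if self.kind == "known-PCB":
            if not 0 <= self.n_cl <= 10:
                raise AnalyteParseError(f"{self.label}: n_cl {self.n_cl} outside 0-10")
        elif not 1 <= self.n_cl <= 10:
            raise AnalyteParseError(
                f"{self.label}: OH-PCB chlorine count {self.n_cl} outside 1-10"
            )
        if not self.coeluters:
            object.__setattr__(self, "coeluters", (self.label,))

    @property
    def family(self) -> str:
        return "PCB" if self.kind == "known-PCB" else "OHPCB"

    def with_rrt(self, rrt: float | None) -> "AnalyteID":
        if rrt is None or self.rrt is not None:
            return self
        return AnalyteID(self.kind, self.label, self.n_cl, float(rrt), self.coeluters)


def _parse_single(label: str) -> AnalyteID:
    m = _UNKNOWN_RE.fullmatch(label)
    if m:
        n_cl = int(m.group(1))
        rrt = round(float(m.group(2)), 3)
        canon = f"{n_cl}@{rrt:.3f}"
        return AnalyteID("unknown-OHPCB", canon, n_cl, rrt)
    m = _OHPCB_RE.fullmatch(label)
    if m:
        pos, prime, num = m.group(1), m.group(2), int(m.group(3))
        n_cl = congener_n_cl(num)
        canon = f"{pos}{prime}-OH-PCB{num}"
        return AnalyteID("known-OHPCB", canon, n_cl)
    m = _PCB_RE.fullmatch(label)
    if m:
        num = int(m.group(1))
        n_cl = congener_n_cl(num)
        return AnalyteID("known-PCB", f"PCB{num}", n_cl)
    raise AnalyteParseError(f"cannot parse analyte label {label!r}")


def parse_analyte_id(label: str) -> AnalyteID:
    """Parse an analyte label into an :class:`AnalyteID`.

    Accepts ``PCBn``, ``<pos>[']-OH-PCBn`` (the prime may be typed as the
    typographic U+2032 or an ASCII apostrophe), the unknown grammar
    ``<n_cl>@<rrt>``, and coelution joins such as ``PCB20 + 28`` or
    ``PCB18 + PCB30``.  Coeluting congeners must share a homologue.
    """
    if label is None or not str(label).strip():
        raise AnalyteParseError("empty analyte label")
    text = str(label).strip().replace("′", "'")
    parts = [p.strip() for p in text.split("+")] if "+" in text else [text]
    if any(not p for p in parts):
        raise AnalyteParseError(f"malformed coelution label {label!r}")
    first = _parse_single(parts[0])
    if len(parts) == 1:
        return first
    prefix = re.sub(r"\d+$", "", parts[0])
    members = [first]
    for part in parts[1:]:
        if re.fullmatch(r"\d+", part):  # shorthand "PCB20 + 28"
            part = prefix + part
        members.append(_parse_single(part))
    kinds = {m.kind for m in members}
    if len(kinds) > 1:
        raise AnalyteParseError(f"{label!r}: coeluting analytes of mixed kind")
    n_cls = {m.n_cl for m in members}
    if len(n_cls) > 1:
        raise AnalyteParseError(
            f"{label!r}: coeluting congeners span homologues {sorted(n_cls)}; "
            "assignment of a shared chlorine count is not defined"
        )
    canon = " + ".join(m.label for m in members)
    return AnalyteID(
        first.kind, canon, first.n_cl, first.rrt, tuple(m.label for m in members)
    )


def format_analyte_id(analyte: AnalyteID) -> str:
    """Canonical text form; the inverse of :func:`parse_analyte_id`."""
    return analyte.label


def _congener_numbers(analyte: AnalyteID) -> list[int]:
    return [int(re.search(r"(\d+)$", lab).group(1)) for lab in analyte.coeluters]


def canonical_order(
    analytes: Iterable[AnalyteID], family: str
) -> list[AnalyteID]:
    """Deterministic analyte ordering used for congener profiles.

    OH-PCBs sort by homologue, then elution order (RRT; analytes without an
    RRT sort after those with one), then label; PCBs sort by congener number.
    """
    analytes = list(analytes)
    if family == "OHPCB":
        if any(a.family != "OHPCB" for a in analytes):
            raise PeakTableError("canonical_order: mixed families in OHPCB ordering")
        key = lambda a: (a.n_cl, a.rrt if a.rrt is not None else math.inf, a.label)
    elif family == "PCB":
        if any(a.family != "PCB" for a in analytes):
            raise PeakTableError("canonical_order: mixed families in PCB ordering")
        key = lambda a: (min(_congener_numbers(a)), a.label)
    else:
        raise PeakTableError(f"unknown family {family!r}")
    return sorted(analytes, key=key)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakRecord:
    """One peak observation in one injection of one run."""

    analyte: AnalyteID
    response: float
    run_id: str
    injection_index: int = 1

    def __post_init__(self) -> None:
        if self.response < 0:
            raise PeakTableError(
                f"{self.run_id}/{self.analyte.label}: negative response"
            )
        if self.injection_index < 1:
            raise PeakTableError("injection_index must be >= 1")


@dataclass(frozen=True)
class CalibrationReplicate:
    """One replicate injection of one authentic standard."""

    analyte: AnalyteID
    standard_mass_ng: float
    response: float
    replicate_index: int

    def __post_init__(self) -> None:
        if self.analyte.kind == "unknown-OHPCB":
            raise PeakTableError(
                f"calibration standard {self.analyte.label}: unknowns have no standard"
            )
        if self.standard_mass_ng <= 0:
            raise PeakTableError(f"{self.analyte.label}: standard mass must be > 0")


def surrogate_label(family: str, n_cl: int) -> str:
    """Label of the isotope-labelled surrogate of a family/homologue."""
    if family not in ("OHPCB", "PCB"):
        raise PeakTableError(f"unknown family {family!r}")
    return f"SURR-{family}-Cl{n_cl}"


def parse_surrogate_label(label: str) -> tuple[str, int]:
    m = _SURR_RE.fullmatch(label)
    if not m:
        raise AnalyteParseError(f"not a surrogate label: {label!r}")
    return m.group(1), int(m.group(2))


@dataclass
class SampleRun:
    """All peaks and reference-compound responses for one sample."""

    sample_id: str
    site: str
    matrix: str  # sediment | aroclor | blank
    sample_mass_g: float
    peaks: list[PeakRecord] = field(default_factory=list)
    internal_standard_responses: dict[str, float] = field(default_factory=dict)
    surrogate_responses: dict[str, float] = field(default_factory=dict)
    spiked_surrogate_mass_ng: float = 25.0

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0:
            raise PeakTableError(f"{self.sample_id}: sample mass must be > 0")
        if self.matrix not in ("sediment", "aroclor", "blank"):
            raise PeakTableError(f"{self.sample_id}: unknown matrix {self.matrix!r}")

    def validate(self) -> None:
        """QA checks: both internal standards present, >=2 injections."""
        for is_label in IS_LABELS:
            if is_label not in self.internal_standard_responses:
                raise PeakTableError(
                    f"sample {self.sample_id}: internal standard {is_label} missing"
                )
        if self.peaks:
            n_inj = len({p.injection_index for p in self.peaks})
            if n_inj < 2:
                warnings.warn(
                    f"sample {self.sample_id}: only {n_inj} injection(s); "
                    ">=2 expected",
                    stacklevel=2,
                )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "calibration": ["analyte", "standard_mass_ng", "response", "replicate"],
    "sample": [
        "sample_id",
        "site",
        "matrix",
        "sample_mass_g",
        "analyte",
        "n_cl",
        "rrt",
        "response",
        "injection",
    ],
    "blank": ["blank_id", "analyte", "mass_ng"],
}


def _load_csv(path, schema: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise PeakTableError(f"{path}: cannot read CSV ({exc})") from exc
    missing = [c for c in _SCHEMAS[schema] if c not in frame.columns]
    if missing:
        raise PeakTableError(f"{path}: missing column(s) {missing} for {schema} schema")
    return frame


def _cell_float(frame_value: str, row: int, column: str, *, allow_blank=False):
    text = frame_value.strip()
    if not text:
        if allow_blank:
            return None
        raise PeakTableError(f"row {row}: column {column!r} is empty")
    try:
        return float(text)
    except ValueError:
        raise PeakTableError(
            f"row {row}: column {column!r} has non-numeric value {text!r}"
        ) from None


def read_calibration_table(path) -> list[CalibrationReplicate]:
    frame = _load_csv(path, "calibration")
    out: list[CalibrationReplicate] = []
    seen: set[tuple[str, int]] = set()
    for i, row in frame.iterrows():
        analyte = parse_analyte_id(row["analyte"])
        mass = _cell_float(row["standard_mass_ng"], i, "standard_mass_ng")
        resp = _cell_float(row["response"], i, "response")
        rep = int(_cell_float(row["replicate"], i, "replicate"))
        key = (analyte.label, rep)
        if key in seen:
            raise PeakTableError(f"row {i}: duplicate (analyte, replicate) {key}")
        seen.add(key)
        out.append(CalibrationReplicate(analyte, mass, resp, rep))
    counts: dict[str, int] = {}
    for rec in out:
        counts[rec.analyte.label] = counts.get(rec.analyte.label, 0) + 1
    short = sorted(lab for lab, n in counts.items() if n != 6)
    if short:
        warnings.warn(
            f"{len(short)} standard(s) without sextuplicate injections "
            f"(e.g. {short[:3]})",
            stacklevel=2,
        )
    return out


def read_sample_table(path) -> list[SampleRun]:
    frame = _load_csv(path, "sample")
    runs: dict[str, SampleRun] = {}
    seen: set[tuple[str, str, int]] = set()
    for i, row in frame.iterrows():
        sid = row["sample_id"].strip()
        if not sid:
            raise PeakTableError(f"row {i}: empty sample_id")
        mass = _cell_float(row["sample_mass_g"], i, "sample_mass_g")
        if sid not in runs:
            runs[sid] = SampleRun(sid, row["site"].strip(), row["matrix"].strip(), mass)
        run = runs[sid]
        if (run.site, run.matrix, run.sample_mass_g) != (
            row["site"].strip(),
            row["matrix"].strip(),
            mass,
        ):
            raise PeakTableError(f"row {i}: inconsistent metadata for sample {sid}")
        label = row["analyte"].strip()
        resp = _cell_float(row["response"], i, "response")
        if label in IS_LABELS:
            run.internal_standard_responses.setdefault(label, resp)
            continue
        if label.startswith("SURR-"):
            parse_surrogate_label(label)
            run.surrogate_responses.setdefault(label, resp)
            continue
        analyte = parse_analyte_id(label)
        rrt = _cell_float(row["rrt"], i, "rrt", allow_blank=True)
        analyte = analyte.with_rrt(rrt)
        n_cl = _cell_float(row["n_cl"], i, "n_cl", allow_blank=True)
        if n_cl is not None and int(n_cl) != analyte.n_cl:
            raise PeakTableError(
                f"row {i}: n_cl column {int(n_cl)} disagrees with parsed "
                f"{analyte.n_cl} for {label!r}"
            )
        inj = int(_cell_float(row["injection"], i, "injection"))
        key = (sid, analyte.label, inj)
        if key in seen:
            raise PeakTableError(f"row {i}: duplicate (sample, analyte, injection) {key}")
        seen.add(key)
        run.peaks.append(PeakRecord(analyte, resp, sid, inj))
    return list(runs.values())


def read_blank_table(path) -> pd.DataFrame:
    """Blank masses as a tidy frame: blank_id, analyte, mass_ng."""
    frame = _load_csv(path, "blank")
    records = []
    seen: set[tuple[str, str]] = set()
    for i, row in frame.iterrows():
        bid = row["blank_id"].strip()
        label = parse_analyte_id(row["analyte"]).label
        mass = _cell_float(row["mass_ng"], i, "mass_ng")
        if mass < 0:
            raise PeakTableError(f"row {i}: negative blank mass")
        key = (bid, label)
        if key in seen:
            raise PeakTableError(f"row {i}: duplicate (blank, analyte) {key}")
        seen.add(key)
        records.append({"blank_id": bid, "analyte": label, "mass_ng": mass})
    return pd.DataFrame.from_records(records, columns=_SCHEMAS["blank"])


def read_peak_table(path, schema: str):
    """Schema-dispatching reader (``calibration`` | ``sample`` | ``blank``)."""
    readers = {
        "calibration": read_calibration_table,
        "sample": read_sample_table,
        "blank": read_blank_table,
    }
    if schema not in readers:
        raise PeakTableError(f"unknown schema {schema!r}")
    return readers[schema](path)


def write_calibration_table(records: Sequence[CalibrationReplicate], path) -> None:
    pd.DataFrame(
        [
            {
                "analyte": r.analyte.label,
                "standard_mass_ng": r.standard_mass_ng,
                "response": r.response,
                "replicate": r.replicate_index,
            }
            for r in records
        ],
        columns=_SCHEMAS["calibration"],
    ).to_csv(path, index=False)


def write_sample_table(samples: Sequence[SampleRun], path) -> None:
    rows = []
    for run in samples:
        base = {
            "sample_id": run.sample_id,
            "site": run.site,
            "matrix": run.matrix,
            "sample_mass_g": run.sample_mass_g,
        }
        for label, resp in run.internal_standard_responses.items():
            rows.append(
                {**base, "analyte": label, "n_cl": "", "rrt": "", "response": resp,
                 "injection": 1}
            )
        for label, resp in run.surrogate_responses.items():
            rows.append(
                {**base, "analyte": label, "n_cl": "", "rrt": "", "response": resp,
                 "injection": 1}
            )
        for peak in run.peaks:
            rows.append(
                {
                    **base,
                    "analyte": peak.analyte.label,
                    "n_cl": peak.analyte.n_cl,
                    "rrt": "" if peak.analyte.rrt is None else f"{peak.analyte.rrt:.3f}",
                    "response": peak.response,
                    "injection": peak.injection_index,
                }
            )
    pd.DataFrame(rows, columns=_SCHEMAS["sample"]).to_csv(path, index=False)


def write_blank_table(blanks: pd.DataFrame, path) -> None:
    blanks.to_csv(path, index=False, columns=_SCHEMAS["blank"])
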