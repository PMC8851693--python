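"""Congener profiles and cosine similarity.

A congener profile is the vector of concentration fractions of one sample
over a canonical analyte ordering (homologue, then elution order).  Profiles
are compared by cosine similarity, cos(theta) = a.b / (|a||b|), which for
nonnegative vectors lies in [0, 1]; 1 means identical congener patterns
regardless of the absolute contamination level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peak_tables import AnalyteID, canonical_order, parse_analyte_id
from .quantification import ConcentrationTable

__all__ = [
    "EmptyProfileError",
    "Profile",
    "SimilarityMatrix",
    "build_profile",
    "profiles_from_table",
    "observed_universe",
    "cosine",
    "similarity_matrix",
    "group_similarity",
    "MIN_DETECTED_CONGENERS",
]

logger = logging.getLogger(__name__)

# Samples with fewer detected congeners cannot support a reliable profile and
# are excluded from similarity analysis (with a logged warning).
MIN_DETECTED_CONGENERS = 5


class EmptyProfileError(ValueError):
    """A sample with no quantifiable mass cannot form a profile."""


@dataclass(frozen=True)
class Profile:
    """Fraction vector of one sample over a shared canonical analyte order."""

    sample_id: str
    family: str
    order: tuple[str, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", frac)
        if frac.shape != (len(self.order),):
            raise ValueError("fractions length must equal the analyte order")
        if np.any(frac < 0):
            raise ValueError("negative fraction")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def n_detected(self) -> int:
        return int(np.count_nonzero(self.fractions))


def _order_labels(universe: Iterable, family: str) -> tuple[str, ...]:
    analytes = [
        a if isinstance(a, AnalyteID) else parse_analyte_id(str(a)) for a in universe
    ]
    return tuple(a.label for a in canonical_order(analytes, family))


def build_profile(
    conc_rows: pd.DataFrame, family: str, universe: Sequence
) -> Profile:
    """Profile of one sample aligned to a shared analyte universe.

    ``conc_rows`` holds that sample's concentration rows; analytes of the
    universe missing from the sample contribute zero.  Raises
    :class:`EmptyProfileError` when the sample's total is zero.
    """
    sub = conc_rows[conc_rows["family"] == family]
    sample_ids = sub["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError("build_profile expects rows of exactly one sample")
    order = _order_labels(universe, family)
    conc_map = dict(zip(sub["analyte"], sub["concentration"]))
    vec = np.array([conc_map.get(label, 0.0) for label in order], dtype=float)
    total = vec.sum()
    if total <= 0:
        raise EmptyProfileError(
            f"sample {sample_ids[0]}: no {family} mass above the LOQ"
        )
    return Profile(str(sample_ids[0]), family, order, vec / total)


def observed_universe(table: ConcentrationTable, family: str) -> list[AnalyteID]:
    """Canonically ordered analytes detected (uncensored) in any sample."""
    frame = table.frame
    sub = frame[(frame["family"] == family) & (frame["concentration"] > 0)]
    analytes = {parse_analyte_id(lab) for lab in sub["analyte"].unique()}
    with_rrt = {}
    for _, row in sub.iterrows():
        if not np.isnan(row["rrt"]):
            with_rrt[row["analyte"]] = float(row["rrt"])
    analytes = {a.with_rrt(with_rrt.get(a.label)) for a in analytes}
    return canonical_order(analytes, family)


def profiles_from_table(
    table: ConcentrationTable, family: str, universe: Sequence | None = None
) -> list[Profile]:
    """One profile per sample of a concentration table (shared universe)."""
    frame = table.frame
    if universe is None:
        universe = observed_universe(table, family)
    profiles = []
    for sample_id, rows in frame.groupby("sample_id", sort=True):
        try:
            profiles.append(build_profile(rows, family, universe))
        except EmptyProfileError:
            logger.warning("sample %s: empty %s profile, skipped", sample_id, family)
    return profiles


def cosine(a: Profile, b: Profile) -> float:
    """Cosine similarity of two profiles over the same analyte order."""
    if a.order != b.order:
        raise ValueError("profiles are not aligned to the same universe")
    na, nb = np.linalg.norm(a.fractions), np.linalg.norm(b.fractions)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm profile")
    value = float(np.dot(a.fractions, b.fractions) / (na * nb))
    return float(min(max(value, 0.0), 1.0))


@dataclass(frozen=True)
class SimilarityMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(m, m.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("unit diagonal required")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("cosine entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def value(self, i: str, j: str) -> float:
        return float(self.matrix[self.ids.index(i), self.ids.index(j)])


def similarity_matrix(profiles: Sequence[Profile]) -> SimilarityMatrix:
    ids = tuple(p.sample_id for p in profiles)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    n = len(profiles)
    m = np.eye(n)
    for i, j in combinations(range(n), 2):
        m[i, j] = m[j, i] = cosine(profiles[i], profiles[j])
    return SimilarityMatrix(ids, m)


def _pair_summary(values: list[float]) -> dict:
    if not values:
        return {"median": None, "mean": None, "sd": None, "n_pairs": 0}
    arr = np.asarray(values)
    return {
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n_pairs": int(arr.size),
    }


def group_similarity(
    profiles: Sequence[Profile],
    grouping: Mapping[str, str],
    min_detected: int = MIN_DETECTED_CONGENERS,
) -> dict:
    """Within- vs between-group cosine similarity summaries.

    ``grouping`` maps sample_id to a group (site, Aroclor, ...).  Profiles
    with fewer than ``min_detected`` detected congeners are excluded first
    (too sparse to be reliable).  Summaries cover all unordered pairs with
    the diagonal excluded; a grouping with only singleton groups leaves the
    within-group summary undefined (``n_pairs`` 0) and is flagged.
    """
    kept, excluded = [], []
    for p in profiles:
        if p.n_detected < min_detected:
            excluded.append(p.sample_id)
            logger.warning(
                "profile %s excluded from similarity: only %d detected congener(s)",
                p.sample_id,
                p.n_detected,
            )
        else:
            kept.append(p)
    missing = [p.sample_id for p in kept if p.sample_id not in grouping]
    if missing:
        raise ValueError(f"samples without a group: {missing}")
    groups = {grouping[p.sample_id] for p in kept}
    if len(groups) < 2:
        raise ValueError("need >=2 groups for a within/between comparison")
    sim = similarity_matrix(kept)
    within, between = [], []
    for i, j in combinations(range(len(kept)), 2):
        value = sim.matrix[i, j]
        if grouping[kept[i].sample_id] == grouping[kept[j].sample_id]:
            within.append(value)
        else:
            between.append(value)
    result = {
        "within": _pair_summary(within),
        "between": _pair_summary(between),
        "matrix": sim,
        "excluded": sorted(excluded),
        "singleton_groups_only": not within,
    }
    if not within:
        logger.warning("all groups are singletons; within-group similarity undefined")
    return result
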