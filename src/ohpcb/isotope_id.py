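"""Theoretical chlorine isotope clusters and homologue assignment.

A molecule with ``n`` chlorines shows an M, M+2, ..., M+2n cluster whose
relative abundances follow the binomial expansion of (p + q)^n with
p = abundance of 35Cl and q = abundance of 37Cl.  Because the two isotopes
differ by 2 Da and chlorine dominates the isotopic envelope of (MeO-)PCBs,
comparing an observed cluster against the ten theoretical patterns assigns
the homologue (chlorine count) of a peak without an authentic standard.
C/H/O isotopes are ignored at this fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "CL35_ABUNDANCE",
    "CL37_ABUNDANCE",
    "IsotopePattern",
    "chlorine_isotope_pattern",
    "assign_homologue",
]

CL35_ABUNDANCE = 0.7577
CL37_ABUNDANCE = 0.2423

_MAX_CL = 10


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances of the M, M+2, ..., M+2n peaks (sum to 1)."""

    n_cl: int
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.intensities) != self.n_cl + 1:
            raise ValueError("pattern length must be n_cl + 1")
        if any(v < 0 for v in self.intensities):
            raise ValueError("negative abundance")
        if abs(sum(self.intensities) - 1.0) > 1e-12:
            raise ValueError("abundances must sum to 1")


def chlorine_isotope_pattern(n_cl: int) -> IsotopePattern:
    """Theoretical chlorine cluster for a molecule with ``n_cl`` chlorines.

    intensities[k] = C(n_cl, k) p^(n_cl-k) q^k with p = 0.7577 (35Cl) and
    q = 0.2423 (37Cl), renormalised to sum exactly to 1.
    """
    if not 0 <= n_cl <= _MAX_CL:
        raise ValueError(f"n_cl {n_cl} outside 0-{_MAX_CL}")
    k = np.arange(n_cl + 1)
    probs = binom.pmf(k, n_cl, CL37_ABUNDANCE)
    probs = probs / probs.sum()
    return IsotopePattern(n_cl, tuple(float(v) for v in probs))


def assign_homologue(
    observed, tolerance: float = 0.15
) -> int | None:
    """Assign a chlorine count to an observed, normalised isotope cluster.

    The observed cluster is compared against every theoretical pattern for
    0-10 chlorines; clusters of unequal length are zero-padded so that a
    truncated tail does not preclude a match.  A candidate matches when every
    abundance agrees within ``tolerance`` (relative to the theoretical value,
    with an absolute floor of ``tolerance``/10 for near-zero peaks).  Returns
    the chlorine count when exactly one candidate matches, otherwise ``None``.
    """
    obs = np.asarray(list(observed), dtype=float)
    if obs.size == 0:
        raise ValueError("empty observation")
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if np.any(obs < 0):
        raise ValueError("negative observed abundance")
    width = max(obs.size, _MAX_CL + 1)
    padded_obs = np.zeros(width)
    padded_obs[: obs.size] = obs
    floor = tolerance / 10.0
    matches = []
    for n_cl in range(_MAX_CL + 1):
        theo = np.zeros(width)
        theo[: n_cl + 1] = chlorine_isotope_pattern(n_cl).intensities
        ok = np.abs(padded_obs - theo) <= np.maximum(tolerance * theo, floor)
        if bool(np.all(ok)):
            matches.append(n_cl)
    if len(matches) == 1:
        return matches[0]
    return None
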