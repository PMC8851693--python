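"""Synthetic studies with known ground truth.

Generates complete inputs for the pipeline — calibration tables, method
blanks, and multi-site sample peak tables — by *inverting* the
quantification model: a true concentration is turned into a peak response
via the true RRF, the internal-standard response, and multiplicative
lognormal noise, so that running the pipeline on the generated tables should
recover the retained ground truth.

The default study emulates the magnitudes of a three-site sediment survey:

* a congener universe of 275 OH-PCB peaks (70 with authentic standards,
  mirroring a typical MeO-PCB standard set of 9 mono- through 1
  nona-chlorinated congeners) and 174 PCB peaks (all with standards);
* an "NBH-like" site (5 samples, total OH-PCBs GM 12 ug/g, dominated by
  4-OH-PCB52 at 18% and 4'-OH-PCB18 at 12% of the total), an "AWL-like"
  site (5 samples, GM 0.38 ug/g, dominated by 3@1.482 and 2@1.232) and an
  "IHSC-like" site (2 samples, GM 0.11 ug/g, dominated by 3@1.482 and
  4-OH-PCB2);
* per-homologue true RRFs on a ln-linear curve with per-congener scatter,
  surrogate recoveries near 100%, and low-level blank contamination sized so
  that censoring bites at the low-concentration sites.

Site profile vectors are built from a fixed per-site stream (independent of
the study seed), so a site's "true" fingerprint is a property of the preset;
the study seed drives only the random draws (totals, noise, blanks).  All
randomness flows from the single study seed through named substreams, so
adding samples never perturbs the calibration or blank draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .peak_tables import (
    AnalyteID,
    CalibrationReplicate,
    PeakRecord,
    SampleRun,
    canonical_order,
    parse_analyte_id,
    surrogate_label,
    write_blank_table,
    write_calibration_table,
    write_sample_table,
    IS_LABELS,
)

__all__ = [
    "SiteSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "build_oh_universe",
    "build_pcb_universe",
    "generate_study",
    "write_study",
    "default_config",
    "nbh_like_preset",
    "awl_like_preset",
    "ihsc_like_preset",
    "OH_SURROGATE_NCLS",
    "PCB_SURROGATE_NCLS",
]

# Homologue composition of the OH-PCB peak universe (chlorine counts 1-10),
# totalling 275 peaks, and of the authentic-standard subset (70 congeners:
# 9 mono-, 5 di-, 6 tri-, 12 tetra-, 13 penta-, 8 hexa-, 10 hepta-, 6 octa-,
# 1 nona-chlorinated).
OH_PEAKS_PER_HOMOLOGUE = (10, 25, 40, 55, 55, 40, 25, 15, 8, 2)
OH_KNOWN_PER_HOMOLOGUE = (9, 5, 6, 12, 13, 8, 10, 6, 1, 0)
# PCB peak universe: 174 peaks over homologues 1-10.
PCB_PEAKS_PER_HOMOLOGUE = (3, 10, 20, 35, 42, 30, 20, 10, 3, 1)

_BZ_RANGES = {
    1: (1, 3),
    2: (4, 15),
    3: (16, 39),
    4: (40, 81),
    5: (82, 127),
    6: (128, 169),
    7: (170, 193),
    8: (194, 205),
    9: (206, 208),
    10: (209, 209),
}

OH_SURROGATE_NCLS = (2, 3, 4, 5, 6, 7)
PCB_SURROGATE_NCLS = tuple(range(1, 11))

_RRT_BASE, _RRT_PER_CL, _RRT_STEP = 0.60, 0.09, 0.0045
# Named peaks pinned to their published retention identities.
_SPECIAL_UNKNOWN_RRT = {2: 1.232, 3: 1.482}
_SPECIAL_KNOWN_RRT = {"4-OH-PCB52": 1.524}


def _stream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named substream: independent of draws made on sibling streams."""
    return np.random.default_rng([seed, zlib.crc32(name.encode()) % 2**31, *extra])


def _known_oh_labels(n_cl: int, count: int) -> list[str]:
    lo, hi = _BZ_RANGES[n_cl]
    if count == 0:
        return []
    labels: list[str] = []
    for pos in ("4", "3'", "3", "2'", "2"):
        for num in range(lo, hi + 1):
            labels.append(f"{pos}-OH-PCB{num}")
            if len(labels) == count:
                break
        if len(labels) == count:
            break
    if len(labels) < count:
        raise ValueError(f"homologue {n_cl}: cannot place {count} known OH-PCBs")
    # Pin the named predominant congeners used by the site presets.
    if n_cl == 3 and "4'-OH-PCB18" not in labels:
        labels[-1] = "4'-OH-PCB18"
    if n_cl == 4 and "4-OH-PCB52" not in labels:
        labels[-1] = "4-OH-PCB52"
    return labels


def build_oh_universe() -> list[AnalyteID]:
    """The OH-PCB peak universe: 275 analytes with deterministic RRTs."""
    analytes: list[AnalyteID] = []
    for h_idx, total in enumerate(OH_PEAKS_PER_HOMOLOGUE):
        n_cl = h_idx + 1
        n_known = OH_KNOWN_PER_HOMOLOGUE[h_idx]
        rrts = [
            round(_RRT_BASE + _RRT_PER_CL * n_cl + _RRT_STEP * j, 3)
            for j in range(total)
        ]
        knowns = _known_oh_labels(n_cl, n_known)
        for j, label in enumerate(knowns):
            rrt = _SPECIAL_KNOWN_RRT.get(label, rrts[j])
            analytes.append(parse_analyte_id(label).with_rrt(rrt))
        unknown_rrts = rrts[n_known:]
        if n_cl in _SPECIAL_UNKNOWN_RRT and unknown_rrts:
            unknown_rrts[-1] = _SPECIAL_UNKNOWN_RRT[n_cl]
        for rrt in unknown_rrts:
            analytes.append(parse_analyte_id(f"{n_cl}@{rrt:.3f}"))
    return canonical_order(analytes, "OHPCB")


def build_pcb_universe() -> list[AnalyteID]:
    """The PCB peak universe: 174 congeners, all with standards.

    PCB204 is skipped (it serves as an internal standard).
    """
    analytes: list[AnalyteID] = []
    for h_idx, count in enumerate(PCB_PEAKS_PER_HOMOLOGUE):
        n_cl = h_idx + 1
        lo, hi = _BZ_RANGES[n_cl]
        numbers = [n for n in range(lo, hi + 1) if n != 204][:count]
        if len(numbers) < count:
            raise ValueError(f"homologue {n_cl}: cannot place {count} PCBs")
        analytes.extend(parse_analyte_id(f"PCB{n}") for n in numbers)
    return canonical_order(analytes, "PCB")


@dataclass
class SiteSpec:
    """One site of a synthetic study: sample count, totals, and fingerprint."""

    name: str
    n_samples: int
    oh_total_gm: float  # ng/g (sediment) or ng/sample (aroclor)
    oh_total_gsd: float
    pcb_total_gm: float
    pcb_total_gsd: float
    oh_profile: np.ndarray  # fractions over the OH universe (canonical order)
    pcb_profile: np.ndarray
    oh_dominants: dict[str, float] = field(default_factory=dict)
    matrix: str = "sediment"
    sample_mass_g: float = 1.0


@dataclass
class SyntheticConfig:
    """Full description of a synthetic study; the ground truth follows from it."""

    sites: list[SiteSpec]
    oh_universe: list[AnalyteID]
    pcb_universe: list[AnalyteID]
    seed: int = 1
    # ln(RRF) = intercept + slope * n_cl + N(0, sigma) per congener
    rrf_intercept: float = 0.5
    rrf_slope: float = -0.12
    rrf_sigma: float = 0.10
    replicate_sigma: float = 0.05  # lognormal sigma of injection noise
    profile_jitter_sigma: float = 0.4  # per-sample congener-fraction jitter
    recovery_gm: float = 1.0
    recovery_gsd: float = 1.30
    blank_gm_ng: float = 0.025  # per-analyte blank contamination level
    blank_gsd: float = 1.9
    blank_cv: float = 0.5  # within-analyte blank variability
    n_blanks: int = 6
    n_injections: int = 2
    n_cal_replicates: int = 6
    standard_mass_ng: float = 25.0
    is_mass_ng: float = 25.0
    is_response: float = 1.0e6
    spiked_surrogate_mass_ng: float = 25.0

    def __post_init__(self) -> None:
        for spec in self.sites:
            for vec, universe in (
                (spec.oh_profile, self.oh_universe),
                (spec.pcb_profile, self.pcb_universe),
            ):
                if len(vec) != len(universe):
                    raise ValueError(
                        f"site {spec.name}: profile length does not match universe"
                    )
                if abs(float(np.sum(vec)) - 1.0) > 1e-9 or np.any(np.asarray(vec) < 0):
                    raise ValueError(f"site {spec.name}: profile is not a fraction vector")
        for name, value in (
            ("rrf_sigma", self.rrf_sigma),
            ("replicate_sigma", self.replicate_sigma),
            ("profile_jitter_sigma", self.profile_jitter_sigma),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.recovery_gsd < 1 or self.blank_gsd < 1:
            raise ValueError("GSD parameters must be >= 1")

    @property
    def known_oh_labels(self) -> frozenset[str]:
        return frozenset(
            a.label for a in self.oh_universe if a.kind == "known-OHPCB"
        )


@dataclass
class SyntheticStudy:
    """Generated tables plus the retained ground truth."""

    config: SyntheticConfig
    calibration: list[CalibrationReplicate]
    calibration_is: dict[str, list[float]]  # IS label -> replicate responses
    blanks: dict[str, pd.DataFrame]  # matrix -> tidy blank table
    samples: list[SampleRun]
    truth: pd.DataFrame  # sample_id, site, analyte, family, n_cl, concentration
    truth_totals: pd.DataFrame  # sample_id, site, family, total
    truth_profiles: dict[tuple[str, str], np.ndarray]
    truth_recoveries: dict[tuple[str, str], float]
    true_rrfs: dict[str, float]

    def profile_order(self, family: str) -> tuple[str, ...]:
        universe = (
            self.config.oh_universe if family == "OHPCB" else self.config.pcb_universe
        )
        return tuple(a.label for a in universe)

    @property
    def is_responses(self) -> dict[str, float]:
        """Mean internal-standard response per IS label in the calibration runs."""
        return {
            label: float(np.mean(vals)) for label, vals in self.calibration_is.items()
        }


def _site_fingerprint(
    universe: Sequence[AnalyteID],
    dominants: dict[str, float],
    n_support: int,
    stream_name: str,
    weight_sigma: float = 1.8,
) -> np.ndarray:
    """Sparse heavy-tailed fraction vector with pinned dominant peaks.

    Drawn from a stream keyed by the site name only, so a preset's
    fingerprint is stable across study seeds.
    """
    rng = _stream(0, stream_name)
    labels = [a.label for a in universe]
    index = {lab: i for i, lab in enumerate(labels)}
    for lab in dominants:
        if lab not in index:
            raise ValueError(f"dominant peak {lab!r} not in universe")
    vec = np.zeros(len(labels))
    dom_total = float(sum(dominants.values()))
    if dom_total >= 1.0:
        raise ValueError("dominant fractions must sum to < 1")
    candidates = [i for i, lab in enumerate(labels) if lab not in dominants]
    support = rng.choice(candidates, size=min(n_support, len(candidates)), replace=False)
    weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=support.size)
    vec[support] = weights / weights.sum() * (1.0 - dom_total)
    for lab, frac in dominants.items():
        vec[index[lab]] = frac
    return vec


def _make_site(
    name: str,
    n_samples: int,
    oh_total_gm: float,
    oh_total_gsd: float,
    pcb_total_gm: float,
    pcb_total_gsd: float,
    oh_dominants: dict[str, float],
    pcb_dominants: dict[str, float],
    oh_universe: Sequence[AnalyteID],
    pcb_universe: Sequence[AnalyteID],
    matrix: str = "sediment",
) -> SiteSpec:
    return SiteSpec(
        name=name,
        n_samples=n_samples,
        oh_total_gm=oh_total_gm,
        oh_total_gsd=oh_total_gsd,
        pcb_total_gm=pcb_total_gm,
        pcb_total_gsd=pcb_total_gsd,
        oh_profile=_site_fingerprint(
            oh_universe, oh_dominants, n_support=78, stream_name=f"profile-oh-{name}"
        ),
        pcb_profile=_site_fingerprint(
            pcb_universe, pcb_dominants, n_support=100, stream_name=f"profile-pcb-{name}"
        ),
        oh_dominants=dict(oh_dominants),
        matrix=matrix,
    )


def _nbh_site(oh_u, pcb_u) -> SiteSpec:
    # GM total OH-PCBs 12 ug/g DW (range ~9.9-18), PCBs 1500 ug/g DW.
    return _make_site(
        "NBH", 5, 12_000.0, 1.25, 1_500_000.0, 2.3,
        {"4-OH-PCB52": 0.18, "4'-OH-PCB18": 0.12},
        {"PCB52": 0.10, "PCB18": 0.06},
        oh_u, pcb_u,
    )


def _awl_site(oh_u, pcb_u) -> SiteSpec:
    # GM total OH-PCBs 0.38 ug/g DW (range ~0.039-2.6), PCBs 150 ug/g DW.
    return _make_site(
        "AWL", 5, 380.0, 3.5, 150_000.0, 5.0,
        {"3@1.482": 0.18, "2@1.232": 0.16},
        {"PCB28": 0.08, "PCB31": 0.06},
        oh_u, pcb_u,
    )


def _ihsc_site(oh_u, pcb_u) -> SiteSpec:
    # Two samples, total OH-PCBs ~0.058 and 0.21 ug/g DW (GM ~0.11 ug/g).
    return _make_site(
        "IHSC", 2, 110.0, 2.5, 38_000.0, 2.5,
        {"3@1.482": 0.26, "4-OH-PCB2": 0.23},
        {"PCB18": 0.07, "PCB28": 0.06},
        oh_u, pcb_u,
    )


def default_config(seed: int = 1) -> SyntheticConfig:
    """The default three-site sediment study (5 + 5 + 2 samples)."""
    oh_u, pcb_u = build_oh_universe(), build_pcb_universe()
    return SyntheticConfig(
        sites=[_nbh_site(oh_u, pcb_u), _awl_site(oh_u, pcb_u), _ihsc_site(oh_u, pcb_u)],
        oh_universe=oh_u,
        pcb_universe=pcb_u,
        seed=seed,
    )


def nbh_like_preset(seed: int = 1) -> SyntheticConfig:
    oh_u, pcb_u = build_oh_universe(), build_pcb_universe()
    return SyntheticConfig(
        sites=[_nbh_site(oh_u, pcb_u)], oh_universe=oh_u, pcb_universe=pcb_u, seed=seed
    )


def awl_like_preset(seed: int = 1) -> SyntheticConfig:
    oh_u, pcb_u = build_oh_universe(), build_pcb_universe()
    return SyntheticConfig(
        sites=[_awl_site(oh_u, pcb_u)], oh_universe=oh_u, pcb_universe=pcb_u, seed=seed
    )


def ihsc_like_preset(seed: int = 1) -> SyntheticConfig:
    oh_u, pcb_u = build_oh_universe(), build_pcb_universe()
    return SyntheticConfig(
        sites=[_ihsc_site(oh_u, pcb_u)], oh_universe=oh_u, pcb_universe=pcb_u, seed=seed
    )


def _lognormal(rng: np.random.Generator, gm: float, gsd: float, size=None):
    return gm * np.exp(rng.normal(0.0, np.log(gsd) if gsd > 1 else 0.0, size=size))


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full synthetic study (calibration, blanks, samples, truth)."""
    seed = config.seed
    oh_labels = [a.label for a in config.oh_universe]
    pcb_labels = [a.label for a in config.pcb_universe]
    all_analytes = list(config.oh_universe) + list(config.pcb_universe)

    # --- true RRFs: ln-linear in chlorine count with per-congener scatter ---
    rng_rrf = _stream(seed, "rrf")
    eps = rng_rrf.normal(0.0, config.rrf_sigma, size=len(all_analytes))
    true_rrfs = {
        a.label: float(
            np.exp(config.rrf_intercept + config.rrf_slope * a.n_cl + e)
        )
        for a, e in zip(all_analytes, eps)
    }

    # --- calibration: all PCBs plus the known OH-PCBs, in sextuplicate ---
    rng_cal = _stream(seed, "calibration")
    standards = [a for a in config.pcb_universe] + [
        a for a in config.oh_universe if a.kind == "known-OHPCB"
    ]
    calibration: list[CalibrationReplicate] = []
    for analyte in standards:
        expected = (
            true_rrfs[analyte.label]
            * (config.standard_mass_ng / config.is_mass_ng)
            * config.is_response
        )
        noise = np.exp(
            rng_cal.normal(0.0, config.replicate_sigma, size=config.n_cal_replicates)
        )
        for r in range(config.n_cal_replicates):
            calibration.append(
                CalibrationReplicate(
                    analyte, config.standard_mass_ng, expected * noise[r], r + 1
                )
            )
    calibration_is = {
        label: [
            float(config.is_response * v)
            for v in np.exp(
                rng_cal.normal(0.0, config.replicate_sigma, config.n_cal_replicates)
            )
        ]
        for label in IS_LABELS
    }

    # --- method blanks (one table per matrix present in the study) ---
    rng_blank = _stream(seed, "blanks")
    matrices = sorted({s.matrix for s in config.sites})
    blank_levels = _lognormal(
        rng_blank, config.blank_gm_ng, config.blank_gsd, size=len(all_analytes)
    )
    blanks: dict[str, pd.DataFrame] = {}
    for matrix in matrices:
        rows = []
        for b in range(config.n_blanks):
            draws = rng_blank.normal(blank_levels, config.blank_cv * blank_levels)
            draws = np.maximum(draws, 0.0)
            for analyte, mass in zip(all_analytes, draws):
                rows.append(
                    {
                        "blank_id": f"{matrix}-blank-{b + 1}",
                        "analyte": analyte.label,
                        "mass_ng": float(mass),
                    }
                )
        blanks[matrix] = pd.DataFrame(rows, columns=["blank_id", "analyte", "mass_ng"])

    # --- samples ---
    samples: list[SampleRun] = []
    truth_rows = []
    truth_profiles: dict[tuple[str, str], np.ndarray] = {}
    truth_recoveries: dict[tuple[str, str], float] = {}
    for s_idx, site in enumerate(config.sites):
        for k in range(site.n_samples):
            rng = _stream(seed, "samples", s_idx, k)
            sample_id = f"{site.name}-{k + 1:02d}"
            run = SampleRun(
                sample_id=sample_id,
                site=site.name,
                matrix=site.matrix,
                sample_mass_g=site.sample_mass_g,
                spiked_surrogate_mass_ng=config.spiked_surrogate_mass_ng,
                internal_standard_responses={
                    label: config.is_response for label in IS_LABELS
                },
            )
            recoveries = {
                "OHPCB": float(_lognormal(rng, config.recovery_gm, config.recovery_gsd)),
                "PCB": float(_lognormal(rng, config.recovery_gm, config.recovery_gsd)),
            }
            truth_recoveries[(sample_id, "OHPCB")] = recoveries["OHPCB"]
            truth_recoveries[(sample_id, "PCB")] = recoveries["PCB"]
            for family, universe, labels, profile, gm, gsd in (
                ("OHPCB", config.oh_universe, oh_labels, site.oh_profile,
                 site.oh_total_gm, site.oh_total_gsd),
                ("PCB", config.pcb_universe, pcb_labels, site.pcb_profile,
                 site.pcb_total_gm, site.pcb_total_gsd),
            ):
                total = float(_lognormal(rng, gm, gsd))
                jitter = np.exp(
                    rng.normal(0.0, config.profile_jitter_sigma, size=len(labels))
                )
                conc = total * np.asarray(profile) * jitter
                conc[np.asarray(profile) == 0.0] = 0.0
                truth_profiles[(sample_id, family)] = (
                    conc / conc.sum() if conc.sum() > 0 else conc.copy()
                )
                r_fam = recoveries[family]
                for analyte, c in zip(universe, conc):
                    truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "site": site.name,
                            "analyte": analyte.label,
                            "family": family,
                            "n_cl": analyte.n_cl,
                            "concentration": float(c),
                        }
                    )
                    if c <= 0:
                        continue
                    mass = c * site.sample_mass_g if site.matrix == "sediment" else c
                    expected = (
                        true_rrfs[analyte.label]
                        * (mass * r_fam / config.is_mass_ng)
                        * config.is_response
                    )
                    for inj in range(1, config.n_injections + 1):
                        noise = float(
                            np.exp(rng.normal(0.0, config.replicate_sigma))
                        )
                        run.peaks.append(
                            PeakRecord(analyte, expected * noise, sample_id, inj)
                        )
                # surrogates: unit RRF, same extraction loss as the analytes
                ncls = OH_SURROGATE_NCLS if family == "OHPCB" else PCB_SURROGATE_NCLS
                for n_cl in ncls:
                    expected = (
                        (config.spiked_surrogate_mass_ng * r_fam / config.is_mass_ng)
                        * config.is_response
                    )
                    noise = np.exp(
                        rng.normal(0.0, config.replicate_sigma, size=config.n_injections)
                    )
                    run.surrogate_responses[surrogate_label(family, n_cl)] = float(
                        expected * noise.mean()
                    )
            samples.append(run)

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "site", "analyte", "family", "n_cl", "concentration"],
    )
    truth_totals = (
        truth.groupby(["sample_id", "site", "family"], as_index=False)["concentration"]
        .sum()
        .rename(columns={"concentration": "total"})
    )
    return SyntheticStudy(
        config=config,
        calibration=calibration,
        calibration_is=calibration_is,
        blanks=blanks,
        samples=samples,
        truth=truth,
        truth_totals=truth_totals,
        truth_profiles=truth_profiles,
        truth_recoveries=truth_recoveries,
        true_rrfs=true_rrfs,
    )


def write_study(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write a study to CSV files; returns the artifact paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    cal_path = os.path.join(out_dir, "calibration.csv")
    write_calibration_table(study.calibration, cal_path)
    # Append the internal-standard rows of the calibration runs.
    is_rows = pd.DataFrame(
        [
            {
                "analyte": label,
                "standard_mass_ng": study.config.is_mass_ng,
                "response": resp,
                "replicate": r + 1,
            }
            for label, values in sorted(study.calibration_is.items())
            for r, resp in enumerate(values)
        ]
    )
    is_rows.to_csv(cal_path, mode="a", header=False, index=False)
    paths["calibration"] = cal_path
    samp_path = os.path.join(out_dir, "samples.csv")
    write_sample_table(study.samples, samp_path)
    paths["samples"] = samp_path
    for matrix, frame in study.blanks.items():
        blank_path = os.path.join(out_dir, f"blanks_{matrix}.csv")
        write_blank_table(frame, blank_path)
        paths[f"blanks_{matrix}"] = blank_path
    truth_path = os.path.join(out_dir, "truth.csv")
    study.truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths
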