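"""End-to-end orchestration: calibrate, quantify, profile, compare, report.

``run`` reads the three input tables (calibration, samples, method blanks),
fits the response model, derives LOQs and recoveries, writes a censored
concentration table, congener profiles and their cosine-similarity matrix,
and a machine-readable ``report.json`` with site summaries and the
nonparametric tests.  Identical inputs, configuration and seed give
byte-identical outputs.

Every decision the method leaves open is a configuration key with its
documented default (censoring boundary, bootstrap size/seed, exact-test size
limits, sparse-profile exclusion threshold), so alternates are testable.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import peak_tables, profiles_similarity, quantification, site_stats
from .quantification import ConcentrationTable
from .response_model import ResponseModel, compute_rrfs, fit_response_model

__all__ = [
    "PipelineConfig",
    "StageError",
    "run",
    "calibrate",
    "analyze_study",
    "build_report",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    calibration_csv: str = "calibration.csv"
    samples_csv: str = "samples.csv"
    blanks_csv: dict[str, str] = field(default_factory=dict)  # matrix -> path
    out_dir: str = "out"
    alpha: float = 0.05
    bootstrap_B: int = 2000
    seed: int = 0
    censor_boundary: str = "below"  # strictly-below-LOQ censoring
    exact_mw_limit: int = site_stats.EXACT_MW_LIMIT
    exact_spearman_limit: int = site_stats.EXACT_SPEARMAN_LIMIT
    min_detected: int = profiles_similarity.MIN_DETECTED_CONGENERS
    min_standards_gm: int = 3
    blank_sample_mass_g: float = 1.0
    is_mass_ng: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")
        if self.censor_boundary not in ("below", "at-or-below"):
            raise ValueError("censor_boundary must be 'below' or 'at-or-below'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def for_directory(cls, in_dir, out_dir, **overrides) -> "PipelineConfig":
        """Config from the standard file layout of a study directory."""
        blanks = {}
        for path in sorted(glob.glob(os.path.join(in_dir, "blanks_*.csv"))):
            matrix = os.path.basename(path)[len("blanks_") : -len(".csv")]
            blanks[matrix] = path
        return cls(
            calibration_csv=os.path.join(in_dir, "calibration.csv"),
            samples_csv=os.path.join(in_dir, "samples.csv"),
            blanks_csv=blanks,
            out_dir=str(out_dir),
            **overrides,
        )


def calibrate(
    records,
    is_responses: dict[str, float],
    is_mass_ng: float = 25.0,
    B: int = 2000,
    seed: int = 0,
    min_standards_gm: int = 3,
) -> ResponseModel:
    """Fit the response model from calibration records.

    The homologue model (used to predict RRFs of OH-PCBs without standards)
    is fitted on the MeO-PCB standards only; PCB standards contribute their
    own per-congener RRFs but are kept out of the OH-PCB homologue means.
    """
    oh = [r for r in records if r.analyte.family == "OHPCB"]
    pcb = [r for r in records if r.analyte.family == "PCB"]
    if not oh and not pcb:
        raise ValueError("no calibration records")
    base = oh if oh else pcb
    is_label = peak_tables.IS_FOR_FAMILY["OHPCB" if oh else "PCB"]
    if is_label not in is_responses:
        raise ValueError(f"calibration lacks internal standard {is_label}")
    rrfs = compute_rrfs(base, is_responses[is_label], is_mass_ng)
    model = fit_response_model(rrfs, B=B, seed=seed, min_standards_gm=min_standards_gm)
    if oh and pcb:
        pcb_is = peak_tables.IS_FOR_FAMILY["PCB"]
        if pcb_is not in is_responses:
            raise ValueError(f"calibration lacks internal standard {pcb_is}")
        pcb_rrfs = compute_rrfs(pcb, is_responses[pcb_is], is_mass_ng)
        by_label: dict[str, list[float]] = {}
        for obs in pcb_rrfs:
            by_label.setdefault(obs.analyte.label, []).append(obs.rrf)
        for label, vals in by_label.items():
            model.per_analyte[label] = float(np.exp(np.mean(np.log(vals))))
    return model


def analyze_study(
    study,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    censor_boundary: str = "below",
) -> tuple[ResponseModel, ConcentrationTable]:
    """Run calibration, LOQ derivation and quantification on an in-memory study.

    Convenience wrapper around the same stages ``run`` executes from CSV
    files; returns the fitted response model and the combined concentration
    table.
    """
    model = calibrate(
        study.calibration,
        study.is_responses,
        is_mass_ng=study.config.is_mass_ng,
        B=B,
        seed=seed,
    )
    loq_tables = {
        matrix: quantification.build_loq_table(frame, matrix, alpha=alpha)
        for matrix, frame in study.blanks.items()
    }
    frames = [
        quantification.concentrations(
            sample,
            model,
            loq_tables[sample.matrix],
            None,
            study.config.is_mass_ng,
            censor_boundary,
        ).frame
        for sample in study.samples
    ]
    return model, ConcentrationTable(pd.concat(frames, ignore_index=True))


def _read_calibration_with_is(path):
    """Calibration records plus the internal-standard responses.

    Rows whose analyte is an internal-standard label are averaged into a
    response map instead of becoming standards.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    is_rows = frame[frame["analyte"].isin(peak_tables.IS_LABELS)]
    std_rows = frame[~frame["analyte"].isin(peak_tables.IS_LABELS)]
    import io

    buf = io.StringIO()
    std_rows.to_csv(buf, index=False)
    buf.seek(0)
    records = peak_tables.read_calibration_table(buf)
    is_responses = {
        label: float(rows["response"].astype(float).mean())
        for label, rows in is_rows.groupby("analyte")
    }
    return records, is_responses


def _summary_dict(values) -> dict:
    return asdict(site_stats.summarize(values))


def build_report(table: ConcentrationTable, similarity: dict | None, config) -> dict:
    """Site summaries, concentration ratios and hypothesis tests as a dict."""
    frame = table.frame
    totals = (
        frame.groupby(["sample_id", "site", "matrix", "family"])["concentration"]
        .sum()
        .reset_index()
    )
    wide = totals.pivot_table(
        index=["sample_id", "site", "matrix"], columns="family", values="concentration"
    ).reset_index()
    for fam in ("OHPCB", "PCB"):
        if fam not in wide.columns:
            wide[fam] = 0.0

    report: dict = {"alpha": config.alpha, "sites": {}, "tests": {}}
    ratios = {}
    for _, row in wide.iterrows():
        if row["PCB"] > 0:
            ratios[row["sample_id"]] = site_stats.ratio_ohpcb_pcb(
                row["OHPCB"], row["PCB"]
            )
    positive_ratios = [v for v in ratios.values() if v > 0]
    report["ratio_ohpcb_pcb_pct"] = {
        "per_sample": {k: ratios[k] for k in sorted(ratios)},
        "gm": site_stats.gm_gsd(positive_ratios)["gm"] if len(positive_ratios) else None,
    }

    for site, rows in wide.groupby("site"):
        entry = {
            "n_samples": int(len(rows)),
            "matrix": rows["matrix"].iloc[0],
            "oh_total": _summary_dict(rows["OHPCB"]),
            "pcb_total": _summary_dict(rows["PCB"]),
        }
        site_ratios = [ratios[s] for s in rows["sample_id"] if s in ratios]
        if site_ratios:
            entry["ratio_pct"] = _summary_dict(site_ratios)
        report["sites"][site] = entry

    # Pairwise site comparisons of total concentrations.
    sites = sorted(wide["site"].unique())
    for fam, key in (("OHPCB", "oh_total_site_comparisons"),
                     ("PCB", "pcb_total_site_comparisons")):
        comparisons = {}
        for i, a in enumerate(sites):
            for b in sites[i + 1 :]:
                xa = wide.loc[wide["site"] == a, fam].to_numpy()
                xb = wide.loc[wide["site"] == b, fam].to_numpy()
                if xa.size < 2 or xb.size < 2:
                    continue
                res = site_stats.mann_whitney_exact(
                    xa, xb, exact_limit=config.exact_mw_limit
                )
                comparisons[f"{a}_vs_{b}"] = asdict(res)
        if comparisons:
            report["tests"][key] = comparisons

    # Within-site OH-PCB vs PCB relationships (needs n >= 3 positive pairs).
    correlations = {}
    for site, rows in wide.groupby("site"):
        mask = (rows["OHPCB"] > 0) & (rows["PCB"] > 0)
        oh = rows.loc[mask, "OHPCB"].to_numpy()
        pcb = rows.loc[mask, "PCB"].to_numpy()
        if oh.size < 3:
            continue
        entry = {}
        try:
            entry["spearman"] = asdict(
                site_stats.spearman_exact(
                    pcb, oh, exact_limit=config.exact_spearman_limit
                )
            )
        except ValueError as exc:
            entry["spearman"] = {"error": str(exc)}
        entry["pearson_log"] = asdict(site_stats.pearson_log(pcb, oh))
        fit = site_stats.loglog_fit(pcb, oh)
        entry["loglog"] = {**asdict(fit), "fold_change_2x": fit.fold_change(2.0)}
        correlations[site] = entry
    if correlations:
        report["tests"]["oh_vs_pcb_by_site"] = correlations

    if similarity is not None:
        report["similarity"] = {
            "family": "OHPCB",
            "within": similarity["within"],
            "between": similarity["between"],
            "excluded": similarity["excluded"],
            "singleton_groups_only": similarity["singleton_groups_only"],
        }
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages; returns the paths of the written artifacts."""
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ohpcb")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, log_path)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, log_path: str) -> dict[str, str]:
    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    records, is_responses = stage(
        "read-calibration", _read_calibration_with_is, config.calibration_csv
    )
    samples = stage("read-samples", peak_tables.read_sample_table, config.samples_csv)
    if not samples:
        raise StageError("read-samples", "no samples in input")
    for sample in samples:
        stage("read-samples", sample.validate)
    blanks = {
        matrix: stage("read-blanks", peak_tables.read_blank_table, path)
        for matrix, path in config.blanks_csv.items()
    }

    model = stage(
        "calibrate",
        calibrate,
        records,
        is_responses,
        config.is_mass_ng,
        config.bootstrap_B,
        config.seed,
        config.min_standards_gm,
    )
    loq_tables = {
        matrix: stage(
            "loq",
            quantification.build_loq_table,
            frame,
            matrix,
            config.alpha,
            config.blank_sample_mass_g,
        )
        for matrix, frame in blanks.items()
    }

    frames = []
    for sample in samples:
        if sample.matrix not in loq_tables:
            raise StageError(
                "quantify",
                f"sample {sample.sample_id}: no blank table for matrix "
                f"{sample.matrix!r}",
            )
        table = stage(
            "quantify",
            quantification.concentrations,
            sample,
            model,
            loq_tables[sample.matrix],
            None,
            config.is_mass_ng,
            config.censor_boundary,
        )
        frames.append(table.frame)
    conc = ConcentrationTable(pd.concat(frames, ignore_index=True))

    oh_profiles = stage(
        "profile", profiles_similarity.profiles_from_table, conc, "OHPCB"
    )
    pcb_profiles = stage(
        "profile", profiles_similarity.profiles_from_table, conc, "PCB"
    )

    grouping = {s.sample_id: s.site for s in samples}
    similarity = None
    sim_matrix = None
    if len({s.site for s in samples}) >= 2:
        similarity = stage(
            "similarity",
            profiles_similarity.group_similarity,
            oh_profiles,
            grouping,
            config.min_detected,
        )
        sim_matrix = similarity["matrix"]
    elif len(oh_profiles) >= 2:
        sim_matrix = stage(
            "similarity", profiles_similarity.similarity_matrix, oh_profiles
        )

    report = stage("stats", build_report, conc, similarity, config)

    paths = {"log": log_path}
    conc_path = os.path.join(config.out_dir, "concentrations.csv")
    conc.to_csv(conc_path)
    paths["concentrations"] = conc_path

    profile_rows = []
    for profile in oh_profiles + pcb_profiles:
        for label, frac in zip(profile.order, profile.fractions):
            profile_rows.append(
                {
                    "sample_id": profile.sample_id,
                    "family": profile.family,
                    "analyte": label,
                    "fraction": frac,
                }
            )
    prof_path = os.path.join(config.out_dir, "profiles.csv")
    pd.DataFrame(
        profile_rows, columns=["sample_id", "family", "analyte", "fraction"]
    ).to_csv(prof_path, index=False)
    paths["profiles"] = prof_path

    if sim_matrix is not None:
        sim_path = os.path.join(config.out_dir, "similarity.csv")
        sim_matrix.to_frame().to_csv(sim_path, index_label="sample_id")
        paths["similarity"] = sim_path

    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    paths["report"] = report_path
    logger.info("pipeline complete: %s", sorted(paths))
    return paths
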