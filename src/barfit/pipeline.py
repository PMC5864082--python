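"""Pipeline orchestration: one config, deterministic artifact tree, report.

Runs catalog → (simulate | count) → per-condition contrasts →
haplo-proficiency/insufficiency calls → co-fitness clustering and
enrichment → colony screen, writing every artifact as TSV/JSON under the
output directory with a header naming the config hash.  All randomness
flows from one master seed through named substreams, so reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from barfit import __version__
from barfit.catalog import (
    CONDITIONS,
    load_catalog,
    load_sample_sheet,
    write_catalog,
    write_sample_sheet,
)
from barfit.cofitness import (
    COMPARISONS,
    build_profiles,
    enrichment,
    glm_select,
    pam_cluster,
    split_by_direction,
)
from barfit.errors import ParameterError, StageError
from barfit.fitness import classify, intersect_calls, run_contrast
from barfit.screen import fit_mixture, normalize_plates, read_plates_tsv, score_strains, write_plates_tsv
from barfit.sim import (
    SimConfig,
    emit_reads,
    make_catalog,
    make_sample_sheet,
    simulate_plates,
    simulate_pool,
    write_fastq,
)
from barfit.tagcount import CountMatrix, count_run

log = logging.getLogger("barfit.pipeline")

DEFAULT_SIM_CONDITIONS = ("Clim30", "Clim36", "Nlim30", "Nlim36")


@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from YAML)."""

    seed: int = 0
    alpha_sig: float = 0.05
    fold: float = 1.5
    upset_theta: str = "log2_1.5"  # or "1.5"
    k: int | None = None  # PAM cluster count; None = silhouette auto-k
    conditions: tuple[str, ...] = DEFAULT_SIM_CONDITIONS
    # simulation block (used when no fastq paths are given)
    simulate: dict = field(default_factory=dict)
    # external inputs
    catalog_path: str | None = None
    sheet_path: str | None = None
    fastq_paths: list[str] = field(default_factory=list)
    plates_path: str | None = None

    def validate(self) -> None:
        if self.alpha_sig <= 0 or self.alpha_sig >= 1:
            raise ParameterError(f"alpha_sig {self.alpha_sig} outside (0, 1)")
        if self.fold <= 1.0:
            raise ParameterError(f"fold threshold must exceed 1, got {self.fold}")
        if self.upset_theta not in ("log2_1.5", "1.5"):
            raise ParameterError("upset_theta must be 'log2_1.5' or '1.5'")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ParameterError(f"unknown condition {c!r}")
        for p in [self.catalog_path, self.sheet_path, self.plates_path, *self.fastq_paths]:
            if p is not None and not Path(p).exists():
                raise ParameterError(f"referenced path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.pop("thresholds", {})
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            alpha_sig=float(thresholds.get("alpha_sig", 0.05)),
            fold=float(thresholds.get("fold", 1.5)),
            upset_theta=str(thresholds.get("upset_theta", "log2_1.5")),
            k=raw.get("k"),
            conditions=tuple(raw.get("conditions", DEFAULT_SIM_CONDITIONS)),
            simulate=raw.get("simulate", {}) or {},
            catalog_path=raw.get("catalog"),
            sheet_path=raw.get("sheet"),
            fastq_paths=list(raw.get("fastq", []) or []),
            plates_path=raw.get("plates"),
        )
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_df(df: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "wt", newline="\n") as fh:
        fh.write(f"# config={tag}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.6g")


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the run report (also written as
    ``report.json``)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    report: dict = {"version": __version__, "config_hash": tag,
                    "config": json.loads(json.dumps(config.__dict__, default=str)),
                    "stages": {}}

    # ---- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.fastq_paths:
            catalog = load_catalog(config.catalog_path)
            sheet = load_sample_sheet(config.sheet_path)
            fastqs = [Path(p) for p in config.fastq_paths]
            truth = None
        else:
            sim_kwargs = {k: v for k, v in config.simulate.items() if k != "plates"}
            sim = SimConfig(seed=config.seed, **sim_kwargs)
            sim.validate()
            catalog = make_catalog(sim.n_strains, tag_length=sim.tag_length,
                                   seed=sim.seed)
            sheet = make_sample_sheet(config.conditions, n_bio_reps=sim.n_bio_reps)
            write_catalog(catalog, outdir / "catalog.tsv")
            write_sample_sheet(sheet, outdir / "sheet.tsv")
            fastq_dir = outdir / "fastq"
            fastq_dir.mkdir(exist_ok=True)
            fastqs = []
            truth_frames = []
            for cond in config.conditions:
                states, tt = simulate_pool(sim, cond)
                truth_frames.append(tt)
                for state in states:
                    row = [r for r in sheet.select(condition=cond, stage=state.stage)
                           if r.replicate == state.replicate][0]
                    up, down, _ = emit_reads(state, catalog, row, sim)
                    for which, reads in (("up", up), ("down", down)):
                        path = fastq_dir / f"{row.sample_id}_{which}.fastq"
                        write_fastq(reads, path)
                        fastqs.append(path)
            truth = pd.concat(truth_frames, ignore_index=True)
            _write_df(truth.set_index("strain_id"), outdir / "truth.tsv", tag)
        report["stages"][stage] = {"strains": len(catalog), "samples": len(sheet),
                                   "fastq_files": len(fastqs)}
        log.info("stage %s: %s", stage, report["stages"][stage])
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    # ---- stage: count ------------------------------------------------------
    stage = "count"
    try:
        cm: CountMatrix = count_run(fastqs, catalog, sheet)
        cm.write(outdir / "counts.tsv", outdir / "accounting.tsv",
                 header_comment=f"config={tag}")
        acc = cm.accounting
        report["stages"][stage] = {
            "reads": int(acc["reads"].sum()), "hits": int(acc["hits"].sum()),
            "ambiguous": int(acc["ambiguous"].sum()),
            "unmatched": int(acc["unmatched"].sum()),
            "no_tag": int(acc["no_tag"].sum()), "unassigned": int(cm.unassigned)}
        log.info("stage %s: %s", stage, report["stages"][stage])
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    # ---- stage: contrasts --------------------------------------------------
    stage = "contrast"
    try:
        contrast_dir = outdir / "contrasts"
        contrast_dir.mkdir(exist_ok=True)
        contrasts: dict[str, pd.DataFrame] = {}
        calls_summary = {}
        for cond in config.conditions:
            for name, (st_a, st_b) in (("BP", ("P", "B")), ("LE", ("ESS", "LSS"))):
                group_a = [r.sample_id for r in sheet.select(condition=cond, stage=st_a)]
                group_b = [r.sample_id for r in sheet.select(condition=cond, stage=st_b)]
                if not group_a or not group_b:
                    continue
                res = run_contrast(cm.counts, group_a, group_b,
                                   alpha_sig=config.alpha_sig, fold=config.fold)
                key = f"{name}_{cond}"
                contrasts[key] = res
                _write_df(res, contrast_dir / f"{key}.tsv", tag)
                calls_summary[key] = {
                    "HP": int((res["call"] == "HP").sum()),
                    "HI": int((res["call"] == "HI").sum())}
        report["stages"][stage] = {"comparisons": len(contrasts),
                                   "calls": calls_summary}
        log.info("stage %s: %d comparisons", stage, len(contrasts))

        theta_fold = 2.0 ** 1.5 if config.upset_theta == "1.5" else 1.5
        for direction in ("HI", "HP"):
            sets = {}
            for key, res in contrasts.items():
                recalled = (res if theta_fold == config.fold else
                            classify(res, alpha_sig=config.alpha_sig, fold=theta_fold))
                sets[key] = set(recalled.index[recalled["call"] == direction])
            if len(sets) >= 2:
                _write_df(intersect_calls(sets).set_index("conditions"),
                          outdir / f"upset_{direction}.tsv", tag)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    # ---- stage: cofitness --------------------------------------------------
    stage = "cofitness"
    try:
        needed = [c for c in COMPARISONS if c in contrasts]
        if len(needed) == len(COMPARISONS):
            profiles, n_dropped = build_profiles(contrasts)
            sel = glm_select(profiles, alpha=0.05)
            retained = profiles.loc[sel.index[sel["retained"]]]
            _write_df(profiles, outdir / "profiles.tsv", tag)
            _write_df(sel, outdir / "glm_selection.tsv", tag)
            if len(retained) >= 3:
                solution = pam_cluster(retained, k=config.k)
                assign = solution.assignment.to_frame()
                assign["subcluster"] = split_by_direction(retained, solution)
                _write_df(assign, outdir / "clusters.tsv", tag)
                enr = enrichment(solution, catalog.classes())
                _write_df(enr.set_index("cluster"), outdir / "enrichment.tsv", tag)
                report["stages"][stage] = {
                    "profiled": len(profiles), "dropped": n_dropped,
                    "retained": len(retained), "k": solution.k,
                    "silhouette": round(solution.silhouette, 4),
                    "enrichment_rows": len(enr)}
            else:
                report["stages"][stage] = {"profiled": len(profiles),
                                           "retained": len(retained), "k": 0}
        else:
            report["stages"][stage] = {"skipped": "needs all 8 comparisons"}
        log.info("stage %s: %s", stage, report["stages"][stage])
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    # ---- stage: screen -----------------------------------------------------
    stage = "screen"
    try:
        if config.plates_path:
            plates = read_plates_tsv(config.plates_path)
        else:
            sim_plates = dict(config.simulate.get("plates", {}))
            n_plate_strains = int(sim_plates.pop("n_strains", 300))
            plates, plate_truth = simulate_plates(
                n_strains=n_plate_strains, seed=config.seed, **sim_plates)
            write_plates_tsv(plates, outdir / "plates.tsv",
                             header_comment=f"config={tag}")
            _write_df(plate_truth.set_index("strain_id"),
                      outdir / "plate_truth.tsv", tag)
        values, wt_mean = normalize_plates(plates)
        fit = fit_mixture(values.to_numpy())
        calls = score_strains(fit, values, wt_mean, alpha=config.alpha_sig)
        _write_df(calls, outdir / "colony_calls.tsv", tag)
        report["stages"][stage] = {
            "plates": len(plates), "strains": len(values),
            "mixture_means": [round(fit.mu1, 4), round(fit.mu2, 4)],
            "converged": fit.converged,
            "significant": int(calls["significant"].sum())}
        log.info("stage %s: %s", stage, report["stages"][stage])
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    with open(outdir / "report.json", "wt") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
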