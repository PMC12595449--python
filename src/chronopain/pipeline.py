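"""End-to-end orchestration: simulate -> score -> actigraphy -> profile ->
DEG cascade, with a reproducibility manifest.

Every stage reads files written by the previous one, so any stage can be
rerun standalone on user-supplied files in the same dialects. All
randomness derives from the single root seed. Defaults that fill gaps the
source protocols leave open are logged with an ``ASSUMPTION`` tag at run
time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import actigraphy as act
from . import deg, io, profiling, synth
from .vonfrey import weighted_time_average

__all__ = ["RunConfig", "RunManifest", "run_all", "load_config"]

log = logging.getLogger("chronopain")

ASSUMPTIONS = [
    "PIR binarization: an epoch is inactive iff its count is 0",
    "immobility rule: >= 40 s of inactive epochs",
    "long activity bouts: strictly > 10 min",
    "weighted averages use trapezoidal time weights (irregular sampling)",
    "k constants derived by ML under a unit-step normal tolerance model",
    "guarding index: 1 - ipsi/contra geometric mean of stance x contact area",
    "affected rule: >= 1 control SD beyond the control mean (inclusive)",
    "DEG fold cutoff on the linear scale: |log2FC| > log2(1.2)",
    "guarding exclusion in the correlation filter is nominal (p >= 0.05)",
]


def _deep_update(base: dict, other: Mapping) -> dict:
    for k, v in other.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "chronopain_out",
    "simulate": True,
    "paths": {  # used when simulate is false
        "behavioral": None, "pir": None, "counts": None, "samples": None,
    },
    "cohort": {"n_per_group": 6},
    "activity": {"days": 7, "n_per_group": 2},
    "profile": {
        "late_day": 180.0,
        "early_window": [0.0, 14.0],
        "early_assay": "vf_threshold_g",
        "classify_assays": ["spt_pct", "oft_center_s", "vf_threshold_g"],
        "control_group": "control",
        "stratify_by_sex": True,
    },
    "degs": {
        "n_genes": 2000,
        "n_per_cell": 8,
        "alpha_nominal": 0.05,
        "alpha_fdr": 0.05,
        "fc_cut": 1.2,
        "fc_scale": "linear",
        "min_cpm": 1.0,
        "min_frac_samples": 0.5,
    },
    "actigraphy": {"min_immobility_s": 40, "long_bout_min": 10.0},
}


@dataclass
class RunConfig:
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        _deep_update(merged, self.options)
        self.options = merged

    def __getitem__(self, key: str) -> Any:
        return self.options[key]

    def hash(self) -> str:
        blob = json.dumps(self.options, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    options: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            options = yaml.safe_load(fh) or {}
    _deep_update(options, {k: v for k, v in overrides.items() if v is not None})
    return RunConfig(options)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    completed: bool = False
    wall_clock_s: float = 0.0

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _simulate_stage(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    seed = int(cfg["seed"])
    design, params = synth.default_design(
        n_per_group=int(cfg["cohort"]["n_per_group"]), seed=seed
    )
    records, truth = synth.generate_cohort(design, params)
    io.write_behavioral_csv(records, outdir / "behavioral.csv")
    truth.to_csv(outdir / "cohort_truth.tsv", sep="\t", index=False,
                 float_format="%.10g")
    ap = synth.ActivitySimParams(days=int(cfg["activity"]["days"]))
    streams = []
    n_act = int(cfg["activity"]["n_per_group"])
    for gi, group in enumerate(design.groups):
        injured = not group.lower().startswith("control")
        for ai in range(n_act):
            streams.append(
                synth.generate_activity_stream(
                    ap, injured=injured, seed=seed + 1000 * gi + ai,
                    animal_id=f"{group}_act{ai:02d}",
                )
            )
    io.write_pir_csv(streams, outdir / "pir.csv")
    samples = synth.default_count_samples(
        n_per_cell=int(cfg["degs"]["n_per_cell"]), seed=seed
    )
    cp = synth.CountSimParams(n_genes=int(cfg["degs"]["n_genes"]), seed=seed)
    counts, gene_truth = synth.generate_counts(cp, samples)
    io.write_counts_tsv(counts, outdir / "counts.tsv")
    io.write_sample_info_tsv(samples, outdir / "samples.tsv")
    gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", float_format="%.10g")
    manifest.stages["simulate"] = {
        "behavioral_rows": int(len(records)),
        "activity_streams": len(streams),
        "genes": int(counts.shape[0]),
        "samples": int(counts.shape[1]),
        "seed": seed,
    }


def _score_stage(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    table = io.read_behavioral_csv(outdir / "behavioral.csv")
    rows = []
    df = table.records.dropna(subset=["value"]).sort_values("day")
    for (animal, assay), grp in df.groupby(["animal_id", "assay"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        days = grp["day"].to_numpy(dtype=float)
        if assay in profiling.LOG_SCALE_ASSAYS:
            avg = 10.0 ** weighted_time_average(np.log10(vals), days)
        else:
            avg = weighted_time_average(vals, days)
        rows.append((animal, assay, len(vals), avg))
    out = pd.DataFrame(
        rows, columns=["animal_id", "assay", "n_timepoints", "weighted_avg"]
    )
    out.to_csv(outdir / "scores_weighted_avg.tsv", sep="\t", index=False,
               float_format="%.10g")
    manifest.stages["score"] = {"rows": int(len(out))}


def _actigraphy_stage(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    streams = io.read_pir_csv(outdir / "pir.csv")
    acfg = cfg["actigraphy"]
    rows = []
    for s in streams:
        cs = act.circadian_summary(
            s,
            min_immobility_s=int(acfg["min_immobility_s"]),
            min_activity_bout_min=float(acfg["long_bout_min"]),
        )
        rows.append({
            "animal_id": cs.animal_id,
            "long_bout_dark_frac": cs.long_bout_dark_frac,
            "dark_immobility_frac": cs.dark_immobility_frac,
            "light_immobility_frac": cs.light_immobility_frac,
            "IS": cs.IS,
            "IV": cs.IV,
            "ls_power_24h": cs.ls_power_24h,
            "ls_peak_period_h": cs.ls_peak_period_h,
            "ls_p_value": cs.ls_p_value,
        })
    pd.DataFrame(rows).to_csv(
        outdir / "circadian_summary.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    manifest.stages["actigraphy"] = {"animals": len(rows)}


def _profile_stage(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    table = io.read_behavioral_csv(outdir / "behavioral.csv")
    pcfg = cfg["profile"]
    late_day = float(pcfg["late_day"])
    control = pcfg["control_group"]
    groups = sorted(set(table.records["group"]) - {control})
    sexes = (
        sorted(set(table.records["sex"])) if pcfg["stratify_by_sex"] else [None]
    )
    cls_rows, frac_rows = [], []
    for assay in pcfg["classify_assays"]:
        direction = table.directionality[assay]
        for sex in sexes:
            ctrl = table.values_at(assay, late_day, [control], sex)
            if len(ctrl) < 2:
                continue
            for group in groups:
                vals = table.values_at(assay, late_day, [group], sex)
                if vals.empty:
                    continue
                res = profiling.classify_affected(vals, ctrl.values, direction)
                for animal, flag in res.affected.items():
                    cls_rows.append((assay, late_day, sex or "pooled", group,
                                     animal, bool(flag)))
                frac_rows.append((assay, late_day, sex or "pooled", group,
                                  res.affected_fraction, len(vals),
                                  res.cutoff_value))
    pd.DataFrame(
        cls_rows,
        columns=["assay", "day", "sex", "group", "animal_id", "affected"],
    ).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    pd.DataFrame(
        frac_rows,
        columns=["assay", "day", "sex", "group", "affected_fraction", "n",
                 "cutoff"],
    ).to_csv(outdir / "affected_fractions.tsv", sep="\t", index=False,
             float_format="%.10g")

    pairs = [
        (("vf_threshold_g", late_day), ("spt_pct", late_day)),
        (("vf_threshold_g", late_day), ("oft_center_s", late_day)),
        (("spt_pct", late_day), ("oft_center_s", late_day)),
    ]
    corr = profiling.correlation_matrix(table, pairs)
    pd.DataFrame(
        [(c.label_a, c.label_b, c.r, c.p, c.n, c.undefined) for c in corr],
        columns=["a", "b", "r", "p", "n", "undefined"],
    ).to_csv(outdir / "correlations.tsv", sep="\t", index=False,
             float_format="%.10g")

    pred_rows = []
    lo, hi = (float(x) for x in pcfg["early_window"])
    for late_assay in ("vf_threshold_g", "spt_pct", "oft_center_s"):
        for group_scope, label in ((None, "all"), (groups, "injured")):
            res = profiling.predict_late_from_early(
                table, early_assay=pcfg["early_assay"], late_assay=late_assay,
                late_day=late_day, early_window_days=(lo, hi),
                groups=group_scope,
            )
            pred_rows.append((label, res.label_a, res.label_b, res.r, res.p,
                              res.n))
    pd.DataFrame(
        pred_rows, columns=["scope", "early", "late", "r", "p", "n"]
    ).to_csv(outdir / "prediction.tsv", sep="\t", index=False,
             float_format="%.10g")
    manifest.stages["profile"] = {
        "classified": len(cls_rows), "correlations": len(corr),
        "predictions": len(pred_rows),
    }


def _deg_stage(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    dcfg = cfg["degs"]
    counts, meta = io.read_counts_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    info = deg.SampleInfo(meta)
    filt = deg.filter_low_expression(
        counts, float(dcfg["min_cpm"]), float(dcfg["min_frac_samples"])
    )
    lc = deg.log2cpm(filt)
    fc_cut, fc_scale = float(dcfg["fc_cut"]), dcfg["fc_scale"]
    res_o, set_o = deg.overall_treatment_degs(
        lc, info, float(dcfg["alpha_nominal"]), fc_cut, fc_scale
    )
    res_l, set_l = deg.nested_late_contrast(
        lc, info, float(dcfg["alpha_fdr"]), fc_cut, fc_scale
    )
    set_corr = deg.phenotype_correlation_filter(lc, info, set_l)
    sets = deg.DEGSets()
    sets.add("overall", set_o)
    sets.add("late", set_l)
    sets.add("corr", set_corr)
    sets.add("overall_and_late", deg.set_algebra(sets, "overall & late"))
    sets.add("overall_not_late", deg.set_algebra(sets, "overall - late"))
    candidates = sets.sets["overall_not_late"]
    ranking = deg.early_late_delta_ranking(lc, info, candidates)
    res_o.stats.rename_axis("gene").to_csv(
        outdir / "deg_overall.tsv", sep="\t", float_format="%.10g")
    res_l.stats.rename_axis("gene").to_csv(
        outdir / "deg_late.tsv", sep="\t", float_format="%.10g")
    membership = pd.DataFrame(
        {name: [g in s for g in lc.index] for name, s in sets.sets.items()},
        index=pd.Index(lc.index, name="gene"),
    )
    membership.to_csv(outdir / "deg_sets.tsv", sep="\t")
    ranking.to_csv(outdir / "deg_delta_ranking.tsv", sep="\t",
                   float_format="%.10g")
    up, down = deg.up_down_split(res_o, set_o)
    manifest.stages["deg"] = {
        "genes_tested": int(lc.shape[0]),
        "overall_degs": len(set_o),
        "overall_up": len(up),
        "overall_down": len(down),
        "late_degs": len(set_l),
        "corr_filtered": len(set_corr),
        "overall_and_late": len(sets.sets["overall_and_late"]),
        "delta_ranked": int(len(ranking)),
    }


STAGES = {
    "score": _score_stage,
    "actigraphy": _actigraphy_stage,
    "profile": _profile_stage,
    "deg": _deg_stage,
}


def run_all(cfg: RunConfig) -> RunManifest:
    """Execute all stages in dependency order; emit outputs plus a manifest.

    The manifest (config hash, seeds, per-stage row/gene counts, version,
    wall clock) is written even when a stage fails, recording partial
    completion.
    """
    t0 = time.perf_counter()
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.hash(), seed=int(cfg["seed"]), version=__version__
    )
    for a in ASSUMPTIONS:
        log.info("ASSUMPTION: %s", a)
    try:
        if cfg["simulate"]:
            _simulate_stage(cfg, outdir, manifest)
        else:
            paths = cfg["paths"]
            for key, fname in (("behavioral", "behavioral.csv"),
                               ("pir", "pir.csv"), ("counts", "counts.tsv"),
                               ("samples", "samples.tsv")):
                src = paths.get(key)
                if src is None:
                    raise FileNotFoundError(
                        f"simulate=false but no input path for {key!r}")
                target = outdir / fname
                if Path(src).resolve() != target.resolve():
                    target.write_bytes(Path(src).read_bytes())
        for name, fn in STAGES.items():
            log.info("stage %s", name)
            fn(cfg, outdir, manifest)
        manifest.completed = True
    finally:
        manifest.wall_clock_s = round(time.perf_counter() - t0, 3)
        manifest.write(outdir / "manifest.json")
    return manifest
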