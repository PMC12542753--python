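"""End-to-end orchestration: annotation -> coverage -> classes -> TSS ->
operons -> antisense (-> host DE -> enrichment), with provenance and a
plain-text report.

Configuration is a nested mapping with named sections; unknown keys are
rejected so typos fail loudly.  Every run writes a provenance record (config
hash, seed, package version) next to its outputs, and reruns with the same
config and seed produce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import GenomeAnnotation, Strand, features_to_table, read_annotation
from .classify import ClassifierConfig, TemporalClass, classify_all
from .coverage import CoverageExperiment, profiles_to_table, read_bedgraph_set, temporal_profile
from .host import call_degs, core_deg_sets, enrich
from .operons import OperonConfig, assemble, operons_to_table, summarize
from .simulate import SimulationSpec, read_fixture, simulate, write_fixture
from .tss import (
    TSSConfig,
    call_antisense_genes,
    detect_tss_both_strands,
    orient_tss,
    tss_to_bed,
)

__all__ = ["PipelineError", "validate_config", "run_full", "report", "DEFAULT_CONFIG"]

log = logging.getLogger("viraltc")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_SECTION_FIELDS = {
    "simulate": {f.name for f in dataclasses.fields(SimulationSpec)},
    "classifier": {f.name for f in dataclasses.fields(ClassifierConfig)} | {"expression_floor"},
    "tss": {f.name for f in dataclasses.fields(TSSConfig)},
    "operon": {f.name for f in dataclasses.fields(OperonConfig)},
    "coverage": {"read_length_proxy"},
    "de": {"alpha", "lfc_floor", "adjust"},
    "enrichment": {"hypergeometric"},
    "antisense": {"antisense_min_timepoints"},
    "io": {"fixture_dir", "outdir"},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "verbosity": 1,
    "simulate": None,  # a mapping of SimulationSpec overrides enables simulation
    "classifier": {},
    "tss": {},
    "operon": {},
    "coverage": {},
    "de": {},
    "enrichment": {},
    "antisense": {},
    "io": {"fixture_dir": None, "outdir": "viraltc_out"},
}


def validate_config(config: dict) -> dict:
    """Merge user config over defaults, rejecting unknown sections/keys."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if key in ("seed", "verbosity"):
            merged[key] = value
            continue
        if key not in _SECTION_FIELDS:
            raise PipelineError("config", f"unknown config section {key!r}")
        if value is None:
            merged[key] = None
            continue
        if not isinstance(value, dict):
            raise PipelineError("config", f"section {key!r} must be a mapping")
        allowed = _SECTION_FIELDS[key]
        bad = set(value) - allowed
        if bad:
            raise PipelineError("config", f"unknown keys in section {key!r}: {sorted(bad)}")
        base = merged.get(key) or {}
        base.update(value)
        merged[key] = base
    return merged


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(name, str(err)) from err
            log.info("stage %-10s %6.2f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_full(config: dict) -> dict:
    """Run every stage; returns the results bundle and writes all outputs."""
    cfg = validate_config(config)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO if cfg["verbosity"] else logging.WARNING)
    outdir = Path(cfg["io"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    truth = None
    host_counts: dict = {}
    category_map = None
    if cfg["simulate"] is not None:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", seed)
        sim_kwargs["timepoints"] = tuple(sim_kwargs.get("timepoints", SimulationSpec.timepoints))
        spec = SimulationSpec(**sim_kwargs)
        bundle = _stage("simulate")(simulate)(spec)
        ann, exp = bundle.annotation, bundle.experiment
        host_counts, category_map, truth = bundle.host_counts, bundle.category_map, bundle.truth
        _stage("simulate")(write_fixture)(bundle, outdir / "fixture")
    else:
        fixture_dir = cfg["io"]["fixture_dir"]
        if fixture_dir is None:
            raise PipelineError("input", "neither a simulation request nor io.fixture_dir given")
        fixture_dir = Path(fixture_dir)
        if (fixture_dir / "ground_truth.json").exists():
            ann, exp, host_counts, category_map, truth = _stage("input")(read_fixture)(fixture_dir)
        else:
            manifest = fixture_dir / "manifest.tsv"
            if not manifest.exists():
                raise PipelineError("input", f"manifest not found: {manifest}")
            ann = _stage("input")(read_annotation)(fixture_dir / "annotation.gff3")
            exp = _stage("input")(read_bedgraph_set)(manifest, ann.genome_length)

    # --- viral side ---------------------------------------------------------
    cov_kwargs = cfg["coverage"]
    clf_cfg = ClassifierConfig(
        **{k: v for k, v in cfg["classifier"].items() if k != "expression_floor"}
    )
    floor = cfg["classifier"].get("expression_floor", 1.0)
    profiles = _stage("profiles")(
        lambda: [
            temporal_profile(exp, f, expression_floor=floor, **cov_kwargs) for f in ann.features
        ]
    )()
    class_table, class_summary = _stage("classify")(classify_all)(profiles, clf_cfg)
    classes = {
        r.feature_id: TemporalClass(r.label) for r in class_table.itertuples()
    }

    tss_cfg = TSSConfig(**cfg["tss"])
    tsss = _stage("tss")(detect_tss_both_strands)(exp, tss_cfg)
    tsss = [orient_tss(t, ann, tss_cfg) for t in tsss]

    op_cfg = OperonConfig(**cfg["operon"])
    operons = _stage("operons")(assemble)(ann, classes, exp, tsss, op_cfg, tss_cfg)
    op_summary = summarize(operons) if operons else None

    anti = _stage("antisense")(call_antisense_genes)(exp, ann, **cfg["antisense"])

    results: dict = {
        "annotation": ann,
        "experiment": exp,
        "profiles": profiles,
        "class_table": class_table,
        "class_summary": class_summary,
        "classes": classes,
        "tss": tsss,
        "operons": operons,
        "operon_summary": op_summary,
        "antisense_calls": anti,
        "truth": truth,
        "enrichment": None,
        "deg_tables": None,
    }

    # --- host side ----------------------------------------------------------
    if host_counts and category_map is not None:
        deg_tables: dict[int, pd.DataFrame] = {}
        enrich_tables = []
        de_kwargs = cfg["de"]
        for t, mats in sorted(host_counts.items()):
            deg = _stage("de")(call_degs)(mats["infected"], mats["control"], **de_kwargs)
            deg_tables[t] = deg
            for direction in ("up", "down"):
                genes = deg.index[deg["direction"] == direction]
                table = enrich(
                    genes,
                    category_map,
                    direction=direction,
                    **cfg["enrichment"],
                )
                if len(table):
                    table.insert(0, "timepoint_min", t)
                    enrich_tables.append(table)
        results["deg_tables"] = deg_tables
        results["enrichment"] = (
            pd.concat(enrich_tables, ignore_index=True) if enrich_tables else pd.DataFrame()
        )
        results["core_up"] = core_deg_sets(
            {t: set(d.index[d["direction"] == "up"]) for t, d in deg_tables.items()}
        )["core"]

    _write_outputs(results, outdir, ann)
    _write_provenance(cfg, outdir)
    (outdir / "report.txt").write_text(report(results))
    return results


def _write_outputs(results: dict, outdir: Path, ann: GenomeAnnotation) -> None:
    features_to_table(ann).to_csv(outdir / "features.tsv", sep="\t", index=False)
    profiles_to_table(results["profiles"]).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    results["class_table"].to_csv(outdir / "classes.tsv", sep="\t", index=False)
    results["class_summary"].to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
    tss_to_bed(results["tss"], ann.genome_id).to_csv(
        outdir / "tss.bed", sep="\t", header=False, index=False
    )
    if results["operons"]:
        operons_to_table(results["operons"]).to_csv(outdir / "operons.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in results["antisense_calls"]],
            "n_timepoints_antisense_dominant": [
                c.n_timepoints_antisense_dominant for c in results["antisense_calls"]
            ],
            "called": [c.called for c in results["antisense_calls"]],
        }
    ).to_csv(outdir / "antisense.tsv", sep="\t", index=False)
    if results.get("deg_tables"):
        for t, deg in results["deg_tables"].items():
            deg.to_csv(outdir / f"deg_t{t}.tsv", sep="\t")
        results["enrichment"].to_csv(outdir / "enrichment.tsv", sep="\t", index=False)


def _write_provenance(cfg: dict, outdir: Path) -> None:
    blob = json.dumps(cfg, sort_keys=True, default=str)
    record = {
        "viraltc_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg["seed"],
    }
    (outdir / "provenance.json").write_text(json.dumps(record, indent=1, default=str))


def plot_class_profiles(profiles, classes, path: str | Path) -> None:
    """One panel per temporal class with every member's percent-of-max curve.

    Requires matplotlib (optional dependency); mirrors the standard
    per-class profile figure of infection time-course studies.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"early": "red", "middle": "green", "middle_down": "black", "late": "blue"}
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.2), sharey=True)
    for ax, (label, color) in zip(axes, colors.items()):
        for p in profiles:
            if classes.get(p.feature_id) is not None and classes[p.feature_id].value == label:
                ax.plot(p.timepoints, p.pct_of_max, color=color, alpha=0.5, lw=1)
        ax.axhline(50, ls=":", color="grey")
        ax.set_title(label)
        ax.set_xlabel("min post-infection")
    axes[0].set_ylabel("% of max expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(results: dict) -> str:
    """Human-readable summary of a finished run."""
    lines = ["viraltc run summary", "===================", ""]
    lines.append("Temporal classes (all annotated features):")
    for row in results["class_summary"].itertuples():
        lines.append(f"  {row.label:<13s} {row.count:4d}  ({row.percent:.1f}%)")
    lines.append("")
    n_sense = sum(1 for t in results["tss"] if t.orientation and t.orientation.value == "sense")
    n_int = sum(
        1 for t in results["tss"] if t.orientation and t.orientation.value == "internal_sense"
    )
    n_anti = sum(
        1 for t in results["tss"] if t.orientation and t.orientation.value == "antisense"
    )
    lines.append(
        f"TSSs detected: {len(results['tss'])} "
        f"(sense {n_sense}, internal {n_int}, antisense {n_anti})"
    )
    if results["operon_summary"]:
        s = results["operon_summary"]
        lines.append(
            f"Transcriptional units: {s['n_units']} covering {s['n_genes']} genes; "
            f"{s['n_monocistronic']} monocistronic ({s['pct_monocistronic']:.1f}%); "
            f"mean {s['mean_genes_per_operon']:.2f} genes/unit"
        )
    called = [c.feature_id for c in results["antisense_calls"] if c.called]
    lines.append(f"Antisense-dominated genes ({len(called)}): {', '.join(called) if called else '-'}")
    lines.append("")
    if results.get("enrichment") is not None:
        enr = results["enrichment"]
        if enr is None or len(enr) == 0:
            lines.append(
                "Host enrichment: omitted (no differentially expressed genes at any timepoint)"
            )
        else:
            lines.append("Host category representation (|signed| >= 2 shown):")
            strong = enr[np.abs(enr["signed_representation"]) >= 2.0]
            for row in strong.itertuples():
                lines.append(
                    f"  t{row.timepoint_min:<4} {row.direction:<4} arCOG {row.category}: "
                    f"{row.deg_count_in_category}/{row.deg_total} vs "
                    f"{row.pct_expected:.2f}% expected -> {row.signed_representation:+.2f}x"
                )
    return "\n".join(lines) + "\n"
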