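"""End-to-end orchestration: inputs -> filter -> structure -> DE -> null -> report.

The pipeline either generates a synthetic fixture set or ingests the four
standard inputs (counts TSV, metadata TSV, VCF, contig-compartment TSV),
runs the SNP filter cascade, partitions loci into mitochondrial and
nuclear compartments, quantifies station structure (AMOVA with permutation
p, PCA, pairwise G'ST), runs the pairwise NB differential-expression
analysis for each configured grouping, builds the randomized-grouping null
for the union DEG count, and reports gamma-Q0.95 exceedance verdicts.

The JSON report contains no wall-clock times or absolute paths, so two
runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import DeThresholds, union_deg_count
from .nullfit import (
    DegenerateNullError,
    SizeConformation,
    empirical_verdict,
    exceedance_test,
    fit_null,
    gamma_q95_ci,
    null_distribution,
)
from .simulate import (
    SimulationConfig,
    compartment_table,
    extend_cohort,
    read_compartments,
    read_counts,
    read_metadata,
    simulate_counts,
    simulate_genotypes,
    simulate_metadata,
)
from .structure import (
    amova_permutation_test,
    genotype_pca,
    gst_density,
    hedrick_gst_pairwise,
    pairwise_distance_matrix,
)
from .variants import FilterParams, partition_compartments, read_vcf, run_filter_cascade

log = logging.getLogger("mitonuc")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; safe to serialize and hash."""

    # either simulate... or give the four input paths
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    counts_path: str | None = None
    metadata_path: str | None = None
    vcf_path: str | None = None
    compartments_path: str | None = None

    filter_params: FilterParams = field(default_factory=FilterParams)
    thresholds: DeThresholds = field(default_factory=DeThresholds)
    groupings: list[str] = field(default_factory=lambda: ["station", "mitotype", "nuclear_type"])
    station_column: str = "station"
    n_iter_null: int = 1000
    n_perm_amova: int = 1000
    n_boot_ci: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "simulate": self.simulate,
            "sim": _sim_to_dict(self.sim) if self.simulate else None,
            "counts_path": self.counts_path,
            "metadata_path": self.metadata_path,
            "vcf_path": self.vcf_path,
            "compartments_path": self.compartments_path,
            "filter_params": vars(self.filter_params).copy(),
            "thresholds": vars(self.thresholds).copy(),
            "groupings": list(self.groupings),
            "station_column": self.station_column,
            "n_iter_null": self.n_iter_null,
            "n_perm_amova": self.n_perm_amova,
            "n_boot_ci": self.n_boot_ci,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "sim" in d and d["sim"]:
            sim_d = dict(d["sim"])
            if "group_design" in sim_d:
                sim_d["group_design"] = {
                    k: [tuple(p) for p in v] for k, v in sim_d["group_design"].items()
                }
            if "libsize_range" in sim_d:
                sim_d["libsize_range"] = tuple(sim_d["libsize_range"])
            cfg.sim = SimulationConfig(**sim_d)
        if "filter_params" in d and d["filter_params"]:
            cfg.filter_params = FilterParams(**d["filter_params"])
        if "thresholds" in d and d["thresholds"]:
            cfg.thresholds = DeThresholds(**d["thresholds"])
        for k in (
            "simulate", "counts_path", "metadata_path", "vcf_path", "compartments_path",
            "groupings", "station_column", "n_iter_null", "n_perm_amova", "n_boot_ci", "seed",
        ):
            if k in d and d[k] is not None:
                setattr(cfg, k, d[k])
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sim_to_dict(sim: SimulationConfig) -> dict:
    d = vars(sim).copy()
    d["group_design"] = {k: [list(p) for p in v] for k, v in sim.group_design.items()}
    d["libsize_range"] = list(sim.libsize_range)
    return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = config.sim
        meta = simulate_metadata(sim)
        counts, truth = simulate_counts(sim, meta)
        cohort = extend_cohort(sim, meta)
        v = simulate_genotypes(sim, cohort)
        comp = compartment_table(v)
        return counts, cohort, v, comp
    for name in ("counts_path", "metadata_path", "vcf_path", "compartments_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise PipelineError("inputs", f"missing input {name}: {p}")
    counts = read_counts(config.counts_path)
    cohort = read_metadata(config.metadata_path)
    v = read_vcf(config.vcf_path)
    comp = read_compartments(config.compartments_path)
    known = set(cohort["sample_id"])
    bad = [s for s in counts.columns if s not in known]
    if bad:
        raise PipelineError("inputs", f"count samples absent from metadata: {bad}")
    return counts, cohort, v, comp


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report as a plain JSON-serializable dict."""
    master = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(np.random.default_rng(child).integers(2**31))
        for name, child in zip(
            ("amova_mito", "amova_nuc", "null", "boot"), master.spawn(4)
        )
    }

    counts, cohort, variants, comp = _load_inputs(config)

    filtered, flog = _stage("filter")(run_filter_cascade)(variants, config.filter_params)
    mito, nuc = _stage("partition")(partition_compartments)(filtered, comp)

    structure_report = {}
    station = cohort.set_index("sample_id")[config.station_column]
    for name, vm, skey in (("mitochondrial", mito, "amova_mito"), ("nuclear", nuc, "amova_nuc")):
        if vm.n_loci == 0 or vm.n_individuals < 3:
            structure_report[name] = None
            continue
        structure_report[name] = _structure_block(
            vm, station, config.n_perm_amova, seeds[skey]
        )

    de_report = {}
    de_samples = [s for s in counts.columns]
    meta_expr = cohort[cohort["sample_id"].isin(de_samples)]
    null_rng = np.random.default_rng(seeds["null"])
    boot_rng = np.random.default_rng(seeds["boot"])
    for grouping in config.groupings:
        if grouping not in cohort.columns:
            raise PipelineError("de", f"grouping column {grouping!r} not in metadata")
        de_report[grouping] = _grouping_block(
            counts, meta_expr, grouping, config, null_rng, boot_rng
        )

    report = {
        "provenance": {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": seeds,
        },
        "filter_log": [
            {
                "stage": s.stage,
                "loci_in": s.loci_in,
                "loci_out": s.loci_out,
                "individuals_in": s.individuals_in,
                "individuals_out": s.individuals_out,
            }
            for s in flog.stages
        ],
        "structure": structure_report,
        "de": de_report,
    }
    return report


@_stage("structure")
def _structure_block(vm, station: pd.Series, n_perm: int, seed: int) -> dict:
    d2 = pairwise_distance_matrix(vm)
    am = amova_permutation_test(d2, station, vm.samples, n_perm=n_perm, seed=seed)
    pca = genotype_pca(vm, n_components=min(5, vm.n_individuals - 1, vm.n_loci))
    labels = station.loc[vm.samples]
    gst = {}
    for a, b in combinations(pd.unique(labels), 2):
        try:
            r = hedrick_gst_pairwise(vm, labels, (a, b))
            gst[f"{a}|{b}"] = {"mean_gst": r.mean_gst, "n_loci_used": r.n_loci_used}
        except ValueError:
            gst[f"{a}|{b}"] = None
    return {
        "n_loci": vm.n_loci,
        "n_individuals": vm.n_individuals,
        "amova": {
            "df_among": am.df_among,
            "df_within": am.df_within,
            "ss_among": am.ss_among,
            "ss_within": am.ss_within,
            "sigma2_among": am.sigma2_among,
            "sigma2_within": am.sigma2_within,
            "pct_among": max(am.pct_among, 0.0),  # report-layer floor
            "pct_within": min(am.pct_within, 100.0),
            "phi_st": am.phi_st,
            "p_value": am.p_value,
        },
        "pca_explained_pct": [float(x) for x in pca.explained_pct],
        "gst_pairs": gst,
    }


def _grouping_block(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str,
    config: PipelineConfig,
    null_rng: np.random.Generator,
    boot_rng: np.random.Generator,
) -> dict:
    observed = _stage(f"de:{grouping}")(union_deg_count)(
        counts, meta, grouping, config.thresholds, keep_tables=False
    )
    sizes = meta.set_index("sample_id").loc[list(counts.columns), grouping].value_counts()
    conf = SizeConformation(tuple(int(x) for x in sizes.sort_index().to_numpy()))
    values = _stage(f"null:{grouping}")(null_distribution)(
        counts, list(counts.columns), conf, config.thresholds,
        n_iter=config.n_iter_null, seed=null_rng,
    )
    try:
        fit = fit_null(values)
        q95, ci = gamma_q95_ci(fit, n_boot=config.n_boot_ci, seed=boot_rng)
        verdict = exceedance_test(observed.union_count, fit)
        fit_block = {
            "selected": fit.selected.name,
            "params": fit.selected.params,
            "aic": {f.name: f.aic for f in fit.candidate_fits},
            "shift": fit.shift,
            "q95": q95,
            "q95_ci": list(ci),
        }
    except DegenerateNullError:
        verdict = empirical_verdict(observed.union_count, values)
        fit_block = {"selected": "empirical", "q95": verdict.q95}
    return {
        "conformation": list(conf.sizes),
        "per_pair_counts": {f"{a}|{b}": n for (a, b), n in sorted(observed.per_pair_counts.items())},
        "union_count": observed.union_count,
        "null_mean": float(np.mean(values)),
        "null_fit": fit_block,
        "verdict": {
            "observed": verdict.observed,
            "q95": verdict.q95,
            "exceeds": verdict.exceeds,
            "empirical_p": verdict.empirical_p,
            "method": verdict.method,
        },
    }


def write_report(report: dict, outdir: str | Path) -> dict[str, Path]:
    """Write report.json plus human-readable TSVs; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["json"] = outdir / "report.json"
    paths["json"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    rows = report.get("filter_log", [])
    paths["filter_log"] = outdir / "filter_log.tsv"
    pd.DataFrame(rows).to_csv(paths["filter_log"], sep="\t", index=False)

    amova_rows = []
    for comp_name, block in (report.get("structure") or {}).items():
        if not block:
            continue
        am = block["amova"]
        amova_rows.append(
            (comp_name, "Between stations", am["df_among"], am["pct_among"], am["p_value"])
        )
        amova_rows.append(
            (comp_name, "Within individuals", am["df_within"], am["pct_within"], "")
        )
    paths["amova"] = outdir / "amova.tsv"
    pd.DataFrame(
        amova_rows,
        columns=["compartment", "source_of_variation", "df", "percentage_of_variation", "p_value"],
    ).to_csv(paths["amova"], sep="\t", index=False)

    deg_rows = []
    gst_rows = []
    for grouping, block in (report.get("de") or {}).items():
        for pair, n in block["per_pair_counts"].items():
            deg_rows.append((grouping, pair, n))
        deg_rows.append((grouping, "UNION", block["union_count"]))
    for comp_name, block in (report.get("structure") or {}).items():
        if not block:
            continue
        for pair, g in block["gst_pairs"].items():
            if g:
                gst_rows.append((comp_name, pair, g["mean_gst"], g["n_loci_used"]))
    paths["deg_counts"] = outdir / "deg_counts.tsv"
    pd.DataFrame(deg_rows, columns=["grouping", "pair", "n_deg"]).to_csv(
        paths["deg_counts"], sep="\t", index=False
    )
    paths["gst"] = outdir / "gst.tsv"
    pd.DataFrame(gst_rows, columns=["compartment", "pair", "mean_gst", "n_loci_used"]).to_csv(
        paths["gst"], sep="\t", index=False
    )
    return paths


def export_gst_densities(vm, station: pd.Series, outdir: str | Path) -> list[Path]:
    """Per-pair G'ST kernel-density TSVs for plotting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    labels = station.loc[vm.samples]
    for a, b in combinations(pd.unique(labels), 2):
        r = hedrick_gst_pairwise(vm, labels, (a, b))
        path = outdir / f"gst_density_{a}_{b}.tsv"
        gst_density(r.per_locus_gst).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
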