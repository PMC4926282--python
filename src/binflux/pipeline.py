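"""End-to-end orchestration: one config in, the study's report set out.

Stages run in a fixed order — read/validate, scaffold length filter,
read-count normalization, bin aggregation, response-group
classification, clustering, category enrichment, inoculum fold change,
trait association — and any failure aborts with the manifest recording
the stages that completed. Reports are deterministic: a rerun with the
same config and seed reproduces every file byte for byte (stage
durations are logged to stderr only, never written to reports).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

import binflux
from binflux import abundance as ab
from binflux import association as assoc
from binflux import dynamics as dyn
from binflux import enrichment as enr
from binflux import io as bio
from binflux import simulate as sim

logger = logging.getLogger("binflux")

STAGES = (
    "io",
    "filter",
    "normalize",
    "aggregate",
    "classify",
    "cluster",
    "enrich",
    "foldchange",
    "associate",
)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: Path
    seed: int = 0
    # either explicit input paths ...
    coverage: Path | None = None
    scaffold_bins: Path | None = None
    annotations: Path | None = None
    design: Path | None = None
    process: Path | None = None
    # ... or a simulation request (community/design/process overrides)
    simulate: dict[str, Any] | None = None
    min_scaffold_length: int = 500
    theta: float = 2.0
    pseudocount: float | str = "auto"
    alpha: float = 0.05
    adjust: str = "bh"
    enrich_groups: list[str] | None = None  # e.g. ["A", "B"]; None = all bins
    traits: list[str] = field(default_factory=lambda: ["methane_yield", "acetate"])
    relative: bool = False  # heatmap on relative abundances

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        inputs = [self.coverage, self.scaffold_bins, self.design]
        if self.simulate is None and any(p is None for p in inputs):
            raise ValueError(
                "config needs either a 'simulate' block or coverage/"
                "scaffold_bins/design input paths"
            )
        if self.simulate is None:
            for p in (self.coverage, self.scaffold_bins, self.annotations,
                      self.design, self.process):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")
        if self.theta <= 1:
            raise ValueError("theta must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjust not in enr.ADJUST_METHODS:
            raise ValueError(f"adjust must be one of {enr.ADJUST_METHODS}")
        unknown = [t for t in self.traits if t not in assoc.TRAITS]
        if unknown:
            raise ValueError(f"unknown trait(s) {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        paths = {
            k: Path(doc[k]) for k in
            ("coverage", "scaffold_bins", "annotations", "design", "process")
            if doc.get(k)
        }
        kwargs = {k: v for k, v in doc.items() if k not in paths}
        return cls(**{**kwargs, **paths})

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "min_scaffold_length": self.min_scaffold_length,
            "theta": self.theta,
            "pseudocount": self.pseudocount,
            "alpha": self.alpha,
            "adjust": self.adjust,
            "enrich_groups": self.enrich_groups,
            "traits": list(self.traits),
            "relative": self.relative,
            "simulate": self.simulate,
        }
        for k in ("coverage", "scaffold_bins", "annotations", "design", "process"):
            v = getattr(self, k)
            d[k] = str(v) if v is not None else None
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_specs(block: dict[str, Any]) -> tuple[sim.CommunitySpec, sim.DesignSpec, sim.ProcessSpec]:
    comm = sim.CommunitySpec(**block.get("community", {}))
    des = sim.DesignSpec(**block.get("design", {}))
    pr_kwargs = dict(block.get("process", {}))
    proc = sim.ProcessSpec(**pr_kwargs)
    return comm, des, proc


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the run manifest (also written to disk).

    Report files land in ``config.output_dir``; simulated inputs are
    materialized under ``<output_dir>/data`` and read back through the
    canonical readers so a simulated run exercises the exact same code
    path as a run on real exports.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool_version": binflux.__version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": {},
        "stage_counts": {},
        "completed_stages": [],
        "warnings": [],
    }

    def finish(stage: str | None = None, error: str | None = None) -> None:
        if error is not None:
            manifest["error"] = f"{stage}: {error}"
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    stage = "io"
    try:
        t0 = time.monotonic()
        if config.simulate is not None:
            block = dict(config.simulate)
            process_noise = bool(block.pop("process_noise", True))
            comm, des, proc = _simulate_specs(block)
            dataset = sim.generate_dataset(
                config.seed, community=comm, design=des, process=proc,
                process_noise=process_noise,
            )
            data_dir = out / "data"
            paths = sim.write_dataset(dataset, data_dir)
            cov_path = paths["coverage"]
            bins_path = paths["scaffold_bins"]
            ann_path = paths["annotations"]
            design_path = paths["design"]
            process_path = paths["process"]
        else:
            cov_path = Path(config.coverage)
            bins_path = Path(config.scaffold_bins)
            ann_path = Path(config.annotations) if config.annotations else None
            design_path = Path(config.design)
            process_path = Path(config.process) if config.process else None

        for name, p in (
            ("coverage", cov_path), ("scaffold_bins", bins_path),
            ("annotations", ann_path), ("design", design_path),
            ("process", process_path),
        ):
            if p is not None:
                manifest["input_checksums"][name] = _sha256(Path(p))

        design = bio.read_design(design_path)
        bin_map = bio.read_scaffold_bins(bins_path)
        cov = bio.read_coverage_table(cov_path, design)
        annotations = (
            bio.read_gene_annotations(ann_path, bin_universe=set(bin_map.values()))
            if ann_path is not None
            else None
        )
        process = bio.read_process_table(process_path) if process_path else None
        manifest["stage_counts"]["io"] = {
            "samples": int(len(design)),
            "scaffolds": int(cov.n_scaffolds),
            "annotation_rows": int(len(annotations)) if annotations is not None else 0,
            "process_rows": int(len(process)) if process is not None else 0,
        }
        manifest["completed_stages"].append("io")
        logger.info("stage io done in %.2fs", time.monotonic() - t0)

        stage = "filter"
        t0 = time.monotonic()
        cov = ab.filter_scaffolds(cov, config.min_scaffold_length)
        manifest["stage_counts"]["filter"] = {"scaffolds_kept": int(cov.n_scaffolds)}
        manifest["completed_stages"].append("filter")
        logger.info("stage filter done in %.2fs", time.monotonic() - t0)

        stage = "normalize"
        t0 = time.monotonic()
        cov = ab.normalize_coverage(cov)
        manifest["stage_counts"]["normalize"] = {
            "reference_sample": ab.normalization_reference(cov.samples)
        }
        manifest["completed_stages"].append("normalize")
        logger.info("stage normalize done in %.2fs", time.monotonic() - t0)

        stage = "aggregate"
        t0 = time.monotonic()
        abund = ab.aggregate_bin_abundance(cov, bin_map)
        abund_table = abund.abundance.reset_index()
        bio.write_report(abund_table, out / "abundance.tsv")
        rel = ab.relative_abundance(abund)
        bio.write_report(rel.abundance.reset_index(), out / "relative_abundance.tsv")
        manifest["stage_counts"]["aggregate"] = {"bins": int(len(abund.bins))}
        manifest["completed_stages"].append("aggregate")
        logger.info("stage aggregate done in %.2fs", time.monotonic() - t0)

        pseudocount = (
            ab.auto_pseudocount(abund.abundance)
            if config.pseudocount == "auto"
            else float(config.pseudocount)
        )

        stage = "classify"
        t0 = time.monotonic()
        work = rel if config.relative else abund
        class_pseudo = (
            ab.auto_pseudocount(work.abundance)
            if config.pseudocount == "auto"
            else float(config.pseudocount)
        )
        groups, summary = dyn.classify_all(
            work, theta=config.theta, pseudocount=class_pseudo
        )
        bio.write_report(groups, out / "groups.tsv")
        bio.write_report(
            pd.DataFrame([summary]).melt(var_name="group", value_name="count"),
            out / "group_summary.tsv",
        )
        manifest["stage_counts"]["classify"] = summary
        manifest["completed_stages"].append("classify")
        logger.info("stage classify done in %.2fs", time.monotonic() - t0)

        stage = "cluster"
        t0 = time.monotonic()
        responsive = sorted(groups.loc[groups["group"] != "NONE", "bin_id"].unique())
        subset = responsive if len(responsive) >= 2 else None
        if subset is not None or len(abund.bins) >= 2:
            order, _ = dyn.cluster_bins(work, subset=subset, pseudocount=class_pseudo)
            order_df = pd.DataFrame(
                {"position": range(len(order)), "bin_id": order}
            )
            bio.write_report(order_df, out / "cluster_order.tsv", sort=False)
            heat = work.abundance.loc[order].reset_index()
            bio.write_report(heat, out / "heatmap.tsv", sort=False)
            n_clustered = len(order)
        else:
            n_clustered = 0
        manifest["stage_counts"]["cluster"] = {"bins_ordered": int(n_clustered)}
        manifest["completed_stages"].append("cluster")
        logger.info("stage cluster done in %.2fs", time.monotonic() - t0)

        stage = "enrich"
        t0 = time.monotonic()
        if annotations is not None:
            if config.enrich_groups is not None:
                wanted = set(config.enrich_groups)
                bins_subset = sorted(
                    groups.loc[groups["group"].isin(wanted), "bin_id"].unique()
                )
                bins_subset = [b for b in bins_subset if b in set(annotations["bin_id"])]
                table = (
                    enr.enrich_all(
                        annotations, bins=bins_subset,
                        alpha=config.alpha, method=config.adjust,
                    )
                    if bins_subset
                    else enr.enrich_all(annotations, alpha=config.alpha,
                                        method=config.adjust).iloc[0:0]
                )
            else:
                table = enr.enrich_all(
                    annotations, alpha=config.alpha, method=config.adjust
                )
            bio.write_report(table, out / "enrichment.tsv")
            manifest["stage_counts"]["enrich"] = {
                "pairs_tested": int(len(table)),
                "enriched": int(table["enriched"].sum()) if len(table) else 0,
            }
        else:
            manifest["stage_counts"]["enrich"] = {"pairs_tested": 0, "enriched": 0}
        manifest["completed_stages"].append("enrich")
        logger.info("stage enrich done in %.2fs", time.monotonic() - t0)

        stage = "foldchange"
        t0 = time.monotonic()
        d = abund.samples
        grp_acc = list(
            d.loc[(d["experimental_set"] == "acclimatized") & (d["period"] == "I"),
                  "sample_id"]
        )
        grp_non = list(
            d.loc[(d["experimental_set"] == "non_acclimatized") & (d["period"] == "I"),
                  "sample_id"]
        )
        if grp_acc and grp_non:
            fc = ab.fold_change(abund, grp_acc, grp_non, pseudocount=pseudocount)
            bio.write_report(fc, out / "foldchange_inoculum.tsv")
            manifest["stage_counts"]["foldchange"] = {"bins": int(len(fc))}
        else:
            manifest["stage_counts"]["foldchange"] = {"bins": 0}
            manifest["warnings"].append(
                "foldchange skipped: need Period-I samples in both sets"
            )
        manifest["completed_stages"].append("foldchange")
        logger.info("stage foldchange done in %.2fs", time.monotonic() - t0)

        stage = "associate"
        t0 = time.monotonic()
        if process is not None:
            counts = {}
            for trait in config.traits:
                obs = assoc.prepare_observations(design, process, trait)
                spec = assoc.GLMSpec(trait=trait)
                fit = assoc.fit_glm(obs, spec)
                lsm = pd.concat(
                    [assoc.lsmeans(fit, e) for e in fit.factor_levels],
                    ignore_index=True,
                )
                tt = pd.concat(
                    [assoc.lsmeans_ttest(fit, e) for e in fit.factor_levels],
                    ignore_index=True,
                )
                bio.write_report(lsm, out / f"lsmeans_{trait}.tsv")
                bio.write_report(tt, out / f"lsmeans_ttests_{trait}.tsv")
                scan = assoc.covariate_scan(
                    obs, abund, trait, alpha=config.alpha
                )
                bio.write_report(scan, out / f"association_{trait}.tsv")
                counts[trait] = int(len(scan))
            manifest["stage_counts"]["associate"] = counts
        else:
            manifest["stage_counts"]["associate"] = {}
            manifest["warnings"].append("associate skipped: no process table")
        manifest["completed_stages"].append("associate")
        logger.info("stage associate done in %.2fs", time.monotonic() - t0)
    except Exception as exc:
        finish(stage, str(exc))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    finish()
    return manifest
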