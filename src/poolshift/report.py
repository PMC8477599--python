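"""Pipeline orchestration and summary reporting.

``run_pipeline`` wires the stages (simulate/load -> filter -> popgen ->
effects -> bridge -> enrich) according to a :class:`RunConfig`, writes every
stage's tabular output as TSV plus a ``summary.json`` whose headline numbers
(per-group significant counts, between-group ratios and percent
differences) are recomputable from the per-locus tables it accompanies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from poolshift import bridge as bridge_mod
from poolshift import effects as effects_mod
from poolshift import enrich as enrich_mod
from poolshift import popgen as popgen_mod
from poolshift.counts import CountTable
from poolshift.effects import CategoryCrosstab
from poolshift.filters import run_filter_cascade
from poolshift.synthdata import SimParams, simulate_experiment, write_truth

log = logging.getLogger("poolshift")


def summarize_crosstab(ct: CategoryCrosstab) -> dict:
    """Derived quantities of a category cross-tabulation.

    Reports, for groups a and b: category margins, significant totals
    (anything but None), counts affected by the seawater treatment
    (Trt + Stage+Trt + Stage*Trt), the percent excess of b over a in total
    significant loci, the percent reduction of a relative to b in
    Stage-only loci, and the a:b treatment-affected ratio as a percent.
    Rounded values use round-half-away-from-zero to the nearest integer.
    """
    a, b = ct.group_a, ct.group_b
    margins = {g: ct.margins(g) for g in (a, b)}
    sig = {g: int(m.drop("None").sum()) for g, m in margins.items()}
    stage = {g: int(m["Stage"]) for g, m in margins.items()}
    trt_affected = {
        g: int(m["Trt"] + m["Stage+Trt"] + m["Stage*Trt"]) for g, m in margins.items()
    }

    def _round(x: float) -> int:
        return int(np.floor(x + 0.5))

    pct_more_sig = 100.0 * (sig[b] - sig[a]) / sig[a] if sig[a] else float("nan")
    pct_fewer_stage = 100.0 * (stage[b] - stage[a]) / stage[b] if stage[b] else float("nan")
    trt_ratio = 100.0 * trt_affected[a] / trt_affected[b] if trt_affected[b] else float("nan")
    return {
        "groups": {"a": a, "b": b},
        "total_loci": ct.total,
        "margins": {g: m.to_dict() for g, m in margins.items()},
        "significant_total": sig,
        "stage_only": stage,
        "treatment_affected": trt_affected,
        "pct_more_significant_b_over_a": pct_more_sig,
        "pct_more_significant_b_over_a_rounded": _round(pct_more_sig),
        "pct_fewer_stage_a_vs_b": pct_fewer_stage,
        "pct_fewer_stage_a_vs_b_rounded": _round(pct_fewer_stage),
        "treatment_ratio_a_over_b_pct": trt_ratio,
        "fraction_significant": {g: sig[g] / ct.total for g in (a, b)},
    }


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (round-trippable YAML)."""

    out_dir: str = "poolshift_run"
    counts_path: str | None = None  # read counts from TSV ...
    simulate: dict | None = None  # ... or simulate (SimParams kwargs)
    # filter cascade
    min_depth: int = 50
    max_depth: int = 1000
    min_allele_reads: int = 1
    min_reps: int = 3
    min_maf: float = 0.01
    presence_groups: str = "both"
    # effects
    alpha: float = 0.05
    bh_family: str = "per_term"
    # popgen
    do_popgen: bool = True
    popgen_stage: str = "day2"
    popgen_treatment: str = "ambient"
    n_boot: int = 1000
    # bridge / enrich
    do_effects: bool = True
    do_bridge: bool = True
    do_enrich: bool = True
    linkage_map_path: str | None = None
    gff_path: str | None = None
    go_map_path: str | None = None
    enrich_window: int = 5000
    n_resamples: int = 10_000
    min_members: int = 2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed or its prerequisite stage was disabled."""


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order; returns the summary dict.

    All outputs land under ``config.out_dir``; the resolved configuration is
    written beside them.  Identical config + seed reproduces the summary
    byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    summary: dict = {"stages": []}

    # --- input counts -----------------------------------------------------
    if config.simulate is not None:
        params = SimParams(**{**config.simulate, "seed": config.seed})
        counts, truth = simulate_experiment(params)
        write_truth(truth, out / "truth.tsv")
        counts.to_tsv(out / "counts.tsv")
    elif config.counts_path is not None:
        counts = CountTable.from_tsv(config.counts_path)
    else:
        raise StageError("input: neither counts_path nor simulate given")
    summary["stages"].append("input")
    log.info("input: %d rows, %d loci", len(counts), counts.df["locus_id"].nunique())

    # --- filter cascade ---------------------------------------------------
    panel = run_filter_cascade(
        counts,
        min_depth=config.min_depth,
        max_depth=config.max_depth,
        min_allele_reads=config.min_allele_reads,
        min_reps=config.min_reps,
        min_maf=config.min_maf,
        groups=config.presence_groups,
    )
    panel.to_dir(out / "panel")
    summary["stages"].append("filter")
    summary["loci_analyzed"] = panel.n_loci
    summary["filter_audit"] = panel.audit
    log.info("filter: %d loci retained", panel.n_loci)
    groups = panel.groups

    # --- popgen -----------------------------------------------------------
    if config.do_popgen and len(groups) == 2:
        pg = popgen_mod.popgen_summary(
            panel,
            groups[0],
            groups[1],
            stage=config.popgen_stage,
            treatment=config.popgen_treatment,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        freqs = popgen_mod.allele_frequencies(panel, level="replicate")
        pca = popgen_mod.replicate_pca(freqs)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        with open(out / "popgen_summary.json", "w") as fh:
            json.dump(pg, fh, indent=2)
        summary["popgen"] = {k: pg[k] for k in ("mean_maf", "mean_pi", "fst", "sfs_ks")}
        summary["stages"].append("popgen")

    # --- effects ----------------------------------------------------------
    effects_by_group: dict[str, pd.DataFrame] = {}
    if config.do_effects:
        for group in groups:
            fitted = effects_mod.fit_group_glms(panel, group)
            classified = effects_mod.classify_effects(
                fitted, alpha=config.alpha, family=config.bh_family
            )
            classified.to_csv(out / f"effects_{group}.tsv", sep="\t")
            effects_by_group[group] = classified
        summary["stages"].append("effects")
        summary["categories"] = {
            g: e["category"].value_counts().to_dict() for g, e in effects_by_group.items()
        }
        summary["interaction_negative_fraction"] = {
            g: effects_mod.interaction_sign_summary(e) for g, e in effects_by_group.items()
        }
        if len(groups) == 2:
            ct, chi2 = effects_mod.crosstab_categories(
                effects_by_group[groups[0]], effects_by_group[groups[1]], groups[0], groups[1]
            )
            ct.matrix.to_csv(out / "crosstab.tsv", sep="\t")
            summary["crosstab"] = summarize_crosstab(ct)
            summary["crosstab"]["chi_square"] = chi2

    # --- bridge -----------------------------------------------------------
    bridged = None
    if config.do_bridge and config.linkage_map_path:
        if not config.do_effects:
            raise StageError("bridge: requires the effects stage (disabled)")
        lmap = bridge_mod.read_linkage_map(config.linkage_map_path)
        loci = panel.loci.reset_index(names="locus_id")
        bridged = bridge_mod.assign_linkage_positions(loci, lmap)
        bridged.to_csv(out / "bridged.tsv", sep="\t", index=False)
        summary["mapped_loci"] = int(bridged["rule"].isin(bridge_mod.RULES[:3]).sum())
        for group, eff in effects_by_group.items():
            table, thresholds = bridge_mod.manhattan_table(bridged, eff)
            table.to_csv(out / f"manhattan_{group}.tsv", sep="\t", index=False)
            summary.setdefault("manhattan_thresholds", {})[group] = thresholds
        summary["stages"].append("bridge")

    # --- enrich -----------------------------------------------------------
    if config.do_enrich and config.gff_path and config.go_map_path:
        if bridged is None:
            raise StageError("enrich: requires the bridge stage output (disabled or no map)")
        genes = enrich_mod.read_gff_genes(config.gff_path)
        go_map = enrich_mod.read_gene_go_map(config.go_map_path)
        mapped = bridged[bridged["rule"].isin(bridge_mod.RULES[:3])]
        pairs, _counts = enrich_mod.genes_near_loci(mapped, genes, window=config.enrich_window)
        enr_summary = {}
        for group, eff in effects_by_group.items():
            for term in ("stage", "trt", "int"):
                scores = enrich_mod.gene_scores(pairs, eff[f"p_{term}"])
                if scores.empty:
                    continue
                res = enrich_mod.gene_score_resampling(
                    scores,
                    go_map,
                    n_resamples=config.n_resamples,
                    min_members=config.min_members,
                    seed=config.seed,
                )
                res.to_csv(out / f"enrichment_{group}_{term}.tsv", sep="\t", index=False)
                enr_summary[f"{group}:{term}"] = int((res["pvalue"] < config.alpha).sum())
        summary["enriched_terms_below_alpha"] = enr_summary
        summary["stages"].append("enrich")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
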