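"""Linkage-group assignment of SNPs through shared genomic scaffolds.

A published marker map (marker_id, scaffold, bp, linkage_group, cM) is used
as a bridge: every SNP on a scaffold carrying mapped markers inherits a
marker's linkage position.  Scaffolds absent from the map, or present on
more than one linkage group, are omitted with a recorded reason.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

RULES = ("one_to_one", "many_to_one", "nearest_of_many", "omitted_no_marker", "omitted_multi_LG")

MAP_COLUMNS = ["marker_id", "scaffold", "position", "linkage_group", "cM"]


def read_linkage_map(path: str | Path) -> pd.DataFrame:
    lmap = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "scaffold": str})
    missing = [c for c in MAP_COLUMNS if c not in lmap.columns]
    if missing:
        raise ValueError(f"linkage map missing columns: {missing}")
    return lmap


def assign_linkage_positions(loci: pd.DataFrame, linkage_map: pd.DataFrame) -> pd.DataFrame:
    """Assign each locus a linkage group and cM position via its scaffold.

    ``loci`` needs columns locus_id, scaffold, position.  Rules:

    * scaffold with one mapped marker -> all its SNPs take that marker's
      position (``one_to_one`` for a single SNP, ``many_to_one`` otherwise);
    * scaffold with several markers on one linkage group -> each SNP takes
      the bp-nearest marker (``nearest_of_many``; equidistant ties resolve
      to the lower-bp marker);
    * scaffold absent from the map or spanning multiple linkage groups ->
      omitted with reason.

    Every input locus appears exactly once in the output.
    """
    if linkage_map["marker_id"].duplicated().any():
        dups = linkage_map.loc[linkage_map["marker_id"].duplicated(), "marker_id"]
        raise ValueError(f"duplicate marker ids in linkage map: {sorted(set(dups))}")

    by_scaffold = {s: sub for s, sub in linkage_map.groupby("scaffold")}
    snps_per_scaffold = loci.groupby("scaffold")["locus_id"].transform("size")

    rows = []
    for (_, locus), n_snps in zip(loci.iterrows(), snps_per_scaffold):
        rec = {
            "locus_id": locus["locus_id"],
            "scaffold": locus["scaffold"],
            "position": locus["position"],
            "linkage_group": np.nan,
            "cM": np.nan,
            "marker_id": None,
            "rule": None,
        }
        markers = by_scaffold.get(locus["scaffold"])
        if markers is None:
            rec["rule"] = "omitted_no_marker"
        elif markers["linkage_group"].nunique() > 1:
            rec["rule"] = "omitted_multi_LG"
        elif len(markers) == 1:
            m = markers.iloc[0]
            rec.update(
                linkage_group=m["linkage_group"],
                cM=m["cM"],
                marker_id=m["marker_id"],
                rule="one_to_one" if n_snps == 1 else "many_to_one",
            )
        else:
            dist = (markers["position"] - locus["position"]).abs()
            # ties resolve to the lower-bp marker
            nearest = markers.loc[
                markers.assign(_d=dist).sort_values(["_d", "position"], kind="stable").index[0]
            ]
            rec.update(
                linkage_group=nearest["linkage_group"],
                cM=nearest["cM"],
                marker_id=nearest["marker_id"],
                rule="nearest_of_many",
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    assert len(out) == len(loci)
    return out


def bh_threshold(pvalues: np.ndarray, fdr: float) -> float:
    """Largest raw p-value called significant by BH step-up at level
    ``fdr``; 0.0 when nothing is called."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[~np.isnan(p)]
    m = p.size
    if m == 0:
        return 0.0
    crit = fdr * np.arange(1, m + 1) / m
    passing = np.flatnonzero(p <= crit)
    if passing.size == 0:
        return 0.0
    return float(p[passing.max()])


def manhattan_table(
    bridged: pd.DataFrame,
    effects: pd.DataFrame,
    terms: tuple[str, ...] = ("stage", "trt"),
    fdr_thresholds: tuple[float, ...] = (0.05, 0.01),
) -> tuple[pd.DataFrame, dict]:
    """Plotting table for mapped loci plus BH significance threshold lines.

    Rows are the successfully assigned loci sorted by (linkage group, cM,
    bp) with ``neg_log10_p_<term>`` columns; loci sharing a (scaffold,
    marker) position are flagged ``co_located``.  Thresholds are expressed
    as the largest raw p called significant at each FDR level, computed per
    term over the mapped loci.
    """
    assigned = bridged[bridged["rule"].isin(RULES[:3])].copy()
    table = assigned.merge(
        effects[[f"p_{t}" for t in terms]].reset_index(names="locus_id"), on="locus_id"
    )
    table = table.sort_values(["linkage_group", "cM", "position"], kind="stable")
    for t in terms:
        with np.errstate(divide="ignore"):
            table[f"neg_log10_p_{t}"] = -np.log10(table[f"p_{t}"])
    dup = table.duplicated(subset=["linkage_group", "cM"], keep=False)
    table["co_located"] = dup
    thresholds = {
        t: {
            str(level): bh_threshold(table[f"p_{t}"].to_numpy(), level)
            for level in fdr_thresholds
        }
        for t in terms
    }
    return table.reset_index(drop=True), thresholds
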