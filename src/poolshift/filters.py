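"""Locus-retention cascade: merged nucleotide counts -> analysis-ready SNP panel.

The filters are applied in a fixed order (depth -> biallelic -> one SNP per
tag -> replicate presence -> minor-allele frequency); each step only changes
membership or missingness, never surviving counts, and every removal is
recorded in an audit trail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from poolshift.counts import NUCLEOTIDES, TAG_LENGTH, CountTable

BASELINE_STAGE = "day2"


@dataclass
class SnpPanel:
    """Filtered biallelic loci with per-sample (c1, c2) read counts.

    ``loci`` is indexed by locus_id with columns scaffold, position, allele1,
    allele2 and one ``baseline_maf_<group>`` column per group (allele2 is the
    minor allele at baseline).  ``c1``/``c2`` are loci x samples count
    matrices (NaN = missing cell); ``samples`` carries the factorial labels.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    c1: pd.DataFrame
    c2: pd.DataFrame
    audit: list = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def groups(self) -> list[str]:
        return sorted(self.samples["group"].unique())

    @property
    def depth(self) -> pd.DataFrame:
        return self.c1 + self.c2

    @property
    def freq(self) -> pd.DataFrame:
        """Allele-2 frequency per (locus, sample); NaN where missing."""
        d = self.depth
        return self.c2 / d.where(d > 0)

    def subset_loci(self, locus_ids, filter_name: str | None = None) -> "SnpPanel":
        locus_ids = [l for l in self.loci.index if l in set(locus_ids)]
        audit = list(self.audit)
        if filter_name is not None:
            audit.append(
                {
                    "filter": filter_name,
                    "loci_in": self.n_loci,
                    "loci_removed": self.n_loci - len(locus_ids),
                }
            )
        return SnpPanel(
            loci=self.loci.loc[locus_ids].copy(),
            samples=self.samples.copy(),
            c1=self.c1.loc[locus_ids].copy(),
            c2=self.c2.loc[locus_ids].copy(),
            audit=audit,
        )

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.loci.to_csv(path / "loci.tsv", sep="\t")
        self.samples.to_csv(path / "samples.tsv", sep="\t")
        long = (
            pd.concat(
                {
                    "c1": self.c1.stack(future_stack=True),
                    "c2": self.c2.stack(future_stack=True),
                },
                axis=1,
            )
            .rename_axis(["locus_id", "sample_id"])
            .dropna(how="all")
            .reset_index()
        )
        long.to_csv(path / "counts.tsv", sep="\t", index=False)
        with open(path / "audit.json", "w") as fh:
            json.dump(self.audit, fh, indent=2)

    @classmethod
    def from_dir(cls, path: str | Path) -> "SnpPanel":
        path = Path(path)
        loci = pd.read_csv(path / "loci.tsv", sep="\t", index_col=0, dtype={"scaffold": str})
        loci.index = loci.index.astype(str)
        samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        long = pd.read_csv(
            path / "counts.tsv", sep="\t", dtype={"locus_id": str, "sample_id": str}
        )
        c1 = long.pivot(index="locus_id", columns="sample_id", values="c1")
        c2 = long.pivot(index="locus_id", columns="sample_id", values="c2")
        c1 = c1.reindex(index=loci.index, columns=samples.index)
        c2 = c2.reindex(index=loci.index, columns=samples.index)
        audit_path = path / "audit.json"
        audit = json.loads(audit_path.read_text()) if audit_path.exists() else []
        return cls(loci=loci, samples=samples, c1=c1, c2=c2, audit=audit)


def depth_filter(
    counts: CountTable, min_depth: int = 50, max_depth: int = 1000
) -> CountTable:
    """Mark cells with total depth outside [min_depth, max_depth] missing.

    Missing cells are dropped rows; loci with no surviving cell disappear.
    """
    if min_depth >= max_depth:
        raise ValueError(f"min_depth ({min_depth}) must be < max_depth ({max_depth})")
    depth = counts.depth
    keep = (depth >= min_depth) & (depth <= max_depth)
    return CountTable(counts.df[keep].reset_index(drop=True))


def _nucleotide_totals(counts: CountTable) -> pd.DataFrame:
    """Per-locus total reads of each nucleotide summed across samples."""
    cols = [f"count{n}" for n in NUCLEOTIDES]
    return counts.df.groupby("locus_id")[cols].sum()


def biallelic_filter(counts: CountTable, min_allele_reads: int = 1) -> CountTable:
    """Drop loci where more than two nucleotides reach ``min_allele_reads``."""
    totals = _nucleotide_totals(counts)
    n_alleles = (totals >= min_allele_reads).sum(axis=1)
    keep_loci = set(n_alleles[n_alleles <= 2].index)
    keep = counts.df["locus_id"].isin(keep_loci)
    return CountTable(counts.df[keep].reset_index(drop=True))


def build_panel(counts: CountTable) -> SnpPanel:
    """Construct a biallelic panel from a (filtered) count table.

    allele1/allele2 are the two most abundant nucleotides overall; the pair
    is then oriented so that allele2 is the minor allele at baseline
    (earliest stage, both groups and treatments combined, read-count
    weighted) and held fixed thereafter.
    """
    df = counts.df
    samples = (
        df[["sample_id", "group", "stage", "treatment", "replicate"]]
        .drop_duplicates()
        .set_index("sample_id")
        .sort_index()
    )
    loci_meta = (
        df[["locus_id", "scaffold", "position"]]
        .drop_duplicates()
        .set_index("locus_id")
        .sort_values(["scaffold", "position"])
    )
    locus_ids = loci_meta.index

    pivots = np.stack(
        [
            df.pivot(index="locus_id", columns="sample_id", values=f"count{n}")
            .reindex(index=locus_ids, columns=samples.index)
            .to_numpy()
            for n in NUCLEOTIDES
        ]
    )  # (4, L, S), NaN = missing cell

    totals = np.nansum(pivots, axis=2)  # (4, L)
    # Stable argsort on descending totals: alphabetical order breaks ties.
    order = np.argsort(-totals, axis=0, kind="stable")
    a1_idx, a2_idx = order[0], order[1]

    baseline_mask = (samples["stage"] == BASELINE_STAGE).to_numpy()
    base_counts = np.nansum(pivots[:, :, baseline_mask], axis=2)  # (4, L)
    L = len(locus_ids)
    swap = base_counts[a2_idx, np.arange(L)] > base_counts[a1_idx, np.arange(L)]
    a1_idx, a2_idx = np.where(swap, a2_idx, a1_idx), np.where(swap, a1_idx, a2_idx)

    c1 = pivots[a1_idx, np.arange(L), :]
    c2 = pivots[a2_idx, np.arange(L), :]

    loci = loci_meta.copy()
    loci["allele1"] = np.array(NUCLEOTIDES)[a1_idx]
    loci["allele2"] = np.array(NUCLEOTIDES)[a2_idx]

    c1 = pd.DataFrame(c1, index=locus_ids, columns=samples.index)
    c2 = pd.DataFrame(c2, index=locus_ids, columns=samples.index)

    for group in sorted(samples["group"].unique()):
        gmask = ((samples["group"] == group) & (samples["stage"] == BASELINE_STAGE)).to_numpy()
        tot2 = np.nansum(c2.to_numpy()[:, gmask], axis=1)
        tot = np.nansum(c1.to_numpy()[:, gmask] + c2.to_numpy()[:, gmask], axis=1)
        with np.errstate(invalid="ignore"):
            f2 = np.where(tot > 0, tot2 / np.maximum(tot, 1), np.nan)
        # allele-2 orientation is fixed across groups, so a single group's
        # allele-2 frequency may exceed 0.5; the group MAF is the folded value
        loci[f"baseline_f2_{group}"] = f2
        loci[f"baseline_maf_{group}"] = np.minimum(f2, 1.0 - f2)

    return SnpPanel(loci=loci, samples=samples, c1=c1, c2=c2, audit=[])


def one_snp_per_tag(panel: SnpPanel) -> SnpPanel:
    """Keep at most one SNP per 36-bp tag on each scaffold.

    Selection: highest total read depth across samples, then lowest position.
    """
    meta = panel.loci.copy()
    meta["tag"] = (meta["position"] - 1) // TAG_LENGTH
    meta["total_depth"] = panel.depth.sum(axis=1, skipna=True)
    meta = meta.sort_values(
        ["scaffold", "tag", "total_depth", "position"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    keep = meta.drop_duplicates(subset=["scaffold", "tag"], keep="first").index
    return panel.subset_loci(keep, "one_snp_per_tag")


def replicate_presence_filter(
    panel: SnpPanel, min_reps: int = 3, groups: str = "both"
) -> SnpPanel:
    """Retain loci with >= min_reps non-missing replicates in every
    stage x treatment cell.

    ``groups='both'`` requires the predicate in every group of the panel;
    ``groups='any'`` in at least one group; a group name restricts the test
    to that group.
    """
    samples = panel.samples
    present = panel.depth.to_numpy() >= 1  # NaN-safe: NaN >= 1 is False
    group_ok = {}
    for group in panel.groups:
        ok = np.ones(panel.n_loci, dtype=bool)
        gsub = samples[samples["group"] == group]
        for (_, _), cell in gsub.groupby(["stage", "treatment"]):
            cols = [panel.samples.index.get_loc(s) for s in cell.index]
            ok &= present[:, cols].sum(axis=1) >= min_reps
        group_ok[group] = ok
    if groups == "both":
        keep_mask = np.logical_and.reduce(list(group_ok.values()))
    elif groups == "any":
        keep_mask = np.logical_or.reduce(list(group_ok.values()))
    elif groups in group_ok:
        keep_mask = group_ok[groups]
    else:
        raise ValueError(f"unknown groups mode {groups!r}")
    keep = panel.loci.index[keep_mask]
    return panel.subset_loci(keep, f"replicate_presence(min_reps={min_reps},groups={groups})")


def maf_filter(panel: SnpPanel, min_maf: float = 0.01) -> SnpPanel:
    """Retain loci with baseline MAF strictly above ``min_maf`` in at least
    one group."""
    maf_cols = [c for c in panel.loci.columns if c.startswith("baseline_maf_")]
    mafs = panel.loci[maf_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        keep_mask = np.nanmax(np.where(np.isnan(mafs), -np.inf, mafs), axis=1) > min_maf
    keep = panel.loci.index[keep_mask]
    return panel.subset_loci(keep, f"maf(min_maf={min_maf})")


def run_filter_cascade(
    counts: CountTable,
    min_depth: int = 50,
    max_depth: int = 1000,
    min_allele_reads: int = 1,
    min_reps: int = 3,
    min_maf: float = 0.01,
    groups: str = "both",
) -> SnpPanel:
    """Apply the full cascade in the canonical order and return the panel."""
    audit = []
    n0 = counts.df["locus_id"].nunique()
    counts = depth_filter(counts, min_depth, max_depth)
    n1 = counts.df["locus_id"].nunique()
    audit.append(
        {"filter": f"depth([{min_depth},{max_depth}])", "loci_in": n0, "loci_removed": n0 - n1}
    )
    counts = biallelic_filter(counts, min_allele_reads)
    n2 = counts.df["locus_id"].nunique()
    audit.append({"filter": "biallelic", "loci_in": n1, "loci_removed": n1 - n2})
    panel = build_panel(counts)
    panel.audit = audit
    panel = one_snp_per_tag(panel)
    panel = replicate_presence_filter(panel, min_reps=min_reps, groups=groups)
    panel = maf_filter(panel, min_maf=min_maf)
    return panel
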