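"""Gene-proximity annotation and gene-score-resampling GO enrichment.

Loci are linked to genes whose annotated intervals overlap a +/-5 kb window
around the SNP.  Each gene's score is the best (minimum) p-value over its
loci, transformed to -log10(p); a GO term's statistic is the mean score of
its member genes and its empirical p-value comes from resampling random
gene sets of equal size from the scored universe.  A simplified
multifunctionality score (normalized rank of GO membership counts) is
attached as a diagnostic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

_P_FLOOR = 1e-300


def read_gff_genes(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene features from a GFF3 file: gene_id, scaffold, start, end."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = [
        {"gene_id": feat.id, "scaffold": feat.seqid, "start": feat.start, "end": feat.end}
        for feat in db.features_of_type(feature_type)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def read_gene_go_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, go_id; one pair per row) -> gene -> GO set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"], dtype=str)
    return {g: set(sub["go_id"]) for g, sub in df.groupby("gene_id")}


def genes_near_loci(
    loci: pd.DataFrame, genes: pd.DataFrame, window: int = 5000
) -> tuple[pd.DataFrame, pd.Series]:
    """Locus-gene pairs where the gene interval overlaps
    [position - window, position + window] (closed, 1-based).

    ``loci`` needs locus_id, scaffold, position; ``genes`` needs gene_id,
    scaffold, start, end.  Loci on scaffolds without annotations yield no
    rows; a per-locus gene count (including zeros) accompanies the pairs.
    """
    pairs = loci[["locus_id", "scaffold", "position"]].merge(genes, on="scaffold")
    hit = (pairs["end"] >= pairs["position"] - window) & (
        pairs["start"] <= pairs["position"] + window
    )
    pairs = pairs[hit][["locus_id", "gene_id", "scaffold", "position", "start", "end"]]
    counts = (
        pairs.groupby("locus_id")["gene_id"]
        .size()
        .reindex(loci["locus_id"], fill_value=0)
        .rename("n_genes")
    )
    return pairs.reset_index(drop=True), counts


def gene_scores(locus_genes: pd.DataFrame, pvalues: pd.Series) -> pd.Series:
    """Gene score = minimum p over the gene's loci (dropping NaN p)."""
    merged = locus_genes.merge(
        pvalues.rename("p").rename_axis("locus_id").reset_index(), on="locus_id"
    ).dropna(subset=["p"])
    return merged.groupby("gene_id")["p"].min()


def multifunctionality_scores(go_map: dict[str, set[str]]) -> pd.Series:
    """Gene multifunctionality in [0, 1]: normalized mid-rank of the number
    of GO memberships (0 = most specific, 1 = most multifunctional)."""
    genes = sorted(go_map)
    counts = np.array([len(go_map[g]) for g in genes], dtype=float)
    n = len(genes)
    if n == 0:
        return pd.Series(dtype=float)
    if n == 1:
        return pd.Series([0.5], index=genes)
    ranks = rankdata(counts, method="average")
    return pd.Series((ranks - 1.0) / (n - 1.0), index=genes, name="mf")


def _null_means(scores: np.ndarray, k: int, n_resamples: int, rng: np.random.Generator) -> np.ndarray:
    """Means of ``n_resamples`` random k-subsets drawn without replacement."""
    G = scores.size
    out = np.empty(n_resamples)
    block = max(1, int(5e6 // max(G, 1)))
    pos = 0
    while pos < n_resamples:
        b = min(block, n_resamples - pos)
        keys = rng.random((b, G))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[pos : pos + b] = scores[idx].mean(axis=1)
        pos += b
    return out


def gene_score_resampling(
    scores: pd.Series,
    go_map: dict[str, set[str]],
    go_names: dict[str, str] | None = None,
    n_resamples: int = 10_000,
    min_members: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical GO-term enrichment by resampling of gene scores.

    ``scores`` maps gene -> p-value; only genes present there form the
    resampling universe.  For each term with >= ``min_members`` scored
    genes, the observed statistic is the mean -log10(p) of its members and
    the empirical p-value is (1 + #{null >= observed}) / (n_resamples + 1).
    Terms with fewer scored members are skipped (reported separately via
    the returned frame's attrs).
    """
    rng = np.random.default_rng(seed)
    universe = scores.index.to_numpy()
    s = -np.log10(np.maximum(scores.to_numpy(dtype=float), _P_FLOOR))
    score_of = dict(zip(universe, s))

    terms: dict[str, list[str]] = {}
    for gene, gos in go_map.items():
        if gene not in score_of:
            continue
        for go in gos:
            terms.setdefault(go, []).append(gene)

    tested = {go: members for go, members in terms.items() if len(members) >= min_members}
    skipped = sorted(set(terms) - set(tested))

    mf = multifunctionality_scores(go_map)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for go in sorted(tested):
        members = tested[go]
        k = len(members)
        obs = float(np.mean([score_of[g] for g in members]))
        if k not in null_cache:
            null_cache[k] = _null_means(s, k, n_resamples, rng)
        null = null_cache[k]
        tol = 1e-9 * max(1.0, abs(obs))
        p_emp = (1.0 + int((null >= obs - tol).sum())) / (n_resamples + 1.0)
        rows.append(
            {
                "go_id": go,
                "name": (go_names or {}).get(go, ""),
                "n_genes": k,
                "score": obs,
                "pvalue": p_emp,
                "mf": float(mf.reindex(members).mean()),
            }
        )
    result = pd.DataFrame(
        rows, columns=["go_id", "name", "n_genes", "score", "pvalue", "mf"]
    ).sort_values("pvalue", kind="stable", ignore_index=True)
    result.attrs["skipped_terms"] = skipped
    result.attrs["n_resamples"] = n_resamples
    result.attrs["universe_size"] = int(universe.size)
    return result
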