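"""Pool-adapted diversity and differentiation statistics.

All estimators work directly on read counts: the allele frequency in a pool
is the read fraction f = c2 / (c1 + c2), nucleotide diversity uses a
read-depth finite-sample correction D/(D-1), and pairwise FST is the
heterozygosity-based (Hudson/Wright) form on pooled group frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from poolshift.filters import SnpPanel


def allele_frequencies(panel: SnpPanel, level: str = "replicate") -> pd.DataFrame:
    """Allele-2 frequency matrix (loci x units) at the requested level.

    ``level='replicate'`` returns one column per sample; ``'cell'`` pools
    replicates read-count-weighted within each group x stage x treatment
    cell; ``'group'`` pools everything within a group.
    """
    if level == "replicate":
        return panel.freq
    if level == "cell":
        keys = ["group", "stage", "treatment"]
    elif level == "group":
        keys = ["group"]
    else:
        raise ValueError(f"unknown level {level!r}")
    out = {}
    for key, cell in panel.samples.groupby(keys):
        label = key if isinstance(key, str) else ":".join(map(str, key))
        cols = cell.index
        num = panel.c2[cols].sum(axis=1, skipna=True)
        den = panel.c1[cols].sum(axis=1, skipna=True) + num
        out[label] = num / den.where(den > 0)
    return pd.DataFrame(out)


def nucleotide_diversity(
    panel: SnpPanel,
    sample_ids=None,
    depth_correction: bool = True,
) -> tuple[pd.Series, float]:
    """Per-locus nucleotide diversity and its mean over loci.

    Per sample, pi = (D/(D-1)) * 2*f*(1-f); cells with depth < 2 are
    excluded; the per-locus value averages samples in scope.  With
    ``depth_correction=False`` the raw 2*f*(1-f) is used.
    """
    cols = list(sample_ids) if sample_ids is not None else list(panel.samples.index)
    d = panel.depth[cols].to_numpy(dtype=float)
    c2 = panel.c2[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = c2 / d
        pi = 2.0 * f * (1.0 - f)
        if depth_correction:
            pi = pi * d / (d - 1.0)
    pi = np.where(d >= 2, pi, np.nan)
    with np.errstate(invalid="ignore"):
        per_locus = np.nanmean(pi, axis=1)
    series = pd.Series(per_locus, index=panel.loci.index, name="pi")
    return series, float(np.nanmean(per_locus))


def _pooled_freq(panel: SnpPanel, sample_ids) -> np.ndarray:
    c2 = panel.c2[list(sample_ids)].sum(axis=1, skipna=True).to_numpy(dtype=float)
    d = panel.depth[list(sample_ids)].sum(axis=1, skipna=True).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d > 0, c2 / np.maximum(d, 1), np.nan)


def fst_from_freqs(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Per-SNP heterozygosity-based FST = (HT - mean(HS)) / HT.

    HS = 2f(1-f) within each group, HT = 2*fbar*(1-fbar) with fbar the
    unweighted mean of the two group frequencies.  SNPs with HT = 0 are NaN.
    Negative values are retained.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    hs = (2 * fa * (1 - fa) + 2 * fb * (1 - fb)) / 2.0
    fbar = (fa + fb) / 2.0
    ht = 2 * fbar * (1 - fbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (ht - hs) / ht
    return np.where(ht > 0, fst, np.nan)


def pairwise_fst(
    panel: SnpPanel, sample_ids_a, sample_ids_b
) -> tuple[pd.Series, float]:
    """Per-SNP FST between two pooled sample sets, plus the mean over
    informative SNPs (HT > 0)."""
    if len(list(sample_ids_a)) == 0 or len(list(sample_ids_b)) == 0:
        raise ValueError("empty sample group")
    fa = _pooled_freq(panel, sample_ids_a)
    fb = _pooled_freq(panel, sample_ids_b)
    fst = fst_from_freqs(fa, fb)
    series = pd.Series(fst, index=panel.loci.index, name="fst")
    informative = fst[~np.isnan(fst)]
    mean = float(informative.mean()) if informative.size else float("nan")
    return series, mean


def bootstrap_ci(
    per_snp_stat,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling loci with replacement.

    NaN entries (uninformative SNPs) are dropped before resampling.
    """
    values = np.asarray(per_snp_stat, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no informative values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


def fold(freqs) -> np.ndarray:
    """Fold allele frequencies onto the minor-allele spectrum [0, 0.5]."""
    f = np.asarray(freqs, dtype=float)
    return np.minimum(f, 1.0 - f)


def sfs_compare(freqs_a, freqs_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on folded MAF spectra."""
    fa = fold(freqs_a)
    fb = fold(freqs_b)
    fa = fa[~np.isnan(fa)]
    fb = fb[~np.isnan(fb)]
    res = stats.ks_2samp(fa, fb, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    n_imputed: int


def replicate_pca(freq_matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of replicate allele-frequency profiles (samples as observations).

    Loci (rows of ``freq_matrix``) are variables; missing cells are
    mean-imputed per locus before the column-centered SVD.  Explained
    variance fractions sum to 1 over all non-trivial components.
    """
    X = freq_matrix.to_numpy(dtype=float).T  # samples x loci
    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        col_means = np.nanmean(X, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        X = np.where(np.isnan(X), col_means[None, :], X)
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    k = n_components or len(s)
    scores = pd.DataFrame(
        (u * s)[:, :k],
        index=freq_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(min(k, len(s)))],
    )
    return PcaResult(scores=scores, explained_variance_ratio=ratio[:k], n_imputed=n_imputed)


def popgen_summary(
    panel: SnpPanel,
    group_a: str,
    group_b: str,
    stage: str = "day2",
    treatment: str = "ambient",
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Group comparison at one design cell: mean MAF, pi, FST with CI, K-S.

    Declares the SNP set used (all loci currently in the panel) in the
    output metadata.
    """
    samples = panel.samples
    sel = (samples["stage"] == stage) & (samples["treatment"] == treatment)
    ids_a = samples.index[sel & (samples["group"] == group_a)]
    ids_b = samples.index[sel & (samples["group"] == group_b)]
    fa = _pooled_freq(panel, ids_a)
    fb = _pooled_freq(panel, ids_b)
    per_snp_fst, mean_fst = pairwise_fst(panel, ids_a, ids_b)
    fst_lo, fst_hi = bootstrap_ci(per_snp_fst, n_boot=n_boot, seed=seed)
    pi_a = nucleotide_diversity(panel, ids_a)[1]
    pi_b = nucleotide_diversity(panel, ids_b)[1]
    ks_stat, ks_p = sfs_compare(fa, fb)
    return {
        "snp_set": {"n_loci": panel.n_loci, "audit": panel.audit},
        "cell": {"stage": stage, "treatment": treatment},
        "mean_maf": {
            group_a: float(np.nanmean(fold(fa))),
            group_b: float(np.nanmean(fold(fb))),
        },
        "mean_pi": {group_a: pi_a, group_b: pi_b},
        "fst": {"mean": mean_fst, "ci95": [fst_lo, fst_hi], "n_boot": n_boot},
        "sfs_ks": {"statistic": ks_stat, "pvalue": ks_p},
    }
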