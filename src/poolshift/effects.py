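"""Per-locus binomial GLMs with type III tests and effect classification.

For each locus the allele-2 read count is modelled as binomial with a
logit link and the full model ``Stage + Trt + Stage:Trt`` under sum-to-zero
contrasts.  Type III p-values come from likelihood-ratio tests comparing the
full model to the model with only that term removed (main effects are tested
with the interaction retained).  p-values are BH-adjusted per term across
loci, and each locus is assigned one exclusive category:

    Stage*Trt  if q_int < alpha
    Stage+Trt  elif q_stage < alpha and q_trt < alpha
    Stage      elif q_stage < alpha
    Trt        elif q_trt < alpha
    None       otherwise

The GLM solver is a vectorized iteratively-reweighted least squares run
across all loci simultaneously; it is validated in the test suite against
statsmodels fits locus by locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from poolshift.filters import SnpPanel

TERMS = ("stage", "trt", "int")
CATEGORY_LEVELS = ("None", "Stage", "Trt", "Stage+Trt", "Stage*Trt")

_MU_EPS = 1e-12


def design_matrix(samples: pd.DataFrame) -> np.ndarray:
    """Sum-to-zero design: intercept, stage, trt, stage:trt columns.

    Stage and treatment levels are coded -1/+1 in sorted-label order
    (day2=-1/day22=+1, ambient=-1/high=+1 with the default labels).
    """
    stage_levels = sorted(samples["stage"].unique())
    trt_levels = sorted(samples["treatment"].unique())
    if len(stage_levels) != 2 or len(trt_levels) != 2:
        raise ValueError("design requires exactly two stages and two treatments")
    s = np.where(samples["stage"] == stage_levels[1], 1.0, -1.0)
    t = np.where(samples["treatment"] == trt_levels[1], 1.0, -1.0)
    return np.column_stack([np.ones_like(s), s, t, s * t])


def binomial_deviance(Y: np.ndarray, N: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Summed binomial deviance per locus; 0*log(0) treated as 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(Y > 0, Y * np.log(Y / (N * mu)), 0.0)
        F = N - Y
        t2 = np.where(F > 0, F * np.log(F / (N * (1.0 - mu))), 0.0)
    t1 = np.where(N > 0, t1, 0.0)
    t2 = np.where(N > 0, t2, 0.0)
    return 2.0 * (t1 + t2).sum(axis=1)


def irls_binomial(
    Y: np.ndarray,
    N: np.ndarray,
    X: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``L`` binomial GLMs sharing one design matrix in a single batch.

    Parameters
    ----------
    Y, N : (L, S) arrays
        Successes and trials; cells with N = 0 carry zero weight (missing).
    X : (S, p) array

    Returns
    -------
    beta : (L, p), deviance : (L,), converged : (L,) bool
    """
    Y = np.asarray(Y, dtype=float)
    N = np.asarray(N, dtype=float)
    L, S = Y.shape
    p = X.shape[1]
    beta = np.zeros((L, p))
    ytot = Y.sum(axis=1)
    ntot = N.sum(axis=1)
    beta[:, 0] = np.log((ytot + 0.5) / (ntot - ytot + 0.5))
    dev = np.full(L, np.inf)
    converged = np.zeros(L, dtype=bool)
    active = np.ones(L, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta[active] @ X.T
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _MU_EPS, 1.0 - _MU_EPS)
        W = N[active] * mu * (1.0 - mu)
        resid = Y[active] - N[active] * mu
        with np.errstate(divide="ignore", invalid="ignore"):
            z = eta + np.where(W > 0, resid / np.maximum(W, _MU_EPS), 0.0)
        A = np.einsum("si,ls,sj->lij", X, W, X)
        A += np.eye(p)[None, :, :] * 1e-10  # guard against exact singularity
        b = np.einsum("si,ls->li", X, W * z)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        eta_new = beta_new @ X.T
        mu_new = np.clip(1.0 / (1.0 + np.exp(-eta_new)), _MU_EPS, 1.0 - _MU_EPS)
        dev_new = binomial_deviance(Y[active], N[active], mu_new)

        idx = np.flatnonzero(active)
        done = np.abs(dev[idx] - dev_new) < tol * (np.abs(dev_new) + 1.0)
        beta[idx] = beta_new
        dev[idx] = dev_new
        converged[idx[done]] = True
        active[idx[done]] = False

    bad = ~np.isfinite(dev)
    converged[bad] = False
    return beta, dev, converged


def fit_group_glms(panel: SnpPanel, group: str) -> pd.DataFrame:
    """Fit the full factorial GLM and type III LR tests for one group.

    Returns a per-locus frame with logit-scale coefficient estimates
    (``beta_stage``, ``beta_trt``, ``beta_int``), deviances, type III
    p-values (``p_stage``, ``p_trt``, ``p_int``) and a convergence flag.
    Loci whose counts are all-allele1 or all-allele2 in every cell are
    degenerate: coefficients NaN, p NaN, flagged unconverged.
    """
    samples = panel.samples[panel.samples["group"] == group]
    if samples.empty:
        raise ValueError(f"no samples in group {group!r}")
    X = design_matrix(samples)
    cols = list(samples.index)
    Y = panel.c2[cols].to_numpy(dtype=float)
    N = panel.depth[cols].to_numpy(dtype=float)
    Y = np.where(np.isnan(N), 0.0, Y)
    N = np.where(np.isnan(N), 0.0, N)

    degenerate = (Y.sum(axis=1) == 0) | (Y.sum(axis=1) == N.sum(axis=1))

    beta, dev_full, conv_full = irls_binomial(Y, N, X)
    out = pd.DataFrame(index=panel.loci.index)
    out["beta_intercept"] = beta[:, 0]
    out["beta_stage"] = beta[:, 1]
    out["beta_trt"] = beta[:, 2]
    out["beta_int"] = beta[:, 3]
    out["deviance_full"] = dev_full

    converged = conv_full.copy()
    for term, col in zip(TERMS, (1, 2, 3)):
        X_red = np.delete(X, col, axis=1)
        _, dev_red, conv_red = irls_binomial(Y, N, X_red)
        lr = np.maximum(dev_red - dev_full, 0.0)
        out[f"lr_{term}"] = lr
        out[f"p_{term}"] = stats.chi2.sf(lr, df=1)
        converged &= conv_red

    converged &= ~degenerate
    for term in TERMS:
        out.loc[~converged, f"p_{term}"] = np.nan
    out.loc[degenerate, ["beta_stage", "beta_trt", "beta_int"]] = np.nan
    out["converged"] = converged
    out["group"] = group
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN inputs stay NaN and are excluded
    from the family."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def classify_effects(
    results: pd.DataFrame, alpha: float = 0.05, family: str = "per_term"
) -> pd.DataFrame:
    """Attach BH q-values and the exclusive effect category to GLM results.

    ``family='per_term'`` (default) runs one BH family per term across loci;
    ``'pooled'`` uses a single family over all three terms.  Non-converged
    loci have NaN p-values and are excluded from the families; their
    category is ``None``.
    """
    out = results.copy()
    if family == "per_term":
        for term in TERMS:
            out[f"q_{term}"] = bh_adjust(out[f"p_{term}"].to_numpy())
    elif family == "pooled":
        stacked = np.concatenate([out[f"p_{term}"].to_numpy() for term in TERMS])
        q = bh_adjust(stacked)
        n = len(out)
        for i, term in enumerate(TERMS):
            out[f"q_{term}"] = q[i * n : (i + 1) * n]
    else:
        raise ValueError(f"unknown BH family scheme {family!r}")

    sig = {term: out[f"q_{term}"].to_numpy() < alpha for term in TERMS}  # NaN -> False
    category = np.full(len(out), "None", dtype=object)
    category[sig["trt"]] = "Trt"
    category[sig["stage"]] = "Stage"
    category[sig["stage"] & sig["trt"]] = "Stage+Trt"
    category[sig["int"]] = "Stage*Trt"
    out["category"] = pd.Categorical(category, categories=list(CATEGORY_LEVELS))
    out["interaction_sign"] = np.where(
        out["category"] == "Stage*Trt", np.where(out["beta_int"] < 0, "-", "+"), "n/a"
    )
    return out


def read_effects(path) -> pd.DataFrame:
    """Read an effect-result TSV written by the pipeline.

    The literal category label "None" must not be parsed as missing data.
    """
    out = pd.read_csv(path, sep="\t", index_col=0)
    out.index = out.index.astype(str)
    out["category"] = pd.Categorical(
        out["category"].fillna("None"), categories=list(CATEGORY_LEVELS)
    )
    if "interaction_sign" in out.columns:
        out["interaction_sign"] = out["interaction_sign"].fillna("n/a")
    return out


@dataclass
class CategoryCrosstab:
    """Cross-tabulation of effect categories between two groups."""

    matrix: pd.DataFrame  # rows: group_a category, cols: group_b category
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        self.matrix = self.matrix.reindex(
            index=list(CATEGORY_LEVELS), columns=list(CATEGORY_LEVELS), fill_value=0
        ).astype(int)

    @classmethod
    def from_effects(
        cls, effects_a: pd.DataFrame, effects_b: pd.DataFrame, group_a: str, group_b: str
    ) -> "CategoryCrosstab":
        merged = effects_a[["category"]].join(
            effects_b[["category"]], lsuffix="_a", rsuffix="_b", how="inner"
        )
        matrix = pd.crosstab(merged["category_a"], merged["category_b"], dropna=False)
        return cls(matrix=matrix, group_a=group_a, group_b=group_b)

    @classmethod
    def from_matrix(cls, matrix, group_a: str, group_b: str) -> "CategoryCrosstab":
        df = pd.DataFrame(
            np.asarray(matrix, dtype=int),
            index=list(CATEGORY_LEVELS),
            columns=list(CATEGORY_LEVELS),
        )
        return cls(matrix=df, group_a=group_a, group_b=group_b)

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def margins(self, which: str) -> pd.Series:
        """Category totals for ``group_a`` (row sums) or ``group_b``."""
        if which == self.group_a:
            return self.matrix.sum(axis=1)
        if which == self.group_b:
            return self.matrix.sum(axis=0)
        raise KeyError(which)

    def significance_table(self) -> pd.DataFrame:
        """2 x 2 collapsing: significant (any category) vs None, by group."""
        rows = {}
        for g in (self.group_a, self.group_b):
            m = self.margins(g)
            rows[g] = {"significant": int(m.drop("None").sum()), "none": int(m["None"])}
        return pd.DataFrame(rows).T

    def chi_square(self, collapsing: str = "sig_vs_not") -> dict:
        """Chi-square comparison of the category distributions of the two
        groups.

        ``collapsing='sig_vs_not'`` (default) tests the 2x2
        significant-vs-None table; ``'full'`` tests the full 2x5 table of
        margins.
        """
        if collapsing == "sig_vs_not":
            table = self.significance_table().to_numpy()
        elif collapsing == "full":
            table = np.vstack(
                [self.margins(self.group_a).to_numpy(), self.margins(self.group_b).to_numpy()]
            )
        else:
            raise ValueError(f"unknown collapsing {collapsing!r}")
        stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return {"statistic": float(stat), "df": int(dof), "pvalue": float(p), "collapsing": collapsing}


def crosstab_categories(
    effects_a: pd.DataFrame,
    effects_b: pd.DataFrame,
    group_a: str = "MBP",
    group_b: str = "wild",
    collapsing: str = "sig_vs_not",
) -> tuple[CategoryCrosstab, dict]:
    """Cross-tabulate per-locus categories of two groups and compare them."""
    ct = CategoryCrosstab.from_effects(effects_a, effects_b, group_a, group_b)
    return ct, ct.chi_square(collapsing)


def interaction_sign_summary(effects: pd.DataFrame) -> float:
    """Fraction of Stage*Trt loci with a negative interaction coefficient.

    NaN when the group has no interaction-classified loci.
    """
    inter = effects[effects["category"] == "Stage*Trt"]
    if inter.empty:
        return float("nan")
    return float((inter["beta_int"] < 0).mean())
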