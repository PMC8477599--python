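"""Synthetic pooled-sequencing count data with known ground truth.

Generates biallelic read-count tables under a 2 groups x 2 stages x
2 treatments x n replicates factorial design.  Each locus belongs to one of
five generating categories — ``none``, ``stage``, ``trt``, ``additive``,
``interaction`` — and its true pool frequency in each design cell is

    inverse_logit( logit(f0) + d_stage*I[late stage]
                             + d_trt*I[high treatment]
                             + d_int*I[late]*I[high] )

Replicate pools first draw ``2 * pool_size`` allele copies binomially
(drift), then reads binomially at a depth sampled from a truncated
log-normal.  ``pool_size=None`` disables the drift layer, giving pure
binomial read sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from poolshift.counts import COUNT_COLUMNS, NUCLEOTIDES, TAG_LENGTH, CountTable

CATEGORIES = ("none", "stage", "trt", "additive", "interaction")

#: Analysis-side category labels corresponding to each generating category.
EXPECTED_CALL = {
    "none": "None",
    "stage": "Stage",
    "trt": "Trt",
    "additive": "Stage+Trt",
    "interaction": "Stage*Trt",
}

GROUPS = ("MBP", "wild")
STAGES = ("day2", "day22")
TREATMENTS = ("ambient", "high")


def _default_props() -> dict:
    return {"none": 0.66, "stage": 0.10, "trt": 0.08, "additive": 0.08, "interaction": 0.08}


def _default_effects() -> dict:
    return {"stage": 1.5, "trt": 1.5, "additive": 1.5, "interaction": 1.5}


@dataclass
class SimParams:
    """Parameters of the factorial pool-seq simulation.

    ``prop_category`` must sum to 1; ``depth_bounds`` is the truncation
    window of the log-normal depth distribution; ``pool_size`` is the number
    of individuals per replicate pool (``None`` = infinite pool, no drift).
    """

    n_loci: int
    n_reps: int = 5
    prop_category: dict = field(default_factory=_default_props)
    effect_logit: dict = field(default_factory=_default_effects)
    founder_maf_beta: tuple[float, float] = (2.0, 8.0)
    depth_lognorm: tuple[float, float] = (np.log(200.0), 0.4)
    depth_bounds: tuple[int, int] = (50, 1000)
    pool_size: int | None = None
    loci_per_scaffold: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_reps < 1:
            raise ValueError("n_loci and n_reps must be positive")
        extra = set(self.prop_category) - set(CATEGORIES)
        if extra:
            raise ValueError(f"unknown categories: {extra}")
        total = sum(self.prop_category.get(c, 0.0) for c in CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        a, b = self.founder_maf_beta
        if a <= 0 or b <= 0:
            raise ValueError("founder MAF Beta parameters must be positive")
        lo, hi = self.depth_bounds
        if not (1 <= lo < hi <= 1000):
            raise ValueError("depth bounds must satisfy 1 <= lo < hi <= 1000")
        if self.pool_size is not None and self.pool_size < 1:
            raise ValueError("pool_size must be >= 1 (or None for infinite)")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.prop_category.get(c, 0.0) for c in CATEGORIES])


def _draw_truth(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_loci
    category = rng.choice(CATEGORIES, size=n, p=params.proportions)
    # Founder minor-allele frequency: Beta draw folded into (0, 0.5].
    f0 = rng.beta(*params.founder_maf_beta, size=n)
    for _ in range(100):
        bad = (f0 <= 0.0) | (f0 >= 1.0)
        if not bad.any():
            break
        f0[bad] = rng.beta(*params.founder_maf_beta, size=int(bad.sum()))
    else:
        raise ValueError("founder MAF distribution puts mass at 0 or 1")
    f0 = np.minimum(f0, 1.0 - f0)

    signs = rng.choice([-1.0, 1.0], size=(n, 3))
    mag = {c: params.effect_logit.get(c, 0.0) for c in CATEGORIES}
    d_stage = np.where(
        category == "stage",
        signs[:, 0] * mag["stage"],
        np.where(category == "additive", signs[:, 0] * mag["additive"], 0.0),
    )
    d_trt = np.where(
        category == "trt",
        signs[:, 1] * mag["trt"],
        np.where(category == "additive", signs[:, 1] * mag["additive"], 0.0),
    )
    d_int = np.where(category == "interaction", signs[:, 2] * mag["interaction"], 0.0)

    pair_idx = rng.integers(0, 4, size=n)
    offset = rng.integers(1, 4, size=n)
    allele1 = np.array(NUCLEOTIDES)[pair_idx]
    allele2 = np.array(NUCLEOTIDES)[(pair_idx + offset) % 4]

    per = params.loci_per_scaffold
    scaffold = np.array([f"scaf{i // per + 1}" for i in range(n)])
    tag_start = np.array([(i % per) * TAG_LENGTH + 1 for i in range(n)])
    position = tag_start + rng.integers(0, TAG_LENGTH, size=n)

    int_sign = np.where(
        category == "interaction", np.where(d_int > 0, "+", "-"), "n/a"
    )
    return pd.DataFrame(
        {
            "locus_id": [f"L{i:06d}" for i in range(n)],
            "category": category,
            "founder_maf": f0,
            "delta_stage": d_stage,
            "delta_trt": d_trt,
            "delta_int": d_int,
            "interaction_sign": int_sign,
            "allele1": allele1,
            "allele2": allele2,
            "scaffold": scaffold,
            "position": position,
        }
    )


def true_cell_frequency(truth: pd.DataFrame, stage: str, treatment: str) -> np.ndarray:
    """Expected allele-2 frequency of every locus in one design cell."""
    is_late = float(stage == STAGES[1])
    is_high = float(treatment == TREATMENTS[1])
    eta = (
        logit(truth["founder_maf"].to_numpy())
        + truth["delta_stage"].to_numpy() * is_late
        + truth["delta_trt"].to_numpy() * is_high
        + truth["delta_int"].to_numpy() * is_late * is_high
    )
    return expit(eta)


def _truncated_lognormal(
    rng: np.random.Generator, meanlog: float, sdlog: float, lo: int, hi: int, size: int
) -> np.ndarray:
    depths = rng.lognormal(meanlog, sdlog, size=size)
    for _ in range(1000):
        bad = (depths < lo) | (depths > hi)
        if not bad.any():
            break
        depths[bad] = rng.lognormal(meanlog, sdlog, size=int(bad.sum()))
    else:  # pathological parameters: clamp the stragglers
        depths = np.clip(depths, lo, hi)
    return np.round(depths).astype(int)


def simulate_experiment(params: SimParams) -> tuple[CountTable, pd.DataFrame]:
    """Simulate the full factorial experiment.

    Returns the merged :class:`~poolshift.counts.CountTable` over all
    samples and the truth table (one row per locus with its generating
    category and logit shifts).  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    truth = _draw_truth(params, rng)
    n = params.n_loci
    lo, hi = params.depth_bounds
    meanlog, sdlog = params.depth_lognorm

    nuc_pos = {n_: i for i, n_ in enumerate(NUCLEOTIDES)}
    a1_idx = truth["allele1"].map(nuc_pos).to_numpy()
    a2_idx = truth["allele2"].map(nuc_pos).to_numpy()

    frames = []
    for group in GROUPS:
        for stage in STAGES:
            for treatment in TREATMENTS:
                p_cell = true_cell_frequency(truth, stage, treatment)
                for rep in range(1, params.n_reps + 1):
                    if params.pool_size is None:
                        pool_freq = p_cell
                    else:
                        copies = 2 * params.pool_size
                        pool_freq = rng.binomial(copies, p_cell) / copies
                    depth = _truncated_lognormal(rng, meanlog, sdlog, lo, hi, n)
                    c2 = rng.binomial(depth, pool_freq)
                    c1 = depth - c2
                    counts = np.zeros((n, 4), dtype=int)
                    counts[np.arange(n), a1_idx] += c1
                    counts[np.arange(n), a2_idx] += c2
                    sample_id = f"{group}_{stage}_{treatment}_r{rep}"
                    frames.append(
                        pd.DataFrame(
                            {
                                "sample_id": sample_id,
                                "group": group,
                                "stage": stage,
                                "treatment": treatment,
                                "replicate": rep,
                                "locus_id": truth["locus_id"],
                                "scaffold": truth["scaffold"],
                                "position": truth["position"],
                                "countA": counts[:, 0],
                                "countC": counts[:, 1],
                                "countG": counts[:, 2],
                                "countT": counts[:, 3],
                            }
                        )
                    )
    df = pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]
    return CountTable(df), truth


@dataclass
class RecoveryResult:
    """Confusion matrix and derived power/FDR of an effect classification."""

    confusion: pd.DataFrame  # truth category (rows) x called category (cols)
    power: pd.Series  # per truth category; NaN when no loci in category
    fdr: float  # false discoveries / max(1, discoveries), category level

    def __repr__(self) -> str:  # pragma: no cover
        return f"RecoveryResult(fdr={self.fdr:.4f})\n{self.confusion}"


def evaluate_recovery(truth: pd.DataFrame, effects: pd.DataFrame) -> RecoveryResult:
    """Score an effect-classification table against the generating truth.

    ``effects`` must carry ``locus_id`` and ``category`` (analysis labels
    ``None``/``Stage``/``Trt``/``Stage+Trt``/``Stage*Trt``); the locus sets
    must match exactly.
    """
    truth_ids = set(truth["locus_id"])
    eff_ids = set(effects["locus_id"])
    if truth_ids != eff_ids:
        raise ValueError(
            f"locus sets differ: {len(truth_ids - eff_ids)} only in truth, "
            f"{len(eff_ids - truth_ids)} only in effects"
        )
    merged = truth.merge(effects[["locus_id", "category"]], on="locus_id", suffixes=("_true", ""))
    called_levels = [EXPECTED_CALL[c] for c in CATEGORIES]
    confusion = pd.crosstab(merged["category_true"], merged["category"]).reindex(
        index=list(CATEGORIES), columns=called_levels, fill_value=0
    )
    confusion.index.name = "truth"
    confusion.columns.name = "called"

    power = {}
    for cat in CATEGORIES:
        total = confusion.loc[cat].sum()
        power[cat] = confusion.loc[cat, EXPECTED_CALL[cat]] / total if total else np.nan
    discoveries = int((merged["category"] != "None").sum())
    false = int(((merged["category"] != "None") & (merged["category_true"] == "none")).sum())
    fdr = false / max(1, discoveries)
    return RecoveryResult(confusion=confusion, power=pd.Series(power), fdr=fdr)


def term_fdr(truth: pd.DataFrame, effects: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term realized false discovery rate at BH level ``alpha``.

    A discovery for term ``stage`` is a locus with ``q_stage < alpha``; it is
    false when the generating ``delta_stage`` is 0 (similarly for ``trt`` and
    ``int``).
    """
    merged = truth.merge(effects, on="locus_id")
    rows = []
    for term, delta in (("stage", "delta_stage"), ("trt", "delta_trt"), ("int", "delta_int")):
        q = merged[f"q_{term}"]
        disc = q < alpha
        false = disc & (merged[delta] == 0.0)
        n_disc = int(disc.sum())
        rows.append(
            {
                "term": term,
                "discoveries": n_disc,
                "false_discoveries": int(false.sum()),
                "fdr": int(false.sum()) / max(1, n_disc),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def random_fastq_records(
    n_reads: int,
    length: int = 50,
    rng: np.random.Generator | None = None,
    low_quality_prob: float = 0.1,
    low_quality: int = 15,
    high_quality: int = 38,
):
    """Minimal FASTQ fixture generator for exercising the read-QC step."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = rng or np.random.default_rng(0)
    records = []
    for i in range(n_reads):
        seq = "".join(rng.choice(list(NUCLEOTIDES), size=length))
        quals = np.where(
            rng.random(length) < low_quality_prob, low_quality, high_quality
        ).tolist()
        rec = SeqRecord(Seq(seq), id=f"read{i}", description="")
        rec.letter_annotations["phred_quality"] = quals
        records.append(rec)
    return records


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "scaffold": str})
    # "n/a" is the literal no-interaction token, not a missing value
    truth["interaction_sign"] = truth["interaction_sign"].fillna("n/a")
    return truth
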