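import numpy as np
import pandas as pd
import pytest

from poolshift.counts import COUNT_COLUMNS, CountTable
from poolshift.filters import run_filter_cascade
from poolshift.synthdata import SimParams, simulate_experiment


def make_count_rows(cells):
    """Build count-table rows from compact cell specs.

    Each cell is (sample_id, group, stage, treatment, replicate, locus_id,
    scaffold, position, {nuc: count, ...}).
    """
    rows = []
    for sample_id, group, stage, treatment, rep, locus, scaf, pos, counts in cells:
        row = {
            "sample_id": sample_id,
            "group": group,
            "stage": stage,
            "treatment": treatment,
            "replicate": rep,
            "locus_id": locus,
            "scaffold": scaf,
            "position": pos,
            "countA": 0,
            "countC": 0,
            "countG": 0,
            "countT": 0,
        }
        for nuc, c in counts.items():
            row[f"count{nuc}"] = c
        rows.append(row)
    return CountTable(pd.DataFrame(rows, columns=COUNT_COLUMNS))


def factorial_counts(per_locus, groups=("MBP", "wild"), n_reps=5):
    """Full 2x2x2xreps table; ``per_locus`` maps locus -> (scaf, pos, counts_fn)
    where counts_fn(group, stage, treatment, rep) -> {nuc: count}."""
    cells = []
    for group in groups:
        for stage in ("day2", "day22"):
            for treatment in ("ambient", "high"):
                for rep in range(1, n_reps + 1):
                    sid = f"{group}_{stage}_{treatment}_r{rep}"
                    for locus, (scaf, pos, fn) in per_locus.items():
                        counts = fn(group, stage, treatment, rep)
                        if counts is None:
                            continue
                        cells.append((sid, group, stage, treatment, rep, locus, scaf, pos, counts))
    return make_count_rows(cells)


@pytest.fixture(scope="session")
def sim_small():
    """400-locus mixed-category simulation shared across tests."""
    params = SimParams(n_loci=400, seed=42)
    counts, truth = simulate_experiment(params)
    return params, counts, truth


@pytest.fixture(scope="session")
def panel_small(sim_small):
    _, counts, _ = sim_small
    return run_filter_cascade(counts)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
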