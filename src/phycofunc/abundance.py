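"""Relative-abundance bookkeeping, trait-weighted site comparisons, rarefaction.

Coverage tables are genome × sample; relative abundance normalizes each
sample column to 100 %. When an ``unbinned`` remainder row is supplied the
binned columns sum to < 100 and the binned fraction of the community is
tracked explicitly (a coverage-based proxy for marker-gene recovery
estimates, not a marker-based method).

Rarefaction is analytic: the expected richness in a random subsample of
``n`` of the ``N`` observations is

    E[S_n] = Σ_i [ 1 − C(N − N_i, n) / C(N, n) ]

evaluated with log-gamma arithmetic so large counts do not overflow.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from phycofunc.pathway_assign import AssignmentMatrix

UNBINNED_ID = "unbinned"


def relative_abundance(coverage_table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample column to percent (column sum = 100).

    Index = genome ids (an ``unbinned`` row, if present, is normalized along
    with the rest so the community total stays 100). Raises on negative
    coverages or an all-zero sample.
    """
    cov = coverage_table.astype(float)
    if (cov.to_numpy() < 0).any():
        raise ValueError("negative coverage values")
    sums = cov.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return 100.0 * cov / sums


def binned_fraction(abundance_table: pd.DataFrame) -> pd.Series:
    """Per-sample percent of the community covered by binned genomes
    (100 minus the ``unbinned`` row; 100 everywhere if no such row)."""
    if UNBINNED_ID in abundance_table.index:
        return 100.0 - abundance_table.loc[UNBINNED_ID]
    return pd.Series(100.0, index=abundance_table.columns)


def cumulative_filter(
    abundance_table: pd.DataFrame, threshold: float = 1.0
) -> list[str]:
    """Genomes whose *cumulative* abundance — the sum of the genome's
    per-sample abundances across all samples — strictly exceeds
    ``threshold`` percent (the heatmap inclusion rule; exactly at the
    threshold is dropped)."""
    table = abundance_table.drop(index=UNBINNED_ID, errors="ignore")
    row_sums = table.sum(axis=1)
    return list(row_sums.index[row_sums > threshold])


def trait_weighted_abundance(
    abundance_table: pd.DataFrame,
    matrix: AssignmentMatrix,
    module_ids: Iterable[str],
    group: str,
    sample_groups: Mapping[str, str],
) -> float:
    """Summed relative abundance of trait carriers, averaged over a site.

    A genome is a carrier if it is assigned ≥ 1 module of ``module_ids``.
    Per sample of the group, carrier abundances are summed; the group value
    is the unweighted mean across the group's samples (percent).
    """
    module_ids = set(module_ids)
    unknown_modules = module_ids - set(matrix.module_ids)
    if unknown_modules:
        raise ValueError(f"unknown module ids: {sorted(unknown_modules)}")
    samples = [s for s, g in sample_groups.items() if g == group]
    if not samples:
        raise ValueError(f"unknown or empty sample group {group!r}")
    missing = set(samples) - set(abundance_table.columns)
    if missing:
        raise ValueError(f"samples not in abundance table: {sorted(missing)}")
    assigned = matrix.assigned
    carriers = [
        g
        for g in assigned.index
        if assigned.loc[g, sorted(module_ids)].any() and g in abundance_table.index
    ]
    per_sample = abundance_table.loc[carriers, samples].sum(axis=0)
    return float(per_sample.mean())


def trait_abundance_by_category(
    abundance_table: pd.DataFrame,
    matrix: AssignmentMatrix,
    category_modules: Mapping[str, Sequence[str]],
    sample_groups: Mapping[str, str],
) -> pd.DataFrame:
    """Trait-carrier abundance for each category × sample group (percent)."""
    groups = sorted(set(sample_groups.values()))
    rows = {
        cat: [
            trait_weighted_abundance(abundance_table, matrix, mods, grp, sample_groups)
            for grp in groups
        ]
        for cat, mods in category_modules.items()
    }
    return pd.DataFrame(rows, index=groups).T


def rarefaction_curve(
    counts: Mapping[str, int] | pd.Series, step: int = 2000
) -> pd.DataFrame:
    """Expected richness at subsample sizes ``step, 2·step, …`` and ``N``.

    Columns ``n`` (subsample size) and ``expected_richness``; the final
    point (n = N) equals the observed richness exactly. Zero-count taxa are
    ignored.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    series = pd.Series(counts).astype(np.int64)
    if (series < 0).any():
        raise ValueError("counts must be non-negative")
    series = series[series > 0]
    n_total = int(series.sum())
    if n_total < 1:
        raise ValueError("total count must be >= 1")
    sizes = list(range(step, n_total + 1, step))
    if not sizes or sizes[-1] != n_total:
        sizes.append(n_total)
    ni = series.to_numpy()
    expected = [_expected_richness(ni, n_total, n) for n in sizes]
    return pd.DataFrame({"n": sizes, "expected_richness": expected})


def _expected_richness(ni: np.ndarray, n_total: int, n: int) -> float:
    # log C(N - Ni, n) - log C(N, n); taxa with N - Ni < n are always seen
    rem = n_total - ni
    prob_absent = np.zeros(len(ni))
    ok = rem >= n
    r = rem[ok]
    log_p = (
        gammaln(r + 1)
        - gammaln(n + 1)
        - gammaln(r - n + 1)
        - (gammaln(n_total + 1) - gammaln(n + 1) - gammaln(n_total - n + 1))
    )
    prob_absent[ok] = np.exp(log_p)
    return float(np.sum(1.0 - prob_absent))


def rarefy_samples(
    count_table: pd.DataFrame, step: int = 2000
) -> pd.DataFrame:
    """Rarefaction curves for every sample column of a taxon × sample count
    table, returned long-form (sample, n, expected_richness)."""
    frames = []
    for sample in count_table.columns:
        curve = rarefaction_curve(count_table[sample], step=step)
        curve.insert(0, "sample", sample)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O helpers

def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome_id")


def read_sample_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))


def infer_sample_groups(samples: Iterable[str]) -> dict[str, str]:
    """Group samples named like ``RZ-A`` by their prefix before the dash."""
    return {s: s.split("-")[0] for s in samples}
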