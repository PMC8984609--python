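"""MAG quality scoring and the two quality gates.

Quality is the standard single-score summary of draft-genome quality::

    quality = completeness (%) − 5 × contamination (%)

Two gates are applied in pipeline order: the *bin-refinement* gate keeps
genomes with completeness > 50 % and contamination < 10 % (strict, as in
MetaWRAP-style refinement); the *tree-inclusion* gate then removes genomes
with quality < 40, so a genome scoring exactly 40 stays in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from phycofunc.util import round_half_away


@dataclass(frozen=True)
class GenomeRecord:
    """One MAG or isolate genome.

    ``ko_set`` is presence/absence only (multi-copy genes collapse);
    ``taxonomy`` is a GTDB-style 7-rank semicolon string
    (``d__...;p__...;...;s__...``).
    """

    genome_id: str
    taxonomy: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    ko_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        _check_range(self.completeness, self.contamination)
        object.__setattr__(self, "ko_set", frozenset(self.ko_set))

    @property
    def quality(self) -> float:
        return quality_score(self.completeness, self.contamination)


@dataclass(frozen=True)
class QualityReport:
    genome_id: str
    quality_score: float
    passed_refinement: bool
    passed_tree_filter: bool


def _check_range(completeness: float, contamination: float) -> None:
    if not 0.0 <= completeness <= 100.0:
        raise ValueError(f"completeness must be in [0, 100], got {completeness}")
    if contamination < 0.0:
        raise ValueError(f"contamination must be >= 0, got {contamination}")


def quality_score(completeness: float, contamination: float) -> float:
    """``completeness − 5 × contamination``; may be negative."""
    _check_range(completeness, contamination)
    return completeness - 5.0 * contamination


def filter_refined(records: Iterable[GenomeRecord]) -> list[GenomeRecord]:
    """Bin-refinement gate: completeness > 50 AND contamination < 10 (strict)."""
    return [r for r in records if r.completeness > 50.0 and r.contamination < 10.0]


def filter_for_tree(
    records: Iterable[GenomeRecord], min_quality: float = 40.0
) -> list[GenomeRecord]:
    """Tree-inclusion gate: drop genomes with quality < ``min_quality``.

    Quality exactly at the threshold is kept (only ``< min_quality`` is
    filtered out).
    """
    return [
        r for r in records
        if quality_score(r.completeness, r.contamination) >= min_quality
    ]


def quality_report(
    records: Sequence[GenomeRecord], min_quality: float = 40.0
) -> list[QualityReport]:
    """Per-genome report of score and both gates (gates evaluated in order:
    a genome failing refinement never reaches the tree set)."""
    refined_ids = {r.genome_id for r in filter_refined(records)}
    out = []
    for r in records:
        q = r.quality
        in_refined = r.genome_id in refined_ids
        out.append(
            QualityReport(
                genome_id=r.genome_id,
                quality_score=q,
                passed_refinement=in_refined,
                passed_tree_filter=in_refined and q >= min_quality,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV I/O

def read_genomes_tsv(path: str | Path) -> list[GenomeRecord]:
    """Read ``genomes.tsv`` (genome_id, taxonomy, completeness, contamination)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "taxonomy": str})
    df["taxonomy"] = df.get("taxonomy", "").fillna("")
    return [
        GenomeRecord(
            genome_id=row.genome_id,
            taxonomy=row.taxonomy,
            completeness=float(row.completeness),
            contamination=float(row.contamination),
        )
        for row in df.itertuples(index=False)
    ]


def attach_annotations(
    records: Sequence[GenomeRecord], annotations: pd.DataFrame
) -> list[GenomeRecord]:
    """Merge a long-form annotation table (columns genome_id, ko_id) into records."""
    ko_by_genome = annotations.groupby("genome_id")["ko_id"].agg(frozenset).to_dict()
    return [
        GenomeRecord(
            genome_id=r.genome_id,
            taxonomy=r.taxonomy,
            completeness=r.completeness,
            contamination=r.contamination,
            ko_set=ko_by_genome.get(r.genome_id, frozenset()),
        )
        for r in records
    ]


def write_quality_report(
    reports: Sequence[QualityReport], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in reports],
            # full precision internally; 2 decimals only at report time
            "quality_score": [round_half_away(r.quality_score, 2) for r in reports],
            "passed_refinement": [r.passed_refinement for r in reports],
            "passed_tree_filter": [r.passed_tree_filter for r in reports],
        }
    ).to_csv(path, sep="\t", index=False)
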