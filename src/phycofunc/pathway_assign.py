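"""Module completeness, key-enzyme gating, and taxon aggregation.

The decision rule: a module is *assigned* to a genome iff its step
completeness (satisfied steps / total steps, an exact rational — never a
rounded percent) is at least the threshold (default 0.6, inclusive) AND every
key-enzyme clause has at least one alternative fully present in the genome's
KO set. Steps are binary — a complex missing one subunit contributes
nothing — which keeps "percent complete" well defined.

An optional *raw KO fraction* mode scores completeness as the fraction of all
identifiers in the module present in the genome, for users whose upstream
tooling computed module integrity that way.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd

from phycofunc.genome_qc import GenomeRecord
from phycofunc.module_catalog import ModuleCatalog, ModuleDefinition, Step
from phycofunc.util import GTDB_RANKS, parse_taxonomy

DEFAULT_THRESHOLD = 0.6


@dataclass(frozen=True)
class AssignmentCell:
    """Diagnostic result of one genome × module evaluation."""

    completeness: Fraction
    keys_present: bool
    assigned: bool


def resolve_aliases(ko_set: Iterable[str], aliases: Mapping[str, str] | None) -> frozenset[str]:
    """Map identifiers through an alias table (symbol → canonical id).

    The original identifiers are kept alongside their resolved forms so a
    catalog written with either vocabulary matches.
    """
    ko_set = frozenset(ko_set)
    if not aliases:
        return ko_set
    return ko_set | frozenset(aliases[k] for k in ko_set if k in aliases)


def step_satisfied(step: Step, ko_set: frozenset[str] | set[str]) -> bool:
    """True iff some alternative's identifiers are all present."""
    return any(alt <= ko_set for alt in step)


def module_completeness(
    definition: ModuleDefinition,
    ko_set: frozenset[str] | set[str],
    *,
    raw_ko_fraction: bool = False,
) -> Fraction:
    """Fraction of steps satisfied, in [0, 1], as an exact rational.

    With ``raw_ko_fraction=True``, the fraction of the module's identifier
    set present instead (alternative scoring mode; not the default).
    """
    ko_set = frozenset(ko_set)
    if raw_ko_fraction:
        idents = definition.identifiers()
        return Fraction(len(idents & ko_set), len(idents))
    n_sat = sum(1 for step in definition.steps if step_satisfied(step, ko_set))
    return Fraction(n_sat, definition.n_steps)


def keys_present(definition: ModuleDefinition, ko_set: frozenset[str] | set[str]) -> bool:
    """True iff every key clause has ≥ 1 alternative fully present.

    Vacuously true when the module declares no key requirements.
    """
    ko_set = frozenset(ko_set)
    return all(step_satisfied(clause, ko_set) for clause in definition.key_requirements)


def assign_module(
    definition: ModuleDefinition,
    ko_set: frozenset[str] | set[str],
    threshold: float | Fraction = DEFAULT_THRESHOLD,
    *,
    raw_ko_fraction: bool = False,
) -> AssignmentCell:
    """Evaluate one genome × module cell.

    ``assigned = (completeness ≥ threshold) AND keys_present``; both
    components are reported for diagnostics. The comparison is inclusive
    and exact (``Fraction(3, 5) >= 0.6`` holds; no 59.999 artifacts).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    threshold = Fraction(threshold).limit_denominator(10**6)
    comp = module_completeness(definition, ko_set, raw_ko_fraction=raw_ko_fraction)
    keys = keys_present(definition, ko_set)
    return AssignmentCell(
        completeness=comp, keys_present=keys, assigned=bool(comp >= threshold and keys)
    )


class AssignmentMatrix:
    """Genome × module assignment results.

    Thin wrapper over three aligned DataFrames (completeness fraction as
    float, keys flag, assigned flag), rows = genome ids, columns = module
    ids, plus the exact cells for programmatic access.
    """

    def __init__(
        self,
        cells: dict[tuple[str, str], AssignmentCell],
        genome_ids: Sequence[str],
        module_ids: Sequence[str],
        threshold: Fraction,
    ):
        self.cells = cells
        self.genome_ids = list(genome_ids)
        self.module_ids = list(module_ids)
        self.threshold = threshold

    def cell(self, genome_id: str, module_id: str) -> AssignmentCell:
        return self.cells[(genome_id, module_id)]

    @property
    def assigned(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [self.cells[(g, m)].assigned for m in self.module_ids]
                for g in self.genome_ids
            ],
            index=self.genome_ids,
            columns=self.module_ids,
            dtype=bool,
        )

    @property
    def completeness(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [float(self.cells[(g, m)].completeness) for m in self.module_ids]
                for g in self.genome_ids
            ],
            index=self.genome_ids,
            columns=self.module_ids,
            dtype=float,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-form table: genome_id, module_id, completeness, keys_present, assigned."""
        rows = [
            (g, m, float(c.completeness), c.keys_present, c.assigned)
            for (g, m), c in (
                ((g, m), self.cells[(g, m)])
                for g in self.genome_ids
                for m in self.module_ids
            )
        ]
        return pd.DataFrame(
            rows,
            columns=["genome_id", "module_id", "completeness", "keys_present", "assigned"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def build_matrix(
    genomes: Sequence[GenomeRecord],
    catalog: ModuleCatalog,
    threshold: float | Fraction = DEFAULT_THRESHOLD,
    *,
    aliases: Mapping[str, str] | None = None,
    raw_ko_fraction: bool = False,
) -> AssignmentMatrix:
    """Evaluate every genome against every catalog module."""
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome ids: {dupes}")
    thr = Fraction(threshold).limit_denominator(10**6)
    cells: dict[tuple[str, str], AssignmentCell] = {}
    for g in genomes:
        ko = resolve_aliases(g.ko_set, aliases)
        for m in catalog:
            cells[(g.genome_id, m.module_id)] = assign_module(
                m, ko, thr, raw_ko_fraction=raw_ko_fraction
            )
    return AssignmentMatrix(cells, ids, list(catalog.module_ids), thr)


def aggregate_by_taxon(
    matrix: AssignmentMatrix,
    genomes: Sequence[GenomeRecord],
    rank: str,
) -> pd.DataFrame:
    """Count assigned genomes per taxon (at ``rank``) per module.

    Genomes with a missing or unparseable name at that rank are grouped
    under ``"unclassified"`` (with a warning per malformed record).
    """
    if rank not in GTDB_RANKS:
        raise ValueError(f"rank must be one of {GTDB_RANKS}, got {rank!r}")
    taxon_of: dict[str, str] = {}
    for g in genomes:
        name = parse_taxonomy(g.taxonomy).get(rank, "")
        if not name:
            if g.taxonomy and "__" not in g.taxonomy:
                warnings.warn(
                    f"genome {g.genome_id}: malformed taxonomy {g.taxonomy!r}; "
                    "grouped as unclassified"
                )
            name = "unclassified"
        taxon_of[g.genome_id] = name
    assigned = matrix.assigned
    if assigned.empty:
        return pd.DataFrame(columns=matrix.module_ids)
    groups = assigned.groupby(
        [taxon_of.get(g, "unclassified") for g in assigned.index]
    ).sum()
    groups.index.name = rank
    return groups.astype(int)
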