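"""Synthetic phycosphere community generator with attached ground truth.

Every input the pipeline consumes can be generated here: genomes carrying
known trait blocks of KOs, a random rooted genome tree, and lognormal
per-sample coverages. The generator is a documented stand-in — no noise
model is claimed to match real metagenomes — but its signatures are
testable:

* KO dropout is i.i.d. Bernoulli per KO with retention probability
  ``completeness / 100`` (incomplete genomes lose pathway genes at random);
* contamination adds ``round(contamination / 100 × |true KO set|)`` KOs
  sampled without replacement from a background pool, giving contamination
  a detectable signature;
* taxonomy strings are GTDB-style 7-rank (``d__;p__;c__;o__;f__;g__;s__``);
* the random stream is split per artifact (genomes / tree / coverage) so
  adding samples never perturbs genome simulation, and a fixed seed fixes
  all outputs bit-for-bit.

Defaults emulate the study design the package targets: 202 genomes, two
sites × three pooled samples (RZ-A…ND-C), completeness ~ U(50, 100)
(mean 75 %), contamination ~ U(0, 10) (mean 5 %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phycofunc.genome_qc import GenomeRecord
from phycofunc.module_catalog import ModuleCatalog
from phycofunc.util import format_taxonomy

_DEFAULT_BACKGROUND = frozenset(f"KB{i:04d}" for i in range(1, 501))

# invented lineage names keyed by trait-group index, purely for plumbing
_PHYLA = (
    "Proteobacteria",
    "Bacteroidota",
    "Actinobacteriota",
    "Chloroflexota",
    "Verrucomicrobiota",
    "Myxococcota",
    "Patescibacteria",
    "Bdellovibrionota",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the community simulator; the defaults are the study design."""

    n_genomes: int = 202
    n_samples: int = 6
    seed: int = 0
    trait_assignment: Mapping[str, tuple[str, ...]] | None = None
    completeness_range: tuple[float, float] = (50.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 10.0)
    background_ko_pool: frozenset[str] = _DEFAULT_BACKGROUND
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    branch_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ConfigurationError("n_genomes must be >= 1")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        for name in ("completeness_range", "contamination_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 100.0):
                raise ConfigurationError(f"{name} must be within [0, 100], got {(lo, hi)}")
        if self.lognormal_sigma < 0:
            raise ConfigurationError("lognormal_sigma must be >= 0")
        if self.branch_rate <= 0:
            raise ConfigurationError("branch_rate must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Truth emitted alongside the data: which modules each genome truly
    carries, its full (pre-dropout) KO set, and its trait group."""

    modules_by_genome: dict[str, frozenset[str]] = field(default_factory=dict)
    true_ko_by_genome: dict[str, frozenset[str]] = field(default_factory=dict)
    group_by_genome: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "modules_by_genome": {
                    g: sorted(m) for g, m in self.modules_by_genome.items()
                },
                "true_ko_by_genome": {
                    g: sorted(k) for g, k in self.true_ko_by_genome.items()
                },
                "group_by_genome": dict(self.group_by_genome),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            modules_by_genome={
                g: frozenset(m) for g, m in raw["modules_by_genome"].items()
            },
            true_ko_by_genome={
                g: frozenset(k) for g, k in raw["true_ko_by_genome"].items()
            },
            group_by_genome=dict(raw["group_by_genome"]),
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "genomes": np.random.default_rng(children[0]),
        "tree": np.random.default_rng(children[1]),
        "coverage": np.random.default_rng(children[2]),
    }


def default_trait_assignment(catalog: ModuleCatalog) -> dict[str, tuple[str, ...]]:
    """One trait group per catalog category carrying all of its modules,
    plus a trait-free background group."""
    groups: dict[str, tuple[str, ...]] = {}
    for cat in sorted({m.category for m in catalog}):
        groups[cat] = tuple(m.module_id for m in catalog if m.category == cat)
    groups["background"] = ()
    return groups


def simulate_genomes(
    config: SimulationConfig, catalog: ModuleCatalog
) -> tuple[list[GenomeRecord], GroundTruth]:
    """Simulate genomes with known trait content plus dropout/contamination.

    Genomes are distributed cyclically over the trait groups; each genome's
    true KO set is the union of all identifiers of its carried modules, so
    every truly carried module is 100 % complete (keys included) before
    dropout.
    """
    if len(catalog) == 0:
        raise ConfigurationError("catalog must be non-empty")
    assignment = (
        dict(config.trait_assignment)
        if config.trait_assignment is not None
        else default_trait_assignment(catalog)
    )
    for group, module_ids in assignment.items():
        unknown = [m for m in module_ids if m not in catalog]
        if unknown:
            raise ConfigurationError(f"group {group!r}: unknown module ids {unknown}")
    group_names = sorted(assignment)
    rng = _streams(config.seed)["genomes"]
    lo_c, hi_c = config.completeness_range
    lo_k, hi_k = config.contamination_range

    records: list[GenomeRecord] = []
    truth = GroundTruth()
    for i in range(config.n_genomes):
        gid = f"MAG-{i + 1}"
        group = group_names[i % len(group_names)]
        carried = frozenset(assignment[group])
        true_kos = frozenset(
            ident for mid in carried for ident in catalog[mid].identifiers()
        )
        completeness = float(rng.uniform(lo_c, hi_c))
        contamination = float(rng.uniform(lo_k, hi_k))

        sorted_kos = sorted(true_kos)
        keep = rng.random(len(sorted_kos)) < completeness / 100.0
        observed = {k for k, kept in zip(sorted_kos, keep) if kept}

        n_gain = round(contamination / 100.0 * len(true_kos))
        pool = sorted(config.background_ko_pool - true_kos)
        if n_gain and pool:
            picked = rng.choice(len(pool), size=min(n_gain, len(pool)), replace=False)
            observed |= {pool[j] for j in picked}

        g_idx = group_names.index(group)
        taxonomy = format_taxonomy(
            {
                "domain": "Bacteria",
                "phylum": _PHYLA[g_idx % len(_PHYLA)],
                "class": f"{group.capitalize()}ia",
                "order": f"{group.capitalize()}ales",
                "family": f"{group.capitalize()}aceae",
                "genus": group.capitalize(),
                "species": f"{group.capitalize()} sp{i + 1}",
            }
        )
        records.append(
            GenomeRecord(
                genome_id=gid,
                taxonomy=taxonomy,
                completeness=completeness,
                contamination=contamination,
                ko_set=frozenset(observed),
            )
        )
        truth.modules_by_genome[gid] = carried
        truth.true_ko_by_genome[gid] = true_kos
        truth.group_by_genome[gid] = group
    return records, truth


def simulate_tree(
    n_leaves: int,
    seed: int,
    *,
    rate: float = 1.0,
    labels: Sequence[str] | None = None,
) -> str:
    """Random rooted binary tree as a newick string.

    Topology by random pairwise joining; branch lengths i.i.d.
    Exponential(``rate``), all strictly positive. Deterministic under the
    seed.
    """
    if n_leaves < 2:
        raise ConfigurationError("n_leaves must be >= 2")
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n_leaves)]
    if len(labels) != n_leaves or len(set(labels)) != n_leaves:
        raise ConfigurationError("labels must be unique and match n_leaves")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[1])

    def _exp() -> float:
        # rejection keeps every branch strictly positive
        while True:
            x = float(rng.exponential(1.0 / rate))
            if x > 0.0:
                return x

    nodes = [str(lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(f"({left}:{_exp():.10g},{right}:{_exp():.10g})")
    return nodes[0] + ";"


def sample_names(n_samples: int, groups: tuple[str, str] = ("RZ", "ND")) -> list[str]:
    """Two-site sample naming: first half RZ-A…, second half ND-A…"""
    n_first = (n_samples + 1) // 2
    names = []
    for idx in range(n_samples):
        grp = groups[0] if idx < n_first else groups[1]
        k = idx if idx < n_first else idx - n_first
        suffix = chr(65 + k) if k < 26 else f"S{k}"
        names.append(f"{grp}-{suffix}")
    return names


def simulate_coverage(
    genomes: Sequence[GenomeRecord],
    n_samples: int,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Lognormal genome × sample coverage table (non-negative), indexed by
    genome_id, columns named per :func:`sample_names`."""
    if not genomes:
        raise ConfigurationError("genomes must be non-empty")
    rng = _streams(config.seed)["coverage"]
    # drawn column-by-column so appending samples leaves earlier columns intact
    data = rng.lognormal(
        config.lognormal_mu, config.lognormal_sigma, size=(n_samples, len(genomes))
    ).T
    return pd.DataFrame(
        data,
        index=pd.Index([g.genome_id for g in genomes], name="genome_id"),
        columns=sample_names(n_samples),
    )


def simulate_all(
    config: SimulationConfig, catalog: ModuleCatalog
) -> dict[str, object]:
    """Run the full generator: genomes + truth, tree over the genome ids,
    coverages."""
    genomes, truth = simulate_genomes(config, catalog)
    newick = (
        simulate_tree(
            len(genomes),
            config.seed,
            rate=config.branch_rate,
            labels=[g.genome_id for g in genomes],
        )
        if len(genomes) >= 2
        else None
    )
    coverage = simulate_coverage(genomes, config.n_samples, config)
    return {"genomes": genomes, "truth": truth, "newick": newick, "coverage": coverage}


def write_outputs(
    outdir: str | Path, config: SimulationConfig, catalog: ModuleCatalog
) -> dict[str, Path]:
    """Emit genomes.tsv, annotations.tsv, tree.nwk, coverage.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_all(config, catalog)
    genomes: list[GenomeRecord] = sim["genomes"]  # type: ignore[assignment]

    paths = {name: outdir / name for name in (
        "genomes.tsv", "annotations.tsv", "tree.nwk", "coverage.tsv", "truth.json"
    )}
    pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "taxonomy": [g.taxonomy for g in genomes],
            "completeness": [g.completeness for g in genomes],
            "contamination": [g.contamination for g in genomes],
        }
    ).to_csv(paths["genomes.tsv"], sep="\t", index=False)
    pd.DataFrame(
        [(g.genome_id, ko) for g in genomes for ko in sorted(g.ko_set)],
        columns=["genome_id", "ko_id"],
    ).to_csv(paths["annotations.tsv"], sep="\t", index=False)
    if sim["newick"] is not None:
        paths["tree.nwk"].write_text(str(sim["newick"]) + "\n")
    sim["coverage"].to_csv(paths["coverage.tsv"], sep="\t")  # type: ignore[union-attr]
    paths["truth.json"].write_text(sim["truth"].to_json())  # type: ignore[union-attr]
    return paths
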