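"""Metabolic-module catalog: definition format, parser, and the shipped catalog.

A *module* is an ordered list of reaction **steps**. Each step is satisfied by
any one of its **alternatives**; an alternative is a set of gene/KO
identifiers that must *all* be present (an enzyme complex). On top of the
steps, a module may declare **key-enzyme clauses**: every clause must have at
least one alternative fully present for the module to count as functional,
regardless of overall completeness. This is a deliberate subset of KEGG's
DEFINITION syntax — no optional ('-') terms and no nested parentheses — which
is sufficient for the trait gene sets shipped here.

File grammar (one module per block, ``#`` comments, blocks end at ``//`` or
at the next ``MODULE`` line)::

    MODULE   M00165  Calvin-Benson-Bassham cycle
    CATEGORY carbon_fixation
    STEP     K01601+K01602,K01601     # comma = OR, '+' = complex (AND)
    STEP     K00855
    KEY      K01601                   # each KEY line is one mandatory clause
    //

Identifiers are either K-numbers (``K\\d{5}``) or gene symbols (``nasA``,
``acdS`` …); matching downstream is exact-string after optional alias
resolution (see :func:`builtin_aliases`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

# A step (or key clause) is a frozenset of alternatives; an alternative is a
# frozenset of identifiers forming a complex.
Alternative = frozenset
Step = frozenset

CATEGORIES = frozenset(
    {
        "carbon_fixation",
        "nitrogen",
        "sulfur",
        "phosphorus",
        "cobalamin",
        "auxin",
        "ethylene",
    }
)


class CatalogError(ValueError):
    """Raised for grammar or consistency errors in a catalog file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ModuleDefinition:
    """One metabolic module: ordered steps plus key-enzyme clauses.

    Parameters
    ----------
    module_id:
        KEGG-style id (``M00165``) or custom id (``CUST_IAM``).
    name:
        Human-readable pathway name.
    category:
        One of :data:`CATEGORIES`.
    steps:
        Ordered tuple; each step a frozenset of alternatives; each
        alternative a frozenset of identifiers that must all be present.
    key_requirements:
        Tuple of clauses with the same shape as a step. Every clause must
        be satisfied for the module's key enzymes to count as present.
    """

    module_id: str
    name: str
    category: str
    steps: tuple[Step, ...]
    key_requirements: tuple[Step, ...] = ()

    def __post_init__(self) -> None:
        if not self.module_id:
            raise CatalogError("module_id must be non-empty")
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"module {self.module_id}: unknown category {self.category!r} "
                f"(expected one of {sorted(CATEGORIES)})"
            )
        if len(self.steps) < 1:
            raise CatalogError(f"module {self.module_id}: needs at least one step")
        for step in self.steps:
            if not step or any(not alt for alt in step) or any(
                not ident for alt in step for ident in alt
            ):
                raise CatalogError(f"module {self.module_id}: empty step or identifier")
        step_idents = self.identifiers()
        for clause in self.key_requirements:
            for alt in clause:
                for ident in alt:
                    if ident not in step_idents:
                        raise CatalogError(
                            f"module {self.module_id}: key identifier {ident!r} "
                            "does not appear in any step"
                        )

    def identifiers(self) -> frozenset[str]:
        """All identifiers mentioned in the steps."""
        return frozenset(i for step in self.steps for alt in step for i in alt)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class ModuleCatalog:
    """An ordered collection of :class:`ModuleDefinition` with unique ids."""

    modules: tuple[ModuleDefinition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if m.module_id in seen:
                raise CatalogError(f"duplicate module_id {m.module_id!r}")
            seen.add(m.module_id)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __contains__(self, module_id: str) -> bool:
        return any(m.module_id == module_id for m in self.modules)

    def __getitem__(self, module_id: str) -> ModuleDefinition:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def module_ids(self) -> tuple[str, ...]:
        return tuple(m.module_id for m in self.modules)

    def by_category(self, category: str) -> "ModuleCatalog":
        return ModuleCatalog(tuple(m for m in self.modules if m.category == category))


def _parse_step_expr(expr: str, line_no: int) -> Step:
    alternatives = []
    for alt_text in expr.split(","):
        alt_text = alt_text.strip()
        if not alt_text:
            raise CatalogError("empty alternative", line_no)
        idents = [p.strip() for p in alt_text.split("+")]
        if any(not p for p in idents):
            raise CatalogError(f"empty identifier in {alt_text!r}", line_no)
        alternatives.append(Alternative(idents))
    if not alternatives:
        raise CatalogError("empty step", line_no)
    return Step(alternatives)


def parse_catalog(text: str) -> ModuleCatalog:
    """Parse catalog text into a validated :class:`ModuleCatalog`.

    Raises :class:`CatalogError` with a line number on grammar errors,
    duplicate ids, empty steps, or key identifiers absent from the steps.
    """
    modules: list[ModuleDefinition] = []
    cur_id: str | None = None
    cur_name = ""
    cur_cat: str | None = None
    cur_steps: list[Step] = []
    cur_keys: list[Step] = []
    cur_line = 0

    def flush() -> None:
        nonlocal cur_id
        if cur_id is None:
            return
        if cur_cat is None:
            raise CatalogError(f"module {cur_id}: missing CATEGORY", cur_line)
        try:
            modules.append(
                ModuleDefinition(
                    module_id=cur_id,
                    name=cur_name,
                    category=cur_cat,
                    steps=tuple(cur_steps),
                    key_requirements=tuple(cur_keys),
                )
            )
        except CatalogError as exc:
            raise CatalogError(str(exc), cur_line) from None
        cur_id = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line == "//":
            flush()
            continue
        parts = line.split(None, 1)
        keyword = parts[0].upper()
        rest = parts[1].strip() if len(parts) > 1 else ""
        if keyword == "MODULE":
            flush()
            fields = rest.split(None, 1)
            if not fields:
                raise CatalogError("MODULE line without an id", line_no)
            cur_id = fields[0]
            cur_name = fields[1] if len(fields) > 1 else ""
            cur_cat = None
            cur_steps, cur_keys = [], []
            cur_line = line_no
        elif cur_id is None:
            raise CatalogError(f"{keyword} outside a MODULE block", line_no)
        elif keyword == "CATEGORY":
            cur_cat = rest
        elif keyword == "STEP":
            cur_steps.append(_parse_step_expr(rest, line_no))
        elif keyword == "KEY":
            cur_keys.append(_parse_step_expr(rest, line_no))
        else:
            raise CatalogError(f"unknown keyword {keyword!r}", line_no)
    flush()
    return ModuleCatalog(tuple(modules))


def _fmt_step(step: Step) -> str:
    return ",".join(sorted("+".join(sorted(alt)) for alt in step))


def serialize_catalog(catalog: ModuleCatalog) -> str:
    """Serialize to catalog text; ``parse_catalog`` round-trips losslessly."""
    blocks = []
    for m in catalog:
        lines = [f"MODULE {m.module_id} {m.name}".rstrip(), f"CATEGORY {m.category}"]
        lines += [f"STEP {_fmt_step(s)}" for s in m.steps]
        lines += [f"KEY {_fmt_step(k)}" for k in m.key_requirements]
        lines.append("//")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + ("\n" if blocks else "")


def _read_data(name: str) -> str:
    return (
        importlib.resources.files("phycofunc").joinpath("data", name).read_text()
    )


def builtin_catalog() -> ModuleCatalog:
    """The shipped trait catalog.

    Covers the six prokaryotic carbon-fixation modules (M00377 Wood-Ljungdahl,
    M00173 rTCA, M00375 HP-HB, M00376 3-HP, M00374 DC-HB, M00165 CBB),
    assimilatory sulfate reduction (M00176), and custom modules for nitrate
    reduction (ANRA/DNRA), denitrification, nitrification, taurine
    metabolism, sulfide/sulfite oxidation, alkaline-phosphatase DOP
    hydrolysis, cobalamin synthesis/remodeling/transport, the four bacterial
    IAA (auxin) biosynthesis routes, and ACC deaminase. Custom entries are a
    curated reconstruction (versioned in the file header); users can swap in
    their own catalog file with the same grammar.
    """
    return parse_catalog(_read_data("builtin_catalog.txt"))


def builtin_aliases() -> dict[str, str]:
    """Gene-symbol → K-number alias map for the carbon-fixation key enzymes.

    Applied to observed KO sets before matching so annotations using symbols
    (``aclA``) hit catalogs written with K-numbers, and vice versa is handled
    by resolving both sides. Matching stays exact-string after resolution.
    """
    out: dict[str, str] = {}
    for line in _read_data("aliases.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, knum = line.split("\t")
        out[symbol] = knum
    return out
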