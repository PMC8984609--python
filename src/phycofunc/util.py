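"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used in printed reports),
    avoiding banker's rounding artifacts like ``round(0.5) == 0``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(GTDB_RANKS, ("d__", "p__", "c__", "o__", "f__", "g__", "s__")))


def parse_taxonomy(taxonomy: str) -> dict[str, str]:
    """Parse a GTDB-style 7-rank string into ``{rank: name}``.

    Missing or empty ranks map to ``""``. Tokens without a recognised rank
    prefix are ignored (the caller decides how to warn).
    """
    out = {rank: "" for rank in GTDB_RANKS}
    prefix_to_rank = {v: k for k, v in _RANK_PREFIX.items()}
    for token in taxonomy.split(";"):
        token = token.strip()
        rank = prefix_to_rank.get(token[:3])
        if rank is not None:
            out[rank] = token[3:]
    return out


def format_taxonomy(names: dict[str, str]) -> str:
    return ";".join(_RANK_PREFIX[r] + names.get(r, "") for r in GTDB_RANKS)
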