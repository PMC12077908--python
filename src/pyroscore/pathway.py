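"""Pathway definitions: gene sets with per-gene directionality.

A pathway activation score is a *signed* gene-set statistic: each gene g in
the pathway carries a directionality d(g) in {+1, -1} stating whether its
transcription (or the abundance of the analogous CSF protein) correlates
positively or negatively with activation of the pathway. Directionality comes
from a curated knowledge base when available, otherwise from the sign of the
gene's CSF-protein correlation with the global disease-severity outcome.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

__all__ = ["PathwaySpec", "assign_directionality"]

_SOURCES = ("knowledge-base", "csf-correlation-sign", "default", "file")


@dataclass(frozen=True)
class PathwaySpec:
    """A gene set with per-gene +1/-1 directionality.

    ``direction`` and ``source`` are keyed by the canonical (upper-case)
    symbol; lookups through :meth:`direction_of` are case-insensitive.
    """

    genes: tuple[str, ...]
    direction: Mapping[str, int]
    source: Mapping[str, str] = field(default_factory=dict)
    name: str = "pathway"

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            key = g.upper()
            if key in seen:
                raise ValueError(f"duplicate pathway gene symbol: {g}")
            seen.add(key)
            d = self.direction.get(key, self.direction.get(g))
            if d not in (1, -1):
                raise ValueError(f"gene {g} lacks a +1/-1 directionality")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in {g.upper() for g in self.genes}

    def direction_of(self, gene: str) -> int:
        key = gene.upper()
        for g in self.genes:
            if g.upper() == key:
                return int(self.direction.get(g.upper(), self.direction.get(g)))
        raise KeyError(f"gene {gene!r} not in pathway {self.name!r}")

    @classmethod
    def from_directions(
        cls, directions: Mapping[str, int], name: str = "pathway", source: str = "file"
    ) -> "PathwaySpec":
        genes = tuple(directions)
        canon = {g.upper(): int(d) for g, d in directions.items()}
        return cls(
            genes=genes,
            direction=canon,
            source={g.upper(): source for g in genes},
            name=name,
        )


def assign_directionality(
    genes: Iterable[str],
    kb_directions: Mapping[str, int] | None,
    csf_correlations: Mapping[str, float] | None,
    name: str = "pathway",
) -> PathwaySpec:
    """Resolve per-gene directionality with knowledge-base precedence.

    The knowledge-base sign wins whenever present; genes absent from it take
    the sign of the analogous CSF protein's severity correlation. Genes with
    neither source are dropped with a warning — a sign is never guessed.
    """
    kb = {k.upper(): int(v) for k, v in (kb_directions or {}).items()}
    csf = {k.upper(): float(v) for k, v in (csf_correlations or {}).items()}
    for g, d in kb.items():
        if d not in (1, -1):
            raise ValueError(f"knowledge-base direction for {g} must be +1 or -1, got {d}")

    kept: list[str] = []
    direction: dict[str, int] = {}
    source: dict[str, str] = {}
    dropped: list[str] = []
    for gene in genes:
        key = gene.upper()
        if key in kb:
            direction[key] = kb[key]
            source[key] = "knowledge-base"
        elif key in csf and csf[key] != 0:
            direction[key] = 1 if csf[key] > 0 else -1
            source[key] = "csf-correlation-sign"
        else:
            dropped.append(gene)
            continue
        kept.append(gene)
    if dropped:
        warnings.warn(
            f"{len(dropped)} pathway gene(s) lacked both a knowledge-base "
            f"direction and a usable CSF correlation and were dropped: "
            f"{', '.join(dropped)}",
            stacklevel=2,
        )
    return PathwaySpec(genes=tuple(kept), direction=direction, source=source, name=name)
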