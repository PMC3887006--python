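"""Regulator→target networks.

A regulatory network is a set of typed, directed edges from *seeds*
(regulators: transcription factors, complexes, functional classes — opaque
identifiers that need not themselves be measured) to target genes.  Two
relation types are modelled, ``Expression`` and ``PromoterBinding``.  The
per-gene *connectivity* (number of incoming filtered edges) is used as a
replication weight in the enrichment rank test to damp hub-driven bias.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

RELATION_TYPES = frozenset({"Expression", "PromoterBinding"})

Edge = tuple[str, str, str]  # (seed, target, relation_type)


class NetworkParseError(ValueError):
    """Malformed network file; message names the offending line."""


class EmptyNetworkError(ValueError):
    """No edges survive parsing/filtering."""


class RegulatoryNetwork:
    """Immutable regulator→target edge set with connectivity queries.

    Parameters
    ----------
    edges
        Iterable of ``(seed, target, relation_type)`` triples.  Duplicate
        triples are dropped with a logged warning; self-edges are kept.
    connectivity_mode
        ``"in"`` (default) counts incoming edges of a gene; ``"total"``
        additionally counts outgoing edges for genes that are also seeds.
    """

    def __init__(self, edges: Iterable[Edge], connectivity_mode: str = "in"):
        if connectivity_mode not in ("in", "total"):
            raise ValueError(f"unknown connectivity_mode: {connectivity_mode!r}")
        seen: set[Edge] = set()
        ordered: list[Edge] = []
        n_dup = 0
        for e in edges:
            seed, target, rtype = e
            if rtype not in RELATION_TYPES:
                raise ValueError(f"unknown relation type: {rtype!r}")
            if e in seen:
                n_dup += 1
                continue
            seen.add(e)
            ordered.append((seed, target, rtype))
        if n_dup:
            logger.warning("dropped %d duplicate edge triples", n_dup)
        if not ordered:
            raise EmptyNetworkError("empty network: no edges")
        self._edges: tuple[Edge, ...] = tuple(sorted(ordered))
        targets: dict[str, set[str]] = defaultdict(set)
        indeg: dict[str, int] = defaultdict(int)
        outdeg: dict[str, int] = defaultdict(int)
        for seed, target, _ in self._edges:
            targets[seed].add(target)
            indeg[target] += 1
            outdeg[seed] += 1
        self._targets = {s: frozenset(t) for s, t in targets.items()}
        self._mode = connectivity_mode
        conn = dict(indeg)
        if connectivity_mode == "total":
            for s, d in outdeg.items():
                if s in conn:
                    conn[s] += d
        self._connectivity = conn

    # -- basic accessors -------------------------------------------------
    @property
    def seeds(self) -> tuple[str, ...]:
        """Regulator identifiers, lexicographically ordered."""
        return tuple(sorted(self._targets))

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self._edges

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def genes(self) -> frozenset[str]:
        """All target genes appearing in the network."""
        return frozenset(self._connectivity)

    def connectivity_map(self) -> dict[str, int]:
        """Per-target connectivity under the active relation filter.

        The values sum to the number of filtered edges (in ``"in"`` mode);
        genes without an incoming edge are absent.
        """
        return dict(self._connectivity)

    def targets_of(self, seed: str) -> frozenset[str]:
        try:
            return self._targets[seed]
        except KeyError:
            raise KeyError(f"unknown seed: {seed!r}") from None

    def downstream_targets(
        self, seed: str, measured_genes: Iterable[str] | None = None
    ) -> frozenset[str]:
        """Targets of *seed*, optionally intersected with the measured genes."""
        t = self.targets_of(seed)
        if measured_genes is None:
            return t
        return t & frozenset(measured_genes)

    # -- io --------------------------------------------------------------
    def to_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("seed\ttarget\trelation\n")
            for seed, target, rtype in self._edges:
                fh.write(f"{seed}\t{target}\t{rtype}\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RegulatoryNetwork({len(self._targets)} seeds, "
            f"{self.n_edges} edges, {len(self._connectivity)} targets)"
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, RegulatoryNetwork) and self._edges == other._edges

    def __hash__(self) -> int:
        return hash(self._edges)


def _parse_edge_list(path: str | Path) -> list[Edge]:
    edges: list[Edge] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "seed":
                continue  # literal header
            if len(parts) != 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            seed, target, rtype = (p.strip() for p in parts)
            if not seed or not target:
                raise NetworkParseError(
                    f"{path}: line {lineno}: empty seed or target"
                )
            if rtype not in RELATION_TYPES:
                raise NetworkParseError(
                    f"{path}: line {lineno}: unknown relation type {rtype!r} "
                    f"(expected one of {sorted(RELATION_TYPES)})"
                )
            edges.append((seed, target, rtype))
    return edges


def _parse_gmt(path: str | Path) -> list[Edge]:
    # GMT: name <TAB> description <TAB> member... ; members get type Expression
    edges: list[Edge] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one member"
                )
            name = parts[0].strip()
            for member in parts[2:]:
                member = member.strip()
                if member:
                    edges.append((name, member, "Expression"))
    return edges


def load_network(
    path: str | Path,
    format: str = "edge_list",
    relation_filter: Iterable[str] | None = None,
    connectivity_mode: str = "in",
) -> RegulatoryNetwork:
    """Load a regulator→target network from an edge list or GMT file.

    Parameters
    ----------
    path
        Tab-separated edge list (``seed<TAB>target<TAB>relation``, ``#``
        comments, optional literal ``seed`` header) or a GMT gene-set file
        (set name = regulator, members typed ``Expression``).
    relation_filter
        Relation types to keep.  Defaults to all known types.  Seeds whose
        every edge is filtered out are dropped.
    """
    if format == "edge_list":
        edges = _parse_edge_list(path)
    elif format == "gmt":
        edges = _parse_gmt(path)
    else:
        raise ValueError(f"unknown network format: {format!r}")
    if relation_filter is None:
        relation_filter = RELATION_TYPES
    rf = frozenset(relation_filter)
    if not rf:
        raise ValueError("relation_filter must be non-empty")
    unknown = rf - RELATION_TYPES
    if unknown:
        raise ValueError(f"unknown relation types in filter: {sorted(unknown)}")
    kept = [e for e in edges if e[2] in rf]
    if not kept:
        raise EmptyNetworkError(
            f"empty network after filtering {path} with {sorted(rf)}"
        )
    return RegulatoryNetwork(kept, connectivity_mode=connectivity_mode)


def connectivity_map(network: RegulatoryNetwork) -> dict[str, int]:
    """Functional alias for :meth:`RegulatoryNetwork.connectivity_map`."""
    return network.connectivity_map()


def downstream_targets(
    network: RegulatoryNetwork, seed: str, measured_genes: Iterable[str]
) -> frozenset[str]:
    """Measured downstream targets of *seed* (may be empty)."""
    return network.downstream_targets(seed, measured_genes)
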