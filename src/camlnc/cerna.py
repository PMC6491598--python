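"""Competing-endogenous-RNA (ceRNA) pairing by shared miRNAs.

Two transcripts bound by the same miRNA(s) form a ceRNA pair.  A pair is
'target-target' when some shared miRNA binds both members perfectly, and
'target-mimic' when the shared miRNAs link the pair through one perfect
and one mimic binding (the classic target-mimicry configuration).  Pairs
whose only shared links are mimic-mimic carry no release-of-repression
logic and are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .data_model import BindingTable, DataError


@dataclass(frozen=True)
class CeRnaPair:
    """Unordered transcript pair sharing at least one miRNA."""

    transcript_a: str
    transcript_b: str
    shared_mirnas: frozenset[str]
    pair_type: str  # 'target-target' or 'target-mimic'

    def __post_init__(self) -> None:
        if self.transcript_a == self.transcript_b:
            raise DataError("a ceRNA pair needs two distinct transcripts")
        if not self.shared_mirnas:
            raise DataError("a ceRNA pair needs a nonempty shared miRNA set")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.transcript_a, self.transcript_b)))


def _binding_modes(bindings: BindingTable) -> dict[str, dict[str, set[str]]]:
    """mirna -> transcript -> set of modes."""
    out: dict[str, dict[str, set[str]]] = {}
    for rec in bindings.records.itertuples():
        out.setdefault(rec.mirna, {}).setdefault(rec.transcript, set()).add(rec.mode)
    return out


def _pair_type(modes_a: set[str], modes_b: set[str]) -> str:
    if "perfect" in modes_a and "perfect" in modes_b:
        return "perfect-perfect"
    if ("perfect" in modes_a and "mimic" in modes_b) or (
        "mimic" in modes_a and "perfect" in modes_b
    ):
        return "perfect-mimic"
    return "mimic-mimic"


def shared_mirna_pairs(
    bindings: BindingTable, include_mimic_mimic: bool = False
) -> list[CeRnaPair]:
    """Enumerate all ceRNA pairs implied by a binding table.

    Typing uses the strongest shared link: any perfect-perfect miRNA makes
    the pair target-target; otherwise any perfect-mimic link makes it
    target-mimic; pairs with only mimic-mimic links are dropped unless
    ``include_mimic_mimic`` (then typed 'mimic-mimic').
    """
    by_mirna = _binding_modes(bindings)
    shared: dict[tuple[str, str], dict[str, str]] = {}
    for mirna, per_tx in by_mirna.items():
        for a, b in combinations(sorted(per_tx), 2):
            shared.setdefault((a, b), {})[mirna] = _pair_type(per_tx[a], per_tx[b])

    pairs = []
    for (a, b), links in sorted(shared.items()):
        kinds = set(links.values())
        if "perfect-perfect" in kinds:
            ptype = "target-target"
        elif "perfect-mimic" in kinds:
            ptype = "target-mimic"
        elif include_mimic_mimic:
            ptype = "mimic-mimic"
        else:
            continue
        pairs.append(CeRnaPair(a, b, frozenset(links), ptype))
    return pairs


def focal_cerna(
    bindings: BindingTable, focal_id: str, include_mimic_mimic: bool = False
) -> tuple[list[CeRnaPair], set[str]]:
    """ceRNA partners of one focal transcript plus the union of competed miRNAs."""
    if focal_id not in set(bindings.records["transcript"]):
        raise DataError(f"focal transcript {focal_id} absent from binding table")
    pairs = [
        p
        for p in shared_mirna_pairs(bindings, include_mimic_mimic=include_mimic_mimic)
        if focal_id in (p.transcript_a, p.transcript_b)
    ]
    competed: set[str] = set()
    for p in pairs:
        competed |= set(p.shared_mirnas)
    return pairs, competed


def pairs_table(pairs: list[CeRnaPair]) -> pd.DataFrame:
    rows = [
        {
            "transcript_a": p.key[0],
            "transcript_b": p.key[1],
            "pair_type": p.pair_type,
            "shared_mirnas": ";".join(sorted(p.shared_mirnas)),
            "n_shared": len(p.shared_mirnas),
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows, columns=["transcript_a", "transcript_b", "pair_type", "shared_mirnas", "n_shared"]
    )


def cerna_network(
    pairs: list[CeRnaPair], node_classes: dict[str, str]
) -> nx.Graph:
    """Tripartite network: miRNA nodes joined to the transcripts of every pair.

    ``node_classes`` maps ids to one of mRNA / lincRNA / lncNAT / miRNA;
    every transcript and shared miRNA must be classified.
    """
    g = nx.Graph()
    for p in pairs:
        for t in p.key:
            if t not in node_classes:
                raise DataError(f"unclassified node {t}")
            g.add_node(t, kind=node_classes[t])
        for m in sorted(p.shared_mirnas):
            kind = node_classes.get(m, "miRNA")
            g.add_node(m, kind=kind)
            for t in p.key:
                g.add_edge(m, t, pair_type=p.pair_type)
    return g


def cerna_network_export(
    pairs: list[CeRnaPair], node_classes: dict[str, str], path: str
) -> nx.Graph:
    """Write the tripartite ceRNA network as GraphML; returns the graph."""
    g = cerna_network(pairs, node_classes)
    nx.write_graphml(g, path)
    return g
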