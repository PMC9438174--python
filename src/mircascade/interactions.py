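"""Validated miRNA->gene interaction tables: loading, filtering, network export.

Interactions are consumed from a flat TSV in the style of a miRTarBase
export — one row per (miRNA, target gene, source) with an ordinal confidence
class — rather than from live database queries, so runs are reproducible
against a fixed snapshot.  Confidence classes are ordered
``low < moderate < high < very_high``; the pipeline default keeps only
high and very-high confidence pairs whose two endpoints both survived the
upstream expression filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "CONFIDENCE_LEVELS",
    "InteractionPair",
    "load_interactions",
    "write_interactions",
    "restrict_and_filter",
    "export_network",
    "strip_species_prefix",
]

logger = logging.getLogger(__name__)

CONFIDENCE_LEVELS = ("low", "moderate", "high", "very_high")
_CONF_RANK = {c: i for i, c in enumerate(CONFIDENCE_LEVELS)}


@dataclass(frozen=True)
class InteractionPair:
    """One validated miRNA->gene edge with its ordinal confidence class."""

    mirna_id: str
    gene_id: str
    confidence: str
    score: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.confidence not in _CONF_RANK:
            raise ValueError(
                f"unknown confidence {self.confidence!r}; accepted: "
                + "/".join(CONFIDENCE_LEVELS)
            )

    @property
    def confidence_rank(self) -> int:
        return _CONF_RANK[self.confidence]


def strip_species_prefix(mirna_id: str) -> str:
    """Drop a leading species prefix from a miRBase mature name
    (``hsa-miR-124-3p`` -> ``miR-124-3p``)."""
    parts = mirna_id.split("-", 1)
    if len(parts) == 2 and len(parts[0]) == 3 and parts[0].islower():
        return parts[1]
    return mirna_id


def load_interactions(path: str | Path) -> list[InteractionPair]:
    """Parse and validate an interaction TSV.

    Required columns: ``mirna_id``, ``gene_id``, ``confidence``, ``source``;
    ``score`` optional.  Duplicates on (miRNA, gene, source) are collapsed
    keeping the highest confidence.  Unknown confidence labels are an error
    listing the accepted labels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "gene_id", "confidence", "source"):
        if col not in df.columns:
            raise ValueError(f"interaction table missing required column {col!r}")
    bad = sorted(set(df["confidence"]) - set(CONFIDENCE_LEVELS))
    if bad:
        raise ValueError(
            f"unknown confidence label(s) {bad}; accepted: " + "/".join(CONFIDENCE_LEVELS)
        )
    pairs: dict[tuple[str, str, str], InteractionPair] = {}
    for row in df.itertuples(index=False):
        score = None
        if hasattr(row, "score") and pd.notna(row.score) and str(row.score) != "":
            score = float(row.score)
        pair = InteractionPair(
            str(row.mirna_id), str(row.gene_id), str(row.confidence), score, str(row.source)
        )
        key = (pair.mirna_id, pair.gene_id, pair.source)
        prev = pairs.get(key)
        if prev is None or pair.confidence_rank > prev.confidence_rank:
            pairs[key] = pair
    return list(pairs.values())


def write_interactions(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mirna_id": [p.mirna_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "confidence": [p.confidence for p in pairs],
            "score": [p.score for p in pairs],
            "source": [p.source for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def restrict_and_filter(
    pairs: Iterable[InteractionPair],
    gene_ids: Iterable[str],
    mirna_ids: Iterable[str],
    min_confidence: str = "high",
) -> list[InteractionPair]:
    """Keep pairs whose gene AND miRNA survived filtering, at/above a confidence.

    Output is monotone non-increasing in ``min_confidence``: lowering the
    threshold can only add pairs.
    """
    if min_confidence not in _CONF_RANK:
        raise ValueError(
            f"unknown confidence {min_confidence!r}; accepted: " + "/".join(CONFIDENCE_LEVELS)
        )
    genes = set(gene_ids)
    mirnas = set(mirna_ids)
    min_rank = _CONF_RANK[min_confidence]
    return [
        p
        for p in pairs
        if p.gene_id in genes and p.mirna_id in mirnas and p.confidence_rank >= min_rank
    ]


def export_network(
    pairs: Iterable[InteractionPair],
    fold_changes: Mapping[str, float],
    path: str | Path,
) -> nx.Graph:
    """Write the bipartite gene/miRNA network as GraphML.

    Node attributes: ``kind`` (gene|mirna), ``fold_change`` (linear scale) and
    ``regulation`` (up/down by fold change vs 1).  Edge attributes:
    ``confidence`` and, when present, ``score``.  Nodes without a supplied
    fold change get 1.0 with a logged warning.  The graph is strictly
    bipartite by construction (edges only connect a miRNA to a gene).
    """
    g = nx.Graph()
    pairs = list(pairs)

    def _node_attrs(node_id: str, kind: str) -> dict:
        fc = fold_changes.get(node_id)
        if fc is None:
            logger.warning("no fold change supplied for %s %s; defaulting to 1.0", kind, node_id)
            fc = 1.0
        regulation = "up" if fc > 1 else ("down" if fc < 1 else "flat")
        return {"kind": kind, "fold_change": float(fc), "regulation": regulation}

    for p in pairs:
        g.add_node(p.gene_id, **_node_attrs(p.gene_id, "gene"))
        g.add_node(p.mirna_id, **_node_attrs(p.mirna_id, "mirna"))
        attrs = {"confidence": p.confidence}
        if p.score is not None:
            attrs["score"] = float(p.score)
        g.add_edge(p.mirna_id, p.gene_id, **attrs)
    nx.write_graphml(g, path)
    return g
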