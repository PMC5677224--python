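"""RDF export of low-/high-level contexts and graph-backed retrieval.

Contexts serialize into a single artifact-owned namespace whose local names
follow the ontology property vocabulary (``hasActivity``, ``hasLocation``,
``hasEmotion``, ``hasFood``, ``hasBloodGlucose``, ``hasBloodPressure``,
``hasUser``, ``hasStartTime``, ``hasEndTime``, ``isContextOf``).  JSON-lines
remains the processing substrate; the graph is an export/interchange format.
Serialization is canonical (triples inserted in sorted order; N-Triples
additionally line-sorted) so export → import → export is byte-stable.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, XSD

from .model import HLCInstance, LLCRecord
from .sync import SyncWindow, synchronize

CF = Namespace("https://contextfuse.example.org/ns#")

_HLC_PROPS = (
    "hasActivity",
    "hasLocation",
    "hasEmotion",
    "hasFood",
    "hasBloodGlucose",
    "hasBloodPressure",
)


def _time_literal(t: float) -> Literal:
    return Literal(f"{t:.3f}", datatype=XSD.decimal)


def build_graph(
    llcs: Sequence[LLCRecord] = (), hlcs: Sequence[HLCInstance] = ()
) -> Graph:
    """One resource per record/instance with its property assertions and
    interval literals."""
    # canonical node numbering: independent of input order
    llcs = sorted(llcs, key=lambda r: (r.user_id, r.start, r.category, r.label or ""))
    hlcs = sorted(hlcs, key=lambda h: (h.user_id, h.start, h.domain))
    triples: List[Tuple] = []
    for i, rec in enumerate(llcs):
        node = CF[f"llc_{i:06d}"]
        triples.append((node, RDF.type, CF.LowLevelContext))
        triples.append((node, CF.category, Literal(rec.category)))
        triples.append((node, CF.hasUser, Literal(rec.user_id)))
        triples.append((node, CF.hasStartTime, _time_literal(rec.start)))
        triples.append((node, CF.hasEndTime, _time_literal(rec.end)))
        if rec.label is not None:
            triples.append((node, CF.hasLabel, CF[rec.label]))
    for i, inst in enumerate(hlcs):
        node = CF[f"hlc_{i:06d}"]
        triples.append((node, RDF.type, CF.HighLevelContext))
        triples.append((node, CF.domain, Literal(inst.domain)))
        triples.append((node, CF.hasUser, Literal(inst.user_id)))
        triples.append((node, CF.hasStartTime, _time_literal(inst.start)))
        triples.append((node, CF.hasEndTime, _time_literal(inst.end)))
        triples.append((CF[f"user_{inst.user_id}"], CF.isContextOf, node))
        for prop in _HLC_PROPS:
            if prop in inst.assertions:
                triples.append((node, CF[prop], CF[inst.assertions[prop]]))
        if inst.inferred_class is not None:
            triples.append((node, CF.inferredClass, CF[inst.inferred_class]))
    graph = Graph()
    graph.bind("cf", CF)
    for t in sorted(triples, key=lambda t: tuple(map(str, t))):
        graph.add(t)
    return graph


def export_rdf(
    llcs: Sequence[LLCRecord] = (),
    hlcs: Sequence[HLCInstance] = (),
    dialect: str = "turtle",
) -> str:
    """Serialize contexts as ``turtle`` or ``nt`` (N-Triples, line-sorted)."""
    if dialect not in ("turtle", "nt"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'turtle' or 'nt'")
    graph = build_graph(llcs, hlcs)
    if dialect == "nt":
        lines = sorted(
            ln for ln in graph.serialize(format="nt").splitlines() if ln.strip()
        )
        return "\n".join(lines) + "\n"
    return graph.serialize(format="turtle")


def import_rdf(text: str, dialect: str = "turtle") -> Graph:
    graph = Graph()
    graph.parse(data=text, format="turtle" if dialect == "turtle" else "nt")
    return graph


def records_from_graph(graph: Graph) -> List[LLCRecord]:
    """Rebuild the low-level records held in an exported graph."""
    records = []
    for node in sorted(graph.subjects(RDF.type, CF.LowLevelContext)):
        label = graph.value(node, CF.hasLabel)
        records.append(
            LLCRecord(
                user_id=str(graph.value(node, CF.hasUser)),
                category=str(graph.value(node, CF.category)),
                start=float(graph.value(node, CF.hasStartTime)),
                end=float(graph.value(node, CF.hasEndTime)),
                label=str(label).rsplit("#", 1)[-1] if label is not None else None,
            )
        )
    records.sort(key=lambda r: (r.user_id, r.start, r.category, r.label or ""))
    return records


# SPARQL retrieval mirroring the union-of-blocks shape: one block for the
# general cross-domain categories, one for nutrition.
_CONCURRENT_QUERY = """
PREFIX cf: <https://contextfuse.example.org/ns#>
SELECT ?llc ?category ?start ?end WHERE {
  {
    ?llc a cf:LowLevelContext ;
         cf:hasUser ?user ;
         cf:category ?category ;
         cf:hasStartTime ?start ;
         cf:hasEndTime ?end .
    FILTER (?category != "Food")
  } UNION {
    ?llc a cf:LowLevelContext ;
         cf:hasUser ?user ;
         cf:category ?category ;
         cf:hasStartTime ?start ;
         cf:hasEndTime ?end .
    FILTER (?category = "Food")
  }
  FILTER (?start >= ?lo && ?start <= ?hi)
}
"""


def query_concurrent(
    graph: Graph,
    user: str,
    window: Tuple[float, float],
    sync_window: Optional[SyncWindow] = None,
) -> List[List[LLCRecord]]:
    """Retrieve one user's records in a time window from the graph and group
    them exactly as the synchronizer would on the original records."""
    lo, hi = window
    rows = graph.query(
        _CONCURRENT_QUERY,
        initBindings={"user": Literal(user), "lo": _time_literal(lo), "hi": _time_literal(hi)},
    )
    records = []
    for row in rows:
        node = row["llc"]
        label = graph.value(node, CF.hasLabel)
        records.append(
            LLCRecord(
                user_id=user,
                category=str(row["category"]),
                start=float(row["start"]),
                end=float(row["end"]),
                label=str(label).rsplit("#", 1)[-1] if label is not None else None,
            )
        )
    records.sort(key=lambda r: (r.start, r.category, r.label or ""))
    return synchronize(records, sync_window, user_id=user)
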