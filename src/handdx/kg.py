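"""In-memory hand-disease knowledge graph.

A property graph of typed entities (Department, Disease, Drug, Food,
Producer) connected by typed directed relations:

==================  =====================  ==========================
Relation            Domain -> Range        Meaning
==================  =====================  ==========================
acompany_with       Disease -> Disease     comorbidity / complication
belongs_to          Disease -> Department  treating department
do_eat              Disease -> Food        recommended food
no_eat              Disease -> Food        food to avoid
recommand_eat       Disease -> Food        recommended recipe
recommand_drug      Disease -> Drug        recommended medication
drugs_of            Producer -> Drug       producer's marketed drug
==================  =====================  ==========================

Each disease additionally carries eight text attributes (desc, cause,
prevention, cure_lasttime, cure_way, cured_probe, easy_get, plus the name
itself) and a free-text symptom list.  The graph is loaded from
line-delimited JSON disease records and held in a :class:`networkx`
multigraph; an optional write-only Cypher-text export is provided for users
who run a graph database.

Entity names are matched exactly after Unicode NFKC normalization and
whitespace trimming; no fuzzy matching.
"""

from __future__ import annotations

import json
import unicodedata
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
from pydantic import BaseModel, Field, field_validator

from .errors import (
    DuplicateDiseaseName,
    SchemaViolation,
    UnknownAttribute,
    UnknownEntity,
)

ENTITY_TYPES = ("Department", "Disease", "Drug", "Food", "Producer")

#: relation type -> (head entity type, tail entity type)
RELATION_SCHEMA: dict[str, tuple[str, str]] = {
    "acompany_with": ("Disease", "Disease"),
    "belongs_to": ("Disease", "Department"),
    "do_eat": ("Disease", "Food"),
    "drugs_of": ("Producer", "Drug"),
    "no_eat": ("Disease", "Food"),
    "recommand_drug": ("Disease", "Drug"),
    "recommand_eat": ("Disease", "Food"),
}

#: the disease attribute types exposed by :func:`attribute`
ATTRIBUTE_TYPES = (
    "name", "desc", "cause", "prevention",
    "cure_lasttime", "cure_way", "cured_probe", "easy_get",
    "symptoms",
)


def normalize_name(name: str) -> str:
    """NFKC-normalize and trim an entity name."""
    return unicodedata.normalize("NFKC", name).strip()


class DiseaseRecord(BaseModel):
    """One line-delimited disease record.

    List-valued fields may be empty; ``drug_producers`` holds
    (producer, drug) pairs.
    """

    name: str
    desc: Optional[str] = None
    cause: Optional[str] = None
    prevention: Optional[str] = None
    cure_lasttime: Optional[str] = None
    cure_way: list[str] = Field(default_factory=list)
    cured_probe: Optional[str] = None
    easy_get: Optional[str] = None
    symptoms: list[str] = Field(default_factory=list)
    departments: list[str] = Field(default_factory=list)
    recommended_foods: list[str] = Field(default_factory=list)
    avoided_foods: list[str] = Field(default_factory=list)
    recommended_recipes: list[str] = Field(default_factory=list)
    recommended_drugs: list[str] = Field(default_factory=list)
    drug_producers: list[tuple[str, str]] = Field(default_factory=list)
    complications: list[str] = Field(default_factory=list)

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        v = normalize_name(v)
        if not v:
            raise ValueError("disease name must be nonempty")
        return v


class KnowledgeGraph:
    """Typed entity/relation store backed by a networkx multigraph."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction ------------------------------------------------------

    def _add_entity(self, name: str, etype: str) -> str:
        name = normalize_name(name)
        if not name:
            raise SchemaViolation(f"empty {etype} name")
        if etype not in ENTITY_TYPES:
            raise SchemaViolation(f"unknown entity type {etype!r}")
        existing = self._g.nodes.get(name)
        if existing is not None and existing["etype"] != etype:
            raise SchemaViolation(
                f"entity {name!r} already typed {existing['etype']}, "
                f"cannot retype as {etype}"
            )
        self._g.add_node(name, etype=etype)
        return name

    def _add_relation(self, head: str, rel_type: str, tail: str) -> None:
        if rel_type not in RELATION_SCHEMA:
            raise SchemaViolation(f"unknown relation type {rel_type!r}")
        dom, rng = RELATION_SCHEMA[rel_type]
        head, tail = normalize_name(head), normalize_name(tail)
        for name, expected in ((head, dom), (tail, rng)):
            node = self._g.nodes.get(name)
            if node is None:
                raise SchemaViolation(f"relation endpoint {name!r} not loaded")
            if node["etype"] != expected:
                raise SchemaViolation(
                    f"{rel_type}: {name!r} is {node['etype']}, expected {expected}"
                )
        if not self._g.has_edge(head, tail, key=rel_type):
            self._g.add_edge(head, tail, key=rel_type)

    # -- queries -----------------------------------------------------------

    def has_entity(self, name: str) -> bool:
        return normalize_name(name) in self._g

    def entity_type(self, name: str) -> str:
        key = normalize_name(name)
        if key not in self._g:
            raise UnknownEntity(f"no entity named {name!r}")
        return self._g.nodes[key]["etype"]

    def entities(self, etype: str | None = None) -> list[str]:
        return sorted(
            n for n, d in self._g.nodes(data=True)
            if etype is None or d["etype"] == etype
        )

    def relations(self) -> set[tuple[str, str, str]]:
        """All (head, rel_type, tail) triples."""
        return {(h, k, t) for h, t, k in self._g.edges(keys=True)}

    def neighbors(self, entity_name: str, rel_type: str, direction: str = "out") -> list[str]:
        """Sorted, deduplicated 1-hop neighbours along ``rel_type``.

        ``direction`` 'out' follows head->tail edges from the entity,
        'in' follows them backwards.
        """
        key = normalize_name(entity_name)
        if key not in self._g:
            raise UnknownEntity(f"no entity named {entity_name!r}")
        if rel_type not in RELATION_SCHEMA:
            raise SchemaViolation(f"unknown relation type {rel_type!r}")
        if direction not in ("out", "in"):
            raise ValueError("direction must be 'out' or 'in'")
        if direction == "out":
            found = {t for _, t, k in self._g.out_edges(key, keys=True) if k == rel_type}
        else:
            found = {h for h, _, k in self._g.in_edges(key, keys=True) if k == rel_type}
        return sorted(found)

    def attribute(self, disease_name: str, attr_type: str):
        """Stored attribute value of a disease, or None when absent."""
        key = normalize_name(disease_name)
        node = self._g.nodes.get(key)
        if node is None or node["etype"] != "Disease":
            raise UnknownEntity(f"no disease named {disease_name!r}")
        if attr_type not in ATTRIBUTE_TYPES:
            raise UnknownAttribute(f"unknown attribute type {attr_type!r}")
        return node.get("attrs", {}).get(attr_type)

    def stats(self) -> dict:
        """Entity and relation counts per type, with totals."""
        by_etype = {t: 0 for t in ENTITY_TYPES}
        for _, d in self._g.nodes(data=True):
            by_etype[d["etype"]] += 1
        by_rel = {r: 0 for r in RELATION_SCHEMA}
        for _, _, k in self._g.edges(keys=True):
            by_rel[k] += 1
        return {
            "entities": by_etype,
            "relations": by_rel,
            "total_entities": sum(by_etype.values()),
            "total_relations": sum(by_rel.values()),
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            dict(self._g.nodes(data=True)) == dict(other._g.nodes(data=True))
            and self.relations() == other.relations()
        )

    # -- export ------------------------------------------------------------

    def to_cypher(self) -> str:
        """Write-only Cypher CREATE statements for the whole graph."""
        def q(s: str) -> str:
            return s.replace("\\", "\\\\").replace("'", "\\'")

        lines = []
        for name in self.entities():
            node = self._g.nodes[name]
            props = [f"name: '{q(name)}'"]
            for k, v in sorted(node.get("attrs", {}).items()):
                if v is None or k == "name":
                    continue
                if isinstance(v, list):
                    items = ", ".join(f"'{q(x)}'" for x in v)
                    props.append(f"{k}: [{items}]")
                else:
                    props.append(f"{k}: '{q(v)}'")
            lines.append(f"CREATE (:{node['etype']} {{{', '.join(props)}}});")
        for head, rel, tail in sorted(self.relations()):
            lines.append(
                f"MATCH (a {{name: '{q(head)}'}}), (b {{name: '{q(tail)}'}}) "
                f"CREATE (a)-[:{rel}]->(b);"
            )
        return "\n".join(lines) + "\n"


def load_records(records: Iterable[DiseaseRecord | dict]) -> KnowledgeGraph:
    """Build a :class:`KnowledgeGraph` from disease records.

    One Disease entity per record; food/drug/department/producer names are
    deduplicated across records; complications become Disease entities
    (stub nodes when no record of their own exists).

    Raises
    ------
    DuplicateDiseaseName
        if two records share a (normalized) disease name.
    SchemaViolation
        on malformed records or type clashes.
    """
    g = KnowledgeGraph()
    parsed: list[DiseaseRecord] = []
    seen: set[str] = set()
    for rec in records:
        if isinstance(rec, dict):
            try:
                rec = DiseaseRecord(**rec)
            except Exception as err:
                raise SchemaViolation(f"bad record: {err}") from None
        if rec.name in seen:
            raise DuplicateDiseaseName(rec.name)
        seen.add(rec.name)
        parsed.append(rec)

    # entities first (complications may forward-reference other records)
    for rec in parsed:
        node = g._add_entity(rec.name, "Disease")
        g._g.nodes[node]["attrs"] = {
            "name": rec.name,
            "desc": rec.desc,
            "cause": rec.cause,
            "prevention": rec.prevention,
            "cure_lasttime": rec.cure_lasttime,
            "cure_way": list(rec.cure_way) or None,
            "cured_probe": rec.cured_probe,
            "easy_get": rec.easy_get,
            "symptoms": list(rec.symptoms) or None,
        }
    for rec in parsed:
        for comp in rec.complications:
            g._add_entity(comp, "Disease")
        for dept in rec.departments:
            g._add_entity(dept, "Department")
        for food in (*rec.recommended_foods, *rec.avoided_foods, *rec.recommended_recipes):
            g._add_entity(food, "Food")
        for drug in rec.recommended_drugs:
            g._add_entity(drug, "Drug")
        for producer, drug in rec.drug_producers:
            g._add_entity(producer, "Producer")
            g._add_entity(drug, "Drug")

    for rec in parsed:
        for comp in rec.complications:
            g._add_relation(rec.name, "acompany_with", comp)
        for dept in rec.departments:
            g._add_relation(rec.name, "belongs_to", dept)
        for food in rec.recommended_foods:
            g._add_relation(rec.name, "do_eat", food)
        for food in rec.avoided_foods:
            g._add_relation(rec.name, "no_eat", food)
        for food in rec.recommended_recipes:
            g._add_relation(rec.name, "recommand_eat", food)
        for drug in rec.recommended_drugs:
            g._add_relation(rec.name, "recommand_drug", drug)
        for producer, drug in rec.drug_producers:
            g._add_relation(producer, "drugs_of", drug)
    return g


def read_records(path: str | Path) -> list[DiseaseRecord]:
    """Parse a UTF-8 line-delimited JSON records file."""
    records = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line:
            continue
        try:
            records.append(DiseaseRecord(**json.loads(line)))
        except Exception as err:
            raise SchemaViolation(f"{path}:{lineno}: {err}") from None
    return records


def load_file(path: str | Path) -> KnowledgeGraph:
    """Load a knowledge graph from a line-delimited JSON records file."""
    return load_records(read_records(path))
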