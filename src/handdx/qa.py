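"""Question answering over the hand-disease knowledge graph.

The pipeline is the classic retrieve-by-template design used by deployed
medical QA systems: a dictionary automaton links question text to graph
entities, a keyword table classifies the question into a closed set of
intents, each intent expands to a fixed query template (an attribute lookup
or a 1-hop neighbour retrieval), the template runs against the graph, and a
per-intent sentence template renders the results.  Retrieval is single-step
(one hop); every retrieved entity is kept (degenerate ranking with all
scores equal and threshold zero), so the answer set equals the retrieved
set.  The whole pipeline is deterministic: identical question and graph give
a byte-identical answer.

Matching is exact substring matching over lower-cased text — entity linking
inherits the knowledge graph's exact-name policy (no fuzzy matching).  The
shipped keyword table is English; an alternative locale table can be passed
to :func:`build_dictionary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._ahocorasick import AhoCorasick
from .errors import EmptyGraph, UnsupportedIntent
from .kg import ATTRIBUTE_TYPES, KnowledgeGraph

INTENT_TYPES = (
    "desc", "cause", "prevention", "cure_way", "cure_lasttime",
    "cured_probe", "easy_get", "symptom", "complication", "department",
    "food_recommend", "food_avoid", "drug_recommend", "drug_producer",
)

#: default (English) trigger table: phrase -> intent type.  Longer phrases
#: win over shorter overlapping ones (e.g. "cure rate" over "cure",
#: "avoid eating" over "eat").
DEFAULT_KEYWORDS: dict[str, str] = {
    "what is": "desc", "tell me about": "desc", "introduction": "desc",
    "introduce": "desc", "describe": "desc",
    "cause": "cause", "causes": "cause", "caused": "cause",
    "why do people get": "cause", "etiology": "cause", "reason for": "cause",
    "prevent": "prevention", "prevention": "prevention",
    "preventive": "prevention", "how to avoid getting": "prevention",
    "treatment": "cure_way", "treat": "cure_way", "therapy": "cure_way",
    "cure": "cure_way", "heal": "cure_way",
    "how long": "cure_lasttime", "duration": "cure_lasttime",
    "treatment cycle": "cure_lasttime",
    "cure rate": "cured_probe", "cure probability": "cured_probe",
    "chance of recovery": "cured_probe", "how likely": "cured_probe",
    "who gets": "easy_get", "susceptible": "easy_get", "prone to": "easy_get",
    "who is at risk": "easy_get",
    "symptom": "symptom", "symptoms": "symptom", "signs of": "symptom",
    "manifestation": "symptom",
    "complication": "complication", "complications": "complication",
    "comorbid": "complication", "comorbidities": "complication",
    "department": "department", "which doctor": "department",
    "specialist": "department", "clinic": "department",
    "eat": "food_recommend", "diet": "food_recommend",
    "food": "food_recommend", "recipes": "food_recommend",
    "avoid eating": "food_avoid", "not eat": "food_avoid",
    "avoid food": "food_avoid", "foods to avoid": "food_avoid",
    "dietary restriction": "food_avoid",
    "drug": "drug_recommend", "drugs": "drug_recommend",
    "medication": "drug_recommend", "medicine": "drug_recommend",
    "producer": "drug_producer", "manufacturer": "drug_producer",
    "who makes": "drug_producer", "produced by": "drug_producer",
}

#: sentence templates keyed by intent
_RENDER_TEMPLATES: dict[str, str] = {
    "desc": "{entity}: {items}",
    "cause": "Causes of {entity}: {items}",
    "prevention": "Prevention of {entity}: {items}",
    "cure_way": "Treatment methods for {entity}: {items}",
    "cure_lasttime": "Typical treatment duration for {entity}: {items}",
    "cured_probe": "Cure probability for {entity}: {items}",
    "easy_get": "Susceptible population for {entity}: {items}",
    "symptom": "Symptoms of {entity}: {items}",
    "complication": "Complications of {entity}: {items}",
    "department": "Departments treating {entity}: {items}",
    "food_recommend": "Recommended foods for {entity}: {items}",
    "food_avoid": "Foods to avoid with {entity}: {items}",
    "drug_recommend": "Recommended drugs for {entity}: {items}",
    "drug_producer": "Producers of {entity}: {items}",
}

CLARIFICATION = (
    "Sorry, I could not find a known disease, food or drug in your question. "
    "Could you rephrase it with the exact name?"
)


@dataclass(frozen=True)
class EntityMatch:
    surface: str
    entity_name: str
    entity_type: str
    span: tuple[int, int]


@dataclass(frozen=True)
class QuestionIntent:
    intent_type: str
    matched_entities: tuple[EntityMatch, ...]


@dataclass(frozen=True)
class QueryPrimitive:
    """One retrieval: an attribute lookup or a 1-hop neighbour lookup."""

    kind: str  # "attribute" | "neighbors"
    entity: str
    target: str  # attribute type, or relation type
    direction: str = "out"  # neighbors only


@dataclass(frozen=True)
class QueryPlan:
    intent_type: str
    primitives: tuple[QueryPrimitive, ...]


@dataclass
class AnswerSet:
    """Results of one question: per-intent items with provenance."""

    results: list[dict] = field(default_factory=list)
    rendered_text: str = ""
    empty_flag: bool = True


@dataclass(frozen=True)
class Dictionary:
    """Entity automaton plus the intent keyword table (both lower-cased)."""

    automaton: AhoCorasick
    entity_index: dict[str, tuple[str, str]]  # lowercase -> (name, type)
    keyword_automaton: AhoCorasick
    keyword_table: dict[str, str]


def build_dictionary(
    g: KnowledgeGraph, keywords: Optional[dict[str, str]] = None
) -> Dictionary:
    """Build the entity-matching automaton and intent keyword table."""
    names = g.entities()
    if not names:
        raise EmptyGraph("cannot build a dictionary from an empty graph")
    keywords = dict(keywords if keywords is not None else DEFAULT_KEYWORDS)
    for phrase, intent in keywords.items():
        if intent not in INTENT_TYPES:
            raise UnsupportedIntent(f"keyword {phrase!r} maps to unknown intent {intent!r}")
    entity_index = {name.lower(): (name, g.entity_type(name)) for name in names}
    lowered = {k.lower(): v for k, v in keywords.items()}
    return Dictionary(
        automaton=AhoCorasick(entity_index),
        entity_index=entity_index,
        keyword_automaton=AhoCorasick(lowered),
        keyword_table=lowered,
    )


def _resolve_longest(
    hits: Sequence[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    """Resolve overlapping matches: longest wins, ties go to the leftmost."""
    kept: list[tuple[int, int, str]] = []
    for hit in sorted(hits, key=lambda h: (-(h[1] - h[0]), h[0])):
        if all(hit[1] <= k[0] or hit[0] >= k[1] for k in kept):
            kept.append(hit)
    return sorted(kept, key=lambda h: h[0])


def match_entities(question: str, dictionary: Dictionary) -> list[EntityMatch]:
    """All graph entities occurring in the question, longest-match resolved,
    sorted by span start."""
    text = question.lower()
    hits = _resolve_longest(list(dictionary.automaton.find_all(text)))
    matches = []
    for start, end, surface in hits:
        name, etype = dictionary.entity_index[surface]
        matches.append(
            EntityMatch(
                surface=question[start:end],
                entity_name=name,
                entity_type=etype,
                span=(start, end),
            )
        )
    return matches


def classify_question(
    question: str,
    matches: Sequence[EntityMatch],
    dictionary: Dictionary,
) -> list[QuestionIntent]:
    """Map trigger phrases to intents.

    One intent per triggered keyword group, ordered by first trigger
    occurrence; with entity matches but no trigger the default intent is
    ``desc``; with no entity matches the list is empty (the caller emits a
    clarification).
    """
    if not matches:
        return []
    text = question.lower()
    # trigger phrases inside a matched entity span are part of the entity
    # name, not a question cue
    spans = [m.span for m in matches]
    hits = [
        h for h in _resolve_longest(list(dictionary.keyword_automaton.find_all(text)))
        if not any(s <= h[0] and h[1] <= e for s, e in spans)
    ]
    ordered: list[str] = []
    for start, _end, phrase in sorted(hits, key=lambda h: h[0]):
        intent = dictionary.keyword_table[phrase]
        if intent not in ordered:
            ordered.append(intent)
    if not ordered:
        ordered = ["desc"]
    ents = tuple(matches)
    return [QuestionIntent(intent, ents) for intent in ordered]


#: intent -> (primitive kind, target, direction); executed per disease entity
_TEMPLATES: dict[str, tuple[tuple[str, str, str], ...]] = {
    "desc": (("attribute", "desc", "out"),),
    "cause": (("attribute", "cause", "out"),),
    "prevention": (("attribute", "prevention", "out"),),
    "cure_way": (("attribute", "cure_way", "out"),),
    "cure_lasttime": (("attribute", "cure_lasttime", "out"),),
    "cured_probe": (("attribute", "cured_probe", "out"),),
    "easy_get": (("attribute", "easy_get", "out"),),
    "symptom": (("attribute", "symptoms", "out"),),
    "complication": (("neighbors", "acompany_with", "out"),),
    "department": (("neighbors", "belongs_to", "out"),),
    "food_recommend": (
        ("neighbors", "do_eat", "out"),
        ("neighbors", "recommand_eat", "out"),
    ),
    "food_avoid": (("neighbors", "no_eat", "out"),),
    "drug_recommend": (("neighbors", "recommand_drug", "out"),),
}


def build_query(intent: QuestionIntent, g: KnowledgeGraph) -> QueryPlan:
    """Expand an intent into its fixed retrieval template.

    Disease-anchored intents run per matched disease; the drug_producer
    intent is a reverse lookup from matched drug entities.
    """
    if not intent.matched_entities:
        raise UnsupportedIntent("an intent needs at least one matched entity")
    prims: list[QueryPrimitive] = []
    if intent.intent_type == "drug_producer":
        for m in intent.matched_entities:
            if g.has_entity(m.entity_name) and g.entity_type(m.entity_name) == "Drug":
                prims.append(
                    QueryPrimitive("neighbors", m.entity_name, "drugs_of", "in")
                )
    elif intent.intent_type in _TEMPLATES:
        for m in intent.matched_entities:
            if g.has_entity(m.entity_name) and g.entity_type(m.entity_name) == "Disease":
                for kind, target, direction in _TEMPLATES[intent.intent_type]:
                    prims.append(QueryPrimitive(kind, m.entity_name, target, direction))
    else:
        raise UnsupportedIntent(f"no query template for intent {intent.intent_type!r}")
    return QueryPlan(intent.intent_type, tuple(prims))


def execute_query(plan: QueryPlan, g: KnowledgeGraph) -> list[dict]:
    """Run every primitive; union results per (entity, intent), deduplicated
    and sorted, keeping provenance.  An unknown entity yields an empty
    result with a warning instead of raising."""
    by_entity: dict[str, dict] = {}
    for prim in plan.primitives:
        slot = by_entity.setdefault(
            prim.entity,
            {"entity": prim.entity, "intent": plan.intent_type,
             "items": [], "provenance": [], "warning": None},
        )
        if not g.has_entity(prim.entity):
            slot["warning"] = f"unknown entity {prim.entity!r}"
            continue
        if prim.kind == "attribute":
            value = g.attribute(prim.entity, prim.target)
            items = (
                [] if value is None
                else list(value) if isinstance(value, list)
                else [value]
            )
            source = f"attribute:{prim.target}"
        else:
            items = g.neighbors(prim.entity, prim.target, prim.direction)
            source = f"relation:{prim.target}:{prim.direction}"
        for item in items:
            if item not in slot["items"]:
                slot["items"].append(item)
                slot["provenance"].append(source)
    for slot in by_entity.values():
        order = sorted(range(len(slot["items"])), key=lambda i: slot["items"][i])
        slot["items"] = [slot["items"][i] for i in order]
        slot["provenance"] = [slot["provenance"][i] for i in order]
    return [by_entity[k] for k in sorted(by_entity)]


def _render(results: list[dict]) -> str:
    sentences = []
    for res in results:
        if not res["items"]:
            continue
        template = _RENDER_TEMPLATES[res["intent"]]
        sentences.append(
            template.format(entity=res["entity"], items="; ".join(res["items"]))
        )
    return "\n".join(sentences)


def answer(
    question: str,
    g: KnowledgeGraph,
    dictionary: Optional[Dictionary] = None,
) -> AnswerSet:
    """End-to-end question answering: match, classify, query, render."""
    question = question.strip()
    if not question:
        return AnswerSet(rendered_text=CLARIFICATION, empty_flag=True)
    if dictionary is None:
        dictionary = build_dictionary(g)
    matches = match_entities(question, dictionary)
    intents = classify_question(question, matches, dictionary)
    if not intents:
        return AnswerSet(rendered_text=CLARIFICATION, empty_flag=True)
    results: list[dict] = []
    for intent in intents:
        results.extend(execute_query(build_query(intent, g), g))
    empty = all(not r["items"] for r in results)
    text = _render(results)
    if not text:
        text = (
            "No information found in the knowledge graph for that question."
        )
    return AnswerSet(results=results, rendered_text=text, empty_flag=empty)
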