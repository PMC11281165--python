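"""A small synthetic hand-disease knowledge graph for examples and tests.

The records below are a miniature stand-in for the crawled 1805-disease
corpus the full system runs on: a handful of hand-related conditions with
the same field layout, including the two canonical worked examples (the
tendon sheath cyst attribute row and the tenosynovitis -> purulent
dactylitis comorbidity triple).  Content is synthetic/illustrative, not
medical advice.
"""

from __future__ import annotations

import json
from pathlib import Path

from .kg import DiseaseRecord, KnowledgeGraph, load_records

_RECORDS: list[dict] = [
    {
        "name": "tendon sheath cyst",
        "desc": (
            "Tendon sheath cyst refers to an internal adhesive that occurs "
            "near the tendon sheath, most often on the back of the wrist."
        ),
        "cause": (
            "The disease is more common in the back of the wrist and foot, "
            "associated with repetitive strain of the tendon sheath."
        ),
        "prevention": (
            "Tendon sheath cysts: pay attention to rest in the affected "
            "area and avoid repetitive overuse."
        ),
        "cure_lasttime": "1–3 weeks",
        "cure_way": ["surgical therapy", "rehabilitation therapy", "supportive therapy"],
        "cured_probe": "80%",
        "easy_get": "More common in young and middle-aged people",
        "symptoms": ["painless lump on the wrist", "local soreness with use"],
        "departments": ["orthopedics"],
        "recommended_foods": ["tofu and seafood soup"],
        "avoided_foods": ["alcohol"],
        "recommended_recipes": [],
        "recommended_drugs": [],
        "drug_producers": [],
        "complications": [],
    },
    {
        "name": "tenosynovitis",
        "desc": "Inflammation of the synovial sheath surrounding a tendon.",
        "cause": "Chronic overuse of the fingers and wrist.",
        "prevention": "Limit repetitive gripping; take regular breaks.",
        "cure_lasttime": "2–4 weeks",
        "cure_way": ["drug therapy", "physical therapy"],
        "cured_probe": "90%",
        "easy_get": "People doing repetitive manual work",
        "symptoms": ["pain along the tendon", "triggering of the finger"],
        "departments": ["orthopedics", "rehabilitation department"],
        "recommended_foods": ["stewed lamb with persimmons"],
        "avoided_foods": ["chili pepper"],
        "recommended_recipes": [],
        "recommended_drugs": ["dexamethasone sodium phosphate injection"],
        "drug_producers": [],
        "complications": ["purulent dactylitis"],
    },
    {
        "name": "hand flexor tendon injury",
        "desc": "Laceration or rupture of the flexor tendons of the hand.",
        "cause": "Sharp trauma to the palmar side of the hand.",
        "prevention": "Use protective gloves when handling sharp objects.",
        "cure_lasttime": "6–8 weeks",
        "cure_way": ["surgical therapy", "rehabilitation therapy"],
        "cured_probe": "85%",
        "easy_get": "Manual workers",
        "symptoms": ["inability to flex the finger"],
        "departments": ["hand surgery"],
        "recommended_foods": ["cashew", "tofu and seafood soup"],
        "avoided_foods": [],
        "recommended_recipes": ["fried eggplant with egg"],
        "recommended_drugs": [],
        "drug_producers": [],
        "complications": ["joint stiffness"],
    },
    {
        "name": "Achilles tendinitis",
        "desc": "Overuse inflammation of the Achilles tendon.",
        "cause": "Sudden increase in repetitive loading.",
        "prevention": "Gradual training progression and stretching.",
        "cure_lasttime": "4–6 weeks",
        "cure_way": ["physical therapy", "supportive therapy"],
        "cured_probe": "95%",
        "easy_get": "Runners and jumping athletes",
        "symptoms": ["heel pain after exercise"],
        "departments": ["orthopedics"],
        "recommended_foods": [],
        "avoided_foods": ["chicken wings"],
        "recommended_recipes": [],
        "recommended_drugs": [],
        "drug_producers": [],
        "complications": [],
    },
    {
        "name": "thallium poisoning",
        "desc": "Systemic poisoning by thallium salts, with neuropathy of the hands.",
        "cause": "Ingestion of thallium-contaminated material.",
        "prevention": "Strict handling rules for thallium compounds.",
        "cure_lasttime": "2–6 weeks",
        "cure_way": ["drug therapy", "supportive therapy"],
        "cured_probe": "70%",
        "easy_get": "Industrial chemical workers",
        "symptoms": ["painful ascending neuropathy", "hair loss"],
        "departments": ["emergency department"],
        "recommended_foods": [],
        "avoided_foods": [],
        "recommended_recipes": [],
        "recommended_drugs": ["renqingmangjue"],
        "drug_producers": [["Renqing Mangjue", "renqingmangjue"]],
        "complications": [],
    },
]


def example_records() -> list[DiseaseRecord]:
    """The fixture records as validated :class:`DiseaseRecord` objects."""
    return [DiseaseRecord(**rec) for rec in _RECORDS]


def example_graph() -> KnowledgeGraph:
    """The fixture knowledge graph."""
    return load_records(example_records())


def write_example_records(path: str | Path) -> Path:
    """Write the fixture as a line-delimited JSON records file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in _RECORDS:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return path
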