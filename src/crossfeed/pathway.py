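"""Pathway-coverage scoring of gene annotation tables.

Each species' annotations (EC / KO / GH / CE terms) are scored against an
ordered pathway definition — by default the eight-step chitin/NAG breakdown
and assimilation pathway, whose steps are assigned to early (polymer binding
and cleavage), mid (oligomer conversion, deacetylation, import) and late
(phosphorylated-NAG assimilation) stages.  A step is covered as soon as any
annotation matches any of its accepted terms; coverage counts distinct
steps, not genes, so the score is always out of the number of steps.

EC matching honours trailing wildcard fields: an accepted term ``3.2.1.-``
(ASCII hyphen or typographic minus) covers any fourth field.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources

logger = logging.getLogger(__name__)

TERM_TYPES = ("EC", "KO", "GH", "CE")
STAGES = ("early", "mid", "late")

_EC_RE = re.compile(r"^\d+\.(\d+|[-−])\.(\d+|[-−])\.([\w-]+|−)$")
_KO_RE = re.compile(r"^K\d{5}$")
_GH_RE = re.compile(r"^GH\d+$")
_CE_RE = re.compile(r"^CE\d+$")
_VALIDATORS = {"EC": _EC_RE, "KO": _KO_RE, "GH": _GH_RE, "CE": _CE_RE}


@dataclass(frozen=True)
class PathwayStep:
    step_id: str
    stage: str
    accepted_terms: frozenset[tuple[str, str]]

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"step {self.step_id!r}: bad stage {self.stage!r}")
        if not self.accepted_terms:
            raise ValueError(f"step {self.step_id!r}: no accepted terms")


@dataclass
class PathwayDefinition:
    name: str
    steps: list[PathwayStep]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @classmethod
    def from_dict(cls, doc: dict) -> "PathwayDefinition":
        steps = [
            PathwayStep(
                step_id=s["step_id"],
                stage=s["stage"],
                accepted_terms=frozenset(
                    (t, term) for t, term in s["accepted_terms"]
                ),
            )
            for s in doc["steps"]
        ]
        return cls(name=doc.get("name", "pathway"), steps=steps)

    @classmethod
    def from_json(cls, path) -> "PathwayDefinition":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def default_chitin_pathway() -> PathwayDefinition:
    """The shipped eight-step chitin/NAG pathway definition."""
    text = resources.files("crossfeed.data").joinpath(
        "chitin_pathway.json").read_text()
    return PathwayDefinition.from_dict(json.loads(text))


@dataclass
class AnnotationTable:
    species_id: str
    #: rows of (gene_id, term_type, term)
    annotations: list[tuple[str, str, str]]


@dataclass
class CoverageScore:
    species_id: str
    covered: int
    covered_steps: set[str]
    per_stage: dict[str, int] = field(default_factory=dict)
    n_steps: int = 8


def _ec_matches(term: str, pattern: str) -> bool:
    """EC equality with '-'/'−' wildcards in the *pattern's* trailing fields."""
    t_fields = term.split(".")
    p_fields = pattern.split(".")
    if len(t_fields) != 4 or len(p_fields) != 4:
        return False
    for tf, pf in zip(t_fields, p_fields):
        if pf in ("-", "−"):
            continue
        if tf != pf:
            return False
    return True


def term_matches(term_type: str, term: str,
                 accepted: tuple[str, str]) -> bool:
    acc_type, acc_term = accepted
    if term_type != acc_type:
        return False
    if term_type == "EC":
        return _ec_matches(term, acc_term)
    return term == acc_term


def score_coverage(table: AnnotationTable,
                   pathway: PathwayDefinition) -> CoverageScore:
    """Count the distinct pathway steps matched by the species' annotations.

    Malformed terms are skipped with a warning, never fatal.
    """
    valid: list[tuple[str, str]] = []
    for gene_id, term_type, term in table.annotations:
        if term_type not in TERM_TYPES:
            logger.warning("%s: gene %s has unknown term type %r, skipped",
                           table.species_id, gene_id, term_type)
            continue
        if not _VALIDATORS[term_type].match(term.replace("−", "-")
                                            if term_type == "EC" else term):
            logger.warning("%s: gene %s has malformed %s term %r, skipped",
                           table.species_id, gene_id, term_type, term)
            continue
        valid.append((term_type, term))

    covered_steps = {
        step.step_id
        for step in pathway.steps
        if any(term_matches(tt, term, acc)
               for tt, term in valid for acc in step.accepted_terms)
    }
    per_stage = {stage: 0 for stage in STAGES}
    for step in pathway.steps:
        if step.step_id in covered_steps:
            per_stage[step.stage] += 1
    return CoverageScore(
        species_id=table.species_id,
        covered=len(covered_steps),
        covered_steps=covered_steps,
        per_stage=per_stage,
        n_steps=pathway.n_steps,
    )


def stage_profile(scores: list[CoverageScore]) -> dict[str, dict[str, int]]:
    """Per-species covered-step counts by pathway stage.

    The tabulation behind early/mid/late role assignment: a species whose
    coverage concentrates in one stage is a candidate for that role in the
    community's division of labour.
    """
    return {
        score.species_id: {stage: score.per_stage.get(stage, 0)
                           for stage in STAGES}
        for score in scores
    }
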