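"""Fundamental and realized metabolic niches.

A species' *fundamental niche* is the set of panel carbon sources on which
its own model predicts growth in monoculture.  The *realized niche* is the
set the pooled (mixed-bag) community model can grow on; it is shared by all
members and, by LP monotonicity under reaction addition, always contains
every member's fundamental niche.  The gap between the two (the realized
delta) measures how much a species stands to gain from cross-feeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import spearmanr

from .core import GROWTH_THRESHOLD, MediumSpec, StoichiometricModel, predicts_growth

#: Carbon-source panel used by default throughout the package: one polymer
#: (chitin), its monomer (NAG), mono- and disaccharides, and amino acids.
DEFAULT_PANEL = (
    "chitin", "glucose", "nag", "serine", "glycine", "alanine",
    "maltose", "xylose", "glutamate", "sucrose", "fructose", "arabinose",
)


@dataclass
class NicheProfile:
    fundamental: dict[str, set[str]]
    realized: set[str]
    sizes: dict[str, int] = field(default_factory=dict)
    realized_delta: dict[str, int] = field(default_factory=dict)
    #: species ids sorted by descending niche size, ties lexicographic
    ranking: list[str] = field(default_factory=list)

    def __post_init__(self):
        for species, niche in self.fundamental.items():
            if not niche <= self.realized:
                raise ValueError(
                    f"fundamental niche of {species!r} not contained in realized"
                )
        self.sizes = {s: len(n) for s, n in self.fundamental.items()}
        self.realized_delta = {
            s: len(self.realized) - len(n) for s, n in self.fundamental.items()
        }
        self.ranking = sorted(self.fundamental, key=lambda s: (-self.sizes[s], s))

    def to_records(self) -> list[dict]:
        return [
            {
                "species_id": s,
                "niche_size": self.sizes[s],
                "realized_delta": self.realized_delta[s],
                "sources": ",".join(sorted(self.fundamental[s])),
            }
            for s in self.ranking
        ]


def fundamental_niche(model: StoichiometricModel,
                      panel: list[MediumSpec],
                      threshold: float = GROWTH_THRESHOLD) -> set[str]:
    """Panel carbon sources on which ``model`` grows in monoculture."""
    return {
        medium.carbon_source
        for medium in panel
        if predicts_growth(model, medium, threshold=threshold)
    }


def realized_niche(community: StoichiometricModel,
                   panel: list[MediumSpec],
                   threshold: float = GROWTH_THRESHOLD) -> set[str]:
    """Panel carbon sources supporting growth of the mixed-bag community."""
    return fundamental_niche(community, panel, threshold=threshold)


def niche_table(models: list[StoichiometricModel],
                community: StoichiometricModel,
                panel: list[MediumSpec],
                threshold: float = GROWTH_THRESHOLD) -> NicheProfile:
    """Full niche profile: per-species fundamentals, community realized niche,
    sizes, deltas and the descending-size ranking."""
    if not models:
        raise ValueError("niche_table needs at least one model")
    fundamentals = {
        m.species_id: fundamental_niche(m, panel, threshold=threshold)
        for m in models
    }
    realized = realized_niche(community, panel, threshold=threshold)
    return NicheProfile(fundamental=fundamentals, realized=realized)


def rank_agreement(sizes: dict[str, float],
                   abundances: dict[str, float]) -> float:
    """Spearman rank correlation (average-rank ties) between niche size and
    community abundance over the same species set."""
    if set(sizes) != set(abundances):
        raise ValueError("sizes and abundances must cover the same species")
    if len(sizes) < 3:
        raise ValueError("rank agreement needs at least 3 species")
    species = sorted(sizes)
    rho = spearmanr([sizes[s] for s in species],
                    [abundances[s] for s in species]).statistic
    return float(rho)
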