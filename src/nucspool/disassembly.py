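"""Stochastic nucleosome disassembly across pulling/relaxation cycles.

Each pulling/relaxation cycle maps the tethered species to a next-cycle
species: nucleosome -> {nucleosome, hexasome, tetrasome, bare DNA} and the
subnucleosomal cascade below it.  At 50 mM KOAc the first-cycle nucleosome
outcome distribution is (0.40, 0.28, 0.28, 0.04): hexasomes or tetrasomes
each ~28% of the time, the nucleosome retained 40%, full dissociation the
complement.  The hexasome/tetrasome own distributions are placeholders (the
cascade is observed but its rates are not printed) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

SPECIES = ("nucleosome", "hexasome", "tetrasome", "bareDNA")

#: particle rank, used to enforce the "equal-or-lower" transition rule
_RANK = {s: i for i, s in enumerate(SPECIES)}

#: first-cycle nucleosome outcome distribution at 50 mM KOAc
DEFAULT_NUCLEOSOME_OUTCOMES = {
    "nucleosome": 0.40, "hexasome": 0.28, "tetrasome": 0.28, "bareDNA": 0.04,
}
#: placeholder cascade rates for the subnucleosomal species
DEFAULT_HEXASOME_OUTCOMES = {
    "nucleosome": 0.0, "hexasome": 0.50, "tetrasome": 0.46, "bareDNA": 0.04,
}
DEFAULT_TETRASOME_OUTCOMES = {
    "nucleosome": 0.0, "hexasome": 0.0, "tetrasome": 0.50, "bareDNA": 0.50,
}


@dataclass(frozen=True)
class DisassemblyModel:
    """Per-species next-cycle outcome distributions.

    ``allow_reengagement`` permits the documented tetrasome -> hexasome
    re-engagement (an H2A-H2B dimer that stayed DNA-bound re-forms a
    hexasome); otherwise transitions must be to equal-or-lower rank.
    """

    outcomes: dict = field(default_factory=lambda: {
        "nucleosome": dict(DEFAULT_NUCLEOSOME_OUTCOMES),
        "hexasome": dict(DEFAULT_HEXASOME_OUTCOMES),
        "tetrasome": dict(DEFAULT_TETRASOME_OUTCOMES),
    })
    condition: str = "50 mM KOAc"
    allow_reengagement: bool = False

    def __post_init__(self) -> None:
        for species, dist in self.outcomes.items():
            if species not in SPECIES:
                raise ValueError(f"unknown species {species!r}")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{species} outcome distribution sums to {total}")
            if any(p < 0 for p in dist.values()):
                raise ValueError("probabilities must be >= 0")
            for target, p in dist.items():
                if p > 0 and _RANK[target] < _RANK[species]:
                    if not (self.allow_reengagement and species == "tetrasome"
                            and target == "hexasome"):
                        raise ValueError(
                            f"{species} -> {target} increases particle rank")

    def probabilities(self, species: str) -> np.ndarray:
        dist = self.outcomes[species]
        return np.array([dist.get(s, 0.0) for s in SPECIES])


@dataclass
class CycleRecord:
    cycle_index: int
    species_before: str
    species_after: str


def simulate_cycles(model: DisassemblyModel, n_molecules: int,
                    max_cycles: int = 20, seed: int = 0,
                    start_species: str = "nucleosome") -> list[list[CycleRecord]]:
    """Sample per-molecule cycle sequences until bare DNA or ``max_cycles``.

    Deterministic for a fixed seed: a single ``default_rng(seed)`` stream
    drives all molecules in order.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    sequences: list[list[CycleRecord]] = []
    for _ in range(n_molecules):
        species = start_species
        records: list[CycleRecord] = []
        for cycle in range(max_cycles):
            if species == "bareDNA":
                break
            nxt = SPECIES[rng.choice(4, p=model.probabilities(species))]
            records.append(CycleRecord(cycle, species, nxt))
            species = nxt
        sequences.append(records)
    return sequences


def first_cycle_fractions(sequences: list[list[CycleRecord]]) -> dict[str, float]:
    """Fraction of first cycles ending in each species."""
    outcomes = [seq[0].species_after for seq in sequences if seq]
    n = len(outcomes)
    return {s: outcomes.count(s) / n for s in SPECIES}


def estimate_outcomes(records: list[CycleRecord], confidence: float = 0.95
                      ) -> dict[str, dict[str, float]]:
    """MLE outcome proportions with Wilson score intervals.

    Returns ``{species_after: {"p": ..., "lo": ..., "hi": ..., "n": ...}}``
    over the pooled records.
    """
    if not records:
        raise ValueError("no records to estimate from")
    n = len(records)
    z = norm.ppf(0.5 + confidence / 2.0)
    out: dict[str, dict[str, float]] = {}
    for s in SPECIES:
        k = sum(1 for r in records if r.species_after == s)
        p = k / n
        denom = 1.0 + z ** 2 / n
        centre = (p + z ** 2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
        out[s] = {"p": p, "lo": max(0.0, centre - half),
                  "hi": min(1.0, centre + half), "n": n}
    return out
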