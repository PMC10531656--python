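"""Functional entities and per-site redundancy / vulnerability.

A functional entity is a unique combination of the four categorical
trait values; species sharing all four values belong to the same
entity.  For an assemblage with S species spread over FE entities
present at the site:

* functional redundancy  FR = S / FE              (mean species per entity)
* functional vulnerability FV = (FE - Σ min(n_i - 1, 1)) / FE
  (the fraction of entities represented by a single species)

FR lies in [1, S]; FV lies in [0, 1].  Both are undefined (NaN) for
empty assemblages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trait_space import TRAIT_COLUMNS, validate_trait_table

__all__ = [
    "FunctionalEntityPartition",
    "assign_functional_entities",
    "functional_redundancy",
    "functional_vulnerability",
    "site_entity_metrics",
]


@dataclass
class FunctionalEntityPartition:
    """Partition of a species pool into functional entities."""

    species_to_entity: dict  # species id -> entity id (0-based)
    entity_traits: list  # entity id -> 4-tuple of trait values
    species: list

    @property
    def n_entities(self) -> int:
        return len(self.entity_traits)

    def entity_ids(self, species: list) -> np.ndarray:
        return np.array([self.species_to_entity[s] for s in species], dtype=int)


def assign_functional_entities(traits: pd.DataFrame) -> FunctionalEntityPartition:
    """Group species by exact equality of their 4 categorical traits.

    Entity ids are assigned in lexicographic order of the trait
    combination so the labelling is stable across runs.
    """
    traits = validate_trait_table(traits)
    combos = [tuple(row) for row in traits[list(TRAIT_COLUMNS)].astype(str).to_numpy()]
    unique = sorted(set(combos))
    combo_to_id = {c: i for i, c in enumerate(unique)}
    mapping = {sp: combo_to_id[c] for sp, c in zip(traits.index, combos)}
    return FunctionalEntityPartition(
        species_to_entity=mapping, entity_traits=unique, species=list(traits.index)
    )


def _entity_counts(entity_ids: np.ndarray) -> np.ndarray:
    return np.array(sorted(Counter(entity_ids.tolist()).values()), dtype=int)


def functional_redundancy(entity_ids: np.ndarray | list) -> float:
    """S / FE over the entities present in the assemblage; NaN if empty."""
    entity_ids = np.asarray(entity_ids)
    if entity_ids.size == 0:
        return float("nan")
    counts = _entity_counts(entity_ids)
    return float(counts.sum() / counts.size)


def functional_vulnerability(entity_ids: np.ndarray | list) -> float:
    """Fraction of present entities that hold exactly one species; NaN if empty."""
    entity_ids = np.asarray(entity_ids)
    if entity_ids.size == 0:
        return float("nan")
    counts = _entity_counts(entity_ids)
    non_singleton = np.minimum(counts - 1, 1).sum()
    return float((counts.size - non_singleton) / counts.size)


def site_entity_metrics(
    community: pd.DataFrame, partition: FunctionalEntityPartition
) -> pd.DataFrame:
    """Per-site table of S, FE_site, FR and FV.

    ``community`` is a binary sites × species matrix whose columns must
    all be present in the partition.
    """
    unknown = [s for s in community.columns if s not in partition.species_to_entity]
    if unknown:
        raise KeyError(f"species without trait data: {unknown[:5]}")
    eids = partition.entity_ids(list(community.columns))
    occ = community.to_numpy(dtype=bool)
    rows = []
    for i in range(occ.shape[0]):
        present = eids[occ[i]]
        s = int(present.size)
        if s == 0:
            rows.append((s, 0, np.nan, np.nan))
            continue
        fe = int(np.unique(present).size)
        rows.append(
            (s, fe, functional_redundancy(present), functional_vulnerability(present))
        )
    return pd.DataFrame(
        rows, index=community.index, columns=["S", "FE_site", "FR", "FV"]
    )
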