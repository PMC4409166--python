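"""Random partitioned experimental design.

The species pool is repeatedly split into disjoint communities of equal
richness so that each species occurs exactly once per partition.  With the
default pool of 12 species, richness levels {1, 2, 3, 6, 12} and two
independent partitions at each intermediate level, the design comprises
12 monocultures + (6+6) pairs + (4+4) triples + (2+2) six-species mixtures
+ 1 full mixture = 37 distinct compositions.  Within a partition, two
species sharing a colony morphology may not be assigned to the same
community (they could not be told apart when plated out at the end); a
conflicted member is swapped with a randomly chosen member of another
community until no conflicts remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ENVIRONMENTS, Composition, Microcosm

#: Default colony morphotypes: six morphologies, two species each, which is
#: what forces occasional swaps at the intermediate richness levels.
DEFAULT_MORPHOTYPES = {
    f"s{i:02d}": m
    for i, m in zip(
        range(1, 13),
        ["white", "yellow", "orange", "pink", "cream", "beige"] * 2,
    )
}


@dataclass
class DesignSpec:
    """Parameters of the random partitioned design."""

    n_species: int = 12
    richness_levels: frozenset = frozenset({1, 2, 3, 6, 12})
    partitions_per_level: int = 2
    replicates: int = 3
    morphotypes: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self):
        self.richness_levels = frozenset(int(x) for x in self.richness_levels)
        for level in self.intermediate_levels:
            if self.n_species % level:
                raise ValueError(
                    f"richness level {level} does not divide n_species={self.n_species}"
                )
        if self.morphotypes is None:
            if self.n_species == 12:
                self.morphotypes = dict(DEFAULT_MORPHOTYPES)
            else:
                self.morphotypes = {s: s for s in self.species}  # all distinct
        missing = [s for s in self.species if s not in self.morphotypes]
        if missing:
            raise ValueError(f"morphotype mapping missing species {missing}")

    @property
    def species(self) -> list[str]:
        return [f"s{i:02d}" for i in range(1, self.n_species + 1)]

    @property
    def intermediate_levels(self) -> list[int]:
        return sorted(l for l in self.richness_levels if 1 < l < self.n_species)


def random_partition(species: Sequence[str], level: int, rng: np.random.Generator) -> list[set]:
    """Split ``species`` into disjoint communities of size ``level``.

    Each species appears in exactly one community of the partition.
    """
    species = list(species)
    if level <= 0 or len(species) % level:
        raise ValueError(f"level {level} does not divide {len(species)} species")
    order = list(rng.permutation(species))
    return [set(order[i : i + level]) for i in range(0, len(order), level)]


def _conflicts(group: set, morphotypes: Mapping[str, str]) -> list[str]:
    """Members of ``group`` whose morphotype occurs more than once in it."""
    counts: dict[str, int] = {}
    for s in group:
        counts[morphotypes[s]] = counts.get(morphotypes[s], 0) + 1
    return sorted(s for s in group if counts[morphotypes[s]] > 1)


def resolve_morphotype_conflicts(
    partition: list[set],
    morphotypes: Mapping[str, str],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> list[set]:
    """Swap members between communities until no community holds two
    species of identical colony morphology.

    Each step picks a conflicted community, one of its conflicted members
    uniformly, then a donor community and member uniformly among those for
    which the swap introduces no new conflict on either side.  Raises if the
    morphotype counts make a conflict-free assignment impossible
    (pigeonhole) or if no resolution is found within ``max_attempts`` swaps.
    """
    partition = [set(g) for g in partition]
    level = len(partition[0])
    counts: dict[str, int] = {}
    for g in partition:
        for s in g:
            counts[morphotypes[s]] = counts.get(morphotypes[s], 0) + 1
    worst = max(counts.values())
    if worst > len(partition):
        raise ValueError(
            f"no conflict-free assignment exists: {worst} species share a "
            f"morphotype but there are only {len(partition)} communities of size {level}"
        )
    for _ in range(max_attempts):
        conflicted = [i for i, g in enumerate(partition) if _conflicts(g, morphotypes)]
        if not conflicted:
            return partition
        i = int(rng.choice(conflicted))
        members = _conflicts(partition[i], morphotypes)
        mover = str(rng.choice(members))
        # legal donors: the swap must fix the mover's duplicate without
        # creating a new one on either side (other pre-existing conflicts
        # may remain; they are handled by later swaps)
        recv_morphs = {morphotypes[s] for s in partition[i] if s != mover}
        legal: list[tuple[int, str]] = []
        for j, g in enumerate(partition):
            if j == i:
                continue
            for cand in sorted(g):
                donor_morphs = {morphotypes[s] for s in g if s != cand}
                if (
                    morphotypes[cand] not in recv_morphs
                    and morphotypes[mover] not in donor_morphs
                ):
                    legal.append((j, cand))
        if not legal:
            continue  # retry from another conflicted community next round
        j, cand = legal[int(rng.integers(len(legal)))]
        partition[i].remove(mover)
        partition[i].add(cand)
        partition[j].remove(cand)
        partition[j].add(mover)
    raise RuntimeError(
        f"could not resolve morphotype conflicts within {max_attempts} swaps "
        f"at level {level}; morphotype counts {counts}"
    )


def generate_design(spec: DesignSpec) -> list[Composition]:
    """Generate the full roster of compositions for a design spec.

    Monocultures, ``partitions_per_level`` independent random partitions at
    each intermediate richness level, and one full mixture.  All
    compositions are distinct as species sets; a partition duplicating an
    earlier composition is re-drawn.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    species = spec.species
    comps: list[Composition] = []
    seen: set[frozenset] = set()
    if 1 in spec.richness_levels:
        for s in species:
            comps.append(Composition(f"M-{s}", frozenset({s}), "mono"))
            seen.add(frozenset({s}))
    for level in spec.intermediate_levels:
        for p in range(spec.partitions_per_level):
            tag = f"{level}{'abcdefgh'[p]}"
            for attempt in range(1000):
                part = random_partition(species, level, rng)
                part = resolve_morphotype_conflicts(part, spec.morphotypes, rng)
                keys = [frozenset(g) for g in part]
                if all(k not in seen for k in keys):
                    break
            else:
                raise RuntimeError(f"could not draw a novel partition at level {level}")
            for k, g in enumerate(part, start=1):
                cid = f"C{level}{'abcdefgh'[p]}-{k}"
                comps.append(Composition(cid, frozenset(g), tag))
                seen.add(frozenset(g))
    if spec.n_species in spec.richness_levels:
        comps.append(Composition("FULL", frozenset(species), "full"))
    return comps


def expand_microcosms(
    design: Sequence[Composition],
    replicates: int = 3,
    environments: Sequence[str] = ENVIRONMENTS,
) -> list[Microcosm]:
    """Cross compositions with environments and replicates: the microcosm roster."""
    if not design:
        raise ValueError("empty design")
    out = []
    for comp in design:
        for env in environments:
            for rep in range(1, replicates + 1):
                out.append(
                    Microcosm(f"{comp.composition_id}.{env}.r{rep}", comp.composition_id, env, rep)
                )
    return out


def design_frame(design: Sequence[Composition]) -> pd.DataFrame:
    """Long-format design table: one row per (composition, member species)."""
    rows = [
        {
            "composition_id": c.composition_id,
            "species_id": s,
            "richness": c.richness,
            "partition_set": c.partition_set,
        }
        for c in design
        for s in sorted(c.members)
    ]
    return pd.DataFrame(rows, columns=["composition_id", "species_id", "richness", "partition_set"])


def compositions_from_frame(frame: pd.DataFrame) -> list[Composition]:
    """Rebuild Composition objects from a design table."""
    comps = []
    for cid, grp in frame.groupby("composition_id", sort=True):
        comps.append(
            Composition(str(cid), frozenset(grp["species_id"]), str(grp["partition_set"].iloc[0]))
        )
    return comps
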