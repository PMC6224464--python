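"""Genotypic vectors, Euclidean distances, and the genotypic tree.

Each population is represented by a vector of mutation frequencies over
the union of mutation keys observed in any population; the ancestral
population is the all-zeros vector.  Pairwise Euclidean distance between
two such vectors,

    ED(x, y) = sqrt( sum_i (Fx_i - Fy_i)^2 ),

is well defined even when a mutation is absent (frequency 0) from one of
the populations.  The distance matrix feeds a neighbor-joining tree rooted
on the ancestral population as outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools
import warnings

import numpy as np

from .trees import DistanceMatrix, Tree, neighbor_joining
from .variants import PopulationMutationTable

__all__ = [
    "GenotypicVector",
    "build_genotypic_vectors",
    "euclidean_distance",
    "genotypic_distance_matrix",
    "genotypic_tree",
    "group_dispersion",
    "ANCESTRAL_ID",
]

ANCESTRAL_ID = "ancestral"


@dataclass
class GenotypicVector:
    population_id: str
    keys: tuple            # ordered union of (position, ref, alt) keys
    values: np.ndarray     # frequency per key, 0 when absent
    scale: float = 1.0     # 1 = fractions, 100 = percent

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.keys):
            raise ValueError("vector length mismatch")
        if ((self.values < 0) | (self.values > self.scale)).any():
            raise ValueError(f"frequencies outside [0,{self.scale}]")


def build_genotypic_vectors(tables: list[PopulationMutationTable],
                            include_ancestral: bool = True,
                            collapse_positions: bool = False,
                            scale: float = 1.0) -> list[GenotypicVector]:
    """Frequency vectors over the sorted union of mutation keys.

    Keys are (position, ref, alt) triples; ``collapse_positions=True``
    switches to bare positions (summing a population's frequencies of
    distinct alleles at the same position, capped at 1).  The ancestral
    population is appended as the all-zeros vector.  ``scale`` rescales
    frequencies (100 = percent); tree topology is scale-invariant but
    branch lengths are not.
    """
    ids = [t.population_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate population ids")
    if collapse_positions:
        keys = tuple(sorted({int(k[0]) for t in tables for k in t.keys()}))
    else:
        keys = tuple(sorted({(int(p), r, a) for t in tables
                             for (p, r, a) in t.keys()}))
    key_index = {k: i for i, k in enumerate(keys)}
    out = []
    for t in tables:
        v = np.zeros(len(keys))
        for (pos, ref, alt), freq in zip(
                t.keys(), t.mutations["frequency"].to_numpy(float)):
            k = int(pos) if collapse_positions else (int(pos), ref, alt)
            v[key_index[k]] = min(v[key_index[k]] + freq, 1.0) \
                if collapse_positions else freq
        out.append(GenotypicVector(t.population_id, keys, v * scale,
                                   scale=scale))
    if include_ancestral:
        out.append(GenotypicVector(ANCESTRAL_ID, keys, np.zeros(len(keys)),
                                   scale=scale))
    return out


def euclidean_distance(x: GenotypicVector, y: GenotypicVector) -> float:
    """Root-sum-square of frequency differences (requires identical keys)."""
    if x.keys != y.keys:
        raise ValueError("genotypic vectors have different key sets")
    return float(np.sqrt(((x.values - y.values) ** 2).sum()))


def genotypic_distance_matrix(vectors: list[GenotypicVector]) -> DistanceMatrix:
    labels = [v.population_id for v in vectors]
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = euclidean_distance(vectors[i], vectors[j])
    return DistanceMatrix(labels, d)


def genotypic_tree(vectors: list[GenotypicVector],
                   outgroup: str | None = ANCESTRAL_ID) -> Tree:
    """NJ tree of genotypic distances, rooted on the ancestral outgroup."""
    if len(vectors) < 3:
        raise ValueError("need at least 3 populations for a tree")
    labels = [v.population_id for v in vectors]
    if outgroup is not None and outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} missing from populations")
    return neighbor_joining(genotypic_distance_matrix(vectors), outgroup=outgroup)


def group_dispersion(vectors: list[GenotypicVector],
                     regime_of: dict[str, str]) -> dict[str, float]:
    """Mean within-regime pairwise Euclidean distance, per regime.

    Populations without a regime label (e.g. the ancestral outgroup) are
    ignored; regimes with fewer than two members are excluded with a warning.
    """
    by_regime: dict[str, list[GenotypicVector]] = {}
    for v in vectors:
        regime = regime_of.get(v.population_id)
        if regime is not None:
            by_regime.setdefault(regime, []).append(v)
    out: dict[str, float] = {}
    for regime, vs in sorted(by_regime.items()):
        if len(vs) < 2:
            warnings.warn(f"regime {regime!r} has <2 populations; excluded "
                          "from dispersion", stacklevel=2)
            continue
        dists = [euclidean_distance(a, b)
                 for a, b in itertools.combinations(vs, 2)]
        out[regime] = float(np.mean(dists))
    return out
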