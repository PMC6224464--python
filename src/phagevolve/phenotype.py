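"""Infectivity readouts, phenotypic profiles, and the phenotypic tree.

Infectivity of population *i* on host *j* at a given virus-per-cell ratio
is the mean fluorescence of the infected replicate cultures divided by the
mean fluorescence of the uninfected control cultures at a fixed readout day
(day 10 by default).  Lower values mean faster decline of the infected
culture, i.e. more efficient infection.  Each population's phenotype is the
6-vector of infectivities over (host, ratio) pairs; pairwise Canberra
distances between these vectors feed a neighbor-joining tree.

Time-course dialect (TSV): population, host, vpc, replicate, day,
fluor_infected, fluor_control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import DistanceMatrix, Tree, neighbor_joining

__all__ = [
    "InfectivityProfile",
    "compute_infectivity",
    "build_phenotypic_profile",
    "build_all_profiles",
    "canberra_distance",
    "phenotypic_distance_matrix",
    "phenotypic_tree",
    "read_timecourse",
    "profiles_to_tsv",
]

CURVE_COLUMNS = ["population", "host", "vpc", "replicate", "day",
                 "fluor_infected", "fluor_control"]


@dataclass
class InfectivityProfile:
    """Ordered 6-vector of infectivity values for one population.

    Ordering is (host_1, low ratio), (host_1, high ratio), (host_2, low), ...
    with hosts sorted lexicographically and ratios ascending, recorded in
    ``conditions``.
    """

    population_id: str
    conditions: list[tuple[str, float]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.conditions):
            raise ValueError("profile length mismatch")
        if (self.values < 0).any():
            raise ValueError("negative infectivity")

    def value_at(self, host: str, vpc: float) -> float:
        for (h, v), x in zip(self.conditions, self.values):
            if h == host and np.isclose(v, vpc):
                return float(x)
        raise KeyError(f"no condition (host={host}, vpc={vpc})")


def compute_infectivity(curves: pd.DataFrame, day: int = 10) -> float:
    """Mean infected fluorescence over mean control fluorescence at ``day``.

    ``curves`` holds the replicate rows of a single population x host x vpc
    combination.  The day must be present in the series; no interpolation is
    attempted (a missing readout day signals a config/data mismatch).
    """
    if curves.empty:
        raise ValueError("no replicate curves supplied")
    at_day = curves.loc[curves["day"] == day]
    if at_day.empty:
        raise ValueError(f"day {day} absent from time course")
    ctrl = at_day["fluor_control"].mean()
    if ctrl <= 0:
        raise ValueError("control fluorescence mean is zero: normalization undefined")
    return float(at_day["fluor_infected"].mean() / ctrl)


def build_phenotypic_profile(population_id: str, curves: pd.DataFrame,
                             day: int = 10) -> InfectivityProfile:
    """Assemble the 6-element infectivity vector of one population."""
    sub = curves.loc[curves["population"] == population_id]
    if sub.empty:
        raise ValueError(f"no curves for population {population_id!r}")
    hosts = sorted(sub["host"].unique())
    vpcs = sorted(sub["vpc"].unique())
    conditions = [(h, v) for h in hosts for v in vpcs]
    values = []
    for host, vpc in conditions:
        cell = sub.loc[(sub["host"] == host) & (sub["vpc"] == vpc)]
        if cell.empty:
            raise ValueError(
                f"population {population_id!r}: missing condition "
                f"(host={host}, vpc={vpc})")
        values.append(compute_infectivity(cell, day=day))
    return InfectivityProfile(population_id, conditions, np.array(values))


def build_all_profiles(curves: pd.DataFrame, day: int = 10
                       ) -> list[InfectivityProfile]:
    return [build_phenotypic_profile(p, curves, day=day)
            for p in sorted(curves["population"].unique())]


def canberra_distance(x, y) -> float:
    """Canberra distance sum_i |x_i - y_i| / (|x_i| + |y_i|).

    Terms with x_i = y_i = 0 contribute 0 (so the all-zero ancestral vector
    compares cleanly against itself).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum())


def phenotypic_distance_matrix(profiles: list[InfectivityProfile]) -> DistanceMatrix:
    labels = [p.population_id for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate population ids")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = canberra_distance(profiles[i].values,
                                                  profiles[j].values)
    return DistanceMatrix(labels, d)


def phenotypic_tree(profiles: list[InfectivityProfile],
                    outgroup: str | None = None) -> Tree:
    return neighbor_joining(phenotypic_distance_matrix(profiles), outgroup=outgroup)


def read_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-course table missing columns: {sorted(missing)}")
    return df


def profiles_to_tsv(profiles: list[InfectivityProfile], path) -> None:
    rows = []
    for p in profiles:
        for (host, vpc), val in zip(p.conditions, p.values):
            rows.append({"population": p.population_id, "host": host,
                         "vpc": vpc, "infectivity": val})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
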