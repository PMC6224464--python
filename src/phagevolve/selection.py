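"""Selection inference: neutral expectation, exact tests, group comparison.

Under neutrality, a random single-nucleotide change inside a coding region
is nonsynonymous about 75% of the time (enumerating the 9 possible changes
of every sense codon of the standard genetic code).  An observed excess of
nonsynonymous SNPs over that expectation indicates positive selection and
is tested with a one-sided exact test.  Regime-level mutation burdens are
compared with the Kruskal-Wallis rank test, and the placement of mutations
relative to hypervariable regions with an upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import math

import numpy as np
from scipy import stats

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "NeutralModel",
    "SelectionTestResult",
    "standard_genetic_code",
    "expected_nonsynonymous_fraction",
    "fisher_selection_test",
    "mutation_count_test",
    "hypergeometric_enrichment",
]

BASES = "ACGT"


def standard_genetic_code() -> dict[str, str]:
    """codon -> one-letter amino acid; stop codons map to '*'."""
    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for c in table.stop_codons:
        code[c] = "*"
    return code


@dataclass
class NeutralModel:
    """Null model for the nonsynonymous fraction of random coding changes.

    ``codon_weights`` lets the null reflect a genome's codon usage;
    ``substitution_weights`` (4x4, from-base x to-base) a mutational
    spectrum.  Uniform defaults reproduce the textbook ~75% expectation.
    ``include_nonsense`` counts changes-to-stop as nonsynonymous; when
    False they are excluded from numerator and denominator.
    """

    genetic_code: dict[str, str] = field(default_factory=standard_genetic_code)
    codon_weights: dict[str, float] | None = None
    substitution_weights: np.ndarray | None = None
    include_nonsense: bool = False

    def __post_init__(self) -> None:
        if not self.genetic_code:
            raise ValueError("empty genetic code")
        if self.substitution_weights is None:
            self.substitution_weights = np.ones((4, 4))
        self.substitution_weights = np.asarray(self.substitution_weights, float)
        if self.substitution_weights.shape != (4, 4):
            raise ValueError("substitution_weights must be 4x4")
        if (self.substitution_weights < 0).any():
            raise ValueError("negative substitution weights")

    def sense_codons(self) -> list[str]:
        return [c for c, aa in self.genetic_code.items() if aa != "*"]

    def weight_of(self, codon: str) -> float:
        if self.codon_weights is None:
            return 1.0
        w = self.codon_weights.get(codon, 0.0)
        if w < 0:
            raise ValueError("negative codon weight")
        return w


def expected_nonsynonymous_fraction(model: NeutralModel | None = None) -> float:
    """Neutral expectation of the nonsynonymous fraction of coding changes.

    Exact weighted enumeration over all sense codons and their nine possible
    single-nucleotide changes.  With the standard code, uniform weights and
    nonsense changes excluded this is 392/526 ~ 0.745 — the ~75% null.
    """
    model = model or NeutralModel()
    code = model.genetic_code
    idx = {b: i for i, b in enumerate(BASES)}
    num = 0.0
    den = 0.0
    for codon in model.sense_codons():
        cw = model.weight_of(codon)
        if cw == 0.0:
            continue
        aa = code[codon]
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                w = cw * model.substitution_weights[idx[codon[pos]], idx[alt]]
                mut = codon[:pos] + alt + codon[pos + 1:]
                mut_aa = code[mut]
                if mut_aa == "*":
                    if model.include_nonsense:
                        den += w
                        num += w
                    continue
                den += w
                if mut_aa != aa:
                    num += w
    if den == 0.0:
        raise ValueError("no admissible substitutions under this model")
    return num / den


@dataclass
class SelectionTestResult:
    n_nonsynonymous: int
    n_synonymous: int
    expected_fraction: float
    p_value: float
    direction: str  # positive / negative / none
    method: str = "fisher"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0,1]")


def fisher_selection_test(n_nonsyn: int, n_syn: int, expected_fraction: float,
                          method: str = "fisher",
                          alpha: float = 0.05) -> SelectionTestResult:
    """One-sided test of nonsynonymous excess over the neutral expectation.

    ``method='fisher'``: Fisher's exact test of the observed counts against
    a pseudo-count expected column (round(N*f), N - round(N*f)) at the same
    total N.  ``method='binomial'``: exact binomial tail of n_nonsyn
    successes in N trials at success probability f.  Both one-sided towards
    excess.
    """
    if n_nonsyn < 0 or n_syn < 0:
        raise ValueError("negative counts")
    n = n_nonsyn + n_syn
    if n == 0:
        raise ValueError("no observations")
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected_fraction must be in (0,1)")

    if method == "fisher":
        exp_nonsyn = round(n * expected_fraction)
        table = [[n_nonsyn, n_syn], [exp_nonsyn, n - exp_nonsyn]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
    elif method == "binomial":
        p = float(stats.binomtest(n_nonsyn, n, expected_fraction,
                                  alternative="greater").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    obs_frac = n_nonsyn / n
    if obs_frac > expected_fraction and p < alpha:
        direction = "positive"
    elif obs_frac < expected_fraction and p < alpha:
        direction = "negative"
    else:
        direction = "none"
    return SelectionTestResult(n_nonsyn, n_syn, expected_fraction, p,
                               direction, method)


def mutation_count_test(counts_by_regime: dict[str, list[int]],
                        method: str = "chi2") -> tuple[float, float]:
    """Kruskal-Wallis H test on per-population mutation counts by regime.

    Returns (H, p).  ``method='chi2'`` uses the chi-square approximation;
    ``method='exact'`` enumerates all relabelings (group sizes <= 10).
    Degenerate all-tied data reports (0.0, 1.0).
    """
    groups = list(counts_by_regime.values())
    if len(groups) < 2:
        raise ValueError("need at least two regimes")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty regime group")
    flat = list(itertools.chain.from_iterable(groups))
    if len(set(flat)) == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    h = float(h)
    if method == "chi2":
        return h, float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if any(len(g) > 10 for g in groups):
        raise ValueError("exact method limited to groups of size <= 10")
    sizes = [len(g) for g in groups]
    n_ge = 0
    n_tot = 0
    pool = flat
    for perm in _distinct_assignments(len(pool), sizes):
        gs = [[pool[i] for i in block] for block in perm]
        hh = _kw_h(gs)
        n_tot += 1
        if hh >= h - 1e-12:
            n_ge += 1
    return h, n_ge / n_tot


def _distinct_assignments(n: int, sizes: list[int]):
    """All partitions of range(n) into ordered blocks of the given sizes."""
    def rec(remaining: tuple[int, ...], sizes: list[int]):
        if not sizes:
            yield []
            return
        k = sizes[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in rec(rest, sizes[1:]):
                yield [combo] + tail
    yield from rec(tuple(range(n)), sizes)


def _kw_h(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H by the direct rank formula."""
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(flat)
    ranks = stats.rankdata(flat)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def hypergeometric_enrichment(n_mut_in_region: int, n_mut_total: int,
                              region_bp: int, genome_bp: int) -> float:
    """Upper-tail hypergeometric P(X >= n_mut_in_region).

    Probability of at least the observed number of mutations landing in the
    region if n_mut_total positions were drawn without replacement from
    genome_bp positions of which region_bp are "region".
    """
    if not 0 <= n_mut_in_region <= n_mut_total:
        raise ValueError("n_mut_in_region outside [0, n_mut_total]")
    if region_bp > genome_bp:
        raise ValueError("region larger than genome")
    if region_bp < 0:
        raise ValueError("negative region size")
    if n_mut_total == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_mut_in_region - 1, genome_bp,
                                    region_bp, n_mut_total))
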