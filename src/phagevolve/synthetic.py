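"""Synthetic inputs emulating a host-range evolution experiment.

Everything the pipeline consumes can be generated here: an annotated phage
genome (FASTA + GFF3), per-population two-library variant-call tables,
infection time-courses, host tRNA repertoires, and metagenomic recruitment
records.  The generator encodes the study design the analysis assumes: one
ancestral population and three regimes of replicate populations evolved on
distinct hosts — an "optimal" host regime accumulating few, largely shared
mutations, and two "sub-optimal" regimes accumulating more numerous,
regime-specific mutations, with correspondingly shifted infectivities.

Determinism: one global seed fans out to per-stage child generators via
fixed offsets (`numpy.random.default_rng([seed, stage, ...])`), so each
stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import Orf, PhageGenome, TrnaGene, normalize_rna, revcomp, \
    translate_codon, write_genome

__all__ = [
    "RegimeParams",
    "SimulationConfig",
    "TrueMutation",
    "TrueMutationSet",
    "default_config",
    "generate_genome",
    "simulate_evolution",
    "simulate_libraries",
    "simulate_infection_curves",
    "simulate_recruitment",
    "write_bundle",
]

# stage offsets for the seed fan-out
_S_GENOME, _S_EVOLVE, _S_LIBS, _S_CURVES, _S_RECRUIT, _S_TRNA = 1, 2, 3, 4, 5, 6

READOUT_DAY = 10
BASES = "ACGT"
_SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                 if translate_codon(a + b + c) != "*"]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


@dataclass
class RegimeParams:
    """Parameters of one evolution regime (one host).

    ``expected_mutation_count`` is the Poisson mean of mutations per evolved
    population.  Mutations are drawn first from a pool shared across all
    regimes (parallel evolution on every host), then from a regime-specific
    pool (host-specific adaptation), and the remainder are private to the
    population.  ``infectivity_ancestral`` is the ancestor's normalized
    day-10 fluorescence ratio on this host (lower = more efficient
    infection); each mutation improves infection of the regime's own host by
    ``infectivity_gain_per_mutation`` (fractional) and degrades infection of
    the other hosts by ``infectivity_cost_per_mutation``.
    """

    expected_mutation_count: float
    infectivity_ancestral: float
    shared_mutation_pool_size: int = 5
    regime_pool_size: int = 4
    # observed nonsynonymous fraction of coding SNPs in the study system
    fraction_nonsynonymous: float = 0.89
    infectivity_gain_per_mutation: float = 0.02
    infectivity_cost_per_mutation: float = 0.01
    library_depth: int = 200
    n_populations: int | None = None   # falls back to config default
    n_false_positives: int = 2         # sub-1% one-library artifacts
    indel_fraction: float = 0.1
    long_deletion_length: int = 120
    long_deletion_prob: float = 0.0
    # population-private mutations segregate at low-to-moderate frequency
    private_freq_range: tuple[float, float] = (0.02, 0.3)
    regime_freq_range: tuple[float, float] = (0.3, 0.9)
    # shared (parallel) mutations segregate at low frequencies, as observed
    # for the host-independent mutations of the study system (~5-16%)
    shared_freq_range: tuple[float, float] = (0.05, 0.16)

    def __post_init__(self) -> None:
        if self.expected_mutation_count < 0:
            raise ValueError("expected_mutation_count must be >= 0")
        if self.infectivity_ancestral <= 0:
            raise ValueError("infectivity_ancestral must be > 0")
        if not 0 <= self.fraction_nonsynonymous <= 1:
            raise ValueError("fraction_nonsynonymous must be in [0,1]")
        if self.library_depth < 20:
            raise ValueError("library_depth must be >= 20 so the "
                             "10-reads-per-strand filter is satisfiable")


@dataclass
class SimulationConfig:
    genome_length: int = 50_000
    n_orfs: int = 20
    n_trna_genes: int = 3
    host_trna_sets: dict[str, set[str]] = field(default_factory=dict)
    regimes: dict[str, RegimeParams] = field(default_factory=dict)
    n_replicate_populations: int = 4
    n_days: int = 12
    seed: int = 0
    mean_orf_length: int | None = None
    minus_strand_fraction: float = 0.3
    vpc_ratios: tuple[float, float] = (0.1, 3.0)
    vpc_low_factor: float = 1.3     # infectivity inflation at the low ratio
    curve_noise_sd: float = 0.02    # lognormal sd of replicate fluorescence

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_orfs <= 0:
            raise ValueError("genome_length and n_orfs must be positive")
        if self.n_trna_genes < 0:
            raise ValueError("n_trna_genes must be >= 0")
        if self.n_days < READOUT_DAY:
            raise ValueError(f"n_days must be >= {READOUT_DAY} (readout day)")
        self.host_trna_sets = {
            h: {normalize_rna(a) for a in acs}
            for h, acs in self.host_trna_sets.items()}
        orf_len = self.orf_length()
        if self.n_orfs * orf_len > self.genome_length:
            raise ValueError("ORFs do not fit in the genome")

    def orf_length(self) -> int:
        if self.mean_orf_length is not None:
            n = self.mean_orf_length
            if n % 3:
                raise ValueError("mean_orf_length must be a multiple of 3")
            return n
        return max(30, int(0.6 * self.genome_length / self.n_orfs) // 3 * 3)

    def n_pops(self, host: str) -> int:
        n = self.regimes[host].n_populations
        return self.n_replicate_populations if n is None else n

    def population_ids(self) -> dict[str, str]:
        """population id -> host id, in deterministic order."""
        out = {}
        for host in sorted(self.regimes):
            for k in range(1, self.n_pops(host) + 1):
                out[f"{host}_p{k}"] = host
        return out

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["host_trna_sets"] = {h: sorted(a) for h, a in self.host_trna_sets.items()}
        for h in d["regimes"]:
            for k in ("private_freq_range", "regime_freq_range", "shared_freq_range"):
                d["regimes"][h][k] = list(d["regimes"][h][k])
        d["vpc_ratios"] = list(self.vpc_ratios)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["regimes"] = {
            h: RegimeParams(**{
                **r, **{k: tuple(r[k]) for k in
                        ("private_freq_range", "regime_freq_range",
                         "shared_freq_range") if k in r}})
            for h, r in d.get("regimes", {}).items()}
        d["host_trna_sets"] = {h: set(a)
                               for h, a in d.get("host_trna_sets", {}).items()}
        if "vpc_ratios" in d:
            d["vpc_ratios"] = tuple(d["vpc_ratios"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale emulation of the study design: 3 hosts, 13 evolved
    populations, regime mutation means 6 / 18 / 30 ordered by decreasing
    host optimality."""
    rng = _rng(seed, _S_TRNA)
    sense = sorted({revcomp(c).replace("T", "U") for c in _SENSE_CODONS})
    hosts = {
        host: set(rng.choice(sense, size=30, replace=False))
        for host in ("hostA_optimal", "hostB_subopt", "hostC_least")
    }
    regimes = {
        "hostA_optimal": RegimeParams(
            expected_mutation_count=6, infectivity_ancestral=0.25,
            regime_pool_size=1, n_populations=4),
        "hostB_subopt": RegimeParams(
            expected_mutation_count=18, infectivity_ancestral=0.5,
            regime_pool_size=4, n_populations=5),
        "hostC_least": RegimeParams(
            expected_mutation_count=30, infectivity_ancestral=0.8,
            regime_pool_size=8, n_populations=4, long_deletion_prob=0.25),
    }
    return SimulationConfig(host_trna_sets=hosts, regimes=regimes, seed=seed)


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(config: SimulationConfig) -> PhageGenome:
    """Random genome carrying the configured ORFs and tRNA genes.

    Every ORF starts with ATG, ends with a stop codon, and contains no
    internal stop codons on its coding strand.  ORFs are non-overlapping;
    tRNA genes sit in intergenic gaps.
    """
    rng = _rng(config.seed, _S_GENOME)
    L = config.genome_length
    orf_len = config.orf_length()
    n = config.n_orfs

    slack = L - n * orf_len
    gaps = rng.multinomial(slack - (n + 1) * 2, np.ones(n + 1) / (n + 1)) + 2
    seq = list(rng.choice(list(BASES), size=L))

    orfs: list[Orf] = []
    cursor = 0
    stop_codons = ["TAA", "TAG", "TGA"]
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor + 1                       # 1-based
        end = start + orf_len - 1
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        n_codons = orf_len // 3
        body = rng.choice(_SENSE_CODONS[1:], size=n_codons - 2)  # skip start
        coding = "ATG" + "".join(body) + str(rng.choice(stop_codons))
        placed = revcomp(coding) if strand == "-" else coding
        seq[start - 1:end] = list(placed)
        orfs.append(Orf(f"orf{i + 1:03d}", start, end, strand))
        cursor = end

    trnas: list[TrnaGene] = []
    if config.n_trna_genes:
        # drop tRNA annotations into the final gap region
        tail_start = orfs[-1].end + 1
        room = L - tail_start - 1
        width = 72
        for j in range(config.n_trna_genes):
            anticodon = "".join(rng.choice(list("ACGU"), size=3))
            s = tail_start + j * max(width + 5, room // max(config.n_trna_genes, 1))
            s = min(s, L - width)
            trnas.append(TrnaGene(f"trna{j + 1}", anticodon, s, s + width - 1))

    return PhageGenome("".join(seq), orfs, trnas, id="synthetic_phage")


# ---------------------------------------------------------------------------
# evolution


@dataclass(frozen=True)
class TrueMutation:
    position: int
    ref: str
    alt: str
    mtype: str        # SNP / INS / DEL
    true_freq: float
    effect: str       # intended effect class (ground truth for round trips)
    gene_id: str
    origin: str       # shared / regime / private

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass
class TrueMutationSet:
    population_id: str
    host_id: str
    mutations: list[TrueMutation]

    def __len__(self) -> int:
        return len(self.mutations)


def _snp_at(genome: PhageGenome, orf: Orf, coding_off: int, new_base: str
            ) -> tuple[int, str, str, str]:
    """(position, ref, alt, effect) for a coding-strand base change."""
    if orf.strand == "+":
        pos = orf.start + coding_off
        ref = genome.base_at(pos)
        alt = new_base
    else:
        pos = orf.end - coding_off
        ref = genome.base_at(pos)
        alt = revcomp(new_base)
    cds = genome.coding_sequence(orf)
    ci = coding_off // 3
    codon = cds[3 * ci: 3 * ci + 3]
    mut = codon[:coding_off % 3] + new_base + codon[coding_off % 3 + 1:]
    anc_aa, mut_aa = translate_codon(codon), translate_codon(mut)
    if mut_aa == anc_aa:
        effect = "synonymous"
    elif mut_aa == "*":
        effect = "nonsense"
    else:
        effect = "nonsynonymous"
    return pos, ref, alt, effect


def _draw_snp(rng: np.random.Generator, genome: PhageGenome,
              want_nonsyn: bool, used: set[int],
              max_tries: int = 500) -> tuple[int, str, str, str]:
    """A random coding SNP of the requested class at an unused position."""
    orfs = genome.orfs
    for _ in range(max_tries):
        orf = orfs[rng.integers(len(orfs))]
        n_codons = orf.length // 3
        ci = int(rng.integers(1, n_codons - 1))     # skip start & stop codons
        off = 3 * ci + int(rng.integers(3))
        cds = genome.coding_sequence(orf)
        cur = cds[off]
        alts = [b for b in BASES if b != cur]
        rng.shuffle(alts)
        for nb in alts:
            pos, ref, alt, effect = _snp_at(genome, orf, off, nb)
            if pos in used:
                break
            is_nonsyn = effect in ("nonsynonymous", "nonsense")
            if is_nonsyn == want_nonsyn:
                return pos, ref, alt, effect
    raise RuntimeError("could not place a SNP of the requested class")


def _draw_pool(rng: np.random.Generator, genome: PhageGenome, size: int,
               frac_nonsyn: float, freq_range: tuple[float, float],
               used: set[int], origin: str,
               orf_subset: list[Orf] | None = None
               ) -> list[tuple[TrueMutation, float]]:
    """Pool of SNP mutations with per-entry base frequencies."""
    sub = PhageGenome(genome.sequence, orf_subset, genome.trna_genes,
                      id=genome.id) if orf_subset else genome
    out = []
    for _ in range(size):
        want_nonsyn = rng.random() < frac_nonsyn
        pos, ref, alt, effect = _draw_snp(rng, sub, want_nonsyn, used)
        used.add(pos)
        base = float(rng.uniform(*freq_range))
        orf = genome.orf_at(pos)
        out.append((TrueMutation(pos, ref, alt, "SNP", base, effect,
                                 orf.id if orf else "intergenic", origin), base))
    return out


def simulate_evolution(genome: PhageGenome, config: SimulationConfig
                       ) -> dict[str, TrueMutationSet]:
    """Ground-truth mutation sets per evolved population.

    Each population draws Poisson(expected_mutation_count) mutations:
    first from its regime's pool (host-specific adaptation is the strongest
    signal, at the highest frequencies), then from the global shared pool
    (low-frequency parallel mutations common to all regimes), the remainder
    private (SNPs at the regime's nonsynonymous fraction, plus occasional
    1-bp indels and, where configured, one long deletion).
    """
    hosts = sorted(config.regimes)
    rng = _rng(config.seed, _S_EVOLVE)
    used: set[int] = set()

    shared_size = max((config.regimes[h].shared_mutation_pool_size for h in hosts),
                      default=0)
    mean_frac = float(np.mean([config.regimes[h].fraction_nonsynonymous
                               for h in hosts])) if hosts else 0.85
    mean_shared_range = tuple(np.mean(
        [config.regimes[h].shared_freq_range for h in hosts], axis=0)) \
        if hosts else (0.1, 0.6)
    shared_pool = _draw_pool(rng, genome, shared_size, mean_frac,
                             mean_shared_range, used, "shared")

    # host-specific pools drawn from disjoint ORF subsets where possible,
    # emulating the regime-specific mutated gene sets
    orf_blocks = np.array_split(np.arange(len(genome.orfs)), max(len(hosts), 1))
    regime_pools: dict[str, list[tuple[TrueMutation, float]]] = {}
    for bi, host in enumerate(hosts):
        p = config.regimes[host]
        subset = [genome.orfs[i] for i in orf_blocks[bi]] or list(genome.orfs)
        regime_pools[host] = _draw_pool(
            rng, genome, p.regime_pool_size, p.fraction_nonsynonymous,
            p.regime_freq_range, used, "regime", orf_subset=subset)

    out: dict[str, TrueMutationSet] = {}
    for host in hosts:
        p = config.regimes[host]
        for k in range(1, config.n_pops(host) + 1):
            pid = f"{host}_p{k}"
            prng = _rng(config.seed, _S_EVOLVE, hosts.index(host), k)
            n = int(prng.poisson(p.expected_mutation_count))
            muts: list[TrueMutation] = []
            pop_used = set(used)

            def jitter(base: float) -> float:
                return float(np.clip(base + prng.normal(0, 0.02), 0.01, 1.0))

            pool = regime_pools[host]
            n_regime = min(len(pool), n)
            idx = prng.choice(len(pool), size=n_regime, replace=False) \
                if n_regime else []
            for i in sorted(idx):
                m, base = pool[i]
                muts.append(TrueMutation(m.position, m.ref, m.alt, m.mtype,
                                         jitter(base), m.effect, m.gene_id,
                                         m.origin))
            n_shared = min(len(shared_pool), n - n_regime)
            idx = prng.choice(len(shared_pool), size=n_shared, replace=False) \
                if n_shared else []
            for i in sorted(idx):
                m, base = shared_pool[i]
                muts.append(TrueMutation(m.position, m.ref, m.alt, m.mtype,
                                         jitter(base), m.effect, m.gene_id,
                                         m.origin))

            n_private = n - n_shared - n_regime
            for _ in range(n_private):
                freq = float(prng.uniform(*p.private_freq_range))
                if prng.random() < p.indel_fraction:
                    m = _draw_indel(prng, genome, pop_used, freq)
                else:
                    want_nonsyn = prng.random() < p.fraction_nonsynonymous
                    pos, ref, alt, effect = _draw_snp(prng, genome,
                                                      want_nonsyn, pop_used)
                    orf = genome.orf_at(pos)
                    m = TrueMutation(pos, ref, alt, "SNP", freq, effect,
                                     orf.id if orf else "intergenic", "private")
                pop_used.add(m.position)
                muts.append(m)

            if p.long_deletion_prob and prng.random() < p.long_deletion_prob:
                muts.append(_draw_long_deletion(prng, genome, pop_used, p))

            muts.sort(key=lambda m: m.key)
            out[pid] = TrueMutationSet(pid, host, muts)
    return out


def _draw_indel(prng: np.random.Generator, genome: PhageGenome,
                used: set[int], freq: float) -> TrueMutation:
    """1-bp insertion or deletion inside a random ORF (a frameshift)."""
    for _ in range(200):
        orf = genome.orfs[prng.integers(len(genome.orfs))]
        pos = int(prng.integers(orf.start + 3, orf.end - 3))
        if pos in used:
            continue
        if prng.random() < 0.5:
            return TrueMutation(pos, genome.base_at(pos), "-", "DEL", freq,
                                "frameshift", orf.id, "private")
        ins = str(prng.choice(list(BASES)))
        return TrueMutation(pos, "-", ins, "INS", freq, "frameshift",
                            orf.id, "private")
    raise RuntimeError("could not place an indel")


def _draw_long_deletion(prng: np.random.Generator, genome: PhageGenome,
                        used: set[int], p: RegimeParams) -> TrueMutation:
    L = p.long_deletion_length
    for _ in range(200):
        orf = genome.orfs[prng.integers(len(genome.orfs))]
        if orf.length < L + 12:
            continue
        pos = int(prng.integers(orf.start + 3, orf.end - L - 3))
        if pos in used:
            continue
        seg = genome.sequence[pos - 1: pos - 1 + L]
        effect = "inframe_indel" if L % 3 == 0 else "frameshift"
        return TrueMutation(pos, seg, "-", "DEL",
                            float(prng.uniform(0.3, 0.9)), effect, orf.id,
                            "private")
    raise RuntimeError("no ORF long enough for the long deletion")


# ---------------------------------------------------------------------------
# sequencing libraries


def simulate_libraries(truth: TrueMutationSet, params: RegimeParams,
                       genome: PhageGenome, seed: int
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two technical-library variant tables around the true frequencies.

    Per library, the observed frequency is Binomial(depth, true_freq)/depth
    (zero-draw mutations are absent from that library's table) and the
    strand read counts split the depth binomially.  ``n_false_positives``
    artifact calls at sub-1% frequency are injected into one library only,
    exercising the two-library reconciliation filter.
    """
    rng = _rng(seed, _S_LIBS)
    depth = params.library_depth
    libs: list[list[dict]] = [[], []]
    for m in truth.mutations:
        for li in (0, 1):
            k = int(rng.binomial(depth, m.true_freq))
            if k == 0:
                continue
            fwd = int(rng.binomial(depth, 0.5))
            libs[li].append({
                "population": truth.population_id, "library": f"lib{li + 1}",
                "position": m.position, "ref": m.ref, "alt": m.alt,
                "type": m.mtype, "frequency": k / depth,
                "fwd_reads": fwd, "rev_reads": depth - fwd,
            })
    used = {m.position for m in truth.mutations}
    for fi in range(params.n_false_positives):
        li = fi % 2
        for _ in range(100):
            pos = int(rng.integers(1, len(genome) + 1))
            if pos not in used:
                break
        used.add(pos)
        ref = genome.base_at(pos)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        fwd = int(rng.binomial(depth, 0.5))
        libs[li].append({
            "population": truth.population_id, "library": f"lib{li + 1}",
            "position": pos, "ref": ref, "alt": alt, "type": "SNP",
            "frequency": float(rng.uniform(0.002, 0.0095)),
            "fwd_reads": fwd, "rev_reads": depth - fwd,
        })
    cols = ["population", "library", "position", "ref", "alt", "type",
            "frequency", "fwd_reads", "rev_reads"]
    return tuple(
        pd.DataFrame(rows, columns=cols).sort_values(
            ["position", "ref", "alt"]).reset_index(drop=True)
        for rows in libs)


# ---------------------------------------------------------------------------
# infection time-courses


def configured_infectivity(config: SimulationConfig, host: str,
                           evolved_on: str | None,
                           n_mutations: int) -> float:
    """Deterministic day-10 infectivity implied by the regime parameters.

    The ancestor scores ``infectivity_ancestral`` on each host; an evolved
    population improves multiplicatively on its own host and degrades on
    the others (capped at 1 = no detectable killing).
    """
    anc = config.regimes[host].infectivity_ancestral
    if evolved_on is None:
        return anc
    p = config.regimes[evolved_on]
    if evolved_on == host:
        return float(np.clip(
            anc * (1.0 - p.infectivity_gain_per_mutation) ** n_mutations,
            0.02, 1.0))
    return float(np.clip(
        anc * (1.0 + p.infectivity_cost_per_mutation) ** n_mutations,
        0.02, 1.0))


def simulate_infection_curves(populations: dict[str, TrueMutationSet],
                              config: SimulationConfig,
                              include_ancestral: bool = True,
                              n_replicates: int = 3) -> pd.DataFrame:
    """Daily fluorescence series for every population x host x ratio.

    The uninfected control grows geometrically; infected cultures decline
    linearly (in ratio to control) to the configured infectivity by the
    readout day, with lognormal replicate noise on the infected series.
    """
    rng = _rng(config.seed, _S_CURVES)
    hosts = sorted(config.regimes)
    days = np.arange(1, config.n_days + 1)
    control = 50.0 * 1.25 ** days               # monotone non-decreasing
    lo, hi = sorted(config.vpc_ratios)

    pops: list[tuple[str, str | None, int]] = []
    if include_ancestral:
        pops.append(("ancestral", None, 0))
    pops += [(pid, ts.host_id, len(ts)) for pid, ts in sorted(populations.items())]

    rows = []
    for pid, evolved_on, nmut in pops:
        for host in hosts:
            base = configured_infectivity(config, host, evolved_on, nmut)
            for vpc in (lo, hi):
                inf = base if vpc == hi else \
                    float(np.clip(base * config.vpc_low_factor, 0.0, 1.0))
                ratio = 1.0 - (1.0 - inf) * np.minimum(days, READOUT_DAY) \
                    / READOUT_DAY
                for rep in range(1, n_replicates + 1):
                    noise = np.exp(rng.normal(0.0, config.curve_noise_sd,
                                              size=len(days)))
                    infected = control * ratio * noise
                    for d, fi, fc in zip(days, infected, control):
                        rows.append({
                            "population": pid, "host": host, "vpc": vpc,
                            "replicate": rep, "day": int(d),
                            "fluor_infected": float(fi),
                            "fluor_control": float(fc),
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagenomic recruitment


def simulate_recruitment(genome: PhageGenome,
                         hvr_spec: list[tuple[int, int]],
                         n_reads: int, seed: int,
                         interior_rate: float = 0.0,
                         read_length_mean: float = 1000.0,
                         read_length_sd: float = 150.0,
                         sub_threshold_fraction: float = 0.05
                         ) -> pd.DataFrame:
    """Alignment records emulating fragment recruitment to the genome.

    ``n_reads`` alignments are attempted at uniform positions; a read whose
    span overlaps a declared hypervariable interval is kept only with
    probability ``interior_rate`` (recruitment fails in the deserts), so
    the emitted accepted-quality record count is slightly below ``n_reads``
    when deserts are declared — and zero when they cover the whole genome
    at rate 0.  A further ``sub_threshold_fraction`` of records violate the
    acceptance rules, to exercise the filters; half of those are
    mate-rescuable.
    """
    L = len(genome)
    spec = sorted((int(s), int(e)) for s, e in hvr_spec)
    for (s, e) in spec:
        if not (1 <= s <= e <= L):
            raise ValueError(f"HVR ({s},{e}) outside genome")
    for (s1, e1), (s2, e2) in zip(spec, spec[1:]):
        if s2 <= e1:
            raise ValueError("HVR intervals overlap")

    rng = _rng(seed, _S_RECRUIT)

    def overlaps_hvr(start: int, end: int) -> bool:
        return any(start <= e and end >= s for s, e in spec)

    rows = []
    placed = 0
    for _ in range(int(n_reads)):
        rl = int(np.clip(rng.normal(read_length_mean, read_length_sd), 350, L))
        start = int(rng.integers(1, max(L - rl + 1, 1) + 1))
        end = min(start + rl - 1, L)
        if overlaps_hvr(start, end) and rng.random() >= interior_rate:
            continue
        placed += 1
        rows.append({
            "read_id": f"read{placed:06d}", "start": start, "end": end,
            "aligned_len": end - start + 1,
            "pct_identity": float(rng.uniform(70, 98)),
            "unaligned_left": int(rng.integers(0, 16)),
            "unaligned_right": int(rng.integers(0, 16)),
            "mate_id": None, "mate_aligned_frac": float(rng.uniform(0.85, 1.0)),
        })
    # pair consecutive accepted-quality reads as mates
    for i in range(0, len(rows) - 1, 2):
        rows[i]["mate_id"] = rows[i + 1]["read_id"]
        rows[i + 1]["mate_id"] = rows[i]["read_id"]

    n_good = len(rows)
    n_sub = int(round(sub_threshold_fraction * placed))
    for j in range(n_sub):
        rl = int(np.clip(rng.normal(read_length_mean, read_length_sd), 350, L))
        start = int(rng.integers(1, max(L - rl + 1, 1) + 1))
        rescuable = j % 2 == 0 and n_good > 0
        rows.append({
            "read_id": f"sub{j + 1:05d}", "start": start,
            "end": min(start + rl - 1, L), "aligned_len": rl,
            "pct_identity": float(rng.uniform(40, 60)),   # fails both rules
            "unaligned_left": int(rng.integers(30, 60)),
            "unaligned_right": int(rng.integers(30, 60)),
            "mate_id": rows[j % n_good]["read_id"] if rescuable else None,
            "mate_aligned_frac": float(rng.uniform(0.85, 1.0)) if rescuable
            else float(rng.uniform(0.0, 0.5)),
        })
    df = pd.DataFrame(rows, columns=["read_id", "start", "end", "aligned_len",
                                     "pct_identity", "unaligned_left",
                                     "unaligned_right", "mate_id",
                                     "mate_aligned_frac"])
    return df


# ---------------------------------------------------------------------------
# bundle writer


def write_bundle(config: SimulationConfig, outdir,
                 hvr_spec: list[tuple[int, int]] | None = None,
                 n_recruitment_reads: int = 10_000) -> dict[str, object]:
    """Generate and write the full synthetic input set for a pipeline run.

    Returns a manifest of written paths plus the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    write_genome(genome, outdir / "genome.fasta", outdir / "genome.gff3")

    truth = simulate_evolution(genome, config)
    vardir = outdir / "variants"
    vardir.mkdir(exist_ok=True)
    variant_paths: dict[str, list[str]] = {}
    for i, (pid, ts) in enumerate(sorted(truth.items())):
        lib_a, lib_b = simulate_libraries(
            ts, config.regimes[ts.host_id], genome,
            seed=config.seed * 100_003 % (2 ** 31) + i)
        pa = vardir / f"{pid}_lib1.tsv"
        pb = vardir / f"{pid}_lib2.tsv"
        lib_a.to_csv(pa, sep="\t", index=False)
        lib_b.to_csv(pb, sep="\t", index=False)
        variant_paths[pid] = [str(pa), str(pb)]

    curves = simulate_infection_curves(truth, config)
    curves.to_csv(outdir / "timecourses.tsv", sep="\t", index=False)

    trna_rows = [{"host_id": h, "anticodon": a}
                 for h in sorted(config.host_trna_sets)
                 for a in sorted(config.host_trna_sets[h])]
    pd.DataFrame(trna_rows).to_csv(outdir / "host_trnas.tsv", sep="\t",
                                   index=False)

    if hvr_spec is None:
        L = len(genome)
        hvr_spec = [(int(0.2 * L), int(0.2 * L) + 599),
                    (int(0.7 * L), int(0.7 * L) + 799)]
    rec = simulate_recruitment(genome, hvr_spec, n_recruitment_reads,
                               seed=config.seed)
    rec.to_csv(outdir / "recruitment.tsv", sep="\t", index=False)

    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "hvr_truth.tsv", "w") as fh:
        fh.write("start\tend\n")
        for s, e in hvr_spec:
            fh.write(f"{s}\t{e}\n")

    return {
        "genome": genome, "truth": truth, "curves": curves,
        "recruitment": rec, "hvr_spec": hvr_spec,
        "paths": {
            "fasta": str(outdir / "genome.fasta"),
            "gff3": str(outdir / "genome.gff3"),
            "variants": variant_paths,
            "timecourses": str(outdir / "timecourses.tsv"),
            "host_trnas": str(outdir / "host_trnas.tsv"),
            "recruitment": str(outdir / "recruitment.tsv"),
            "config": str(outdir / "config.yaml"),
        },
    }
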