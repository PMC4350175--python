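"""Wright-Fisher simulation of an evolving chemostat population.

Models a large asexual bacterial population held at constant size by
continuous dilution, with the lineage structure typical of glucose-limited
chemostat evolution experiments: a handful of strongly beneficial "driver"
genes that tolerate many alternative loss-of-function alleles (the substrate
of soft sweeps), later-acting drivers, a negatively frequency-dependent
lineage excluded by epistasis from the dominant adapted background, a
fitness-neutral mutator that raises the genome-wide mutation rate, and a
large supply of neutral passengers.

The population is a multiset of genotypes (sets of mutation ids).  Each
generation, offspring counts are drawn multinomially with probabilities
proportional to count x fitness, then new mutations arrive as Poisson events
on random genome positions.  Continuous culture time is converted to
discrete generations through the dilution rate (one generation per
population doubling, ``24*D/ln 2`` generations per day).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger("chemosweep.popsim")

BASES = "ACGT"

# standard bacterial/nuclear code; '*' marks stops so stop gain/loss compares
# as an amino-acid change (nonsynonymous)
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MUT_CLASSES = ("SNP", "S-indel", "L-indel", "duplication")
GENE_ROLES = ("driver_strong", "driver_late", "freq_dep", "mutator", "neutral")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with a role in the selective landscape.

    ``n_target_sites`` is the number of positions at which a nonsynonymous
    change (or an inactivating indel) confers the role's effect; the sites
    are spread evenly across the gene.  Benefit is loss-of-function-like:
    any one hit at a target site is equivalent to any other, so distinct
    alleles of one gene are mutually redundant.
    """

    name: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    role: str = "neutral"
    s: float = 0.0
    n_target_sites: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.name}: bad coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if self.role not in GENE_ROLES:
            raise ValueError(f"gene {self.name}: unknown role {self.role!r}")
        if self.s < 0:
            raise ValueError(f"gene {self.name}: selection coefficient must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def target_sites(self) -> frozenset[int]:
        """Evenly spaced 1-based positions whose hit confers the role."""
        n = min(self.n_target_sites, self.length)
        if n <= 0:
            return frozenset()
        pos = np.linspace(self.start, self.end, num=n)
        return frozenset(int(round(p)) for p in pos)


@dataclass(frozen=True)
class MutationRecord:
    """One genomic change segregating in the population."""

    id: str
    position: int
    ref: str
    alt: str
    mut_class: str  # SNP | S-indel | L-indel | duplication
    gene: str  # gene name or "intergenic"
    effect: str  # nonsynonymous | synonymous | noncoding
    role: str  # gene role if the change is activating, else "passenger"


class Genotype:
    """An immutable set of mutations plus cached fitness-relevant flags."""

    __slots__ = ("id", "mutation_ids", "driver_genes", "freq_dep", "mutator", "_hash")

    def __init__(
        self,
        gid: int,
        mutation_ids: tuple[str, ...],
        driver_genes: frozenset[str],
        freq_dep: bool,
        mutator: bool,
    ):
        self.id = gid
        self.mutation_ids = mutation_ids
        self.driver_genes = driver_genes
        self.freq_dep = freq_dep
        self.mutator = mutator
        self._hash = hash(gid)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genotype) and other.id == self.id

    def __repr__(self) -> str:
        return f"Genotype({self.id}, n_mut={len(self.mutation_ids)})"


ANCESTOR = Genotype(0, (), frozenset(), False, False)


@dataclass
class PopulationState:
    """Genotype -> count map for one generation; counts always sum to N."""

    generation: int
    counts: dict[Genotype, int]

    @property
    def size(self) -> int:
        return sum(self.counts.values())


@dataclass
class SimConfig:
    """Parameters of the chemostat simulation.

    Defaults describe a desk-scale version of a 60-day glucose-limited
    chemostat run at dilution rate 0.1/h sampled 11 times: population size
    1e6 (the real culture is ~1.6e10; drift and detection noise are
    correspondingly stronger here), a 100 kb genome standing in for the
    4.6 Mb chromosome, and a per-base mutation rate high enough to supply
    multiple independent driver alleles within ~208 generations.
    """

    N: int = 1_000_000
    genome_length: int = 100_000
    mu: float = 5e-9  # per base per generation
    mutator_fold: float = 100.0
    dilution_rate: float = 0.1  # per hour
    duration_days: float = 60.0
    sample_days: tuple[float, ...] = (5, 7, 14, 20, 28, 35, 40, 45, 50, 56, 60)
    genes: tuple[GeneModel, ...] = ()
    freq_dep_s: float = 0.2  # s_h: benefit of the freq-dep lineage when rare
    freq_dep_c: float = 1.0  # c: slope of the fitness decline with carrier frequency
    epistasis_genes: tuple[str, ...] = ("rpoS",)
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            # proportions of the mutation classes observed in pooled-sequencing
            # studies of this system (SNPs dominate; indels and duplications rare)
            "SNP": 0.98158,
            "S-indel": 0.01658,
            "L-indel": 0.00147,
            "duplication": 0.00037,
        }
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = default_gene_models(self.genome_length)

    def validate(self) -> list[str]:
        """Return a list of every constraint violation (empty when valid)."""
        errors: list[str] = []
        if self.N < 1_000:
            errors.append(f"N: population size must be >= 1000, got {self.N}")
        if self.genome_length < 1:
            errors.append("genome_length: must be positive")
        if self.mu < 0:
            errors.append(f"mu: mutation rate must be >= 0, got {self.mu}")
        if self.mutator_fold < 1:
            errors.append("mutator_fold: must be >= 1")
        if self.dilution_rate < 0:
            errors.append(f"dilution_rate: must be >= 0, got {self.dilution_rate}")
        if self.duration_days < 0:
            errors.append("duration_days: must be >= 0")
        days = list(self.sample_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            errors.append(f"sample_days: must be strictly increasing, got {days}")
        if days and (days[0] < 0 or days[-1] > self.duration_days):
            errors.append(
                f"sample_days: must lie within [0, {self.duration_days}], got {days}"
            )
        if not math.isfinite(self.mu * self.genome_length * self.N):
            errors.append("mu * genome_length * N must be finite")
        if self.freq_dep_s < 0 or self.freq_dep_c < 0:
            errors.append("freq_dep_s and freq_dep_c must be >= 0")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-6:
            errors.append(f"class_fractions: must sum to 1, got {total}")
        if set(self.class_fractions) - set(MUT_CLASSES):
            errors.append(f"class_fractions: unknown classes {set(self.class_fractions) - set(MUT_CLASSES)}")
        prev_end = 0
        for g in sorted(self.genes, key=lambda g: g.start):
            if g.start <= prev_end:
                errors.append(f"genes: {g.name} overlaps a previous gene")
            if g.end > self.genome_length:
                errors.append(f"genes: {g.name} extends past the genome end")
            prev_end = max(prev_end, g.end)
        return errors

    def require_valid(self) -> "SimConfig":
        errors = self.validate()
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))
        return self

    def gene_by_name(self) -> dict[str, GeneModel]:
        return {g.name: g for g in self.genes}


def default_gene_models(genome_length: int = 100_000) -> tuple[GeneModel, ...]:
    """The default selective landscape.

    Seven named genes carry the roles seen in glucose-limited chemostat
    populations -- three strong drivers with many redundant target sites
    (sigma-factor / repressor / activator loss-of-function classes), two
    late drivers (one with a single target site, the hard-sweep candidate),
    a frequency-dependent gene and a mutator -- and the rest of the genome
    is tiled with neutral genes so that roughly 90% of positions are coding,
    as in a compact bacterial chromosome.  Selection coefficients are free
    parameters of the model (strong drivers 0.15/0.12, late drivers 0.10).
    """
    special = [
        # (name, length, strand, role, s, n_target_sites)
        ("rpoS", 990, "+", "driver_strong", 0.15, 30),
        ("mglD", 1041, "-", "driver_strong", 0.15, 30),
        ("malT", 2706, "+", "driver_strong", 0.12, 60),
        ("malE", 1191, "-", "driver_late", 0.10, 12),
        ("sdhC", 390, "+", "driver_late", 0.10, 1),
        ("hfq", 309, "+", "freq_dep", 0.0, 8),
        ("mutL", 1848, "-", "mutator", 0.0, 6),
    ]
    genes: list[GeneModel] = []
    gap = 120
    pos = 1 + gap
    i_special = 0
    i_filler = 0
    while pos < genome_length - gap:
        if i_special < len(special):
            name, length, strand, role, s, nt = special[i_special]
            i_special += 1
        else:
            name = f"yn{i_filler:03d}"
            length = 900
            strand = "+" if i_filler % 2 == 0 else "-"
            role, s, nt = "neutral", 0.0, 0
            i_filler += 1
        end = pos + length - 1
        if end > genome_length - gap:
            break
        genes.append(GeneModel(name, pos, end, strand, role, s, nt))
        pos = end + 1 + gap
    return tuple(genes)


class GeneIndex:
    """Position -> gene lookup over non-overlapping genes."""

    def __init__(self, genes: Sequence[GeneModel]):
        ordered = sorted(genes, key=lambda g: g.start)
        self._genes = ordered
        self._starts = np.array([g.start for g in ordered])
        self._ends = np.array([g.end for g in ordered])
        self._targets = {g.name: g.target_sites() for g in ordered}

    def find(self, position: int) -> GeneModel | None:
        i = int(np.searchsorted(self._starts, position, side="right")) - 1
        if i >= 0 and position <= self._ends[i]:
            return self._genes[i]
        return None

    def is_target(self, gene: GeneModel, position: int) -> bool:
        return position in self._targets[gene.name]


@dataclass
class TruthTable:
    """Ground-truth allele frequencies at each sampled day.

    ``mutations`` is indexed by mutation id and carries the record metadata
    plus ``lineage_id`` (the genotype in which the mutation arose);
    ``freqs`` holds one column per sample day.
    """

    mutations: pd.DataFrame
    freqs: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.freqs.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("truth frequencies must lie in [0, 1]")
        if not self.mutations.index.equals(self.freqs.index):
            raise ValueError("mutations and freqs must share the same index")

    @property
    def sample_days(self) -> list[float]:
        return [float(c) for c in self.freqs.columns]

    def to_tsv(self, truth_path, linkage_path=None) -> None:
        out = self.mutations.join(self.freqs)
        out.to_csv(truth_path, sep="\t", index_label="mutation_id")
        if linkage_path is not None:
            self.mutations[["lineage_id"]].to_csv(
                linkage_path, sep="\t", index_label="mutation_id"
            )

    @classmethod
    def read_tsv(cls, truth_path) -> "TruthTable":
        df = pd.read_csv(truth_path, sep="\t", index_col="mutation_id")
        meta_cols = [c for c in df.columns if not _is_number(c)]
        day_cols = [c for c in df.columns if _is_number(c)]
        freqs = df[day_cols].copy()
        freqs.columns = [float(c) for c in day_cols]
        return cls(mutations=df[meta_cols].copy(), freqs=freqs)


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def generations_per_day(dilution_rate: float) -> float:
    """Generations per day in continuous culture at dilution rate D (1/h).

    At steady state growth balances dilution, so the population doubles
    every ln 2 / D hours: 24*D/ln 2 generations per day.
    """
    if dilution_rate < 0:
        raise ValueError(f"dilution rate must be >= 0, got {dilution_rate}")
    return 24.0 * dilution_rate / math.log(2.0)


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def annotate_effect(
    position: int,
    ref: str,
    alt: str,
    gene_models: Sequence[GeneModel] | GeneIndex,
    genome_sequence: str,
) -> str:
    """Classify a SNP as synonymous / nonsynonymous / noncoding.

    Translates the affected codon (standard code, strand aware) before and
    after the change.  Any amino-acid change, including stop gain or loss,
    counts as nonsynonymous.  Positions outside all genes are noncoding.
    """
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"not a SNP: {ref}>{alt}")
    if genome_sequence[position - 1] != ref:
        raise ValueError(
            f"ref mismatch at {position}: genome has {genome_sequence[position - 1]}, got {ref}"
        )
    gene = index.find(position)
    if gene is None:
        return "noncoding"
    if gene.strand == "+":
        offset = position - gene.start
        codon_start = gene.start + 3 * (offset // 3)  # 1-based
        codon = genome_sequence[codon_start - 1 : codon_start + 2]
        within = position - codon_start
        mutated = codon[:within] + alt + codon[within + 1 :]
    else:
        offset = gene.end - position
        codon_end = gene.end - 3 * (offset // 3)  # 1-based, 5' end on - strand
        codon_fwd = genome_sequence[codon_end - 3 : codon_end]
        within_fwd = position - (codon_end - 2)
        mutated_fwd = codon_fwd[:within_fwd] + alt + codon_fwd[within_fwd + 1 :]
        codon = codon_fwd.translate(_COMPLEMENT)[::-1]
        mutated = mutated_fwd.translate(_COMPLEMENT)[::-1]
    if len(codon) < 3:  # truncated codon at a gene edge: treat conservatively
        return "nonsynonymous"
    return "synonymous" if CODON_TO_AA[codon] == CODON_TO_AA[mutated] else "nonsynonymous"


def fitness_of(
    genotype: Genotype, population_state: PopulationState, config: SimConfig
) -> float:
    """Relative fitness of a genotype in the current population.

    Distinct mutated driver genes multiply fitness by (1+s) once each,
    regardless of how many alleles of the gene the genotype carries.  A
    frequency-dependent carrier gains the factor (1 + s_h - c*x_h), where
    x_h is the current total frequency of freq-dep carriers -- unless
    epistasis blocks it (the genotype also carries a driver mutation in an
    epistasis gene).  Mutator and passenger mutations are fitness neutral.
    """
    x_h = freq_dep_carrier_frequency(population_state)
    return _fitness(genotype, x_h, config, config.gene_by_name())


def freq_dep_carrier_frequency(state: PopulationState) -> float:
    n = state.size
    if n == 0:
        return 0.0
    carriers = sum(c for g, c in state.counts.items() if g.freq_dep)
    return carriers / n


def _fitness(
    genotype: Genotype, x_h: float, config: SimConfig, genes: Mapping[str, GeneModel]
) -> float:
    w = 1.0
    for name in genotype.driver_genes:
        w *= 1.0 + genes[name].s
    if genotype.freq_dep and not (set(config.epistasis_genes) & genotype.driver_genes):
        w *= 1.0 + config.freq_dep_s - config.freq_dep_c * x_h
    return max(w, 0.0)


def freq_dep_equilibrium(
    s_h: float,
    c: float,
    x0: float = 0.01,
    tol: float = 1e-9,
    max_iter: int = 1_000_000,
) -> float:
    """Deterministic (infinite-N) equilibrium of a freq-dep lineage vs a
    neutral resident.

    Iterates x' = x*w_h / (x*w_h + 1 - x) with w_h = 1 + s_h - c*x until
    stationary.  The fixed point is x* = s_h/c (where w_h equals the
    resident's fitness 1).
    """
    x = float(x0)
    for _ in range(max_iter):
        w_h = max(1.0 + s_h - c * x, 0.0)
        mean_w = x * w_h + (1.0 - x)
        if mean_w == 0.0:
            return 0.0
        x_next = x * w_h / mean_w
        if abs(x_next - x) < tol:
            return x_next
        x = x_next
    return x


# ---------------------------------------------------------------------------
# simulation engine
# ---------------------------------------------------------------------------

class Simulation:
    """Holds the genome, gene index and mutation registry for one run.

    Use :meth:`step` to advance one Wright-Fisher generation or :meth:`run`
    for a full sampled time course.  ``rng`` defaults to a generator seeded
    from ``config.seed``.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator | None = None):
        config.require_valid()
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.gene_index = GeneIndex(config.genes)
        self._genes_by_name = config.gene_by_name()
        self._genome: str | None = None
        self.registry: dict[str, MutationRecord] = {}
        self._origin: dict[str, int] = {}  # mutation id -> genotype id of origin
        self._next_gid = 1
        self._next_mid = 0
        self._class_names = list(config.class_fractions)
        self._class_probs = np.array([config.class_fractions[c] for c in self._class_names])

    @property
    def genome(self) -> str:
        if self._genome is None:
            # genome drawn from a fixed stream so that mutation timing does
            # not depend on when the sequence is first needed
            genome_rng = np.random.default_rng(
                np.random.SeedSequence(self.config.seed if self.config.seed is not None else 0).spawn(1)[0]
            )
            self._genome = random_genome(self.config.genome_length, genome_rng)
        return self._genome

    def initial_state(self) -> PopulationState:
        return PopulationState(generation=0, counts={ANCESTOR: self.config.N})

    # -- one generation -----------------------------------------------------

    def step(self, state: PopulationState, rng: np.random.Generator | None = None) -> PopulationState:
        """Advance one generation: multinomial selection, then mutation."""
        rng = rng if rng is not None else self.rng
        cfg = self.config
        if state.size == 0:
            raise ValueError("cannot step an empty population")
        genotypes = list(state.counts)
        counts = np.array([state.counts[g] for g in genotypes], dtype=float)
        n = counts.sum()
        x_h = sum(c for g, c in state.counts.items() if g.freq_dep) / n
        w = np.array([_fitness(g, x_h, cfg, self._genes_by_name) for g in genotypes])
        weights = counts * w
        total = weights.sum()
        if total <= 0:
            raise ValueError("total fitness is zero; population is inviable")
        new_counts = rng.multinomial(cfg.N, weights / total)

        out: dict[Genotype, int] = {
            g: int(c) for g, c in zip(genotypes, new_counts) if c > 0
        }
        if cfg.mu > 0:
            self._mutate(out, rng)
        return PopulationState(generation=state.generation + 1, counts=out)

    def _mutate(self, counts: dict[Genotype, int], rng: np.random.Generator) -> None:
        cfg = self.config
        u = cfg.mu * cfg.genome_length
        events: list[Genotype] = []
        for g in list(counts):
            u_eff = u * (cfg.mutator_fold if g.mutator else 1.0)
            k = min(rng.poisson(counts[g] * u_eff), counts[g])
            events.extend([g] * k)
        if not events:
            return
        t = len(events)
        positions = rng.integers(1, cfg.genome_length + 1, size=t)
        classes = rng.choice(len(self._class_names), size=t, p=self._class_probs)
        for parent, pos, ci in zip(events, positions, classes):
            if counts.get(parent, 0) <= 0:
                continue  # parent lineage exhausted by earlier events this generation
            child = self._spawn(parent, int(pos), self._class_names[ci], rng)
            counts[parent] -= 1
            if counts[parent] == 0:
                del counts[parent]
            counts[child] = counts.get(child, 0) + 1

    def _spawn(
        self, parent: Genotype, position: int, mut_class: str, rng: np.random.Generator
    ) -> Genotype:
        gene = self.gene_index.find(position)
        gene_name = gene.name if gene is not None else "intergenic"
        ref = self.genome[position - 1]
        if mut_class == "SNP":
            alt = rng.choice([b for b in BASES if b != ref])
            effect = (
                annotate_effect(position, ref, alt, self.gene_index, self.genome)
                if gene is not None
                else "noncoding"
            )
        elif mut_class == "S-indel":
            alt = ref + rng.choice(list(BASES)) if rng.random() < 0.5 else "-1"
            effect = "noncoding"
        elif mut_class == "L-indel":
            alt = f"<INS:{int(rng.integers(50, 1500))}>"
            effect = "noncoding"
        else:  # duplication
            alt = f"<DUP:{int(rng.integers(1000, 30000))}>"
            effect = "noncoding"

        activating = False
        if gene is not None and gene.role != "neutral" and self.gene_index.is_target(gene, position):
            if mut_class == "SNP":
                activating = effect == "nonsynonymous"
            elif mut_class in ("S-indel", "L-indel"):
                activating = True
        role = gene.role if activating else "passenger"

        mid = f"m{self._next_mid}"
        self._next_mid += 1
        self.registry[mid] = MutationRecord(
            id=mid, position=position, ref=ref, alt=str(alt),
            mut_class=mut_class, gene=gene_name, effect=effect, role=role,
        )
        gid = self._next_gid
        self._next_gid += 1
        driver_genes = parent.driver_genes
        if role in ("driver_strong", "driver_late"):
            driver_genes = driver_genes | {gene_name}
        child = Genotype(
            gid,
            parent.mutation_ids + (mid,),
            driver_genes,
            parent.freq_dep or role == "freq_dep",
            parent.mutator or role == "mutator",
        )
        self._origin[mid] = gid
        return child

    # -- full run -----------------------------------------------------------

    def run(self) -> TruthTable:
        """Run the configured time course and return true trajectories.

        Samples the generation nearest each sample day; mutations that are
        never present at any sampled generation are dropped from the truth
        table (they exist transiently between samples).
        """
        cfg = self.config
        gpd = generations_per_day(cfg.dilution_rate)
        n_gen = math.ceil(cfg.duration_days * gpd)
        sample_gens = {min(int(round(d * gpd)), n_gen): d for d in cfg.sample_days}

        state = self.initial_state()
        snapshots: dict[float, dict[str, float]] = {}
        if state.generation in sample_gens:
            snapshots[sample_gens[state.generation]] = {}
        for _ in range(n_gen):
            state = self.step(state)
            if state.generation in sample_gens:
                snapshots[sample_gens[state.generation]] = self._frequencies(state)
        self.final_state = state
        return self._build_truth(snapshots, list(cfg.sample_days))

    def _frequencies(self, state: PopulationState) -> dict[str, float]:
        n = state.size
        acc: dict[str, float] = {}
        for g, c in state.counts.items():
            for mid in g.mutation_ids:
                acc[mid] = acc.get(mid, 0.0) + c
        return {mid: v / n for mid, v in acc.items()}

    def _build_truth(
        self, snapshots: dict[float, dict[str, float]], sample_days: list[float]
    ) -> TruthTable:
        seen = sorted(
            {mid for snap in snapshots.values() for mid in snap},
            key=lambda m: int(m[1:]),
        )
        freqs = pd.DataFrame(
            0.0, index=pd.Index(seen, name="mutation_id"), columns=[float(d) for d in sample_days]
        )
        for day, snap in snapshots.items():
            for mid, f in snap.items():
                freqs.at[mid, float(day)] = f
        meta = pd.DataFrame(
            [
                {
                    "position": r.position, "ref": r.ref, "alt": r.alt,
                    "mut_class": r.mut_class, "gene": r.gene, "effect": r.effect,
                    "role": r.role, "lineage_id": self._origin[r.id],
                }
                for r in (self.registry[m] for m in seen)
            ],
            index=freqs.index,
        )
        if meta.empty:
            meta = pd.DataFrame(
                columns=["position", "ref", "alt", "mut_class", "gene", "effect", "role", "lineage_id"],
                index=freqs.index,
            )
        return TruthTable(mutations=meta, freqs=freqs)


def step_generation(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """One Wright-Fisher generation (convenience wrapper over Simulation)."""
    return Simulation(config, rng=rng).step(state, rng)


def run_simulation(config: SimConfig, rng: np.random.Generator | None = None) -> TruthTable:
    """Simulate the configured time course and return the truth table."""
    sim = Simulation(config, rng=rng)
    truth = sim.run()
    logger.info(
        "simulated %d generations; %d mutations present at sampled days",
        math.ceil(config.duration_days * generations_per_day(config.dilution_rate)),
        len(truth.freqs),
    )
    return truth


# ---------------------------------------------------------------------------
# planted-lineage truth (benchmark generator with exact known linkage)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedLineage:
    """A lineage seeded at generation 0 with known member mutations.

    ``mutations`` lists (gene, role) pairs; every member mutation is private
    to the lineage, so their true trajectories are identical -- the ground
    truth for linkage/cohort benchmarks.
    """

    fitness: float
    init_freq: float
    mutations: tuple[tuple[str, str], ...]


def planted_lineage_truth(
    lineages: Sequence[PlantedLineage],
    N: int,
    sample_days: Sequence[float],
    dilution_rate: float = 0.1,
    duration_days: float = 60.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TruthTable:
    """Multi-type Wright-Fisher run over pre-seeded lineages (no new mutation).

    Lineage ``i`` gets lineage_id ``i`` and its mutations get ids
    ``p{i}_{j}``.  The residual ancestor (frequency 1 - sum init_freq)
    carries nothing.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    init = np.array([lin.init_freq for lin in lineages], dtype=float)
    if init.sum() > 1.0 + 1e-12:
        raise ValueError("initial lineage frequencies exceed 1")
    w = np.array([lin.fitness for lin in lineages] + [1.0])
    counts = np.zeros(len(lineages) + 1, dtype=np.int64)
    counts[:-1] = np.round(init * N).astype(np.int64)
    counts[-1] = N - counts[:-1].sum()

    gpd = generations_per_day(dilution_rate)
    n_gen = math.ceil(duration_days * gpd)
    sample_gens = {min(int(round(d * gpd)), n_gen): d for d in sample_days}

    traj: dict[float, np.ndarray] = {}
    if 0 in sample_gens:
        traj[sample_gens[0]] = counts[:-1] / N
    for gen in range(1, n_gen + 1):
        weights = counts * w
        counts = rng.multinomial(N, weights / weights.sum())
        if gen in sample_gens:
            traj[sample_gens[gen]] = counts[:-1] / N

    rows, meta_rows = [], []
    for i, lin in enumerate(lineages):
        for j, (gene, role) in enumerate(lin.mutations):
            mid = f"p{i}_{j}"
            rows.append((mid, [traj[d][i] for d in sample_days]))
            meta_rows.append(
                {
                    "position": 1 + i * 1000 + j, "ref": "A", "alt": "G",
                    "mut_class": "SNP", "gene": gene, "effect": "nonsynonymous",
                    "role": role, "lineage_id": i,
                }
            )
    index = pd.Index([r[0] for r in rows], name="mutation_id")
    freqs = pd.DataFrame(
        [r[1] for r in rows], index=index, columns=[float(d) for d in sample_days]
    )
    meta = pd.DataFrame(meta_rows, index=index)
    if meta.empty:
        meta = pd.DataFrame(
            columns=["position", "ref", "alt", "mut_class", "gene", "effect", "role", "lineage_id"],
            index=index,
        )
    return TruthTable(mutations=meta, freqs=freqs)
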