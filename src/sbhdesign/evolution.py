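"""Structure-constrained loop evolution.

Two search strategies over the sensing-loop sequence space:

* :func:`exhaustive_evolve` enumerates every sequence of a small variable
  region and ranks them by folding score - the global optimum, feasible up
  to 4^8 candidates.
* :func:`ga_evolve` is the elitist genetic algorithm used to evolve a
  shared ASO-sensing loop (ASL) across several spacers: a pool of random
  loops is grown each generation by single-point recombination, point
  mutation and fresh random loops, every candidate is scored by the product
  of per-spacer folding scores, and only the fittest N survive.

Ties between equal-scoring loops are broken by GC content closest to 50%,
then by the shortest homopolymer run, then lexicographically (total order,
which also makes ranked output byte-reproducible).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .folding import (
    TargetStructure,
    folding_score,
    predict_mfe,
    spacer_folding_score,
)
from .grammar import ASL, DEFAULT_0B_PATTERN, SpacerRecord
from .sequences import RNA_BASES, gc_fraction, max_homopolymer_run, revcomp_rna

MAX_EXHAUSTIVE_REGION = 8


@dataclass(frozen=True)
class ASLContext:
    """Design context of the sensing loop within the SBH(0B) stem.

    The flanks are forced by the stem design (they extend the stem by
    ``len(flank5)`` base pairs and fix the open-loop register), so evolution
    only explores the single-stranded core. ``core_length`` defaults to the
    14-nt ASO footprint.
    """

    flank5: str = "GGC"
    core_length: int = 14

    @property
    def flank3(self) -> str:
        return revcomp_rna(self.flank5)

    def make_asl(self, core: str) -> ASL:
        if len(core) != self.core_length:
            raise ValueError(
                f"core length {len(core)} != context core_length {self.core_length}"
            )
        return ASL(self.flank5 + core + self.flank3, flank_len=len(self.flank5))

    def repair(self, sequence: str) -> ASL:
        """Re-impose the forced stem-complementary flanks on a 20-mer."""
        k = len(self.flank5)
        return ASL(self.flank5 + sequence[k : len(sequence) - k] + self.flank3,
                   flank_len=k)


@dataclass
class GAConfig:
    """Genetic-algorithm knobs: pool of 150, at least 20 generations, and a
    stop after the best score stalls for 2 consecutive generations.

    The number of mutated and fresh random loops injected per generation and
    the per-base mutation rate are free parameters of the method; defaults
    are half the pool size each and 0.05 per core base.
    """

    pool_size: int = 150
    max_generations: int = 20
    stall_generations: int = 2
    mutated_per_generation: int | None = None
    random_per_generation: int | None = None
    mutation_rate: float = 0.05
    seed: int = 0
    hard_cap_factor: int = 5

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if not 0.0 < self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.mutated_per_generation is None:
            self.mutated_per_generation = self.pool_size // 2
        if self.random_per_generation is None:
            self.random_per_generation = self.pool_size // 2
        for name in ("max_generations", "stall_generations",
                     "mutated_per_generation", "random_per_generation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FitnessRecord:
    """A scored loop candidate with its tie-break attributes."""

    asl: ASL
    per_spacer_scores: tuple[float, ...]
    product_score: float
    gc_fraction: float
    max_homopolymer_run: int

    @classmethod
    def from_scores(cls, asl: ASL, scores: tuple[float, ...]) -> "FitnessRecord":
        product = 1.0
        for s in scores:
            product *= s
        return cls(
            asl=asl,
            per_spacer_scores=scores,
            product_score=product,
            gc_fraction=gc_fraction(asl.sequence),
            max_homopolymer_run=max_homopolymer_run(asl.sequence),
        )


def tiebreak_rank(records: list[FitnessRecord]) -> list[FitnessRecord]:
    """Total ordering: score desc, |GC - 0.5| asc, homopolymer run asc,
    sequence lexicographic asc."""
    return sorted(
        records,
        key=lambda r: (
            -r.product_score,
            abs(r.gc_fraction - 0.5),
            r.max_homopolymer_run,
            r.asl.sequence,
        ),
    )


def random_asl(context: ASLContext, rng: random.Random) -> ASL:
    """Uniform random core with the forced stem-complementary flanks."""
    core = "".join(rng.choice(RNA_BASES) for _ in range(context.core_length))
    return context.make_asl(core)


def recombine(a: ASL, b: ASL, rng: random.Random,
              context: ASLContext | None = None) -> tuple[ASL, ASL]:
    """Single-point crossover at a uniform interior position; children are
    repaired to restore the flank constraint."""
    if len(a.sequence) != len(b.sequence):
        raise ValueError("parents differ in length")
    context = context or ASLContext(a.flank5, len(a.core))
    k = rng.randrange(1, len(a.sequence))
    c1 = a.sequence[:k] + b.sequence[k:]
    c2 = b.sequence[:k] + a.sequence[k:]
    return context.repair(c1), context.repair(c2)


def mutate(asl: ASL, rate: float, rng: random.Random,
           context: ASLContext | None = None) -> ASL:
    """Independent per-core-base substitution to a different base with the
    given probability; flanks are left forced."""
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must lie in (0, 1)")
    context = context or ASLContext(asl.flank5, len(asl.core))
    core = list(asl.core)
    for i, base in enumerate(core):
        if rng.random() < rate:
            core[i] = rng.choice([b for b in RNA_BASES if b != base])
    return context.make_asl("".join(core))


def exhaustive_evolve(
    template: str,
    variable_region: tuple[int, int],
    target: TargetStructure,
    engine=None,
    max_region: int = MAX_EXHAUSTIVE_REGION,
) -> list[tuple[str, float]]:
    """Enumerate every fill of ``template[start:end]`` and rank by score.

    Returns (sequence, score) sorted by score descending with the standard
    tie-breaks; the top entry is the global optimum for the region. Refuses
    regions longer than ``max_region`` (use the GA instead).
    """
    start, end = variable_region
    if not 0 <= start < end <= len(template):
        raise ValueError("variable region outside the template")
    if end - start > max_region:
        raise ValueError(
            f"variable region of {end - start} nt exceeds the exhaustive "
            f"limit of {max_region}; use ga_evolve for larger spaces"
        )
    ranked: list[tuple[str, float]] = []
    for fill in itertools.product(RNA_BASES, repeat=end - start):
        seq = template[:start] + "".join(fill) + template[end:]
        score = float(folding_score(predict_mfe(seq, engine), target))
        ranked.append((seq, score))
    ranked.sort(key=lambda t: (
        -t[1],
        abs(gc_fraction(t[0][start:end]) - 0.5),
        max_homopolymer_run(t[0][start:end]),
        t[0],
    ))
    return ranked


def exhaustive_shared_loop(
    spacers: list[SpacerRecord],
    context: ASLContext,
    engine=None,
    bulge_pattern: tuple = DEFAULT_0B_PATTERN,
    max_region: int = MAX_EXHAUSTIVE_REGION,
) -> list[FitnessRecord]:
    """Global optimum of the shared-loop problem by core enumeration.

    The independent oracle for the GA: every possible core is scored with
    the same product-of-FS_i fitness and ranked with the same tie-breaks.
    """
    if not spacers:
        raise ValueError("at least one spacer is required")
    if context.core_length > max_region:
        raise ValueError(
            f"core length {context.core_length} exceeds the exhaustive limit"
        )
    records = []
    for fill in itertools.product(RNA_BASES, repeat=context.core_length):
        asl = context.make_asl("".join(fill))
        scores = tuple(
            float(spacer_folding_score(asl, sp, engine, bulge_pattern))
            for sp in spacers
        )
        records.append(FitnessRecord.from_scores(asl, scores))
    return tiebreak_rank(records)


@dataclass
class GARun:
    """Outcome of one GA run: final ranked pool plus a per-generation trace."""

    ranked: list[FitnessRecord]
    generations: int
    best_per_generation: list[float] = field(default_factory=list)

    @property
    def best(self) -> FitnessRecord:
        return self.ranked[0]


def ga_evolve(
    spacers: list[SpacerRecord],
    config: GAConfig | None = None,
    engine=None,
    context: ASLContext | None = None,
    bulge_pattern: tuple = DEFAULT_0B_PATTERN,
) -> GARun:
    """Evolve a shared ASO-sensing loop across ``spacers``.

    Per generation: (1) every pool member is recombined with a uniformly
    chosen partner and both offspring join the pool; (2) mutated copies of
    pool members are added; (3) fresh random loops are added; (4) all
    candidates are scored by the product of per-spacer folding scores and
    the top ``pool_size`` unique loops survive. The loop stops once the
    generation count exceeds ``max_generations`` and the best score has been
    unchanged for ``stall_generations`` consecutive generations, or at a
    hard cap of ``hard_cap_factor * max_generations``. Fully reproducible
    under a fixed seed.
    """
    if not spacers:
        raise ValueError("at least one spacer is required")
    config = config or GAConfig()
    context = context or ASLContext()
    rng = random.Random(config.seed)

    cache: dict[str, tuple[float, ...]] = {}

    def scores_of(asl: ASL) -> tuple[float, ...]:
        key = asl.sequence
        if key not in cache:
            cache[key] = tuple(
                float(spacer_folding_score(asl, sp, engine, bulge_pattern))
                for sp in spacers
            )
        return cache[key]

    def select(candidates: list[ASL]) -> list[FitnessRecord]:
        seen: set[str] = set()
        records = []
        for asl in candidates:
            if asl.sequence in seen:
                continue
            seen.add(asl.sequence)
            records.append(FitnessRecord.from_scores(asl, scores_of(asl)))
        return tiebreak_rank(records)[: config.pool_size]

    pool = [random_asl(context, rng) for _ in range(config.pool_size)]
    survivors = select(pool)

    best_trace: list[float] = []
    stall = 0
    generation = 0
    hard_cap = config.hard_cap_factor * config.max_generations
    while True:
        generation += 1
        parents = [r.asl for r in survivors]
        candidates = list(parents)
        for member in parents:
            partner = parents[rng.randrange(len(parents))]
            c1, c2 = recombine(member, partner, rng, context)
            candidates.extend((c1, c2))
        for _ in range(config.mutated_per_generation):
            base = parents[rng.randrange(len(parents))]
            candidates.append(mutate(base, config.mutation_rate, rng, context))
        for _ in range(config.random_per_generation):
            candidates.append(random_asl(context, rng))
        survivors = select(candidates)

        best = survivors[0].product_score
        if best_trace and best == best_trace[-1]:
            stall += 1
        else:
            stall = 0
        best_trace.append(best)
        if generation > config.max_generations and stall >= config.stall_generations:
            break
        if generation >= hard_cap:
            break

    return GARun(ranked=survivors, generations=generation,
                 best_per_generation=best_trace)


def plant_shared_loop_instance(
    n_spacers: int,
    engine=None,
    context: ASLContext | None = None,
    probe_core: str | None = None,
    seed: int = 0,
    gc_target: float = 0.6,
    max_tries: int = 2000,
) -> tuple[list[SpacerRecord], ASL]:
    """Construct spacers on which a known loop folds perfectly.

    Draws random spacers and keeps those whose SBH(0B) hairpin with the
    probe loop reaches folding score 1.0 - a planted instance whose global
    optimum is known, used to validate loop-evolution recovery.
    """
    context = context or ASLContext()
    probe = context.make_asl(probe_core or "A" * context.core_length)
    rng = random.Random(seed)
    spacers: list[SpacerRecord] = []
    tries = 0
    while len(spacers) < n_spacers:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"no planted instance found in {max_tries} draws"
            )
        seq = "".join(
            rng.choice("GC") if rng.random() < gc_target else rng.choice("AU")
            for _ in range(20)
        )
        try:
            spacer = SpacerRecord(f"planted_{len(spacers) + 1}", seq)
        except ValueError:
            continue
        fs = float(spacer_folding_score(probe, spacer, engine))
        if fs == 1.0:
            spacers.append(spacer)
    return spacers, probe
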