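"""Thermodynamic folding backend and structure-similarity scoring.

The design pipeline needs three things from a folding engine: the
minimum-free-energy (MFE) structure of a candidate guide, its free energy,
and (optionally) base-pair probabilities. The engine is pluggable; the
default backend wraps the ViennaRNA dynamic-programming fold at 37 degrees C
with the default parameter set. Everything above the engine - expected-fold
construction and the per-spacer folding score FS_i in [0, 1] - is
engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .grammar import ASL, DEFAULT_0B_PATTERN, SBHConstruct, SpacerRecord, assemble_sbh
from .sequences import normalize_rna, pairs_from_dotbracket

DEFAULT_TEMPERATURE_C = 37.0


class EngineUnavailableError(RuntimeError):
    """No folding backend could be loaded."""


@dataclass(frozen=True)
class FoldResult:
    """An MFE prediction: sequence, dot-bracket structure, energy (kcal/mol)."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure length differs from sequence length")

    def pair_map(self) -> dict[int, int]:
        return pairs_from_dotbracket(self.structure)


@dataclass(frozen=True)
class TargetStructure:
    """The expected fold: dot-bracket plus a mask of asserted positions.

    Positions outside the mask (typically the scaffold) are ignored by the
    folding score; within the mask, brackets assert a specific partner and
    dots assert the unpaired state.
    """

    structure: str
    constrained_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.constrained_mask):
            raise ValueError("mask length differs from structure length")
        pairs_from_dotbracket(self.structure)  # validates bracket balance

    def pair_map(self) -> dict[int, int]:
        return pairs_from_dotbracket(self.structure)

    @property
    def n_constrained(self) -> int:
        return sum(self.constrained_mask)


@dataclass(frozen=True)
class FoldingScore:
    """Similarity of a predicted fold to the expected fold, in [0, 1]."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"folding score {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


class ViennaRNAEngine:
    """MFE folding via the ViennaRNA python bindings (default parameters).

    Deterministic: identical sequence, temperature and parameter set give
    identical structures and energies across runs.
    """

    name = "viennarna"

    def __init__(self, temperature: float = DEFAULT_TEMPERATURE_C) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - env without bindings
            raise EngineUnavailableError(
                "ViennaRNA python bindings not importable; install the "
                "viennarna package or supply another engine object with a "
                "fold(seq) -> FoldResult method"
            ) from exc
        self._RNA = RNA
        self.temperature = temperature
        self._md = RNA.md()
        self._md.temperature = temperature

    @property
    def version(self) -> str:
        return self._RNA.__version__

    def fold(self, seq: str) -> FoldResult:
        seq = normalize_rna(seq)
        if not seq:
            raise ValueError("cannot fold an empty sequence")
        fc = self._RNA.fold_compound(seq, self._md)
        structure, mfe = fc.mfe()
        return FoldResult(sequence=seq, structure=structure, mfe=round(mfe, 2))

    def pair_probabilities(self, seq: str) -> list[list[float]]:
        """Equilibrium base-pair probability matrix (0-based, symmetric)."""
        seq = normalize_rna(seq)
        fc = self._RNA.fold_compound(seq, self._md)
        fc.pf()
        bpp = fc.bpp()  # 1-based upper-triangular
        n = len(seq)
        mat = [[0.0] * n for _ in range(n)]
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p = bpp[i][j]
                if p > 0.0:
                    mat[i - 1][j - 1] = p
                    mat[j - 1][i - 1] = p
        return mat


@lru_cache(maxsize=1)
def default_engine() -> ViennaRNAEngine:
    return ViennaRNAEngine()


def predict_mfe(seq: str, engine=None) -> FoldResult:
    """Minimum-free-energy structure of ``seq`` under the given engine."""
    engine = engine or default_engine()
    return engine.fold(seq)


def target_structure(construct: SBHConstruct) -> TargetStructure:
    """Expected fold of a construct from its design pairing.

    Back-fold positions open brackets, covered spacer positions close them,
    bulges / loop cores / free spacer nucleotides are dots, and scaffold
    positions are left unconstrained.
    """
    n = len(construct.full_sequence)
    chars = ["."] * n
    for i, j in construct.pairs:
        chars[i], chars[j] = "(", ")"
    mask = [True] * n
    if construct.scaffold_included:
        s0, s1 = construct.regions["scaffold"]
        for p in range(s0, s1):
            mask[p] = False
    return TargetStructure("".join(chars), tuple(mask))


def folding_score(
    pred: FoldResult,
    target: TargetStructure,
    mode: str = "mfe",
    pair_probs: list[list[float]] | None = None,
) -> FoldingScore:
    """Per-spacer folding score FS_i: similarity of prediction to target.

    Default ``mfe`` mode: the fraction of constrained positions whose
    pairing state matches the target, where a bracket requires the identical
    partner and a dot requires the unpaired state. ``probability`` mode
    averages, over constrained positions, the engine's probability of the
    target pair (or of being unpaired at target dots); it needs the
    ``pair_probs`` matrix from ``engine.pair_probabilities``.
    """
    if len(pred.structure) != len(target.structure):
        raise ValueError(
            f"prediction length {len(pred.structure)} != target length "
            f"{len(target.structure)}"
        )
    tmap = target.pair_map()
    n_constrained = target.n_constrained
    if n_constrained == 0:
        return FoldingScore(1.0)

    if mode == "mfe":
        pmap = pred.pair_map()
        matches = 0
        for pos, constrained in enumerate(target.constrained_mask):
            if not constrained:
                continue
            if tmap.get(pos) == pmap.get(pos):
                matches += 1
        return FoldingScore(matches / n_constrained)

    if mode == "probability":
        if pair_probs is None:
            raise ValueError("probability mode needs a pair_probs matrix")
        total = 0.0
        for pos, constrained in enumerate(target.constrained_mask):
            if not constrained:
                continue
            partner = tmap.get(pos)
            if partner is None:
                total += 1.0 - sum(pair_probs[pos])
            else:
                total += pair_probs[pos][partner]
        return FoldingScore(min(1.0, max(0.0, total / n_constrained)))

    raise ValueError(f"unknown folding-score mode {mode!r}")


def asl_hairpin(
    asl: ASL,
    spacer: SpacerRecord,
    bulge_pattern: tuple = DEFAULT_0B_PATTERN,
) -> SBHConstruct:
    """The ASL-spacer hairpin scored during loop evolution: SBH(0B) stem
    with the sensing loop at the apex."""
    return assemble_sbh(spacer, loop_unit=asl.as_unit(), free_count_x=0,
                        bulge_pattern=bulge_pattern)


def spacer_folding_score(
    asl: ASL,
    spacer: SpacerRecord,
    engine=None,
    bulge_pattern: tuple = DEFAULT_0B_PATTERN,
    mode: str = "mfe",
) -> FoldingScore:
    """FS_i of one ASL against one spacer's SBH(0B) hairpin."""
    construct = asl_hairpin(asl, spacer, bulge_pattern)
    pred = predict_mfe(construct.full_sequence, engine)
    return folding_score(pred, target_structure(construct), mode=mode)


def combined_score(
    asl: ASL,
    spacers: list[SpacerRecord],
    engine=None,
    bulge_pattern: tuple = DEFAULT_0B_PATTERN,
    mode: str = "mfe",
) -> float:
    """Product of per-spacer folding scores FS_1 ... FS_p for a shared loop."""
    if not spacers:
        raise ValueError("at least one spacer is required")
    product = 1.0
    for sp in spacers:
        product *= float(spacer_folding_score(asl, sp, engine, bulge_pattern, mode))
        if product == 0.0:
            break
    return product


def stem_free_energy(
    construct: SBHConstruct,
    engine=None,
    include_scaffold: bool = False,
) -> float:
    """MFE of the hairpin region (back-fold + loop + spacer), kcal/mol.

    The scaffold is excluded by default: its own structure would dominate
    the value, and the quantity of interest is the stability of the
    spacer-blocking stem. ``include_scaffold`` folds the whole guide.
    """
    seq = construct.full_sequence if include_scaffold else construct.hairpin_sequence
    result = predict_mfe(seq, engine)
    return result.mfe


def duplex_stem_energy(construct: SBHConstruct, engine=None) -> float:
    """Alternative stability proxy: fold back-fold and spacer joined by an
    inert linker loop, ignoring the cleaving unit's own sequence."""
    linker = "GAAA"
    seq = construct.region_seq("backfold") + linker + construct.region_seq("spacer")
    return predict_mfe(seq, engine).mfe
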