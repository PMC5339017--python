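"""Construct grammar: deterministic assembly of SBH and iSBH guide RNAs.

A spacer-blocking hairpin (SBH) guide reads, 5' to 3':

    back-fold  --  loop / cleaving unit  --  spacer  [-- scaffold]

The back-fold is the reverse complement of the loop-proximal spacer segment,
so the guide folds into a hairpin that sequesters the spacer and silences
the CRISPR transcriptional regulator until the loop is cleaved. Superscript
``x`` in SBH(x) counts spacer nucleotides left free (unpaired) at the
scaffold-proximal 3' end; bulges are extra unpaired nucleotides inserted in
the stem to tune its separation energy.

Coordinates are 0-based half-open throughout; position 0 is the 5'-most
nucleotide of the assembled guide. Bulge positions are expressed as paired
stem depths counted from the loop-proximal end of the stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .sequences import is_watson_crick, normalize_rna, revcomp_rna
from .units import BASIC_LOOP, SCAFFOLDS, CleavingUnit

MIN_SPACER_LEN = 10
MAX_SPACER_LEN = 20

#: Default bulged-stem pattern of the SBH(0B) design: two 2-nt bulges on the
#: spacer strand (back-fold skips the complements, spacer stays intact for
#: DNA targeting) at paired-stem depths 5 and 12 from the loop.
DEFAULT_0B_PATTERN: tuple["BulgeElement", ...]

#: SBH(0B*) adds a basal 2-nt bulge one pair above the stem base, the
#: destabilizing variant that abolishes silencing.
DEFAULT_0BSTAR_PATTERN: tuple["BulgeElement", ...]


class GeometryError(ValueError):
    """A bulge pattern or graft request does not fit the stem."""


class NotCleavableError(ValueError):
    """Residual-nucleotide accounting requested on a unit without cut site."""


@dataclass(frozen=True)
class SpacerRecord:
    """A named guide spacer (RNA, 10-20 nt), the design target."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("spacer name must be non-empty")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not MIN_SPACER_LEN <= len(self.sequence) <= MAX_SPACER_LEN:
            raise ValueError(
                f"spacer {self.name!r}: length {len(self.sequence)} outside "
                f"[{MIN_SPACER_LEN}, {MAX_SPACER_LEN}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class BulgeElement:
    """An unpaired insertion in the stem.

    ``stem_index`` is the number of base pairs between the loop and the
    bulge; ``strand`` selects whether the unpaired nucleotides sit on the
    spacer strand (the back-fold skips their complements) or on the
    back-fold strand (extra filler nucleotides are inserted).
    """

    stem_index: int
    length: int = 2
    strand: str = "spacer"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("bulge length must be >= 1")
        if self.stem_index < 0:
            raise ValueError("stem_index must be >= 0")
        if self.strand not in ("spacer", "backfold"):
            raise ValueError(f"unknown bulge strand {self.strand!r}")


DEFAULT_0B_PATTERN = (BulgeElement(5, 2), BulgeElement(12, 2))
DEFAULT_0BSTAR_PATTERN = (BulgeElement(5, 2), BulgeElement(12, 2), BulgeElement(13, 2))


@dataclass(frozen=True)
class ASL:
    """An ASO-sensing loop: single-stranded core plus 3-nt closing flanks.

    The default geometry is 20 nt: a 14-nt core held open for ASO pairing,
    flanked by three nucleotides on each side that pair with each other and
    extend the stem, fixing the loop register. Core length is configurable
    (small cores make the design space exhaustively searchable).
    """

    sequence: str
    flank_len: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 2 * self.flank_len + 1:
            raise ValueError("ASL shorter than its two flanks")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def flank5(self) -> str:
        return self.sequence[: self.flank_len]

    @property
    def core(self) -> str:
        return self.sequence[self.flank_len : -self.flank_len]

    @property
    def flank3(self) -> str:
        return self.sequence[-self.flank_len :]

    def as_unit(self) -> CleavingUnit:
        """Expose the loop as a graftable unit with its flank pairs."""
        n = len(self.sequence)
        pairs = tuple((i, n - 1 - i) for i in range(self.flank_len))
        return CleavingUnit(name="ASL", sequence=self.sequence, internal_pairs=pairs)


@dataclass(frozen=True)
class SBHConstruct:
    """A fully assembled hairpin guide with explicit expected pairing.

    ``regions`` maps region names (backfold, loop, spacer, scaffold) to
    half-open intervals whose concatenated slices reproduce
    ``full_sequence``. ``pairs`` is the expected (target) base-pair set of
    the design, used both for structure scoring and residual-nucleotide
    accounting. ``spacer_offset`` counts 5' spacer nucleotides removed by
    stem-shortening grafts (0 for plain assemblies).
    """

    spacer: SpacerRecord
    free_count_x: int
    bulge_pattern: tuple[BulgeElement, ...]
    loop_unit: CleavingUnit
    backfold: str
    full_sequence: str
    regions: dict[str, tuple[int, int]]
    scaffold_included: bool
    pairs: tuple[tuple[int, int], ...]
    cut_site: int | None = None
    spacer_offset: int = 0
    geometry: str = "apex"

    def region_seq(self, name: str) -> str:
        start, end = self.regions[name]
        return self.full_sequence[start:end]

    @property
    def hairpin_sequence(self) -> str:
        """Back-fold + loop + spacer, scaffold excluded."""
        end = self.regions["spacer"][1]
        return self.full_sequence[:end]

    @property
    def stem_pair_count(self) -> int:
        """Number of back-fold:spacer base pairs (graft-monotone quantity)."""
        b0, b1 = self.regions["backfold"]
        s0, s1 = self.regions["spacer"]
        return sum(1 for i, j in self.pairs if b0 <= i < b1 and s0 <= j < s1)

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out


def revcomp(seq: str) -> str:  # re-export used by callers of the grammar
    return revcomp_rna(seq)


def _validate_pattern(
    pattern: tuple[BulgeElement, ...], covered: int
) -> tuple[BulgeElement, ...]:
    pattern = tuple(sorted(pattern))
    spacer_bulge_nt = sum(b.length for b in pattern if b.strand == "spacer")
    paired_len = covered - spacer_bulge_nt
    if paired_len < 0:
        raise GeometryError("bulge pattern consumes more spacer than the stem covers")
    seen: set[tuple[int, str]] = set()
    for b in pattern:
        if b.stem_index > paired_len:
            raise GeometryError(
                f"bulge at stem depth {b.stem_index} beyond paired stem "
                f"length {paired_len}"
            )
        key = (b.stem_index, b.strand)
        if key in seen:
            raise GeometryError(f"overlapping bulges at stem depth {b.stem_index}")
        seen.add(key)
    return pattern


def build_backfold(
    spacer: SpacerRecord,
    free_count_x: int,
    bulge_pattern: tuple[BulgeElement, ...] = (),
    fill: str = "A",
) -> str:
    """Back-fold strand for an SBH(x) stem over the given spacer.

    The back-fold reverse-complements the loop-proximal (5') ``len - x``
    spacer nucleotides; spacer-strand bulges are realized as skipped
    complements, back-fold-strand bulges as inserted ``fill`` nucleotides.
    """
    backfold, _pairs, _bulges = _build_stem(spacer, free_count_x, bulge_pattern, fill)
    return backfold


def _build_stem(
    spacer: SpacerRecord,
    free_count_x: int,
    bulge_pattern: tuple[BulgeElement, ...],
    fill: str = "A",
) -> tuple[str, list[tuple[int, int]], dict[str, list[int]]]:
    """Construct the stem: back-fold string plus the pairing map.

    Returns ``(backfold, pairs, bulge_positions)`` where ``pairs`` holds
    (backfold_local_index, spacer_local_index) tuples and
    ``bulge_positions`` lists the local indices of unpaired bulge
    nucleotides per strand.
    """
    L = len(spacer)
    if not 0 <= free_count_x <= L:
        raise ValueError(f"free_count_x {free_count_x} outside [0, {L}]")
    covered = L - free_count_x
    pattern = _validate_pattern(tuple(bulge_pattern), covered)
    paired_len = covered - sum(b.length for b in pattern if b.strand == "spacer")

    by_depth: dict[int, list[BulgeElement]] = {}
    for b in pattern:
        by_depth.setdefault(b.stem_index, []).append(b)

    seq = spacer.sequence
    loop_first: list[str] = []  # back-fold, loop-proximal end first
    rev_pairs: list[tuple[int, int]] = []  # (index into loop_first, spacer idx)
    bulges = {"spacer": [], "backfold": []}
    s = 0
    for depth in range(paired_len + 1):
        for b in by_depth.get(depth, ()):
            if b.strand == "spacer":
                bulges["spacer"].extend(range(s, s + b.length))
                s += b.length
            else:
                for _ in range(b.length):
                    bulges["backfold"].append(len(loop_first))
                    loop_first.append(fill)
        if depth < paired_len:
            loop_first.append(revcomp_rna(seq[s]))
            rev_pairs.append((len(loop_first) - 1, s))
            s += 1
    assert s == covered
    B = len(loop_first)
    backfold = "".join(reversed(loop_first))
    pairs = [(B - 1 - k, sp) for k, sp in rev_pairs]
    bulge_positions = {
        "spacer": bulges["spacer"],
        "backfold": [B - 1 - k for k in bulges["backfold"]],
    }
    return backfold, pairs, bulge_positions


def assemble_sbh(
    spacer: SpacerRecord,
    loop_unit: CleavingUnit = BASIC_LOOP,
    free_count_x: int = 0,
    bulge_pattern: tuple[BulgeElement, ...] = (),
    include_scaffold: bool = False,
    scaffold: str = "tracr",
    fill: str = "A",
) -> SBHConstruct:
    """Assemble back-fold + loop + spacer (+ scaffold) into a construct."""
    backfold, stem_pairs, _ = _build_stem(spacer, free_count_x, tuple(bulge_pattern), fill)
    B = len(backfold)
    U = len(loop_unit.sequence)
    L = len(spacer)
    scaffold_seq = SCAFFOLDS[scaffold] if include_scaffold else ""
    full = backfold + loop_unit.sequence + spacer.sequence + scaffold_seq
    regions = {
        "backfold": (0, B),
        "loop": (B, B + U),
        "spacer": (B + U, B + U + L),
    }
    if include_scaffold:
        regions["scaffold"] = (B + U + L, len(full))
    pairs = [(bf, B + U + sp) for bf, sp in stem_pairs]
    pairs += [(B + i, B + j) for i, j in loop_unit.internal_pairs]
    cut = B + loop_unit.cut_offset if loop_unit.cut_offset is not None else None
    return SBHConstruct(
        spacer=spacer,
        free_count_x=free_count_x,
        bulge_pattern=tuple(sorted(tuple(bulge_pattern))),
        loop_unit=loop_unit,
        backfold=backfold,
        full_sequence=full,
        regions=regions,
        scaffold_included=include_scaffold,
        pairs=tuple(sorted(pairs)),
        cut_site=cut,
    )


def graft_unit(construct: SBHConstruct, unit: CleavingUnit) -> SBHConstruct:
    """Graft a cleaving unit at the apex or at a stem bulge.

    Apex grafts swap the loop for the unit. Bulge grafts implement the
    stem-shortened "medium" (distal, loop-proximal bulge) and "nano"
    (proximal, scaffold-proximal bulge) geometries: the stem segment between
    the apex and the chosen bulge is deleted on both strands, the unit
    bridges the cut points, and as much of the unit's post-cut 3' tail as
    fits is fused into the redesigned stem (paired against a rebuilt
    back-fold segment), so the post-cleavage 5' residue stays structured.
    """
    if unit.graft_mode == "apex":
        grafted = assemble_sbh(
            construct.spacer,
            loop_unit=unit,
            free_count_x=construct.free_count_x,
            bulge_pattern=construct.bulge_pattern,
            include_scaffold=construct.scaffold_included,
        )
        return replace(grafted, geometry="full")

    spacer_bulges = [b for b in construct.bulge_pattern if b.strand == "spacer"]
    if not spacer_bulges:
        raise GeometryError(
            f"graft mode {unit.graft_mode!r} requires a bulged stem"
        )
    if unit.graft_mode == "distal_bulge":
        anchor = min(spacer_bulges, key=lambda b: b.stem_index)
        geometry = "medium"
    else:
        anchor = max(spacer_bulges, key=lambda b: b.stem_index)
        geometry = "nano"
    d = anchor.stem_index

    spacer_seq = construct.spacer.sequence
    L = len(spacer_seq)
    # spacer nucleotides removed: d paired + earlier spacer bulges + anchor
    del_sp = d + sum(
        b.length for b in spacer_bulges if b.stem_index < d
    ) + anchor.length
    del_bf = d + sum(
        b.length
        for b in construct.bulge_pattern
        if b.strand == "backfold" and b.stem_index <= d
    )
    backfold_remaining = construct.backfold[: len(construct.backfold) - del_bf]

    tail = unit.sequence[unit.cut_offset :] if unit.cut_offset is not None else ""
    absorbed = min(len(tail), d)
    new_backfold = backfold_remaining + revcomp_rna(tail[:absorbed])
    B2 = len(new_backfold)
    U = len(unit.sequence)
    spacer_remaining = spacer_seq[del_sp:]
    scaffold_seq = (
        construct.region_seq("scaffold") if construct.scaffold_included else ""
    )
    full = new_backfold + unit.sequence + spacer_remaining + scaffold_seq
    regions = {
        "backfold": (0, B2),
        "loop": (B2, B2 + U),
        "spacer": (B2 + U, B2 + U + len(spacer_remaining)),
    }
    if construct.scaffold_included:
        regions["scaffold"] = (B2 + U + len(spacer_remaining), len(full))

    pairs: list[tuple[int, int]] = [(B2 + i, B2 + j) for i, j in unit.internal_pairs]
    if unit.cut_offset is not None:
        pairs += [
            (B2 - 1 - i, B2 + unit.cut_offset + i) for i in range(absorbed)
        ]
    # retained stem pairs, re-indexed after the two-strand deletion
    b_old0, _ = construct.regions["backfold"]
    s_old0, _ = construct.regions["spacer"]
    for i, j in construct.pairs:
        if b_old0 <= i < len(construct.backfold) and s_old0 <= j:
            bf_local, sp_local = i - b_old0, j - s_old0
            if sp_local >= del_sp and bf_local < len(backfold_remaining):
                pairs.append((bf_local, B2 + U + sp_local - del_sp))

    remaining_bulges = tuple(
        BulgeElement(b.stem_index - d, b.length, b.strand)
        for b in construct.bulge_pattern
        if b.stem_index > d and not (b.strand == "spacer" and b is anchor)
    )
    cut = B2 + unit.cut_offset if unit.cut_offset is not None else None
    return SBHConstruct(
        spacer=construct.spacer,
        free_count_x=construct.free_count_x,
        bulge_pattern=remaining_bulges,
        loop_unit=unit,
        backfold=new_backfold,
        full_sequence=full,
        regions=regions,
        scaffold_included=construct.scaffold_included,
        pairs=tuple(sorted(pairs)),
        cut_site=cut,
        spacer_offset=del_sp,
        geometry=geometry,
    )


def residual_5p_nt(construct: SBHConstruct) -> int:
    """Unstructured nucleotides left 5' of the spacer after cleavage.

    Counts positions between the unit's cut site and the spacer region that
    are unpaired in the expected fold: these remain covalently attached to
    the active guide after in-silico cleavage but are neither part of the
    spacer nor held in a helix.
    """
    if construct.cut_site is None:
        raise NotCleavableError(
            f"loop unit {construct.loop_unit.name!r} has no cut site"
        )
    paired = construct.paired_positions()
    spacer_start = construct.regions["spacer"][0]
    return sum(
        1 for p in range(construct.cut_site, spacer_start) if p not in paired
    )


def apply_u6_g(seq: str) -> str:
    """Prefix the G required at +1 by U6-promoter transcription; idempotent."""
    if not seq:
        raise ValueError("empty sequence")
    return seq if seq[0] == "G" else "G" + seq


def check_backfold_complementarity(construct: SBHConstruct) -> bool:
    """True when every expected stem pair is Watson-Crick complementary."""
    seq = construct.full_sequence
    return all(is_watson_crick(seq[i], seq[j]) for i, j in construct.pairs)
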