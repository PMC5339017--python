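"""Systematic construct generators: the SBH(x) series and bulge sliding.

Both produce a :class:`SeriesReport` with one scored entry per construct
(sequence, predicted structure, stem MFE, cloning oligos), mirroring the
batch design workflows a bench scientist runs before picking a candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .folding import FoldResult, predict_mfe
from .grammar import BulgeElement, SBHConstruct, SpacerRecord, assemble_sbh
from .oligos import OligoPair, cloning_oligos
from .units import BASIC_LOOP, CleavingUnit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeriesEntry:
    """One construct of a series with its fold and synthesis oligos."""

    label: str
    x_or_offset: int
    construct: SBHConstruct
    fold: FoldResult
    stem_mfe: float
    oligos: OligoPair

    @property
    def flagged(self) -> bool:
        """Set when the entry exceeded the report's MFE ceiling."""
        return getattr(self, "_flagged", False)


@dataclass
class SeriesReport:
    """Ordered design-series output plus the parameters that produced it."""

    entries: list[SeriesEntry]
    parameters: dict
    flagged_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def _entry(label: str, index: int, construct: SBHConstruct, engine) -> SeriesEntry:
    fold = predict_mfe(construct.hairpin_sequence, engine)
    return SeriesEntry(
        label=label,
        x_or_offset=index,
        construct=construct,
        fold=fold,
        stem_mfe=fold.mfe,
        oligos=cloning_oligos(construct),
    )


def sbh_series(
    spacer: SpacerRecord,
    loop_unit: CleavingUnit = BASIC_LOOP,
    engine=None,
    mfe_ceiling: float | None = None,
) -> SeriesReport:
    """All SBH(x) hairpins for one spacer, x = 0 .. len(spacer).

    x counts free (unpaired) 3' spacer nucleotides, so x = len(spacer) is
    the degenerate native guide with a 5' loop appendage. Entries whose stem
    MFE exceeds ``mfe_ceiling`` are flagged, not dropped.
    """
    entries = []
    flagged = []
    for x in range(len(spacer) + 1):
        construct = assemble_sbh(spacer, loop_unit=loop_unit, free_count_x=x)
        entry = _entry(f"SBH({x})", x, construct, engine)
        entries.append(entry)
        if mfe_ceiling is not None and entry.stem_mfe > mfe_ceiling:
            flagged.append(entry.label)
    log.info("sbh_series: spacer=%s entries=%d", spacer.name, len(entries))
    return SeriesReport(
        entries=entries,
        parameters={
            "operation": "sbh_series",
            "spacer": spacer.name,
            "loop_unit": loop_unit.name,
            "x_range": [0, len(spacer)],
        },
        flagged_labels=flagged,
    )


def pattern_placements(
    pattern: tuple[BulgeElement, ...], covered_stem_len: int
) -> list[tuple[BulgeElement, ...]]:
    """Every 1-nt translation of a bulge pattern that fits the stem.

    The pattern is anchored by its loop-proximal element; a placement is
    valid when every bulge depth stays within the paired stem (depths in
    ``[0, paired_len]`` where ``paired_len`` deducts spacer-strand bulge
    nucleotides from the covered stem length). Closed form: placements =
    paired_len - depth_span + 1.
    """
    if not pattern:
        raise ValueError("empty bulge pattern")
    pattern = tuple(sorted(pattern))
    base = pattern[0].stem_index
    relative = [b.stem_index - base for b in pattern]
    spacer_nt = sum(b.length for b in pattern if b.strand == "spacer")
    paired_len = covered_stem_len - spacer_nt
    placements = []
    for offset in range(paired_len + 1):
        if offset + relative[-1] > paired_len:
            break
        placements.append(tuple(
            BulgeElement(offset + rel, b.length, b.strand)
            for rel, b in zip(relative, pattern)
        ))
    return placements


def slide_bulges(
    spacer: SpacerRecord,
    loop_unit: CleavingUnit = BASIC_LOOP,
    pattern: tuple[BulgeElement, ...] = (BulgeElement(0, 2),),
    engine=None,
    free_count_x: int = 0,
    mfe_ceiling: float | None = None,
) -> SeriesReport:
    """All bulged SBH constructs from sliding ``pattern`` along the stem.

    One entry per translation offset at which the whole pattern fits; the
    pattern's internal spacing is preserved. A pattern that never fits
    yields an empty report with a warning.
    """
    covered = len(spacer) - free_count_x
    placements = pattern_placements(tuple(pattern), covered)
    entries = []
    flagged = []
    for offset, placed in enumerate(placements):
        construct = assemble_sbh(
            spacer, loop_unit=loop_unit, free_count_x=free_count_x,
            bulge_pattern=placed,
        )
        entry = _entry(f"offset_{offset}", offset, construct, engine)
        entries.append(entry)
        if mfe_ceiling is not None and entry.stem_mfe > mfe_ceiling:
            flagged.append(entry.label)
    if not entries:
        log.warning(
            "slide_bulges: pattern never fits a %d-nt covered stem", covered
        )
    log.info("slide_bulges: spacer=%s placements=%d", spacer.name, len(entries))
    return SeriesReport(
        entries=entries,
        parameters={
            "operation": "slide_bulges",
            "spacer": spacer.name,
            "loop_unit": loop_unit.name,
            "pattern": [
                {"stem_index": b.stem_index, "length": b.length, "strand": b.strand}
                for b in sorted(pattern)
            ],
            "free_count_x": free_count_x,
        },
        flagged_labels=flagged,
    )
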