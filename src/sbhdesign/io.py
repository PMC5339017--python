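"""Spacer ingestion, synthetic fixtures, report serialization, manifests."""

from __future__ import annotations

import dataclasses
import json
import logging
import random
from pathlib import Path

from Bio import SeqIO

from .enumeration import SeriesReport
from .evolution import FitnessRecord
from .grammar import SBHConstruct, SpacerRecord
from .sequences import AlphabetError  # noqa: F401  (re-exported for callers)

log = logging.getLogger(__name__)

REPORT_FORMATS = ("tsv", "json", "fasta", "vienna")

SERIES_COLUMNS = (
    "x_or_offset", "label", "sequence", "structure", "mfe_kcal_mol",
    "top_oligo", "bottom_oligo",
)
FITNESS_COLUMNS_PREFIX = ("rank", "asl", "core")
FITNESS_COLUMNS_SUFFIX = ("product_score", "gc_fraction", "max_homopolymer_run")


def read_spacers(path: str | Path) -> list[SpacerRecord]:
    """Read spacers from FASTA or one-sequence-per-line text.

    Sequences are normalized to RNA (T->U, uppercase); duplicate names and
    out-of-range lengths are rejected.
    """
    path = Path(path)
    text = path.read_text()
    records: list[SpacerRecord] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(SpacerRecord(rec.id, str(rec.seq)))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, seq = line.split("\t", 1)
            else:
                name, seq = f"spacer_{lineno}", line
            records.append(SpacerRecord(name, seq))
    names = [r.name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate spacer names: {sorted(dupes)}")
    log.info("read %d spacers from %s", len(records), path)
    return records


def synth_spacers(
    n: int,
    gc_target: float = 0.5,
    seed: int = 0,
    length: int = 20,
    prefix: str = "synth",
) -> list[SpacerRecord]:
    """Deterministic random spacers with the requested expected GC content.

    The fixture generator for tests and demos: each base is G/C with
    probability ``gc_target`` (split evenly), A/U otherwise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must lie in [0, 1]")
    rng = random.Random(seed)
    out = []
    for i in range(n):
        seq = "".join(
            rng.choice("GC") if rng.random() < gc_target else rng.choice("AU")
            for _ in range(length)
        )
        out.append(SpacerRecord(f"{prefix}_{i + 1}", seq))
    return out


def synthetic_cts_spacers() -> list[SpacerRecord]:
    """Two fixed synthetic reporter-target spacers used in demos and checks.

    Synthetic stand-ins for a pair of CRISPR-target-site spacers: moderately
    GC-rich 20-mers drawn once from the fixture generator and frozen by
    seed. They are not genomic sequences.
    """
    return synth_spacers(2, gc_target=0.55, seed=17, prefix="synthetic_cts")


def construct_to_dict(construct: SBHConstruct) -> dict:
    """JSON-ready dump of a construct record."""
    d = dataclasses.asdict(construct)
    d["loop_unit"] = construct.loop_unit.name
    d["regions"] = {k: list(v) for k, v in construct.regions.items()}
    d["pairs"] = [list(p) for p in construct.pairs]
    d["bulge_pattern"] = [
        {"stem_index": b.stem_index, "length": b.length, "strand": b.strand}
        for b in construct.bulge_pattern
    ]
    return d


def construct_fasta_record(construct: SBHConstruct) -> str:
    """FASTA entry with region annotations in the description line."""
    regions = ";".join(
        f"{name}={a}-{b}" for name, (a, b) in construct.regions.items()
    )
    header = (
        f">{construct.spacer.name}|x={construct.free_count_x}"
        f"|loop={construct.loop_unit.name}|{regions}"
    )
    return f"{header}\n{construct.full_sequence}\n"


def _series_rows(report: SeriesReport) -> list[dict]:
    rows = []
    for e in report.entries:
        rows.append({
            "x_or_offset": e.x_or_offset,
            "label": e.label,
            "sequence": e.fold.sequence,
            "structure": e.fold.structure,
            "mfe_kcal_mol": f"{e.stem_mfe:.2f}",
            "top_oligo": e.oligos.top,
            "bottom_oligo": e.oligos.bottom,
        })
    return rows


def fitness_rows(records: list[FitnessRecord]) -> tuple[tuple[str, ...], list[dict]]:
    """Stable tabular view of ranked loop candidates."""
    p = len(records[0].per_spacer_scores) if records else 0
    fs_cols = tuple(f"fs_{i + 1}" for i in range(p))
    columns = FITNESS_COLUMNS_PREFIX + fs_cols + FITNESS_COLUMNS_SUFFIX
    rows = []
    for rank, r in enumerate(records, start=1):
        row = {
            "rank": rank,
            "asl": r.asl.sequence,
            "core": r.asl.core,
            "product_score": f"{r.product_score:.6f}",
            "gc_fraction": f"{r.gc_fraction:.4f}",
            "max_homopolymer_run": r.max_homopolymer_run,
        }
        for i, s in enumerate(r.per_spacer_scores):
            row[f"fs_{i + 1}"] = f"{s:.6f}"
        rows.append(row)
    return columns, rows


def _write_tsv(columns, rows, path: Path) -> None:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in columns))
    path.write_text("\n".join(lines) + "\n")


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Serialize a SeriesReport or ranked FitnessRecord list.

    Formats: ``tsv`` (stable documented columns), ``json`` (lossless round
    trip), ``fasta`` (sequences), ``vienna`` (sequence, dot-bracket and
    ``(mfe)`` line per entry; series reports only).
    """
    path = Path(path)
    if format not in REPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {REPORT_FORMATS}")

    if isinstance(report, SeriesReport):
        rows = _series_rows(report)
        if format == "tsv":
            _write_tsv(SERIES_COLUMNS, rows, path)
        elif format == "json":
            path.write_text(json.dumps(
                {"parameters": report.parameters, "entries": rows}, indent=2,
            ) + "\n")
        elif format == "fasta":
            path.write_text("".join(
                f">{r['label']}\n{r['sequence']}\n" for r in rows
            ))
        else:  # vienna
            path.write_text("".join(
                f">{r['label']}\n{r['sequence']}\n{r['structure']} "
                f"({r['mfe_kcal_mol']})\n" for r in rows
            ))
        return

    records: list[FitnessRecord] = list(report)
    columns, rows = fitness_rows(records)
    if format == "tsv":
        _write_tsv(columns, rows, path)
    elif format == "json":
        path.write_text(json.dumps({"entries": rows}, indent=2) + "\n")
    elif format == "fasta":
        path.write_text("".join(
            f">asl_rank_{r['rank']}\n{r['asl']}\n" for r in rows
        ))
    else:
        raise ValueError("vienna format applies to series reports only")


def load_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_run_manifest(path: str | Path, *, inputs: dict, config: dict,
                       seed: int, engine_name: str, engine_version: str) -> None:
    """Reproducibility manifest: inputs + config + seed + engine version."""
    Path(path).write_text(json.dumps({
        "inputs": inputs,
        "config": config,
        "seed": seed,
        "engine": {"name": engine_name, "version": engine_version},
    }, indent=2, sort_keys=True) + "\n")
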