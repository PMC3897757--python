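"""BED12 custom-track serialization of LD architectures.

Conventions, stated once and tested everywhere: panel positions are
1-based; BED is 0-based half-open, so a SNP at position ``pos`` maps to
``[pos - 1, pos)``.  Every record is emitted as 12 columns (browsers accept
BED12 uniformly); a cluster becomes a single record spanning its members,
with one 1-bp block per member SNP — the intron-style connecting line
between blocks is the horizontal line joining SNPs in perfect LD.  Strand
is fixed to ``+`` (SNP panels are strandless) and score to 0.  Output is
UTF-8, Unix newlines, tab-delimited, with deterministic record order.
"""
from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .architectures import Architecture, Track, maf_color
from .clusters import Cluster
from .errors import ContractError, DuplicatePositionWarning
from .model import Marker

__all__ = [
    "BedRecord",
    "cluster_to_bed",
    "snp_to_bed",
    "snp_names_track",
    "write_architecture",
    "export_cluster_ids",
    "validate_bed12",
    "parse_bed12",
]

DEFAULT_COLOR = (0, 0, 0)


@dataclass(frozen=True)
class BedRecord:
    """One 12-column BED record (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    name: str
    score: int = 0
    strand: str = "+"
    item_rgb: tuple[int, int, int] = DEFAULT_COLOR
    block_sizes: tuple[int, ...] = field(default=(1,))
    block_starts: tuple[int, ...] = field(default=(0,))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ContractError(
                f"record {self.name!r}: need 0 <= chromStart < chromEnd, "
                f"got [{self.start}, {self.end})"
            )
        if len(self.block_sizes) != len(self.block_starts) or not self.block_sizes:
            raise ContractError(f"record {self.name!r}: block lists mismatched or empty")
        if self.block_starts[0] != 0:
            raise ContractError(f"record {self.name!r}: first blockStart must be 0")
        if any(s < 1 for s in self.block_sizes):
            raise ContractError(f"record {self.name!r}: every blockSize must be >= 1")
        if any(b >= a for a, b in zip(self.block_starts[1:], self.block_starts)):
            raise ContractError(f"record {self.name!r}: blockStarts must strictly increase")
        if self.block_starts[-1] + self.block_sizes[-1] != self.end - self.start:
            raise ContractError(
                f"record {self.name!r}: last block must end at chromEnd"
            )

    @property
    def block_count(self) -> int:
        return len(self.block_sizes)

    def to_line(self) -> str:
        rgb = ",".join(str(c) for c in self.item_rgb)
        sizes = ",".join(str(s) for s in self.block_sizes)
        starts = ",".join(str(s) for s in self.block_starts)
        return "\t".join(
            [
                self.chrom, str(self.start), str(self.end), self.name,
                str(self.score), self.strand, str(self.start), str(self.end),
                rgb, str(self.block_count), sizes, starts,
            ]
        )


def cluster_to_bed(
    cluster: Cluster, color: tuple[int, int, int] = DEFAULT_COLOR
) -> BedRecord:
    """One BED12 record for a cluster: 1-bp blocks joined by a line.

    Members sharing a base-pair position collapse to one block with a
    warning.
    """
    positions = sorted({mk.pos for mk in cluster.members})
    if len(positions) < len(cluster.members):
        warnings.warn(
            f"cluster {cluster.name!r}: duplicate member positions collapsed "
            "into one block",
            DuplicatePositionWarning,
            stacklevel=2,
        )
    first = positions[0]
    return BedRecord(
        chrom=cluster.chrom,
        start=first - 1,
        end=positions[-1],
        name=cluster.name,
        item_rgb=color,
        block_sizes=tuple(1 for _ in positions),
        block_starts=tuple(p - first for p in positions),
    )


def snp_to_bed(marker: Marker, color: tuple[int, int, int] = DEFAULT_COLOR) -> BedRecord:
    """A single-SNP record: one 1-bp block at [pos - 1, pos)."""
    return BedRecord(
        chrom=marker.chrom, start=marker.pos - 1, end=marker.pos,
        name=marker.id, item_rgb=color,
    )


def snp_names_track(markers: Sequence[Marker]) -> list[BedRecord]:
    """One 1-bp record per marker, named by its id."""
    return [snp_to_bed(mk) for mk in markers]


def _fmt_r2(value: float) -> str:
    """Three decimal places, round half up (never bankers)."""
    return str(Decimal(repr(value)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _sanitize(name: str) -> str:
    return re.sub(r"[^\w.\-]", "_", name)


def _item_color(arch: Architecture, item: Cluster | Marker) -> tuple[int, int, int]:
    if not arch.params.color_by_maf:
        return DEFAULT_COLOR
    if isinstance(item, Cluster):
        vals = [arch.mafs[mid] for mid in item.member_ids if mid in arch.mafs]
        m = sum(vals) / len(vals) if vals else 0.0
    else:
        m = arch.mafs.get(item.id, 0.0)
    return maf_color(m)


def _track_records(arch: Architecture, track: Track) -> list[BedRecord]:
    records = []
    for item in track.items:
        color = _item_color(arch, item)
        if isinstance(item, Cluster):
            records.append(cluster_to_bed(item, color=color))
        else:
            records.append(snp_to_bed(item, color=color))
    records.sort(key=lambda r: (r.start, r.end, r.name))
    return records


def track_header(arch: Architecture, track: Track) -> str:
    name = track.name
    if track.r2 is not None:
        name = f"{name}_r2_{_fmt_r2(track.r2)}"
    header = (
        f'track name="{_sanitize(name)}" '
        f'description="{arch.kind}-centered architecture {arch.center}" '
        "visibility=2"
    )
    if arch.params.color_by_maf:
        header += ' itemRgb="On"'
    return header


def write_architecture(arch: Architecture, out_path: str | os.PathLike) -> str:
    """Serialize an architecture to one BED file, one ``track`` line per track.

    Records within a track are ordered by chromStart; tracks keep the
    architecture's order.  Two runs with identical inputs produce
    byte-identical files.
    """
    lines: list[str] = []
    for track in arch.tracks:
        lines.append(track_header(arch, track))
        lines.extend(rec.to_line() for rec in _track_records(arch, track))
    with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(out_path)


def export_cluster_ids(arch: Architecture, out_dir: str | os.PathLike) -> list[str]:
    """Write one ``<cluster_name>.txt`` per cluster with member ids, one per line."""
    os.makedirs(out_dir, exist_ok=True)
    paths: list[str] = []
    for cluster in arch.clusters:
        path = os.path.join(str(out_dir), f"{_sanitize(cluster.name)}.txt")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(cluster.member_ids) + "\n")
        paths.append(path)
    return paths


def parse_bed12(path: str | os.PathLike) -> dict[str, list[BedRecord]]:
    """Parse an emitted BED file back into records grouped by track name.

    Strict: every data line must have exactly 12 well-formed columns and
    satisfy the BED12 block invariants (re-checked by BedRecord).
    """
    tracks: dict[str, list[BedRecord]] = {}
    current = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("track"):
                m = re.search(r'name="([^"]*)"', line)
                if not m:
                    raise ContractError(f"{path}:{lineno}: track line without name")
                current = m.group(1)
                tracks[current] = []
                continue
            if current is None:
                raise ContractError(f"{path}:{lineno}: record before any track line")
            fields = line.split("\t")
            if len(fields) != 12:
                raise ContractError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = int(fields[4])
                thick_start, thick_end = int(fields[6]), int(fields[7])
                rgb = tuple(int(c) for c in fields[8].split(","))
                block_count = int(fields[9])
                sizes = tuple(int(s) for s in fields[10].rstrip(",").split(","))
                starts = tuple(int(s) for s in fields[11].rstrip(",").split(","))
            except ValueError:
                raise ContractError(f"{path}:{lineno}: malformed numeric field") from None
            if fields[5] not in ("+", "-", "."):
                raise ContractError(f"{path}:{lineno}: bad strand {fields[5]!r}")
            if (thick_start, thick_end) != (start, end):
                raise ContractError(f"{path}:{lineno}: thickStart/thickEnd mismatch")
            if block_count != len(sizes):
                raise ContractError(f"{path}:{lineno}: blockCount != len(blockSizes)")
            if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
                raise ContractError(f"{path}:{lineno}: bad itemRgb {fields[8]!r}")
            tracks[current].append(
                BedRecord(
                    chrom=fields[0], start=start, end=end, name=fields[3],
                    score=score, strand=fields[5], item_rgb=rgb,  # type: ignore[arg-type]
                    block_sizes=sizes, block_starts=starts,
                )
            )
    return tracks


def validate_bed12(path: str | os.PathLike) -> int:
    """Strict BED12 validation of an emitted file; returns the record count."""
    tracks = parse_bed12(path)
    return sum(len(records) for records in tracks.values())
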