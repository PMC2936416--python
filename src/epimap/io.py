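"""Domain types and readers/writers for screen data.

Coordinate conventions
----------------------
Nucleotide and residue coordinates are 1-based inclusive everywhere inside
the package ("amino acids 13-174" denotes 162 residues).  The single
exception is BED export, which follows the standard 0-based half-open
convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

CLONE_TABLE_COLUMNS = (
    "clone_id",
    "prey_name",
    "accession",
    "nt_start",
    "nt_stop",
    "frame",
    "sense",
    "pbs",
)


class Frame(str, Enum):
    """Reading-frame status of a prey insert relative to its source ORF."""

    IF = "IF"
    OOF = "OOF"


class Sense(str, Enum):
    """Orientation of the insert in the prey (activation-domain) vector."""

    SENSE = "sense"
    ANTISENSE = "antisense"


class PBSCategory(str, Enum):
    """Confidence category: A (best) .. D, E (promiscuous prey), F (known artifact)."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    NA = "NA"


@dataclass(frozen=True)
class ReferenceORF:
    """A named coding sequence; the coordinate system clones are mapped onto.

    ``cds_start``/``cds_stop`` are 1-based inclusive nucleotide positions of
    the first and last coding base on ``mrna_seq``.  ``protein_length``
    excludes the stop codon.
    """

    id: str
    accession: str
    mrna_seq: str
    cds_start: int
    cds_stop: int

    def __post_init__(self) -> None:
        if self.cds_start < 1:
            raise ValidationError(f"{self.id}: cds_start must be >= 1")
        if self.cds_stop > len(self.mrna_seq):
            raise ValidationError(
                f"{self.id}: cds_stop {self.cds_stop} beyond sequence "
                f"length {len(self.mrna_seq)}"
            )
        if self.cds_stop < self.cds_start:
            raise ValidationError(f"{self.id}: cds_stop < cds_start")
        if (self.cds_stop - self.cds_start + 1) % 3 != 0:
            raise ValidationError(
                f"{self.id}: CDS length {self.cds_stop - self.cds_start + 1} "
                "not divisible by 3"
            )

    @property
    def protein_length(self) -> int:
        return (self.cds_stop - self.cds_start + 1) // 3


@dataclass(frozen=True)
class CloneRecord:
    """One retained prey clone from a screen (one row of a clone table)."""

    clone_id: str
    prey_name: str
    accession: str
    nt_start: int
    nt_stop: int
    frame: Frame
    sense: Sense
    pbs: PBSCategory = PBSCategory.NA

    def __post_init__(self) -> None:
        if self.nt_start > self.nt_stop:
            raise ValidationError(
                f"clone {self.clone_id}: nt_start {self.nt_start} > "
                f"nt_stop {self.nt_stop}"
            )
        if self.nt_start < 1:
            raise ValidationError(f"clone {self.clone_id}: nt_start must be >= 1")


@dataclass(frozen=True)
class FragmentInterval:
    """A 1-based inclusive residue interval on a reference protein."""

    orf_id: str
    aa_start: int
    aa_stop: int
    clone_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_stop:
            raise ValidationError(
                f"invalid interval [{self.aa_start},{self.aa_stop}] on {self.orf_id}"
            )

    def __len__(self) -> int:
        return self.aa_stop - self.aa_start + 1

    def contains(self, other: "FragmentInterval") -> bool:
        return self.aa_start <= other.aa_start and other.aa_stop <= self.aa_stop

    def overlaps(self, other: "FragmentInterval") -> bool:
        return self.aa_start <= other.aa_stop and other.aa_start <= self.aa_stop


@dataclass
class ScreenTable:
    """All retained clones of one screen (one bait against one library)."""

    screen_id: str
    bait_name: str
    records: list[CloneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.clone_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"screen {self.screen_id}: duplicate clone ids {dupes}"
            )

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_cds_table(path: Union[str, Path]) -> dict[str, tuple[int, int | None]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "id" not in df.columns or "cds_start" not in df.columns:
        raise FormatError(f"{path}: CDS table needs columns 'id' and 'cds_start'")
    out: dict[str, tuple[int, int | None]] = {}
    for _, row in df.iterrows():
        stop = None
        if "cds_stop" in df.columns and pd.notna(row.get("cds_stop")):
            stop = int(row["cds_stop"])
        out[str(row["id"])] = (int(row["cds_start"]), stop)
    return out


def read_reference_fasta(
    path: Union[str, Path],
    cds_table: Union[str, Path, None] = None,
) -> list[ReferenceORF]:
    """Read reference ORFs from FASTA, optionally with a CDS-offset table.

    Without a table each record is taken as fully coding (``cds_start=1``,
    ``cds_stop=len``); a length not divisible by 3 is then an error.  The
    table (TSV: id, cds_start[, cds_stop]) may give only ``cds_start``, in
    which case ``cds_stop`` is clamped down to the last complete codon.
    """
    offsets = _read_cds_table(cds_table) if cds_table is not None else {}
    orfs: list[ReferenceORF] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record '{rec.id}' has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id '{rec.id}'")
        seen.add(rec.id)
        if rec.id in offsets:
            cds_start, cds_stop = offsets[rec.id]
            if cds_stop is None:
                n_codons = (len(seq) - cds_start + 1) // 3
                if n_codons < 1:
                    raise ValidationError(
                        f"{rec.id}: no complete codon downstream of "
                        f"cds_start {cds_start}"
                    )
                cds_stop = cds_start + 3 * n_codons - 1
        else:
            cds_start, cds_stop = 1, len(seq)
        orfs.append(
            ReferenceORF(
                id=rec.id,
                accession=rec.description.split()[1]
                if len(rec.description.split()) > 1
                else rec.id,
                mrna_seq=seq,
                cds_start=cds_start,
                cds_stop=cds_stop,
            )
        )
    if not orfs:
        raise FormatError(f"{path}: no FASTA records found")
    return orfs


def read_clone_table(
    path: Union[str, Path],
    screen_id: str | None = None,
    bait_name: str = "",
) -> ScreenTable:
    """Parse a tab-separated clone table into a :class:`ScreenTable`.

    Expected header: clone_id, prey_name, accession, nt_start, nt_stop,
    frame, sense, pbs.  Lines starting with '#' are comments.  Unknown pbs
    values are mapped to NA with a warning; out-of-frame rows are retained.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in CLONE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records: list[CloneRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        try:
            nt_start, nt_stop = int(row["nt_start"]), int(row["nt_stop"])
        except ValueError as exc:
            raise FormatError(f"{path} row {rownum}: non-integer coordinate") from exc
        try:
            frame = Frame(row["frame"])
            sense = Sense(row["sense"])
        except ValueError as exc:
            raise FormatError(
                f"{path} row {rownum}: bad frame/sense value ({exc})"
            ) from exc
        pbs_raw = str(row["pbs"]).strip()
        try:
            pbs = PBSCategory(pbs_raw) if pbs_raw else PBSCategory.NA
        except ValueError:
            logger.warning(
                "%s row %d: unknown pbs value %r mapped to NA", path, rownum, pbs_raw
            )
            pbs = PBSCategory.NA
        try:
            records.append(
                CloneRecord(
                    clone_id=row["clone_id"],
                    prey_name=row["prey_name"],
                    accession=row["accession"],
                    nt_start=nt_start,
                    nt_stop=nt_stop,
                    frame=frame,
                    sense=sense,
                    pbs=pbs,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from exc
    return ScreenTable(
        screen_id=screen_id or path.stem, bait_name=bait_name, records=records
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_clone_table(table: ScreenTable, path: Union[str, Path]) -> None:
    """Write a ScreenTable in the clone-table TSV dialect (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# screen: {table.screen_id}\tbait: {table.bait_name}\n")
        fh.write("\t".join(CLONE_TABLE_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                "\t".join(
                    [
                        r.clone_id,
                        r.prey_name,
                        r.accession,
                        str(r.nt_start),
                        str(r.nt_stop),
                        r.frame.value,
                        r.sense.value,
                        r.pbs.value,
                    ]
                )
                + "\n"
            )


def _interval_fields(iv) -> tuple[str, int, int, str]:
    """Normalise FragmentInterval / SIDResult-like objects to a 4-tuple."""
    name = getattr(iv, "clone_id", "") or ""
    if hasattr(iv, "support"):  # SIDResult duck type
        flag = "complete" if iv.complete else "partial"
        name = f"SID|support={iv.support}|{flag}"
    return iv.orf_id, iv.aa_start, iv.aa_stop, name or "fragment"


def write_intervals(
    intervals: Sequence,
    fmt: str,
    path: Union[str, Path],
) -> None:
    """Write residue intervals (fragments or SIDs) as bed, tsv, or json.

    TSV and JSON keep the internal 1-based inclusive convention; BED is
    converted to 0-based half-open.  An empty collection yields a valid
    empty file (header only).
    """
    if fmt not in ("bed", "tsv", "json"):
        raise UsageError(f"unknown interval format {fmt!r} (use bed, tsv or json)")
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "bed":
            fh.write("# coordinates: 0-based half-open (BED)\n")
            for iv in intervals:
                orf_id, start, stop, name = _interval_fields(iv)
                fh.write(f"{orf_id}\t{start - 1}\t{stop}\t{name}\n")
        elif fmt == "tsv":
            fh.write("# coordinates: 1-based inclusive\n")
            fh.write("orf_id\taa_start\taa_stop\tlength\tname\n")
            for iv in intervals:
                orf_id, start, stop, name = _interval_fields(iv)
                fh.write(f"{orf_id}\t{start}\t{stop}\t{stop - start + 1}\t{name}\n")
        else:
            payload = {
                "coordinates": "1-based inclusive",
                "intervals": [
                    dict(
                        zip(
                            ("orf_id", "aa_start", "aa_stop", "name"),
                            _interval_fields(iv),
                        )
                    )
                    for iv in intervals
                ],
            }
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_reference_fasta(orfs: Iterable[ReferenceORF], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for orf in orfs:
            fh.write(f">{orf.id} {orf.accession}\n")
            for i in range(0, len(orf.mrna_seq), 60):
                fh.write(orf.mrna_seq[i : i + 60] + "\n")
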