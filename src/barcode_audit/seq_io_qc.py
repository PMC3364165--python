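"""Sequence and specimen-table I/O, frame anchoring, and quality screening.

COI barcodes are treated as anchored to the fixed 658-site Folmer coordinate
frame: full-length reads cover sites 1-658 and short 5'-amplicons cover a
prefix (typically 325 sites).  No alignment is performed; the barcode region
is assumed indel-free, and any surviving gap character is a QC failure.

Quality screening translates each sequence under the invertebrate
mitochondrial genetic code (NCBI table 5) in the reading frame that
minimises in-frame stop codons; any remaining stop, an internal gap, or a
sequence shorter than the configured minimum fails QC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._encoding import ALLOWED_CHARS, frame_array

__all__ = [
    "SpecimenRecord",
    "AnchoredSequence",
    "QCReport",
    "PROVISIONAL_NAME_RE",
    "is_provisional_label",
    "read_barcode_fasta",
    "write_barcode_fasta",
    "read_specimen_table",
    "write_specimen_table",
    "anchor_to_barcode_frame",
    "choose_reading_frame",
    "qc_sequence",
    "apply_qc",
]

DEFAULT_MIN_LENGTH = 300

ID_CONFIDENCE_VALUES = ("expert", "propagated", "unidentified")
LIFE_STAGE_VALUES = ("larva", "subimago", "imago", "unknown")

#: Genus followed by "sp." (optional space) plus taxonomist initials and a serial,
#: e.g. "Heptagenia sp.LJ1" or the older spaced form "Acerpenna sp. CHU1".
PROVISIONAL_NAME_RE = re.compile(r"^[A-Z][A-Za-z]* sp\. ?[A-Za-z]+[0-9]+$")

INVERTEBRATE_MITO_TABLE = 5


def is_provisional_label(species_label: str) -> bool:
    return bool(PROVISIONAL_NAME_RE.match(species_label))


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher specimen: taxonomy, confidence and locality."""

    specimen_id: str
    family: str
    genus: str
    species_label: str
    is_provisional: bool = False
    id_confidence: str = "expert"
    life_stage: str = "unknown"
    country: str = ""
    state_province: str = ""
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.id_confidence not in ID_CONFIDENCE_VALUES:
            raise ValueError(f"bad id_confidence {self.id_confidence!r}")
        if self.life_stage not in LIFE_STAGE_VALUES:
            raise ValueError(f"bad life_stage {self.life_stage!r}")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class AnchoredSequence:
    """Nucleotides placed on the 658-site barcode frame, with QC state."""

    specimen_id: str
    bases: str
    start: int = 1
    qc_status: str = "pass"
    frame_offset: int = 0

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """1-based inclusive last covered frame position."""
        return self.start + self.length - 1

    def frame_codes(self) -> np.ndarray:
        """uint8 codes on the full 658-site frame (MISSING off-coverage)."""
        return frame_array(self.bases, self.start)


@dataclass
class QCReport:
    specimen_id: str
    frame_offset: int
    stop_codon_positions: list[int] = field(default_factory=list)
    has_indel: bool = False
    decision: str = "pass"


# ---------------------------------------------------------------------------
# FASTA / table I/O


def read_barcode_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a barcode FASTA into ``(specimen_id, bases)`` pairs.

    The header token before the first whitespace is the specimen id.
    Sequences are upper-cased and U is mapped to T.  Duplicate ids or an
    empty file raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        out.append((rec.id, seq))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate specimen ids in {path}: {', '.join(dups)}")
    return out


def write_barcode_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(bases), id=specimen_id, description="")
        for specimen_id, bases in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_REQUIRED_COLUMNS = ("specimen_id", "family", "genus", "species")
_OPTIONAL_COLUMNS = (
    "id_confidence",
    "life_stage",
    "country",
    "state_province",
    "latitude",
    "longitude",
)
TABLE_COLUMNS = _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read a tab-separated specimen metadata table (BOLD-export style).

    Required columns: specimen_id, family, genus, species.  Optional
    columns default to "unknown"/empty/missing.  Provisional labels are
    detected from the species column.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"specimen table missing required column(s): {', '.join(missing_cols)}")

    def _coord(val: str) -> float | None:
        return float(val) if val.strip() else None

    records = []
    for row in df.itertuples(index=False):
        get = lambda col, default="": getattr(row, col, default) if col in df.columns else default
        species = get("species")
        records.append(
            SpecimenRecord(
                specimen_id=get("specimen_id"),
                family=get("family"),
                genus=get("genus"),
                species_label=species,
                is_provisional=is_provisional_label(species),
                id_confidence=get("id_confidence") or "expert",
                life_stage=get("life_stage") or "unknown",
                country=get("country"),
                state_province=get("state_province"),
                latitude=_coord(get("latitude")),
                longitude=_coord(get("longitude")),
            )
        )
    ids = [r.specimen_id for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValueError(f"duplicate specimen ids in table: {', '.join(dups)}")
    return records


def write_specimen_table(path: str | Path, records: Sequence[SpecimenRecord]) -> None:
    """Write records as UTF-8 TSV in the fixed canonical column order."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "family": r.family,
                "genus": r.genus,
                "species": r.species_label,
                "id_confidence": r.id_confidence,
                "life_stage": r.life_stage,
                "country": r.country,
                "state_province": r.state_province,
                "latitude": "" if r.latitude is None else repr(r.latitude),
                "longitude": "" if r.longitude is None else repr(r.longitude),
            }
        )
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Anchoring and QC


def anchor_to_barcode_frame(
    specimen_id: str,
    bases: str,
    min_len: int = DEFAULT_MIN_LENGTH,
    start: int = 1,
) -> AnchoredSequence:
    """Anchor a sequence to the 658-site barcode frame.

    Short amplicons are 5'-anchored at site 1 unless an explicit ``start``
    is given.  The reading frame offset is chosen to minimise in-frame stop
    codons under the invertebrate mitochondrial code.  Sequences shorter
    than ``min_len`` are marked ``too_short``.
    """
    bad = set(bases) - ALLOWED_CHARS
    if bad:
        raise ValueError(
            f"{specimen_id}: non-nucleotide characters {sorted(bad)!r} in sequence"
        )
    seq = AnchoredSequence(specimen_id=specimen_id, bases=bases, start=start)
    seq.frame_codes()  # validates the span against the frame
    seq.frame_offset = choose_reading_frame(bases)[0]
    if len(bases) < min_len:
        seq.qc_status = "too_short"
    return seq


def _stop_positions(bases: str, offset: int) -> list[int]:
    """1-based codon-start positions of in-frame stops (table 5)."""
    coding = bases[offset:].replace("-", "N")
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        return []
    protein = str(Seq(coding).translate(table=INVERTEBRATE_MITO_TABLE))
    return [offset + 3 * i + 1 for i, aa in enumerate(protein) if aa == "*"]


def choose_reading_frame(bases: str) -> tuple[int, list[int]]:
    """Pick the offset in {0,1,2} minimising in-frame stops; ties -> smallest.

    Returns ``(offset, stop_codon_positions)`` for the chosen offset.
    """
    best: tuple[int, list[int]] | None = None
    for offset in (0, 1, 2):
        stops = _stop_positions(bases, offset)
        if best is None or len(stops) < len(best[1]):
            best = (offset, stops)
    assert best is not None
    return best


def qc_sequence(seq: AnchoredSequence, min_len: int = DEFAULT_MIN_LENGTH) -> QCReport:
    """Screen one anchored sequence for stop codons and indels.

    Decision precedence: too_short, then indel (a gap invalidates the
    reading frame), then stop_codon, then pass.
    """
    offset, stops = choose_reading_frame(seq.bases)
    has_indel = "-" in seq.bases
    if seq.length < min_len:
        decision = "too_short"
    elif has_indel:
        decision = "indel"
    elif stops:
        decision = "stop_codon"
    else:
        decision = "pass"
    return QCReport(
        specimen_id=seq.specimen_id,
        frame_offset=offset,
        stop_codon_positions=stops,
        has_indel=has_indel,
        decision=decision,
    )


def apply_qc(
    seqs: Iterable[AnchoredSequence], min_len: int = DEFAULT_MIN_LENGTH
) -> tuple[list[AnchoredSequence], list[QCReport]]:
    """QC every sequence; returns sequences with qc_status set, plus reports."""
    out_seqs, reports = [], []
    for seq in seqs:
        report = qc_sequence(seq, min_len=min_len)
        out_seqs.append(replace_status(seq, report))
        reports.append(report)
    return out_seqs, reports


def replace_status(seq: AnchoredSequence, report: QCReport) -> AnchoredSequence:
    new = AnchoredSequence(
        specimen_id=seq.specimen_id,
        bases=seq.bases,
        start=seq.start,
        qc_status=report.decision,
        frame_offset=report.frame_offset,
    )
    return new
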