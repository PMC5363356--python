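"""miRBase-style annotation handling.

Parses hairpin (precursor) and mature FASTA records, and anchors each mature
sequence on its hairpin so that 5'-offset arithmetic downstream has a
well-defined origin.  Internal coordinates are 0-based, half-open; GFF3 input
(1-based, inclusive, per the standard) is converted at the boundary.

Sequences are normalized to the RNA alphabet (T -> U, upper case) on input:
vendors print DNA, miRBase prints RNA, and the two must compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import gffutils
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(sequence: str, record_id: str = "<sequence>") -> str:
    """Upper-case, map T to U, and reject anything outside {A,C,G,U}."""
    seq = str(sequence).upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-ACGTU symbol(s): {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA stem-loop sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"hairpin {self.id!r} has an empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"hairpin {self.id!r} contains invalid symbol(s): {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """Placement of one mature miRNA on its hairpin.

    ``start``/``end`` are 0-based half-open on the hairpin; ``arm`` is ``5p``
    when the mature begins in the 5' half of the precursor, else ``3p``.
    """

    mirna_id: str
    hairpin_id: str
    start: int
    end: int
    arm: str
    reference_sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.mirna_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mirna_id}: arm must be 5p or 3p, got {self.arm!r}")


def load_fasta(path: str | Path, molecule: str = "hairpin"):
    """Load a FASTA file of hairpins or matures.

    Returns ``{id: Hairpin}`` for ``molecule="hairpin"`` and a plain
    ``{id: sequence}`` mapping for ``molecule="mature"``.  Duplicate ids,
    empty files and non-ACGTU symbols are errors.
    """
    if molecule not in ("hairpin", "mature"):
        raise ValueError(f"molecule must be 'hairpin' or 'mature', got {molecule!r}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = normalize_rna(str(rec.seq), rec.id)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if molecule == "hairpin":
        return {rid: Hairpin(rid, seq) for rid, seq in records.items()}
    return records


def _assign_arm(start: int, hairpin_length: int) -> str:
    return "5p" if start < hairpin_length / 2 else "3p"


def locate_mature(hairpin: Hairpin, mature_seq: str, mirna_id: str) -> MatureAnnotation:
    """Anchor a mature sequence on its hairpin by exact substring search.

    A mature occurring more than once leaves the 5'-offset origin undefined,
    so ambiguity is an error rather than a silent first match; explicit GFF3
    coordinates resolve such cases.
    """
    mature = normalize_rna(mature_seq, mirna_id)
    occurrences = []
    pos = hairpin.sequence.find(mature)
    while pos != -1:
        occurrences.append(pos)
        pos = hairpin.sequence.find(mature, pos + 1)
    if not occurrences:
        raise ValueError(
            f"{mirna_id}: mature sequence not found in hairpin {hairpin.id!r}"
        )
    if len(occurrences) > 1:
        raise ValueError(
            f"{mirna_id}: mature sequence occurs {len(occurrences)} times in "
            f"hairpin {hairpin.id!r}; provide explicit coordinates (GFF3 input)"
        )
    start = occurrences[0]
    end = start + len(mature)
    return MatureAnnotation(
        mirna_id=mirna_id,
        hairpin_id=hairpin.id,
        start=start,
        end=end,
        arm=_assign_arm(start, len(hairpin)),
        reference_sequence=mature,
    )


def load_gff3_coordinates(
    path: str | Path, hairpins: Mapping[str, Hairpin]
) -> list[MatureAnnotation]:
    """Read mature coordinates from a miRBase-dialect GFF3 file.

    Expects ``miRNA`` features whose seqid column names a loaded hairpin;
    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open, and the reference sequence is sliced from the hairpin.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    annotations: list[MatureAnnotation] = []
    for feat in db.features_of_type("miRNA"):
        hp_id = feat.seqid
        if hp_id not in hairpins:
            raise ValueError(f"GFF3 entry references unknown precursor {hp_id!r}")
        hairpin = hairpins[hp_id]
        start0 = feat.start - 1
        end0 = feat.end
        if not (0 <= start0 < end0 <= len(hairpin)):
            raise ValueError(
                f"GFF3 coordinates [{feat.start}, {feat.end}] fall outside "
                f"hairpin {hp_id!r} of length {len(hairpin)}"
            )
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        annotations.append(
            MatureAnnotation(
                mirna_id=name,
                hairpin_id=hp_id,
                start=start0,
                end=end0,
                arm=_assign_arm(start0, len(hairpin)),
                reference_sequence=hairpin.sequence[start0:end0],
            )
        )
    return annotations


def write_annotation_table(annotations, path: str | Path) -> None:
    """Write annotations as the TSV consumed by the quantification step."""
    with open(path, "w") as fh:
        fh.write("mirna_id\thairpin_id\tstart\tend\tarm\treference_sequence\n")
        for ann in annotations:
            fh.write(
                f"{ann.mirna_id}\t{ann.hairpin_id}\t{ann.start}\t{ann.end}\t"
                f"{ann.arm}\t{ann.reference_sequence}\n"
            )
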