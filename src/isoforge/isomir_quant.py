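"""5'-offset quantification of miRNA reads and canonical reassignment calls.

Adapter-trimmed, collapsed reads are mapped to hairpins by exact substring
match and classified by the offset of their 5' start relative to the
annotated mature start.  Offsets are restricted to the window {-2..+2}:
negative offsets are 5'-extended variants, positive offsets 5'-trimmed ones.
A miRNA whose dominant form sits at a non-zero offset, is expressed above a
CPM detection threshold and carries at least half the windowed reads is
flagged for reannotation, with the dominant variant proposed as the new
canonical sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import Hairpin, MatureAnnotation, normalize_rna

OFFSET_WINDOW = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class ReadRecord:
    """A collapsed small-RNA read with its multiplicity."""

    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class AlignmentHit:
    read: ReadRecord
    hairpin_id: str
    start: int


@dataclass
class MappingResult:
    hits: list[AlignmentHit]
    unmapped_reads: int
    unmapped_count: int
    mapped_count: int

    @property
    def library_size(self) -> int:
        """Total mapped read count — the CPM denominator."""
        return self.mapped_count


@dataclass
class OffsetProfile:
    mirna_id: str
    counts_by_offset: dict[int, int]
    windowed_total: int
    percent_by_offset: dict[int, float]
    cpm: float
    canonical_fraction: float

    def __post_init__(self) -> None:
        bad = set(self.counts_by_offset) - set(OFFSET_WINDOW)
        if bad:
            raise ValueError(f"offsets outside window {OFFSET_WINDOW}: {sorted(bad)}")
        if self.windowed_total > 0:
            total_pct = sum(self.percent_by_offset.values())
            if abs(total_pct - 100.0) > 1e-9:
                raise ValueError(f"percentages sum to {total_pct}, expected 100")
        if not (0.0 <= self.canonical_fraction <= 1.0):
            raise ValueError("canonical_fraction outside [0, 1]")


@dataclass(frozen=True)
class ReassignmentCall:
    mirna_id: str
    dominant_offset: int
    dominant_fraction: float
    cpm: float
    flagged: bool
    proposed_sequence: str = ""


def write_collapsed_fasta(reads: Iterable[ReadRecord], path) -> None:
    """Write collapsed reads as ``>seq{N}_x{count}`` FASTA records."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f">seq{i}_x{read.count}\n{read.sequence}\n")


def read_reads(path, fmt: str | None = None) -> list[ReadRecord]:
    """Load reads from collapsed FASTA (``>seq{N}_x{count}``) or FASTQ.

    FASTQ records count 1 each and are collapsed by sequence; FASTA headers
    without an ``_x{count}`` suffix default to count 1.
    """
    from collections import Counter

    from Bio import SeqIO

    from .annotation_io import normalize_rna

    path = str(path)
    if fmt is None:
        fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    collapsed: Counter[str] = Counter()
    for rec in SeqIO.parse(path, fmt):
        count = 1
        if fmt == "fasta" and "_x" in rec.id:
            try:
                count = int(rec.id.rsplit("_x", 1)[1])
            except ValueError:
                count = 1
        collapsed[normalize_rna(str(rec.seq), rec.id)] += count
    return [ReadRecord(seq, c) for seq, c in sorted(collapsed.items())]


def map_reads(
    reads: Iterable[ReadRecord], hairpins: Mapping[str, Hairpin]
) -> MappingResult:
    """Exact full-length substring mapping of reads onto hairpins.

    A read matching k hairpins yields k hits, each carrying the full count
    (per-locus percentages are ratios, unaffected by the shared constant).
    Multiple occurrences within one hairpin all become hits.
    """
    if not hairpins:
        raise ValueError("empty hairpin set")
    hits: list[AlignmentHit] = []
    unmapped_reads = 0
    unmapped_count = 0
    mapped_count = 0
    for read in reads:
        seq = read.sequence
        matched = False
        for hp in hairpins.values():
            pos = hp.sequence.find(seq)
            while pos != -1:
                hits.append(AlignmentHit(read=read, hairpin_id=hp.id, start=pos))
                matched = True
                pos = hp.sequence.find(seq, pos + 1)
        if matched:
            mapped_count += read.count
        else:
            unmapped_reads += 1
            unmapped_count += read.count
    return MappingResult(
        hits=hits,
        unmapped_reads=unmapped_reads,
        unmapped_count=unmapped_count,
        mapped_count=mapped_count,
    )


def cpm(count: int, library_size: int) -> float:
    """Counts per million mapped reads."""
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    return count / library_size * 1e6


def offset_profile(
    hits: Sequence[AlignmentHit],
    annotation: MatureAnnotation,
    library_size: int,
) -> OffsetProfile:
    """Classify hits on one hairpin by 5' start offset from the mature start.

    Only hits with offset in {-2..+2} that overlap the mature interval enter
    the counts; both the numerator and the percentage denominator exclude
    everything else.
    """
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    counts: dict[int, int] = {}
    canonical_count = 0
    for hit in hits:
        if hit.hairpin_id != annotation.hairpin_id:
            continue
        offset = hit.start - annotation.start
        if offset < OFFSET_WINDOW[0] or offset > OFFSET_WINDOW[-1]:
            continue
        read_end = hit.start + len(hit.read.sequence)
        if read_end <= annotation.start or hit.start >= annotation.end:
            continue  # does not overlap the mature arm
        counts[offset] = counts.get(offset, 0) + hit.read.count
        if hit.read.sequence == annotation.reference_sequence:
            canonical_count += hit.read.count
    windowed_total = sum(counts.values())
    if windowed_total == 0:
        return OffsetProfile(
            mirna_id=annotation.mirna_id,
            counts_by_offset={},
            windowed_total=0,
            percent_by_offset={},
            cpm=0.0,
            canonical_fraction=0.0,
        )
    percents = {o: 100.0 * c / windowed_total for o, c in counts.items()}
    return OffsetProfile(
        mirna_id=annotation.mirna_id,
        counts_by_offset=counts,
        windowed_total=windowed_total,
        percent_by_offset=percents,
        cpm=cpm(windowed_total, library_size),
        canonical_fraction=canonical_count / windowed_total,
    )


def _dominant_offset(percent_by_offset: Mapping[int, float]) -> int:
    """Argmax offset; ties prefer an alternative form over the annotated
    start (a 50/50 split reads as 'at least 50%' for the variant), then the
    smaller |offset|, then the negative (5'-extended) one."""
    best = max(percent_by_offset.values())
    candidates = [o for o, p in percent_by_offset.items() if p == best]
    return min(candidates, key=lambda o: (o == 0, abs(o), o > 0))


def call_reassignment(
    profile: OffsetProfile,
    annotation: MatureAnnotation,
    hairpin: Hairpin,
    cpm_threshold: float = 20.0,
    fraction_threshold: float = 0.5,
) -> ReassignmentCall:
    """Flag a miRNA whose dominant 5' form differs from the annotated start.

    Flagged iff CPM >= ``cpm_threshold`` (detection), the dominant offset is
    non-zero, and the dominant form carries >= ``fraction_threshold`` of the
    windowed reads.  The proposed canonical sequence shifts the 5' end by the
    dominant offset and keeps the annotated 3' end.
    """
    if profile.windowed_total == 0:
        return ReassignmentCall(profile.mirna_id, 0, 0.0, profile.cpm, False)
    dom = _dominant_offset(profile.percent_by_offset)
    dom_fraction = profile.percent_by_offset[dom] / 100.0
    flagged = (
        profile.cpm >= cpm_threshold
        and dom != 0
        and dom_fraction >= fraction_threshold
    )
    proposed = ""
    if flagged:
        new_start = annotation.start + dom
        if not (0 <= new_start < annotation.end <= len(hairpin)):
            raise ValueError(
                f"{profile.mirna_id}: shifted 5' start {new_start} exceeds "
                f"hairpin bounds"
            )
        proposed = hairpin.sequence[new_start : annotation.end]
    return ReassignmentCall(
        mirna_id=profile.mirna_id,
        dominant_offset=dom,
        dominant_fraction=dom_fraction,
        cpm=profile.cpm,
        flagged=flagged,
        proposed_sequence=proposed,
    )


def canonical_fraction_table(
    profiles: Iterable[OffsetProfile], min_counts: int = 30
) -> pd.DataFrame:
    """Per-miRNA fraction of reads exactly matching the reference sequence.

    Only miRNAs with at least ``min_counts`` assigned reads are reported.
    """
    rows = [
        (p.mirna_id, p.canonical_fraction)
        for p in profiles
        if p.windowed_total >= min_counts
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "canonical_fraction"])


def concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Squared Pearson correlation of canonical fractions over shared miRNAs."""
    merged = table_a.merge(table_b, on="mirna_id", suffixes=("_a", "_b")).dropna()
    if len(merged) < 2:
        raise ValueError(f"need >= 2 shared miRNAs, got {len(merged)}")
    a = merged["canonical_fraction_a"].to_numpy(float)
    b = merged["canonical_fraction_b"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the fraction vectors")
    r = stats.pearsonr(a, b).statistic
    return float(r**2)


def profiles_to_table(profiles: Iterable[OffsetProfile]) -> pd.DataFrame:
    """Flatten profiles into the TSV layout used by the analysis drivers."""
    cols = {"-2": "m2", "-1": "m1", "0": "0", "1": "p1", "2": "p2"}
    rows = []
    for p in profiles:
        row: dict[str, object] = {"mirna_id": p.mirna_id}
        for off in OFFSET_WINDOW:
            tag = cols[str(off)]
            row[f"c_{tag}"] = p.counts_by_offset.get(off, 0)
            row[f"pct_{tag}"] = p.percent_by_offset.get(off, 0.0)
        row["windowed_total"] = p.windowed_total
        row["cpm"] = p.cpm
        row["canonical_fraction"] = p.canonical_fraction
        rows.append(row)
    return pd.DataFrame(rows)
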