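"""Seed-complementarity target scanning with seed-shift awareness.

Scans transcript (or 3'UTR) sequences for sites complementary to a miRNA
seed, classifies them into the canonical site-type taxonomy (6mer, 7mer-m8,
7mer-A1, 8mer), annotates each with the free energy of the seed-anchored
duplex, and classifies sites by whether they are recognized by the canonical
miRNA, its 5'-extended isomiR, or shared by both registers.

A 5'-isomiR built by prepending one uridine shifts the seed register by one
base: the isomiR's positions 2-7 equal the canonical positions 1-6, so the
two registers read overlapping but distinct site repertoires — the property
this module exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .annotation_io import normalize_rna
from .energy import EnergyModel, WATSON_CRICK, pairs

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

MATCH_TYPES = ("6mer", "7mer-m8", "7mer-A1", "8mer")
DEFAULT_DG_CUTOFF = -20.0  # kcal/mol


def reverse_complement(sequence: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(sequence))
    except KeyError as exc:
        raise ValueError(f"invalid RNA symbol {exc.args[0]!r}") from None


def extract_seed(sequence: str, kind: str) -> str:
    """Seed substring at 1-based positions 2-7 (hexamer) or 2-8 (heptamer)."""
    if len(sequence) < 8:
        raise ValueError(f"sequence of length {len(sequence)} is too short (< 8)")
    if kind == "hexamer_2_7":
        return sequence[1:7]
    if kind == "heptamer_2_8":
        return sequence[1:8]
    raise ValueError(f"unknown seed kind {kind!r}")


@dataclass(frozen=True)
class SeedSpec:
    """A miRNA sequence with its seed substrings and register label."""

    mirna_id: str
    sequence: str
    seed7: str
    seed6: str
    register: str  # "canonical" | "five_prime_extended"

    @classmethod
    def from_sequence(
        cls, mirna_id: str, sequence: str, register: str = "canonical"
    ) -> "SeedSpec":
        seq = normalize_rna(sequence, mirna_id)
        if register not in ("canonical", "five_prime_extended"):
            raise ValueError(f"unknown register {register!r}")
        return cls(
            mirna_id=mirna_id,
            sequence=seq,
            seed7=extract_seed(seq, "heptamer_2_8"),
            seed6=extract_seed(seq, "hexamer_2_7"),
            register=register,
        )

    @property
    def variant_label(self) -> str:
        return "canonical" if self.register == "canonical" else "isomir"


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with an optional transcript-relative 3'UTR."""

    id: str
    sequence: str
    gene_id: Optional[str] = None
    utr3: Optional[tuple[int, int]] = None  # 0-based half-open

    def region_sequence(self, region: str) -> str:
        if region == "full_transcript":
            return self.sequence
        if region == "utr3":
            if self.utr3 is None:
                raise ValueError(f"transcript {self.id!r} has no 3'UTR annotation")
            return self.sequence[self.utr3[0] : self.utr3[1]]
        raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class SiteMatch:
    transcript_id: str
    region: str
    start: int  # 0-based on the scanned region, start of the literal site
    end: int
    match_type: str
    delta_g: float
    matched_variants: frozenset[str]
    seed_start: int = 0  # start of the hexamer core within the region


def duplex_delta_g(
    mirna: str,
    site_context: str,
    energy: EnergyModel,
    anchor: Optional[int] = None,
) -> float:
    """ΔG of the seed-anchored duplex between a miRNA and a site context.

    The hexamer core (reverse complement of seed positions 2-7) is located in
    ``site_context`` (at ``anchor`` if given), pairing is extended outward in
    both directions while Watson-Crick or G·U pairing holds (wobbles are
    allowed in the extension, never required in the core), and the nearest-
    neighbor sum over the maximal contiguous duplex is returned.  With
    several cores present the most stable duplex is reported.
    """
    mirna = normalize_rna(mirna, "<mirna>")
    context = normalize_rna(site_context, "<site>")
    core = reverse_complement(mirna[1:7])
    if anchor is not None:
        anchors = [anchor]
        if context[anchor : anchor + 6] != core:
            raise ValueError("anchor does not sit on a seed-complementary core")
    else:
        anchors = []
        pos = context.find(core)
        while pos != -1:
            anchors.append(pos)
            pos = context.find(core, pos + 1)
        if not anchors:
            raise ValueError("no seed-complementary core pairable in site context")
    best = None
    for s in anchors:
        # miRNA position index i (0-based) pairs context index j = s + 6 - i
        lo, hi = 1, 6  # seed core: miRNA indices 1..6
        while lo - 1 >= 0 and s + 6 - (lo - 1) < len(context) and pairs(
            mirna[lo - 1], context[s + 6 - (lo - 1)]
        ):
            lo -= 1
        while hi + 1 < len(mirna) and s + 6 - (hi + 1) >= 0 and pairs(
            mirna[hi + 1], context[s + 6 - (hi + 1)]
        ):
            hi += 1
        dg = energy.initiation
        for i in range(lo, hi):
            top = mirna[i : i + 2]
            bottom = context[s + 6 - i] + context[s + 6 - (i + 1)]
            dg += energy.stack(top, bottom)
        for i in (lo, hi):
            p = (mirna[i], context[s + 6 - i])
            if p not in WATSON_CRICK or p in (("A", "U"), ("U", "A")):
                dg += energy.terminal_penalty
        if best is None or dg < best:
            best = dg
    return round(best, 10)


def _site_records(
    scanned: str, seed: SeedSpec, pos: int
) -> list[tuple[str, int, int]]:
    """Match types satisfied by the hexamer core at ``pos``, with the literal
    site interval each type spans."""
    m8_partner = reverse_complement(seed.sequence[7])
    has_m8 = pos > 0 and scanned[pos - 1] == m8_partner
    has_a1 = pos + 6 < len(scanned) and scanned[pos + 6] == "A"
    records = [("6mer", pos, pos + 6)]
    if has_m8:
        records.append(("7mer-m8", pos - 1, pos + 6))
    if has_a1:
        records.append(("7mer-A1", pos, pos + 7))
    if has_m8 and has_a1:
        records.append(("8mer", pos - 1, pos + 7))
    return records


def scan_sites(
    transcript: Transcript,
    seed: SeedSpec,
    match_types: Iterable[str] = MATCH_TYPES,
    region: str = "utr3",
    energy: Optional[EnergyModel] = None,
    cutoff: Optional[float] = DEFAULT_DG_CUTOFF,
    context_pad: int = 15,
) -> list[SiteMatch]:
    """Scan one transcript region for seed-complementary sites.

    A 6mer site is an exact occurrence of the reverse complement of seed
    positions 2-7; 7mer-m8 adds pairing to position 8, 7mer-A1 an adenine
    opposite position 1, 8mer both.  Every requested type a site satisfies is
    reported (an 8mer is also a 7mer-m8, a 7mer-A1 and a 6mer).  Each site is
    annotated with the seed-anchored duplex ΔG and retained iff
    ΔG <= ``cutoff`` (``cutoff=None`` disables the filter).
    """
    match_types = set(match_types)
    unknown = match_types - set(MATCH_TYPES)
    if unknown:
        raise ValueError(f"unknown match types: {sorted(unknown)}")
    model = energy if energy is not None else EnergyModel.default()
    scanned = transcript.region_sequence(region)
    core = reverse_complement(seed.seed6)
    sites: list[SiteMatch] = []
    pos = scanned.find(core)
    while pos != -1:
        lo = max(0, pos - context_pad)
        dg = duplex_delta_g(
            seed.sequence, scanned[lo : pos + 6 + context_pad], model, anchor=pos - lo
        )
        if cutoff is None or dg <= cutoff:
            for mtype, start, end in _site_records(scanned, seed, pos):
                if mtype in match_types:
                    sites.append(
                        SiteMatch(
                            transcript_id=transcript.id,
                            region=region,
                            start=start,
                            end=end,
                            match_type=mtype,
                            delta_g=dg,
                            matched_variants=frozenset({seed.variant_label}),
                            seed_start=pos,
                        )
                    )
        pos = scanned.find(core, pos + 1)
    return sites


@dataclass
class SharingSummary:
    canonical_only: int
    isomir_only: int
    shared: int
    sites: list[SiteMatch] = field(default_factory=list)

    def counts(self) -> tuple[int, int, int]:
        return (self.canonical_only, self.isomir_only, self.shared)


def _clusters(sites: Sequence[SiteMatch]) -> list[list[SiteMatch]]:
    """Merge overlapping site records into physical-site clusters."""
    out: list[list[SiteMatch]] = []
    for site in sorted(sites, key=lambda s: (s.start, s.end)):
        if out and site.start < max(s.end for s in out[-1]):
            out[-1].append(site)
        else:
            out.append([site])
    return out


def classify_sharing(
    canonical_sites: Sequence[SiteMatch],
    isomir_sites: Sequence[SiteMatch],
) -> SharingSummary:
    """Partition physical sites into canonical-only / isomiR-only / shared.

    A canonical cluster and an isomiR cluster are *shared* when they overlap
    and their union pairs canonical positions 1-8, i.e. the canonical cluster
    pairs position 8 (a 7mer-m8 or 8mer record) and the isomiR cluster covers
    the transcript base opposite canonical position 1.  Bare-6mer overlaps
    produced by the one-base register shift are not shared sites.
    """
    tids = {s.transcript_id for s in canonical_sites} | {
        s.transcript_id for s in isomir_sites
    }
    if len(tids) > 1:
        raise ValueError(f"sites from multiple transcripts: {sorted(tids)}")
    regions = {s.region for s in canonical_sites} | {s.region for s in isomir_sites}
    if len(regions) > 1:
        raise ValueError(f"sites from multiple regions: {sorted(regions)}")
    can_clusters = _clusters(canonical_sites)
    iso_clusters = _clusters(isomir_sites)
    edges: list[tuple[int, int]] = []
    for ci, cc in enumerate(can_clusters):
        for ii, ic in enumerate(iso_clusters):
            c_lo, c_hi = min(s.start for s in cc), max(s.end for s in cc)
            i_lo, i_hi = min(s.start for s in ic), max(s.end for s in ic)
            if c_hi <= i_lo or i_hi <= c_lo:
                continue  # no overlap
            m8_records = [s for s in cc if s.match_type in ("7mer-m8", "8mer")]
            if not m8_records:
                continue
            # position opposite canonical position 1 = m8-site start + 7
            pos1 = min(s.start for s in m8_records) + 7
            if any(s.start <= pos1 < s.end for s in ic):
                edges.append((ci, ii))
    shared_can = {ci for ci, _ in edges}
    shared_iso = {ii for _, ii in edges}
    # shared physical sites = connected components of the overlap graph
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ci, ii in edges:
        a, b = find(("c", ci)), find(("i", ii))
        if a != b:
            parent[a] = b
    n_shared = len({find(("c", ci)) for ci, _ in edges})
    labelled: list[SiteMatch] = []
    both = frozenset({"canonical", "isomir"})
    for ci, cc in enumerate(can_clusters):
        for s in cc:
            labelled.append(
                replace(s, matched_variants=both) if ci in shared_can else s
            )
    for ii, ic in enumerate(iso_clusters):
        for s in ic:
            labelled.append(
                replace(s, matched_variants=both) if ii in shared_iso else s
            )
    return SharingSummary(
        canonical_only=len(can_clusters) - len(shared_can),
        isomir_only=len(iso_clusters) - len(shared_iso),
        shared=n_shared,
        sites=labelled,
    )


def predict_targets(
    transcriptome: Sequence[Transcript],
    seed: SeedSpec,
    match_types: Iterable[str] = MATCH_TYPES,
    region: str = "utr3",
    energy: Optional[EnergyModel] = None,
    cutoff: Optional[float] = DEFAULT_DG_CUTOFF,
) -> set[str]:
    """Genes with at least one retained site — the predicted-target set."""
    if not transcriptome:
        raise ValueError("empty transcriptome")
    model = energy if energy is not None else EnergyModel.default()
    genes: set[str] = set()
    for tx in transcriptome:
        gene = tx.gene_id if tx.gene_id is not None else tx.id
        if gene in genes:
            continue
        if scan_sites(tx, seed, match_types, region, model, cutoff):
            genes.add(gene)
    return genes
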