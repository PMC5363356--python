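"""Synthetic inputs with ground-truth ledgers for every pipeline stage.

Each generator is a pure function of a :class:`SimConfig` (same seed, same
bytes) and returns, next to its primary output, a ledger holding the planted
truth — drawn read counts per (miRNA, offset), planted site positions,
repressed gene sets — sufficient to score the downstream stage without
re-deriving anything.

What is emulated: per-miRNA 5'-offset read mixtures at controlled
proportions and depth (small RNA libraries of differentiating airway
cultures, and spike-in mixes of two variant sequences in a complex
background); transcript sets with planted canonical-only / isomiR-only /
shared seed sites on an otherwise site-free background; and per-condition
expression tables with planted repression of designated target sets.
Substitution errors only — indels would move 5' starts and confound the
offset ground truth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import Hairpin, MatureAnnotation
from .expression_filter import ExpressionMatrix, fold_change_table
from .isomir_quant import ReadRecord
from .target_scan import SeedSpec, Transcript, reverse_complement

_BASES = np.array(list("ACGU"))


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    rng_seed: int = 17
    # --- hairpins / reads ---
    n_mirnas: int = 20
    mature_length: int = 22
    flank_length: int = 8
    offset_proportions: dict[str, dict[int, float]] = field(default_factory=dict)
    u_start_mirnas: tuple[str, ...] = ()
    mirna_weights: Optional[dict[str, float]] = None
    depth: int = 100_000
    error_rate: float = 0.0
    # --- transcriptome ---
    utr_length: int = 400
    n_background_genes: int = 5
    planted_sites: tuple[tuple[str, str, int], ...] = ()
    # --- expression ---
    n_genes: int = 1000
    conditions: tuple[str, ...] = (
        "miR-Neg",
        "miR-34b",
        "miR-449c",
        "isomiR-34b",
        "isomiR-449c",
    )
    control: str = "miR-Neg"
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.1
    target_min_baseline: float = 4.5
    planted_repression: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        for mirna, props in self.offset_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{mirna}: offset proportions sum to {total}, expected 1"
                )
            if any(o < -2 or o > 2 for o in props):
                raise ValueError(f"{mirna}: offsets outside the -2..+2 window")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# hairpins


def gen_hairpins(config: SimConfig):
    """Hairpins embedding one mature each, with >= 2 nt flanks so every
    offset in -2..+2 yields a realizable read."""
    if config.n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if config.flank_length < 2:
        raise ValueError(
            "flank_length must be >= 2 so offsets -2..+2 are realizable"
        )
    rng = np.random.default_rng(config.rng_seed)
    hairpins: dict[str, Hairpin] = {}
    annotations: list[MatureAnnotation] = []
    ledger: dict[str, dict] = {}
    for i in range(config.n_mirnas):
        mirna_id = f"mir{i:03d}"
        for _ in range(100):
            mature = _random_seq(rng, config.mature_length)
            if mirna_id in config.u_start_mirnas:
                mature = "U" + mature[1:]
            hp_seq = (
                _random_seq(rng, config.flank_length)
                + mature
                + _random_seq(rng, config.flank_length)
            )
            if hp_seq.count(mature) == 1:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError(f"{mirna_id}: could not embed a unique mature")
        hp_id = f"hp-{mirna_id}"
        start = config.flank_length
        end = start + config.mature_length
        hairpins[hp_id] = Hairpin(hp_id, hp_seq)
        annotations.append(
            MatureAnnotation(
                mirna_id=mirna_id,
                hairpin_id=hp_id,
                start=start,
                end=end,
                arm="5p" if start < len(hp_seq) / 2 else "3p",
                reference_sequence=mature,
            )
        )
        ledger[mirna_id] = {
            "hairpin_id": hp_id,
            "start": start,
            "end": end,
            "mature": mature,
        }
    return hairpins, annotations, {"mirnas": ledger}


# ---------------------------------------------------------------------------
# read libraries


def gen_read_library(
    config: SimConfig,
    hairpins: Mapping[str, Hairpin],
    annotations: Sequence[MatureAnnotation],
):
    """Multinomial read mixture over (miRNA, 5' offset) categories.

    Reads shift the 5' start by the drawn offset and keep the annotated 3'
    end; substitution errors are applied per base at ``error_rate``.  The
    ledger stores the exact drawn counts per category (the pre-error truth).
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    ann_by_id = {a.mirna_id: a for a in annotations}
    categories: list[tuple[str, int]] = []
    probs: list[float] = []
    weights = config.mirna_weights or {a.mirna_id: 1.0 for a in annotations}
    total_w = sum(weights.values())
    for ann in annotations:
        props = config.offset_proportions.get(ann.mirna_id, {0: 1.0})
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{ann.mirna_id}: proportions sum to {total}")
        w = weights.get(ann.mirna_id, 0.0) / total_w
        for off, p in sorted(props.items()):
            categories.append((ann.mirna_id, off))
            probs.append(w * p)
    if config.depth == 0:
        return [], {"drawn_counts": {}, "library_size": 0}
    draws = rng.multinomial(config.depth, np.asarray(probs))
    collapsed: Counter[str] = Counter()
    drawn: dict[str, dict[int, int]] = {}
    for (mirna_id, off), n in zip(categories, draws):
        if n == 0:
            continue
        drawn.setdefault(mirna_id, {})[off] = int(n)
        ann = ann_by_id[mirna_id]
        hp = hairpins[ann.hairpin_id]
        read = hp.sequence[ann.start + off : ann.end]
        if config.error_rate > 0:
            L = len(read)
            p_any = 1.0 - (1.0 - config.error_rate) ** L
            n_err = rng.binomial(n, p_any)
            collapsed[read] += int(n - n_err)
            for _ in range(int(n_err)):
                seq = list(read)
                while True:  # condition on >= 1 substitution
                    flips = rng.random(L) < config.error_rate
                    if flips.any():
                        break
                for j in np.where(flips)[0]:
                    choices = [b for b in "ACGU" if b != seq[j]]
                    seq[j] = choices[rng.integers(3)]
                collapsed["".join(seq)] += 1
        else:
            collapsed[read] += int(n)
    reads = [
        ReadRecord(sequence=seq, count=count)
        for seq, count in sorted(collapsed.items())
    ]
    return reads, {"drawn_counts": drawn, "library_size": int(draws.sum())}


# ---------------------------------------------------------------------------
# transcriptomes with planted sites


def _core_for_kind(kind: str, canonical: SeedSpec, rng: np.random.Generator) -> str:
    """Planted site core plus deterministic flank bases.

    For a 5'-extended isomiR ``U + X`` the three core kinds are built from
    the canonical sequence X:
    - canonical_only: revcomp(X[1:8]) — canonical 7mer-m8; the 3' flank is
      neither A (no A1) nor complement(X[0]) (no isomiR hexamer).
    - shared: revcomp(X[0:8]) — pairs canonical positions 1-8, read by both
      registers.
    - isomir_only: revcomp(X[0:7]) — isomiR 7mer-m8; the 5' flank avoids
      complement(X[7]) so canonical position 8 stays unpaired.  The canonical
      bare hexamer is inherently contained (one-base shift), so exclusivity
      holds at 7mer-m8/8mer stringency.
    """
    X = canonical.sequence
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}

    def pick(exclude: set[str]) -> str:
        allowed = [b for b in "ACGU" if b not in exclude]
        return allowed[rng.integers(len(allowed))]

    if kind == "canonical_only":
        core = reverse_complement(X[1:8])
        left = pick({comp[X[7]]})  # keep it a 7mer-m8, not longer
        right = pick({"A", comp[X[0]]})
        return left + core + right
    if kind == "shared":
        core = reverse_complement(X[0:8])
        left = pick(set())
        right = pick({"A"})
        return left + core + right
    if kind == "isomir_only":
        core = reverse_complement(X[0:7])
        left = pick({comp[X[7]]})
        right = pick({"A"})
        return left + core + right
    raise ValueError(f"unknown core kind {kind!r}")


def _sitefree_background(
    rng: np.random.Generator, length: int, forbidden: Sequence[str], attempts: int = 500
) -> str:
    for _ in range(attempts):
        seq = _random_seq(rng, length)
        if not any(f in seq for f in forbidden):
            return seq
    raise RuntimeError(
        "could not draw a site-free background; use a longer UTR or fewer sites"
    )


def gen_transcriptome(
    config: SimConfig, canonical: SeedSpec, isomir: SeedSpec
):
    """Transcripts whose 3'UTRs carry planted seed-site architectures.

    Background sequence is rejection-sampled so that no unplanted occurrence
    of either register's seed-hexamer complement exists; planted cores sit at
    ledgered positions with >= 2 nt site-free spacing.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    forbidden = [
        reverse_complement(canonical.seed6),
        reverse_complement(isomir.seed6),
    ]
    pad = 30
    transcripts: list[Transcript] = []
    ledger: dict[str, dict] = {}

    plan: dict[str, list[str]] = {}
    for gene, kind, count in config.planted_sites:
        plan.setdefault(gene, []).extend([kind] * count)
    for i in range(config.n_background_genes):
        plan.setdefault(f"bg{i:03d}", [])

    def _count(seq: str, word: str) -> int:
        n, pos = 0, seq.find(word)
        while pos != -1:
            n, pos = n + 1, seq.find(word, pos + 1)
        return n

    for gene, kinds in plan.items():
        # expected exact occurrences after planting: every core kind carries
        # the canonical hexamer complement; shared and isomir_only also carry
        # the isomiR one (the one-base register shift).
        want_can = len(kinds)
        want_iso = sum(k in ("shared", "isomir_only") for k in kinds)
        for _attempt in range(50):
            pieces = [_core_for_kind(k, canonical, rng) for k in kinds]
            core_len = sum(len(p) for p in pieces)
            n_gaps = len(pieces) + 1
            free = config.utr_length - core_len
            if free < 2 * n_gaps:
                raise ValueError(
                    f"{gene}: utr_length {config.utr_length} too short for "
                    f"{len(pieces)} sites with 2 nt spacing"
                )
            cuts = np.sort(rng.integers(0, free - 2 * n_gaps + 1, size=n_gaps - 1))
            gap_lens = np.diff(np.concatenate([[0], cuts, [free - 2 * n_gaps]])) + 2
            utr_parts: list[str] = []
            positions: list[int] = []
            cursor = 0
            for j, piece in enumerate(pieces):
                gap = _sitefree_background(rng, int(gap_lens[j]), forbidden)
                utr_parts.append(gap)
                cursor += len(gap)
                positions.append(cursor + 1)  # +1: flank base precedes the core
                utr_parts.append(piece)
                cursor += len(piece)
            utr_parts.append(_sitefree_background(rng, int(gap_lens[-1]), forbidden))
            utr = "".join(utr_parts)
            head = _sitefree_background(rng, pad, forbidden)
            # junctions may still have created a spurious core: verify counts
            if (
                _count(head + utr, forbidden[0]) == want_can
                and _count(head + utr, forbidden[1]) == want_iso
            ):
                break
        else:
            raise RuntimeError(
                f"{gene}: could not assemble a junction-clean UTR; "
                "use a longer UTR"
            )
        transcripts.append(
            Transcript(
                id=f"tx-{gene}",
                sequence=head + utr,
                gene_id=gene,
                utr3=(pad, pad + len(utr)),
            )
        )
        ledger[gene] = {
            "kinds": kinds,
            "core_positions_in_utr": positions,
            "utr_interval": (pad, pad + len(utr)),
        }
    return transcripts, {"genes": ledger}


# ---------------------------------------------------------------------------
# expression tables


@dataclass
class ExpressionTables:
    log2cpm: ExpressionMatrix
    log2fc: pd.DataFrame
    counts: pd.DataFrame
    ledger: dict


def gen_expression_tables(config: SimConfig) -> ExpressionTables:
    """Per-condition log2 CPM tables with planted repression.

    Baseline expression is log-normal (normal on the log2 scale); each
    condition adds independent per-gene noise, and designated target genes
    receive the planted log2 fold-change effect.  Counts are derived from
    CPM at a nominal library size for interface completeness.
    """
    rng = np.random.default_rng(config.rng_seed + 3)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    gene_set = set(genes)
    for cond, (targets, _) in config.planted_repression.items():
        if cond not in config.conditions:
            raise ValueError(f"planted repression on unknown condition {cond!r}")
        unknown = set(targets) - gene_set
        if unknown:
            raise ValueError(f"{cond}: effect on unknown gene(s) {sorted(unknown)[:5]}")
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    # planted targets emulate predicted-target genes, which are detectably
    # expressed in the assay: keep their baselines above the CPM floor
    planted_all = {
        g for targets, _ in config.planted_repression.values() for g in targets
    }
    for gi in (genes.index(g) for g in sorted(planted_all)):
        while baseline[gi] < config.target_min_baseline:
            baseline[gi] = rng.normal(config.baseline_mean, config.baseline_sd)
    data = {}
    for cond in config.conditions:
        col = baseline + rng.normal(0.0, config.noise_sd, config.n_genes)
        if cond in config.planted_repression:
            targets, effect = config.planted_repression[cond]
            idx = [genes.index(g) for g in targets]
            col = col.copy()
            col[idx] += effect
        data[cond] = col
    log2cpm = pd.DataFrame(data, index=genes)
    matrix = ExpressionMatrix(data=log2cpm, control=config.control)
    fc = fold_change_table(matrix)
    counts = np.rint(np.exp2(log2cpm) / 1e6 * 2e7).astype(int)
    ledger = {
        "planted": {
            cond: {"genes": sorted(targets), "effect": effect}
            for cond, (targets, effect) in config.planted_repression.items()
        }
    }
    return ExpressionTables(log2cpm=matrix, log2fc=fc, counts=counts, ledger=ledger)


# ---------------------------------------------------------------------------
# presets


#: Printed mimic sequences of the two focal miRNAs (canonical register).
MIR34B_CANONICAL = "AGGCAGUGUCAUUAGCUGAUUGU"
MIR449C_CANONICAL = "AGGCAGUGUAUUGCUAGCGGCUGU"


def focal_seed_pairs() -> dict[str, tuple[SeedSpec, SeedSpec]]:
    """Canonical and 5'-isomiR (U-prepended) seed specs for both focal miRNAs."""
    out = {}
    for name, seq in (("miR-34b", MIR34B_CANONICAL), ("miR-449c", MIR449C_CANONICAL)):
        out[name] = (
            SeedSpec.from_sequence(name, seq, "canonical"),
            SeedSpec.from_sequence(
                f"5p-isomiR-{name}", "U" + seq, "five_prime_extended"
            ),
        )
    return out


def preset_config(name: str, seed: int = 17) -> SimConfig:
    """Named study-condition presets.

    - ``haec``: airway-culture-like library; the two focal miRNAs carry the
      observed variant mixtures (92/8 and 75/25 at offset +1 vs 0 relative
      to the database entry) among database-concordant background miRNAs.
    - ``spikein``: two spiked variant pairs (one 1:1, one skewed 9:1) in a
      complex background.
    - ``transcriptome``: an RRAS-like gene carrying three canonical-only
      sites plus one shared site, one isomiR-only gene, background genes.
    - ``expression``: planted repression of variant-specific target sets,
      canonical sets larger than isomiR sets with partial overlaps.
    """
    if name == "haec":
        return SimConfig(
            rng_seed=seed,
            n_mirnas=20,
            depth=200_000,
            u_start_mirnas=("mir000", "mir001"),
            offset_proportions={
                # reads relative to the U-extended database entry:
                # +1 = the abundant family-register form, 0 = the entry itself
                "mir000": {0: 0.08, 1: 0.92},  # miR-34b-like split
                "mir001": {0: 0.25, 1: 0.75},  # miR-449c-like split
            },
        )
    if name == "spikein":
        weights = {f"mir{i:03d}": 1.0 for i in range(12)}
        weights["mir000"] = weights["mir001"] = 3.0
        return SimConfig(
            rng_seed=seed,
            n_mirnas=12,
            depth=100_000,
            u_start_mirnas=("mir000", "mir001"),
            offset_proportions={
                "mir000": {0: 0.5, 1: 0.5},  # the 1:1 mix
                "mir001": {0: 0.1, 1: 0.9},  # a skewed mix
            },
            mirna_weights=weights,
        )
    if name == "transcriptome":
        return SimConfig(
            rng_seed=seed,
            utr_length=400,
            n_background_genes=5,
            planted_sites=(
                ("RRAS_like", "canonical_only", 3),
                ("RRAS_like", "shared", 1),
                ("ISO_only_gene", "isomir_only", 1),
            ),
        )
    if name == "expression":
        rng = np.random.default_rng(seed + 4)
        genes = [f"g{i:04d}" for i in range(1000)]
        pick = lambda n, pool: tuple(
            sorted(rng.choice(pool, size=n, replace=False))
        )
        t_34b = pick(60, genes)
        t_449c = tuple(sorted(set(t_34b[:20]) | set(pick(30, genes[200:]))))
        i_34b = tuple(sorted(set(t_34b[:10]) | set(pick(15, genes[400:]))))
        i_449c = tuple(sorted(set(t_449c[:6]) | set(pick(9, genes[600:]))))
        return SimConfig(
            rng_seed=seed,
            n_genes=1000,
            planted_repression={
                "miR-34b": (t_34b, -2.0),
                "miR-449c": (t_449c, -2.0),
                "isomiR-34b": (i_34b, -2.0),
                "isomiR-449c": (i_449c, -2.0),
            },
        )
    raise ValueError(f"unknown preset {name!r}")
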