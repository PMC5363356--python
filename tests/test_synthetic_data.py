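"""Ground-truth generators: determinism, ledgers, recoverability."""

import numpy as np
import pytest

from isoforge.annotation_io import locate_mature
from isoforge.isomir_quant import (
    call_reassignment,
    map_reads,
    offset_profile,
)
from isoforge.synthetic_data import (
    SimConfig,
    focal_seed_pairs,
    gen_expression_tables,
    gen_hairpins,
    gen_read_library,
    gen_transcriptome,
    preset_config,
)
from isoforge.expression_filter import down_filter
from isoforge.target_scan import classify_sharing, scan_sites


class TestGenHairpins:
    def test_deterministic(self):
        cfg = SimConfig(rng_seed=3, n_mirnas=5)
        a = gen_hairpins(cfg)
        b = gen_hairpins(cfg)
        assert {k: h.sequence for k, h in a[0].items()} == {
            k: h.sequence for k, h in b[0].items()
        }

    def test_ledger_coordinates_revalidated_by_locate_mature(self):
        hairpins, annotations, ledger = gen_hairpins(SimConfig(rng_seed=3, n_mirnas=8))
        for ann in annotations:
            hp = hairpins[ann.hairpin_id]
            relocated = locate_mature(hp, ann.reference_sequence, ann.mirna_id)
            assert (relocated.start, relocated.end) == (ann.start, ann.end)
            truth = ledger["mirnas"][ann.mirna_id]
            assert (truth["start"], truth["end"]) == (ann.start, ann.end)

    def test_u_start_mirna_hairpin_holds_both_registers(self):
        cfg = SimConfig(rng_seed=3, n_mirnas=2, u_start_mirnas=("mir000",))
        hairpins, annotations, _ = gen_hairpins(cfg)
        ann = annotations[0]
        hp = hairpins[ann.hairpin_id]
        mature = ann.reference_sequence
        assert mature.startswith("U")
        assert mature in hp.sequence and mature[1:] in hp.sequence

    def test_flank_constraint_enforced(self):
        with pytest.raises(ValueError, match="flank"):
            gen_hairpins(SimConfig(rng_seed=0, n_mirnas=1, flank_length=1))


class TestGenReadLibrary:
    def test_depth_zero_is_empty(self):
        cfg = SimConfig(rng_seed=4, n_mirnas=2, depth=0)
        hairpins, annotations, _ = gen_hairpins(cfg)
        reads, ledger = gen_read_library(cfg, hairpins, annotations)
        assert reads == [] and ledger["library_size"] == 0

    def test_fixed_seed_byte_identical(self):
        cfg = SimConfig(rng_seed=4, n_mirnas=3, depth=5000, error_rate=0.01)
        hairpins, annotations, _ = gen_hairpins(cfg)
        a, _ = gen_read_library(cfg, hairpins, annotations)
        b, _ = gen_read_library(cfg, hairpins, annotations)
        assert a == b

    def test_drawn_counts_sum_to_depth(self):
        cfg = SimConfig(rng_seed=4, n_mirnas=3, depth=5000)
        hairpins, annotations, _ = gen_hairpins(cfg)
        _, ledger = gen_read_library(cfg, hairpins, annotations)
        total = sum(
            c for per in ledger["drawn_counts"].values() for c in per.values()
        )
        assert total == 5000 == ledger["library_size"]

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(rng_seed=0, offset_proportions={"mir000": {0: 0.5, 1: 0.4}})

    def test_even_mixture_recovered_by_quantifier(self):
        """A 1:1 spike of two 5' variants is sequenced at ~equal proportion."""
        cfg = SimConfig(
            rng_seed=11,
            n_mirnas=2,
            depth=20_000,
            u_start_mirnas=("mir000",),
            offset_proportions={"mir000": {0: 0.5, 1: 0.5}},
        )
        hairpins, annotations, _ = gen_hairpins(cfg)
        reads, _ = gen_read_library(cfg, hairpins, annotations)
        result = map_reads(reads, hairpins)
        ann = annotations[0]
        hits = [h for h in result.hits if h.hairpin_id == ann.hairpin_id]
        prof = offset_profile(hits, ann, result.library_size)
        n = prof.windowed_total
        sd_pct = 100 * np.sqrt(0.25 / n)
        assert prof.percent_by_offset[0] == pytest.approx(50.0, abs=3 * sd_pct)

    def test_substitution_errors_leave_truth_in_ledger(self):
        cfg = SimConfig(rng_seed=4, n_mirnas=2, depth=10_000, error_rate=0.02)
        hairpins, annotations, _ = gen_hairpins(cfg)
        reads, ledger = gen_read_library(cfg, hairpins, annotations)
        assert sum(r.count for r in reads) == 10_000
        assert len(reads) > 2  # error copies exist as distinct sequences


class TestGenTranscriptome:
    def test_background_is_site_free(self):
        canonical, isomir = focal_seed_pairs()["miR-34b"]
        cfg = SimConfig(rng_seed=5, planted_sites=(), n_background_genes=4)
        txs, _ = gen_transcriptome(cfg, canonical, isomir)
        for t in txs:
            assert scan_sites(t, canonical, cutoff=None) == []
            assert scan_sites(t, isomir, cutoff=None) == []

    def test_rras_like_architecture(self):
        """Three canonical-only cores and one shared core are recovered as
        sharing counts (3, 0, 1)."""
        canonical, isomir = focal_seed_pairs()["miR-34b"]
        cfg = preset_config("transcriptome", seed=5)
        txs, ledger = gen_transcriptome(cfg, canonical, isomir)
        rras = next(t for t in txs if t.gene_id == "RRAS_like")
        summary = classify_sharing(
            scan_sites(rras, canonical, cutoff=None),
            scan_sites(rras, isomir, cutoff=None),
        )
        assert summary.counts() == (3, 0, 1)
        assert ledger["genes"]["RRAS_like"]["kinds"].count("canonical_only") == 3

    def test_isomir_only_core_exclusive_at_seven_mer_stringency(self):
        canonical, isomir = focal_seed_pairs()["miR-34b"]
        cfg = preset_config("transcriptome", seed=5)
        txs, _ = gen_transcriptome(cfg, canonical, isomir)
        gene = next(t for t in txs if t.gene_id == "ISO_only_gene")
        strict = ["7mer-m8", "7mer-A1", "8mer"]
        assert scan_sites(gene, canonical, match_types=strict, cutoff=None) == []
        assert len(scan_sites(gene, isomir, match_types=strict, cutoff=None)) >= 1

    def test_deterministic(self):
        canonical, isomir = focal_seed_pairs()["miR-34b"]
        cfg = preset_config("transcriptome", seed=9)
        a, _ = gen_transcriptome(cfg, canonical, isomir)
        b, _ = gen_transcriptome(cfg, canonical, isomir)
        assert [t.sequence for t in a] == [t.sequence for t in b]

    def test_utr_too_short_rejected(self):
        canonical, isomir = focal_seed_pairs()["miR-34b"]
        cfg = SimConfig(
            rng_seed=5, utr_length=30, planted_sites=(("g", "canonical_only", 5),)
        )
        with pytest.raises(ValueError, match="too short"):
            gen_transcriptome(cfg, canonical, isomir)


class TestGenExpressionTables:
    def test_planted_repression_recovered(self):
        """Planted -2.0 effects on expressed genes pass the down filter."""
        cfg = preset_config("expression", seed=2)
        tables = gen_expression_tables(cfg)
        result = down_filter(tables.log2cpm, tables.log2fc)
        for cond, truth in tables.ledger["planted"].items():
            planted = set(truth["genes"])
            recovered = result.per_condition[cond] & planted
            assert len(recovered) >= round(0.96 * len(planted))
            assert not result.per_condition[cond] - planted  # no false positives

    def test_zero_effect_gives_empty_downset(self):
        cfg = SimConfig(rng_seed=2, n_genes=300, planted_repression={})
        tables = gen_expression_tables(cfg)
        result = down_filter(tables.log2cpm, tables.log2fc)
        assert result.union == set()

    def test_deterministic(self):
        cfg = preset_config("expression", seed=2)
        a = gen_expression_tables(cfg)
        b = gen_expression_tables(cfg)
        assert a.log2cpm.data.equals(b.log2cpm.data)

    def test_unknown_gene_rejected(self):
        cfg = SimConfig(
            rng_seed=2, n_genes=10, planted_repression={"miR-34b": (("nope",), -2.0)}
        )
        with pytest.raises(ValueError, match="unknown gene"):
            gen_expression_tables(cfg)

    def test_canonical_overlap_exceeds_isomir_overlap(self):
        """With the canonical target set planted larger, the canonical
        down-regulated/predicted intersection dominates — the qualitative
        Venn pattern."""
        from isoforge.expression_filter import overlap_counts

        cfg = preset_config("expression", seed=2)
        tables = gen_expression_tables(cfg)
        result = down_filter(tables.log2cpm, tables.log2fc)
        predicted = {c: set(v["genes"]) for c, v in tables.ledger["planted"].items()}
        oc = overlap_counts(
            result.per_condition,
            predicted,
            [(("miR-34b", "miR-34b"), ("isomiR-34b", "isomiR-34b"))],
        )[0]
        assert oc.n_a > oc.n_b
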