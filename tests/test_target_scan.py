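"""Seed extraction, duplex energies, site scanning and sharing logic."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoforge.energy import EnergyModel, helix_delta_g
from isoforge.synthetic_data import MIR34B_CANONICAL, MIR449C_CANONICAL
from isoforge.target_scan import (
    SeedSpec,
    Transcript,
    classify_sharing,
    duplex_delta_g,
    extract_seed,
    predict_targets,
    reverse_complement,
    scan_sites,
)


class TestSeeds:
    @pytest.mark.parametrize(
        "sequence,kind,expected",
        [
            (MIR34B_CANONICAL, "hexamer_2_7", "GGCAGU"),
            ("U" + MIR34B_CANONICAL, "hexamer_2_7", "AGGCAG"),
            (MIR449C_CANONICAL, "hexamer_2_7", "GGCAGU"),
            ("U" + MIR449C_CANONICAL, "hexamer_2_7", "AGGCAG"),
            (MIR34B_CANONICAL, "heptamer_2_8", "GGCAGUG"),
        ],
    )
    def test_seed_extraction(self, sequence, kind, expected):
        assert extract_seed(sequence, kind) == expected

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            extract_seed("ACGUACG", "hexamer_2_7")

    @given(st.text(alphabet="ACGU", min_size=8, max_size=24))
    @settings(max_examples=100, deadline=None)
    def test_one_base_register_shift(self, x):
        """Prepending a U shifts the hexamer seed by one base: the extended
        variant's positions 2-7 equal the canonical positions 1-6."""
        assert extract_seed("U" + x, "hexamer_2_7") == x[0:6]

    def test_seedspec_fields(self):
        spec = SeedSpec.from_sequence("m", MIR34B_CANONICAL)
        assert spec.seed6 == spec.sequence[1:7]
        assert spec.seed7 == spec.sequence[1:8]


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCAGUG", "CACUGCC"), ("AGGCAGU", "ACUGCCU"), ("", "")],
    )
    def test_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGT")  # DNA not normalized here


class TestEnergyModel:
    def test_single_pair_is_initiation_only(self, energy_model):
        # one base pair, no stacks, G-C ends carry no terminal penalty
        assert helix_delta_g("G", "C", energy_model) == energy_model.initiation

    def test_helix_energy_matches_viennarna(self, energy_model):
        """Dual route: nearest-neighbor summation vs RNAeval on full helices."""
        cases = ["GGCC", "GACUG", "GGCAGUG", "ACGUA"]
        for top in cases:
            bottom_3to5 = "".join(
                {"A": "U", "U": "A", "G": "C", "C": "G"}[b] for b in top
            )
            ours = helix_delta_g(top, bottom_3to5, energy_model)
            seq = f"{top}&{bottom_3to5[::-1]}"
            struct = "(" * len(top) + "&" + ")" * len(top)
            out = subprocess.run(
                ["RNAeval", "-d2"],
                input=f"{seq}\n{struct}\n",
                capture_output=True,
                text=True,
            ).stdout
            ref = float(out.strip().splitlines()[-1].split("(")[-1].rstrip(")"))
            assert ours == pytest.approx(ref, abs=0.15)

    def test_seed_duplex_equals_hand_summed_stacks(self, energy_model):
        """Seed-only duplex of the heptamer against its complement equals the
        explicit ledger of 6 stack increments + initiation from the table."""
        seed7 = "GGCAGUG"
        site = reverse_complement(seed7)
        expected = energy_model.initiation
        partners = site[::-1]  # 3'->5' under the seed
        for i in range(6):
            expected += energy_model.stack_table[
                f"{seed7[i:i+2]}/{partners[i:i+2]}"
            ]
        assert helix_delta_g(seed7, partners, energy_model) == pytest.approx(expected)


class TestDuplexDeltaG:
    def test_extension_stabilizes(self, energy_model):
        """Full-length complementarity is far more stable than the bare seed."""
        site_seed = "AAA" + reverse_complement(MIR34B_CANONICAL[1:7]) + "AAA"
        site_full = "AAA" + reverse_complement(MIR34B_CANONICAL) + "AAA"
        dg_seed = duplex_delta_g(MIR34B_CANONICAL, site_seed, energy_model)
        dg_full = duplex_delta_g(MIR34B_CANONICAL, site_full, energy_model)
        assert dg_full < dg_seed
        assert dg_full < -20.0 < dg_seed

    def test_no_core_rejected(self, energy_model):
        with pytest.raises(ValueError, match="core"):
            duplex_delta_g(MIR34B_CANONICAL, "A" * 30, energy_model)

    def test_cutoff_comparisons(self, energy_model):
        site_full = "GG" + reverse_complement(MIR34B_CANONICAL) + "GG"
        dg = duplex_delta_g(MIR34B_CANONICAL, site_full, energy_model)
        assert dg <= -20.0  # retained at the default cutoff
        dg_weak = duplex_delta_g(
            MIR34B_CANONICAL,
            "GG" + reverse_complement(MIR34B_CANONICAL[1:7]) + "GG",
            energy_model,
        )
        assert dg_weak > -20.0  # discarded at the default cutoff


def tx(seq, tid="t1", gene=None):
    return Transcript(id=tid, sequence=seq, gene_id=gene, utr3=(0, len(seq)))


class TestScanSites:
    def test_eight_mer_site(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        sites = scan_sites(
            tx("AAACACUGCCAAA"), canonical, cutoff=None, energy=energy_model
        )
        eight = [s for s in sites if s.match_type == "8mer"]
        assert len(eight) == 1
        assert eight[0].start == 3
        assert eight[0].end == 11

    def test_no_sites_on_poly_a(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        assert scan_sites(tx("A" * 30), canonical, cutoff=None, energy=energy_model) == []

    def test_shared_core_hits_both_registers(self, mir34b_seeds, energy_model):
        """The 8-base complement of canonical positions 1-8 carries
        overlapping 7mer-m8 sites for canonical and isomiR registers."""
        canonical, isomir = mir34b_seeds
        utr = tx("AAA" + "CACUGCCU" + "AAA")
        can = scan_sites(utr, canonical, cutoff=None, energy=energy_model)
        iso = scan_sites(utr, isomir, cutoff=None, energy=energy_model)
        assert any(s.match_type == "7mer-m8" for s in can)
        assert any(s.match_type == "7mer-m8" for s in iso)

    def test_missing_utr_annotation_rejected(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        bare = Transcript(id="t", sequence="ACGU" * 10)
        with pytest.raises(ValueError, match="3'UTR"):
            scan_sites(bare, canonical, region="utr3", energy=energy_model)

    def test_containment_of_match_types(self, mir34b_seeds, energy_model):
        """An 8mer position is also reported under 6mer, 7mer-m8, 7mer-A1."""
        canonical, _ = mir34b_seeds
        sites = scan_sites(
            tx("AAACACUGCCAAA"), canonical, cutoff=None, energy=energy_model
        )
        types = {s.match_type for s in sites}
        assert types == {"6mer", "7mer-m8", "7mer-A1", "8mer"}

    def test_site_counts_monotone_in_cutoff(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        utr = tx("GG" + reverse_complement(MIR34B_CANONICAL) + "GGAAACACUGCCAAA")
        n = [
            len(scan_sites(utr, canonical, cutoff=c, energy=energy_model))
            for c in (None, 0.0, -10.0, -20.0, -40.0, -60.0)
        ]
        assert n == sorted(n, reverse=True)

    def test_bruteforce_sixmer_oracle(self, mir34b_seeds, energy_model):
        """6mer scan equals sliding-window equality on random transcripts."""
        canonical, _ = mir34b_seeds
        core = reverse_complement(canonical.seed6)
        rng = np.random.default_rng(7)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGU"), size=rng.integers(50, 1000)))
            found = {
                s.start
                for s in scan_sites(
                    tx(seq), canonical, match_types=["6mer"], cutoff=None,
                    energy=energy_model,
                )
            }
            brute = {
                i for i in range(len(seq) - 5) if seq[i : i + 6] == core
            }
            assert found == brute

    def test_no_accidental_double_strand_scan(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        fwd = tx("AAACACUGCCAAA")
        rev = tx(reverse_complement(fwd.sequence))
        assert scan_sites(fwd, canonical, cutoff=None, energy=energy_model)
        assert not scan_sites(rev, canonical, cutoff=None, energy=energy_model)


class TestClassifySharing:
    def test_disjoint_sites_not_shared(self, mir34b_seeds, energy_model):
        canonical, isomir = mir34b_seeds
        utr = tx("AA" + "CCACUGCCG" + "A" * 20 + "ACUGCCU" + "AA")
        can = scan_sites(utr, canonical, cutoff=None, energy=energy_model)
        iso = scan_sites(utr, isomir, cutoff=None, energy=energy_model)
        summary = classify_sharing(can, iso)
        assert summary.shared == 0

    def test_shared_core_counted_once(self, mir34b_seeds, energy_model):
        canonical, isomir = mir34b_seeds
        utr = tx("AAA" + "CACUGCCU" + "AAA")
        summary = classify_sharing(
            scan_sites(utr, canonical, cutoff=None, energy=energy_model),
            scan_sites(utr, isomir, cutoff=None, energy=energy_model),
        )
        assert summary.counts() == (0, 0, 1)

    def test_mixed_transcripts_rejected(self, mir34b_seeds, energy_model):
        canonical, isomir = mir34b_seeds
        a = scan_sites(tx("AAACACUGCCAAA", "t1"), canonical, cutoff=None, energy=energy_model)
        b = scan_sites(tx("AAACUGCCUAAAA", "t2"), isomir, cutoff=None, energy=energy_model)
        with pytest.raises(ValueError, match="transcripts"):
            classify_sharing(a, b)


class TestPredictTargets:
    def test_gene_set_semantics(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        site = reverse_complement(MIR34B_CANONICAL)  # strong full-length site
        with_sites = tx("GG" + site + "GG" + site + "GG", "t1", gene="hit")
        without = tx("A" * 60, "t2", gene="miss")
        genes = predict_targets([with_sites, without], canonical, energy=energy_model)
        assert genes == {"hit"}

    def test_weak_sites_fail_energy_cutoff(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        weak = tx("AAA" + reverse_complement(canonical.seed6) + "AAA", "t1", gene="g")
        assert predict_targets([weak], canonical, energy=energy_model) == set()
        assert predict_targets([weak], canonical, energy=energy_model, cutoff=None) == {"g"}

    def test_empty_transcriptome_rejected(self, mir34b_seeds, energy_model):
        canonical, _ = mir34b_seeds
        with pytest.raises(ValueError, match="empty"):
            predict_targets([], canonical, energy=energy_model)
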