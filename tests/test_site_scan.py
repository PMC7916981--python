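import numpy as np
import pytest

from _oracles import brute_force_scan
from conftest import random_rna
from mirprio.seqio import MiRNARecord, UTRRecord
from mirprio.site_scan import (
    duplex_energy,
    infer_pairing,
    rna22_like_sites,
    scan_seed_sites,
)


def as_tuples(sites):
    return sorted((s.start, s.end, s.site_class, s.mismatches, s.wobbles) for s in sites)


class TestScanSeedSites:
    def test_perfect_seed_complement_found(self, mir425):
        # seed AUGACA; its reverse complement is UGUCAU
        utr = UTRRecord("G1", "AAAAUGUCAUAAAA")
        (site,) = scan_seed_sites(mir425, utr, max_mismatch=0)
        assert (site.start, site.end) == (4, 10)
        assert utr.sequence[site.start : site.end] == "UGUCAU"
        assert site.mismatches == 0 and site.wobbles == 0

    def test_no_pairing_possible_on_homopolymer(self, mir425):
        # seed complement UGUCAU has >= 3 non-A-pairing positions
        utr = UTRRecord("G1", "A" * 10)
        assert scan_seed_sites(mir425, utr) == []

    def test_single_substitution_counts_one_mismatch(self, mir425):
        # UGUCAU -> UGUCAC: the C faces seed position 2 (A), an A:C mismatch
        utr = UTRRecord("G1", "AAAAUGUCACAAAA")
        found = as_tuples(scan_seed_sites(mir425, utr))
        assert found == brute_force_scan(mir425, utr)
        assert any(t[3] == 1 for t in found)

    def test_substitution_opposite_u_is_a_wobble_not_mismatch(self, mir425):
        # UGUCAU -> UGUCGU: the G faces seed position 3 (U), a U:G wobble
        utr = UTRRecord("G1", "AAAAUGUCGUAAAA")
        (site,) = scan_seed_sites(mir425, utr)
        assert (site.mismatches, site.wobbles) == (0, 1)
        assert as_tuples([site]) == brute_force_scan(mir425, utr)

    def test_site_class_upgrades(self):
        mirna = MiRNARecord("mirX", "UAAGGCACGCGGUGAAUGCC")
        # seed AAGGCA -> complement UGCCUU; position 8 is C, pairs G
        core = "UGCCUU"
        utr7 = UTRRecord("G7", "AAA" + core + "G"[::-1] + "AAA")
        # 7mer needs the G 5' of the hexamer on the target
        utr7 = UTRRecord("G7", "AAG" + core + "CAA")
        sites = {s.site_class: s for s in scan_seed_sites(mirna, utr7, max_mismatch=0)}
        assert "7mer" in sites
        utr8 = UTRRecord("G8", "AAG" + core + "AAA")
        sites8 = {s.site_class: s for s in scan_seed_sites(mirna, utr8, max_mismatch=0)}
        assert "8mer" in sites8
        s8 = sites8["8mer"]
        assert s8.end - s8.start == 8

    def test_oracle_equivalence_random_pairs(self, reference_mirnas, rng):
        for trial in range(100):
            mirna = reference_mirnas[trial % len(reference_mirnas)]
            utr = UTRRecord("G", random_rna(rng, int(rng.integers(20, 200))))
            mm = int(rng.integers(0, 2))
            wb = int(rng.integers(0, 2))
            assert as_tuples(scan_seed_sites(mirna, utr, mm, wb)) == brute_force_scan(
                mirna, utr, mm, wb
            )

    def test_monotone_in_budgets(self, reference_mirnas, rng):
        for trial in range(20):
            mirna = reference_mirnas[trial % len(reference_mirnas)]
            utr = UTRRecord("G", random_rna(rng, 150))
            base = len(scan_seed_sites(mirna, utr, 0, 0))
            more_mm = len(scan_seed_sites(mirna, utr, 1, 0))
            more_wb = len(scan_seed_sites(mirna, utr, 0, 1))
            both = len(scan_seed_sites(mirna, utr, 1, 1))
            assert base <= more_mm <= both
            assert base <= more_wb <= both


class TestDuplexEnergy:
    def test_gg_cc_stack_hand_sum(self):
        # three consecutive GG/CC stacks, each -3.26
        res = duplex_energy("GGGG", "CCCC")
        assert res.energy == pytest.approx(3 * -3.26)

    def test_unpaired_only_penalties(self):
        res = duplex_energy("AAAA", "CCCC")  # no pairing possible
        assert all(c == "unpaired" for c in res.pairing)
        assert res.energy == pytest.approx(4 * 0.5)

    def test_reversal_invariance_for_palindromic_stacks(self, rng):
        # a stack is its own reversal only when each strand is homogeneous
        # across the stack (e.g. GG/CC, AA/UU); homopolymer duplexes are
        # therefore exactly the reversal-invariant cases
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(20):
            base = str(rng.choice(list("ACGU")))
            m = base * int(rng.integers(2, 12))
            t = "".join(comp[c] for c in m)[::-1]
            fwd = duplex_energy(m, t).energy
            rev = duplex_energy(m[::-1], t[::-1]).energy
            assert fwd == pytest.approx(rev)

    def test_fully_paired_duplex_is_stabilizing(self, rng):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(50):
            m = random_rna(rng, int(rng.integers(2, 15)))
            t = "".join(comp[c] for c in reversed(m))
            assert duplex_energy(m, t).energy <= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("GG", "CCC")

    def test_wrong_mask_rejected(self):
        with pytest.raises(ValueError, match="Watson-Crick"):
            duplex_energy("AA", "AA", pairing=("WC", "WC"))


class TestRna22LikeSites:
    @pytest.fixture()
    def strong_pair(self):
        # GC-rich miRNA whose full-length duplex is very stable
        mirna = MiRNARecord("mirGC", "GGCCGGCCGGCCGGCCGGCCAA")
        # perfect complement of the whole mature sequence, embedded in A's
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        target_core = "".join(comp[c] for c in reversed(mirna.sequence))
        utr = UTRRecord("G1", "AAAA" + target_core + "AAAA")
        return mirna, utr

    def test_strong_site_emitted_at_minus12(self, strong_pair):
        mirna, utr = strong_pair
        hits = rna22_like_sites(mirna, utr, energy_cutoff=-12.0)
        assert hits
        energy = min(d.energy for _, d in hits)
        # hand check: full-WC duplex of a GC-rich 22-mer is far below -20
        assert energy < -20.0
        assert rna22_like_sites(mirna, utr, energy_cutoff=-20.0)

    def test_weak_au_site_not_emitted(self):
        mirna = MiRNARecord("mirAU", "UAAUAAUAAUAAUAAUAAUA")
        comp = {"A": "U", "U": "A"}
        target_core = "".join(comp[c] for c in reversed(mirna.sequence))
        utr = UTRRecord("G1", "GG" + target_core + "GG")
        # all-AU stacks are at most -1.33 each; 19 stacks > -26 but the
        # seed-region stacks alone cannot reach -12 for short pairing runs;
        # verify against the duplex energy itself rather than guessing
        hits_all = rna22_like_sites(mirna, utr, energy_cutoff=0.0)
        assert hits_all
        energies = [d.energy for _, d in hits_all]
        strict = rna22_like_sites(mirna, utr, energy_cutoff=-30.0)
        assert [d.energy for _, d in strict] == [e for e in energies if e <= -30.0]

    def test_cutoff_subset_property(self, reference_mirnas, rng):
        for trial in range(20):
            mirna = reference_mirnas[trial % len(reference_mirnas)]
            utr = UTRRecord("G", random_rna(rng, 200, gc=0.6))
            loose = {
                (s.start, s.end) for s, _ in rna22_like_sites(mirna, utr, -12.0)
            }
            strict = {
                (s.start, s.end) for s, _ in rna22_like_sites(mirna, utr, -20.0)
            }
            assert strict <= loose

    def test_seed_len_8_keeps_only_8mers(self, strong_pair):
        mirna, utr = strong_pair
        for site, _ in rna22_like_sites(mirna, utr, energy_cutoff=0.0, seed_len=8):
            assert site.site_class == "8mer"


class TestPlantedRecovery:
    def test_planted_sites_recovered_exactly(self, reference_mirnas):
        from mirprio.synthetic import PlantedSiteSpec, SyntheticSpec, gen_utrs

        spec = SyntheticSpec(
            seed=7,
            n_utrs=40,
            planted_sites=[
                PlantedSiteSpec(
                    mirna=reference_mirnas[i % len(reference_mirnas)].name,
                    site_class=["8mer", "7mer", "6mer-seed"][i % 3],
                    mismatches=i % 2,
                )
                for i in range(40)
            ],
        )
        utrs, truth = gen_utrs(spec)
        by_gene = {u.gene: u for u in utrs}
        mirnas = {m.name: m for m in spec.mirnas}
        for row in truth.itertuples():
            found = scan_seed_sites(mirnas[row.mirna], by_gene[row.gene])
            match = [
                s
                for s in found
                if (s.start, s.end, s.site_class) == (row.start, row.end, row.site_class)
            ]
            assert match, f"planted site not recovered: {row}"
            assert match[0].mismatches == row.mismatches
            assert match[0].wobbles == row.wobbles
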