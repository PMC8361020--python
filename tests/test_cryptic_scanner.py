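"""Cryptic splice-site scanning, in-silico splicing and proteomics helpers."""

import numpy as np
import pytest

from hskit import cryptic_scanner as cs
from hskit import splice_atlas as sa
from hskit._genetics import CODONS, STOP_CODONS


def _flat_pfm(kind, favored=None):
    """Near-uniform PFM; `favored` maps position -> base given extra weight."""
    counts = np.full((4, 18), 10, dtype=int)
    for pos, base in (favored or {}).items():
        counts[:, pos] = 1
        counts[sa.BASES.index(base), pos] = 37
    return sa.PositionFrequencyMatrix(kind, counts, int(counts[:, 0].sum()))


class TestScanCandidates:
    def test_planted_donor_found_at_boundary(self):
        cds = "AAA" * 4 + "CTTCAGGTAAGT" + "AAA" * 4
        donor_pfm = _flat_pfm("donor", {9: "G", 10: "T"})
        acceptor_pfm = _flat_pfm("acceptor", {7: "A", 8: "G"})
        cands = cs.scan_candidates(cds, donor_pfm, acceptor_pfm, min_score=-100)
        donor_positions = [c.junction_pos for c in cands if c.kind == "donor"]
        assert 18 in donor_positions  # CAG|GT boundary
        assert cds[18:20] == "GT"

    def test_no_gt_means_no_donor_candidates(self):
        cds = "CAACCACCA" * 4
        pfm = _flat_pfm("donor")
        cands = cs.scan_candidates(cds, pfm, pfm, min_score=-100)
        assert [c for c in cands if c.kind == "donor"] == []

    def test_short_cds_warns_and_returns_empty(self, caplog):
        pfm = _flat_pfm("donor")
        with caplog.at_level("WARNING"):
            assert cs.scan_candidates("ATGGTA", pfm, pfm) == []
        assert "shorter" in caplog.text

    def test_score_equals_bruteforce_log_odds_sum(self, toy_atlas):
        cds = "ACGTGA" * 3 + "CTTCAGGTAAGTCCCGAT" + "TGCAGA" * 3
        dpfm, apfm = toy_atlas["donor_pfm"], toy_atlas["acceptor_pfm"]
        cands = cs.scan_candidates(cds, dpfm, apfm, min_score=-1000)
        pfms = {"donor": dpfm, "acceptor": apfm}
        assert cands
        for c in cands:
            ctx = cds[c.junction_pos - 9 : c.junction_pos + 9]
            counts = pfms[c.kind].counts
            brute = 0.0
            for j, b in enumerate(ctx):
                smoothed = counts[:, j] + 1.0
                p = smoothed[sa.BASES.index(b)] / smoothed.sum()
                brute += np.log2(p / 0.25)
            assert c.score == pytest.approx(brute)

    def test_default_threshold_is_consensus_minus_margin(self, toy_atlas):
        pwm = sa.log_odds_pwm(toy_atlas["donor_pfm"])
        assert cs.default_min_score(pwm) == pytest.approx(
            pwm.max(axis=0).sum() - 6.0
        )


class TestEnumerateCrypticIntrons:
    def _cands(self, donors, acceptors):
        d = [cs.SpliceSiteCandidate("donor", p, s, "GT") for p, s in donors]
        a = [cs.SpliceSiteCandidate("acceptor", p, s, "AG") for p, s in acceptors]
        return d, a

    def test_all_pairings_match_bruteforce(self):
        cds = "ACGT" * 60
        donors, acceptors = self._cands([(10, 1.0), (50, 2.0)], [(120, 1.5), (200, 0.5)])
        introns = cs.enumerate_cryptic_introns(cds, donors, acceptors, min_len=50)
        brute = {
            (d.junction_pos, a.junction_pos)
            for d in donors
            for a in acceptors
            if a.junction_pos - d.junction_pos >= 50
        }
        assert {i.interval for i in introns} == brute
        scores = [i.combined_score for i in introns]
        assert scores == sorted(scores, reverse=True)

    def test_acceptor_upstream_excluded(self):
        cds = "ACGT" * 60
        donors, acceptors = self._cands([(100, 1.0)], [(40, 1.0)])
        assert cs.enumerate_cryptic_introns(cds, donors, acceptors) == []

    def test_min_length_excludes_short_spacing(self):
        cds = "ACGT" * 60
        donors, acceptors = self._cands([(10, 1.0)], [(50, 1.0)])
        assert cs.enumerate_cryptic_introns(cds, donors, acceptors, min_len=50) == []
        assert len(cs.enumerate_cryptic_introns(cds, donors, acceptors, min_len=40)) == 1

    def test_gc_filter(self):
        cds = "A" * 100 + "G" * 100 + "A" * 100
        donors, acceptors = self._cands([(10, 1.0), (110, 1.0)], [(90, 1.0), (190, 1.0)])
        introns = cs.enumerate_cryptic_introns(cds, donors, acceptors, min_len=50, max_gc=0.5)
        assert all(i.gc <= 0.5 for i in introns)
        assert (110, 190) not in {i.interval for i in introns}

    def test_frame_preservation_flag(self):
        cds = "ACGT" * 60
        donors, acceptors = self._cands([(9, 0.0)], [(141, 0.0), (143, 0.0)])
        introns = {i.length: i for i in cs.enumerate_cryptic_introns(cds, donors, acceptors)}
        assert introns[132].frame_preserving and not introns[134].frame_preserving


class TestSpliceOut:
    def test_manual_concatenation(self):
        cds = "ATGCTTCAG" + "GTAAGTCCCTTTCAG" + "GGATGA"
        intron = cs.CrypticIntron(
            cs.SpliceSiteCandidate("donor", 9, 0.0, "GT"),
            cs.SpliceSiteCandidate("acceptor", 24, 0.0, "AG"),
            15, 0.4, False,
        )
        assert cs.splice_out(cds, [intron]) == "ATGCTTCAGGGATGA"

    def test_empty_intron_list_is_identity(self):
        assert cs.splice_out("ATGAAATAG", []) == "ATGAAATAG"

    def test_overlapping_introns_error(self):
        mk = lambda d, a: cs.CrypticIntron(
            cs.SpliceSiteCandidate("donor", d, 0.0, "GT"),
            cs.SpliceSiteCandidate("acceptor", a, 0.0, "AG"),
            a - d, 0.4, (a - d) % 3 == 0,
        )
        with pytest.raises(ValueError, match="overlap"):
            cs.splice_out("A" * 200, [mk(10, 100), mk(50, 150)])

    def test_length_conservation_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(60, 400))
            cds = "".join(rng.choice(list("ACGT"), n))
            d = int(rng.integers(0, n - 10))
            a = int(rng.integers(d + 1, n))
            intron = cs.CrypticIntron(
                cs.SpliceSiteCandidate("donor", d, 0.0, "GT"),
                cs.SpliceSiteCandidate("acceptor", a, 0.0, "AG"),
                a - d, 0.5, (a - d) % 3 == 0,
            )
            out = cs.splice_out(cds, [intron])
            assert len(out) == n - (a - d)
            assert intron.frame_preserving == ((a - d) % 3 == 0)


class TestCharacterizeVariant:
    def test_hand_translated_variant(self):
        var = cs.characterize_variant("ATGCTTCAGGGATGA", "ATGCTTCAG" + "X" * 0 + "GTAAGTCCCTTTCAG" + "GGATGA")
        assert var.protein == "MLQG"
        assert not var.has_ptc

    def test_ptc_flagged(self):
        cds = "ATG" + "AAA" * 8 + "TAA"
        variant = "ATG" + "TAA" + "AAA" * 6 + "TAA"
        var = cs.characterize_variant(variant, cds)
        assert var.has_ptc and var.protein == "M"

    def test_junction_bookkeeping_for_frame_preserving_deletion(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        intron = cs.CrypticIntron(
            cs.SpliceSiteCandidate("donor", 12, 0.0, "GT"),
            cs.SpliceSiteCandidate("acceptor", 24, 0.0, "AG"),
            12, 0.5, True,
        )
        var = cs.characterize_variant(cs.splice_out(cds, [intron]), cds, [intron])
        assert var.frame_preserving
        assert var.deleted_aa == 4
        assert var.junction_codon_index == 4
        assert var.junction_positions_nt == (12,)

    def test_too_short_variant_errors(self):
        with pytest.raises(ValueError, match="shorter than one codon"):
            cs.characterize_variant("AT", "ATGAAATAG")


# frozen average residue masses (independent of the implementation path)
AVG_RESIDUE_DA = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


class TestProteinMass:
    def test_glycine(self):
        assert cs.protein_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cs.protein_mass("")

    def test_nonstandard_residue_errors(self):
        with pytest.raises(ValueError, match="non-standard"):
            cs.protein_mass("ACDX")

    def test_water_bookkeeping_additivity(self):
        x, y = "MKWVTF", "ISLLFLFSSAYS"
        assert cs.protein_mass(x) + cs.protein_mass(y) == pytest.approx(
            cs.protein_mass(x + y) + 18.02, abs=0.01
        )

    def test_matches_residue_table_oracle(self):
        for protein in ("VVGGEDAKPGEHNIEETEHTEQKR", "MKWVTFISLL", "ACDEFGHIKLMNPQRSTVWY"):
            expected = sum(AVG_RESIDUE_DA[a] for a in protein) + 18.0153
            assert cs.protein_mass(protein) == pytest.approx(expected, abs=0.05)


class TestDigestTrypsin:
    def test_cleaves_after_k_and_r(self):
        assert cs.digest_trypsin("MKRGPR") == ["MK", "R", "GPR"]

    def test_proline_blocks_cleavage(self):
        assert cs.digest_trypsin("AKPR") == ["AKPR"]

    def test_junction_peptide_context_stays_uncut(self):
        # the AKP context keeps the junction-spanning region in one piece:
        # no cut after the K of ...DAK|P...
        protein = "SAR" + "VVGGEDAKPGEHNIEETEHTEQKR" + "STALDK"
        spanning = [p for p in cs.digest_trypsin(protein) if "DAKPGEH" in p]
        assert spanning == ["VVGGEDAKPGEHNIEETEHTEQK"]
        # the diagnostic MS peptide itself carries one missed cleavage
        assert "VVGGEDAKPGEHNIEETEHTEQKR" in cs.digest_trypsin(
            protein, missed_cleavages=1
        )

    def test_concatenation_identity_and_missed_cleavage_bound(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(1000):
            protein = "".join(rng.choice(aas, int(rng.integers(1, 80))))
            peptides = cs.digest_trypsin(protein)
            assert "".join(peptides) == protein
            for k in (1, 2):
                for pep in cs.digest_trypsin(protein, missed_cleavages=k):
                    internal = cs.digest_trypsin(pep)
                    assert len(internal) <= k + 1

    def test_matches_reference_cleavage_rule(self):
        """Cross-check against the pyteomics expasy trypsin rule."""
        from pyteomics.parser import cleave, expasy_rules

        rng = np.random.default_rng(6)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        n_checked = 0
        while n_checked < 50:
            protein = "".join(rng.choice(aas, 60))
            if "WKP" in protein or "MRP" in protein:
                continue  # expasy adds rare sub-exceptions at these contexts
            assert set(cs.digest_trypsin(protein)) == cleave(
                protein, expasy_rules["trypsin"], missed_cleavages=0
            )
            n_checked += 1


class TestJunctionPeptides:
    def _variant(self, junction_nt, protein):
        return cs.SpliceVariantModel(
            variant_seq="X", protein=protein, has_ptc=False, mass_da=0.0,
            frame_preserving=True, junction_positions_nt=(junction_nt,),
        )

    def test_straddling_peptide_returned(self):
        protein = "MAAAKWWWWR"
        var = self._variant(21, protein)  # junction inside WWWW
        peptides = cs.digest_trypsin(protein)
        assert cs.junction_peptides(var, peptides) == ["WWWWR"]

    def test_junction_at_cleavage_boundary_gives_empty_set(self):
        protein = "MAAAKWWWWR"
        var = self._variant(15, protein)  # junction exactly after ...K
        assert cs.junction_peptides(var, cs.digest_trypsin(protein)) == []

    def test_full_length_variant_has_no_junction_peptides(self):
        var = cs.SpliceVariantModel(
            variant_seq="X", protein="MAAAK", has_ptc=False, mass_da=0.0,
            frame_preserving=True, junction_positions_nt=(),
        )
        assert cs.junction_peptides(var, ["MAAAK"]) == []

    def test_frameshifted_variant_errors(self):
        var = cs.SpliceVariantModel(
            variant_seq="X", protein="MA", has_ptc=True, mass_da=0.0,
            frame_preserving=False,
        )
        with pytest.raises(ValueError, match="frameshift"):
            cs.junction_peptides(var, ["MA"])


class TestPlantedIntronRecovery:
    def test_planted_pair_ranks_first_with_consensus_context(self, toy_atlas):
        from hskit import fixtures as fx

        dpfm, apfm = toy_atlas["donor_pfm"], toy_atlas["acceptor_pfm"]
        dcons = sa.consensus_window(dpfm)[9:]
        acons = sa.consensus_window(apfm)[:9]
        for seed in (0, 3, 11):
            cds, truth = fx.make_cds_with_cryptic_intron(
                cds_len=900, intron_len=132, intron_gc=0.39,
                donor_context=dcons, acceptor_context=acons, seed=seed,
            )
            cands = cs.scan_candidates(cds, dpfm, apfm)
            introns = cs.enumerate_cryptic_introns(cds, cands, cands, min_len=50)
            planted = (truth.items["donor_pos"], truth.items["acceptor_pos"])
            assert planted in {i.interval for i in introns}
            assert introns[0].interval == planted
            var = cs.characterize_variant(cs.splice_out(cds, [introns[0]]), cds, [introns[0]])
            assert var.deleted_aa == 44 and var.frame_preserving
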