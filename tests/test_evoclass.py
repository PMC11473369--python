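import itertools

import numpy as np
import pandas as pd
import pytest

from ribevol.evoclass import (EvoClassError, HomologyEvidence, OrfModel,
                              active_genes, assign_gene_age, assign_orf_age,
                              classify_structure, collapse_orfs,
                              inframe_intact_fraction, replicated_orfs)
from ribevol.pipeline import classify_genomes


def _fpkm(rows, samples=4, species="human"):
    df = pd.DataFrame(rows).T
    df.columns = [f"{species}_{i}" for i in range(samples)]
    return df, pd.Series(species, index=df.columns)


class TestActiveGenes:
    def test_rule_arithmetic(self):
        fpkm, species = _fpkm({
            "kept": [0.6, 0.6, 0.6, 2.9],     # mean 1.175, 3 reps >= 0.5
            "one_rep": [4.0, 0.0, 0.0, 0.0],  # mean 1.0 but 1 rep >= 0.5
            "low_mean": [0.4, 0.4, 0.4, 0.4],  # mean < 1
        })
        out = active_genes(fpkm, species)
        assert out["human"] == {"kept"}

    def test_too_few_replicates_errors(self):
        fpkm, species = _fpkm({"g": [1.0, 1.0]}, samples=2)
        with pytest.raises(EvoClassError, match="unsatisfiable"):
            active_genes(fpkm, species)

    def test_min_reps_override(self):
        fpkm, species = _fpkm({"g": [2.0, 2.0]}, samples=2)
        out = active_genes(fpkm, species, min_reps=2)
        assert out["human"] == {"g"}


def _orf(orf_id, start, length_codons, start_codon="ATG", strand="+",
         host="host", species="human"):
    return OrfModel(orf_id, host, species, "chr1", strand,
                    [(start, start + 3 * length_codons)],
                    start_codon=start_codon, n_samples_predicted=3)


class TestReplicatedOrfs:
    @pytest.mark.parametrize("n_pred,host,expected", [
        (3, "active_host", True),
        (5, "inactive_host", False),
        (2, "active_host", False),
    ])
    def test_rules(self, n_pred, host, expected):
        orf = OrfModel("o", host, "human", "chr1", "+", [(0, 30)],
                       n_samples_predicted=n_pred)
        kept = replicated_orfs([orf], {"human": {"active_host"}})
        assert (len(kept) == 1) == expected


class TestCollapseOrfs:
    def test_aug_priority_beats_length(self):
        # 60-codon AUG and 63-codon GUG ORFs sharing 58 in-frame codons
        aug = _orf("aug", 30, 60)
        gug = _orf("gug", 24, 63, start_codon="GTG")
        # shared in-frame positions: codon starts 30,33,... overlap region
        rep = collapse_orfs([aug, gug])
        assert rep["aug"] == rep["gug"] == "aug"

    def test_below_threshold_not_merged(self):
        a = _orf("a", 0, 50)
        b = _orf("b", 60, 50)  # frame-compatible but only 30/50 shared
        assert collapse_orfs([a, b])["a"] != collapse_orfs([a, b])["b"]

    def test_equal_aug_orfs_lexicographic_tiebreak(self):
        a = _orf("orfB", 0, 50)
        b = _orf("orfA", 0, 50)
        rep = collapse_orfs([a, b])
        assert rep["orfB"] == "orfA"

    def test_different_frame_never_merged(self):
        a = _orf("a", 0, 50)
        b = _orf("b", 1, 50)  # shifted by 1 nt: no shared codon starts
        rep = collapse_orfs([a, b])
        assert rep["a"] == "a" and rep["b"] == "b"

    def test_order_independence(self):
        orfs = [_orf("x", 0, 40), _orf("y", 3, 40), _orf("z", 200, 20),
                _orf("w", 6, 40, start_codon="CTG")]
        base = collapse_orfs(orfs)
        for perm in itertools.permutations(orfs):
            assert collapse_orfs(list(perm)) == base

    def test_transitive_closure(self):
        # a~b and b~c but a!~c directly: all one group
        a = _orf("a", 0, 40)
        b = _orf("b", 3, 40)
        c = _orf("c", 6, 41)
        rep = collapse_orfs([a, b, c])
        assert len(set(rep.values())) == 1


class TestInframeIntactFraction:
    def test_identical_counterpart(self):
        assert inframe_intact_fraction(10, "ATG" + "GCT" * 9) == 1.0

    def test_stop_at_codon_20(self):
        seq = "ATG" + "GCT" * 19 + "TAA" + "GCT" * 79
        assert inframe_intact_fraction(100, seq) == pytest.approx(0.20)

    def test_single_nt_deletion_frameshift(self):
        # 1-nt gap inside codon 30 with no later restoration
        seq = "ATG" + "GCT" * 29 + "G-T" + "GCT" * 69
        assert inframe_intact_fraction(100, seq) == pytest.approx(0.30)

    def test_inframe_3nt_gap_not_disrupting(self):
        # full-codon deletion keeps the frame; downstream stays intact
        seq = "ATG" + "GCT" * 10 + "---" + "GCT" * 8
        frac = inframe_intact_fraction(20, seq)
        assert frac == pytest.approx(19 / 20)  # one codon's worth missing

    def test_stop_after_frameshift_ignored(self):
        # frameshift at codon 2 dominates a later stop
        seq = "ATG" + "G-T" + "GCT" * 5 + "TAA" + "GCT" * 2
        assert inframe_intact_fraction(10, seq) == pytest.approx(0.1)


def _evidence(orf_id, fractions: dict[str, str | None]):
    out = []
    for sp, seq in fractions.items():
        out.append(HomologyEvidence(
            feature_id=orf_id, target_species=sp,
            liftover_status="unique_full" if seq is not None else "none",
            counterpart_sequence=seq))
    return out


class TestClassifyStructure:
    def test_orphan_when_never_aligned(self):
        orf = _orf("o", 0, 10)
        structure, fractions = classify_structure(
            orf, _evidence("o", {"chimp": None, "mouse": None}))
        assert structure == "orphan" and fractions == {}

    def test_de_novo_when_all_truncated(self):
        orf = _orf("o", 0, 10)
        trunc = "ATG" + "TAA" + "GCT" * 8  # stop at codon 1 -> fraction 0.1
        structure, fractions = classify_structure(
            orf, _evidence("o", {"chimp": trunc, "rhesus": trunc}))
        assert structure == "de_novo"
        assert all(f <= 0.3 for f in fractions.values())

    def test_intact_when_any_preserved_under_all_rule(self):
        orf = _orf("o", 0, 10)
        trunc = "ATG" + "TAA" + "GCT" * 8
        full = "ATG" + "GCT" * 9
        ev = _evidence("o", {"chimp": trunc, "rhesus": full})
        assert classify_structure(orf, ev)[0] == "intact"
        assert classify_structure(orf, ev, rule="any")[0] == "de_novo"

    def test_raising_cutoff_shrinks_de_novo_set(self):
        orf = _orf("o", 0, 10)
        seqs = ["ATG" + "GCT" * (k - 1) + "TAA" + "GCT" * (9 - k)
                for k in range(1, 9)]
        calls = []
        for cutoff in (0.5, 0.7, 0.9):
            n = sum(classify_structure(
                orf, _evidence("o", {"chimp": s}),
                truncation_cutoff=cutoff)[0] == "de_novo" for s in seqs)
            calls.append(n)
        assert calls == sorted(calls, reverse=True)


class TestAgeCalls:
    def test_no_evidence_is_species_specific(self):
        assert assign_gene_age([], "g1", "human") == "species_specific"

    def test_chimp_transcribed_homolog_is_hominini(self):
        ev = [HomologyEvidence("g", "chimp", "unique_full",
                               target_feature="g_chimp",
                               target_transcribed=True)]
        assert assign_gene_age(ev, "g", "human") == "hominini_specific"

    def test_rhesus_homolog_is_preserved(self):
        ev = [HomologyEvidence("g", "rhesus", "unique_full",
                               target_feature="g_rhesus",
                               target_transcribed=True)]
        assert assign_gene_age(ev, "g", "human") == "preserved"

    def test_blast_above_cutoff_not_a_homolog(self):
        # E-value 1e-3 only, no liftover: fails the 1e-4 rule upstream, so
        # the evidence row carries no transcribed flag
        ev = [HomologyEvidence("g", "chimp", "none", blast_best_evalue=1e-3,
                               target_transcribed=False)]
        assert assign_gene_age(ev, "g", "human") == "species_specific"

    def test_orf_counterpart_reads_force_preserved(self):
        ev = [HomologyEvidence("o", "chimp", "unique_full",
                               counterpart_pooled_riboseq_reads=12)]
        assert assign_orf_age(ev, "o", "human") == "preserved"

    def test_orf_low_reads_stay_young(self):
        ev = [HomologyEvidence("o", "chimp", "unique_full",
                               counterpart_pooled_riboseq_reads=3)]
        assert assign_orf_age(ev, "o", "human") == "species_specific"

    def test_orf_hominini_with_quiet_rhesus_counterpart(self):
        ev = [HomologyEvidence("o", "chimp", "unique_full",
                               target_feature="o_chimp",
                               target_translated=True,
                               counterpart_pooled_riboseq_reads=50),
              HomologyEvidence("o", "rhesus", "unique_full",
                               counterpart_pooled_riboseq_reads=3)]
        assert assign_orf_age(ev, "o", "human") == "hominini_specific"


class TestEndToEndToyGenomes:
    def test_all_calls_match_planted_truth(self, toy_genomes):
        calls = classify_genomes(toy_genomes)
        merged = calls.merge(toy_genomes.truth, on="feature_id")
        assert (merged["age"] == merged["true_age"]).all()
        young_sorfs = merged[(merged["kind_x"] == "sorf")
                             & merged["age"].isin(["species_specific",
                                                   "hominini_specific"])]
        assert (young_sorfs["structure"]
                == young_sorfs["true_structure"]).all()
        preserved = merged[merged["age"] == "preserved"]
        assert preserved["structure"].isna().all()

    def test_intact_fraction_matches_engineered_value(self, toy_genomes):
        calls = classify_genomes(toy_genomes).set_index("feature_id")
        truth = toy_genomes.truth.set_index("feature_id")
        for fid in ("sorf3_human", "sorf5_rhesus"):
            expected = truth.loc[fid, "expected_intact_fraction"]
            orf = next(o for o in toy_genomes.orfs if o.orf_id == fid)
            tol = 1.0 / orf.length_codons  # within one codon
            assert abs(calls.loc[fid, "min_intact_fraction"]
                       - expected) <= tol
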