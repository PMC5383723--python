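"""Locus diversity statistics against brute-force and analytic oracles."""

import itertools
from collections import Counter

import numpy as np
import pytest

from duosnp.popgen import (
    CdsModel,
    LocusAlignment,
    codon_effect,
    collapse_haplotypes,
    haplotype_diversity,
    indel_events,
    nucleotide_diversity,
    segregating_sites,
    summarize_locus,
    trim_alignment,
    watterson_theta,
)
from conftest import random_alignment


def aln_of(seqs, name="locus"):
    return LocusAlignment(name=name, names=[f"s{i}" for i in range(len(seqs))],
                          seqs=list(seqs))


def brute_pi(seqs):
    """Double loop over all sequence pairs, gap/N columns excluded."""
    length = len(seqs[0])
    cols = [j for j in range(length) if all(s[j] in "ACGT" for s in seqs)]
    diffs = sum(sum(1 for j in cols if a[j] != b[j])
                for a, b in itertools.combinations(seqs, 2))
    n = len(seqs)
    return diffs / (n * (n - 1) / 2) / len(cols)


class TestSegregatingSites:
    def test_transition_column(self):
        seqs = ["A" * 20] * 46 + ["A" * 9 + "G" + "A" * 10] * 6
        sites = segregating_sites(aln_of(seqs))
        assert len(sites) == 1
        assert sites[0].column == 10
        assert sites[0].change_class == "transition"
        assert sites[0].alleles == (("A", 46), ("G", 6))

    def test_transversion_and_multiallelic(self):
        base = "C" * 10
        seqs = [base, base, "C" * 4 + "A" + "C" * 5, "C" * 4 + "T" + "C" * 5]
        (s,) = segregating_sites(aln_of(seqs))
        assert s.change_class == "multiallelic"  # C, A and T all observed
        seqs = [base, base, base, "C" * 4 + "A" + "C" * 5]
        (s,) = segregating_sites(aln_of(seqs))
        assert s.change_class == "transversion"

    def test_planted_ts_tv_composition_recovered(self, rng):
        bases = np.array(list("ACGT"))
        background = rng.choice(bases, size=200)
        rows = np.tile(background, (12, 1))
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        transversion = {"A": "T", "G": "C", "C": "A", "T": "G"}
        cols = rng.choice(200, size=10, replace=False)
        for i, c in enumerate(cols):
            table = transition if i < 3 else transversion
            carriers = rng.choice(12, size=5, replace=False)
            for r in carriers:
                rows[r, c] = table[background[c]]
        sites = segregating_sites(aln_of(["".join(r) for r in rows]))
        assert {s.column for s in sites} == {c + 1 for c in cols}
        by_class = Counter(s.change_class for s in sites)
        assert by_class == {"transition": 3, "transversion": 7}

    def test_gap_and_n_columns_excluded(self):
        seqs = ["ACGT", "AC-T", "ANGT", "TCGT"]
        sites = segregating_sites(aln_of(seqs))
        # only columns 4 (all clean, monomorphic) and 1 (has variation but
        # clean) are analyzed; columns 2 and 3 carry N or gap
        assert [s.column for s in sites] == [1]
        assert aln_of(seqs).net_length == 2


class TestTrim:
    def test_window_reduces_analyzed_length(self):
        seqs = ["A" * 952] * 5
        trimmed = trim_alignment(aln_of(seqs), (52, 900))
        assert trimmed.length == 849

    def test_identity_window_is_noop(self):
        a = aln_of(["ACGTACGT"] * 3)
        assert trim_alignment(a, (1, 8)).seqs == a.seqs

    def test_trimming_away_the_only_snp_drops_s(self):
        seqs = ["AAAA"] * 4 + ["GAAA"] * 2
        assert len(segregating_sites(aln_of(seqs))) == 1
        trimmed = trim_alignment(aln_of(seqs), (2, 4))
        assert segregating_sites(trimmed) == []

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            trim_alignment(aln_of(["ACGT"] * 2), (3, 2))


class TestIndels:
    def test_gap_free_alignment_has_none(self):
        assert indel_events(aln_of(["ACGT" * 10] * 6)) == 0

    def test_single_gap_run_is_one_event(self):
        seqs = ["ACGTACGTAC"] * 5 + ["ACG---GTAC"[:10]]
        assert indel_events(aln_of(seqs)) == 1

    def test_shared_identical_runs_merge(self):
        seqs = ["ACGTACGTAC"] * 4 + ["ACG---GTAC"[:10]] * 2
        assert indel_events(aln_of(seqs)) == 1

    def test_distinct_runs_count_separately(self):
        seqs = ["ACGTACGTAC"] * 4 + ["AC--ACGTAC", "ACGTAC--AC"]
        assert indel_events(aln_of(seqs)) == 2


class TestPi:
    def test_monomorphic_alignment_is_zero(self):
        assert nucleotide_diversity(aln_of(["ACGT" * 5] * 8)) == 0.0

    def test_matches_double_loop_oracle_on_random_alignments(self, rng):
        for _ in range(25):
            seqs = random_alignment(rng, n=int(rng.integers(3, 12)),
                                    length=int(rng.integers(20, 120)),
                                    n_variable=int(rng.integers(0, 10)))
            assert nucleotide_diversity(aln_of(seqs)) == pytest.approx(
                brute_pi(seqs), abs=1e-12)

    def test_single_site_pi_equals_hd_identity(self):
        # for one biallelic site: pi * L = 2k(n-k)/(n(n-1)) = Hd
        for n, k, L in [(52, 6, 654), (51, 6, 459), (20, 7, 100)]:
            seqs = (["A" * L] * (n - k)
                    + [("T" + "A" * (L - 1))] * k)
            a = aln_of(seqs)
            pi = nucleotide_diversity(a)
            hd = haplotype_diversity(collapse_haplotypes(a))
            expected = 2 * k * (n - k) / (n * (n - 1))
            assert pi * L == pytest.approx(expected, abs=1e-12)
            assert hd == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_sequence_reordering(self, rng):
        seqs = random_alignment(rng, n=9, length=60)
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        assert nucleotide_diversity(aln_of(seqs)) == pytest.approx(
            nucleotide_diversity(aln_of(shuffled)), abs=1e-15)

    def test_removing_monomorphic_column_only_rescales(self, rng):
        seqs = random_alignment(rng, n=8, length=50, n_variable=5)
        a = aln_of(seqs)
        mono = next(j for j in range(50)
                    if len({s[j] for s in seqs}) == 1)
        cut = aln_of([s[:mono] + s[mono + 1:] for s in seqs])
        assert len(segregating_sites(a)) == len(segregating_sites(cut))
        assert nucleotide_diversity(a) * a.net_length == pytest.approx(
            nucleotide_diversity(cut) * cut.net_length, abs=1e-12)


class TestWatterson:
    @pytest.mark.parametrize("S, n, L, expected", [
        (1, 52, 654, 0.00034),
        (2, 54, 626, 0.0007),
        (1, 51, 459, 0.00048),
    ])
    def test_reported_locus_values(self, S, n, L, expected):
        digits = len(str(expected).split(".")[1])
        assert round(watterson_theta(S, n, L), digits) == expected

    def test_zero_segregating_sites(self):
        assert watterson_theta(0, 10, 500) == 0.0

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 1, 100)

    def test_agrees_with_pi_under_neutral_coalescent(self):
        """theta_w and pi estimate the same parameter; over 200 neutral
        coalescent loci their means should agree within a factor of two."""
        import msprime

        pis, thetas = [], []
        L = 1000
        for seed in range(1, 201):
            ts = msprime.sim_ancestry(
                samples=10, ploidy=1, population_size=1.0,
                sequence_length=L, random_seed=seed)
            mts = msprime.sim_mutations(
                ts, rate=5 / (4 * L), random_seed=seed,
                model=msprime.BinaryMutationModel())
            rows = np.full((10, L), "A")
            for var in mts.variants():
                col = int(var.site.position)
                alleles = np.array(["A", "G"])
                rows[:, col] = alleles[np.minimum(var.genotypes, 1)]
            seqs = ["".join(r) for r in rows]
            a = aln_of(seqs)
            pis.append(nucleotide_diversity(a) * L)
            S = len(segregating_sites(a))
            thetas.append(watterson_theta(S, 10, a.net_length) * L)
        ratio = np.mean(thetas) / np.mean(pis)
        assert 0.5 < ratio < 2.0


class TestHaplotypes:
    def test_single_biallelic_site_two_haplotypes(self):
        seqs = ["A" * 10] * 46 + [("T" + "A" * 9)] * 6
        haps = collapse_haplotypes(aln_of(seqs))
        assert sorted(haps.values()) == [6, 46]
        assert round(haplotype_diversity(haps), 3) == 0.208

    def test_monomorphic_collapses_to_one(self):
        haps = collapse_haplotypes(aln_of(["ACGT"] * 7))
        assert len(haps) == 1
        assert haplotype_diversity(haps) == 0.0

    def test_three_haplotype_configuration(self):
        # 43 reference / 6 carrying site 1 / 5 carrying site 2
        ref = "A" * 20
        h1 = "G" + ref[1:]
        h2 = ref[:10] + "T" + ref[11:]
        a = aln_of([ref] * 43 + [h1] * 6 + [h2] * 5)
        haps = collapse_haplotypes(a)
        assert len(haps) == 3
        assert round(haplotype_diversity(haps), 3) == 0.352

    def test_all_distinct_haplotypes_give_exactly_one(self):
        assert haplotype_diversity(Counter({f"h{i}": 1 for i in range(9)})) == 1.0

    def test_invariant_under_relabeling(self):
        counts = {"AAT": 4, "GAT": 3, "AGT": 2}
        relabeled = {"x": 4, "y": 3, "z": 2}
        assert haplotype_diversity(counts) == haplotype_diversity(relabeled)

    def test_ambiguous_sequences_excluded_from_counting(self):
        seqs = ["A" * 10] * 5 + ["T" + "A" * 9] * 3 + ["N" + "A" * 9]
        a = aln_of(seqs)
        sites = [s for s in segregating_sites_force(a)]
        haps = collapse_haplotypes(a, sites)
        assert sum(haps.values()) == 8


def segregating_sites_force(aln):
    """Site detection ignoring the net-column rule, for the ambiguity test:
    a column that is polymorphic among unambiguous bases still defines a
    haplotype column even when one sequence carries N there."""
    from duosnp.popgen import SegregatingSite

    out = []
    for j in range(aln.length):
        obs = Counter(s[j] for s in aln.seqs if s[j] in "ACGT")
        if len(obs) >= 2:
            out.append(SegregatingSite(
                column=j + 1,
                alleles=tuple(sorted(obs.items(), key=lambda kv: -kv[1])),
                change_class="transversion"))
    return out


class TestCodonEffects:
    def cds(self, length, intron=None, frame=0, strand="+"):
        if intron is None:
            return CdsModel(intervals=[(1, length)], frame=frame, strand=strand)
        s, e = intron
        return CdsModel(intervals=[(1, s - 1), (e + 1, length)],
                        frame=frame, strand=strand)

    def build(self, codons_major, codons_minor, site_offset, k_minor=2, n=8):
        ref = "".join(codons_major)
        alt = ref[:site_offset] + codons_minor + ref[site_offset + 1:]
        return aln_of([ref] * (n - k_minor) + [alt] * k_minor)

    def test_glu_to_asp_nonsynonymous(self):
        a = self.build(["GAA", "CCC"], "T", 2)  # GAA -> GAT at codon pos 3
        (s,) = segregating_sites(a)
        annotated = codon_effect(s, self.cds(6), a)
        assert annotated.effect == "nonsynonymous"
        assert annotated.aa_change == ("E", "D")

    def test_wobble_synonymous(self):
        a = self.build(["GCC", "CCC"], "T", 2)  # GCC -> GCT
        (s,) = segregating_sites(a)
        assert codon_effect(s, self.cds(6), a).effect == "synonymous"

    def test_ala_to_val_nonsynonymous(self):
        a = self.build(["GCA", "CCC"], "T", 1)  # GCA -> GTA at codon pos 2
        (s,) = segregating_sites(a)
        annotated = codon_effect(s, self.cds(6), a)
        assert annotated.effect == "nonsynonymous"
        assert annotated.aa_change == ("A", "V")

    def test_intron_site_is_noncoding(self):
        ref = "GAAGGGCCC"
        alt = "GAAGTGCCC"
        a = aln_of([ref] * 5 + [alt] * 2)
        (s,) = segregating_sites(a)
        model = self.cds(9, intron=(4, 6))
        assert codon_effect(s, model, a).effect == "noncoding"

    def test_partial_terminal_codon_is_na(self):
        ref = "GAAGG"
        alt = "GAAGT"
        a = aln_of([ref] * 4 + [alt] * 2)
        (s,) = segregating_sites(a)
        assert codon_effect(s, self.cds(5), a).effect == "NA"

    def test_minus_strand_translation(self):
        # plus-strand TTC at cols 1-3; minus strand reads revcomp = GAA (Glu);
        # variant T->A at col 1 gives revcomp GAT? col1 is last read position
        ref = "TTCCCC"
        alt = "ATCCCC"
        a = aln_of([ref] * 5 + [alt] * 2)
        (s,) = segregating_sites(a)
        annotated = codon_effect(s, self.cds(6, strand="-"), a)
        assert annotated.effect == "nonsynonymous"
        assert annotated.aa_change[0] == "E"


class TestSummarize:
    def test_single_transversion_locus_reconstruction(self):
        seqs = ["C" * 654] * 46 + ["C" * 299 + "A" + "C" * 354] * 6
        summary = summarize_locus(aln_of(seqs, name="hsf-like"))
        row = summary.table_row()
        assert row["n_snps"] == 1 and row["transversions"] == 1
        assert row["n_haplotypes"] == 2
        assert row["snp_frequency"] == "1/654"
        assert row["pi"] == 0.00032 and row["theta_w"] == 0.00034
        assert row["haplotype_diversity"] == 0.208

    def test_seed_size_locus_reconstruction(self):
        seqs = ["G" * 459] * 45 + ["G" * 119 + "C" + "G" * 339] * 6
        row = summarize_locus(aln_of(seqs)).table_row()
        assert row["pi"] == 0.00046
        assert row["haplotype_diversity"] == 0.212

    def test_summary_consistent_with_component_operations(self, rng):
        for _ in range(10):
            seqs = random_alignment(rng, n=int(rng.integers(4, 10)),
                                    length=80, n_variable=6)
            a = aln_of(seqs)
            summary = summarize_locus(a)
            sites = segregating_sites(a)
            assert summary.n_segregating == len(sites)
            assert summary.pi == nucleotide_diversity(a)
            assert summary.theta_w == watterson_theta(len(sites), a.n,
                                                      a.net_length)
            haps = collapse_haplotypes(a)
            assert summary.n_haplotypes == len(haps)
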