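"""DR taxonomy, host calls, PAM inference, scrambling and the sweep."""

import numpy as np
import pytest

from crisprmge.crispr import DirectRepeat, Spacer
from crisprmge.hostpam import (Lineage, RANKS, UNASSIGNED, assign_dr_taxonomy,
                               call_host, infer_pam, remnant_sweep, scramble)
from crisprmge.protospacer import ProtospacerLocus
from crisprmge.seqcore import Interval, SeqRecord, canonical, revcomp

from conftest import random_dna


def lineage(phylum: str, tag: str = "x") -> Lineage:
    return Lineage(("Bacteria", phylum, f"c{tag}", f"o{tag}", f"f{tag}",
                    f"g{tag}", f"s{tag}"))


def genome_with_array(rng, gid: str, dr: str, n_copies: int,
                      spacer_len: int = 35) -> SeqRecord:
    parts = [random_dna(rng, 2000), dr]
    for _ in range(n_copies - 1):
        parts += [random_dna(rng, spacer_len), dr]
    parts.append(random_dna(rng, 2000))
    return SeqRecord(gid, "".join(parts))


def make_locus(spacer_id: str, dr_ids, start=0, strand="+", contig="c"):
    return ProtospacerLocus(spacer_id,
                            Interval(contig, start, start + 30, strand),
                            1.0, validated=True, dr_ids=frozenset(dr_ids))


class TestDrTaxonomy:
    def test_single_phylum_assigned(self, rng):
        dr = DirectRepeat("DR1", random_dna(rng, 32))
        genomes = [genome_with_array(rng, "g1", dr.seq, 5),
                   genome_with_array(rng, "g2", dr.seq, 4)]
        lineages = {"g1": lineage("Firmicutes", "1"),
                    "g2": lineage("Firmicutes", "2")}
        tax = assign_dr_taxonomy([dr], genomes, lineages)[0]
        assert tax.assignment["phylum"] == "Firmicutes"
        assert tax.assignment["domain"] == "Bacteria"
        assert tax.assignment["genus"] == UNASSIGNED  # genomes disagree

    def test_conflicting_phyla_unassigned(self, rng):
        dr = DirectRepeat("DR1", random_dna(rng, 32))
        genomes = [genome_with_array(rng, "g1", dr.seq, 5),
                   genome_with_array(rng, "g2", dr.seq, 4)]
        lineages = {"g1": lineage("Firmicutes", "1"),
                    "g2": lineage("Verrucomicrobia", "2")}
        tax = assign_dr_taxonomy([dr], genomes, lineages)[0]
        assert tax.assignment["phylum"] == UNASSIGNED
        assert tax.assignment["domain"] == "Bacteria"

    def test_isolated_hits_do_not_support(self, rng):
        """Two DR copies far apart are not a validated CRISPR locus."""
        dr = DirectRepeat("DR1", random_dna(rng, 32))
        seq = (random_dna(rng, 1000) + dr.seq + random_dna(rng, 2000)
               + dr.seq + random_dna(rng, 1000))
        tax = assign_dr_taxonomy([dr], [SeqRecord("g1", seq)],
                                 {"g1": lineage("Firmicutes")})[0]
        assert all(v == UNASSIGNED for v in tax.assignment.values())
        assert tax.supporting_loci == []

    def test_missing_lineage_errors(self, rng):
        dr = DirectRepeat("DR1", random_dna(rng, 32))
        with pytest.raises(ValueError):
            assign_dr_taxonomy([dr], [SeqRecord("g1", random_dna(rng, 1000))],
                               {})


class TestCallHost:
    def _taxonomies(self, rng, mapping):
        out = []
        for dr_id, phylum in mapping.items():
            dr = DirectRepeat(dr_id, random_dna(rng, 32))
            genome = genome_with_array(rng, f"g_{dr_id}", dr.seq, 4)
            tax = assign_dr_taxonomy([dr], [genome],
                                     {genome.id: lineage(phylum, dr_id)})[0]
            out.append(tax)
        return out

    def test_unanimous_loci_call_taxon(self, rng):
        taxes = self._taxonomies(rng, {"DR1": "Firmicutes"})
        loci = [make_locus(f"s{i}", ["DR1"], start=100 * i) for i in range(12)]
        call = call_host("tr1", loci, taxes, "phylum")
        assert call.call == "Firmicutes"
        assert call.assigned_protospacers == 12
        assert call.top_fraction == 1.0

    def test_nine_assigned_loci_is_na(self, rng):
        taxes = self._taxonomies(rng, {"DR1": "Firmicutes"})
        loci = [make_locus(f"s{i}", ["DR1"], start=100 * i) for i in range(9)]
        assert call_host("tr1", loci, taxes, "phylum").call == "NA"

    def test_mixed_taxa_ambiguous(self, rng):
        taxes = self._taxonomies(rng, {"DR1": "Firmicutes",
                                       "DR2": "Bacteroidetes"})
        loci = [make_locus(f"a{i}", ["DR1"], start=100 * i) for i in range(8)] \
            + [make_locus(f"b{i}", ["DR2"], start=5000 + 100 * i)
               for i in range(7)]
        call = call_host("tr1", loci, taxes, "phylum")
        assert call.call == "AMBIGUOUS"
        assert call.top_fraction == pytest.approx(8 / 15)

    def test_exclusiveness_boundary_is_strict(self, rng):
        """Exactly 90% exclusiveness is AMBIGUOUS; above 90% is a call."""
        taxes = self._taxonomies(rng, {"DR1": "Firmicutes",
                                       "DR2": "Bacteroidetes"})
        nine_one = [make_locus(f"a{i}", ["DR1"], start=100 * i)
                    for i in range(9)] \
            + [make_locus("b0", ["DR2"], start=5000)]
        assert call_host("t", nine_one, taxes, "phylum").call == "AMBIGUOUS"
        ten_one = nine_one + [make_locus("a9", ["DR1"], start=2000)]
        assert call_host("t", ten_one, taxes, "phylum").call == "Firmicutes"

    def test_count_boundary_at_ten(self, rng):
        taxes = self._taxonomies(rng, {"DR1": "Firmicutes"})
        ten = [make_locus(f"s{i}", ["DR1"], start=100 * i) for i in range(10)]
        assert call_host("t", ten, taxes, "phylum").call == "Firmicutes"
        assert call_host("t", ten[:9], taxes, "phylum").call == "NA"

    def test_rank_monotone_assignment(self, rng):
        """Loci assigned at a lower rank stay assigned at higher ranks."""
        taxes = self._taxonomies(rng, {"DR1": "Firmicutes",
                                       "DR2": "Firmicutes"})
        loci = [make_locus(f"s{i}", ["DR1" if i % 2 else "DR2"],
                           start=100 * i) for i in range(12)]
        upper = None
        for rank in reversed(RANKS):  # species up to domain
            n = call_host("t", loci, taxes, rank).assigned_protospacers
            if upper is not None:
                assert n >= upper
            upper = n


class TestPam:
    def test_single_protospacer_literal_flanks(self, rng):
        seq = random_dna(rng, 200)
        loci = [make_locus("s1", ["DR1"], start=100)]
        p5, p3 = infer_pam("t", loci, {"c": seq})
        assert p5.low_support and p5.n_protospacers == 1
        expected5 = seq[90:100]
        got5 = "".join("ACGT"[int(np.argmax(row))] for row in p5.counts)
        assert got5 == expected5
        expected3 = seq[130:140]
        got3 = "".join("ACGT"[int(np.argmax(row))] for row in p3.counts)
        assert got3 == expected3

    def test_minus_strand_orientation(self, rng):
        seq = random_dna(rng, 200)
        loci = [make_locus("s1", ["DR1"], start=100, strand="-")]
        p5, _ = infer_pam("t", loci, {"c": seq})
        got5 = "".join("ACGT"[int(np.argmax(row))] for row in p5.counts)
        assert got5 == revcomp(seq[130:140])

    def test_uniform_flanks_give_all_n_consensus(self, rng):
        seq = random_dna(rng, 20_000)
        loci = [make_locus(f"s{i}", ["DR1"], start=50 + 150 * i)
                for i in range(100)]
        p5, p3 = infer_pam("t", loci, {"c": seq})
        assert p5.consensus() == "N" * 10
        assert p3.consensus() == "N" * 10


class TestScramble:
    def test_lengths_and_determinism(self, rng):
        recs = [SeqRecord(f"r{i}", random_dna(rng, int(rng.integers(100, 2000))))
                for i in range(10)]
        a = scramble(recs, seed=9)
        b = scramble(recs, seed=9)
        assert [len(x.seq) for x in a] == [len(r.seq) for r in recs]
        assert [x.seq for x in a] == [y.seq for y in b]
        assert scramble(recs, seed=10)[0].seq != a[0].seq

    def test_aggregate_frequencies_preserved(self, rng):
        # GC-rich input: scrambled output mirrors the skewed composition
        seq = "".join(rng.choice(list("GGGCCCAT"), size=1_000_000))
        out = scramble([SeqRecord("r", seq)], seed=3)[0].seq
        for b in "ACGT":
            assert abs(out.count(b) / len(out) - seq.count(b) / len(seq)) < 0.02


class TestRemnantSweep:
    def test_threshold_arithmetic_and_monotonicity(self, rng):
        target = random_dna(rng, 5000)
        exact = target[1000:1030]
        mut = list(target[2000:2030])
        for p in (3, 9, 17, 25):
            mut[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[p]]
        mutated = "".join(mut)  # 26/30 = 86.7% identity
        spacers = [Spacer("exact", canonical(exact), oriented_seq=exact),
                   Spacer("mut", canonical(mutated), oriented_seq=mutated)]
        table = remnant_sweep(spacers, [SeqRecord("t", target)], [])
        counts = dict(zip(table.threshold, table.mapped_to_TR))
        assert counts[1.00] == 1          # only the exact spacer
        assert counts[0.87] == 1
        assert counts[0.86] == 2          # mutated spacer enters at 86%
        assert counts[0.80] == 2
        assert (np.diff(table.mapped_to_TR) <= 0).all()
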