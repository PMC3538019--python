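"""In-silico PCR-RFLP: primer location, amplification, digestion, calling."""
import numpy as np
import pandas as pd
import pytest
from Bio import Restriction
from Bio.Seq import Seq
from pyroaei._sequence import find_sites, random_seq, revcomp
from pyroaei.errors import (
    AmbiguousAmplificationError,
    AssayError,
    NoAmplificationError,
    UninformativeAssayError,
)
from pyroaei.io_formats import EnzymeRecord, builtin_enzymes, get_enzyme
from pyroaei.rflp_genotyping import (
    FragmentPattern,
    PrimerPair,
    amplify,
    call_genotype,
    digest,
    genotype_population,
    locate_primers,
    select_heterozygotes,
)
from pyroaei.synthetic_data import (
    PopulationSpec,
    SnpSpec,
    generate_rflp_template,
    simulate_genotypes,
)

MSE_I = get_enzyme("MseI")


# ---------------------------------------------------------------------------
# primer location and amplification
# ---------------------------------------------------------------------------

FWD = "ACGTACGTACGTAGGC"
REV = "TTCCGGAATTGCAGGT"  # appears as its reverse complement on the template


def _template(middle: str) -> str:
    return "GG" + FWD + middle + revcomp(REV) + "AA"


def test_locate_verbatim_primer():
    t = _template("TTTTTTTTTT")
    pair = PrimerPair(forward=FWD, reverse=REV)
    start, end = locate_primers(t, pair)
    assert (start, end) == (2, len(t) - 2)


def test_locate_with_forced_mismatch():
    t = _template("TTTTTTTTTT")
    # primer carries a G where the template has the original base, 4 from the 3' end
    mutated = FWD[:-5] + "G" + FWD[-4:]
    assert mutated != FWD
    pair = PrimerPair(forward=mutated, reverse=REV, forward_forced=((4, "G"),))
    start, _ = locate_primers(t, pair)
    assert start == 2
    # without declaring the forced position the same primer fails
    with pytest.raises(NoAmplificationError):
        locate_primers(t, PrimerPair(forward=mutated, reverse=REV))


def test_duplicated_primer_site_is_ambiguous():
    t = _template("TT" + FWD + "TT")
    with pytest.raises(AmbiguousAmplificationError):
        locate_primers(t, PrimerPair(forward=FWD, reverse=REV))


def test_no_amplification():
    with pytest.raises(NoAmplificationError):
        locate_primers("A" * 100, PrimerPair(forward=FWD, reverse=REV))


def test_amplicon_equals_template_span_without_forced():
    t = _template("TTTTGGGGCCCC")
    amp = amplify(t, PrimerPair(forward=FWD, reverse=REV))
    assert amp.sequence == t[2:-2]
    assert amp.coords_on_template == (2, len(t) - 2)


def test_forced_base_incorporated_into_product():
    t = _template("TTTTGGGGCCCC")
    mutated = FWD[:-4] + "G" + FWD[-3:]  # A -> G, 4th base from the 3' end
    assert mutated != FWD
    pair = PrimerPair(forward=mutated, reverse=REV, forward_forced=((3, "G"),))
    amp = amplify(t, pair)
    span = t[2:-2]
    diffs = [i for i, (a, b) in enumerate(zip(amp.sequence, span)) if a != b]
    assert diffs == [len(FWD) - 4]  # exactly the forced position


def test_allele_pair_amplicons_differ_only_at_snp():
    mid_a, mid_b = "TTTTGTTTT", "TTTTCTTTT"
    pair = PrimerPair(forward=FWD, reverse=REV)
    amp_a = amplify(_template(mid_a), pair)
    amp_b = amplify(_template(mid_b), pair)
    diffs = [i for i, (a, b) in enumerate(zip(amp_a.sequence, amp_b.sequence)) if a != b]
    assert diffs == [len(FWD) + 4]


def test_primer_validation():
    with pytest.raises(AssayError, match="shorter"):
        PrimerPair(forward="ACGT", reverse=REV)
    with pytest.raises(AssayError, match="forced"):
        PrimerPair(forward=FWD, reverse=REV, forward_forced=((9, FWD[-10]),))


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def test_digest_mse_i_hand_example():
    assert digest("GGTTAAGG", MSE_I).fragment_lengths == (3, 5)


def test_digest_no_site_single_fragment():
    assert digest("GGGGGGGG", MSE_I).fragment_lengths == (8,)


def test_digest_iupac_site_matches_brute_force_expansion():
    # Fnu4HI-style GCNGC; brute-force over every concrete N expansion
    enz = EnzymeRecord("Fnu4HI", "GCNGC", 2, 3)
    seq = "AAGCAGCAA"
    expected_sites = {
        i
        for base in "ACGT"
        for i in range(len(seq) - 4)
        if seq[i:i + 5] == f"GC{base}GC"
    }
    assert expected_sites == set(find_sites(seq, "GCNGC"))
    assert len(expected_sites) == 1
    assert len(digest(seq, enz).fragment_lengths) == 2  # exactly one cut


def test_digestion_conservation_random():
    """Fragment lengths always sum to the amplicon length."""
    rng = np.random.default_rng(1)
    enzymes = list(builtin_enzymes().values())
    for _ in range(300):
        seq = random_seq(rng, int(rng.integers(20, 400)))
        enz = enzymes[rng.integers(len(enzymes))]
        assert digest(seq, enz).total() == len(seq)


def test_palindromic_strand_equivalence():
    """Palindromic sites yield identical cut sets from plus- and minus-strand scans."""
    rng = np.random.default_rng(2)
    pals = [e for e in builtin_enzymes().values() if e.is_palindromic]
    for _ in range(200):
        seq = random_seq(rng, 300)
        enz = pals[rng.integers(len(pals))]
        rec = enz.recognition
        plus_cuts = {s + enz.cut_offset_top for s in find_sites(seq, rec)}
        minus_cuts = {s + len(rec) - enz.cut_offset_bottom for s in find_sites(seq, revcomp(rec))}
        assert plus_cuts == minus_cuts


def _site_destruction_possible(seq: str, enz) -> bool:
    """True if any site's cut lands inside another site's span (either strand):
    there the left-to-right destruction rule of complete digestion diverges
    from Bio.Restriction, which cuts every site."""
    L = len(enz.recognition)
    events = [(s, s + enz.cut_offset_top, s + enz.cut_offset_bottom)
              for s in find_sites(seq, enz.recognition)]
    events += [(s, s + L - enz.cut_offset_bottom, s + L - enz.cut_offset_top)
               for s in find_sites(seq, revcomp(enz.recognition))]
    spans = {(s, s + L) for s, _, _ in events}
    return any(
        a < cut < b
        for s, top, bottom in events
        for cut in (top, bottom)
        for (a, b) in spans
        if (a, b) != (s, s + L)
    )


ORACLE_ENZYMES = ["MseI", "RsaI", "HaeIII", "EcoRI", "HhaI", "DdeI", "HinfI", "AluI",
                  "PvuII", "SspI", "MspI", "NlaIII", "AciI", "AvaII", "AvaI", "EarI", "BccI"]


@pytest.mark.parametrize("name", ORACLE_ENZYMES)
def test_digest_agrees_with_biopython_restriction(name):
    """Independent oracle: Bio.Restriction digestion of random sequences,
    on the cases where no site-destruction interaction arises."""
    enz = builtin_enzymes()[name]
    bio = getattr(Restriction, name)
    rng = np.random.default_rng(1000 + ORACLE_ENZYMES.index(name))
    compared = 0
    for _ in range(40):
        seq = random_seq(rng, 250)
        if _site_destruction_possible(seq, enz):
            continue
        compared += 1
        mine = sorted(digest(seq, enz).fragment_lengths)
        # coincident cuts from opposite-orientation sites make Bio emit a
        # phantom zero-length fragment; a gel has no such band
        oracle = sorted(len(f) for f in bio.catalyse(Seq(seq), linear=True) if len(f) > 0)
        assert mine == oracle
    assert compared >= 20


def test_overlapping_sites_resolved_left_to_right():
    # TTAATTAA: MseI sites at 0 and 4; cutting the first (at 1) leaves the
    # second intact (cut 1 is outside span [4, 8)), so both are cut
    pat = digest("GG" + "TTAATTAA" + "GG", MSE_I)
    assert pat.total() == 12
    assert pat.fragment_lengths == (3, 4, 5)
    # GCGCGC: HhaI (GCG^C) sites at 0 and 2 overlap; the left cut at 3 falls
    # inside the right site's span [2, 6) and destroys it -> single cut
    pat = digest("GG" + "GCGCGC" + "GG", get_enzyme("HhaI"))
    assert pat.fragment_lengths == (5, 5)


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

A_PATTERN = FragmentPattern((3, 5))
B_PATTERN = FragmentPattern((8,))


@pytest.mark.parametrize(
    "observed, expected",
    [
        ((3, 5), "AA"),
        ((8,), "BB"),
        ((3, 5, 8), "AB"),
        ((4, 4), "ambiguous"),
    ],
)
def test_call_genotype(observed, expected):
    assert call_genotype(observed, A_PATTERN, B_PATTERN).call == expected


def test_uninformative_assay_rejected():
    with pytest.raises(UninformativeAssayError):
        call_genotype((3, 5), A_PATTERN, FragmentPattern((5, 3)))


def test_equal_length_fragments_merge_on_gel():
    # (4, 4) and (4,) are the same single band on a gel
    pat = FragmentPattern((4, 4))
    assert pat.gel_bands == frozenset({4})
    assert pat.fragment_lengths == (4, 4)  # but the report keeps both


# ---------------------------------------------------------------------------
# heterozygote selection
# ---------------------------------------------------------------------------

def _genotype_frame(n_het, n_total=40, gene="LEP"):
    calls = ["AB"] * n_het + ["AA"] * (n_total - n_het)
    return pd.DataFrame({gene: calls}, index=[f"B{i:02d}" for i in range(n_total)])


def test_minimum_qualifying_count_is_five_of_forty():
    sel = select_heterozygotes(_genotype_frame(5), min_het_fraction=0.125)["LEP"]
    assert sel.min_required == 5
    assert sel.passed
    assert len(sel.het_ids) == 5


def test_four_heterozygotes_fail():
    assert not select_heterozygotes(_genotype_frame(4), min_het_fraction=0.125)["LEP"].passed


def test_zero_fraction_passes_everything():
    assert select_heterozygotes(_genotype_frame(0), min_het_fraction=0.0)["LEP"].passed


# ---------------------------------------------------------------------------
# end-to-end genotype recovery on synthetic assays
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("enzyme_name, alleles, force", [
    ("MseI", ("T", "C"), False),
    ("EcoRI", ("A", "G"), False),
    ("PvuII", ("G", "A"), True),
    ("HaeIII", ("C", "T"), True),
])
def test_population_genotype_recovery(enzyme_name, alleles, force):
    """Simulated genotypes are recovered exactly by amplify/digest/call."""
    syn = generate_rflp_template(alleles, get_enzyme(enzyme_name), force_site=force, seed=5)
    spec = PopulationSpec(n_animals=40, snps=(SnpSpec("SYN", alleles[0], alleles[1], 0.5),))
    truth = simulate_genotypes(spec, seed=11)["SYN"]
    calls = genotype_population(syn.assay, syn.templates, truth)
    assert all(c.call == truth[c.animal] for c in calls)
    assert {c.call for c in calls} == {"AA", "AB", "BB"}  # informative draw
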