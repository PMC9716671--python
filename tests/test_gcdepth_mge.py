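"""Divergence screening, match classification, prophage and defence scans."""
import numpy as np
import pandas as pd
import pytest

from strataphy._seq import BASES, decode, random_codes, revcomp
from strataphy import recruit
from strataphy.gcdepth_mge import (
    align_local, classify_matches, defence_screen, detect_prophage,
    gc_depth_screen,
)
from strataphy.recruit import coverage_table, map_reads, pileup
from strataphy.simulate import SampleDesign, simulate_sample


def _mutate(seq, fraction, rng):
    out = list(seq)
    idx = rng.choice(len(out), int(fraction * len(out)), replace=False)
    for i in idx:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture(scope="module")
def ref_contig():
    return decode(random_codes(np.random.default_rng(88), 30_000, 55.0))


def test_identical_query_classified_good(ref_contig):
    res = classify_matches({"q": ref_contig[2000:15000]}, {"r": ref_contig})
    assert res.loc[0, "class"] == "good"
    assert res.loc[0, "best_identity"] == 100.0
    assert res.loc[0, "alignment_fraction"] == pytest.approx(1.0)


def test_no_shared_kmers_classified_no_match(ref_contig):
    # a poly-G query shares no 13-mer with the reference on either strand
    ref = ref_contig[:5000]
    assert "G" * 13 not in ref and "C" * 13 not in ref
    res = classify_matches({"q": "G" * 2000}, {"r": ref})
    assert res.loc[0, "class"] == "no-match"


def test_low_identity_query(ref_contig, rng):
    query = _mutate(ref_contig[1000:6000], 0.25, rng)  # ~75% identity
    res = classify_matches({"q": query}, {"r": ref_contig})
    assert res.loc[0, "class"] == "low-identity"


def test_short_perfect_hit_is_low_af_first(ref_contig, rng):
    """An 800 bp perfect hit on a 10 kb query fails AF before length:
    the ladder applies low-AF ahead of short."""
    query = (decode(random_codes(rng, 4000, 55.0)) + ref_contig[1000:1800]
             + decode(random_codes(rng, 5200, 55.0)))
    res = classify_matches({"q": query}, {"r": ref_contig})
    assert res.loc[0, "class"] == "low-AF"
    assert res.loc[0, "best_length"] == pytest.approx(800, abs=30)


def test_short_class_reachable(ref_contig, rng):
    """A 900 bp query aligning fully is 'short' (AF fine, < 1 kb)."""
    res = classify_matches({"q": ref_contig[500:1400]}, {"r": ref_contig})
    assert res.loc[0, "class"] == "short"


def test_reverse_strand_query(ref_contig):
    res = classify_matches({"q": revcomp(ref_contig[2000:12000])},
                           {"r": ref_contig})
    assert res.loc[0, "class"] == "good"


def test_classify_agrees_with_dp_aligner(ref_contig, rng):
    """Exhaustive affine-gap local DP (Biopython) as the oracle on small
    substitution-divergent fixtures."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2

    subject = ref_contig[:5000]
    cases = {
        "identical": subject[1000:3500],
        "diverged08": _mutate(subject[500:3000], 0.08, rng),
        "diverged25": _mutate(subject[500:3000], 0.25, rng),
        "embedded": (decode(random_codes(rng, 1200, 55.0)) + subject[2000:2800]
                     + decode(random_codes(rng, 1000, 55.0))),
    }
    res = classify_matches(cases, {"r": subject}).set_index("query_id")
    for qid, qseq in cases.items():
        aln = aligner.align(qseq, subject)[0]
        qa, sa = aln[0], aln[1]
        ident = sum(1 for x, y in zip(qa, sa) if x == y and x != "-")
        cols = sum(1 for x, y in zip(qa, sa) if x != "-" and y != "-")
        oracle_identity = 100.0 * ident / cols
        oracle_len = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
        oracle_af = (aln.aligned[0][-1][1] - aln.aligned[0][0][0]) / len(qseq)
        if oracle_identity < 80:
            oracle_class = "low-identity"
        elif oracle_af < 0.5:
            oracle_class = "low-AF"
        elif oracle_len < 1000:
            oracle_class = "short"
        else:
            oracle_class = "good"
        assert res.loc[qid, "class"] == oracle_class
        assert res.loc[qid, "best_identity"] == pytest.approx(
            oracle_identity, abs=1.5)


def test_gc_depth_screen_filters(ref_contig, rng):
    low_gc = decode(random_codes(rng, 12_000, 20.0))
    short = ref_contig[:9_900]
    divergent = _mutate(ref_contig[500:13_000], 0.07, rng)  # ~93% identity
    same = ref_contig[2000:14_000]
    contigs = {"short": short, "lowgc": low_gc, "div": divergent, "same": same}
    tracks = {k: 40.0 for k in contigs}
    res = gc_depth_screen(contigs, tracks, {"mag": ref_contig}).set_index("contig_id")
    assert "short" not in res.index  # 9.9 kb: below the length floor
    assert "lowgc" not in res.index  # outside the 30-80% GC window
    assert res.loc["div", "follow_up"]
    assert res.loc["div", "class"] == "divergent-candidate"
    assert res.loc["same", "class"] == "target-like"
    assert res.loc["div", "mean_depth"] == 40.0


def test_prophage_detection(accessory_pair):
    pair, truth = accessory_pair
    genome = pair.genome_a
    s, e = truth.prophage["A"]
    design = SampleDesign("pp", "oxic", "summer", 0.0, 60.0)
    reads = simulate_sample(pair, design, truth, prophage_multiplier=10.0,
                            seed=900)
    aln = map_reads(reads, genome)
    track = pileup(aln, reads, genome)
    table = coverage_table({"pp": track}, genome)
    viral = {
        "virA": genome.sequence[s:s + 2500],
        "virB": genome.sequence[s + 1500:e],
        "virLonely": genome.sequence[s + 500:s + 2000],
    }
    res = detect_prophage({"mag": genome.sequence}, viral,
                          coverage_table=table, genes=genome.genes)
    assert len(res) == 1
    row = res.iloc[0]
    assert row["evidence"] == "both"
    assert row["start"] <= s + 100 and row["end"] >= e - 100
    assert row["mean_relative_coverage"] > 500.0


def test_single_viral_match_not_alignment_evidence(accessory_pair, rng):
    """A region matching only one viral sequence gets no alignment call."""
    pair, truth = accessory_pair
    genome = pair.genome_a
    viral = {"only": genome.sequence[100:2600]}  # outside the prophage
    res = detect_prophage({"mag": genome.sequence}, viral)
    assert res.empty


def test_uniform_coverage_no_prophage(accessory_pair):
    pair, truth = accessory_pair
    genome = pair.genome_a
    design = SampleDesign("flat", "oxic", "summer", 0.0, 60.0)
    reads = simulate_sample(pair, design, truth, seed=901)  # multiplier 1
    aln = map_reads(reads, genome)
    table = coverage_table({"flat": pileup(aln, reads, genome)}, genome)
    unrelated = {
        f"v{i}": decode(random_codes(np.random.default_rng(910 + i), 3000, 55.0))
        for i in range(2)
    }
    res = detect_prophage({"mag": genome.sequence}, unrelated,
                          coverage_table=table, genes=genome.genes)
    assert res.empty


PROT = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
        "FEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWERVMGDGERQFST"
        "LKSTVEAIWAGIKATEAAVSEEFGLAPFLPDQIHFVHSQELLSRYPDLDAKGRERAIAKDLGAVFL"
        "VGIGGKLSDGHRHDVRAPDYDDWSTPSELGHAGLNGDILVWNPVLEDAFELSSMGIRVDADTLKHQ"
        "LALTGDEDRLELEWHQALLRGEMPQTIGGGIGQSRLTMLLLQLPHIGQVQAGVWPAAVR")


def test_identical_protein_hits(rng):
    hits = defence_screen({"q": PROT}, {"ref": PROT})
    assert len(hits) == 1
    assert hits.loc[0, "identity"] == 100.0
    assert hits.loc[0, "query_coverage"] == 100.0
    assert hits.loc[0, "evalue"] < 1e-50


def test_distant_full_length_homolog_hits(rng):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    mutant = list(PROT)
    idx = rng.choice(len(mutant), int(0.6 * len(mutant)), replace=False)
    for i in idx:
        mutant[i] = aa[int(rng.integers(0, 20))]
    hits = defence_screen({"q": "".join(mutant)}, {"ref": PROT})
    assert len(hits) == 1
    assert 30.0 < hits.loc[0, "identity"] < 70.0
    assert hits.loc[0, "query_coverage"] > 50.0


def test_shuffled_queries_rarely_hit(rng):
    """Permutation control: composition-preserving shuffles stay below the
    e-value threshold in at least 95% of trials."""
    n_hit = 0
    letters = np.array(list(PROT))
    for _ in range(100):
        q = "".join(rng.permutation(letters))
        if len(defence_screen({"q": q}, {"ref": PROT})):
            n_hit += 1
    assert n_hit <= 5


def test_thresholds_are_monotone_post_filters(rng):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    queries = {}
    for frac in (0.2, 0.45, 0.7):
        mutant = list(PROT)
        idx = rng.choice(len(mutant), int(frac * len(mutant)), replace=False)
        for i in idx:
            mutant[i] = aa[int(rng.integers(0, 20))]
        queries[f"m{frac}"] = "".join(mutant)
    strict = defence_screen(queries, {"ref": PROT})
    loose = defence_screen(queries, {"ref": PROT}, max_evalue=1e-2,
                           min_identity=10.0, min_coverage=20.0)
    strict_pairs = set(map(tuple, strict[["query_id", "subject_id"]].values))
    loose_pairs = set(map(tuple, loose[["query_id", "subject_id"]].values))
    assert strict_pairs <= loose_pairs


def test_nucleotide_input_rejected():
    with pytest.raises(ValueError):
        defence_screen({"q": "ACGTACGTACGT"}, {"ref": PROT})
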