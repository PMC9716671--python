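"""Variant calling against planted truth and hand-built pileups."""
import numpy as np
import pytest

from strataphy._seq import decode, encode, random_codes
from strataphy import recruit, variants
from strataphy.recruit import DepthTrack, map_reads, pileup
from strataphy.simulate import ReadSet
from strataphy.variants import (
    VariantCall, call_indels, call_snps, read_vcf, site_frequencies,
    stable_mutations, write_vcf,
)
from tests.conftest import make_sample


def _track_from_counts(ref: str, site_counts: dict[int, dict[str, int]],
                       background_depth: int = 0) -> DepthTrack:
    """Hand-built track: 1-based site -> allele ('A'..'T' or 'del') counts;
    everywhere else, background_depth reads of the reference base."""
    codes = encode(ref)
    counts = np.zeros((5, len(ref)), dtype=np.int32)
    counts[codes, np.arange(len(ref))] = background_depth
    for pos, alleles in site_counts.items():
        counts[:, pos - 1] = 0
        for allele, n in alleles.items():
            row = 4 if allele == "del" else "ACGT".index(allele)
            counts[row, pos - 1] = n
    return DepthTrack("ref", "s", counts)


REF = decode(random_codes(np.random.default_rng(5), 400, 50.0))


@pytest.mark.parametrize(
    "depth_alt,called",
    [((19, 19), False),  # depth 19, alt fraction 1.0: below the depth floor
     ((100, 95), True),  # depth 100, fraction 0.95: passes both filters
     ((100, 89), False),  # fraction 0.89: below the 0.9 frequency floor
     ((20, 18), True)],  # boundary: depth exactly 20, fraction 0.9
)
def test_snp_filters(depth_alt, called):
    depth, alt = depth_alt
    alt_base = "A" if REF[9] != "A" else "C"
    tr = _track_from_counts(
        REF, {10: {alt_base: alt, REF[9]: depth - alt}}, background_depth=50
    )
    calls = call_snps(tr, REF)
    positions = {c.position for c in calls}
    assert (10 in positions) == called


def test_snp_frequency_counts_all_covering_reads():
    """Deletion-bearing reads stay in the denominator."""
    alt_base = "A" if REF[19] != "A" else "C"
    tr = _track_from_counts(REF, {20: {alt_base: 90, "del": 10}},
                            background_depth=50)
    calls = call_snps(tr, REF)
    call = next(c for c in calls if c.position == 20)
    assert call.frequency == pytest.approx(0.9)
    assert call.depth == 100


def test_min_freq_validation():
    tr = _track_from_counts(REF, {}, background_depth=30)
    with pytest.raises(ValueError):
        call_snps(tr, REF, min_freq=1.5)


def test_pure_b_sample_recovers_planted_snps_exactly(small_pair):
    """Error-free pure-phylotype calls equal the truth table: the planted
    backbone SNPs plus the two 16S marker sites on the primary copy."""
    pair, truth = small_pair
    _, reads = make_sample(pair, truth, sample_id="pb", fraction_b=1.0,
                           depth=100.0, seed=41, error_rate=0.0)
    aln = map_reads(reads, pair.genome_a)
    track = pileup(aln, reads, pair.genome_a)
    calls = call_snps(track, pair.genome_a)
    got = {(c.position, c.ref_allele, c.alt_allele) for c in calls}
    want = {(pa + 1, ref, alt) for _, pa, _, ref, alt in truth.backbone_snps}
    for (p217, p231), (a1, a2), (b1, b2) in [(
        truth.marker_sites["A"][0], pair.marker_a_alleles, pair.marker_b_alleles
    )]:
        want |= {(p217 + 1, a1, b1), (p231 + 1, a2, b2)}
    assert got == want  # precision = recall = 1
    assert all(c.frequency >= 0.9 and c.depth >= 20 for c in calls)


def test_no_call_below_depth_floor_property(small_pair):
    pair, truth = small_pair
    _, reads = make_sample(pair, truth, sample_id="lo", fraction_b=1.0,
                           depth=60.0, seed=42)
    aln = map_reads(reads, pair.genome_a)
    track = pileup(aln, reads, pair.genome_a)
    assert all(c.depth >= 20 for c in call_snps(track, pair.genome_a))


def _deletion_fixture(rng, carrier_fraction=1.0, del_len=4):
    ref = decode(random_codes(rng, 2000, 50.0))
    mutant = ref[:900] + ref[900 + del_len:]
    recs = []
    # keep the event well inside every read so the gapped path always wins
    for i, start in enumerate(range(795, 860, 2)):
        src = mutant if (i * 997 % 100) < carrier_fraction * 100 else ref
        recs.append((f"d{i}", src[start:start + 150]))
    return ref, ReadSet.from_sequences(recs)


def test_planted_deletion_called_with_full_support(rng):
    ref, reads = _deletion_fixture(rng)
    aln = map_reads(reads, ref)
    track = pileup(aln, reads, len(ref))
    from strataphy.simulate import AnnotatedGenome
    genome = AnnotatedGenome("ref", ref, [])
    calls = call_indels(aln, reads, track, genome)
    assert len(calls) == 1
    call = calls[0]
    assert call.type == "deletion"
    assert len(call.alt_allele) == 4
    assert call.frequency == pytest.approx(1.0)
    assert abs(call.position - 900) <= 10  # left-aligned near the planted site


def test_half_carried_deletion_frequency(rng):
    ref, reads = _deletion_fixture(rng, carrier_fraction=0.5)
    aln = map_reads(reads, ref)
    track = pileup(aln, reads, len(ref))
    from strataphy.simulate import AnnotatedGenome
    calls = call_indels(aln, reads, track, AnnotatedGenome("ref", ref, []))
    assert len(calls) == 1
    assert calls[0].frequency == pytest.approx(0.5, abs=0.1)


def test_no_indels_without_planting(small_pair):
    pair, truth = small_pair
    _, reads = make_sample(pair, truth, sample_id="ni", fraction_b=0.0,
                           depth=40.0, seed=43, error_rate=0.0)
    aln = map_reads(reads, pair.genome_a)
    track = pileup(aln, reads, pair.genome_a)
    assert call_indels(aln, reads, track, pair.genome_a) == []


def test_left_normalisation_in_homopolymer(rng):
    """A deletion inside an A-run reports at the run's leftmost placement."""
    core = decode(random_codes(rng, 1000, 50.0))
    ref = core[:500] + "AAAAAA" + core[500:]
    mutant = core[:500] + "AAAA" + core[500:]  # delete 2 A's
    recs = [(f"r{i}", mutant[s:s + 150]) for i, s in enumerate(range(390, 480, 3))]
    reads = ReadSet.from_sequences(recs)
    aln = map_reads(reads, ref)
    track = pileup(aln, reads, len(ref))
    from strataphy.simulate import AnnotatedGenome
    calls = call_indels(aln, reads, track, AnnotatedGenome("ref", ref, []))
    dels = [c for c in calls if c.type == "deletion"]
    assert len(dels) == 1
    assert dels[0].position == 500  # anchored at the base before the A-run


def test_site_frequencies_worked_example():
    tr = _track_from_counts(REF, {217: {"T": 7, "A": 93}, 231: {"T": 4, "G": 96}},
                            background_depth=100)
    mf = site_frequencies(tr, [217, 231], ["T", "T"])
    assert mf["frequency"].tolist() == pytest.approx([0.07, 0.04])
    assert mf["usable"].all()


def test_site_frequencies_below_depth_flagged():
    tr = _track_from_counts(REF, {50: {"T": 1, "A": 9}}, background_depth=100)
    mf = site_frequencies(tr, [50], ["T"])
    assert not mf["usable"].iloc[0]
    assert mf["depth"].iloc[0] == 10  # depth recorded even when unusable
    with pytest.raises(ValueError):
        site_frequencies(tr, [50], ["Z"])
    with pytest.raises(ValueError):
        site_frequencies(tr, [0], ["T"])


def _call(pos, sample=""):
    return VariantCall("m", pos, "A", "T", "SNP", 30, 1.0, sample)


def test_stable_mutations_by_definition():
    samples = {}
    meta = {}
    periods = ["p1", "p2", "p3", "p4"]
    for depth_label in ("oxic1", "anoxic1"):
        for per in periods:
            sid = f"{depth_label}_{per}"
            meta[sid] = (depth_label, per)
            calls = []
            if depth_label == "oxic1":
                calls.append(_call(100, sid))  # in all 4 periods: stable
                if per != "p4":
                    calls.append(_call(200, sid))  # 3 of 4: dynamic
            samples[sid] = calls
    stable, dynamic = stable_mutations(samples, meta)
    keys = {k[1] for k in stable}
    assert keys == {100}
    assert {k[1] for k in dynamic} == {200}


def test_stable_mutations_single_period_rejected():
    with pytest.raises(ValueError):
        stable_mutations({"s": []}, {"s": ("oxic1", "p1")})


def test_planted_fixed_difference_stable_across_periods(clean_pair):
    """Marker SNPs present in every period at one depth come out stable."""
    pair, truth = clean_pair
    calls_by_sample = {}
    meta = {}
    for i, per in enumerate(["p1", "p2"]):
        sid = f"ox_{per}"
        _, reads = make_sample(pair, truth, sample_id=sid, fraction_b=1.0,
                               depth=60.0, seed=50 + i, error_rate=0.0)
        aln = map_reads(reads, pair.genome_a)
        track = pileup(aln, reads, pair.genome_a)
        calls_by_sample[sid] = call_snps(track, pair.genome_a)
        meta[sid] = ("oxic1", per)
    stable, dynamic = stable_mutations(calls_by_sample, meta)
    marker_positions = {p + 1 for p in truth.marker_sites["A"][0]}
    assert marker_positions <= {k[1] for k in stable}
    assert not dynamic


def test_vcf_roundtrip(tmp_path):
    calls = [
        VariantCall("m", 42, "A", "T", "SNP", 55, 0.95, "s1"),
        VariantCall("m", 99, "G", "TTAC", "insertion", 40, 0.5, "s1"),
        VariantCall("m", 120, "C", "GG", "deletion", 33, 1.0, "s1"),
    ]
    path = tmp_path / "out.vcf"
    write_vcf(calls, path)
    text = path.read_text()
    assert text.startswith("##fileformat=VCFv4.2")
    back = read_vcf(path)
    assert sorted(back, key=lambda c: c.position) == calls


def test_variant_call_validation():
    with pytest.raises(ValueError):
        VariantCall("m", 1, "A", "T", "SNV", 30, 0.5)
    with pytest.raises(ValueError):
        VariantCall("m", 1, "A", "T", "SNP", 30, 1.5)
    with pytest.raises(ValueError):
        VariantCall("m", 1, "A", "T", "SNP", 0, 0.5)
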