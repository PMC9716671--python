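"""SNP and indel calling from pileups, with temporal stability labelling.

Calling works directly from per-base allele counts: a site is reported as
a SNP when at least ``min_depth`` reads cover it and the most frequent
non-reference base accounts for at least ``min_freq`` of all covering
reads (defaults 20 and 0.9). Indels are collected from the gapped rescue
alignments, left-normalised, and filtered by the same depth floor.
Frequencies are computed against all reads covering the site, deletions
included. No depth ceiling is applied.

Marker-site frequencies are a separate query: diagnostic sub-population
alleles are reported at any frequency (no 0.9 floor), flagged unusable
below the depth floor.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import BASES, revcomp_codes
from .recruit import AlignmentSet, DepthTrack
from .simulate import AnnotatedGenome, ReadSet

VARIANT_TYPES = ("SNP", "insertion", "deletion")


@dataclass(frozen=True)
class VariantCall:
    ref_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    type: str  # SNP / insertion / deletion
    depth: int
    frequency: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.type!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency outside [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def key(self) -> tuple:
        """Sample-independent identity of the variant."""
        return (self.ref_id, self.position, self.ref_allele,
                self.alt_allele, self.type)


def call_snps(
    track: DepthTrack,
    reference: AnnotatedGenome | str,
    min_freq: float = 0.9,
    min_depth: int = 20,
    sample_id: str | None = None,
) -> list[VariantCall]:
    """Report sites where the dominant non-reference base reaches
    ``min_freq`` of all covering reads at depth >= ``min_depth``.

    Only the single most frequent alternate base is reported per site;
    with the default 0.9 floor co-occurring alternates cannot both pass.
    """
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must be in (0, 1]")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if isinstance(reference, AnnotatedGenome):
        ref_codes = reference.codes
    else:
        from ._seq import encode
        ref_codes = encode(reference)
    L = len(track)
    if ref_codes.size != L:
        raise ValueError("track/reference length mismatch")

    depth = track.depth
    bases = track.allele_counts[:4].astype(np.int64)
    cols = np.arange(L)
    masked = bases.copy()
    valid_ref = ref_codes < 4
    masked[ref_codes[valid_ref], cols[valid_ref]] = -1
    alt_code = masked.argmax(axis=0)
    alt_count = masked[alt_code, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
    called = (depth >= min_depth) & (freq >= min_freq) & (alt_count > 0)

    sample = sample_id if sample_id is not None else track.sample_id
    return [
        VariantCall(
            ref_id=track.ref_id, position=int(p) + 1,
            ref_allele=BASES[ref_codes[p]], alt_allele=BASES[alt_code[p]],
            type="SNP", depth=int(depth[p]), frequency=float(freq[p]),
            sample_id=sample,
        )
        for p in np.flatnonzero(called)
    ]


def _left_normalise(seq_codes: np.ndarray, pos: int, event: np.ndarray) -> int:
    """Shift an indel left while the base before it equals its last base."""
    n = event.size
    while pos > 0 and seq_codes[pos - 1] == event[n - 1]:
        event = np.roll(event, 1)
        pos -= 1
    return pos


def call_indels(
    alignments: AlignmentSet,
    reads: ReadSet,
    track: DepthTrack,
    reference: AnnotatedGenome,
    min_depth: int = 20,
    sample_id: str | None = None,
) -> list[VariantCall]:
    """Collect indel events from gapped alignments, left-aligned and
    reported at the 1-based position of the base preceding the event.

    Requires the mapper's gapped rescue; supporting fraction is the number
    of event-carrying reads over the read depth at the anchor base.
    """
    ref_codes = reference.codes
    depth = track.depth
    support: dict[tuple, int] = {}
    merge_gap = 3  # edit-equivalent split events re-join across tiny gaps
    for row, cigar in alignments.cigars.items():
        rpos = int(alignments.start[row])
        codes = reads.codes[int(alignments.read_index[row])]
        if alignments.strand[row]:
            codes = revcomp_codes(codes)
        qpos = 0
        events: list[list] = []  # [type, ref_pos, length, insert_codes]
        for num, op in re.findall(r"(\d+)([=XIDM])", cigar):
            n = int(num)
            if op in "=XM":
                rpos += n
                qpos += n
            elif op == "D":
                events.append(["deletion", rpos, n, None])
                rpos += n
            else:  # I
                events.append(["insertion", rpos, n, codes[qpos:qpos + n].copy()])
                qpos += n
        # merge same-type events separated by <= merge_gap matched bases:
        # the optimal edit path is not unique, and a contiguous indel can
        # come back split when an intervening base happens to match
        merged: list[list] = []
        for ev in events:
            if (merged and merged[-1][0] == ev[0]
                    and ev[1] - (merged[-1][1] + merged[-1][2]) <= merge_gap):
                prev = merged[-1]
                prev[2] += ev[2]
                if ev[0] == "insertion":
                    prev[3] = np.concatenate([prev[3], ev[3]])
            else:
                merged.append(list(ev))
        for vtype, pos, n, ins in merged:
            if vtype == "deletion":
                event = ref_codes[pos:pos + n].copy()
                p = _left_normalise(ref_codes, pos, event)
                seq = "".join(BASES[c] for c in ref_codes[p:p + n])
            else:
                p = _left_normalise(ref_codes, pos, ins)
                off = p - pos
                ev2 = np.roll(ins, off % n) if n else ins
                seq = "".join(BASES[c] for c in ev2)
            support[(p, vtype, seq)] = support.get((p, vtype, seq), 0) + 1

    sample = sample_id if sample_id is not None else track.sample_id
    calls = []
    for (p, vtype, seq), n_sup in sorted(support.items()):
        anchor = max(p - 1, 0)
        d = int(depth[anchor])
        if d < min_depth:
            continue
        calls.append(VariantCall(
            ref_id=track.ref_id, position=anchor + 1,
            ref_allele=BASES[ref_codes[anchor]], alt_allele=seq,
            type=vtype, depth=d, frequency=min(1.0, n_sup / d),
            sample_id=sample,
        ))
    return calls


def site_frequencies(
    track: DepthTrack,
    positions: list[int],
    alleles: list[str] | str,
    min_depth: int = 20,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Frequency of an expected alternate base at given 1-based sites.

    No frequency floor: these are sub-population markers reported at any
    value. Sites below ``min_depth`` are flagged unusable but their depth
    is still recorded.
    """
    if isinstance(alleles, str):
        alleles = [alleles] * len(positions)
    if len(alleles) != len(positions):
        raise ValueError("positions/alleles length mismatch")
    depth = track.depth
    rows = []
    sample = sample_id if sample_id is not None else track.sample_id
    for pos, allele in zip(positions, alleles):
        if allele not in BASES:
            raise ValueError(f"unknown allele symbol {allele!r}")
        if not 1 <= pos <= len(track):
            raise ValueError(f"position {pos} outside reference")
        i = pos - 1
        d = int(depth[i])
        count = int(track.allele_counts[BASES.index(allele), i])
        rows.append({
            "sample_id": sample, "position": pos, "allele": allele,
            "frequency": count / d if d else np.nan, "depth": d,
            "usable": d >= min_depth,
        })
    return pd.DataFrame(rows)


def stable_mutations(
    calls_by_sample: dict[str, list[VariantCall]],
    metadata: dict[str, tuple[str, str]],
) -> tuple[set[tuple], set[tuple]]:
    """Split variant keys into stable and dynamic sets.

    A variant is stable when, for at least one depth stratum, it is
    present in every time period sampled at that depth; everything else
    observed is dynamic. Requires at least two periods overall.
    """
    periods_by_depth: dict[str, set[str]] = {}
    for sample, (depth_label, period) in metadata.items():
        periods_by_depth.setdefault(depth_label, set()).add(period)
    if all(len(p) < 2 for p in periods_by_depth.values()):
        raise ValueError("stability undefined with a single time period")

    seen: dict[tuple, dict[str, set[str]]] = {}
    for sample, calls in calls_by_sample.items():
        depth_label, period = metadata[sample]
        for call in calls:
            seen.setdefault(call.key, {}).setdefault(depth_label, set()).add(period)

    stable, dynamic = set(), set()
    for key, by_depth in seen.items():
        if any(
            len(by_depth.get(d, ())) == len(periods) and len(periods) >= 2
            for d, periods in periods_by_depth.items()
        ):
            stable.add(key)
        else:
            dynamic.add(key)
    return stable, dynamic


# ---------------------------------------------------------------------------
# minimal VCF I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">
##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP, insertion or deletion">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Merged sample id">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: list[VariantCall], path) -> None:
    """Fixed-column VCF with depth/frequency in INFO. Indels are encoded
    VCF-style: anchor base plus event sequence."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(calls, key=lambda c: (c.ref_id, c.position, c.alt_allele)):
            if c.type == "SNP":
                ref, alt = c.ref_allele, c.alt_allele
            elif c.type == "insertion":
                ref, alt = c.ref_allele, c.ref_allele + c.alt_allele
            else:
                ref, alt = c.ref_allele + c.alt_allele, c.ref_allele
            info = (f"DP={c.depth};AF={c.frequency:.6g};TYPE={c.type};"
                    f"SAMPLE={c.sample_id or '.'}")
            fh.write(f"{c.ref_id}\t{c.position}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def read_vcf(path) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";"))
            vtype = fields["TYPE"]
            if vtype == "SNP":
                ref_allele, alt_allele = ref, alt
            elif vtype == "insertion":
                ref_allele, alt_allele = ref, alt[len(ref):]
            else:
                ref_allele, alt_allele = ref[0], ref[len(alt):]
            sample = fields.get("SAMPLE", ".")
            calls.append(VariantCall(
                ref_id=chrom, position=int(pos), ref_allele=ref_allele,
                alt_allele=alt_allele, type=vtype, depth=int(fields["DP"]),
                frequency=float(fields["AF"]),
                sample_id="" if sample == "." else sample,
            ))
    return calls


def marker_table(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample marker-frequency frames into one table with
    frequencies in percent (the supplementary-table layout)."""
    df = pd.concat(frames, ignore_index=True)
    df["frequency_pct"] = 100.0 * df["frequency"]
    return df[["sample_id", "position", "allele", "frequency_pct", "depth", "usable"]]
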