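"""Phylotype deconvolution from 16S marker SNPs and rRNA copy-number
estimation by read-depth ratio.

Two diagnostic SNPs inside the 16S rRNA gene (default offsets 217 and 231)
separate the two phylotypes of the species. In a merged sample the
fraction of reads carrying the minority phylotype's alleles at those sites
estimates its contribution to the total population; the *smaller* of the
two site frequencies is taken, as a proxy for reads carrying both marker
alleles at once (the min rule). Copy number of the 16S gene is estimated
from the ratio of marker-site depth under stringent 100%-identity
recruitment to the whole-genome median depth: a genome with two
near-identical copies shows a ratio near 2, a single-copy genome near 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import BASES
from .recruit import map_reads_exact, median_mag_depth, pileup_segments
from .simulate import AnnotatedGenome, ReadSet


@dataclass
class PhylotypeEstimate:
    sample_id: str
    contribution_b: float | None  # percent
    contribution_a: float | None  # percent, 100 - contribution_b
    usable: bool
    depth_a: float | None = None  # fold coverage, filled by phylotype_depth
    depth_b: float | None = None
    marker_frequencies: dict[int, float] | None = None  # position -> fraction


@dataclass
class CopyRatio:
    sample_id: str
    ratio: float  # 16S marker-site median depth / genome median depth
    estimated_copies: int
    fractional: bool  # ratio sits between integers; reported raw


class UnusableEstimateError(ValueError):
    pass


def contribution(markers: pd.DataFrame, sample_id: str | None = None) -> PhylotypeEstimate:
    """Phylotype-B contribution from one sample's marker-site frequencies.

    ``markers`` is a ``site_frequencies`` frame for the two marker sites.
    contribution_B = min over marker sites of the diagnostic-allele
    frequency, in percent; usable only when every marker site had depth
    above the floor.
    """
    if sample_id is not None:
        markers = markers[markers["sample_id"] == sample_id]
    if markers.empty or markers["position"].nunique() < 2:
        raise ValueError("both marker sites are required")
    sid = sample_id or (markers["sample_id"].iloc[0] if "sample_id" in markers else "")
    if not bool(markers["usable"].all()):
        return PhylotypeEstimate(sid, None, None, usable=False)
    freqs = {int(r.position): float(r.frequency) for r in markers.itertuples()}
    contrib_b = 100.0 * min(freqs.values())
    return PhylotypeEstimate(
        sid, contrib_b, 100.0 - contrib_b, usable=True, marker_frequencies=freqs
    )


def phylotype_depth(
    estimate: PhylotypeEstimate, mag_median: float
) -> tuple[float, float]:
    """Fold-coverage depth of each phylotype: contribution x genome median.

    depth_A + depth_B equals the genome median exactly.
    """
    if not estimate.usable:
        raise UnusableEstimateError("cannot assign depths to an unusable estimate")
    if mag_median < 0:
        raise ValueError("mag_median must be non-negative")
    depth_b = estimate.contribution_b / 100.0 * mag_median
    depth_a = mag_median - depth_b
    estimate.depth_a, estimate.depth_b = depth_a, depth_b
    return depth_a, depth_b


def both_marker_read_fraction(
    reads: ReadSet,
    alignments,
    marker_genome_positions: tuple[int, ...],
    alt_alleles: tuple[str, ...],
) -> tuple[float, int]:
    """Cross-check of the min rule: fraction of recruited reads that span
    BOTH marker genome positions and carry the phylotype-B allele at each.

    The min rule is motivated as a proxy for exactly this per-read
    quantity, available when the read length covers the marker span.
    Returns (fraction, number of spanning reads).
    """
    from ._seq import revcomp_codes

    lo = min(marker_genome_positions)
    hi = max(marker_genome_positions)
    want = [BASES.index(a) for a in alt_alleles]
    n_span = 0
    n_both = 0
    rows = np.flatnonzero(
        (alignments.start <= lo) & (alignments.end > hi)
    )
    for row in rows:
        if int(row) in alignments.cigars:
            continue  # gapped reads: offsets are not positional, skip
        codes = reads.codes[int(alignments.read_index[row])]
        if alignments.strand[row]:
            codes = revcomp_codes(codes)
        s = int(alignments.start[row])
        n_span += 1
        got = [codes[p - s] for p in marker_genome_positions]
        if all(got[i] == want[i] for i in range(len(want))):
            n_both += 1
    return (n_both / n_span if n_span else np.nan), n_span


def rrna_copy_ratio(
    reads: ReadSet,
    reference: AnnotatedGenome | str,
    mag_median: float,
    marker_positions: tuple[int, ...] | None = None,
    sample_id: str = "",
) -> CopyRatio:
    """16S copy-number estimate from the stringent read-depth ratio.

    Reads are recruited at exactly 100% identity onto the genome's
    canonical 16S gene sequence (identical copies collapse onto this one
    coordinate system); the ratio is the median depth at the marker sites
    over the whole-genome median depth. Ratios near 2 indicate two copies.
    """
    if mag_median <= 0:
        raise ZeroDivisionError("genome median depth must be positive")
    if isinstance(reference, AnnotatedGenome):
        if not reference.rrna_loci:
            raise ValueError("reference genome has no annotated 16S locus")
        rrna_seq = reference.rrna_sequence(0)
        if marker_positions is None:
            marker_positions = reference.rrna_loci[0].marker_offsets
    else:
        rrna_seq = reference
        if marker_positions is None:
            raise ValueError("marker_positions required with a bare 16S sequence")
    segs = map_reads_exact(reads, rrna_seq)
    depth = pileup_segments(segs, len(rrna_seq))
    marker_depths = np.array([depth[p - 1] for p in marker_positions], dtype=float)
    ratio = float(np.median(marker_depths)) / mag_median
    est = int(round(ratio)) if ratio > 0 else 0
    est = max(est, 1) if ratio > 0 else 0
    fractional = abs(ratio - round(ratio)) > 0.25
    return CopyRatio(sample_id, ratio, est, fractional)


def estimate_table(estimates: list[PhylotypeEstimate],
                   metadata: dict[str, dict] | None = None) -> pd.DataFrame:
    """Per-sample contribution/depth table (supplementary-table layout)."""
    metadata = metadata or {}
    rows = []
    for e in estimates:
        meta = metadata.get(e.sample_id, {})
        rows.append({
            "sample_id": e.sample_id,
            "zone": meta.get("depth_zone", meta.get("zone", "")),
            "period": meta.get("period", ""),
            "contribution_A_pct": e.contribution_a,
            "contribution_B_pct": e.contribution_b,
            "depth_A": e.depth_a, "depth_B": e.depth_b,
            "usable": e.usable,
        })
    return pd.DataFrame(rows)
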