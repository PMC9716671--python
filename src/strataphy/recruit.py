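"""Fragment recruitment and coverage arithmetic.

Recruits reads onto a reference genome with a k-mer-seeded, ungapped
Hamming-scored mapper plus an optional gapped rescue step (edlib), builds
per-base depth and allele-count tracks from the placements, and computes
the coverage statistics used throughout the pipeline: whole-genome median
depth, per-gene fold coverage, gene relative coverage (gene coverage over
genome median, in percent) and per-zone relative-coverage means.

A read with several equally good placements is assigned to the placement
with the smallest reference coordinate (the "first best site" rule), so
multi-copy loci accumulate the coverage of all their copies on the first
copy and can exceed 100% relative coverage.

All coordinates are 0-based half-open internally; reports and variant
output are 1-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp_codes
from .simulate import AnnotatedGenome, Gene, ReadSet

_CHUNK = 65536


class EmptyReferenceError(ValueError):
    pass


@dataclass
class AlignmentSet:
    """One record per mapped read against a single reference."""

    ref_id: str
    ref_length: int
    read_index: np.ndarray  # index into the ReadSet
    start: np.ndarray  # 0-based
    end: np.ndarray  # half-open
    identity: np.ndarray  # percent over the aligned read span
    strand: np.ndarray  # bool, True = reverse
    span: np.ndarray  # aligned read bases
    cigars: dict[int, str] = field(default_factory=dict)  # row -> cigar (gapped only)

    def __len__(self) -> int:
        return self.read_index.size

    def to_frame(self, reads: ReadSet) -> pd.DataFrame:
        return pd.DataFrame({
            "read_id": [reads.names[i] for i in self.read_index],
            "ref_id": self.ref_id,
            "ref_start": self.start,
            "ref_end": self.end,
            "strand": np.where(self.strand, "-", "+"),
            "percent_identity": np.round(self.identity, 3),
            "aligned_read_span": self.span,
        })

    def to_tsv(self, path, reads: ReadSet) -> None:
        self.to_frame(reads).to_csv(path, sep="\t", index=False)

    def to_sam(self, path, reads: ReadSet) -> None:
        """Minimal SAM: mandatory columns only, ungapped reads as full
        matches, gapped reads with their rescue CIGAR."""
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            fh.write(f"@SQ\tSN:{self.ref_id}\tLN:{self.ref_length}\n")
            for row in range(len(self)):
                i = int(self.read_index[row])
                flag = 16 if self.strand[row] else 0
                seq = reads.sequence(i)
                if self.strand[row]:
                    seq = decode(revcomp_codes(encode(seq)))
                cigar = self.cigars.get(row, f"{int(self.span[row])}M")
                fh.write(
                    f"{reads.names[i]}\t{flag}\t{self.ref_id}\t"
                    f"{int(self.start[row]) + 1}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n"
                )


class _KmerIndex:
    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        n = codes.size - k + 1
        if n <= 0:
            raise EmptyReferenceError("reference shorter than the seed length")
        powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        kmers = windows.astype(np.uint64) @ powers
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.positions = order.astype(np.int64)
        self.powers = powers

    def lookup(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_kmers, query, side="left")
        hi = np.searchsorted(self.sorted_kmers, query, side="right")
        return lo, hi


def _expand_hits(lo: np.ndarray, cnt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten searchsorted ranges into hit indices plus source rows."""
    total = int(cnt.sum())
    rows = np.repeat(np.arange(cnt.size), cnt)
    offsets = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    return rows, np.repeat(lo, cnt) + offsets


def _candidates(
    mat: np.ndarray, index: _KmerIndex, rl: int, max_hits: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seed-derived (read, candidate_start) pairs for one orientation."""
    k = index.k
    seed_offsets = sorted({0, (rl - k) // 2, rl - k})
    reads_out, starts_out = [], []
    for off in seed_offsets:
        q = mat[:, off:off + k].astype(np.uint64) @ index.powers
        lo, hi = index.lookup(q)
        cnt = np.minimum(hi - lo, max_hits)
        rows, hit_idx = _expand_hits(lo, cnt)
        starts = index.positions[hit_idx] - off
        reads_out.append(rows)
        starts_out.append(starts)
    reads = np.concatenate(reads_out)
    starts = np.concatenate(starts_out)
    ok = (starts >= 0) & (starts <= index.positions.size + index.k - 1 - rl)
    return reads[ok], starts[ok]


def _mismatch_counts(
    ref_codes: np.ndarray, mat: np.ndarray, reads: np.ndarray, starts: np.ndarray
) -> np.ndarray:
    rl = mat.shape[1]
    out = np.empty(reads.size, dtype=np.int32)
    ar = np.arange(rl)
    for i in range(0, reads.size, _CHUNK):
        sl = slice(i, min(i + _CHUNK, reads.size))
        windows = ref_codes[starts[sl, None] + ar]
        out[sl] = np.count_nonzero(windows != mat[reads[sl]], axis=1)
    return out


def map_reads(
    reads: ReadSet,
    reference: AnnotatedGenome | str,
    min_identity: float = 85.0,
    seed_length: int = 15,
    gapped_rescue: bool = True,
    band: int = 5,
    max_hits_per_seed: int = 32,
    ref_id: str | None = None,
) -> AlignmentSet:
    """Recruit reads to one reference at or above ``min_identity`` percent.

    Ungapped placements are scored by Hamming distance over the full read;
    reads whose best ungapped placement falls below the identity floor are
    retried with a banded gapped alignment (edlib) around their seed
    neighbourhood, so indel-bearing reads still recruit. Each read yields
    at most one record; ties go to the smallest reference coordinate, then
    to the forward strand.
    """
    if not 0.0 < min_identity <= 100.0:
        raise ValueError("min_identity must be in (0, 100]")
    if len(reads) == 0:
        raise ValueError("no reads supplied")
    if isinstance(reference, AnnotatedGenome):
        ref_codes, ref_name = reference.codes, reference.id
        ref_seq = reference.sequence
    else:
        ref_seq = reference
        ref_codes, ref_name = encode(reference), ref_id or "ref"
    if ref_codes.size == 0:
        raise EmptyReferenceError("empty reference")
    rl = reads.read_length
    if ref_codes.size < rl:
        raise EmptyReferenceError("reference shorter than the read length")

    index = _KmerIndex(ref_codes, seed_length)
    fwd = reads.codes
    rev = revcomp_codes(reads.codes)

    cand_read, cand_start, cand_mm, cand_rc = [], [], [], []
    for rc, mat in ((0, fwd), (1, rev)):
        r, s = _candidates(mat, index, rl, max_hits_per_seed)
        if r.size == 0:
            continue
        key = r.astype(np.int64) * (ref_codes.size + 1) + s
        _, uniq = np.unique(key, return_index=True)
        r, s = r[uniq], s[uniq]
        mm = _mismatch_counts(ref_codes, mat, r, s)
        cand_read.append(r)
        cand_start.append(s)
        cand_mm.append(mm)
        cand_rc.append(np.full(r.size, rc, dtype=np.int8))

    max_mm = int(np.floor(rl * (1.0 - min_identity / 100.0)))
    rows: dict[str, list] = {"read": [], "start": [], "end": [], "mm": [],
                             "rc": [], "span": []}
    cigars: dict[int, str] = {}
    best_mm_by_read = np.full(len(reads), rl + 1, dtype=np.int32)

    if cand_read:
        r = np.concatenate(cand_read)
        s = np.concatenate(cand_start)
        mm = np.concatenate(cand_mm)
        rc = np.concatenate(cand_rc)
        order = np.lexsort((rc, s, mm, r))
        r, s, mm, rc = r[order], s[order], mm[order], rc[order]
        first = np.ones(r.size, dtype=bool)
        first[1:] = r[1:] != r[:-1]
        r, s, mm, rc = r[first], s[first], mm[first], rc[first]
        np.minimum.at(best_mm_by_read, r, mm)
        ok = mm <= max_mm
        rows["read"].append(r[ok])
        rows["start"].append(s[ok])
        rows["end"].append(s[ok] + rl)
        rows["mm"].append(mm[ok])
        rows["rc"].append(rc[ok].astype(bool))
        rows["span"].append(np.full(int(ok.sum()), rl, dtype=np.int32))

    # --- banded gapped rescue for reads whose ungapped best is too poor ---
    rescued = {"read": [], "start": [], "end": [], "identity": [], "rc": [],
               "span": [], "cigar": []}
    if gapped_rescue and max_mm > 0:
        import edlib

        seeded = np.zeros(len(reads), dtype=bool)
        if cand_read:
            for arr in cand_read:
                seeded[np.unique(arr)] = True
        need = np.flatnonzero(seeded & (best_mm_by_read > max_mm))
        for i in need:
            best = None
            for rc, mat in ((False, fwd), (True, rev)):
                res = edlib.align(decode(mat[i]), ref_seq, mode="HW",
                                  task="path", k=max_mm)
                if res["editDistance"] < 0:
                    continue
                loc = min(res["locations"])
                entry = (res["editDistance"], loc[0], rc, loc[1] + 1, res["cigar"])
                if best is None or entry < best:
                    best = entry
            if best is not None:
                dist, start, rc, end, cigar = best
                rescued["read"].append(i)
                rescued["start"].append(start)
                rescued["end"].append(end)
                rescued["identity"].append(100.0 * (1.0 - dist / rl))
                rescued["rc"].append(rc)
                rescued["span"].append(rl)
                rescued["cigar"].append(cigar)

    read_idx = np.concatenate(rows["read"] + [np.asarray(rescued["read"], dtype=np.int64)])
    start = np.concatenate(rows["start"] + [np.asarray(rescued["start"], dtype=np.int64)])
    end = np.concatenate(rows["end"] + [np.asarray(rescued["end"], dtype=np.int64)])
    ident_ungapped = [100.0 * (rl - m) / rl for m in rows["mm"]]
    identity = np.concatenate(
        [np.asarray(x, dtype=np.float64) for x in ident_ungapped]
        + [np.asarray(rescued["identity"], dtype=np.float64)]
    )
    strand = np.concatenate(rows["rc"] + [np.asarray(rescued["rc"], dtype=bool)])
    span = np.concatenate(rows["span"] + [np.asarray(rescued["span"], dtype=np.int32)])

    n_ungapped = read_idx.size - len(rescued["read"])
    cigars = {n_ungapped + j: c for j, c in enumerate(rescued["cigar"])}

    order = np.argsort(read_idx, kind="stable")
    remap = np.empty(order.size, dtype=np.int64)
    remap[order] = np.arange(order.size)
    cigars = {int(remap[row]): c for row, c in cigars.items()}
    return AlignmentSet(
        ref_name, int(ref_codes.size),
        read_idx[order], start[order], end[order],
        identity[order], strand[order], span[order], cigars,
    )


def map_reads_exact(
    reads: ReadSet,
    reference: str,
    seed_length: int = 15,
    min_segment: int = 30,
    max_hits_per_seed: int = 8,
) -> pd.DataFrame:
    """Stringent local recruitment at exactly 100% identity.

    Used for the 16S copy-number procedure: reads are placed on a single
    gene coordinate system and contribute only their maximal error-free
    segments (length >= ``min_segment``), so a read with a sequencing error
    still covers the marker sites through its clean fragment, and reads
    from every identical gene copy collapse onto the one reference.
    Returns a segment table (read, start, end) rather than an
    AlignmentSet, since a read may contribute two flanking segments.
    """
    ref_codes = encode(reference)
    rl = reads.read_length
    if ref_codes.size < max(rl, seed_length):
        raise EmptyReferenceError("reference shorter than the read length")
    index = _KmerIndex(ref_codes, seed_length)
    segs: list[tuple[int, int, int, int]] = []  # (read, anchor, start, end)
    ar = np.arange(rl)
    for rc, mat in ((0, reads.codes), (1, revcomp_codes(reads.codes))):
        r, s = _candidates(mat, index, rl, max_hits_per_seed)
        if r.size == 0:
            continue
        key = r.astype(np.int64) * (ref_codes.size + 1) + s
        _, uniq = np.unique(key, return_index=True)
        r, s = r[uniq], s[uniq]
        for i in range(0, r.size, _CHUNK):
            sl = slice(i, min(i + _CHUNK, r.size))
            windows = ref_codes[s[sl, None] + ar]
            neq = windows != mat[r[sl]]
            for j in np.flatnonzero(neq.sum(axis=1) <= rl - min_segment):
                mism = np.flatnonzero(neq[j])
                bounds = np.concatenate(([-1], mism, [rl]))
                runs = np.diff(bounds) - 1
                anchor = int(s[sl][j])
                for b in np.flatnonzero(runs >= min_segment):
                    lo = int(bounds[b]) + 1
                    segs.append((int(r[sl][j]), anchor,
                                 anchor + lo, anchor + lo + int(runs[b])))
    if not segs:
        return pd.DataFrame(columns=["read_index", "start", "end"])
    df = pd.DataFrame(segs, columns=["read_index", "anchor", "start", "end"])
    df = df.drop_duplicates(["read_index", "anchor", "start", "end"])
    # one placement per read: keep the anchor with the most matching bases,
    # ties to the smallest reference coordinate (first best site)
    df["len"] = df["end"] - df["start"]
    tot = (
        df.groupby(["read_index", "anchor"])["len"].sum()
        .reset_index()
        .sort_values(["read_index", "len", "anchor"],
                     ascending=[True, False, True])
        .drop_duplicates("read_index")
    )
    best = pd.MultiIndex.from_frame(tot[["read_index", "anchor"]])
    df = df.set_index(["read_index", "anchor"]).loc[best].reset_index()
    return df[["read_index", "start", "end"]].reset_index(drop=True)


@dataclass
class DepthTrack:
    """Per-base depth and allele counts for one reference in one sample."""

    ref_id: str
    sample_id: str
    allele_counts: np.ndarray  # (5, L): rows A, C, G, T, deletion

    @property
    def depth(self) -> np.ndarray:
        return self.allele_counts.sum(axis=0)

    def __len__(self) -> int:
        return self.allele_counts.shape[1]

    def to_bedgraph(self, path) -> None:
        depth = self.depth
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.sample_id}"\n')
            for s, e in zip(starts, ends):
                fh.write(f"{self.ref_id}\t{s}\t{e}\t{int(depth[s])}\n")


def _apply_cigar(
    counts: np.ndarray, ref_pos: int, read_codes: np.ndarray, cigar: str
) -> None:
    """Walk an edlib extended CIGAR laying read bases onto the counts."""
    import re

    qpos = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(num)
        if op in "=XM":
            for t in range(n):
                c = read_codes[qpos + t]
                if c < 4:
                    counts[c, ref_pos + t] += 1
            ref_pos += n
            qpos += n
        elif op == "D":
            counts[4, ref_pos:ref_pos + n] += 1
            ref_pos += n
        else:  # insertion: consumes read only
            qpos += n


def pileup(
    alignments: AlignmentSet, reads: ReadSet, reference: AnnotatedGenome | int
) -> DepthTrack:
    """Build the per-base depth/allele track from recruited reads.

    Conserves depth: the sum of the depth array equals the total aligned
    reference span of the mapped reads.
    """
    L = len(reference) if not isinstance(reference, int) else reference
    if len(alignments) and int(alignments.end.max()) > L:
        raise ValueError("alignment beyond reference bounds")
    counts = np.zeros((5, L), dtype=np.int32)
    rl = reads.read_length

    gapped = set(alignments.cigars)
    ungapped = np.asarray(
        [i for i in range(len(alignments)) if i not in gapped], dtype=np.int64
    )
    if ungapped.size:
        ridx = alignments.read_index[ungapped]
        starts = alignments.start[ungapped]
        strands = alignments.strand[ungapped]
        ar = np.arange(rl)
        flat = counts.reshape(-1)
        for i in range(0, ridx.size, _CHUNK):
            sl = slice(i, min(i + _CHUNK, ridx.size))
            mat = reads.codes[ridx[sl]].copy()
            rc = strands[sl]
            if rc.any():
                mat[rc] = revcomp_codes(mat[rc])
            pos = starts[sl, None] + ar
            valid = mat < 4
            lin = mat.astype(np.int64) * L + pos
            flat += np.bincount(lin[valid].reshape(-1), minlength=5 * L).astype(np.int32)

    for row in gapped:
        i = int(alignments.read_index[row])
        codes = reads.codes[i]
        if alignments.strand[row]:
            codes = revcomp_codes(codes)
        _apply_cigar(counts, int(alignments.start[row]), codes, alignments.cigars[row])

    sample = reads.names[0].split("|")[0] if reads.names else ""
    ref_id = alignments.ref_id
    return DepthTrack(ref_id, sample, counts)


def pileup_segments(segments: pd.DataFrame, length: int) -> np.ndarray:
    """Depth array from a (start, end) segment table (stringent-mode pileup)."""
    delta = np.zeros(length + 1, dtype=np.int64)
    np.add.at(delta, segments["start"].to_numpy(), 1)
    np.add.at(delta, segments["end"].to_numpy(), -1)
    return np.cumsum(delta[:-1])


# ---------------------------------------------------------------------------
# coverage arithmetic
# ---------------------------------------------------------------------------


def median_mag_depth(track: DepthTrack | np.ndarray) -> float:
    """Median per-base read depth over the whole reference, zeros included."""
    depth = track.depth if isinstance(track, DepthTrack) else np.asarray(track)
    if depth.size == 0:
        raise ValueError("empty depth track")
    return float(np.median(depth))


def gene_coverage(track: DepthTrack | np.ndarray, start: int, end: int) -> float:
    """Mean per-base depth over a gene: sum of depths / number of bases."""
    depth = track.depth if isinstance(track, DepthTrack) else np.asarray(track)
    if end <= start:
        raise ValueError("zero-length gene")
    if start < 0 or end > depth.size:
        raise ValueError("gene outside reference bounds")
    return float(depth[start:end].mean())


def relative_coverage(
    gene_cov: float, mag_median: float, cap: float | None = None
) -> float:
    """Gene coverage over whole-genome median depth, in percent.

    Uncapped by default; multi-copy genes can exceed 100%. A display cap
    (e.g. 120) may be supplied.
    """
    if mag_median <= 0:
        raise ZeroDivisionError("genome median depth must be positive")
    value = gene_cov / mag_median * 100.0
    return min(value, cap) if cap is not None else value


def coverage_table(
    tracks: dict[str, DepthTrack],
    genome: AnnotatedGenome,
    metadata: dict[str, dict] | None = None,
    cap: float | None = None,
) -> pd.DataFrame:
    """Per-gene, per-sample coverage and relative coverage table."""
    rows = []
    metadata = metadata or {}
    for sample_id, track in tracks.items():
        depth = track.depth
        med = float(np.median(depth))
        meta = metadata.get(sample_id, {})
        for g in genome.genes:
            cov = float(depth[g.start:g.end].mean())
            rel = relative_coverage(cov, med, cap) if med > 0 else np.nan
            rows.append({
                "gene_id": g.gene_id, "sample_id": sample_id,
                "gene_coverage": cov, "relative_coverage": rel,
                "zone": meta.get("depth_zone", meta.get("zone", "")),
                "season": meta.get("season", ""),
                "period": meta.get("period", ""),
            })
    return pd.DataFrame(rows)


def zone_mean_relative_coverage(table: pd.DataFrame, zone: str) -> float:
    """Mean relative coverage over all samples (depths and periods) in a zone."""
    sub = table.loc[table["zone"] == zone, "relative_coverage"]
    if sub.empty:
        raise ValueError(f"no samples in zone {zone!r}")
    return float(sub.mean())
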