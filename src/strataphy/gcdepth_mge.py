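"""Divergence, prophage and defence-gene screening.

Four screens anchored on explicit threshold ladders rather than on any
particular alignment engine:

* GC-vs-depth: contigs of >= 10 kb and 30-80% GC are profiled; those in
  the GC neighbourhood of the target genome (default 45-80%) are aligned
  to it, and contigs with high alignment fraction but < 95% identity are
  flagged as divergent-relative candidates.
* Genome-vs-genome match classification: queries are binned, in order, as
  no-match, low-identity (< 80%), low alignment fraction (< 50% of the
  query aligned), short (< 1 kb aligned) or good.
* Prophage detection: a region is supported by alignment evidence when it
  matches more than one distinct viral sequence at > 95% identity, and by
  coverage evidence when its genes sit at a mean relative coverage of at
  least ``hc_multiplier`` x 100% (prophage copies outnumber host genomes).
* Defence-gene screening: local protein alignment (BLOSUM62, affine gaps)
  filtered by e-value < 1e-5, identity > 30% and query coverage > 50%.

The nucleotide aligner is a minimal seeded local aligner (k-mer hits
clustered by diagonal, X-drop ungapped extension, match +1 / mismatch -1)
adequate for desk-scale substitution-divergent sequences;
alignment-fraction denominators use the query length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode, revcomp, gc_percent
from .recruit import DepthTrack, _KmerIndex

# Karlin-Altschul parameters: standard ungapped BLOSUM62 defaults
KA_LAMBDA = 0.318
KA_K = 0.13

MATCH_CLASSES = ("no-match", "low-identity", "low-AF", "short", "good")


@dataclass
class LocalHit:
    """One local nucleotide alignment between a query and a subject."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float  # percent over the aligned length
    length: int  # aligned subject span
    strand: str = "+"

    @property
    def matches(self) -> float:
        return self.identity / 100.0 * self.length


def _best_diagonal_hit(
    q_codes: np.ndarray, s_codes: np.ndarray, k: int, xdrop: int
) -> LocalHit | None:
    """Best-scoring single-diagonal local alignment (match +1, mismatch -1),
    found by clustering shared k-mers by diagonal and X-drop extending."""
    if s_codes.size < k or q_codes.size < k:
        return None
    index = _KmerIndex(s_codes, k)
    powers = index.powers
    windows = np.lib.stride_tricks.sliding_window_view(q_codes, k)
    qk = windows.astype(np.uint64) @ powers
    lo, hi = index.lookup(qk)
    cnt = np.minimum(hi - lo, 64)
    if cnt.sum() == 0:
        return None
    qpos = np.repeat(np.arange(qk.size), cnt)
    offsets = np.arange(int(cnt.sum())) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    spos = index.positions[np.repeat(lo, cnt) + offsets]
    diag = spos - qpos

    best = None
    for d in np.unique(diag):
        sel = diag == d
        q_hits = qpos[sel]
        q_lo, q_hi = int(q_hits.min()), int(q_hits.max()) + k

        # X-drop extension on the diagonal in both directions
        def extend(start: int, step: int) -> int:
            run, sc, best_sc, best_i = start, 0, 0, start
            while True:
                q = run + step
                s = q + d
                if q < 0 or q >= q_codes.size or s < 0 or s >= s_codes.size:
                    break
                sc += 1 if q_codes[q] == s_codes[s] else -1
                if sc > best_sc:
                    best_sc, best_i = sc, q
                if best_sc - sc > xdrop:
                    break
                run = q
            return best_i

        left = extend(q_lo, -1) if q_lo > 0 else q_lo
        right = extend(q_hi - 1, +1) + 1 if q_hi < q_codes.size else q_hi
        neq = q_codes[left:right] != s_codes[left + d:right + d]
        length = right - left
        mism = int(neq.sum())
        score = length - 2 * mism
        if length <= 0:
            continue
        hit = LocalHit(
            q_start=left, q_end=right, s_start=int(left + d), s_end=int(right + d),
            identity=100.0 * (length - mism) / length, length=length,
        )
        if best is None or score > best[0]:
            best = (score, hit)
    return best[1] if best else None


def align_local(
    query: str, subject: str, k: int = 13, xdrop: int = 20, min_score: int = 25
) -> LocalHit | None:
    """Best local nucleotide alignment of query against subject, both
    strands, or None when the sequences share no seed or only chance-level
    similarity (alignment score below ``min_score``)."""
    q = encode(query)
    s = encode(subject)
    fwd = _best_diagonal_hit(q, s, k, xdrop)
    rc_hit = _best_diagonal_hit(encode(revcomp(query)), s, k, xdrop)
    if rc_hit is not None:
        n = q.size
        rc_hit = LocalHit(
            q_start=n - rc_hit.q_end, q_end=n - rc_hit.q_start,
            s_start=rc_hit.s_start, s_end=rc_hit.s_end,
            identity=rc_hit.identity, length=rc_hit.length, strand="-",
        )
    cands = [
        h for h in (fwd, rc_hit)
        if h is not None and 2 * h.matches - h.length >= min_score
    ]
    if not cands:
        return None
    return max(cands, key=lambda h: h.matches)


def classify_matches(
    queries: dict[str, str],
    references: dict[str, str],
    low_identity: float = 80.0,
    min_af: float = 0.5,
    min_length: int = 1000,
) -> pd.DataFrame:
    """Classify each query by its best alignment to any reference.

    Ladder, applied in order: no-match -> low-identity (< 80%) -> low-AF
    (< 50% of the query aligned) -> short (< 1 kb aligned) -> good.
    Alignment fraction uses the query length as denominator.
    """
    rows = []
    for qid, qseq in queries.items():
        best: LocalHit | None = None
        for rseq in references.values():
            hit = align_local(qseq, rseq)
            if hit is not None and (best is None or hit.matches > best.matches):
                best = hit
        if best is None:
            rows.append({"query_id": qid, "best_identity": np.nan,
                         "alignment_fraction": 0.0, "best_length": 0,
                         "class": "no-match"})
            continue
        af = (best.q_end - best.q_start) / len(qseq)
        if best.identity < low_identity:
            cls = "low-identity"
        elif af < min_af:
            cls = "low-AF"
        elif best.length < min_length:
            cls = "short"
        else:
            cls = "good"
        rows.append({"query_id": qid, "best_identity": best.identity,
                     "alignment_fraction": af, "best_length": best.length,
                     "class": cls})
    return pd.DataFrame(rows)


def gc_depth_screen(
    contigs: dict[str, str],
    tracks: dict[str, "DepthTrack | np.ndarray | float"],
    reference_contigs: dict[str, str] | None = None,
    min_len: int = 10_000,
    gc_window: tuple[float, float] = (30.0, 80.0),
    neighbourhood: tuple[float, float] = (45.0, 80.0),
    divergent_identity: float = 95.0,
    min_af: float = 0.5,
) -> pd.DataFrame:
    """GC-content vs read-depth screen for divergent relatives.

    Contigs shorter than ``min_len`` or outside ``gc_window`` are
    excluded. Contigs inside the GC ``neighbourhood`` of the target are
    flagged for alignment follow-up; with reference contigs supplied they
    are classified target-like (>= 95% identity, AF > 50%),
    divergent-candidate (< 95% identity, AF > 50%) or unclassified.
    """
    rows = []
    for cid, seq in contigs.items():
        length = len(seq)
        gc = gc_percent(seq)
        if length < min_len or not gc_window[0] <= gc <= gc_window[1]:
            continue
        tr = tracks.get(cid)
        if isinstance(tr, DepthTrack):
            mean_depth = float(tr.depth.mean())
        elif tr is None:
            mean_depth = np.nan
        else:
            mean_depth = float(np.mean(tr))
        follow_up = neighbourhood[0] <= gc <= neighbourhood[1]
        cls = "unclassified"
        identity = np.nan
        af = np.nan
        if follow_up and reference_contigs:
            best = None
            for rseq in reference_contigs.values():
                hit = align_local(seq, rseq)
                if hit is not None and (best is None or hit.matches > best.matches):
                    best = hit
            if best is not None:
                identity = best.identity
                af = (best.q_end - best.q_start) / length
                if af > min_af:
                    cls = ("target-like" if identity >= divergent_identity
                           else "divergent-candidate")
        rows.append({"contig_id": cid, "length": length, "gc": gc,
                     "mean_depth": mean_depth, "follow_up": follow_up,
                     "best_identity": identity, "alignment_fraction": af,
                     "class": cls})
    return pd.DataFrame(rows)


def _merge_intervals(ivs: list[tuple[int, int, str]]) -> list[tuple[int, int, set]]:
    """Merge overlapping (start, end, label) intervals, unioning labels."""
    out: list[tuple[int, int, set]] = []
    for s, e, lab in sorted(ivs):
        if out and s <= out[-1][1]:
            ps, pe, labs = out[-1]
            out[-1] = (ps, max(pe, e), labs | {lab})
        else:
            out.append((s, e, {lab}))
    return out


def detect_prophage(
    mag_contigs: dict[str, str],
    viral_refs: dict[str, str],
    coverage_table: pd.DataFrame | None = None,
    genes: list | None = None,
    min_identity: float = 95.0,
    hc_multiplier: float = 5.0,
    min_hit_length: int = 500,
) -> pd.DataFrame:
    """Putative prophage regions from viral alignment and coverage evidence.

    Alignment evidence needs > ``min_identity`` percent matches to at
    least two distinct viral sequences over a merged region. Coverage
    evidence needs genes at mean relative coverage >=
    ``hc_multiplier`` x 100% (prophage copy number exceeding the host's).
    Overlapping regions are merged; each reports its evidence type.
    """
    by_contig: dict[str, list[tuple[int, int, str]]] = {c: [] for c in mag_contigs}
    for vid, vseq in viral_refs.items():
        for cid, cseq in mag_contigs.items():
            hit = align_local(vseq, cseq)
            if hit is None or hit.identity <= min_identity:
                continue
            if hit.length < min_hit_length:
                continue
            by_contig[cid].append((hit.s_start, hit.s_end, vid))

    # genes: Gene objects (single-contig genome) or (gene_id, start, end
    # [, contig_id]) tuples for multi-contig references
    only_contig = next(iter(mag_contigs)) if len(mag_contigs) == 1 else None
    gene_pos: dict[str, tuple[int, int, str | None]] = {}
    if genes is not None:
        for g in genes:
            if hasattr(g, "gene_id"):
                gene_pos[g.gene_id] = (g.start, g.end, only_contig)
            else:
                gid, s, e, *rest = g
                gene_pos[gid] = (s, e, rest[0] if rest else only_contig)

    hc_genes: dict[str, list[tuple[int, int, str]]] = {c: [] for c in mag_contigs}
    if coverage_table is not None and gene_pos:
        mean_rel = coverage_table.groupby("gene_id")["relative_coverage"].mean()
        for gid, rel in mean_rel.items():
            if gid in gene_pos and rel >= hc_multiplier * 100.0:
                s, e, cid = gene_pos[gid]
                if cid is not None:
                    hc_genes[cid].append((s, e, f"hc:{gid}"))

    rows = []
    for cid in mag_contigs:
        aln_regions = _merge_intervals(by_contig[cid])
        cov_regions = _merge_intervals(hc_genes[cid])
        pooled = []
        for s, e, labs in aln_regions:
            if len(labs) >= 2:  # multiple distinct viral sequences required
                pooled.append((s, e, "alignment"))
        for s, e, _ in cov_regions:
            pooled.append((s, e, "coverage"))
        for s, e, kinds in _merge_intervals(pooled):
            evidence = "both" if kinds == {"alignment", "coverage"} else kinds.pop()
            region_rel = np.nan
            if coverage_table is not None and gene_pos:
                inside = [
                    gid for gid, (gs, ge, gcid) in gene_pos.items()
                    if gcid == cid and gs < e and ge > s
                ]
                if inside:
                    region_rel = float(
                        coverage_table[coverage_table["gene_id"].isin(inside)]
                        ["relative_coverage"].mean()
                    )
            rows.append({"contig_id": cid, "start": s, "end": e,
                         "evidence": evidence,
                         "mean_relative_coverage": region_rel})
    return pd.DataFrame(
        rows, columns=["contig_id", "start", "end", "evidence",
                       "mean_relative_coverage"],
    )


_NUC = set("ACGTUN")


def defence_screen(
    mag_proteins: dict[str, str],
    reference_proteins: dict[str, str],
    max_evalue: float = 1e-5,
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
) -> pd.DataFrame:
    """Protein-homology screen for defence genes.

    Local alignment with BLOSUM62 and affine gaps (open -11, extend -1);
    a hit is reported iff identity > ``min_identity`` percent, query
    coverage > ``min_coverage`` percent and Karlin-Altschul e-value <
    ``max_evalue`` against the searched database size. The thresholds are
    pure post-filters: loosening any one can only grow the hit set.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for name, seq in list(mag_proteins.items()) + list(reference_proteins.items()):
        if seq and set(seq.upper()) <= _NUC:
            raise ValueError(f"sequence {name!r} looks nucleotide, not protein")

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    db_size = sum(len(s) for s in reference_proteins.values())
    rows = []
    for qid, qseq in mag_proteins.items():
        for rid, rseq in reference_proteins.items():
            try:
                aln = aligner.align(qseq, rseq)[0]
            except (IndexError, ValueError):
                continue
            score = aln.score
            if score <= 0:
                continue
            qa, ra = aln[0], aln[1]
            cols = len(qa)
            ident_cols = sum(1 for x, y in zip(qa, ra) if x == y and x != "-")
            aligned_cols = sum(1 for x, y in zip(qa, ra) if x != "-" and y != "-")
            if aligned_cols == 0:
                continue
            identity = 100.0 * ident_cols / aligned_cols
            q_span = sum(1 for x in qa if x != "-")
            coverage = 100.0 * q_span / len(qseq)
            evalue = KA_K * len(qseq) * db_size * np.exp(-KA_LAMBDA * score)
            if identity > min_identity and coverage > min_coverage and evalue < max_evalue:
                rows.append({"query_id": qid, "subject_id": rid,
                             "score": float(score), "identity": identity,
                             "query_coverage": coverage, "evalue": evalue,
                             "aligned_columns": cols})
    return pd.DataFrame(
        rows, columns=["query_id", "subject_id", "score", "identity",
                       "query_coverage", "evalue", "aligned_columns"],
    )
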