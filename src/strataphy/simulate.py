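"""Synthetic two-phylotype community generator.

Builds a pair of near-identical genomes standing in for two sub-species
phylotypes of one cyanobacterial species: a shared gene backbone, two (or
one) nearly identical 16S rRNA copies per genome carrying two diagnostic
marker SNPs that distinguish the phylotypes, optional accessory gene
insertions private to one genome with zone-dependent population carriage,
and an optional prophage cassette that can be emitted at elevated copy
number. Reads are single-end, fixed-length, substitution-error-only, with
names that encode the source genome and position so every downstream stage
can be checked against the planted truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from ._seq import BASES, decode, encode, gc_percent, random_codes, revcomp_codes

GENE_CATEGORIES = ("core", "accessory", "prophage", "rrna16S", "marker_host")
DEPTH_ZONES = ("oxic", "interface", "anoxic")
SEASONS = ("summer", "winter", "spring")

# canonical 16S length: full-length gene as assembled in the reference bins
DEFAULT_RRNA_LENGTH = 1489
DEFAULT_MARKER_POSITIONS = (217, 231)  # 1-based offsets within the 16S gene


class SizingError(ValueError):
    """Requested gene content does not fit in the requested genome length."""


@dataclass
class Gene:
    gene_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    category: str = "core"

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RrnaLocus:
    """One 16S rRNA copy: genome interval plus within-gene marker offsets."""

    start: int
    end: int
    marker_offsets: tuple[int, ...] = DEFAULT_MARKER_POSITIONS  # 1-based in gene

    @property
    def marker_genome_positions(self) -> tuple[int, ...]:
        """0-based genome coordinates of the marker sites."""
        return tuple(self.start + off - 1 for off in self.marker_offsets)


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    genes: list[Gene]
    rrna_loci: list[RrnaLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode(self.sequence)
        return self._codes

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.codes)

    def validate(self) -> None:
        n = len(self.sequence)
        for g in self.genes:
            if not (0 <= g.start < g.end <= n):
                raise ValueError(f"gene {g.gene_id} outside sequence bounds")
        for loc in self.rrna_loci:
            if loc.end - loc.start < 1400:
                raise ValueError("16S locus shorter than 1400 bp")
            if not (0 <= loc.start < loc.end <= n):
                raise ValueError("16S locus outside sequence bounds")

    def rrna_sequence(self, copy: int = 0) -> str:
        loc = self.rrna_loci[copy]
        return self.sequence[loc.start:loc.end]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class AccessorySpec:
    """A gene private to one genome, carried by a zone-dependent fraction
    of that phylotype's population."""

    genome: str  # "A" or "B"
    length: int = 900
    carriage: dict[str, float] = field(
        default_factory=lambda: {"oxic": 1.0, "interface": 1.0, "anoxic": 1.0}
    )
    name: str | None = None

    def __post_init__(self) -> None:
        if self.genome not in ("A", "B"):
            raise ValueError("accessory genome must be 'A' or 'B'")
        for z, f in self.carriage.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"carriage fraction {f} for zone {z} outside [0, 1]")


@dataclass
class PhylotypePair:
    genome_a: AnnotatedGenome
    genome_b: AnnotatedGenome
    backbone_identity: float
    marker_positions: tuple[int, ...] = DEFAULT_MARKER_POSITIONS
    marker_a_alleles: tuple[str, ...] = ("A", "G")
    marker_b_alleles: tuple[str, ...] = ("T", "T")

    def genome(self, which: str) -> AnnotatedGenome:
        return self.genome_a if which == "A" else self.genome_b


@dataclass
class SampleDesign:
    sample_id: str
    depth_zone: str
    season: str
    fraction_b: float
    total_depth: float
    env: dict[str, float] = field(default_factory=dict)
    period: str = ""

    def __post_init__(self) -> None:
        if self.depth_zone not in DEPTH_ZONES:
            raise ValueError(f"unknown depth zone {self.depth_zone!r}")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if not 0.0 <= self.fraction_b <= 1.0:
            raise ValueError("fraction_b outside [0, 1]")
        if self.total_depth <= 0:
            raise ValueError("total_depth must be positive")


@dataclass
class MixtureDesign:
    samples: list[SampleDesign]

    def __iter__(self) -> Iterator[SampleDesign]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class TruthTable:
    """Planted ground truth for one simulated pair and its samples."""

    rrna_copies: int
    marker_positions: tuple[int, ...]
    # (backbone_pos, pos_in_A, pos_in_B, ref_base, alt_base), all 0-based
    backbone_snps: list[tuple[int, int, int, str, str]] = field(default_factory=list)
    # genome label -> one tuple of 0-based marker genome positions per 16S copy
    marker_sites: dict[str, list[tuple[int, ...]]] = field(default_factory=dict)
    # gene_id -> {"genome", "start", "end", "carriage"}
    accessory: dict[str, dict] = field(default_factory=dict)
    # genome label -> (start, end) of the prophage cassette, or absent
    prophage: dict[str, tuple[int, int]] = field(default_factory=dict)
    # sample_id -> per-sample truth
    samples: dict[str, dict] = field(default_factory=dict)

    def snp_positions(self, genome: str) -> list[int]:
        idx = 1 if genome == "A" else 2
        return [s[idx] for s in self.backbone_snps]


class ReadSet:
    """Fixed-length single-end reads held as a (n, read_length) code matrix."""

    def __init__(self, names: list[str], codes: np.ndarray):
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D (reads x positions) array")
        if len(names) != codes.shape[0]:
            raise ValueError("names/codes length mismatch")
        self.names = names
        self.codes = np.ascontiguousarray(codes, dtype=np.uint8)

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i: int) -> str:
        return decode(self.codes[i])

    @classmethod
    def from_sequences(cls, records: Iterable[tuple[str, str]]) -> "ReadSet":
        names, seqs = [], []
        for name, seq in records:
            names.append(name)
            seqs.append(encode(seq))
        if not names:
            return cls([], np.zeros((0, 0), dtype=np.uint8))
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("ReadSet requires fixed-length reads")
        return cls(names, np.vstack(seqs))

    @classmethod
    def concat(cls, parts: list["ReadSet"]) -> "ReadSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls([], np.zeros((0, 0), dtype=np.uint8))
        names = [n for p in parts for n in p.names]
        return cls(names, np.vstack([p.codes for p in parts]))

    def to_fastq(self, path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i, name in enumerate(self.names):
                fh.write(f"@{name}\n{self.sequence(i)}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        from Bio import SeqIO

        return cls.from_sequences(
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")
        )


# ---------------------------------------------------------------------------
# genome pair construction
# ---------------------------------------------------------------------------


def _make_rrna_copies(
    rng: np.random.Generator,
    rrna_length: int,
    copies: int,
    copy_divergence: int,
    marker_positions: tuple[int, ...],
    marker_alleles: tuple[str, ...],
    gc: float,
) -> list[np.ndarray]:
    """One canonical 16S sequence plus near-identical additional copies.

    Within-genome copy divergence is planted well downstream of the marker
    sites (past position 700) so markers stay diagnostic.
    """
    base = random_codes(rng, rrna_length, gc)
    for pos, allele in zip(marker_positions, marker_alleles):
        base[pos - 1] = BASES.index(allele)
    out = [base]
    lo = max(max(marker_positions) + 50, 700)
    for _ in range(1, copies):
        var = base.copy()
        if copy_divergence > 0:
            sites = rng.choice(
                np.arange(lo, rrna_length), size=copy_divergence, replace=False
            )
            for s in sites:
                var[s] = (var[s] + rng.integers(1, 4)) % 4
        out.append(var)
    return out


def simulate_pair(
    length: int = 100_000,
    gc: float = 60.0,
    n_genes: int = 40,
    snp_rate: float = 0.004,
    accessory_spec: list[AccessorySpec] | None = None,
    rrna_copies: int = 2,
    rrna_copy_divergence: int = 1,
    prophage_length: int = 0,
    marker_positions: tuple[int, ...] = DEFAULT_MARKER_POSITIONS,
    marker_a_alleles: tuple[str, ...] = ("A", "G"),
    marker_b_alleles: tuple[str, ...] = ("T", "T"),
    rrna_length: int = DEFAULT_RRNA_LENGTH,
    seed: int = 0,
) -> tuple[PhylotypePair, TruthTable]:
    """Simulate two phylotype genomes of one species plus their truth table.

    Genome B equals genome A except for backbone SNPs planted at
    ``snp_rate`` per eligible base (16S loci excluded), the diagnostic
    marker alleles in every 16S copy, and accessory insertions private to
    one genome. Deterministic for a fixed seed.
    """
    if length < 50_000:
        raise SizingError("genome length must be at least 50 kb")
    if rrna_copies not in (1, 2, 3):
        raise ValueError("rrna_copies must be 1, 2 or 3")
    if not 0.0 <= snp_rate < 0.05:
        raise ValueError("snp_rate outside [0, 0.05)")
    accessory_spec = list(accessory_spec or [])
    rng = np.random.default_rng(seed)

    # --- lay out genes on the shared backbone -----------------------------
    core_lens = rng.integers(600, 1200, size=n_genes)
    gaps = rng.integers(120, 400, size=n_genes + rrna_copies + 2)
    n_prophage_genes = 0
    if prophage_length:
        n_prophage_genes = max(1, prophage_length // 1000)
    needed = (
        int(core_lens.sum())
        + rrna_copies * rrna_length
        + prophage_length
        + int(gaps.sum())
        + 400
    )
    if needed > length:
        raise SizingError(
            f"genome of {length} bp cannot host {n_genes} genes, "
            f"{rrna_copies} 16S copies and a {prophage_length} bp prophage "
            f"({needed} bp required)"
        )

    # item list: ("core", len) / ("rrna", idx) / ("prophage", len)
    items: list[tuple[str, int]] = [("core", int(l)) for l in core_lens]
    rrna_slots = [max(1, n_genes // 4), max(2, (3 * n_genes) // 4)][:rrna_copies]
    if rrna_copies == 3:
        rrna_slots = [n_genes // 5, n_genes // 2, (4 * n_genes) // 5]
    for i, slot in enumerate(sorted(rrna_slots)):
        items.insert(slot + i, ("rrna", i))
    if prophage_length:
        items.insert(len(items) // 2, ("prophage", prophage_length))

    backbone = random_codes(rng, length, gc)
    rrna_seqs = _make_rrna_copies(
        rng, rrna_length, rrna_copies, rrna_copy_divergence,
        marker_positions, marker_a_alleles, gc,
    )

    genes: list[Gene] = []
    rrna_loci: list[RrnaLocus] = []
    prophage_iv: tuple[int, int] | None = None
    pos = 200
    gi = 0
    for j, (kind, val) in enumerate(items):
        pos += int(gaps[min(j, len(gaps) - 1)])
        if kind == "core":
            gi += 1
            genes.append(Gene(f"gene{gi:04d}", pos, pos + val,
                              "+" if rng.random() < 0.5 else "-", "core"))
            pos += val
        elif kind == "rrna":
            backbone[pos:pos + rrna_length] = rrna_seqs[val]
            genes.append(Gene(f"rrna16S_{val + 1}", pos, pos + rrna_length, "+", "rrna16S"))
            rrna_loci.append(RrnaLocus(pos, pos + rrna_length, marker_positions))
            pos += rrna_length
        else:  # prophage cassette as a run of equal-size genes
            prophage_iv = (pos, pos + val)
            glen = val // n_prophage_genes
            for p in range(n_prophage_genes):
                s = pos + p * glen
                e = pos + val if p == n_prophage_genes - 1 else s + glen
                genes.append(Gene(f"prophage{p + 1:02d}", s, e, "+", "prophage"))
            pos += val

    # --- genome B edits on the backbone -----------------------------------
    in_rrna = np.zeros(length, dtype=bool)
    for loc in rrna_loci:
        in_rrna[loc.start:loc.end] = True
    eligible = np.flatnonzero(~in_rrna)
    n_snps = rng.binomial(eligible.size, snp_rate)
    snp_pos = np.sort(rng.choice(eligible, size=n_snps, replace=False))
    backbone_b = backbone.copy()
    shifts = rng.integers(1, 4, size=n_snps).astype(np.uint8)
    backbone_b[snp_pos] = (backbone_b[snp_pos] + shifts) % 4
    for loc in rrna_loci:
        for off, allele in zip(marker_positions, marker_b_alleles):
            backbone_b[loc.start + off - 1] = BASES.index(allele)

    # --- accessory insertions ---------------------------------------------
    tail = pos + 200  # insertions go in the unused tail, one after another
    inserts: dict[str, list[tuple[int, int, str]]] = {"A": [], "B": []}  # (pos, len, id)
    acc_truth: dict[str, dict] = {}
    for i, spec in enumerate(accessory_spec):
        name = spec.name or f"acc{i + 1:02d}"
        at = tail + i * 50  # distinct backbone anchor per insertion
        if at + spec.length > length:
            raise SizingError("accessory genes do not fit in the genome tail")
        inserts[spec.genome].append((at, spec.length, name))
        acc_truth[name] = {"genome": spec.genome, "carriage": dict(spec.carriage)}

    def build(which: str, bb: np.ndarray) -> AnnotatedGenome:
        ins = sorted(inserts[which])
        pieces, gmap_pts, gmap_off = [], [0], [0]
        cur = 0
        offset = 0
        new_genes = [dataclasses.replace(g) for g in genes]
        acc_genes = []
        for at, ln, name in ins:
            pieces.append(bb[cur:at])
            seq = random_codes(rng, ln, gc)
            pieces.append(seq)
            acc_genes.append((name, at + offset, at + offset + ln))
            cur = at
            offset += ln
            gmap_pts.append(at)
            gmap_off.append(offset)
        pieces.append(bb[cur:])
        full = np.concatenate(pieces)

        pts = np.asarray(gmap_pts)
        offs = np.asarray(gmap_off)

        def shift(p: int) -> int:
            return p + int(offs[np.searchsorted(pts, p, side="right") - 1])

        for g in new_genes:
            g.start, g.end = shift(g.start), shift(g.end)
        for name, s, e in acc_genes:
            new_genes.append(Gene(name, s, e, "+", "accessory"))
        new_loci = [
            RrnaLocus(shift(l.start), shift(l.end), l.marker_offsets)
            for l in rrna_loci
        ]
        genome = AnnotatedGenome(which, decode(full), new_genes, new_loci)
        genome._shift = shift  # backbone -> genome coordinate map
        return genome

    genome_a = build("A", backbone)
    genome_b = build("B", backbone_b)
    genome_a.validate()
    genome_b.validate()

    truth = TruthTable(rrna_copies=rrna_copies, marker_positions=marker_positions)
    truth.backbone_snps = [
        (int(p), genome_a._shift(int(p)), genome_b._shift(int(p)),
         BASES[backbone[p]], BASES[backbone_b[p]])
        for p in snp_pos
    ]
    truth.marker_sites = {
        "A": [l.marker_genome_positions for l in genome_a.rrna_loci],
        "B": [l.marker_genome_positions for l in genome_b.rrna_loci],
    }
    for name, info in acc_truth.items():
        g = (genome_a if info["genome"] == "A" else genome_b).gene(name)
        truth.accessory[name] = {**info, "start": g.start, "end": g.end}
    if prophage_iv is not None:
        truth.prophage = {
            "A": (genome_a._shift(prophage_iv[0]), genome_a._shift(prophage_iv[1])),
            "B": (genome_b._shift(prophage_iv[0]), genome_b._shift(prophage_iv[1])),
        }

    n_eligible = eligible.size
    identity = 1.0 - (n_snps / n_eligible if n_eligible else 0.0)
    pair = PhylotypePair(
        genome_a, genome_b, identity, marker_positions,
        marker_a_alleles, marker_b_alleles,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _midpoint_weights(
    genome: AnnotatedGenome,
    truth: TruthTable,
    zone: str,
    read_length: int,
    prophage_multiplier: float,
) -> np.ndarray:
    n_starts = len(genome) - read_length + 1
    w = np.ones(n_starts)
    half = read_length // 2  # midpoint of a read starting at s is s + half

    def clamp(lo: int, hi: int) -> tuple[int, int]:
        return max(0, lo - half), min(n_starts, hi - half)

    for info in truth.accessory.values():
        if info["genome"] != genome.id:
            continue
        lo, hi = clamp(info["start"], info["end"])
        w[lo:hi] = info["carriage"].get(zone, 1.0)
    if genome.id in truth.prophage:
        lo, hi = clamp(*truth.prophage[genome.id])
        w[lo:hi] = prophage_multiplier
    return w


def simulate_sample(
    pair: PhylotypePair,
    design: SampleDesign,
    truth: TruthTable,
    read_length: int = 150,
    error_rate: float = 0.002,
    prophage_multiplier: float = 1.0,
    background_reads: int = 0,
    seed: int = 0,
) -> ReadSet:
    """Draw one merged sample's reads from the two phylotype genomes.

    Each read comes from genome B with probability ``design.fraction_b``;
    start positions are uniform apart from accessory-carriage thinning and
    prophage copy-number amplification; substitution errors are planted at
    ``error_rate`` per base. Read names encode sample, source genome,
    source start and strand. Updates ``truth.samples`` in place.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate outside [0, 0.05]")
    if read_length < 50:
        raise ValueError("read_length must be at least 50")
    rng = np.random.default_rng(seed)

    parts: list[ReadSet] = []
    n_by_genome = {}
    for which, frac in (("A", 1.0 - design.fraction_b), ("B", design.fraction_b)):
        genome = pair.genome(which)
        if frac <= 0.0:
            n_by_genome[which] = 0
            continue
        w = _midpoint_weights(genome, truth, design.depth_zone, read_length,
                              prophage_multiplier)
        lam = design.total_depth * frac * w.sum() / read_length
        n = int(rng.poisson(lam))
        n_by_genome[which] = n
        if n == 0:
            continue
        cdf = np.cumsum(w)
        starts = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
        starts = np.minimum(starts, len(w) - 1).astype(np.int64)
        is_rc = rng.random(n) < 0.5

        mat = genome.codes[starts[:, None] + np.arange(read_length)]
        # plant substitution errors as a sparse scatter over the read matrix
        n_err = rng.binomial(n * read_length, error_rate)
        if n_err:
            flat = rng.integers(0, n * read_length, size=n_err)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            mat.reshape(-1)[flat] = (mat.reshape(-1)[flat] + shift) % 4
        if is_rc.any():
            mat[is_rc] = revcomp_codes(mat[is_rc])
        names = [
            f"{design.sample_id}|{which}|{s}|{'-' if rc else '+'}|{i}"
            for i, (s, rc) in enumerate(zip(starts, is_rc))
        ]
        parts.append(ReadSet(names, mat))

    if background_reads:
        mat = rng.choice(4, size=(background_reads, read_length)).astype(np.uint8)
        names = [f"{design.sample_id}|bg|-1|+|{i}" for i in range(background_reads)]
        parts.append(ReadSet(names, mat))

    reads = ReadSet.concat(parts)
    n_total = n_by_genome["A"] + n_by_genome["B"]
    truth.samples[design.sample_id] = {
        "fraction_b": design.fraction_b,
        "depth_zone": design.depth_zone,
        "season": design.season,
        "period": design.period,
        "total_depth": design.total_depth,
        "n_reads": n_total,
        "n_reads_b": n_by_genome["B"],
        "prophage_multiplier": prophage_multiplier,
        "env": dict(design.env),
    }
    return reads


def default_mixture_design() -> MixtureDesign:
    """A stratified-lake sampling design emulating the study layout.

    Seven depths collapsed into three zones, sampled over several time
    periods; the B phylotype peaks at the oxic-anoxic interface while the
    A phylotype dominates the oxic zone. Environmental columns follow the
    lake's stratification: salinity rises and dissolved oxygen falls with
    depth, so phylotype-A abundance correlates negatively with depth and
    salinity and positively with DO.
    """
    depths = [
        ("surface", "oxic", 0.0), ("oxic1", "oxic", 5.0), ("oxic2", "oxic", 12.5),
        ("interface", "interface", 14.0), ("anoxic1", "anoxic", 15.0),
        ("anoxic2", "anoxic", 18.5), ("anoxic3", "anoxic", 23.5),
    ]
    periods = [("Nov08", "spring"), ("Jul14", "winter"),
               ("Oct14", "spring"), ("Dec14", "summer")]
    frac_b = {"oxic": 0.06, "interface": 0.45, "anoxic": 0.30}
    depth_scale = {"oxic": 1.0, "interface": 0.6, "anoxic": 0.35}
    samples = []
    for dname, zone, depth_m in depths:
        for period, season in periods:
            if zone == "anoxic" and season == "winter":
                continue  # winter anoxic samples were never collected
            samples.append(SampleDesign(
                sample_id=f"{dname}_{period}",
                depth_zone=zone,
                season=season,
                fraction_b=frac_b[zone],
                total_depth=200.0 * depth_scale[zone],
                env={
                    "depth_m": depth_m,
                    "salinity": 18.0 + 1.1 * depth_m,
                    "DO": max(0.0, 12.0 - 0.9 * depth_m),
                    "temperature": 8.0 - 0.5 * depth_m,
                },
                period=period,
            ))
    return MixtureDesign(samples)
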