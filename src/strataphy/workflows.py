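"""End-to-end simulation experiments used for validation.

Each function runs the full pipeline — simulate, recruit, pileup, estimate
— under fixed study conditions and returns the raw per-seed results, so
the same recipes back both the test suite and the reproduction script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import recruit
from .diffcov import differential_coverage, gene_counts
from .phylotype import contribution, rrna_copy_ratio
from .simulate import (
    AccessorySpec, SampleDesign, simulate_pair, simulate_sample,
)
from .variants import site_frequencies


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds derived from one master seed, kept < 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def copy_ratio_experiment(
    rrna_copies: int,
    n_seeds: int = 10,
    length: int = 100_000,
    depth: float = 200.0,
    read_length: int = 150,
    error_rate: float = 0.002,
    seed: int = 1,
) -> list[float]:
    """Stringent 16S read-depth ratios for genomes with a known copy number.

    Per seed: simulate a genome pair, draw a pure-A sample at uniform
    depth, recruit to the genome for the median, recruit at 100% identity
    to the 16S gene, and take the marker-site/genome depth ratio.
    """
    ratios = []
    for s in _child_seeds(seed, n_seeds):
        pair, truth = simulate_pair(length=length, rrna_copies=rrna_copies, seed=s)
        design = SampleDesign("cr", "oxic", "summer", 0.0, depth)
        reads = simulate_sample(pair, design, truth, read_length=read_length,
                                error_rate=error_rate, seed=s + 1)
        aln = recruit.map_reads(reads, pair.genome_a)
        track = recruit.pileup(aln, reads, pair.genome_a)
        med = recruit.median_mag_depth(track)
        ratios.append(rrna_copy_ratio(reads, pair.genome_a, med).ratio)
    return ratios


def phylotype_recovery_experiment(
    fractions: tuple[float, ...] = (0.05, 0.2, 0.5),
    n_seeds: int = 20,
    length: int = 50_000,
    n_genes: int = 30,
    depth: float = 300.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Marker-SNP deconvolution error across known mixture fractions.

    One genome pair per master seed; per seed and fraction, a mixed sample
    is recruited and the min-rule contribution is compared with truth.
    Returns a frame with fraction, seed, estimate and absolute error (in
    percentage points).
    """
    pair, truth = simulate_pair(length=length, n_genes=n_genes, snp_rate=0.004,
                                rrna_copies=2, seed=seed)
    positions = [p + 1 for p in truth.marker_sites["A"][0]]
    alleles = list(pair.marker_b_alleles)
    rows = []
    for i, s in enumerate(_child_seeds(seed + 1, n_seeds)):
        for frac in fractions:
            design = SampleDesign(f"m{i}", "interface", "spring", frac, depth)
            reads = simulate_sample(pair, design, truth, seed=s + int(frac * 1000))
            aln = recruit.map_reads(reads, pair.genome_a)
            track = recruit.pileup(aln, reads, pair.genome_a)
            mf = site_frequencies(track, positions, alleles)
            est = contribution(mf)
            rows.append({
                "fraction_b": frac, "seed": s,
                "estimate_pct": est.contribution_b,
                "abs_error_pp": abs(est.contribution_b - 100.0 * frac),
            })
    return pd.DataFrame(rows)


def null_calibration_experiment(
    n_seeds: int = 20,
    n_genes: int = 200,
    n_per_group: int = 6,
    mean_log: float = np.log(300.0),
    dispersion: float = 0.05,
    seed: int = 1,
) -> list[float]:
    """Type-I error of the NB Wald test on all-null count matrices.

    Counts are drawn from a negative binomial with lognormal gene means
    and no group differences; returns the per-seed fraction of genes with
    raw P <= 0.05.
    """
    fracs = []
    r = 1.0 / dispersion
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        mu = rng.lognormal(mean_log, 0.7, n_genes)
        p = r / (r + mu[:, None])
        counts = rng.negative_binomial(r, p, size=(n_genes, 2 * n_per_group))
        cols = [f"s{i}" for i in range(2 * n_per_group)]
        df = pd.DataFrame(counts, columns=cols)
        meta = pd.DataFrame(
            {"zone": ["oxic"] * n_per_group + ["anoxic"] * n_per_group},
            index=cols,
        )
        res = differential_coverage(df, meta, "zone", "oxic", "anoxic")
        fracs.append(float((res["P"] <= 0.05).mean()))
    return fracs


def planted_power_experiment(
    n_seeds: int = 20,
    carriage_high: float = 0.8,
    carriage_low: float = 0.2,
    depth: float = 100.0,
    n_per_group: int = 3,
    seed: int = 1,
) -> list[bool]:
    """Detection of a planted zone-biased accessory gene, read-level.

    The accessory gene is carried by ``carriage_high`` of the anoxic
    population and ``carriage_low`` of the oxic one (a 4-fold difference
    at the defaults). Per seed, 3 samples per zone go through recruitment,
    midpoint counting and the NB Wald test; returns whether the gene was
    flagged by the volcano rule with the anoxic-positive sign.
    """
    spec = [AccessorySpec(
        genome="B",
        carriage={"oxic": carriage_low, "interface": 0.5,
                  "anoxic": carriage_high},
        name="acc",
    )]
    hits = []
    for s in _child_seeds(seed, n_seeds):
        pair, truth = simulate_pair(length=50_000, n_genes=30, snp_rate=0.002,
                                    rrna_copies=2, accessory_spec=spec, seed=s)
        genome = pair.genome_b
        counts, meta = {}, {}
        for i, zone in enumerate(["oxic"] * n_per_group + ["anoxic"] * n_per_group):
            sid = f"{zone}{i}"
            design = SampleDesign(sid, zone, "summer", 1.0, depth)
            reads = simulate_sample(pair, design, truth, seed=s + i + 1)
            aln = recruit.map_reads(reads, genome)
            counts[sid] = gene_counts(aln, genome.genes, sid)
        df = pd.DataFrame(counts)
        meta = pd.DataFrame(
            {"zone": [sid.rstrip("0123456789") for sid in df.columns]},
            index=df.columns,
        )
        res = differential_coverage(df, meta, "zone", "anoxic", "oxic")
        hits.append(bool(res.loc["acc", "significant"]
                         and res.loc["acc", "log2FC"] > 1.0))
    return hits
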