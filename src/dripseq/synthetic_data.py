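"""Synthetic RNA-Seq study generator.

Emulates the structure of a five-strain knockout study in an
intron-poor yeast: a control strain plus four mutants (two NMD-like,
two EJC-like), three biological replicates each (15 libraries), genes
of which a minority host introns of at least 50 bp, per-library depth
spread matching the roughly 1.6-fold range seen in real sequencing
runs, log-normal baseline expression, NB count noise, strain-specific
gene-level DE effects, and strain-specific intron-retention shifts
(upf1-like mutants retain more, y14-like mutants retain less).

Counts are drawn at the feature level; reads are then placed uniformly
inside their feature, which makes the count matrix an exact function of
the read stream under intersection-strict counting (the round-trip
identity exercised in the tests). Sequence content is never simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, IntronFeature, extract_introns
from .counting import AlignedRead, CountMatrix

_CONTROL = "ku70"


@dataclass
class StrainEffects:
    """Per-strain truth specification.

    ``de_fraction`` of genes receive a log2 expression shift drawn from
    N(de_log2_mean, de_log2_sd) with random sign; ``dr_fraction`` of
    introns have their retention multiplied by ``dr_multiplier`` (or
    divided, when ``dr_direction`` is 'down')."""

    de_fraction: float = 0.0
    de_log2_mean: float = 2.0
    de_log2_sd: float = 0.25
    dr_fraction: float = 0.0
    dr_multiplier: float = 8.0
    dr_direction: str = "up"  # 'up' = more retained, 'down' = less


@dataclass
class SimulationScenario:
    """Generator configuration; the defaults are the study conditions.

    Depth multipliers are drawn uniformly over a 1.61-fold range
    (the 18.3-29.5 M spread of a real run, scaled down to ~50-80 k reads
    per library so a full pipeline run takes seconds)."""

    seed: int = 0
    n_genes: int = 500
    intron_probability: float = 0.3
    min_intron_length: int = 50
    intron_length_log_mean: float = 4.8  # ~120 bp median
    intron_length_log_sd: float = 0.35
    exon_length_log_mean: float = 6.9  # ~1 kb median
    exon_length_log_sd: float = 0.45
    base_depth: float = 1.0
    depth_spread: float = 29.5 / 18.3  # max/min per-library multiplier
    expression_log_mean: float = 4.0  # log of expected reads per gene
    expression_log_sd: float = 1.0
    dispersion: float = 0.05
    retention_min: float = 0.02
    retention_max: float = 0.15
    n_replicates: int = 3
    strains: dict[str, StrainEffects] = field(default_factory=lambda: {
        _CONTROL: StrainEffects(),
        "upf1": StrainEffects(de_fraction=0.05, dr_fraction=0.3,
                              dr_multiplier=8.0, dr_direction="up"),
        "upf2": StrainEffects(de_fraction=0.05, dr_fraction=0.05,
                              dr_multiplier=8.0, dr_direction="up"),
        "mago": StrainEffects(de_fraction=0.02, dr_fraction=0.05,
                              dr_multiplier=8.0, dr_direction="up"),
        "y14": StrainEffects(de_fraction=0.1, dr_fraction=0.3,
                             dr_multiplier=8.0, dr_direction="down"),
    })
    control: str = _CONTROL

    @property
    def library_ids(self) -> list[str]:
        return [f"{s}_r{r+1}" for s in self.strains
                for r in range(self.n_replicates)]

    def meta(self) -> pd.DataFrame:
        rows = [(f"{s}_r{r+1}", s, str(r + 1)) for s in self.strains
                for r in range(self.n_replicates)]
        return pd.DataFrame(rows, columns=["library_id", "strain", "replicate"]
                            ).set_index("library_id")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    de_genes: dict[str, dict[str, float]]  # strain -> gene_id -> log2 effect
    dr_introns: dict[str, dict[str, str]]  # strain -> intron_id -> direction
    depth_multipliers: pd.Series  # per library

    def true_de(self, strain: str) -> set[str]:
        return set(self.de_genes.get(strain, {}))

    def true_dr(self, strain: str) -> set[str]:
        return set(self.dr_introns.get(strain, {}))


def dr_benchmark_scenario(
    seed: int = 0,
    direction: str = "up",
    n_introns: int = 200,
    true_fraction: float = 0.25,
    multiplier: float = 8.0,
    dispersion: float = 0.05,
    mutant: str = "mut",
) -> SimulationScenario:
    """Two-strain benchmark for differential-retention recovery.

    One mutant versus control, 3 vs 3 replicates, ``n_introns``
    intron-bearing genes of which ``true_fraction`` carry a strong
    (``multiplier``-fold) retention shift in the given direction, no
    gene-level DE. Expression and baseline retention are set so that
    tested introns carry the kind of read counts that survive the
    40-RPK filter, mirroring the filtered universe the retention test
    actually operates on.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    return SimulationScenario(
        seed=seed,
        n_genes=n_introns,
        intron_probability=1.0,
        expression_log_mean=5.5,
        expression_log_sd=0.6,
        retention_min=0.1,
        retention_max=0.3,
        dispersion=dispersion,
        strains={
            _CONTROL: StrainEffects(),
            mutant: StrainEffects(dr_fraction=true_fraction,
                                  dr_multiplier=multiplier,
                                  dr_direction=direction),
        },
    )


def shifted_mass_scenario(
    seed: int = 0,
    multiplier: float = 4.0,
    n_introns: int = 150,
    dispersion: float = 0.05,
) -> SimulationScenario:
    """Benchmark for the borrowed-normalization contract.

    Every intron of the mutant strain is retained ``multiplier``-fold
    more while gene expression (hence sequencing depth per gene) is
    unchanged: the mutant's total intron mass shifts although the
    gene-level depths do not. Size factors estimated from the intron
    sub-matrix alone absorb the shift; gene-derived factors do not.
    """
    return SimulationScenario(
        seed=seed,
        n_genes=n_introns,
        intron_probability=1.0,
        expression_log_mean=5.5,
        expression_log_sd=0.6,
        retention_min=0.05,
        retention_max=0.15,
        dispersion=dispersion,
        strains={
            _CONTROL: StrainEffects(),
            "shifted": StrainEffects(dr_fraction=1.0,
                                     dr_multiplier=multiplier,
                                     dr_direction="up"),
        },
    )


def simulate_annotation(
    scenario: SimulationScenario,
) -> tuple[list[GeneModel], list[IntronFeature]]:
    """Lay out non-overlapping genes on synthetic chromosomes.

    Intron-bearing genes get two exons separated by a gap of at least
    ``min_intron_length``; others a single exon. Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(scenario.seed)
    genes: list[GeneModel] = []
    per_chrom = 100
    pos = 0
    chrom_i = 1
    for g in range(scenario.n_genes):
        if g > 0 and g % per_chrom == 0:
            chrom_i += 1
            pos = 0
        chrom = f"chr{chrom_i}"
        gid = f"g{g+1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exon_len = int(np.clip(rng.lognormal(
            scenario.exon_length_log_mean, scenario.exon_length_log_sd), 200, 20000))
        if rng.random() < scenario.intron_probability:
            intron_len = int(np.clip(rng.lognormal(
                scenario.intron_length_log_mean, scenario.intron_length_log_sd),
                scenario.min_intron_length, 5000))
            l1 = exon_len // 2
            exons = [(pos, pos + l1),
                     (pos + l1 + intron_len, pos + exon_len + intron_len)]
            pos += exon_len + intron_len
        else:
            exons = [(pos, pos + exon_len)]
            pos += exon_len
        pos += int(rng.integers(100, 500))  # intergenic gap
        genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                               exons=exons))
    introns = extract_introns(genes, scenario.min_intron_length)
    return genes, introns


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: float) -> np.ndarray:
    """NB draws with mean ``mean`` and variance mean + alpha * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    scenario: SimulationScenario,
    genes: list[GeneModel],
    introns: list[IntronFeature],
) -> tuple[CountMatrix, CountMatrix, SimulationTruth]:
    """Draw NB gene and intron count matrices plus the truth table.

    Gene counts: K ~ NB(depth_j * mu_g * 2^(DE effect), alpha).
    Intron counts: K ~ NB(depth_j * mu_g * rho_i * retention multiplier,
    alpha), where rho_i is the baseline retention fraction of intron i
    in its host gene's expression.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    meta = scenario.meta()
    libs = list(meta.index)
    n_lib = len(libs)

    lo = scenario.base_depth
    hi = scenario.base_depth * scenario.depth_spread
    depth = pd.Series(rng.uniform(lo, hi, size=n_lib), index=libs)

    gene_ids = [g.gene_id for g in genes]
    mu = rng.lognormal(scenario.expression_log_mean,
                       scenario.expression_log_sd, size=len(genes))
    mu_g = pd.Series(mu, index=gene_ids)

    intron_ids = [i.intron_id for i in introns]
    hosts = pd.Series({i.intron_id: i.gene_id for i in introns})
    rho = pd.Series(rng.uniform(scenario.retention_min, scenario.retention_max,
                                size=len(introns)), index=intron_ids)

    de_genes: dict[str, dict[str, float]] = {}
    dr_introns: dict[str, dict[str, str]] = {}
    gene_effect = pd.DataFrame(1.0, index=gene_ids, columns=list(scenario.strains))
    ret_effect = pd.DataFrame(1.0, index=intron_ids, columns=list(scenario.strains))
    for strain, eff in scenario.strains.items():
        if strain == scenario.control:
            continue
        de_genes[strain] = {}
        dr_introns[strain] = {}
        if eff.de_fraction > 0 and gene_ids:
            n_de = int(round(eff.de_fraction * len(gene_ids)))
            chosen = rng.choice(gene_ids, size=n_de, replace=False)
            for gid in chosen:
                l2 = rng.normal(eff.de_log2_mean, eff.de_log2_sd)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                gene_effect.loc[gid, strain] = 2.0 ** (sign * l2)
                de_genes[strain][gid] = sign * l2
        if eff.dr_fraction > 0 and intron_ids:
            n_dr = int(round(eff.dr_fraction * len(intron_ids)))
            chosen = rng.choice(intron_ids, size=n_dr, replace=False)
            mult = (eff.dr_multiplier if eff.dr_direction == "up"
                    else 1.0 / eff.dr_multiplier)
            for iid in chosen:
                ret_effect.loc[iid, strain] = mult
                dr_introns[strain][iid] = (
                    "more_retained" if eff.dr_direction == "up"
                    else "less_retained")

    strain_of = meta["strain"]
    gene_mean = np.empty((len(gene_ids), n_lib))
    intron_mean = np.empty((len(intron_ids), n_lib))
    for j, lib in enumerate(libs):
        s = strain_of.loc[lib]
        gm = mu_g.to_numpy() * gene_effect[s].to_numpy() * depth.loc[lib]
        gene_mean[:, j] = gm
        if intron_ids:
            host_mu = (mu_g.loc[hosts].to_numpy()
                       * gene_effect[s].loc[hosts].to_numpy())
            intron_mean[:, j] = (host_mu * rho.to_numpy()
                                 * ret_effect[s].to_numpy() * depth.loc[lib])

    gene_counts = _nb_draw(rng, gene_mean, scenario.dispersion)
    gene_cm = CountMatrix(
        pd.DataFrame(gene_counts, index=gene_ids, columns=libs),
        pd.Series({g.gene_id: g.length for g in genes}),
        meta,
    )
    if intron_ids:
        intron_counts = _nb_draw(rng, intron_mean, scenario.dispersion)
        intron_cm = CountMatrix(
            pd.DataFrame(intron_counts, index=intron_ids, columns=libs),
            pd.Series({i.intron_id: i.length for i in introns}),
            meta,
        )
    else:
        intron_cm = CountMatrix(
            pd.DataFrame(np.empty((0, n_lib), dtype=int), columns=libs),
            pd.Series(dtype=np.int64), meta,
        )
    truth = SimulationTruth(de_genes=de_genes, dr_introns=dr_introns,
                            depth_multipliers=depth)
    return gene_cm, intron_cm, truth


def simulate_reads(
    scenario: SimulationScenario,
    features: list[GeneModel] | list[IntronFeature],
    counts: CountMatrix,
    read_length: int = 50,
    boundary_fraction: float = 0.0,
    genes_by_id: dict[str, GeneModel] | None = None,
) -> dict[str, list[AlignedRead]]:
    """Emit one uniformly placed read per counted unit, per library.

    Reads are single-block and lie fully inside their feature, so
    intersection-strict counting reproduces the count matrix exactly.
    With ``boundary_fraction`` > 0 on intron features, that fraction of
    reads instead straddles the upstream exon/intron junction (requires
    ``genes_by_id``), producing reads that are ambiguous against a
    combined gene+intron feature set.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    intervals: dict[str, tuple[str, int, int]] = {}
    for f in features:
        if isinstance(f, GeneModel):
            s, e = f.span
            intervals[f.gene_id] = (f.chrom, s, e)
        else:
            intervals[f.intron_id] = (f.chrom, f.start, f.end)
    streams: dict[str, list[AlignedRead]] = {}
    for lib in counts.library_ids:
        reads: list[AlignedRead] = []
        col = counts.counts[lib]
        for fid, n in col.items():
            if n == 0:
                continue
            chrom, start, end = intervals[fid]
            flen = end - start
            rl = min(read_length, flen)
            for k in range(int(n)):
                if boundary_fraction > 0 and rng.random() < boundary_fraction:
                    # straddle the feature's 5' boundary
                    left = max(start - rl // 2, 0)
                    reads.append(AlignedRead(
                        read_id=f"{lib}:{fid}:{k}:b", chrom=chrom,
                        blocks=((left, left + rl),)))
                    continue
                offset = int(rng.integers(0, flen - rl + 1))
                reads.append(AlignedRead(
                    read_id=f"{lib}:{fid}:{k}", chrom=chrom,
                    blocks=((start + offset, start + offset + rl),)))
        streams[lib] = reads
    return streams


def write_sam(
    streams: dict[str, list[AlignedRead]],
    chrom_lengths: dict[str, int],
    out_dir,
    read_length_tag: str = "50M",
) -> dict[str, str]:
    """Write one SAM file per library; returns library -> path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    header_lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom, length in chrom_lengths.items():
        header_lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for lib, reads in streams.items():
        path = os.path.join(out_dir, f"{lib}.sam")
        with open(path, "w") as fh:
            fh.write("\n".join(header_lines) + "\n")
            for r in reads:
                length = r.blocks[0][1] - r.blocks[0][0]
                fh.write(
                    f"{r.read_id}\t0\t{r.chrom}\t{r.blocks[0][0] + 1}\t60\t"
                    f"{length}M\t*\t0\t0\t*\t*\n"
                )
        paths[lib] = path
    return paths
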