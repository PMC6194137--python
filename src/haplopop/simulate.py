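"""Synthetic haplodiploid population datasets.

Generates multi-population haploid genotype matrices with island-model
differentiation (Balding–Nichols allele frequencies), block-structured
local LD, heterozygous-artifact and missingness noise, optional planted
behavior-associated SNPs, and outgroup haplotypes carrying the ancestral
allele — everything the downstream stages assume, without external data.

LD is induced by a block latent-variable coupling: within each
``recomb_block_bp`` block an individual's calls at every SNP share one
uniform draw (call = 1 iff u < population frequency), which preserves the
per-SNP Bernoulli marginals exactly while correlating calls within the
block; blocks are independent, so r² decays to background beyond the
block scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from haplopop.pipeline_io import write_metadata, write_vcf
from haplopop.types import HET, MISSING, GenotypeMatrix, SampleRecord, VariantRecord

_BASES = np.array(list("ACGT"))


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's denominator)."""
    return float(sum(1.0 / i for i in range(1, n)))


@dataclass
class SimConfig:
    """Parameters of the synthetic haplodiploid dataset."""

    n_populations: int = 6
    samples_per_population: int = 25
    n_snps: int = 10_000
    scaffold_layout: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"scaffold_{i + 1}", 400_000) for i in range(5)]
    )
    behavior_assignment: dict[str, str] | None = None  # population -> social/solitary
    fst_target: float = 0.06
    ancestral_maf_law: str = "uniform"  # 'uniform' on [0.05, 0.5] | 'neutral_sfs'
    n_causal: int = 0
    causal_shift: float = 0.0
    het_artifact_rate: float = 0.002
    missing_rate: float = 0.01
    n_outgroup: int = 2
    recomb_block_bp: int = 500
    n_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        for name, rate in (
            ("het_artifact_rate", self.het_artifact_rate),
            ("missing_rate", self.missing_rate),
            ("causal_shift", self.causal_shift),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        if self.genome_length < self.n_snps:
            raise ValueError("scaffold layout cannot accommodate n_snps")
        if self.ancestral_maf_law not in ("uniform", "neutral_sfs"):
            raise ValueError(f"unknown ancestral_maf_law {self.ancestral_maf_law!r}")

    @property
    def populations(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    @property
    def behavior(self) -> dict[str, str]:
        if self.behavior_assignment is not None:
            return dict(self.behavior_assignment)
        pops = self.populations
        half = len(pops) // 2
        return {p: ("social" if i < half else "solitary") for i, p in enumerate(pops)}

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.scaffold_layout)

    @property
    def n_ingroup(self) -> int:
        return self.n_populations * self.samples_per_population

    @classmethod
    def for_target_diversity(
        cls, target_pi: float, n_haploids: int | None = None, **kwargs
    ) -> "SimConfig":
        """Choose n_snps so expected per-site diversity matches ``target_pi``.

        Calibrated for the neutral-SFS frequency law, under which pairwise
        diversity and Watterson's theta coincide in expectation:
        S = target * a_n * L.
        """
        kwargs.setdefault("ancestral_maf_law", "neutral_sfs")
        cfg = cls(n_snps=1, **kwargs)
        n = n_haploids if n_haploids is not None else cfg.n_ingroup
        s = int(round(target_pi * harmonic_number(n) * cfg.genome_length))
        kwargs["n_snps"] = max(s, 1)
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulation, for recovery tests and polarization checks."""

    variant_names: list[str]
    causal_ids: list[str]
    population_names: list[str]
    pop_freqs: np.ndarray  # [n_populations x n_snps]
    ancestral_freq: np.ndarray  # [n_snps] frequency of the alt allele in the ancestor
    ancestral_allele: np.ndarray  # [n_snps] 0 = ref ancestral, 1 = alt ancestral

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant": self.variant_names,
                "is_causal": [v in set(self.causal_ids) for v in self.variant_names],
                "ancestral_allele": np.where(self.ancestral_allele == 0, "ref", "alt"),
                "ancestral_freq": self.ancestral_freq,
            }
        )
        for i, pop in enumerate(self.population_names):
            df[f"freq_{pop}"] = self.pop_freqs[i]
        return df


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ancestral and per-population alt-allele frequencies.

    Returns (pop_freqs [n_pops x n_snps], ancestral [n_snps],
    causal_index [n_causal]).  Population frequencies follow the
    Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) law around the ancestral
    frequency; F -> 0 degenerates to copying the ancestral frequency.
    Causal SNPs get +shift/2 on social populations and -shift/2 on
    solitary ones, clipped to [0, 1].
    """
    m = config.n_snps
    if config.ancestral_maf_law == "uniform":
        p_anc = rng.uniform(0.05, 0.5, size=m)
    else:
        # unfolded neutral SFS over derived counts i = 1..n-1, P(i) ∝ 1/i
        n = config.n_ingroup
        i = np.arange(1, n)
        w = (1.0 / i) / np.sum(1.0 / i)
        p_anc = rng.choice(i, size=m, p=w) / n
    f = config.fst_target
    if f <= 0:
        pop_freqs = np.tile(p_anc, (config.n_populations, 1))
    else:
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pop_freqs = rng.beta(a, b, size=(config.n_populations, m))
    # place causal SNPs where the +-shift/2 displacement is realizable without
    # clipping away most of the signal; fall back to all SNPs if impossible
    if config.n_causal:
        half = config.causal_shift / 2.0
        eligible = np.flatnonzero((p_anc - half >= 0.05) & (p_anc + half <= 0.95))
        pool = eligible if len(eligible) >= config.n_causal else np.arange(m)
        causal_index = np.sort(rng.choice(pool, size=config.n_causal, replace=False))
    else:
        causal_index = np.empty(0, dtype=int)
    if config.n_causal and config.causal_shift > 0:
        behavior = config.behavior
        for k, pop in enumerate(config.populations):
            sign = 1.0 if behavior[pop] == "social" else -1.0
            pop_freqs[k, causal_index] = np.clip(
                pop_freqs[k, causal_index] + sign * config.causal_shift / 2.0, 0.0, 1.0
            )
    return pop_freqs, p_anc, causal_index


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _assign_positions(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Distribute SNPs across scaffolds proportionally to length.

    Returns (scaffold_index [m], pos [m], 1-based), sorted by scaffold then
    position, unique within scaffold.
    """
    lengths = np.array([length for _, length in config.scaffold_layout], dtype=float)
    counts = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    # distribute the remainder to the largest scaffolds first
    for i in np.argsort(-lengths)[: config.n_snps - counts.sum()]:
        counts[i] += 1
    scaf_idx = []
    positions = []
    for i, ((_, length), c) in enumerate(zip(config.scaffold_layout, counts)):
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=c, replace=False))
        scaf_idx.append(np.full(c, i))
        positions.append(pos)
    return np.concatenate(scaf_idx), np.concatenate(positions)


def simulate_genotypes(
    config: SimConfig,
    pop_freqs: np.ndarray,
    p_anc: np.ndarray,
    causal_index: np.ndarray,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw the haploid call matrix plus noise and outgroup haplotypes."""
    m = config.n_snps
    scaf_idx, positions = _assign_positions(config, rng)
    block_id = scaf_idx.astype(np.int64) * 10**9 + positions // config.recomb_block_bp
    _, block_codes = np.unique(block_id, return_inverse=True)
    n_blocks = block_codes.max() + 1

    n_in = config.n_ingroup
    pop_of_sample = np.repeat(np.arange(config.n_populations), config.samples_per_population)

    u = rng.uniform(size=(n_blocks, n_in))  # one latent draw per block per individual
    calls_in = (u[block_codes, :] < pop_freqs[pop_of_sample, :].T).astype(np.int8)

    # outgroup carries the ancestral allele (rounded to the major one)
    anc_allele = (p_anc > 0.5).astype(np.int8)
    calls_out = np.tile(anc_allele[:, None], (1, config.n_outgroup))

    calls = np.concatenate([calls_in, calls_out], axis=1)

    noise = rng.uniform(size=calls.shape)
    calls = calls.copy()
    calls[noise < config.het_artifact_rate] = HET
    calls[(noise >= config.het_artifact_rate) & (noise < config.het_artifact_rate + config.missing_rate)] = MISSING

    # alleles and site qualities
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    quals = np.round(rng.uniform(50.0, 1000.0, size=m), 2)

    variants = []
    for j in range(m):
        scaffold = config.scaffold_layout[scaf_idx[j]][0]
        variants.append(
            VariantRecord(
                scaffold=scaffold,
                pos=int(positions[j]),
                ref_allele=str(_BASES[ref_idx[j]]),
                alt_alleles=(str(_BASES[alt_idx[j]]),),
                qual=float(quals[j]),
            )
        )

    behavior = config.behavior
    samples = [
        SampleRecord(
            sample_id=f"{pop}_{i + 1:03d}",
            population=pop,
            behavior=behavior[pop],
            is_outgroup=False,
        )
        for pop in config.populations
        for i in range(config.samples_per_population)
    ]
    samples += [
        SampleRecord(
            sample_id=f"outgroup_{i + 1}",
            population="outgroup",
            behavior="unknown",
            is_outgroup=True,
        )
        for i in range(config.n_outgroup)
    ]

    gm = GenotypeMatrix(calls, variants, samples)
    names = [v.name for v in gm.variants]
    truth = SimTruth(
        variant_names=names,
        causal_ids=[names[j] for j in causal_index],
        population_names=config.populations,
        pop_freqs=pop_freqs,
        ancestral_freq=p_anc,
        ancestral_allele=anc_allele,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimConfig, rng: np.random.Generator) -> str:
    """Emit a GFF3 string of non-overlapping stranded genes with >= 2 exons.

    Every CDS length is divisible by 3; genes are separated by gaps well
    beyond the 10 kb proximal window so some positions stay intergenic.
    """
    lines = ["##gff-version 3"]
    for scaffold, length in config.scaffold_layout:
        lines.append(f"##sequence-region {scaffold} 1 {length}")
    placed = 0
    scaffold_cursor = [(scaffold, 12_000, length) for scaffold, length in config.scaffold_layout]
    gi = 0
    while placed < config.n_genes:
        if gi >= len(scaffold_cursor):
            raise ValueError("insufficient scaffold space for requested n_genes")
        scaffold, cursor, length = scaffold_cursor[gi]
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(60, 400, size=n_exons) * 3  # each exon fully coding
        intron_lens = rng.integers(80, 600, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        if cursor + span + 12_000 > length:
            gi += 1
            continue
        strand = "+" if rng.uniform() < 0.5 else "-"
        gene_id = f"gene{placed + 1:04d}"
        start = cursor
        exons = []
        s = start
        for k in range(n_exons):
            e = s + int(exon_lens[k]) - 1
            exons.append((s, e))
            s = e + 1 + (int(intron_lens[k]) if k < n_exons - 1 else 0)
        end = exons[-1][1]
        # phases in transcription order
        order = exons if strand == "+" else exons[::-1]
        phases = {}
        cum = 0
        for seg in order:
            phases[seg] = (3 - cum % 3) % 3
            cum += seg[1] - seg[0] + 1
        lines.append(
            f"{scaffold}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}"
        )
        mrna_id = f"{gene_id}.t1"
        lines.append(
            f"{scaffold}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={mrna_id};Parent={gene_id}"
        )
        for k, (es, ee) in enumerate(exons):
            lines.append(
                f"{scaffold}\tsim\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                f"ID={mrna_id}.exon{k + 1};Parent={mrna_id}"
            )
            lines.append(
                f"{scaffold}\tsim\tCDS\t{es}\t{ee}\t.\t{strand}\t{phases[(es, ee)]}\t"
                f"ID={mrna_id}.cds;Parent={mrna_id}"
            )
        placed += 1
        scaffold_cursor[gi] = (scaffold, end + int(rng.integers(15_000, 30_000)), length)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def simulate_matrix(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate the genotype matrix and truth only (no files)."""
    rng = np.random.default_rng(config.seed)
    pop_freqs, p_anc, causal = simulate_frequencies(config, rng)
    return simulate_genotypes(config, pop_freqs, p_anc, causal, rng)


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit VCF + GFF3 + metadata TSV + truth TSV; deterministic under seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pop_freqs, p_anc, causal = simulate_frequencies(config, rng)
    gm, truth = simulate_genotypes(config, pop_freqs, p_anc, causal, rng)
    gff_text = simulate_gene_models(config, rng)

    paths = {
        "vcf": out / "simulated.vcf",
        "gff": out / "genes.gff3",
        "metadata": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(gm, paths["vcf"])
    paths["gff"].write_text(gff_text)
    write_metadata(gm.samples, paths["metadata"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths
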