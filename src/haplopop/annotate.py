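"""Positional SNP annotation, outgroup polarization, and enrichment tests.

Positional classes, resolved in priority order when a SNP falls in
windows of several genes:

    coding (synonymous/non-synonymous/other) > intron > downstream_1kb >
    upstream_5kb > gene_proximal_10kb > intergenic

Windows are strand-aware: upstream extends against transcription from the
TSS, downstream extends past the final CDS base in transcription
direction.  Coding effects need scaffold sequence; without it CDS SNPs
are classed ``exon_other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import hypergeom

from haplopop.types import ALT, REF, GeneModel, GenotypeMatrix, VariantRecord

DEFAULT_WINDOWS = {"upstream": 5000, "downstream": 1000, "proximal": 10_000}

# smaller rank = higher priority
_CLASS_PRIORITY = {
    "exon_nonsynonymous": 0,
    "exon_synonymous": 0,
    "exon_other": 0,
    "intron": 1,
    "downstream_1kb": 2,
    "upstream_5kb": 3,
    "gene_proximal_10kb": 4,
    "intergenic": 5,
}

POSITIONAL_CLASSES = tuple(_CLASS_PRIORITY)


@dataclass
class SnpAnnotation:
    variant: str
    scaffold: str
    pos: int
    positional_class: str
    gene_id: str | None = None
    distance_to_gene: int = -1  # bp to the assigned gene's span; 0 inside


@dataclass
class EnrichmentResult:
    k: int  # hits in class within the selection
    big_k: int  # class members in the background
    n: int  # selection size
    big_n: int  # background size
    p_value: float


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def codon_effect(ref_codon: str, offset: int, alt_base: str) -> str:
    """'synonymous' or 'nonsynonymous' for a single-base codon substitution."""
    if len(ref_codon) != 3 or offset not in (0, 1, 2):
        raise ValueError("need a 3-base codon and offset in {0,1,2}")
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    same = str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate())
    return "exon_synonymous" if same else "exon_nonsynonymous"


def _cds_index(gene: GeneModel, pos: int) -> int | None:
    """0-based index of a genomic position within the spliced CDS, or None."""
    cum = 0
    for s, e, _ in gene.cds_segments:
        lo, hi = min(s, e), max(s, e)
        if lo <= pos <= hi:
            return cum + (pos - lo if gene.strand == "+" else hi - pos)
        cum += hi - lo + 1
    return None


def _spliced_cds_genomic_positions(gene: GeneModel) -> list[int]:
    out: list[int] = []
    for s, e, _ in gene.cds_segments:
        lo, hi = min(s, e), max(s, e)
        rng = range(lo, hi + 1) if gene.strand == "+" else range(hi, lo - 1, -1)
        out.extend(rng)
    return out


def _coding_class(
    gene: GeneModel,
    variant: VariantRecord,
    seqs: Mapping[str, object] | None,
) -> str:
    idx = _cds_index(gene, variant.pos)
    if idx is None:
        return "exon_other"  # exonic but non-CDS (UTR)
    phase0 = gene.cds_segments[0][2] if gene.cds_segments else 0
    if seqs is None or gene.scaffold not in seqs or idx < phase0:
        return "exon_other"
    codon_number = (idx - phase0) // 3
    codon_start = phase0 + 3 * codon_number
    genomic = _spliced_cds_genomic_positions(gene)
    if codon_start + 2 >= len(genomic):
        return "exon_other"  # trailing incomplete codon
    seq = seqs[gene.scaffold]
    bases = []
    for gpos in genomic[codon_start : codon_start + 3]:
        base = str(seq[gpos - 1 : gpos]).upper()
        if gene.strand == "-":
            base = base.translate(_COMPLEMENT)
        bases.append(base)
    offset = idx - codon_start
    ref_base = variant.ref_allele.upper()
    alt_base = variant.alt_alleles[0].upper()
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    bases[offset] = ref_base  # trust the VCF ref at the variant site
    return codon_effect("".join(bases), offset, alt_base)


def _classify_for_gene(
    gene: GeneModel,
    variant: VariantRecord,
    windows: Mapping[str, int],
    seqs: Mapping[str, object] | None,
) -> tuple[str, int] | None:
    """(class, distance-to-span) of this SNP relative to one gene, or None."""
    pos = variant.pos
    if gene.start <= pos <= gene.end:
        in_exon = any(min(s, e) <= pos <= max(s, e) for s, e in gene.exon_segments)
        if in_exon:
            return _coding_class(gene, variant, seqs), 0
        return "intron", 0

    distance = gene.start - pos if pos < gene.start else pos - gene.end
    up, down = windows["upstream"], windows["downstream"]
    if gene.strand == "+":
        in_upstream = gene.tss - up <= pos < gene.tss
        in_downstream = gene.last_codon_end < pos <= gene.last_codon_end + down
    else:
        in_upstream = gene.tss < pos <= gene.tss + up
        in_downstream = gene.last_codon_end - down <= pos < gene.last_codon_end
    if in_downstream:
        return "downstream_1kb", distance
    if in_upstream:
        return "upstream_5kb", distance
    if distance <= windows["proximal"]:
        return "gene_proximal_10kb", distance
    return None


def annotate_snp(
    variant: VariantRecord,
    genes: Sequence[GeneModel],
    windows: Mapping[str, int] = DEFAULT_WINDOWS,
    seqs: Mapping[str, object] | None = None,
) -> SnpAnnotation:
    """Assign exactly one positional class, resolving overlaps by priority.

    Among genes giving the same-priority class, the nearest gene wins.
    """
    best: tuple[int, int, str, str] | None = None  # (priority, distance, gene_id, class)
    for gene in genes:
        if gene.scaffold != variant.scaffold:
            continue
        hit = _classify_for_gene(gene, variant, windows, seqs)
        if hit is None:
            continue
        cls, dist = hit
        cand = (_CLASS_PRIORITY[cls], dist, gene.gene_id, cls)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return SnpAnnotation(
            variant=variant.name,
            scaffold=variant.scaffold,
            pos=variant.pos,
            positional_class="intergenic",
        )
    return SnpAnnotation(
        variant=variant.name,
        scaffold=variant.scaffold,
        pos=variant.pos,
        positional_class=best[3],
        gene_id=best[2],
        distance_to_gene=best[1],
    )


def annotate_table(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneModel],
    windows: Mapping[str, int] = DEFAULT_WINDOWS,
    seqs: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    rows = [annotate_snp(v, genes, windows, seqs) for v in variants]
    return pd.DataFrame(
        {
            "variant": [r.variant for r in rows],
            "scaffold": [r.scaffold for r in rows],
            "pos": [r.pos for r in rows],
            "positional_class": [r.positional_class for r in rows],
            "gene_id": [r.gene_id for r in rows],
            "distance_to_gene": [r.distance_to_gene for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# outgroup polarization
# ---------------------------------------------------------------------------

def polarize_alleles(gm: GenotypeMatrix) -> np.ndarray:
    """Derived-allele assignment per SNP from the outgroup haplotypes.

    Returns an object array over {'ref', 'alt', 'unpolarized'}: if every
    called outgroup haplotype carries one allele, the other allele is
    derived; discordant or fully missing outgroups leave the site
    unpolarized.
    """
    out_cols = gm.calls[:, ~gm.ingroup_mask]
    if out_cols.shape[1] == 0:
        return np.array(["unpolarized"] * gm.n_variants, dtype=object)
    any_ref = (out_cols == REF).any(axis=1)
    any_alt = (out_cols == ALT).any(axis=1)
    derived = np.where(
        any_ref & ~any_alt, "alt", np.where(any_alt & ~any_ref, "ref", "unpolarized")
    )
    return derived.astype(object)


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def positional_enrichment(
    hits: pd.DataFrame, background: pd.DataFrame, positional_class: str
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of a positional class among hit SNPs.

    ``hits`` and ``background`` are annotation tables; the background is
    the full set of tested SNPs (hits included).
    """
    n = len(hits)
    if n == 0:
        raise ValueError("empty hit list")
    big_n = len(background)
    k = int((hits["positional_class"] == positional_class).sum())
    big_k = int((background["positional_class"] == positional_class).sum())
    return EnrichmentResult(
        k=k, big_k=big_k, n=n, big_n=big_n,
        p_value=hypergeom_upper_tail(k, big_k, n, big_n),
    )


def gene_set_enrichment(
    candidate_genes: Sequence[str],
    gene_set: Sequence[str],
    universe: Sequence[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap of candidates with a gene set."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    cand = set(candidate_genes)
    gset = set(gene_set)
    if not cand <= uni or not gset <= uni:
        raise ValueError("candidate genes and gene set must be subsets of the universe")
    k = len(cand & gset)
    return EnrichmentResult(
        k=k, big_k=len(gset), n=len(cand), big_n=len(uni),
        p_value=hypergeom_upper_tail(k, len(gset), len(cand), len(uni)),
    )
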