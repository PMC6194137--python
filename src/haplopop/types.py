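"""Core domain types shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Genotype call alphabet for haploid individuals.  Heterozygous calls are
# genotyping artifacts in haploids and are flagged, never dosage-coded.
REF = 0          # homozygous/haploid reference call
ALT = 1          # homozygous/haploid first-alt call
ALT_OTHER = 2    # homozygous call of a second or later alt allele
HET = -1         # heterozygous artifact
MISSING = -2     # no call

CALL_DTYPE = np.int8


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site: coordinates, alleles and site quality."""

    scaffold: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        if self.qual < 0:
            raise ValueError(f"qual must be non-negative, got {self.qual}")

    @property
    def variant_class(self) -> str:
        """'snp' iff ref and every alt are single bases, else 'indel'/'other'."""
        if len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles):
            return "snp"
        if len(self.ref_allele) != len(self.alt_alleles[0]) or any(
            len(a) != len(self.ref_allele) for a in self.alt_alleles
        ):
            return "indel"
        return "other"

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold, self.pos)

    @property
    def name(self) -> str:
        return self.variant_id or f"{self.scaffold}:{self.pos}"


@dataclass(frozen=True)
class SampleRecord:
    """Individual metadata: population of origin, behavior group, outgroup flag."""

    sample_id: str
    population: str
    behavior: str  # 'social' | 'solitary' | 'unknown'
    is_outgroup: bool = False

    def __post_init__(self) -> None:
        if self.behavior not in ("social", "solitary", "unknown"):
            raise ValueError(f"invalid behavior {self.behavior!r}")
        if self.is_outgroup and self.behavior != "unknown":
            raise ValueError("outgroup samples must have behavior 'unknown'")


class GenotypeMatrix:
    """Variants x samples call matrix over {REF, ALT, ALT_OTHER, HET, MISSING}.

    The substrate of every statistic downstream of the VCF reader.  Calls
    are stored as int8 codes (see module constants); indices carry the full
    variant and sample metadata in matching order.
    """

    def __init__(
        self,
        calls: np.ndarray,
        variants: Sequence[VariantRecord],
        samples: Sequence[SampleRecord],
    ) -> None:
        calls = np.asarray(calls, dtype=CALL_DTYPE)
        if calls.ndim != 2:
            raise ValueError("calls must be 2-D (variants x samples)")
        if calls.shape != (len(variants), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        self.calls = calls
        self.variants = list(variants)
        self.samples = list(samples)

    # -- shape ---------------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    # -- masks & metadata ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ingroup_mask(self) -> np.ndarray:
        return np.array([not s.is_outgroup for s in self.samples], dtype=bool)

    @property
    def behavior_labels(self) -> np.ndarray:
        return np.array([s.behavior for s in self.samples], dtype=object)

    @property
    def population_labels(self) -> np.ndarray:
        return np.array([s.population for s in self.samples], dtype=object)

    @property
    def scaffolds(self) -> np.ndarray:
        return np.array([v.scaffold for v in self.variants], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def quals(self) -> np.ndarray:
        return np.array([v.qual for v in self.variants], dtype=float)

    # -- derived numeric views ----------------------------------------------
    def called_mask(self) -> np.ndarray:
        """True where the call is an interpretable haploid genotype (0/1/other-alt)."""
        return self.calls >= 0

    def biallelic_called_mask(self) -> np.ndarray:
        """True where the call is REF or ALT (usable for allele frequencies)."""
        return (self.calls == REF) | (self.calls == ALT)

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Float matrix of 0/1 haploid dosages with HET/MISSING/ALT_OTHER as NaN.

        With ``impute_mean`` NaNs are replaced by the per-variant mean dosage
        (0.0 at fully-uncallable sites).
        """
        d = np.where(self.biallelic_called_mask(), self.calls, np.nan).astype(float)
        if impute_mean:
            with np.errstate(invalid="ignore"):
                means = np.nanmean(d, axis=1)
            means = np.nan_to_num(means)
            idx = np.where(np.isnan(d))
            d[idx] = means[idx[0]]
        return d

    # -- subsetting ----------------------------------------------------------
    def take_variants(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            [self.variants[i] for i in index],
            self.samples,
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.variants,
            [self.samples[i] for i in index],
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenotypeMatrix({self.n_variants} variants x {self.n_samples} samples)"


@dataclass
class GeneModel:
    """Stranded gene model anchoring positional annotation windows.

    Coordinates are 1-based inclusive (GFF3 convention).  ``cds_segments``
    and ``exon_segments`` are sorted in transcription order: ascending start
    for '+' genes, descending for '-'.
    """

    gene_id: str
    scaffold: str
    strand: str  # '+' | '-'
    start: int  # genomic span, 1-based inclusive
    end: int
    exon_segments: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError("gene start must be <= end")

    @property
    def tss(self) -> int:
        """Transcription-direction-first transcript coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def last_codon_end(self) -> int:
        """Transcription-direction-most CDS base (the stop codon's final base)."""
        if not self.cds_segments:
            return self.end if self.strand == "+" else self.start
        if self.strand == "+":
            return max(e for _, e, _ in self.cds_segments)
        return min(s for s, _, _ in self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)
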