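"""Post-calling filter cascade for haploid resequencing data.

Order is fixed: individuals first (heterozygosity fraction), then variants,
with allele frequencies and missingness recomputed on the retained sample
set.  Site filters are evaluated independently so the report tallies every
filter a site fails; outgroup genotypes never count toward site filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from haplopop.types import ALT, ALT_OTHER, HET, MISSING, REF, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_qual: float = 30.0
    max_het_individuals: int = 15       # remove site if H-count >= this
    max_individual_het_fraction: float = 0.30
    max_uncalled: int = 16              # remove site if M-count >= this
    min_maf: float = 0.05
    require_biallelic: bool = True
    drop_indels: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.max_het_individuals < 0 or self.max_uncalled < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0.0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")


@dataclass
class QCReport:
    """Per-filter removal tallies; a site counts under every filter it fails."""

    n_variants_in: int = 0
    n_samples_in: int = 0
    removed_samples: list[str] = field(default_factory=list)
    removed_not_snp: int = 0
    removed_low_qual: int = 0
    removed_het_excess: int = 0
    removed_uncalled: int = 0
    removed_low_maf: int = 0
    removed_multiallelic: int = 0
    n_variants_out: int = 0
    n_samples_out: int = 0

    def to_dict(self) -> dict:
        return {
            "variants_in": self.n_variants_in,
            "samples_in": self.n_samples_in,
            "samples_removed": len(self.removed_samples),
            "not_snp": self.removed_not_snp,
            "low_qual": self.removed_low_qual,
            "het_excess": self.removed_het_excess,
            "uncalled": self.removed_uncalled,
            "low_maf": self.removed_low_maf,
            "multiallelic": self.removed_multiallelic,
            "variants_out": self.n_variants_out,
            "samples_out": self.n_samples_out,
        }


def filter_individuals(
    gm: GenotypeMatrix, th: QCThresholds
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove individuals whose heterozygous-call fraction exceeds the cap.

    The fraction is H-count over non-missing calls.  Individuals with no
    non-missing calls at all are removed with a warning.  Outgroup samples
    are subject to the same rule.
    """
    het = (gm.calls == HET).sum(axis=0)
    called = (gm.calls != MISSING).sum(axis=0)
    removed = np.zeros(gm.n_samples, dtype=bool)
    for i in range(gm.n_samples):
        if called[i] == 0:
            log.warning("sample %s has no called genotypes; removing", gm.sample_ids[i])
            removed[i] = True
        elif het[i] / called[i] > th.max_individual_het_fraction:
            removed[i] = True
    removed_ids = [gm.sample_ids[i] for i in np.flatnonzero(removed)]
    if removed_ids:
        log.info("filter_individuals: removed %d of %d samples", len(removed_ids), gm.n_samples)
    return gm.take_samples(~removed), removed_ids


def site_minor_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site MAF over biallelic calls of ingroup samples (H/M excluded).

    Sites with no usable calls get MAF 0 (removed by any positive min_maf).
    """
    sub = gm.calls[:, gm.ingroup_mask]
    alt = (sub == ALT).sum(axis=1)
    n = ((sub == REF) | (sub == ALT)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_variants(
    gm: GenotypeMatrix, th: QCThresholds
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the site-level filter cascade; individual filtering is assumed done."""
    report = QCReport(n_variants_in=gm.n_variants, n_samples_in=gm.n_samples)
    if gm.n_variants == 0:
        return gm, report

    ingroup = gm.ingroup_mask
    sub = gm.calls[:, ingroup]
    quals = gm.quals
    het_count = (sub == HET).sum(axis=1)
    missing_count = (sub == MISSING).sum(axis=1)
    maf = site_minor_allele_frequency(gm)
    is_snp = np.array([v.variant_class == "snp" for v in gm.variants])
    multi = np.array([len(v.alt_alleles) > 1 for v in gm.variants]) | (
        (sub == ALT_OTHER).any(axis=1)
    )

    fails = {}
    fails["not_snp"] = ~is_snp if th.drop_indels else np.zeros(gm.n_variants, bool)
    fails["low_qual"] = quals < th.min_qual
    fails["het_excess"] = het_count >= th.max_het_individuals
    fails["uncalled"] = missing_count >= th.max_uncalled
    fails["low_maf"] = maf < th.min_maf
    fails["multiallelic"] = multi if th.require_biallelic else np.zeros(gm.n_variants, bool)

    report.removed_not_snp = int(fails["not_snp"].sum())
    report.removed_low_qual = int(fails["low_qual"].sum())
    report.removed_het_excess = int(fails["het_excess"].sum())
    report.removed_uncalled = int(fails["uncalled"].sum())
    report.removed_low_maf = int(fails["low_maf"].sum())
    report.removed_multiallelic = int(fails["multiallelic"].sum())

    keep = ~np.logical_or.reduce(list(fails.values()))
    out = gm.take_variants(keep)
    report.n_variants_out = out.n_variants
    report.n_samples_out = out.n_samples
    log.info(
        "filter_variants: %d -> %d sites (%s)",
        gm.n_variants,
        out.n_variants,
        {k: int(v.sum()) for k, v in fails.items()},
    )
    return out, report


def run_qc(
    gm: GenotypeMatrix, th: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Full cascade: individuals first, then sites on the retained cohort."""
    th = th or QCThresholds()
    gm2, removed = filter_individuals(gm, th)
    out, report = filter_variants(gm2, th)
    report.removed_samples = removed
    report.n_samples_in = gm.n_samples
    return out, report
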