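"""Readers/writers for the formats the pipeline touches, plus run configuration.

External coordinates (VCF, GFF3) are 1-based inclusive; all internal interval
arithmetic is half-open 0-based.  :func:`to_internal` / :func:`to_external`
are the converting bijections.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from haplopop.types import (
    ALT,
    ALT_OTHER,
    HET,
    MISSING,
    REF,
    GeneModel,
    GenotypeMatrix,
    SampleRecord,
    VariantRecord,
)

log = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "population", "behavior", "is_outgroup"]


class MetadataError(KeyError):
    """A VCF sample is absent from the metadata table."""


class VcfParseError(ValueError):
    """Malformed VCF content; carries the offending line number when known."""


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive interval -> half-open 0-based."""
    return start_1based - 1, end_1based


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """Half-open 0-based interval -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | os.PathLike) -> list[SampleRecord]:
    """Read the 4-column sample table (sample_id, population, behavior, is_outgroup)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                population=row.population,
                behavior=row.behavior,
                is_outgroup=str(row.is_outgroup).strip().lower() in ("1", "true", "yes"),
            )
        )
    return records


def write_metadata(samples: Iterable[SampleRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.population, s.behavior, int(s.is_outgroup)) for s in samples],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _code_call(alleles: list[int]) -> int:
    """Map a genotype's allele indices to the haploid call alphabet.

    Single-allele ('0') and homozygous-diploid ('0/0') dialects collapse to
    the same code; '/' vs '|' is immaterial.  Unequal alleles are the
    heterozygous-artifact code, any missing allele the missing code.
    """
    if any(a < 0 for a in alleles):
        return MISSING
    if len(set(alleles)) > 1:
        return HET
    a = alleles[0]
    if a == 0:
        return REF
    if a == 1:
        return ALT
    return ALT_OTHER


def read_vcf(path: str | os.PathLike, metadata: list[SampleRecord]) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, normalizing haploid genotype coding.

    Every VCF sample must appear in ``metadata``; samples present in the
    metadata but absent from the VCF are ignored.  Multiallelic sites are
    retained (QC removes them later); alleles are never split.
    """
    from cyvcf2 import VCF

    by_id = {s.sample_id: s for s in metadata}
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error surface
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = []
    for sid in vcf.samples:
        if sid not in by_id:
            raise MetadataError(f"VCF sample {sid!r} missing from metadata table")
        samples.append(by_id[sid])

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            variants.append(
                VariantRecord(
                    scaffold=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_alleles=tuple(rec.ALT) if rec.ALT else ("<NON_REF>",),
                    qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                    variant_id=rec.ID,
                )
            )
            # rec.genotypes: per sample [allele, (allele,) phased-flag]
            row = np.fromiter(
                (_code_call([a for a in g[:-1]]) for g in rec.genotypes),
                dtype=np.int8,
                count=len(samples),
            )
            rows.append(row)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record near data line {lineno + 1}: {exc}") from exc

    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    gm = GenotypeMatrix(calls, variants, samples)
    log.info("read_vcf: %d variants x %d samples from %s", gm.n_variants, gm.n_samples, path)
    return gm


_CODE_TO_GT = {REF: "0/0", ALT: "1/1", HET: "0/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 with diploid-style genotype strings.

    Round-trips through :func:`read_vcf` exactly (calls, variant order,
    sample order).  ALT_OTHER calls are written as homozygous second-alt.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaffold in dict.fromkeys(v.scaffold for v in gm.variants):
            length = max(v.pos for v in gm.variants if v.scaffold == scaffold) + 1000
            fh.write(f"##contig=<ID={scaffold},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for i, v in enumerate(gm.variants):
            gts = [
                _CODE_TO_GT.get(c, "2/2")
                for c in gm.calls[i]
            ]
            fh.write(
                f"{v.scaffold}\t{v.pos}\t{v.variant_id or '.'}\t{v.ref_allele}\t"
                f"{','.join(v.alt_alleles)}\t{v.qual:g}\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read GFF3 gene models (gene/mRNA/exon/CDS) via an in-memory gffutils DB.

    If a gene has several mRNAs, the isoform with the longest total CDS is
    kept.  Segments are returned in transcription order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        best = None
        best_len = -1
        for mrna in db.children(g, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            exons = list(db.children(mrna, featuretype="exon", order_by="start"))
            total = sum(c.end - c.start + 1 for c in cds)
            if total > best_len:
                best_len = total
                best = (cds, exons)
        if best is None:
            cds = list(db.children(g, featuretype="CDS", order_by="start"))
            exons = list(db.children(g, featuretype="exon", order_by="start"))
            best = (cds, exons)
        cds, exons = best
        reverse = g.strand == "-"
        cds_sorted = sorted(cds, key=lambda c: c.start, reverse=reverse)
        exon_sorted = sorted(exons, key=lambda e: e.start, reverse=reverse)
        genes.append(
            GeneModel(
                gene_id=g.id,
                scaffold=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                exon_segments=[(e.start, e.end) for e in exon_sorted],
                cds_segments=[
                    (c.start, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
                    for c in cds_sorted
                ],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables of the pipeline; defaults are the published thresholds."""

    # variant QC
    min_qual: float = 30.0
    max_het_individuals: int = 15
    max_individual_het_fraction: float = 0.30
    max_uncalled: int = 16
    min_maf: float = 0.05
    require_biallelic: bool = True
    drop_indels: bool = True
    # popgen
    ld_window_bp: int = 50_000
    prune_window_snps: int = 50
    prune_step_snps: int = 5
    prune_vif_threshold: float = 2.0
    n_permutations: int = 1000
    permutation_subset: int = 100_000
    # gwas / annotation
    fdr_q_threshold: float = 5e-5
    upstream_bp: int = 5000
    downstream_bp: int = 1000
    proximal_bp: int = 10_000
    # misc
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        """Load a flat ``key = value`` file; unknown keys are an error."""
        values: dict[str, object] = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                default = getattr(cls, key)
                if isinstance(default, bool):
                    values[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    values[key] = int(val)
                else:
                    values[key] = float(val)
        return cls(**values)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    config: RunConfig | None = None,
    inputs: Iterable[str | os.PathLike] = (),
) -> list[Path]:
    """Write stage outputs as TSVs with stable column order plus a manifest.

    Any table with ``scaffold``/``pos`` columns is sorted by coordinate
    first, so reruns with identical inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        if {"scaffold", "pos"} <= set(df.columns):
            df = df.sort_values(["scaffold", "pos"], kind="mergesort")
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "tables": [p.name for p in written],
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(mpath)
    return written
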