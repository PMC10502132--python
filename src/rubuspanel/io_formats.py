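"""VCF and design-table IO.

Reading goes through cyvcf2 (htslib); writing emits plain VCF 4.2 text so the
round trip ``read_vcf(write_vcf(gm))`` is exact at the GT/site level. Design
tables are two-column TSV (sample, group) with optional header and ``#``
comments.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .core import GROUP_LABELS, GenotypeMatrix, LocusInfo, PanelDesign, PanelError


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed."""


class UnsupportedPloidyError(ValueError):
    """Raised on non-diploid GT entries, naming the offending record."""


def _locus_id(chrom: str, pos: int, ref: str, alt: str, vcf_id: str | None) -> str:
    if vcf_id and vcf_id != ".":
        return vcf_id
    return f"{chrom}:{pos}:{ref}:{alt}"


def read_vcf(path, source: str) -> tuple[GenotypeMatrix, list[LocusInfo]]:
    """Parse diploid GT fields to ALT dosage.

    Multi-allelic records are retained with ``is_biallelic=False`` (removed
    later by QC); their dosage is the count of non-REF alleles. Any genotype
    with a missing allele, including half calls like ``0/.``, becomes missing.
    Phase is ignored.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises bare exceptions on bad headers
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    loci: list[LocusInfo] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        alts = var.ALT or []
        dosage = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # last element is the phase flag
            if len(alleles) != 2:
                raise UnsupportedPloidyError(
                    f"non-diploid genotype (ploidy {len(alleles)}) for sample "
                    f"{samples[i]} at {var.CHROM}:{var.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                continue  # missing or half-called -> missing
            dosage[i] = float((alleles[0] != 0) + (alleles[1] != 0))
        alt = alts[0] if alts else "."
        loci.append(
            LocusInfo(
                locus_id=_locus_id(var.CHROM, var.POS, var.REF, alt, var.ID),
                source=source,
                seq_name=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=alt if alt != "." else var.REF + "?",
                is_biallelic=len(alts) == 1,
            )
        )
        columns.append(dosage)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    gm = GenotypeMatrix(samples, [l.locus_id for l in loci], dosage)
    return gm, loci


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    "##source=rubuspanel",
    '##INFO=<ID=SRC,Number=1,Type=String,Description="Originating call set (MOC or MID)">',
    '##INFO=<ID=SCAF,Number=1,Type=String,Description="Scaffold coordinate seq:pos for MID-only markers">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def write_vcf(
    gm: GenotypeMatrix,
    loci: list[LocusInfo],
    path,
    depths: np.ndarray | None = None,
    info_extra: dict[str, str] | None = None,
) -> Path:
    """Write a VCF 4.2 text file; inverse of :func:`read_vcf`.

    ``depths``, if given, is a samples x loci integer matrix emitted as the
    per-genotype DP field (missing genotypes get '.'). ``info_extra`` maps
    locus_id to an extra INFO fragment (e.g. scaffold back-references).
    """
    if len(loci) != gm.n_loci or [l.locus_id for l in loci] != gm.loci:
        raise PanelError("locus registry does not match the LocusInfo list")
    if depths is not None and depths.shape != gm.dosage.shape:
        raise PanelError("depth matrix shape does not match dosage matrix")
    path = Path(path)
    contigs = list(dict.fromkeys(l.seq_name for l in loci))
    with open(path, "w") as fh:
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        fmt = "GT" if depths is None else "GT:DP"
        for j, locus in enumerate(loci):
            info = f"SRC={locus.source}"
            if info_extra and locus.locus_id in info_extra:
                info += ";" + info_extra[locus.locus_id]
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                gt = _GT_STRINGS.get(d, "./.")
                if depths is None:
                    cells.append(gt)
                else:
                    dp = "." if not np.isfinite(d) else str(int(depths[i, j]))
                    cells.append(f"{gt}:{dp}")
            fh.write(
                "\t".join(
                    [
                        locus.seq_name,
                        str(locus.pos),
                        locus.locus_id,
                        locus.ref_allele,
                        locus.alt_allele,
                        ".",
                        "PASS",
                        info,
                        fmt,
                    ]
                    + cells
                )
                + "\n"
            )
    return path


def read_design(path) -> PanelDesign:
    """Read a two-column (sample, group) TSV into a :class:`PanelDesign`."""
    assignments: dict[str, str] = {}
    dupes: list[str] = []
    bad: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PanelError(f"line {lineno}: expected two tab-separated columns")
            sample, group = parts[0].strip(), parts[1].strip()
            if not assignments and group.lower() in ("group", "label", "family"):
                continue  # header row
            if sample in assignments:
                dupes.append(sample)
            if group not in GROUP_LABELS:
                bad.append((sample, group))
            assignments[sample] = group
    if dupes:
        raise PanelError(f"duplicate sample rows: {sorted(set(dupes))}")
    if bad:
        raise PanelError(
            f"labels outside {GROUP_LABELS}: {bad[:10]}"
        )
    return PanelDesign(assignments=assignments)


def write_design(design: PanelDesign, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in design.assignments.items():
            fh.write(f"{sample}\t{group}\n")
    return path


@dataclasses.dataclass
class DepthSummary:
    """Mean sequencing depth; ``available`` is False when the VCF has no DP."""

    available: bool
    overall: float | None = None
    per_sample: dict[str, float] | None = None


def mean_depth(path) -> DepthSummary:
    """Arithmetic mean of non-missing per-genotype DP, per sample and pooled."""
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    if "##FORMAT=<ID=DP" not in vcf.raw_header:
        warnings.warn(f"{path}: no per-genotype DP field; depth unavailable")
        return DepthSummary(available=False)
    samples = list(vcf.samples)
    total = np.zeros(len(samples))
    count = np.zeros(len(samples))
    for var in vcf:
        dp = var.format("DP")
        if dp is None:
            continue
        dp = dp.reshape(len(samples)).astype(float)
        ok = dp >= 0  # htslib encodes missing as a negative sentinel
        total[ok] += dp[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        per = total / count
    per_sample = {s: float(per[i]) for i, s in enumerate(samples) if count[i] > 0}
    if count.sum() == 0:
        return DepthSummary(available=False)
    return DepthSummary(
        available=True,
        overall=float(total.sum() / count.sum()),
        per_sample=per_sample,
    )
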