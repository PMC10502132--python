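"""Marker quality control: biallelic -> call rate -> MAF -> LD prune.

Filter order is fixed and every removal is logged with the stage at which
the locus died, so input = output + removals always holds and the pipeline
is idempotent. Boundary semantics default to inclusive (call rate >= 0.90,
MAF >= 0.05); a strict mode switches both to ``>``.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from ._corr import pairwise_r
from .core import GenotypeMatrix, LocusInfo, PanelError


@dataclasses.dataclass
class QCReport:
    """Per-stage survivor counts, removal log, and per-sequence marker counts."""

    stage_counts: dict[str, int]  # stage -> surviving loci after that stage
    removals: pd.DataFrame  # columns: locus_id, stage
    per_seq_counts: pd.Series  # surviving markers per chromosome/scaffold
    thresholds: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.stage_counts["input"], 0)]
        prev = self.stage_counts["input"]
        for stage in ("biallelic", "call_rate", "maf", "ld_prune"):
            n = self.stage_counts[stage]
            rows.append((stage, n, prev - n))
            prev = n
        return pd.DataFrame(rows, columns=["stage", "surviving", "removed"])


def _subset(gm: GenotypeMatrix, loci: list[LocusInfo], keep: np.ndarray):
    idx = np.flatnonzero(keep)
    return gm.take_loci(idx), [loci[i] for i in idx]


def filter_biallelic(
    gm: GenotypeMatrix, loci: list[LocusInfo]
) -> tuple[GenotypeMatrix, list[LocusInfo], list[str]]:
    """Drop loci flagged multi-allelic by the VCF reader."""
    keep = np.array([l.is_biallelic for l in loci], dtype=bool)
    removed = [l.locus_id for l, k in zip(loci, keep) if not k]
    gm2, loci2 = _subset(gm, loci, keep)
    return gm2, loci2, removed


def call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing genotypes per locus."""
    return np.isfinite(gm.dosage).mean(axis=0)


def filter_call_rate(
    gm: GenotypeMatrix,
    loci: list[LocusInfo],
    threshold: float = 0.90,
    strict: bool = False,
) -> tuple[GenotypeMatrix, list[LocusInfo], list[str]]:
    """Keep loci with call rate >= threshold (> in strict mode)."""
    if not 0.0 < threshold <= 1.0:
        raise PanelError(f"call-rate threshold must be in (0,1], got {threshold}")
    cr = call_rate(gm)
    keep = cr > threshold if strict else cr >= threshold
    removed = [l.locus_id for l, k in zip(loci, keep) if not k]
    gm2, loci2 = _subset(gm, loci, keep)
    return gm2, loci2, removed


def filter_maf(
    gm: GenotypeMatrix,
    loci: list[LocusInfo],
    threshold: float = 0.05,
    strict: bool = False,
) -> tuple[GenotypeMatrix, list[LocusInfo], list[str]]:
    """Keep loci with MAF >= threshold (> in strict mode); monomorphic always removed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(gm.dosage, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = np.isfinite(maf) & (maf > 0)
    keep &= (maf > threshold) if strict else (maf >= threshold)
    removed = [l.locus_id for l, k in zip(loci, keep) if not k]
    gm2, loci2 = _subset(gm, loci, keep)
    return gm2, loci2, removed


def _check_sorted(loci: list[LocusInfo]) -> None:
    keys = [(l.seq_name, l.pos) for l in loci]
    if keys != sorted(keys):
        raise PanelError("loci must be sorted by (seq_name, pos); sort before pruning")


def prune_ld(
    gm: GenotypeMatrix,
    loci: list[LocusInfo],
    r2_threshold: float = 0.99,
    window_bp: int = 1_000_000,
    min_overlap: int = 20,
) -> tuple[GenotypeMatrix, list[LocusInfo], list[str]]:
    """Greedy left-to-right LD pruning within a physical window.

    For each kept locus, any later locus on the same sequence within
    ``window_bp`` whose squared dosage correlation exceeds ``r2_threshold``
    is dropped (first-kept-wins). Correlations use pairwise-complete
    observations; pairs with fewer than ``min_overlap`` shared calls are
    never pruned.
    """
    _check_sorted(loci)
    L = gm.n_loci
    keep = np.ones(L, dtype=bool)
    seqs = np.array([l.seq_name for l in loci])
    pos = np.array([l.pos for l in loci])
    D = gm.dosage
    for seq in pd.unique(seqs):
        idx = np.flatnonzero(seqs == seq)
        spos = pos[idx]
        for ii in range(idx.size):
            i = idx[ii]
            if not keep[i]:
                continue
            hi = int(np.searchsorted(spos, spos[ii] + window_bp, side="left"))
            cand = idx[ii + 1 : hi]
            cand = cand[keep[cand]]
            if cand.size == 0:
                continue
            r, n = pairwise_r(D[:, [i]], D[:, cand])
            r2 = r[0] ** 2
            drop = np.isfinite(r2) & (r2 > r2_threshold) & (n[0] >= min_overlap)
            keep[cand[drop]] = False
    removed = [loci[i].locus_id for i in np.flatnonzero(~keep)]
    gm2, loci2 = _subset(gm, loci, keep)
    return gm2, loci2, removed


def qc_pipeline(
    gm: GenotypeMatrix,
    loci: list[LocusInfo],
    call_rate_threshold: float = 0.90,
    maf_threshold: float = 0.05,
    ld_r2_threshold: float = 0.99,
    window_bp: int = 1_000_000,
    strict: bool = False,
    min_overlap: int = 20,
) -> tuple[GenotypeMatrix, list[LocusInfo], QCReport]:
    """Compose the four filters in fixed order and log every removal."""
    counts = {"input": gm.n_loci}
    log: list[tuple[str, str]] = []

    gm, loci, rem = filter_biallelic(gm, loci)
    log += [(r, "biallelic") for r in rem]
    counts["biallelic"] = gm.n_loci

    gm, loci, rem = filter_call_rate(gm, loci, call_rate_threshold, strict)
    log += [(r, "call_rate") for r in rem]
    counts["call_rate"] = gm.n_loci

    gm, loci, rem = filter_maf(gm, loci, maf_threshold, strict)
    log += [(r, "maf") for r in rem]
    counts["maf"] = gm.n_loci

    gm, loci, rem = prune_ld(gm, loci, ld_r2_threshold, window_bp, min_overlap)
    log += [(r, "ld_prune") for r in rem]
    counts["ld_prune"] = gm.n_loci

    if gm.n_loci == 0:
        warnings.warn("QC removed every locus; downstream stages will be empty")
    per_seq = pd.Series([l.seq_name for l in loci]).value_counts().sort_index()
    report = QCReport(
        stage_counts=counts,
        removals=pd.DataFrame(log, columns=["locus_id", "stage"]),
        per_seq_counts=per_seq,
        thresholds={
            "call_rate": call_rate_threshold,
            "maf": maf_threshold,
            "ld_r2": ld_r2_threshold,
            "window_bp": window_bp,
            "strict": float(strict),
        },
    )
    return gm, loci, report
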