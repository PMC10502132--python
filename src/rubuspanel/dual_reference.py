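"""Harmonize two call sets of the same panel into a "unique" marker matrix.

The same variant called against two reference assemblies shows up as two
columns with near-perfect genotype correlation across samples (|r| ~ 1; the
sign is negative when the assemblies disagree on which allele is REF).
Coincident columns are detected by all-pairs pairwise-complete Pearson
correlation, resolved to a one-to-one matching, and the duplicate copy is
dropped from the scaffold-anchored (MID) set, keeping the chromosome-anchored
(MOC) copy.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from ._corr import pairwise_r
from .core import GenotypeMatrix, LocusInfo, PanelError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MarkerPair:
    """An accepted coincident-marker pair across the two call sets."""

    moc_locus_id: str
    mid_locus_id: str
    r: float  # signed Pearson correlation of dosages
    n_overlap: int
    flipped: bool  # r < 0: REF/ALT coding differs between assemblies


def match_markers(
    gm_moc: GenotypeMatrix,
    gm_mid: GenotypeMatrix,
    r_threshold: float = 0.98,
    min_overlap: int = 20,
    signed: bool = False,
) -> list[MarkerPair]:
    """Detect coincident markers between the two call sets.

    Candidates are column pairs with |r| >= ``r_threshold`` (r >= threshold
    in ``signed`` mode, which refuses coding flips) and at least
    ``min_overlap`` pairwise-complete samples. Candidates are resolved
    greedily to a one-to-one matching by descending |r|, ties broken by
    larger overlap then lexicographic locus ids. Constant columns have
    undefined correlation and are excluded (logged).
    """
    if set(gm_moc.samples) != set(gm_mid.samples):
        raise PanelError("call sets do not share a sample registry")
    if gm_mid.samples != gm_moc.samples:
        gm_mid = gm_mid.subset_samples(gm_moc.samples)

    r, n = pairwise_r(gm_moc.dosage, gm_mid.dosage)
    n_const = int(np.isnan(r).all(axis=1).sum() + np.isnan(r).all(axis=0).sum())
    if n_const:
        logger.info("%d constant/undefined columns excluded from matching", n_const)
    score = r if signed else np.abs(r)
    with np.errstate(invalid="ignore"):
        cand = np.argwhere((score >= r_threshold) & (n >= min_overlap))
    if cand.size == 0:
        return []
    keys = sorted(
        (
            (
                -abs(r[i, j]),
                -n[i, j],
                gm_moc.loci[i],
                gm_mid.loci[j],
                i,
                j,
            )
            for i, j in cand
        )
    )
    used_moc: set[int] = set()
    used_mid: set[int] = set()
    pairs: list[MarkerPair] = []
    for _, _, moc_id, mid_id, i, j in keys:
        if i in used_moc or j in used_mid:
            continue
        used_moc.add(i)
        used_mid.add(j)
        pairs.append(
            MarkerPair(
                moc_locus_id=moc_id,
                mid_locus_id=mid_id,
                r=float(r[i, j]),
                n_overlap=int(n[i, j]),
                flipped=bool(r[i, j] < 0),
            )
        )
    return pairs


def build_unique_matrix(
    gm_moc: GenotypeMatrix,
    loci_moc: list[LocusInfo],
    gm_mid: GenotypeMatrix,
    loci_mid: list[LocusInfo],
    pairs: list[MarkerPair],
) -> tuple[GenotypeMatrix, list[LocusInfo], pd.DataFrame]:
    """Union of the call sets with the MID copy of each pair removed.

    Output columns = all MOC columns + unpaired MID columns, so
    ``|unique| = |MOC| + |MID| - |pairs|``. The link table carries
    (chromosome, position, scaffold, position, r, flipped) per accepted
    pair — the input for circos-style cross-assembly visualisation.
    """
    if gm_mid.samples != gm_moc.samples:
        gm_mid = gm_mid.subset_samples(gm_moc.samples)
    moc_ids = set(gm_moc.loci)
    mid_ids = set(gm_mid.loci)
    for p in pairs:
        if p.moc_locus_id not in moc_ids or p.mid_locus_id not in mid_ids:
            raise PanelError(
                f"pair ({p.moc_locus_id}, {p.mid_locus_id}) references unknown loci"
            )
    paired_mid = {p.mid_locus_id for p in pairs}
    keep_mid = [i for i, lid in enumerate(gm_mid.loci) if lid not in paired_mid]

    dosage = np.hstack([gm_moc.dosage, gm_mid.dosage[:, keep_mid]])
    loci = list(loci_moc) + [loci_mid[i] for i in keep_mid]
    gm = GenotypeMatrix(
        gm_moc.samples, gm_moc.loci + [gm_mid.loci[i] for i in keep_mid], dosage
    )

    moc_info = {l.locus_id: l for l in loci_moc}
    mid_info = {l.locus_id: l for l in loci_mid}
    link = pd.DataFrame(
        [
            (
                moc_info[p.moc_locus_id].seq_name,
                moc_info[p.moc_locus_id].pos,
                mid_info[p.mid_locus_id].seq_name,
                mid_info[p.mid_locus_id].pos,
                p.r,
                p.flipped,
            )
            for p in pairs
        ],
        columns=["chrom", "chrom_pos", "scaffold", "scaffold_pos", "r", "flipped"],
    )
    return gm, loci, link
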