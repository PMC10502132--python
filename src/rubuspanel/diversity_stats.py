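"""Diversity statistics: MAF, PIC, Ho, GD, molecular inbreeding and Ne.

Per-locus statistics are functions of the within-group ALT frequency
p = (sum of dosages) / (2 * non-missing calls):

    MAF = min(p, 1-p)
    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2      (Botstein's biallelic PIC)
    GD  = 2 p (1-p)                         (expected heterozygosity)

The molecular inbreeding coefficient of individual j is computed from the
identity of its two alleles over its S callable SNPs. Under the
allele-identity reading (default) a homozygous locus contributes 2 and a
heterozygous locus 1 to the double sum, and the coefficient reduces exactly
to F_ej = 1 - Ho_j, the proportion of homozygous loci. A literal mode that
scores the het indicator (0 hom / 1 het) instead is provided for audit; it
reduces to F_ej = 2*Ho_j - 1 and can be negative. The effective population
size follows Ne = 1 / (2 * mean F).
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PanelDesign, PanelError

INBREEDING_MODES = ("allele_identity", "het_indicator_literal")

#: Table-row order for the group report
REPORT_GROUPS = ("ALL", "Pr", "Ps", "JG", "JS", "JT")


def allele_freq(gm: GenotypeMatrix, samples: list[str] | None = None) -> np.ndarray:
    """Per-locus ALT frequency on non-missing calls; NaN where no calls."""
    d = gm.dosage if samples is None else gm.dosage[gm.sample_indices(samples)]
    if d.shape[0] == 0:
        raise PanelError("empty sample subset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(d, axis=0) / 2.0


def maf(p) -> np.ndarray:
    """Minor allele frequency min(p, 1-p)."""
    p = np.asarray(p, dtype=float)
    return np.minimum(p, 1.0 - p)


def pic(p) -> np.ndarray:
    """Polymorphic information content, biallelic closed form."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


def gd(p) -> np.ndarray:
    """Genetic diversity (expected heterozygosity) 2p(1-p)."""
    p = np.asarray(p, dtype=float)
    return 2.0 * p * (1.0 - p)


def observed_het(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-locus, per-individual) fraction of non-missing calls that are het."""
    het = gm.dosage == 1.0
    called = np.isfinite(gm.dosage)
    with np.errstate(invalid="ignore"):
        per_locus = het.sum(axis=0) / called.sum(axis=0)
        per_ind = het.sum(axis=1) / called.sum(axis=1)
    return per_locus, per_ind


def inbreeding_fej(gm: GenotypeMatrix, mode: str = "allele_identity") -> np.ndarray:
    """Per-individual molecular inbreeding coefficient F_ej.

    ``allele_identity`` (default): F_ej = proportion of homozygous loci
    = 1 - Ho_j, bounded in [0, 1]. ``het_indicator_literal``: F_ej =
    2*Ho_j - 1, the reduction obtained when the per-locus score is the
    heterozygosity indicator instead of allele identity.
    """
    if mode not in INBREEDING_MODES:
        raise PanelError(f"unknown inbreeding mode {mode!r}")
    _, ho_j = observed_het(gm)
    if mode == "allele_identity":
        return 1.0 - ho_j
    return 2.0 * ho_j - 1.0


def effective_size(mean_f: float) -> float:
    """Effective population size Ne = 1 / (2 * mean F).

    Non-positive mean inbreeding has no finite Ne under this estimator;
    infinity is returned with a warning rather than raising.
    """
    if not np.isfinite(mean_f) or mean_f <= 0:
        warnings.warn(f"mean inbreeding {mean_f} <= 0: Ne undefined (infinite)")
        return float("inf")
    return 1.0 / (2.0 * mean_f)


@dataclasses.dataclass
class DiversityReport:
    """Group-level diversity table plus per-locus and per-individual detail."""

    summary: pd.DataFrame  # index: group; columns n, Ne, MAF, PIC, Ho, GD, F
    per_locus: pd.DataFrame  # index: locus; columns p, MAF, PIC, Ho, GD (ALL samples)
    per_individual: pd.DataFrame  # index: sample; columns group, Ho, F
    inbreeding_mode: str

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "table1_mirror.tsv", "w") as fh:
            fh.write(f"# inbreeding_mode={self.inbreeding_mode}\n")
            self.summary.to_csv(fh, sep="\t", float_format="%.6g")
        self.per_locus.to_csv(out / "per_locus.tsv", sep="\t", float_format="%.6g")
        self.per_individual.to_csv(
            out / "per_individual.tsv", sep="\t", float_format="%.6g"
        )


def _group_row(gm: GenotypeMatrix, samples: list[str], mode: str) -> dict[str, float]:
    sub = gm.subset_samples(samples)
    p = allele_freq(sub)
    defined = np.isfinite(p)
    ho_locus, _ = observed_het(sub)
    f = inbreeding_fej(sub, mode)
    f = f[np.isfinite(f)]
    mean_f = float(np.mean(f)) if f.size else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "n": len(samples),
            "Ne": effective_size(mean_f) if np.isfinite(mean_f) else float("nan"),
            "MAF": float(np.mean(maf(p[defined]))),
            "PIC": float(np.mean(pic(p[defined]))),
            "Ho": float(np.nanmean(ho_locus)),
            "GD": float(np.mean(gd(p[defined]))),
            "F": mean_f,
        }


def group_report(
    gm: GenotypeMatrix, design: PanelDesign, mode: str = "allele_identity"
) -> DiversityReport:
    """Diversity table with one row per group and an ALL row.

    Allele frequencies are recomputed within each group's samples; group
    means are unweighted across that group's loci/individuals. Loci with no
    calls in a group are excluded from its means. Empty groups are skipped
    with a warning. The ALL row uses every sample in the matrix.
    """
    if mode not in INBREEDING_MODES:
        raise PanelError(f"unknown inbreeding mode {mode!r}")
    groups = design.groups()
    rows = {}
    for g in REPORT_GROUPS:
        if g == "ALL":
            samples = list(gm.samples)
        else:
            samples = [s for s in groups.get(g, []) if s in set(gm.samples)]
        if not samples:
            warnings.warn(f"group {g} has no samples in the matrix; skipped")
            continue
        rows[g] = _group_row(gm, samples, mode)
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "group"

    p = allele_freq(gm)
    ho_locus, ho_ind = observed_het(gm)
    per_locus = pd.DataFrame(
        {"p": p, "MAF": maf(p), "PIC": pic(p), "Ho": ho_locus, "GD": gd(p)},
        index=pd.Index(gm.loci, name="locus_id"),
    )
    labels = [design.assignments.get(s, "") for s in gm.samples]
    per_individual = pd.DataFrame(
        {
            "group": labels,
            "Ho": ho_ind,
            "F": inbreeding_fej(gm, mode),
        },
        index=pd.Index(gm.samples, name="sample"),
    )
    return DiversityReport(
        summary=summary,
        per_locus=per_locus,
        per_individual=per_individual,
        inbreeding_mode=mode,
    )
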