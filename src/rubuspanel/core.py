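"""Core containers for testcross SNP panels.

Genotypes are stored as ALT-allele dosages: 0 (hom REF), 1 (het), 2 (hom ALT),
with ``numpy.nan`` as the single missing sentinel. The dosage matrix is
samples x loci; every statistic in the package operates on this substrate.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

#: valid per-sample group labels in a panel design
GROUP_LABELS = ("Pr", "Ps", "JG", "JS", "JT", "CHECK")

#: call-set tags: MOC = chromosome-anchored reference, MID = scaffold-anchored
SOURCES = ("MOC", "MID")

MISSING = np.nan


class PanelError(ValueError):
    """Base class for consistency errors in panel containers."""


@dataclasses.dataclass
class LocusInfo:
    """Per-marker metadata.

    ``seq_name`` is a chromosome name for the MOC call set and a scaffold name
    for the MID call set; ``pos`` is 1-based (VCF convention). Multi-allelic
    records read from a VCF are retained but flagged via ``is_biallelic`` so
    the QC stage can remove them.
    """

    locus_id: str
    source: str
    seq_name: str
    pos: int
    ref_allele: str
    alt_allele: str
    is_biallelic: bool = True

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise PanelError(f"unknown call-set source {self.source!r}")
        if self.pos < 1:
            raise PanelError(f"position must be >= 1, got {self.pos} at {self.locus_id}")
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"REF == ALT at {self.locus_id}")

    def flipped(self) -> "LocusInfo":
        """Return a copy with REF/ALT swapped (dosage recoding x -> 2-x)."""
        return dataclasses.replace(
            self, ref_allele=self.alt_allele, alt_allele=self.ref_allele
        )


class GenotypeMatrix:
    """Samples x loci ALT-dosage matrix with sample and locus registries."""

    def __init__(self, samples: Sequence[str], loci: Sequence[str], dosage) -> None:
        self.samples = list(samples)
        self.loci = list(loci)
        self.dosage = np.asarray(dosage, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.dosage.ndim != 2:
            raise PanelError("dosage must be 2-D (samples x loci)")
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise PanelError(
                f"dosage shape {self.dosage.shape} does not match registries "
                f"({len(self.samples)} samples, {len(self.loci)} loci)"
            )
        if len(set(self.samples)) != len(self.samples):
            raise PanelError("duplicate sample identifiers")
        if len(set(self.loci)) != len(self.loci):
            raise PanelError("duplicate locus identifiers")
        vals = self.dosage[np.isfinite(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
            raise PanelError(f"dosage entries must be 0/1/2/missing; found {bad[:5]}")

    # -- registry helpers ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([index[n] for n in names], dtype=int)
        except KeyError as exc:
            raise PanelError(f"unknown sample {exc.args[0]!r}") from None

    def locus_indices(self, ids: Iterable[str]) -> np.ndarray:
        index = {l: i for i, l in enumerate(self.loci)}
        try:
            return np.array([index[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise PanelError(f"unknown locus {exc.args[0]!r}") from None

    # -- subsetting ---------------------------------------------------------
    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.samples, [self.loci[i] for i in idx], self.dosage[:, idx]
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.loci, self.dosage[idx, :]
        )

    def subset_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        return self.take_samples(self.sample_indices(names))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.loci, self.dosage.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Exact equality including registries; NaN matches NaN."""
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and self.dosage.shape == other.dosage.shape
            and bool(
                np.array_equal(self.dosage, other.dosage, equal_nan=True)
            )
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci)"


@dataclasses.dataclass
class PanelDesign:
    """Sample -> group assignment plus family metadata.

    Groups follow the testcross layout: one resistant tester parent (Pr),
    susceptible donor parents (Ps), three half-sib F1 families (JG, JS, JT)
    and an unrelated check cultivar (CHECK).
    """

    assignments: dict[str, str]
    families: dict[str, tuple[str, str]] | None = None  # family -> (tester, donor)

    def __post_init__(self) -> None:
        bad = {g for g in self.assignments.values() if g not in GROUP_LABELS}
        if bad:
            raise PanelError(f"unknown group labels: {sorted(bad)}")

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {g: [] for g in GROUP_LABELS}
        for sample, group in self.assignments.items():
            out[group].append(sample)
        return out

    def labels_for(self, samples: Iterable[str]) -> list[str]:
        try:
            return [self.assignments[s] for s in samples]
        except KeyError as exc:
            raise PanelError(f"sample {exc.args[0]!r} has no group label") from None

    def group_sizes(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.groups().items()}
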