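"""Synthetic interspecific testcross panels with dual-call-set emulation.

The generator mirrors the structure of a raspberry testcross experiment: one
heterozygous black-raspberry tester crossed to three red-raspberry donor
cultivars, producing three F1 half-sib families, plus an unrelated check.
A fraction of loci is fixed for alternate alleles between the species
(tester hom-REF, donors hom-ALT), which makes every hybrid heterozygous
there — the interspecific signature that pushes observed heterozygosity
above the mid-parent value.

The same panel is then "called" against two emulated references: the MOC set
keeps chromosome coordinates; the MID set re-maps loci onto scaffolds and
adds genotype errors, missing calls and REF/ALT coding flips. The pairing of
shared loci across the two sets is recorded as ground truth for the
dual-reference matching stage.

Loci segregate independently (no recombination model): no downstream
statistic here needs genetic linkage; LD-decay test data come from a
dedicated generator in :mod:`rubuspanel.ld_analysis`.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, LocusInfo, PanelDesign, PanelError

PARENT_NAMES = ("Jewel", "Golden_Bliss", "Himbo_Top", "Salmon")
FAMILY_DONOR = {"JG": "Golden_Bliss", "JT": "Himbo_Top", "JS": "Salmon"}
CHECK_NAME = "Heritage"


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the testcross-panel generator.

    Defaults are the study conditions the pipeline is meant to emulate:
    three half-sib families of 43/38/35 individuals (116 hybrids), seven
    chromosomes, a highly heterozygous tester (0.77) and less heterozygous
    donors (0.58), a mean sequencing depth of 32x, and two call sets sharing
    ~40% of loci with occasional coding flips.
    """

    n_loci: int = 5000
    n_chromosomes: int = 7
    chrom_length_bp: int = 40_000_000
    family_sizes: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"JG": 43, "JT": 38, "JS": 35}
    )
    tester_het_rate: float = 0.77
    donor_het_rate: float = 0.58
    fixed_divergence_rate: float = 0.08
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.002
    dual_overlap_fraction: float = 0.40
    coding_flip_prob: float = 0.20
    n_scaffolds: int = 100
    mean_depth: float = 32.0
    depth_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "tester_het_rate": self.tester_het_rate,
            "donor_het_rate": self.donor_het_rate,
            "fixed_divergence_rate": self.fixed_divergence_rate,
            "missing_rate": self.missing_rate,
            "genotype_error_rate": self.genotype_error_rate,
            "dual_overlap_fraction": self.dual_overlap_fraction,
            "coding_flip_prob": self.coding_flip_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise PanelError(f"{name} must be in [0,1], got {p}")
        if self.n_loci < 1:
            raise PanelError("n_loci must be >= 1")
        if any(v < 0 for v in self.family_sizes.values()):
            raise PanelError("family sizes must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise PanelError("invalid chromosome layout")


@dataclasses.dataclass
class TruthRecord:
    """Generator ground truth used as the oracle in parameter-recovery tests."""

    parents: GenotypeMatrix
    #: loci x families matrix of Mendelian expected offspring heterozygosity
    expected_het: pd.DataFrame
    #: sample -> family ("JG"/"JT"/"JS") for hybrids only
    family_of: dict[str, str]
    #: cross-call-set locus pairing (moc_id, mid_id, flipped); filled by
    #: :func:`emulate_dual_callsets`
    pairing: pd.DataFrame | None = None


def _rng(cfg: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


_BASES = np.array(list("ACGT"))


def simulate_parents(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[LocusInfo]]:
    """Draw the four parental genotypes and the chromosome map.

    Loci are placed uniformly at random on the chromosomes and sorted by
    (chromosome, position). At a ``fixed_divergence_rate`` fraction of loci
    the tester is hom-REF and all donors hom-ALT; elsewhere each parent is
    heterozygous with its own rate, otherwise hom-REF/hom-ALT with equal
    probability.
    """
    rng = _rng(cfg, rng)
    L = cfg.n_loci
    chrom = rng.integers(0, cfg.n_chromosomes, size=L)
    pos = rng.integers(1, cfg.chrom_length_bp + 1, size=L)
    # enforce unique (chrom, pos) so locus ids are unique
    while True:
        key = chrom.astype(np.int64) * (cfg.chrom_length_bp + 1) + pos
        _, first = np.unique(key, return_index=True)
        if first.size == L:
            break
        dup = np.setdiff1d(np.arange(L), first)
        pos[dup] = rng.integers(1, cfg.chrom_length_bp + 1, size=dup.size)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]

    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    loci = [
        LocusInfo(
            locus_id=f"chr{c + 1}:{p}:{r}:{a}",
            source="MOC",
            seq_name=f"chr{c + 1}",
            pos=int(p),
            ref_allele=r,
            alt_allele=a,
        )
        for c, p, r, a in zip(chrom, pos, _BASES[ref_idx], _BASES[alt_idx])
    ]

    divergent = rng.random(L) < cfg.fixed_divergence_rate
    dosage = np.empty((4, L))
    for i, name in enumerate(PARENT_NAMES):
        het_rate = cfg.tester_het_rate if name == "Jewel" else cfg.donor_het_rate
        het = rng.random(L) < het_rate
        hom = np.where(rng.random(L) < 0.5, 0.0, 2.0)
        dosage[i] = np.where(het, 1.0, hom)
    dosage[0, divergent] = 0.0  # tester hom-REF
    dosage[1:, divergent] = 2.0  # donors hom-ALT
    gm = GenotypeMatrix(list(PARENT_NAMES), [l.locus_id for l in loci], dosage)
    return gm, loci


def expected_offspring_het(tester_dosage: np.ndarray, donor_dosage: np.ndarray) -> np.ndarray:
    """Mendelian P(offspring heterozygous) per locus; NaN propagates."""
    pt = tester_dosage / 2.0
    pd_ = donor_dosage / 2.0
    return pt * (1 - pd_) + (1 - pt) * pd_


def _gametes(dosage_row: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent gametes (rows) from one parent; NaN dosage -> NaN allele."""
    p = dosage_row / 2.0
    draw = (rng.random((n, p.size)) < p).astype(float)
    draw[:, ~np.isfinite(p)] = np.nan
    return draw


def simulate_testcross(
    parents: GenotypeMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, PanelDesign, TruthRecord]:
    """Cross the tester to each donor; return panel + design + truth.

    The panel holds the four parents, the hybrids of every family and the
    check. Each offspring locus receives one uniformly random allele from
    the tester and one from its donor; a missing parental genotype
    propagates to missing offspring genotypes. The check is an unrelated
    sample drawn from the donors' allele frequencies (HWE draw).
    """
    rng = _rng(cfg, rng)
    d = dict(zip(parents.samples, parents.dosage))
    tester = d["Jewel"]
    L = parents.n_loci

    rows, names, assignments = [], [], {}
    for p in PARENT_NAMES:
        rows.append(d[p])
        names.append(p)
        assignments[p] = "Pr" if p == "Jewel" else "Ps"

    family_of: dict[str, str] = {}
    exp_het = {}
    for fam in ("JG", "JT", "JS"):
        n_off = int(cfg.family_sizes.get(fam, 0))
        donor = d[FAMILY_DONOR[fam]]
        exp_het[fam] = expected_offspring_het(tester, donor)
        if n_off == 0:
            continue
        off = _gametes(tester, n_off, rng) + _gametes(donor, n_off, rng)
        for i in range(n_off):
            name = f"{fam}{i + 1:03d}"
            rows.append(off[i])
            names.append(name)
            assignments[name] = fam
            family_of[name] = fam

    donor_p = np.nanmean(np.stack([d[FAMILY_DONOR[f]] for f in FAMILY_DONOR]), axis=0) / 2.0
    check = rng.binomial(2, np.nan_to_num(donor_p, nan=0.5)).astype(float)
    check[~np.isfinite(donor_p)] = np.nan
    rows.append(check)
    names.append(CHECK_NAME)
    assignments[CHECK_NAME] = "CHECK"

    panel = GenotypeMatrix(names, parents.loci, np.vstack(rows))
    design = PanelDesign(
        assignments=assignments,
        families={f: ("Jewel", FAMILY_DONOR[f]) for f in FAMILY_DONOR},
    )
    truth = TruthRecord(
        parents=parents,
        expected_het=pd.DataFrame(exp_het, index=parents.loci),
        family_of=family_of,
    )
    return panel, design, truth


def add_genotype_noise(
    dosage: np.ndarray,
    missing_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply single-step genotype errors (0<->1<->2) then missingness."""
    out = dosage.copy()
    if error_rate > 0:
        err = (rng.random(out.shape) < error_rate) & np.isfinite(out)
        step = np.where(rng.random(out.shape) < 0.5, -1.0, 1.0)
        step[out == 0] = 1.0  # single-step, never 0<->2
        step[out == 2] = -1.0
        out[err] = out[err] + step[err]
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = np.nan
    return out


def _scaffold_map(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split chromosomes at uniform breakpoints into ~n_scaffolds scaffolds.

    Returns per-chromosome (start positions sorted, global scaffold index).
    """
    per = np.full(cfg.n_chromosomes, cfg.n_scaffolds // cfg.n_chromosomes)
    per[: cfg.n_scaffolds % cfg.n_chromosomes] += 1
    out = {}
    k = 0
    for c in range(cfg.n_chromosomes):
        n_scaf = max(int(per[c]), 1)
        breaks = np.sort(
            rng.integers(2, cfg.chrom_length_bp, size=n_scaf - 1)
        ) if n_scaf > 1 else np.array([], dtype=int)
        starts = np.concatenate(([1], breaks))
        out[f"chr{c + 1}"] = (starts, np.arange(k, k + starts.size))
        k += starts.size
    return out


def emulate_dual_callsets(
    panel: GenotypeMatrix,
    loci: list[LocusInfo],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, list[LocusInfo], GenotypeMatrix, list[LocusInfo], pd.DataFrame]:
    """Emulate calling the same panel against two reference assemblies.

    A ``dual_overlap_fraction`` of loci appears in both call sets; the rest
    is split evenly into set-private loci. The MOC set keeps chromosome
    coordinates and clean genotypes. The MID set gets scaffold coordinates,
    independent genotype errors, missing entries, and REF/ALT flips
    (dosage x -> 2-x) at ``coding_flip_prob``. Returns
    (gm_moc, loci_moc, gm_mid, loci_mid, pairing truth).
    """
    rng = _rng(cfg, rng)
    L = panel.n_loci
    perm = rng.permutation(L)
    n_shared = int(round(cfg.dual_overlap_fraction * L))
    shared = perm[:n_shared]
    private = perm[n_shared:]
    half = private.size // 2
    moc_idx = np.sort(np.concatenate([shared, private[:half]]))
    mid_idx = np.sort(np.concatenate([shared, private[half:]]))
    shared_set = set(shared.tolist())

    gm_moc = panel.take_loci(moc_idx)
    loci_moc = [loci[i] for i in moc_idx]

    scaf = _scaffold_map(cfg, rng)
    flip = rng.random(mid_idx.size) < cfg.coding_flip_prob
    mid_dosage = add_genotype_noise(
        panel.dosage[:, mid_idx], cfg.missing_rate, cfg.genotype_error_rate, rng
    )
    mid_dosage[:, flip] = 2.0 - mid_dosage[:, flip]

    loci_mid: list[LocusInfo] = []
    pairing_rows = []
    for k, i in enumerate(mid_idx):
        base = loci[i]
        starts, scaf_ids = scaf[base.seq_name]
        s = int(np.searchsorted(starts, base.pos, side="right") - 1)
        seq = f"scaffold_{scaf_ids[s] + 1:04d}"
        p = int(base.pos - starts[s] + 1)
        ref, alt = base.ref_allele, base.alt_allele
        if flip[k]:
            ref, alt = alt, ref
        info = LocusInfo(
            locus_id=f"{seq}:{p}:{ref}:{alt}",
            source="MID",
            seq_name=seq,
            pos=p,
            ref_allele=ref,
            alt_allele=alt,
        )
        loci_mid.append(info)
        if i in shared_set:
            pairing_rows.append((base.locus_id, info.locus_id, bool(flip[k])))

    order = np.lexsort(
        ([l.pos for l in loci_mid], [l.seq_name for l in loci_mid])
    )
    loci_mid = [loci_mid[i] for i in order]
    gm_mid = GenotypeMatrix(
        panel.samples, [l.locus_id for l in loci_mid], mid_dosage[:, order]
    )
    pairing = pd.DataFrame(pairing_rows, columns=["moc_id", "mid_id", "flipped"])
    return gm_moc, loci_moc, gm_mid, loci_mid, pairing


def simulate_depths(
    shape: tuple[int, int], cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-call read depths: negative binomial with the configured mean."""
    rng = _rng(cfg, rng)
    r = cfg.depth_dispersion
    p = r / (r + cfg.mean_depth)
    return rng.negative_binomial(r, p, size=shape)


def simulate_panel(cfg: SimulationConfig):
    """One-call orchestration: parents -> testcross -> dual call sets.

    Returns a dict with keys ``panel, design, truth, loci, gm_moc, loci_moc,
    gm_mid, loci_mid`` — everything the downstream stages consume. Fully
    deterministic in ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    parents, loci = simulate_parents(cfg, rng)
    panel, design, truth = simulate_testcross(parents, cfg, rng)
    gm_moc, loci_moc, gm_mid, loci_mid, pairing = emulate_dual_callsets(
        panel, loci, cfg, rng
    )
    truth.pairing = pairing
    return {
        "panel": panel,
        "design": design,
        "truth": truth,
        "loci": loci,
        "gm_moc": gm_moc,
        "loci_moc": loci_moc,
        "gm_mid": gm_mid,
        "loci_mid": loci_mid,
    }
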