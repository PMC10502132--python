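"""End-to-end orchestration: simulate -> QC -> merge -> diversity/structure/LD.

A run either starts from a pair of input VCFs plus a design TSV, or asks the
synthetic generator for a panel. All stages log their parameters; a run
manifest (JSON with the config, seed and sha256 checksums of every output)
makes re-runs bit-identical and verifiable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypeMatrix, LocusInfo, PanelDesign
from .diversity_stats import group_report
from .dual_reference import build_unique_matrix, match_markers
from .io_formats import read_design, read_vcf, write_design, write_vcf
from .ld_analysis import decay_distance, decay_frame, pairwise_ld
from .marker_qc import qc_pipeline
from .structure_analysis import dapc, pca, vanraden_g, ward_tree
from .synthetic_panel import SimulationConfig, simulate_depths, simulate_panel

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "rubuspanel_out"
    seed: int = 0
    # inputs: either simulate, or provide VCF paths + design
    simulate: bool = True
    sim: SimulationConfig | None = None
    moc_vcf: str | None = None
    mid_vcf: str | None = None
    design_tsv: str | None = None
    # QC
    call_rate: float = 0.90
    maf: float = 0.05
    ld_r2: float = 0.99
    window_bp: int = 1_000_000
    strict_thresholds: bool = False
    # merge
    match_r_threshold: float = 0.98
    match_min_overlap: int = 20
    match_signed: bool = False
    # diversity / structure / LD
    inbreeding_mode: str = "allele_identity"
    n_pca: int = 45
    n_da: int = 2
    k_max: int = 8
    target_r2: float = 0.20
    ld_min_pairs: int = 50


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _structure_outputs(gm: GenotypeMatrix, cfg: RunConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    rel = vanraden_g(gm)
    _write_tsv(rel.to_frame(), out / "G.tsv", index=True)
    scores, var_exp = pca(rel)
    k_show = min(10, scores.shape[1])
    _write_tsv(
        pd.DataFrame(
            scores[:, :k_show],
            index=pd.Index(rel.samples, name="sample"),
            columns=[f"PC{i + 1}" for i in range(k_show)],
        ),
        out / "pca_scores.tsv",
        index=True,
    )
    tree = ward_tree(rel)
    (out / "tree.nwk").write_text(tree.newick() + "\n")
    res = dapc(
        gm, n_pca=cfg.n_pca, n_da=cfg.n_da, k_range=range(1, cfg.k_max + 1), seed=cfg.seed
    )
    _write_tsv(res.bic_curve, out / "bic_curve.tsv")
    _write_tsv(
        pd.DataFrame(
            res.membership,
            index=pd.Index(res.samples, name="sample"),
            columns=[f"group_{g + 1}" for g in range(res.k)],
        ),
        out / "membership.tsv",
        index=True,
    )
    _write_tsv(
        pd.DataFrame(
            {"sample": res.samples, "group": res.assignments + 1}
        ),
        out / "dapc_assignments.tsv",
    )
    return {
        "dapc_k": int(res.k),
        "pc1_pc2_variance": float(var_exp[:2].sum()),
        "ward_cut3": tree.cut(3).tolist(),
        "dapc_assignments": res.assignments.tolist(),
        "samples": res.samples,
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns a summary dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed}

    # ---- stage: inputs (simulation or files) ------------------------------
    if cfg.simulate:
        sim_cfg = cfg.sim or SimulationConfig(seed=cfg.seed)
        logger.info("simulating panel (seed %d)", sim_cfg.seed)
        sim = simulate_panel(sim_cfg)
        gm_moc, loci_moc = sim["gm_moc"], sim["loci_moc"]
        gm_mid, loci_mid = sim["gm_mid"], sim["loci_mid"]
        design = sim["design"]
        rng = np.random.default_rng(sim_cfg.seed + 1)
        write_vcf(
            gm_moc, loci_moc, out / "moc.vcf",
            depths=simulate_depths(gm_moc.dosage.shape, sim_cfg, rng),
        )
        write_vcf(
            gm_mid, loci_mid, out / "mid.vcf",
            depths=simulate_depths(gm_mid.dosage.shape, sim_cfg, rng),
        )
        write_design(design, out / "design.tsv")
        if sim["truth"].pairing is not None:
            _write_tsv(sim["truth"].pairing, out / "truth_pairing.tsv")
        summary["simulated"] = True
    else:
        if not (cfg.moc_vcf and cfg.design_tsv):
            raise ValueError("non-simulated run needs moc_vcf and design_tsv")
        gm_moc, loci_moc = read_vcf(cfg.moc_vcf, "MOC")
        design = read_design(cfg.design_tsv)
        if cfg.mid_vcf:
            gm_mid, loci_mid = read_vcf(cfg.mid_vcf, "MID")
        else:
            gm_mid = loci_mid = None  # single-call-set degraded mode
        summary["simulated"] = False

    # ---- stage: QC per call set ------------------------------------------
    gm_moc, loci_moc, rep_moc = qc_pipeline(
        gm_moc, loci_moc, cfg.call_rate, cfg.maf, cfg.ld_r2, cfg.window_bp,
        cfg.strict_thresholds,
    )
    _write_tsv(rep_moc.to_frame(), out / "qc_moc.tsv")
    summary["qc_moc"] = rep_moc.stage_counts
    if gm_mid is not None:
        gm_mid, loci_mid, rep_mid = qc_pipeline(
            gm_mid, loci_mid, cfg.call_rate, cfg.maf, cfg.ld_r2, cfg.window_bp,
            cfg.strict_thresholds,
        )
        _write_tsv(rep_mid.to_frame(), out / "qc_mid.tsv")
        summary["qc_mid"] = rep_mid.stage_counts

    # ---- stage: dual-reference merge -------------------------------------
    matrices: dict[str, tuple[GenotypeMatrix, list[LocusInfo]]] = {"Moc": (gm_moc, loci_moc)}
    if gm_mid is not None:
        pairs = match_markers(
            gm_moc, gm_mid, cfg.match_r_threshold, cfg.match_min_overlap,
            cfg.match_signed,
        )
        gm_unique, loci_unique, link = build_unique_matrix(
            gm_moc, loci_moc, gm_mid, loci_mid, pairs
        )
        _write_tsv(link, out / "link_table.tsv")
        scaf_info = {
            l.locus_id: f"SCAF={l.seq_name}:{l.pos}" for l in loci_unique if l.source == "MID"
        }
        write_vcf(gm_unique, loci_unique, out / "unique.vcf", info_extra=scaf_info)
        matrices["Unique"] = (gm_unique, loci_unique)
        matrices["Mid"] = (gm_mid, loci_mid)
        summary["n_pairs"] = len(pairs)
        summary["n_markers"] = {
            "Moc": gm_moc.n_loci, "Mid": gm_mid.n_loci, "Unique": gm_unique.n_loci
        }
    else:
        logger.info("single call set: merge-refs skipped")
        summary["n_markers"] = {"Moc": gm_moc.n_loci}

    # ---- stage: diversity + structure per matrix --------------------------
    comparison_rows = []
    for name, (gm, _loci) in matrices.items():
        report = group_report(gm, design, cfg.inbreeding_mode)
        report.write(out / f"diversity_{name}")
        st = _structure_outputs(gm, cfg, out / f"structure_{name}")
        summary[f"structure_{name}"] = {
            "dapc_k": st["dapc_k"], "pc1_pc2_variance": st["pc1_pc2_variance"]
        }
        summary[f"diversity_{name}"] = {
            c: float(report.summary.loc["ALL", c]) for c in ("Ne", "MAF", "PIC", "Ho", "GD", "F")
        }
        row = {"matrix": name, "n_markers": gm.n_loci}
        row.update(summary[f"diversity_{name}"])
        row["dapc_k"] = st["dapc_k"]
        comparison_rows.append(row)
    _write_tsv(pd.DataFrame(comparison_rows), out / "matrix_comparison.tsv")

    # ---- stage: LD on the chromosome-anchored matrix ----------------------
    gm, loci = matrices["Moc"]
    ld_pairs = pairwise_ld(gm, loci, cfg.window_bp)
    _write_tsv(ld_pairs, out / "ld_pairs.tsv")
    estimates = decay_distance(
        ld_pairs, gm.n_samples, cfg.target_r2, cfg.ld_min_pairs, cfg.window_bp
    )
    _write_tsv(decay_frame(estimates), out / "ld_decay.tsv")
    summary["ld_decay_bp"] = {
        e.seq_name: e.decay_bp for e in estimates
    }

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
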