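"""Shared fixtures: hand-written VCFs, a hand-built QC matrix, cached simulations."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import rubuspanel as rp

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1
chr1\t200\tsnp2\tG\tT\t.\tPASS\t.\tGT\t1/1\t./.
chr1\t300\t.\tT\tA\t.\tPASS\t.\tGT\t0|1\t1|0
"""

# hand transcription of TINY_VCF (samples x loci)
TINY_DOSAGE = np.array(
    [
        [0.0, 2.0, 1.0],
        [1.0, np.nan, 1.0],
    ]
)


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture
def vcf_writer(tmp_path):
    """Write arbitrary VCF text to a temp file."""

    def _write(text: str, name: str = "fixture.vcf"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def _col(pattern, n=10):
    """Repeat a short dosage pattern to n samples."""
    reps = -(-n // len(pattern))
    return (pattern * reps)[:n]


@pytest.fixture
def qc_fixture():
    """20 hand-built loci: 2 triallelic, 3 low call rate, 4 monomorphic,
    1 exact duplicate; 10 clean survivors."""
    n = 10
    cols, loci = [], []
    patterns = [
        [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
        [2, 0, 1, 2, 0, 1, 2, 0, 1, 1],
        [1, 2, 0, 0, 2, 1, 1, 0, 2, 2],
        [0, 0, 1, 1, 2, 2, 0, 1, 2, 1],
        [2, 1, 0, 2, 1, 0, 1, 2, 0, 0],
        [1, 1, 2, 0, 0, 2, 2, 1, 0, 1],
        [0, 2, 2, 1, 0, 1, 2, 0, 1, 2],
        [2, 2, 0, 1, 1, 0, 0, 2, 1, 0],
        [1, 0, 1, 2, 2, 0, 1, 1, 2, 2],
    ]
    spec = []
    # 2 triallelic (otherwise clean)
    spec += [("tri", patterns[0]), ("tri", patterns[1])]
    # 3 with 30% missing
    for pat in patterns[2:5]:
        c = [float(x) for x in pat]
        c[0] = c[4] = c[8] = np.nan
        spec.append(("lowcall", c))
    # 4 monomorphic
    spec += [("mono", [0.0] * n), ("mono", [2.0] * n), ("mono", [0.0] * n), ("mono", [2.0] * n)]
    # duplicate pair: keeper + exact copy
    spec += [("keep", patterns[5]), ("dup", patterns[5])]
    # 9 clean survivors to reach 20 loci
    spec += [("keep", p) for p in (patterns[6], patterns[7], patterns[8])]
    spec += [("keep", list(reversed(p))) for p in (patterns[0], patterns[1], patterns[2])]
    spec += [("keep", [p[(i + 3) % n] for i in range(n)]) for p in (patterns[3], patterns[4], patterns[6])]
    for i, (kind, pat) in enumerate(spec):
        loci.append(
            rp.LocusInfo(
                locus_id=f"l{i + 1}",
                source="MOC",
                seq_name="chr1",
                pos=(i + 1) * 50_000,
                ref_allele="A",
                alt_allele="C",
                is_biallelic=(kind != "tri"),
            )
        )
        cols.append([float(x) for x in pat])
    gm = rp.GenotypeMatrix(
        [f"s{i + 1}" for i in range(n)],
        [l.locus_id for l in loci],
        np.array(cols).T,
    )
    kinds = [k for k, _ in spec]
    return gm, loci, kinds


@pytest.fixture(scope="session")
def default_sim():
    """A small default-conditions panel reused across read-only tests."""
    return rp.simulate_panel(rp.SimulationConfig(n_loci=1200, seed=7))


@pytest.fixture(scope="session")
def family_panel():
    """3-family panel with clearly divergent donors, for structure tests."""
    cfg = rp.SimulationConfig(n_loci=3000, seed=21)
    return rp.simulate_panel(cfg), cfg


def hybrids_of(panel, design):
    names = [s for s in panel.samples if design.assignments[s] in ("JG", "JT", "JS")]
    return panel.subset_samples(names), [design.assignments[s] for s in names]
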