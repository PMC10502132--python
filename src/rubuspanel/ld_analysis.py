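"""Linkage disequilibrium within a physical window and decay-distance fits.

LD between two loci is the squared Pearson correlation of their dosages over
pairwise-complete samples. Decay is summarized per chromosome by fitting the
Hill–Weir sample-size-adjusted expectation of r^2 as a function of distance,

    E[r^2](C) = (10+C) / ((2+C)(11+C))
                * (1 + (3+C)(12+12C+C^2) / (n (2+C)(11+C))),   C = rho * d,

and reporting the smallest distance where the fitted curve reaches the
target r^2 (default 0.20). When the fit fails, 10-kb bin means with linear
interpolation of the first crossing serve as fallback; the method used is
recorded per chromosome.

Because the testcross generator has no recombination model, LD-decay test
data come from :func:`simulate_decay_pairs`, which draws (distance, r^2)
pairs directly around a known decay curve.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from ._corr import pairwise_r
from .core import GenotypeMatrix, LocusInfo


def hill_weir_r2(d, rho: float, n: int) -> np.ndarray:
    """Expected r^2 at distance ``d`` for recombination scale ``rho`` and sample size ``n``."""
    C = rho * np.asarray(d, dtype=float)
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    adj = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    return base * adj


def pairwise_ld(
    gm: GenotypeMatrix,
    loci: list[LocusInfo],
    window_bp: int = 1_000_000,
    min_overlap: int = 20,
) -> pd.DataFrame:
    """All same-sequence locus pairs closer than ``window_bp``.

    Returns a frame with columns (seq_name, locus_a, locus_b, distance_bp,
    r2, n). Pairs with fewer than ``min_overlap`` pairwise-complete samples
    are skipped (their count is in ``frame.attrs['n_skipped']``). A
    scaffold-typed call set triggers a warning — decay over scaffold
    coordinates has limited interpretation — but is still computed.
    """
    if any(l.source == "MID" for l in loci):
        warnings.warn(
            "LD computed on scaffold coordinates; decay interpretation is limited"
        )
    seqs = np.array([l.seq_name for l in loci])
    pos = np.array([l.pos for l in loci])
    ids = np.array([l.locus_id for l in loci])
    D = gm.dosage
    rows = []
    n_skipped = 0
    for seq in pd.unique(seqs):
        idx = np.flatnonzero(seqs == seq)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        spos = pos[idx]
        for ii in range(idx.size):
            hi = int(np.searchsorted(spos, spos[ii] + window_bp, side="left"))
            cand = idx[ii + 1 : hi]
            if cand.size == 0:
                continue
            r, n = pairwise_r(D[:, [idx[ii]]], D[:, cand])
            r2 = r[0] ** 2
            for jj, j in enumerate(cand):
                if n[0, jj] < min_overlap or not np.isfinite(r2[jj]):
                    n_skipped += 1
                    continue
                rows.append(
                    (
                        seq,
                        ids[idx[ii]],
                        ids[j],
                        int(abs(spos[jj + ii + 1] - spos[ii])),
                        float(r2[jj]),
                        int(n[0, jj]),
                    )
                )
    out = pd.DataFrame(
        rows, columns=["seq_name", "locus_a", "locus_b", "distance_bp", "r2", "n"]
    )
    out.attrs["n_skipped"] = n_skipped
    return out


@dataclasses.dataclass
class DecayEstimate:
    """Per-sequence LD decay summary."""

    seq_name: str
    n_pairs: int
    method: str | None  # "hill_weir" | "binned" | None
    rho: float | None
    decay_bp: float | None
    reason: str | None = None  # populated when decay_bp is undefined


def _binned_crossing(
    dist: np.ndarray, r2: np.ndarray, target: float, bin_bp: int = 10_000
) -> float | None:
    bins = (dist // bin_bp).astype(int)
    frame = pd.DataFrame({"bin": bins, "r2": r2})
    means = frame.groupby("bin")["r2"].mean()
    centers = (means.index.to_numpy() + 0.5) * bin_bp
    vals = means.to_numpy()
    for i in range(len(vals) - 1):
        if vals[i] >= target >= vals[i + 1]:
            if vals[i] == vals[i + 1]:
                return float(centers[i])
            t = (vals[i] - target) / (vals[i] - vals[i + 1])
            return float(centers[i] + t * (centers[i + 1] - centers[i]))
    return None


def decay_distance(
    pairs: pd.DataFrame,
    n_samples: int,
    target_r2: float = 0.20,
    min_pairs: int = 50,
    window_bp: int = 1_000_000,
) -> list[DecayEstimate]:
    """Fit the decay curve per sequence and locate the target-r^2 crossing.

    The crossing is searched up to 10x the window; a curve that never
    reaches the target there is reported as undefined with a reason, never
    fabricated.
    """
    out: list[DecayEstimate] = []
    for seq, sub in pairs.groupby("seq_name", sort=True):
        n_pairs = len(sub)
        if n_pairs < min_pairs:
            out.append(
                DecayEstimate(seq, n_pairs, None, None, None, reason="too few pairs")
            )
            continue
        dist = sub["distance_bp"].to_numpy(dtype=float)
        r2 = sub["r2"].to_numpy(dtype=float)
        est = None
        try:
            (rho,), _ = curve_fit(
                lambda d, rho: hill_weir_r2(d, rho, n_samples),
                dist,
                r2,
                p0=[1e-5],
                bounds=(1e-15, 1.0),
                maxfev=10_000,
            )
            f = lambda d: hill_weir_r2(d, rho, n_samples) - target_r2
            d_max = 10.0 * window_bp
            if f(1.0) <= 0:
                est = DecayEstimate(seq, n_pairs, "hill_weir", float(rho), 1.0)
            elif f(d_max) > 0:
                est = DecayEstimate(
                    seq,
                    n_pairs,
                    "hill_weir",
                    float(rho),
                    None,
                    reason=f"fitted curve stays above {target_r2} within 10x window",
                )
            else:
                d_star = brentq(f, 1.0, d_max)
                est = DecayEstimate(seq, n_pairs, "hill_weir", float(rho), float(d_star))
        except (RuntimeError, ValueError):
            est = None
        if est is None:
            cross = _binned_crossing(dist, r2, target_r2)
            if cross is None:
                est = DecayEstimate(
                    seq, n_pairs, "binned", None, None, reason="no bin crossing found"
                )
            else:
                est = DecayEstimate(seq, n_pairs, "binned", None, cross)
        out.append(est)
    return out


def decay_frame(estimates: list[DecayEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in estimates])


def simulate_decay_pairs(
    rho: float,
    n_samples: int,
    n_pairs: int = 5000,
    max_distance_bp: int = 1_000_000,
    noise_sd: float = 0.08,
    seed: int = 0,
    seq_name: str = "chr1",
) -> pd.DataFrame:
    """Draw (distance, r^2) pairs around a known Hill–Weir decay curve.

    Distances are uniform in (0, ``max_distance_bp``); observed r^2 is the
    curve value plus Gaussian noise, truncated to [0, 1]. Output matches the
    :func:`pairwise_ld` schema, so :func:`decay_distance` can be tested
    against the analytically known crossing.
    """
    rng = np.random.default_rng(seed)
    dist = rng.integers(1, max_distance_bp, size=n_pairs)
    true = hill_weir_r2(dist, rho, n_samples)
    r2 = np.clip(true + rng.normal(0.0, noise_sd, size=n_pairs), 0.0, 1.0)
    return pd.DataFrame(
        {
            "seq_name": seq_name,
            "locus_a": [f"a{i}" for i in range(n_pairs)],
            "locus_b": [f"b{i}" for i in range(n_pairs)],
            "distance_bp": dist,
            "r2": r2,
            "n": n_samples,
        }
    )


def true_decay_crossing(
    rho: float, n_samples: int, target_r2: float = 0.20, d_max: float = 1e8
) -> float:
    """Analytic crossing distance of the noiseless curve (test oracle)."""
    f = lambda d: hill_weir_r2(d, rho, n_samples) - target_r2
    return float(brentq(f, 1.0, d_max))
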