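"""Phase-distribution characterization and condition-paired comparisons.

Covers four analyses run on the consensus phases of called cycling genes:

* a two-sample Kolmogorov–Smirnov comparison of phase distributions
  (the circle is cut at a configurable ZT hour to linearize it — the
  p-value depends on the cut, so the cut is reported with the result);
* peak finding on a von Mises kernel density over the 24 h circle;
* the per-gene signed phase shift between two conditions for genes
  cycling in both, with its circular mean and fraction advanced;
* paired Wilcoxon signed-rank tests of per-gene expression variance and
  of fitted amplitudes between conditions.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import TimeCourseMatrix
from .rhythm import TWO_PI, circular_mean

log = logging.getLogger(__name__)


def _as_phases(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        x = x["consensus_phase"]
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)] % 24.0


def compare_phase_distributions(a, b, cut: float = 0.0) -> dict:
    """Two-sample KS test of two phase samples linearized at ``cut``.

    Phases are mapped to ``(phase − cut) mod 24`` before the test; the cut
    (default ZT0, lights-on) is echoed in the result because the KS
    statistic on circular data depends on where the circle is opened.
    """
    pa, pb = _as_phases(a), _as_phases(b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("both phase samples must be non-empty")
    res = stats.ks_2samp((pa - cut) % 24.0, (pb - cut) % 24.0)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "cut": float(cut), "n_a": int(pa.size), "n_b": int(pb.size)}


def phase_density_peaks(phases, kernel_concentration: float = 8.0,
                        grid_step: float = 0.1,
                        prominence_frac: float = 0.5,
                        min_mean_ratio: float = 1.2) -> list[float]:
    """Peaks of a von Mises kernel density on the 24 h circle.

    The density at grid point θ is the mean of von Mises kernels of
    concentration κ (``kernel_concentration``) centred on the data; the
    default κ = 8 (kernel SD ≈ 1.35 h) resolves peaks ≥ 4 h apart.  Peaks
    are strict local maxima on the circular grid whose density exceeds
    both ``prominence_frac`` of the global maximum and ``min_mean_ratio``
    times the mean density (the latter suppresses the wiggles of a flat
    sample).  Returned in descending density order; fewer peaks than a
    caller hoped for is not an error.
    """
    p = _as_phases(phases)
    if p.size < 5:
        raise ValueError("need at least 5 phases for density estimation")
    grid = np.arange(0.0, 24.0, grid_step)
    tg = grid * (TWO_PI / 24.0)
    td = p * (TWO_PI / 24.0)
    kappa = float(kernel_concentration)
    dens = np.exp(kappa * np.cos(tg[:, None] - td[None, :])).mean(axis=1)
    dens /= TWO_PI * special.i0(kappa)

    is_max = (dens > np.roll(dens, 1)) & (dens > np.roll(dens, -1))
    thresh = max(prominence_frac * dens.max(), min_mean_ratio * dens.mean())
    idx = np.flatnonzero(is_max & (dens >= thresh))
    order = np.argsort(dens[idx])[::-1]
    return [float(grid[i]) for i in idx[order]]


def paired_phase_shift(calls_18: pd.DataFrame,
                       calls_25: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Signed phase shift between conditions for genes cycling in both.

    The shift is ``phase_25 − phase_18`` wrapped into (−12, 12] h; a
    positive value means the gene peaks *earlier* at 18°C (a phase advance
    in the cold).  Returns the per-gene table and a summary with the
    circular mean shift and the fraction of genes advanced.
    """
    cyc18 = set(calls_18.index[calls_18["is_cycling"]])
    cyc25 = set(calls_25.index[calls_25["is_cycling"]])
    common = [g for g in calls_18.index if g in cyc18 and g in cyc25]
    if not common:
        raise ValueError("no gene is called cycling in both conditions")
    p18 = calls_18.loc[common, "consensus_phase"].to_numpy(dtype=float)
    p25 = calls_25.loc[common, "consensus_phase"].to_numpy(dtype=float)
    s = (p25 - p18) % 24.0
    shift = np.where(s > 12.0, s - 24.0, s)  # (−12, 12]
    table = pd.DataFrame(
        {"phase_18": p18, "phase_25": p25, "shift_hours": shift},
        index=pd.Index(common, name="gene_id"),
    )
    mean_shift = circular_mean(shift)
    if not math.isnan(mean_shift) and mean_shift > 12.0:
        mean_shift -= 24.0
    summary = {
        "n_common": len(common),
        "mean_shift_hours": mean_shift,
        "fraction_advanced": float(np.mean(shift > 0)),
    }
    return table, summary


def _paired_signed_rank(x: np.ndarray, y: np.ndarray,
                        label_a: str, label_b: str) -> dict:
    """Two-tailed Wilcoxon signed-rank on paired values, with direction."""
    if x.size != y.size:
        raise ValueError("paired samples differ in length")
    if x.size < 2:
        raise ValueError("signed-rank test undefined for fewer than 2 pairs")
    d = y - x
    med = float(np.median(d))
    direction = label_b if med > 0 else (label_a if med < 0 else "tie")
    if np.all(d == 0):
        log.warning("all paired differences are zero; p = 1 by convention")
        return {"statistic": float("nan"), "p_value": 1.0,
                "direction": "tie", "n": int(x.size)}
    res = stats.wilcoxon(x, y, alternative="two-sided")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "direction": direction, "n": int(x.size)}


def paired_variance_test(mat_a: TimeCourseMatrix, mat_b: TimeCourseMatrix,
                         genes: Sequence[str],
                         label_a: str = "a", label_b: str = "b") -> dict:
    """Paired test of per-gene expression variance between two matrices.

    Each gene's sample variance is computed across all samples of each
    matrix (pool experiments beforehand with
    :func:`~cyclenet.preprocess.concat_samples` if desired); the paired
    variances are compared by a two-tailed Wilcoxon signed-rank test.
    ``direction`` names the matrix with the larger median variance.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    va = mat_a.values.loc[genes].var(axis=1, ddof=1).to_numpy()
    vb = mat_b.values.loc[genes].var(axis=1, ddof=1).to_numpy()
    return _paired_signed_rank(va, vb, label_a, label_b)


def paired_amplitude_test(fits_a: pd.DataFrame, fits_b: pd.DataFrame,
                          common_cyclers: Sequence[str],
                          label_a: str = "a", label_b: str = "b") -> dict:
    """Paired signed-rank test of fitted amplitudes of common cyclers."""
    genes = list(common_cyclers)
    if not genes:
        raise ValueError("empty common-cycler list")
    aa = fits_a.loc[genes, "amplitude"].to_numpy(dtype=float)
    ab = fits_b.loc[genes, "amplitude"].to_numpy(dtype=float)
    return _paired_signed_rank(aa, ab, label_a, label_b)
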