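"""Harmonic-regression rhythm detection and circular phase statistics.

Each gene's time course is fit by ordinary least squares to the fixed-period
cosinor model

    y(t) = m + a·cos(2π (t − φ) / T),          T = 24 h

via the linear parameterization ``y ~ 1 + cos(2πt/T) + sin(2πt/T)``.
Rhythmicity is scored by the F-test of the two harmonic coefficients being
jointly zero (df 2 and n−3).  The amplitude is ``sqrt(β_cos² + β_sin²)``
and the peak phase is ``(T/2π)·atan2(β_sin, β_cos) mod T`` in ZT hours.

A gene is called cycling when the evidence replicates: harmonic p < 0.1 in
*both* independent experiments and the two phase estimates agree to within
3 h of circular distance.  Under a flat null with uniform p-values and a
uniform chance phase difference on [0, 12] h, the expected number of chance
calls among N genes is N · 0.1² · (3/12); :func:`expected_chance_cyclers`
computes this expectation and :func:`false_discovery_summary` converts it
into per-condition false-discovery percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import TimeCourseMatrix

log = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

#: columns of a per-gene harmonic-fit table
FIT_COLUMNS = ("mesor", "amplitude", "phase", "f_stat", "p_value", "n_obs", "period")


@dataclass(frozen=True)
class HarmonicFit:
    """Cosinor fit of one gene at a fixed period.

    ``phase`` is the ZT time of the model peak in [0, 24); it is NaN when
    the amplitude is exactly zero (constant series), in which case
    ``p_value`` is 1 by convention.
    """

    gene_id: str
    mesor: float
    amplitude: float
    phase: float
    f_stat: float
    p_value: float
    n_obs: int
    period: float = 24.0


def _harmonic_design(times: np.ndarray, period: float) -> np.ndarray:
    w = TWO_PI / period
    return np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])


def _fit_matrix(times: np.ndarray, Y: np.ndarray, period: float) -> dict[str, np.ndarray]:
    """Vectorized cosinor fit of many genes sharing one time vector.

    ``Y`` has shape (n_obs, n_genes).  Returns per-gene arrays.
    """
    n = times.size
    if n != Y.shape[0]:
        raise ValueError("times and values have different lengths")
    distinct = np.unique(np.round(np.mod(times, period), 9))
    if distinct.size < 4:
        raise ValueError("need at least 4 distinct timepoints (mod period)")

    X = _harmonic_design(times, period)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < 3:
        raise ValueError("singular harmonic design (timepoints degenerate mod period)")
    resid = Y - X @ beta
    sse_full = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    sse_reduced = np.einsum("ij,ij->j", centered, centered)

    df2 = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((sse_reduced - sse_full) / 2.0) / (sse_full / df2)
        p = stats.f.sf(f, 2, df2)
    p = np.where(np.isinf(f), 0.0, p)

    amplitude = np.hypot(beta[1], beta[2])
    phase = (period / TWO_PI) * np.arctan2(beta[2], beta[1]) % period

    # exactly constant series: amplitude 0, phase undefined, p = 1
    constant = Y.max(axis=0) == Y.min(axis=0)
    amplitude = np.where(constant, 0.0, amplitude)
    phase = np.where(constant | (amplitude == 0), np.nan, phase)
    f = np.where(constant, 0.0, f)
    p = np.where(constant, 1.0, p)
    return {
        "mesor": beta[0],
        "amplitude": amplitude,
        "phase": phase,
        "f_stat": f,
        "p_value": p,
        "n_obs": np.full(Y.shape[1], n),
        "period": np.full(Y.shape[1], period),
    }


def fit_harmonic(times: Sequence[float], values: Sequence[float],
                 period: float = 24.0, gene_id: str = "") -> HarmonicFit:
    """Fit the fixed-period cosinor model to a single gene's series.

    Replicate measurements enter as independent observations; ``times``
    may therefore contain repeated values, but at least 4 distinct
    timepoints (mod period) are required.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)[:, None]
    r = _fit_matrix(t, y, period)
    return HarmonicFit(
        gene_id=gene_id,
        mesor=float(r["mesor"][0]),
        amplitude=float(r["amplitude"][0]),
        phase=float(r["phase"][0]),
        f_stat=float(r["f_stat"][0]),
        p_value=float(r["p_value"][0]),
        n_obs=int(r["n_obs"][0]),
        period=period,
    )


def fit_harmonic_table(mat: TimeCourseMatrix, period: float = 24.0,
                       log_transform: bool = False) -> pd.DataFrame:
    """Cosinor-fit every gene of a matrix; one row per gene.

    With ``log_transform`` the model is fit to log2(TPM + 1) instead of
    raw TPM.
    """
    Y = mat.values.to_numpy(dtype=float).T  # (n_obs, n_genes)
    if log_transform:
        Y = np.log2(Y + 1.0)
    r = _fit_matrix(mat.zt_hours, Y, period)
    out = pd.DataFrame(r, index=pd.Index(mat.genes, name="gene_id"))
    out["n_obs"] = out["n_obs"].astype(int)
    return out[list(FIT_COLUMNS)]


# -- circular helpers -----------------------------------------------------

def phase_difference(phi1, phi2, period: float = 24.0):
    """Circular distance between two phases on the 24 h clock, in [0, 12].

    Symmetric, zero at identity and ``period/2`` at the antipode; inputs
    are reduced mod ``period``.  Accepts scalars or arrays.
    """
    d = np.abs(np.asarray(phi1, dtype=float) - np.asarray(phi2, dtype=float)) % period
    out = np.minimum(d, period - d)
    return float(out) if out.ndim == 0 else out


def circular_mean(phases: Sequence[float], period: float = 24.0,
                  tol: float = 1e-9) -> float:
    """Mean direction of phases on the ``period``-hour circle, in [0, period).

    Returns NaN when the resultant vector length is below ``tol`` (e.g. an
    antipodal pair), for which no mean direction exists.
    """
    ang = np.asarray(phases, dtype=float) * (TWO_PI / period)
    if ang.size == 0:
        raise ValueError("circular_mean of empty sequence")
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    if np.hypot(c, s) < tol:
        return float("nan")
    out = (math.atan2(s, c) * period / TWO_PI) % period
    # float residue can land the mod infinitesimally below `period`
    return 0.0 if period - out < 1e-9 else float(out)


def circular_correlation(a: Sequence[float], b: Sequence[float],
                         period: float = 24.0) -> float:
    """Jammalamadaka–SenGupta circular correlation of two phase samples.

        r = Σ sin(α−ᾱ) sin(β−β̄) / sqrt(Σ sin²(α−ᾱ) Σ sin²(β−β̄))

    with ᾱ, β̄ the circular mean directions.  Returns NaN when either
    sample has zero circular variance.
    """
    alpha = np.asarray(a, dtype=float) * (TWO_PI / period)
    beta = np.asarray(b, dtype=float) * (TWO_PI / period)
    if alpha.size != beta.size:
        raise ValueError("samples have different lengths")
    if alpha.size < 3:
        raise ValueError("need at least 3 paired phases")
    da = np.sin(alpha - math.atan2(np.sin(alpha).mean(), np.cos(alpha).mean()))
    db = np.sin(beta - math.atan2(np.sin(beta).mean(), np.cos(beta).mean()))
    denom = math.sqrt((da ** 2).sum() * (db ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((da * db).sum() / denom)


# -- the dual-experiment call --------------------------------------------

def call_cycling(fits_v1: pd.DataFrame, fits_v2: pd.DataFrame,
                 p_thresh: float = 0.1, dphi_max_hours: float = 3.0,
                 condition: str | None = None) -> pd.DataFrame:
    """Apply the replicated cycling criterion to two experiments' fits.

    A gene is cycling iff ``p < p_thresh`` in both experiments *and* the
    circular distance between the two phase estimates is strictly below
    ``dphi_max_hours``.  The consensus phase (circular mean of the two
    estimates) is reported for called genes only.

    Returns a DataFrame indexed by gene with columns
    ``p_v1, p_v2, phase_v1, phase_v2, delta_phi, is_cycling,
    consensus_phase`` (plus ``condition`` if given).
    """
    if p_thresh <= 0 or dphi_max_hours <= 0:
        raise ValueError("thresholds must be positive")
    in_v2 = set(fits_v2.index)
    common = [g for g in fits_v1.index if g in in_v2]
    n_excluded = len(set(fits_v1.index) ^ set(fits_v2.index))
    if n_excluded:
        log.warning("excluding %d genes present in only one experiment", n_excluded)
    if not common:
        raise ValueError("fit tables share no genes")

    f1, f2 = fits_v1.loc[common], fits_v2.loc[common]
    period = float(f1["period"].iloc[0])
    dphi = phase_difference(f1["phase"].to_numpy(), f2["phase"].to_numpy(), period)
    with np.errstate(invalid="ignore"):
        cyc = ((f1["p_value"].to_numpy() < p_thresh)
               & (f2["p_value"].to_numpy() < p_thresh)
               & (dphi < dphi_max_hours))

    # circular mean of two phases, vectorized via phasor sum
    w = TWO_PI / period
    z = np.exp(1j * w * f1["phase"].to_numpy()) + np.exp(1j * w * f2["phase"].to_numpy())
    consensus = (np.angle(z) / w) % period
    consensus = np.where(period - consensus < 1e-9, 0.0, consensus)
    consensus = np.where(cyc, consensus, np.nan)

    out = pd.DataFrame(
        {
            "p_v1": f1["p_value"].to_numpy(),
            "p_v2": f2["p_value"].to_numpy(),
            "phase_v1": f1["phase"].to_numpy(),
            "phase_v2": f2["phase"].to_numpy(),
            "delta_phi": dphi,
            "is_cycling": cyc,
            "consensus_phase": consensus,
        },
        index=pd.Index(common, name="gene_id"),
    )
    if condition is not None:
        out["condition"] = condition
    return out


def expected_chance_cyclers(n_genes: int, p_thresh: float = 0.1,
                            dphi_max_hours: float = 3.0) -> float:
    """Expected number of chance calls under the flat independent null.

    Both experiments' p-values uniform and independent, and the chance
    phase difference uniform on [0, 12] h:

        E = n_genes · p_thresh² · (dphi_max_hours / 12)
    """
    if not 0 < p_thresh <= 1:
        raise ValueError("p_thresh must be in (0, 1]")
    if not 0 < dphi_max_hours <= 12:
        raise ValueError("dphi_max_hours must be in (0, 12]")
    return n_genes * p_thresh ** 2 * (dphi_max_hours / 12.0)


def false_discovery_summary(n_tested: int, n_called: Mapping[str, int],
                            p_thresh: float = 0.1,
                            dphi_max_hours: float = 3.0) -> dict:
    """Expected chance cyclers and the implied FDR percent per condition."""
    expected = expected_chance_cyclers(n_tested, p_thresh, dphi_max_hours)
    per_condition = {
        cond: {
            "n_called": int(k),
            "fdr_percent": 100.0 * expected / k if k else float("nan"),
        }
        for cond, k in n_called.items()
    }
    return {
        "n_tested": int(n_tested),
        "expected_chance_cyclers": expected,
        "per_condition": per_condition,
    }
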