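"""Synthetic study generator with known ground truth.

Emulates the structure of a two-experiment, two-temperature circadian
bulk RNA-seq study: samples every 2 h across a stable two-day window, a
minority of genes rhythmic at a fixed 24 h period, phases optionally
organized on a gene-interaction network, and multiplicative lognormal
noise on TPM.  Both experiments share each gene's true phase but receive
independent noise and a small per-gene phase jitter, mirroring the
replication logic of the real design (two independently sequenced
experiments, V1 and V2).

Phase organization is planted by iterated local circular averaging: each
cycling gene's unit phasor is repeatedly pulled toward the mean phasor of
its cycling neighbours with weight ``coupling``; ``coupling = 0`` leaves
phases independent of network position.

All randomness flows from one master seed through named substreams
(network / planting / noise), so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import TimeCourseMatrix, write_tpm_matrix

log = logging.getLogger(__name__)

TRUTH_COLUMNS = ("gene_id", "is_cycling", "phase_true",
                 "amplitude_true", "mesor_true", "condition")

_STREAM_IDS = {"network": 101, "planting": 211, "noise": 307}


def _substream(seed: int, stream: str, *labels: str) -> np.random.Generator:
    """Named, label-salted child generator of the master seed."""
    salt = [int.from_bytes(hashlib.md5(l.encode()).digest()[:4], "big")
            for l in labels]
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAM_IDS[stream], *salt]))


@dataclass(frozen=True)
class SimDesign:
    """Sampling design and noise model for one simulated study.

    Defaults follow the emulated study: samples every 2 h across a 48 h
    window (ZT 0–46, 24 timepoints), one replicate, two experiments, a
    fixed 24 h period, 20% multiplicative noise, and a 0.5 h SD per-gene
    phase jitter between experiments.
    """

    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 48, 2))
    n_replicates: int = 1
    experiments: tuple[str, ...] = ("V1", "V2")
    period: float = 24.0
    noise_cv: float = 0.2
    inter_experiment_phase_jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.unique(np.round(tp % self.period, 9)).size < 6:
            raise ValueError("need >= 6 distinct timepoints per period "
                             "to resolve one harmonic")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.inter_experiment_phase_jitter_sd < 0:
            raise ValueError("phase jitter SD must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_network(n_nodes: int, mean_degree: float,
                     model: str = "erdos_renyi", seed: int = 0) -> nx.Graph:
    """Random undirected simple graph over synthetic gene identifiers.

    ``model`` is one of ``erdos_renyi`` (edge probability
    ``mean_degree/(n−1)``), ``watts_strogatz`` (ring lattice of even
    degree ``mean_degree``, 10% rewiring) or ``barabasi_albert``
    (``m = mean_degree/2`` attachments).  Parameters that leave the model
    undefined (odd ring-lattice degree, non-integral m) are rejected.
    Deterministic given ``seed``.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if not 0 < mean_degree < n_nodes:
        raise ValueError("mean_degree must be in (0, n_nodes)")
    rng_seed = int(_substream(seed, "network").integers(2 ** 31))
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(n_nodes, mean_degree / (n_nodes - 1), seed=rng_seed)
    elif model == "watts_strogatz":
        k = int(round(mean_degree))
        if abs(mean_degree - k) > 1e-9 or k % 2:
            raise ValueError("watts_strogatz requires an even integer mean degree")
        g = nx.watts_strogatz_graph(n_nodes, k, p=0.1, seed=rng_seed)
    elif model == "barabasi_albert":
        m = int(round(mean_degree / 2))
        if m < 1 or abs(mean_degree / 2 - m) > 1e-9:
            raise ValueError("barabasi_albert requires mean_degree = 2m, m >= 1")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=rng_seed)
    else:
        raise ValueError(f"unknown network model: {model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    width = len(str(n_nodes - 1))
    return nx.relabel_nodes(g, {i: f"g{i:0{width}d}" for i in g.nodes})


def plant_phases(net: nx.Graph, frac_cycling: float, coupling: float,
                 n_smooth: int, seed: int = 0, condition: str = "18C",
                 mesor_median: float = 50.0, mesor_sigma: float = 0.6,
                 rel_amplitude: tuple[float, float] = (0.3, 0.8)) -> pd.DataFrame:
    """Mark a random subset of nodes cycling and plant their phases.

    ``round(frac_cycling·|V|)`` nodes are drawn uniformly and given
    initial phases uniform on [0, 24); ``n_smooth`` rounds of circular
    relaxation then replace each cycling node's unit phasor by
    ``(1−coupling)·own + coupling·(mean phasor of cycling neighbours)``,
    renormalized.  ``coupling = 0`` leaves phases independent of network
    position; isolated cycling nodes keep their initial phase.

    Mesors are lognormal around ``mesor_median`` TPM; cycling amplitudes
    are a uniform ``rel_amplitude`` fraction of the gene's mesor and
    non-cycling amplitudes are exactly 0 (their phase is NaN).
    """
    if not 0 < frac_cycling <= 1:
        raise ValueError("frac_cycling must be in (0, 1]")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = _substream(seed, "planting", condition)
    nodes = sorted(net.nodes, key=str)
    n = len(nodes)
    n_cyc = int(round(frac_cycling * n))
    cyc_idx = np.sort(rng.choice(n, size=n_cyc, replace=False))
    is_cyc = np.zeros(n, dtype=bool)
    is_cyc[cyc_idx] = True

    phases = np.full(n, np.nan)
    z = np.exp(1j * rng.uniform(0.0, 2.0 * math.pi, size=n_cyc))
    if coupling > 0 and n_smooth > 0:
        sub = net.subgraph([nodes[i] for i in cyc_idx])
        adj = nx.to_scipy_sparse_array(sub, nodelist=[nodes[i] for i in cyc_idx],
                                       format="csr")
        deg = np.asarray(adj.sum(axis=1)).ravel()
        has_nb = deg > 0
        for _ in range(n_smooth):
            nb_mean = np.zeros_like(z)
            nb_mean[has_nb] = (adj @ z)[has_nb] / deg[has_nb]
            znew = np.where(has_nb, (1 - coupling) * z + coupling * nb_mean, z)
            mag = np.abs(znew)
            z = np.where(mag > 1e-12, znew / np.where(mag > 0, mag, 1.0), z)
    phases[cyc_idx] = (np.angle(z) % (2.0 * math.pi)) * (24.0 / (2.0 * math.pi))

    mesor = rng.lognormal(math.log(mesor_median), mesor_sigma, size=n)
    amp = np.zeros(n)
    amp[cyc_idx] = mesor[cyc_idx] * rng.uniform(*rel_amplitude, size=n_cyc)
    return pd.DataFrame({
        "gene_id": nodes,
        "is_cycling": is_cyc,
        "phase_true": phases,
        "amplitude_true": amp,
        "mesor_true": mesor,
        "condition": condition,
    })


def simulate_experiment(truth: pd.DataFrame, design: SimDesign,
                        experiment: str = "V1") -> TimeCourseMatrix:
    """Simulate one experiment's TPM matrix from a truth table.

    Cycling genes follow ``mesor + amplitude·cos(2π(t − φ − ε)/period)``
    with a per-gene, per-experiment phase jitter ε ~ N(0, jitter SD); flat
    genes sit at their mesor.  Every value is multiplied by lognormal
    noise of unit mean and CV ``design.noise_cv`` and clipped at 0
    (multiplicative lognormal noise cannot produce negative TPM; the clip
    is a guard).  Deterministic given ``design.seed``.
    """
    condition = str(truth["condition"].iloc[0])
    rng = _substream(design.seed, "noise", experiment, condition)

    genes = truth["gene_id"].to_list()
    mesor = truth["mesor_true"].to_numpy(dtype=float)
    amp = truth["amplitude_true"].to_numpy(dtype=float)
    phase = np.nan_to_num(truth["phase_true"].to_numpy(dtype=float))
    if (mesor <= 0).any():
        raise ValueError("mesor_true must be positive")
    if (amp < 0).any() or (amp[~truth["is_cycling"].to_numpy()] != 0).any():
        raise ValueError("non-cycling genes must have amplitude_true = 0")

    eps = rng.normal(0.0, design.inter_experiment_phase_jitter_sd, size=len(genes))
    times = np.repeat(np.asarray(design.timepoints, dtype=float),
                      design.n_replicates)
    reps = np.tile(np.arange(1, design.n_replicates + 1), len(design.timepoints))

    w = 2.0 * math.pi / design.period
    signal = mesor[:, None] + amp[:, None] * np.cos(
        w * (times[None, :] - (phase + eps)[:, None]))
    signal = np.clip(signal, 0.0, None)
    if design.noise_cv > 0:
        sigma2 = math.log1p(design.noise_cv ** 2)
        factor = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=signal.shape)
        signal = signal * factor
    signal = np.clip(signal, 0.0, None)

    sample_ids = [f"{experiment}_{condition}_ZT{t:04.1f}_r{r}"
                  for t, r in zip(times, reps)]
    values = pd.DataFrame(signal, index=pd.Index(genes, name="gene_id"),
                          columns=sample_ids)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "zt_hours": times,
        "replicate": reps,
        "experiment": experiment,
        "condition": condition,
    })
    return TimeCourseMatrix(values, meta)


def simulate_study(truths: Mapping[str, pd.DataFrame],
                   design: SimDesign) -> dict[tuple[str, str], TimeCourseMatrix]:
    """Simulate every experiment × condition matrix of a study.

    ``truths`` maps condition label → truth table; all experiments of the
    design share each condition's true phases but draw independent noise
    and jitter.
    """
    out: dict[tuple[str, str], TimeCourseMatrix] = {}
    for condition, truth in truths.items():
        for experiment in design.experiments:
            out[(experiment, condition)] = simulate_experiment(
                truth, design, experiment=experiment)
    return out


def write_fixture_bundle(outdir: Path | str, net: nx.Graph,
                         truths: Mapping[str, pd.DataFrame] | pd.DataFrame,
                         matrices: Mapping[tuple[str, str], TimeCourseMatrix],
                         ) -> dict[str, Path]:
    """Write a complete synthetic study as plain TSV files.

    Emits ``edges.tsv`` (two-column edge list), ``truth_<condition>.tsv``,
    and per (experiment, condition) ``tpm_<exp>_<cond>.tsv`` +
    ``samples_<exp>_<cond>.tsv``; all round-trip losslessly through the
    readers in :mod:`cyclenet.preprocess` and :mod:`cyclenet.network` at
    the fixed formatting precision.  Returns the written paths.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        edge_path = outdir / "edges.tsv"
        with open(edge_path, "w") as fh:
            fh.write("#gene_a\tgene_b\n")
            for a, b in sorted((sorted(map(str, e)) for e in net.edges)):
                fh.write(f"{a}\t{b}\n")
        paths["edges"] = edge_path

        if isinstance(truths, pd.DataFrame):
            truths = {str(truths["condition"].iloc[0]): truths}
        for condition, truth in truths.items():
            p = outdir / f"truth_{condition}.tsv"
            truth.loc[:, list(TRUTH_COLUMNS)].to_csv(
                p, sep="\t", index=False, float_format="%.6g")
            paths[f"truth_{condition}"] = p

        for (exp, cond), mat in matrices.items():
            mp = outdir / f"tpm_{exp}_{cond}.tsv"
            sp = outdir / f"samples_{exp}_{cond}.tsv"
            write_tpm_matrix(mat, mp, sp)
            paths[f"tpm_{exp}_{cond}"] = mp
            paths[f"samples_{exp}_{cond}"] = sp
        return paths
    except OSError as err:
        raise OSError(f"failed writing fixture bundle under {outdir}: {err}") from err


def read_truth_table(path: Path | str) -> pd.DataFrame:
    """Read a truth table written by :func:`write_fixture_bundle`."""
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str})
    t["is_cycling"] = t["is_cycling"].astype(bool)
    return t
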