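"""Network phase-organization analysis.

Tests whether cycling genes that are close on a gene-interaction network
have more similar peak phases than distant ones.  The workflow:

1. load an undirected simple graph from a two-column edge list and extract
   its largest connected component (LCC);
2. sanity checks — are the network's cycling genes representative of all
   cyclers in phase (KS), unremarkable in degree (KS), and are they more
   tightly clustered on the graph than chance (Wilcoxon rank-sum on
   pairwise geodesic distances)?
3. the profile of median pairwise phase difference Δφ per geodesic
   distance class, its linear trend across classes, and a permutation
   null that re-places the cycling genes uniformly on the LCC (keeping
   the observed phase multiset) to obtain an empirical p-value per class.

Empirical p-values use the add-one estimator
``(1 + #{null ≤ observed}) / (1 + n_perm)`` and therefore never reach 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .phase import compare_phase_distributions
from .rhythm import phase_difference

log = logging.getLogger(__name__)


# -- graph I/O and basics -------------------------------------------------

def load_edge_list(path: Path | str) -> nx.Graph:
    """Read an undirected simple graph from a two-column TSV edge list.

    Lines starting with ``#`` and blank lines are skipped.  Duplicate
    edges (in either orientation) are merged and self-loops dropped, with
    counts logged; nodes mentioned only in self-loops are kept.  Malformed
    lines raise with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    g = nx.Graph()
    n_loops = n_dup = n_edges_seen = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            a, b = parts
            n_edges_seen += 1
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_edges_seen == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_loops or n_dup:
        log.info("%s: dropped %d self-loops, %d duplicate edges", path, n_loops, n_dup)
    return g


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component.

    Size ties are broken deterministically in favour of the component
    containing the lexicographically smallest node.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(net))
    best = min(comps, key=lambda c: (-len(c), min(map(str, c))))
    return net.subgraph(best).copy()


def _distance_matrix(net: nx.Graph,
                     nodelist: Sequence | None = None) -> tuple[np.ndarray, list]:
    """All-pairs unweighted shortest-path hop counts (BFS), as a dense
    float matrix with ``inf`` for unreachable pairs."""
    nodes = list(nodelist) if nodelist is not None else sorted(net.nodes, key=str)
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csr")
    D = shortest_path(adj, method="D", unweighted=True, directed=False)
    return D, nodes


def geodesic_distances(net: nx.Graph, sources: Sequence | None = None,
                       targets: Sequence | None = None) -> pd.DataFrame:
    """BFS hop-count table between ``sources`` (rows) and ``targets``
    (columns); unreachable pairs are ``inf``.  Unknown node IDs raise."""
    all_nodes = set(net.nodes)
    sources = list(sources) if sources is not None else sorted(all_nodes, key=str)
    targets = list(targets) if targets is not None else sources
    unknown = [n for n in (*sources, *targets) if n not in all_nodes]
    if unknown:
        raise KeyError(f"nodes not in graph: {sorted(set(map(str, unknown)))}")
    tset = set(targets)
    out = pd.DataFrame(np.inf, index=sources, columns=targets)
    for s in sources:
        lengths = nx.single_source_shortest_path_length(net, s)
        for t, d in lengths.items():
            if t in tset:
                out.at[s, t] = float(d)
    return out


# -- sanity checks on the cycling subset ---------------------------------

def representativeness_test(phases_network_genes, phases_all_cyclers,
                            cut: float = 0.0) -> dict:
    """KS comparison of the network cyclers' phases against all cyclers."""
    return compare_phase_distributions(phases_network_genes, phases_all_cyclers, cut=cut)


def degree_comparison(net: nx.Graph, subset: Sequence) -> dict:
    """Two-sample KS between the subset's degrees and all node degrees."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    unknown = [n for n in subset if n not in net]
    if unknown:
        raise KeyError(f"nodes not in graph: {sorted(map(str, unknown))}")
    deg_all = np.array([d for _, d in net.degree()], dtype=float)
    deg_sub = np.array([net.degree(n) for n in subset], dtype=float)
    res = stats.ks_2samp(deg_sub, deg_all)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_subset": len(subset), "n_all": net.number_of_nodes()}


def localization_test(net: nx.Graph, subset: Sequence,
                      pair_ceiling: int = 10_000_000, seed: int = 0) -> dict:
    """Are the subset's pairwise geodesic distances smaller than those of
    all LCC node pairs?

    One-sided Wilcoxon rank-sum (Mann–Whitney U) with alternative
    "subset distances smaller".  All-pairs distances are computed exactly
    by repeated BFS; above ``pair_ceiling`` pairs a uniform subsample of
    that size is drawn with the fixed ``seed`` and reported.
    """
    lcc = largest_connected_component(net)
    surv = [n for n in subset if n in lcc]
    dropped = len(list(subset)) - len(surv)
    if dropped:
        log.warning("localization_test: dropped %d subset nodes outside the LCC", dropped)
    if len(surv) < 2:
        raise ValueError("fewer than 2 subset nodes inside the LCC")

    D, nodes = _distance_matrix(lcc)
    pos = {n: i for i, n in enumerate(nodes)}
    iu = np.triu_indices(len(nodes), k=1)
    d_all = D[iu]
    sub_idx = np.array([pos[n] for n in surv])
    su = np.triu_indices(len(surv), k=1)
    d_sub = D[np.ix_(sub_idx, sub_idx)][su]

    subsampled = False
    if d_all.size > pair_ceiling:
        rng = np.random.default_rng(seed)
        d_all = rng.choice(d_all, size=pair_ceiling, replace=False)
        subsampled = True
    res = stats.mannwhitneyu(d_sub, d_all, alternative="less")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_subset_pairs": int(d_sub.size), "n_all_pairs": int(d_all.size),
            "subsampled": subsampled, "seed": seed}


# -- the distance–phase profile ------------------------------------------

def _profile_from_pairs(d_pairs: np.ndarray, dphi_pairs: np.ndarray,
                        d_max: int | None, min_pairs: int) -> pd.DataFrame:
    finite = np.isfinite(d_pairs)
    d_pairs, dphi_pairs = d_pairs[finite], dphi_pairs[finite]
    rows = []
    for d in np.unique(d_pairs.astype(int)):
        if d < 1 or (d_max is not None and d > d_max):
            continue
        mask = d_pairs == d
        n = int(mask.sum())
        if n >= min_pairs:
            rows.append({"distance": int(d), "n_pairs": n,
                         "median_dphi": float(np.median(dphi_pairs[mask]))})
    return pd.DataFrame(rows, columns=["distance", "n_pairs", "median_dphi"])


def phase_distance_profile(distances: pd.DataFrame, phases,
                           d_max: int | None = None,
                           min_pairs: int = 50) -> pd.DataFrame:
    """Median Δφ of cycling-gene pairs at each geodesic distance class.

    ``distances`` is a square symmetric hop-count table over the cycling
    genes (see :func:`geodesic_distances`); ``phases`` maps each of those
    genes to its phase in ZT hours.  Classes with fewer than ``min_pairs``
    pairs (default 50 — medians at sparse classes are unstable) are
    dropped; ``d_max`` of None keeps every sufficiently populated class.
    """
    genes = list(distances.index)
    ph = pd.Series(phases)
    missing = [g for g in genes if g not in ph.index or np.isnan(ph[g])]
    if missing:
        raise KeyError(f"phases missing for genes: {sorted(map(str, missing))[:5]}")
    phi = ph.loc[genes].to_numpy(dtype=float)
    D = distances.to_numpy(dtype=float)
    iu = np.triu_indices(len(genes), k=1)
    prof = _profile_from_pairs(D[iu], phase_difference(phi[iu[0]], phi[iu[1]]),
                               d_max, min_pairs)
    if prof.empty:
        log.warning("no distance class reaches %d pairs; empty profile", min_pairs)
    return prof


def median_trend(profile: pd.DataFrame) -> dict:
    """OLS of per-class median Δφ on geodesic distance (one point per
    class, unweighted); slope in hours per hop with a two-sided t-test p.

    A perfectly flat profile returns slope 0 with p = 1 by convention
    (the t statistic is 0/0 there).
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 distance classes for a trend")
    x = profile["distance"].to_numpy(dtype=float)
    y = profile["median_dphi"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "p_value": 1.0}
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "p_value": float(res.pvalue)}


# -- permutation null -----------------------------------------------------

@dataclass
class PhaseOrganizationResult:
    """Observed distance–phase profile with its permutation null.

    ``null_medians`` has one row per permutation and one column per
    distance class of ``profile`` (NaN where a permutation produced no
    pair at that class).  ``empirical_p`` maps each distance to the
    add-one one-sided (or two-sided) p-value computed from exactly those
    null vectors.  ``trend`` is the observed profile's linear trend, or
    None when fewer than 3 classes exist.
    """

    profile: pd.DataFrame
    null_medians: np.ndarray
    empirical_p: dict[int, float]
    trend: dict | None
    n_perm: int
    seed: int
    alternative: str = "less"
    n_missing_per_class: dict[int, int] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-ready summary: per-class observed median, null quantiles
        (2.5/50/97.5%), empirical p, plus the trend."""
        classes = []
        for j, row in self.profile.reset_index(drop=True).iterrows():
            col = self.null_medians[:, j]
            col = col[~np.isnan(col)]
            q = (np.percentile(col, [2.5, 50, 97.5]).tolist()
                 if col.size else [None, None, None])
            d = int(row["distance"])
            classes.append({
                "distance": d,
                "n_pairs": int(row["n_pairs"]),
                "median_dphi_obs": float(row["median_dphi"]),
                "null_q2.5": q[0], "null_median": q[1], "null_q97.5": q[2],
                "empirical_p": self.empirical_p[d],
                "n_null_missing": self.n_missing_per_class.get(d, 0),
            })
        return {"classes": classes, "trend": self.trend, "n_perm": self.n_perm,
                "seed": self.seed, "alternative": self.alternative}


def permutation_null(net: nx.Graph, cycling_nodes: Sequence, phases,
                     n_perm: int = 5000, seed: int = 0,
                     d_max: int | None = None, min_pairs: int = 50,
                     alternative: str = "less") -> PhaseOrganizationResult:
    """Permutation test of phase organization on the network.

    The observed statistic is the median Δφ per geodesic-distance class
    among the cycling genes.  Each of ``n_perm`` permutations draws
    ``len(cycling_nodes)`` positions uniformly without replacement from
    the LCC and attaches the observed phase multiset to them in random
    order, preserving both the number of cyclers and their phases.  The
    per-class empirical p is ``(1 + #{null median ≤ observed}) /
    (1 + n_perm)`` (one-sided "smaller than null"; ``alternative`` may be
    ``"greater"`` or ``"two-sided"``).  Deterministic given ``seed``.
    """
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lcc = largest_connected_component(net)
    cyc = list(cycling_nodes)
    if len(cyc) < 2:
        raise ValueError("need at least 2 cycling nodes")
    outside = [n for n in cyc if n not in lcc]
    if outside:
        raise ValueError(f"cycling nodes outside the LCC: {sorted(map(str, outside))[:5]}")

    ph = pd.Series(phases)
    phi_obs = ph.loc[cyc].to_numpy(dtype=float)
    if np.isnan(phi_obs).any():
        raise ValueError("NaN phase among cycling nodes")

    D, nodes = _distance_matrix(lcc)
    pos = {n: i for i, n in enumerate(nodes)}
    k, n = len(cyc), len(nodes)
    iu = np.triu_indices(k, k=1)

    obs_idx = np.array([pos[g] for g in cyc])
    d_obs = D[np.ix_(obs_idx, obs_idx)][iu]
    dphi_obs = phase_difference(phi_obs[iu[0]], phi_obs[iu[1]])
    profile = _profile_from_pairs(d_obs, dphi_obs, d_max, min_pairs)
    if profile.empty:
        raise ValueError("no distance class reaches min_pairs in the observed data")
    classes = profile["distance"].to_numpy()
    obs_med = profile["median_dphi"].to_numpy()

    rng = np.random.default_rng(seed)
    null_medians = np.full((n_perm, classes.size), np.nan)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        phi = rng.permutation(phi_obs)  # phase multiset preserved
        d_b = D[np.ix_(idx, idx)][iu]
        dphi_b = phase_difference(phi[iu[0]], phi[iu[1]])
        for j, d in enumerate(classes):
            mask = d_b == d
            if mask.any():
                null_medians[b, j] = np.median(dphi_b[mask])
    n_missing = {int(d): int(np.isnan(null_medians[:, j]).sum())
                 for j, d in enumerate(classes)}

    emp = {}
    for j, d in enumerate(classes):
        col = null_medians[:, j]
        with np.errstate(invalid="ignore"):
            n_le = int(np.nansum(col <= obs_med[j]))
            n_ge = int(np.nansum(col >= obs_med[j]))
        p_le = (1 + n_le) / (1 + n_perm)
        p_ge = (1 + n_ge) / (1 + n_perm)
        if alternative == "less":
            emp[int(d)] = p_le
        elif alternative == "greater":
            emp[int(d)] = p_ge
        else:
            emp[int(d)] = min(1.0, 2.0 * min(p_le, p_ge))

    trend = median_trend(profile) if len(profile) >= 3 else None
    return PhaseOrganizationResult(
        profile=profile, null_medians=null_medians, empirical_p=emp,
        trend=trend, n_perm=n_perm, seed=seed, alternative=alternative,
        n_missing_per_class=n_missing,
    )
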