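"""Synthetic ROI time-series cohorts with planted network structure.

Generates two-group cohorts whose functional connectomes have known
ground truth: a modular planted graph (148 nodes by default, matching a
whole-cortex sulco-gyral parcellation), designated hub nodes forced to
high degree, a group effect that weakens within-module coupling in one
group (lowering its clustering coefficient), a binary genotype label
that modulates between-module connectivity with opposite sign in the
two groups (moving modularity and small-worldness in opposite
directions), and node morphometry (volume, thickness) linearly coupled
to the planted group difference in node degree.

The generative chain is: planted adjacency -> precision matrix
I - coupling * A (positive definite by construction for coupling below
1/lambda_max(A)) -> covariance by inversion -> Gaussian AR(1) series
whose stationary covariance is exactly that matrix.  Connected node
pairs therefore carry strictly stronger correlations than unconnected
pairs, so density thresholding of a long sample recovers the planted
edges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import BinaryGraph
from .prep import RoiTimeSeries

__all__ = [
    "PlantedNetworkSpec",
    "CohortSpec",
    "make_planted_graph",
    "graph_to_covariance",
    "default_coupling",
    "sample_cohort",
    "sample_morphometry",
    "write_cohort",
]

#: Degree target for planted hubs, in SDs above the mean degree.  Hubs are
#: planted far above the +2 SD hub-detection convention: with a realistic
#: handful of hubs per network the hubs themselves inflate the SD of the
#: nodal centrality distribution and would mask each other if planted at
#: the detection boundary, so a hub is made a categorical property of the
#: network rather than a borderline one.
HUB_TARGET_SD = 4.0

#: Default planted hub sets for two-group cohorts: six hubs per group,
#: four shared and two group-unique, mirroring the partially overlapping
#: hub distributions reported for clinical vs control connectomes.
DEFAULT_HUB_NODES_A = (7, 23, 58, 91, 102, 131)
DEFAULT_HUB_NODES_B = (7, 23, 30, 58, 91, 110)

#: When hubs are planted, non-designated nodes are rewired down below
#: mean + this * SD, so chance high-degree background nodes do not blur
#: the planted hub set (the designated hubs are then the *complete*
#: ground-truth hub set, not merely members of it).
BACKGROUND_CAP_SD = 1.5

#: Additive signal baseline, so synthetic series have a realistic
#: (BOLD-like) positive mean and a meaningful temporal SNR.
SIGNAL_BASELINE = 500.0

#: Fraction of the positive-definiteness bound 1/lambda_max(A) used when
#: no explicit coupling is given.
AUTO_COUPLING_FRACTION = 0.85


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Ground-truth network for one cohort.

    ``p_within``/``p_between`` are the edge probabilities inside and
    across modules; ``hub_nodes`` are forced to degree at least
    mean + 2 SD of the degree sequence by preferential rewiring;
    ``coupling`` maps adjacency to covariance (None = auto, a fixed
    fraction of the positive-definiteness bound); ``ar_coeff`` is the
    lag-1 temporal autocorrelation of every ROI.
    """

    n_nodes: int = 148
    n_modules: int = 6
    p_within: float = 0.4
    p_between: float = 0.02
    hub_nodes: tuple[int, ...] = ()
    coupling: float | None = None
    ar_coeff: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_between < self.p_within <= 1:
            raise ValueError("need 0 <= p_between < p_within <= 1")
        if self.n_nodes < 2 * self.n_modules:
            raise ValueError("need n_nodes >= 2 * n_modules")
        object.__setattr__(self, "hub_nodes",
                           tuple(int(h) for h in self.hub_nodes))
        if any(h < 0 or h >= self.n_nodes for h in self.hub_nodes):
            raise ValueError("hub indices must lie in [0, n_nodes)")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.coupling is not None and self.coupling <= 0:
            raise ValueError("coupling must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Study design: group sizes and planted effect magnitudes.

    ``group_effect`` scales down within-module coupling in group B
    (0.5 halves it, targeting a clustering deficit); ``genotype_split``
    is the fraction of "S"-labelled subjects per group;
    ``genotype_effect`` multiplies between-module edge probability for S
    carriers, with opposite sign in the two groups (S raises p_between
    in group B and lowers it in group A), moving modularity and the
    small-world index in opposite directions across groups;
    ``volume_coupling`` is the slope from planted per-node degree
    differences to node-volume differences; ``noise_sd`` is the
    morphometry noise.  ``hub_nodes_b`` optionally gives group B its own
    hub list (default: same hubs as group A).
    """

    n_per_group: tuple[int, int] = (30, 30)
    n_timepoints: int = 250
    group_effect: float = 0.5
    genotype_split: tuple[float, float] = (0.7, 0.8)
    genotype_effect: float = 0.0
    volume_coupling: float = -1.0
    noise_sd: float = 1.0
    hub_nodes_b: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if not 0 <= self.group_effect < 1:
            raise ValueError("group_effect must lie in [0, 1)")
        if any(not 0 <= f <= 1 for f in self.genotype_split):
            raise ValueError("genotype_split fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.hub_nodes_b is not None:
            object.__setattr__(self, "hub_nodes_b",
                               tuple(int(h) for h in self.hub_nodes_b))


def _module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal module blocks."""
    labels = np.empty(n_nodes, dtype=int)
    for m, chunk in enumerate(np.array_split(np.arange(n_nodes), n_modules)):
        labels[chunk] = m
    return labels


def _plant_hubs(adj: np.ndarray, hubs: Sequence[int],
                rng: np.random.Generator,
                max_retries: int = 1000) -> None:
    """Rewire edges toward hub nodes until each clears the degree target.

    Moves randomly chosen edges between non-hub nodes onto the hub
    (preserving total edge count) until the hub degree reaches
    mean + HUB_TARGET_SD * SD of the degree sequence, comfortably above
    the mean + 2 SD hub floor.  Bounded retries: an error
    naming the node is raised when the background graph cannot supply
    enough edges (p_within too low for the requested hub degree).
    """
    n = adj.shape[0]
    hub_set = set(int(h) for h in hubs)
    for h in hubs:
        retries = 0
        while True:
            deg = adj.sum(axis=0)
            target = deg.mean() + HUB_TARGET_SD * deg.std()
            if deg[h] >= target:
                break
            if retries >= max_retries or deg[h] >= n - 1:
                raise ValueError(
                    f"infeasible hub constraint for node {h}: cannot reach "
                    f"degree {target:.1f} (p_within too low to support the "
                    "requested hub degree)")
            i, j = np.nonzero(np.triu(adj, k=1))
            donor_mask = np.array([
                a not in hub_set and b not in hub_set and a != h and b != h
                for a, b in zip(i, j)])
            candidates = np.nonzero(donor_mask)[0]
            if candidates.size == 0:
                raise ValueError(
                    f"infeasible hub constraint for node {h}: no donor edges "
                    "left to rewire (p_within too low)")
            e = int(rng.choice(candidates))
            a, b = int(i[e]), int(j[e])
            w = a if rng.random() < 0.5 else b
            if adj[h, w]:
                retries += 1
                continue
            adj[a, b] = adj[b, a] = 0
            adj[h, w] = adj[w, h] = 1
    _cap_background(adj, hub_set, rng)


def _cap_background(adj: np.ndarray, hub_set: set[int],
                    rng: np.random.Generator,
                    max_moves: int = 2000) -> None:
    """Rewire chance high-degree background nodes below the hub band.

    A binomial background leaves ~2% of nodes above mean + 2 SD by
    chance; if such nodes survive, the designated hub list is not the
    complete ground truth.  Excess edges of non-designated nodes above
    mean + BACKGROUND_CAP_SD * SD are moved onto random low-degree
    non-hub nodes (edge count preserved).
    """
    for _ in range(max_moves):
        deg = adj.sum(axis=0)
        mu, sd = deg.mean(), deg.std()
        cap = mu + BACKGROUND_CAP_SD * sd
        offenders = [v for v in np.argsort(-deg)
                     if v not in hub_set and deg[v] > cap]
        if not offenders:
            return
        off = int(offenders[0])
        neighbors = [w for w in np.nonzero(adj[off])[0] if w not in hub_set]
        recipients = [v for v in np.nonzero(deg < mu)[0]
                      if v not in hub_set and v != off]
        moved = False
        for _attempt in range(20):
            if not neighbors or not recipients:
                break
            w = int(rng.choice(neighbors))
            v = int(rng.choice(recipients))
            if v != w and not adj[v, w]:
                adj[off, w] = adj[w, off] = 0
                adj[v, w] = adj[w, v] = 1
                moved = True
                break
        if not moved:  # cannot improve this node; accept as-is
            return


def _planted_adjacency(spec: PlantedNetworkSpec,
                       p_between_mult: float = 1.0,
                       hub_nodes: Sequence[int] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency + module labels for one (possibly modulated) cell.

    The same seed always produces the same uniform draw per node pair,
    so cells that differ only in ``p_between_mult`` share almost all of
    their edges — genotype variants are coherent perturbations of one
    underlying network, not independent graphs.
    """
    n = spec.n_nodes
    modules = _module_assignment(n, spec.n_modules)
    rng = np.random.default_rng(spec.seed)
    u = rng.random((n, n))
    u = np.triu(u, k=1)
    same = modules[:, None] == modules[None, :]
    p_between = min(spec.p_between * p_between_mult, 1.0)
    p = np.where(same, spec.p_within, p_between)
    adj = ((u < p) & (np.triu(np.ones((n, n), dtype=bool), k=1))).astype(np.int8)
    adj = adj | adj.T
    hubs = spec.hub_nodes if hub_nodes is None else tuple(hub_nodes)
    if hubs:
        _plant_hubs(adj, hubs, rng)
    return adj, modules


def make_planted_graph(
    spec: PlantedNetworkSpec,
) -> tuple[BinaryGraph, np.ndarray]:
    """Generate the planted modular graph and its module assignment."""
    adj, modules = _planted_adjacency(spec)
    n = spec.n_nodes
    m_total = n * (n - 1) // 2
    labels = [f"roi_{i:03d}" for i in range(n)]
    density = int(adj.sum()) / 2 / m_total
    return BinaryGraph(adj, density, labels), modules


def default_coupling(adjacency: np.ndarray,
                     fraction: float = AUTO_COUPLING_FRACTION) -> float:
    """Coupling at a fixed fraction of the positive-definiteness bound.

    I - c*A is positive definite iff c < 1/lambda_max(A) (A is
    non-negative, so its spectral radius is its largest eigenvalue).
    """
    a = np.asarray(adjacency, dtype=float)
    if a.sum() == 0:
        return 0.0
    lam = float(np.linalg.eigvalsh(a)[-1])
    return fraction / lam


def graph_to_covariance(adjacency: np.ndarray | BinaryGraph,
                        coupling: float | np.ndarray) -> np.ndarray:
    """Covariance implied by a graph: inverse of I - coupling * A.

    ``coupling`` may be a scalar or a symmetric per-edge weight matrix
    (already elementwise-multiplied semantics: precision off-diagonals
    are -coupling on edges).  The construction guarantees that connected
    pairs have strictly larger absolute correlation than unconnected
    pairs within the same module-path structure, and is positive
    definite whenever the spectral radius of the weighted adjacency is
    below 1 (checked by Cholesky).
    """
    a = _adjacency_array(adjacency)
    n = a.shape[0]
    if np.isscalar(coupling):
        w = float(coupling) * a
    else:
        w = np.asarray(coupling, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weight matrix shape must match adjacency")
        w = w * (a != 0)
    if not np.allclose(w, w.T):
        raise ValueError("coupling weights must be symmetric")
    precision = np.eye(n) - w
    try:
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "implied precision matrix is not positive definite; "
            "use a smaller coupling") from exc
    cov = np.linalg.inv(precision)
    return (cov + cov.T) / 2.0


def _adjacency_array(adjacency: np.ndarray | BinaryGraph) -> np.ndarray:
    if isinstance(adjacency, BinaryGraph):
        return adjacency.adjacency.astype(float)
    return np.asarray(adjacency, dtype=float)


def _cell_covariance(spec: PlantedNetworkSpec, cohort: CohortSpec,
                     group: str, genotype: str
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(adjacency, covariance) of one group x genotype design cell."""
    sign = -1.0 if group == "A" else 1.0
    mult = 1.0 + sign * cohort.genotype_effect if genotype == "S" else 1.0
    hubs = spec.hub_nodes if group == "A" else (
        cohort.hub_nodes_b if cohort.hub_nodes_b is not None
        else spec.hub_nodes)
    adj, modules = _planted_adjacency(spec, p_between_mult=mult,
                                      hub_nodes=hubs)
    c = spec.coupling if spec.coupling is not None else default_coupling(adj)
    w = c * adj.astype(float)
    if group == "B" and cohort.group_effect > 0:
        same = modules[:, None] == modules[None, :]
        w[same] *= (1.0 - cohort.group_effect)
    cov = graph_to_covariance(adj, w)
    return adj, cov


def _ar1_series(chol: np.ndarray, n_timepoints: int, ar: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian AR(1) with exact marginal covariance L @ L.T.

    x_t = ar * x_{t-1} + sqrt(1 - ar^2) * e_t with e_t ~ N(0, Sigma) and
    x_0 ~ N(0, Sigma): the lag-0 covariance equals Sigma at every t, so
    the temporal model does not distort the planted correlations.
    """
    n = chol.shape[0]
    innov = rng.standard_normal((n_timepoints, n)) @ chol.T
    if ar == 0:
        return innov
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - ar * ar)
    for t in range(1, n_timepoints):
        x[t] = ar * x[t - 1] + scale * innov[t]
    return x


def sample_cohort(
    net: PlantedNetworkSpec, cohort: CohortSpec
) -> tuple[list[RoiTimeSeries], pd.DataFrame, dict]:
    """Draw a full two-group cohort of ROI time series.

    Returns the per-subject series (with a constant signal baseline
    added so temporal SNR is realistic), a manifest (subject_id, group,
    genotype, BMI and anxiety-score covariates), and a ground-truth
    record holding the planted adjacency per group, module labels, hub
    lists, per-node planted degree differences and all effect
    parameters.
    """
    n = net.n_nodes
    if cohort.n_timepoints < n:
        warnings.warn(
            f"n_timepoints ({cohort.n_timepoints}) < n_nodes ({n}): "
            "correlation matrices will be rank-deficient",
            RuntimeWarning, stacklevel=2)
    labels = [f"roi_{i:03d}" for i in range(n)]
    rng = np.random.default_rng(net.seed)

    # Design cells share the seeded edge draw, so genotype variants are
    # coherent perturbations of one planted network.
    cells: dict[tuple[str, str], np.ndarray] = {}
    adjacencies: dict[tuple[str, str], np.ndarray] = {}
    for group in ("A", "B"):
        for genotype in ("S", "LL"):
            adj, cov = _cell_covariance(net, cohort, group, genotype)
            adjacencies[(group, genotype)] = adj
            cells[(group, genotype)] = np.linalg.cholesky(cov)

    series: list[RoiTimeSeries] = []
    rows: list[dict] = []
    bmi_params = {"A": (21.7, 2.9), "B": (15.8, 1.8)}
    for gi, group in enumerate(("A", "B")):
        n_g = cohort.n_per_group[gi]
        n_s = int(round(cohort.genotype_split[gi] * n_g))
        for s in range(n_g):
            genotype = "S" if s < n_s else "LL"
            sid = f"{group}{s + 1:03d}"
            data = _ar1_series(cells[(group, genotype)],
                               cohort.n_timepoints, net.ar_coeff, rng)
            series.append(RoiTimeSeries(sid, data + SIGNAL_BASELINE, labels))
            mu, sd = bmi_params[group]
            rows.append({
                "subject_id": sid,
                "group": group,
                "genotype": genotype,
                "bmi": round(float(rng.normal(mu, sd)), 2),
                "stai": round(float(rng.normal(40.0, 10.0)), 1),
            })
    manifest = pd.DataFrame(rows)

    # Ground-truth degree difference between groups, from the unmodulated
    # (genotype multiplier = 1) group graphs.
    base_a, _ = _planted_adjacency(net, hub_nodes=net.hub_nodes)
    base_b, modules = _planted_adjacency(
        net, hub_nodes=(cohort.hub_nodes_b
                        if cohort.hub_nodes_b is not None
                        else net.hub_nodes))
    deg_diff = base_a.sum(axis=0).astype(float) - base_b.sum(axis=0)
    ground_truth = {
        "roi_labels": labels,
        "module_labels": modules.tolist(),
        "hub_nodes_a": list(net.hub_nodes),
        "hub_nodes_b": list(cohort.hub_nodes_b
                            if cohort.hub_nodes_b is not None
                            else net.hub_nodes),
        "adjacency_a": base_a.tolist(),
        "adjacency_b": base_b.tolist(),
        "degree_diff_a_minus_b": deg_diff.tolist(),
        "subjects": [
            {"subject_id": r["subject_id"], "group": r["group"],
             "genotype": r["genotype"]} for r in rows],
        "network_spec": asdict(net),
        "cohort_spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cohort).items()},
    }
    return series, manifest, ground_truth


def sample_morphometry(ground_truth: dict, cohort: CohortSpec,
                       seed: int | None = None) -> pd.DataFrame:
    """Per-subject node volumes and thicknesses coupled to degree deltas.

    The group difference in mean node volume is
    ``volume_coupling * (planted degree difference) + N(0, noise_sd)``
    per node; thickness follows the same law at 1/100 scale.  Subject
    volumes scatter around their group's node mean with SD ``noise_sd``.
    With ``noise_sd = 0`` the structure-function regression is exact.
    """
    deg_diff = np.asarray(ground_truth["degree_diff_a_minus_b"], dtype=float)
    labels = ground_truth["roi_labels"]
    if seed is None:
        seed = int(ground_truth["network_spec"]["seed"]) + 10_000
    rng = np.random.default_rng(seed)
    n = len(labels)
    base_vol = rng.normal(1000.0, 50.0, size=n)
    base_thk = rng.normal(2.5, 0.15, size=n)
    dv = cohort.volume_coupling * deg_diff \
        + rng.normal(0.0, cohort.noise_sd, size=n)
    dt = 0.01 * (cohort.volume_coupling * deg_diff) \
        + rng.normal(0.0, 0.01 * cohort.noise_sd, size=n)
    rows = []
    for subj in ground_truth["subjects"]:
        sign = 0.5 if subj["group"] == "A" else -0.5
        vol = base_vol + sign * dv + rng.normal(0, cohort.noise_sd, size=n)
        thk = base_thk + sign * dt + rng.normal(0, 0.01 * cohort.noise_sd,
                                                size=n)
        for i, lab in enumerate(labels):
            rows.append({
                "subject_id": subj["subject_id"],
                "group": subj["group"],
                "node": lab,
                "volume": vol[i],
                "thickness": thk[i],
            })
    return pd.DataFrame(rows)


def write_cohort(
    out_dir: str | Path,
    series: Sequence[RoiTimeSeries],
    manifest: pd.DataFrame,
    ground_truth: dict,
    morphometry: pd.DataFrame | None = None,
) -> Path:
    """Write a cohort directory: per-subject TSVs, manifest, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in series:
        s.to_tsv(out / f"{s.subject_id}.tsv")
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(ground_truth, sort_keys=True))
    if morphometry is not None:
        morphometry.to_csv(out / "morphometry.tsv", sep="\t", index=False)
    return out
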