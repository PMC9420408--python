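"""Synthetic data with the statistical structure the pipeline assumes.

Generates birth-death time trees with extant and fossil tips (fossil
recovery as a Poisson process along lineages), discrete ordered/unordered
characters evolved under the Mk model (through the same transition kernel
the reconstruction code uses), tip geocoordinates evolved under bivariate
Brownian motion on the unwrapped lon/lat plane, and multi-locality fossil
occurrence tables with uniform age ranges — so every pipeline stage is
testable end to end without any external archive.

All randomness flows through :class:`numpy.random.Generator` (PCG64);
the same :class:`SimulationConfig` always yields byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .charmatrix import CharacterMatrix, OccurrenceRecord, write_occurrences_csv
from .discrete import MkModel, transition_probs
from .trees import Node, TimeTree, write_newick
from .geo import wrap_longitude

__all__ = [
    "SimulationConfig",
    "simulate_fbd_tree",
    "yule_tree",
    "simulate_discrete",
    "simulate_matrix",
    "simulate_geo_bm",
    "make_occurrences",
    "generate_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults emulate a clade like the sea cows: ~50 Ma of history, a
    modest net diversification with heavy extinction, a handful of living
    survivors, tens of fossil tips, slow multistate morphological
    evolution, and trans-oceanic-scale geographic dispersal.
    """

    seed: int = 0
    birth_rate: float = 0.12  # lambda, events/Ma per lineage
    death_rate: float = 0.09  # mu
    fossil_rate: float = 0.04  # psi, fossil recovery events/Ma per lineage
    crown_age: float = 50.0  # Ma
    mk_rate: float = 0.02  # per-allowed-move rate per Ma per character
    n_characters: int = 83
    k_states: int = 3
    ordered_fraction: float = 0.22  # share of ordered multistate characters
    n_zones: int = 5
    bm_sigma: tuple = ((18.0, 0.0), (0.0, 6.0))  # deg^2/Ma, (lon, lat)
    root_lonlat: tuple[float, float] = (0.0, 25.0)
    multi_locality_fraction: float = 0.4
    max_localities: int = 3
    jitter_km: float = 300.0  # locality scatter around the true coordinate
    extant_range_km: float = 1500.0  # spread of extant range samples
    n_extant_samples: int = 10
    age_half_width: float = 1.0  # Ma; uniform range half-width
    age_midpoint_offset_frac: float = 0.0  # asymmetry knob, in (-1, 1)
    min_extant: int = 2
    min_fossil: int = 2
    max_retries: int = 1000

    def __post_init__(self):
        if not (self.birth_rate > self.death_rate >= 0.0):
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.fossil_rate < 0:
            raise ValueError("fossil_rate must be >= 0")
        sig = np.asarray(self.bm_sigma, dtype=float)
        if sig.shape != (2, 2) or not np.allclose(sig, sig.T):
            raise ValueError("bm_sigma must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(sig) < -1e-12):
            raise ValueError("bm_sigma must be positive semi-definite")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _prune_to_sampled(root: Node, sampled: set[int]) -> Optional[Node]:
    """Keep lineages with sampled descendants; suppress unary nodes."""

    def build(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if id(node) in sampled:
                return Node(node.label, node.age)
            return None
        kept = [b for c in node.children if (b := build(c)) is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(node.label, node.age)
        for c in kept:
            new.add_child(c)
        return new

    return build(root)


def simulate_fbd_tree(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> TimeTree:
    """Forward birth-death simulation from the crown age with Poisson
    fossil recovery; extinct lineages without sampled descendants are
    pruned.  Each fossil recovery becomes a terminal tip (sampled
    ancestors are detached as zero-length pendants whose branch grows if
    the continuing lineage dies out unsampled).  Retries until the
    configured minimum numbers of extant and fossil tips survive."""
    if rng is None:
        rng = config.rng()
    lam, mu, psi = config.birth_rate, config.death_rate, config.fossil_rate
    total_rate = lam + mu + psi

    for _ in range(config.max_retries):
        root = Node(None, config.crown_age)
        left = Node(None, config.crown_age)
        right = Node(None, config.crown_age)
        root.add_child(left)
        root.add_child(right)
        # active = (attachment node, forward time); forward time 0 = crown
        active: list[tuple[Node, float]] = [(left, 0.0), (right, 0.0)]
        sampled: set[int] = set()
        n_extant = n_fossil = 0

        while active:
            idx = int(rng.integers(len(active)))
            node, tau = active.pop(idx)
            wait = rng.exponential(1.0 / total_rate)
            tau_new = tau + wait
            if tau_new >= config.crown_age:
                node.age = 0.0
                n_extant += 1
                node.label = f"ext{n_extant}"
                sampled.add(id(node))
                continue
            node.age = config.crown_age - tau_new
            u = rng.random() * total_rate
            if u < lam:  # speciation
                a, b = Node(None, node.age), Node(None, node.age)
                node.add_child(a)
                node.add_child(b)
                active.append((a, tau_new))
                active.append((b, tau_new))
            elif u < lam + mu:  # extinction (unsampled tip)
                pass
            else:  # fossil recovery: pendant fossil tip + continuation
                # bifurcate slightly above the sample so the fossil tip
                # carries a positive terminal branch
                tau_node = tau_new - 0.1 * wait
                node.age = config.crown_age - tau_node
                n_fossil += 1
                fossil = Node(f"fos{n_fossil}", config.crown_age - tau_new)
                cont = Node(None, node.age)
                node.add_child(fossil)
                node.add_child(cont)
                sampled.add(id(fossil))
                active.append((cont, tau_node))

        if n_extant < config.min_extant or n_fossil < config.min_fossil:
            continue
        pruned = _prune_to_sampled(root, sampled)
        if pruned is None or pruned.is_leaf:
            continue
        tree = TimeTree(pruned)
        if len(tree.tips()) >= 2:
            tree.validate()
            return tree
    raise RuntimeError(
        "clade extinct (or below minimum tip counts) in every retry; "
        "adjust rates or raise max_retries"
    )


def yule_tree(
    n_tips: int,
    rng: np.random.Generator,
    birth_rate: float = 1.0,
    prefix: str = "t",
) -> TimeTree:
    """Pure-birth tree conditioned on ``n_tips`` extant tips (all at age
    0); a convenient random-topology generator for calibration studies."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    # forward times of speciation events from the crown
    times = [0.0]
    k = 2
    t = 0.0
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        times.append(t)
        k += 1
    t += rng.exponential(1.0 / (birth_rate * k))
    depth = t  # crown-to-present span

    root = Node(None, depth)
    active = [Node(None, depth), Node(None, depth)]
    root.add_child(active[0])
    root.add_child(active[1])
    for tau in times[1:]:
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.age = depth - tau
        a, b = Node(None, node.age), Node(None, node.age)
        node.add_child(a)
        node.add_child(b)
        active.extend([a, b])
    for i, node in enumerate(active, 1):
        node.age = 0.0
        node.label = f"{prefix}{i}"
    return TimeTree(root)


# ---------------------------------------------------------------------------
# Discrete characters
# ---------------------------------------------------------------------------


def _allowed_moves(state: int, k: int, ordered: bool) -> list[int]:
    if ordered:
        return [s for s in (state - 1, state + 1) if 0 <= s < k]
    return [s for s in range(k) if s != state]


def simulate_discrete(
    tree: TimeTree,
    k_states: int,
    rate: float,
    ordered: bool,
    rng: np.random.Generator,
    return_paths: bool = False,
):
    """Evolve one discrete character down the tree.

    The root state is uniform; child states are drawn from the same Mk
    transition kernel the reconstruction code exponentiates
    (:func:`paleophylo.discrete.transition_probs`).  With
    ``return_paths=True`` branches are simulated event by event (Gillespie;
    distributionally identical for this kernel) and the per-branch state
    paths are returned alongside, keyed by child node id."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    states: dict[int, int] = {}
    paths: dict[int, list[tuple[float, int]]] = {}
    root_state = int(rng.integers(k_states))
    states[tree.root.id] = root_state
    if rate == 0.0:
        for node in tree.preorder():
            states[node.id] = root_state
            if node.parent is not None and return_paths:
                paths[node.id] = [(node.parent.age, root_state)]
    elif return_paths:
        for parent, child in tree.branch_iter():
            s = states[parent.id]
            t = parent.age  # ages decrease toward the present
            path = [(t, s)]
            while True:
                n_moves = len(_allowed_moves(s, k_states, ordered))
                wait = rng.exponential(1.0 / (rate * n_moves))
                if t - wait <= child.age:
                    break
                t -= wait
                s = int(rng.choice(_allowed_moves(s, k_states, ordered)))
                path.append((t, s))
            states[child.id] = s
            paths[child.id] = path
    else:
        model = MkModel(k=k_states, ordered=ordered, rate=rate)
        pcache: dict[float, np.ndarray] = {}
        for parent, child in tree.branch_iter():
            dt = parent.age - child.age
            if dt not in pcache:
                pcache[dt] = transition_probs(model, dt)
            p = pcache[dt][states[parent.id]]
            states[child.id] = int(rng.choice(k_states, p=p))
    tip_states = {n.label: states[n.id] for n in tree.tips()}
    if return_paths:
        return tip_states, paths
    return tip_states


def simulate_matrix(
    tree: TimeTree,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> CharacterMatrix:
    """Simulate a taxa x characters matrix under the configured Mk model;
    the leading ``ordered_fraction`` of characters are ordered."""
    if rng is None:
        rng = config.rng()
    n_ordered = int(round(config.ordered_fraction * config.n_characters))
    cols, ordered_flags = [], []
    taxa = tree.taxa
    for j in range(config.n_characters):
        is_ordered = j < n_ordered
        tip_states = simulate_discrete(
            tree, config.k_states, config.mk_rate, is_ordered, rng
        )
        cols.append([tip_states[t] for t in taxa])
        ordered_flags.append(is_ordered)
    data = np.array(cols, dtype=np.int16).T
    return CharacterMatrix(taxa, data, ordered=ordered_flags)


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def simulate_geo_bm(
    tree: TimeTree,
    sigma,
    root_lonlat: tuple[float, float],
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]]:
    """Bivariate Brownian motion of (lon, lat) down the tree: increments
    are Gaussian with covariance ``sigma * dt`` on the unwrapped plane
    (matching the reconstruction model); longitudes are wrapped to
    (-180, 180] only on output and latitudes are clipped to [-90, 90]."""
    sig = np.asarray(sigma, dtype=float)
    w, v = np.linalg.eigh(sig)
    sqrt_sig = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    pos: dict[int, np.ndarray] = {
        tree.root.id: np.asarray(root_lonlat, dtype=float)
    }
    for parent, child in tree.branch_iter():
        dt = parent.age - child.age
        step = sqrt_sig @ rng.standard_normal(2) * math.sqrt(dt)
        pos[child.id] = pos[parent.id] + step
    out = {}
    for tip in tree.tips():
        lon, lat = pos[tip.id]
        out[tip.label] = (wrap_longitude(lon), float(np.clip(lat, -90.0, 90.0)))
    return out


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


def _jitter(point, km, rng) -> tuple[float, float]:
    lon, lat = point
    dlat = rng.normal(0.0, km) / 111.32 if km > 0 else 0.0
    coslat = max(math.cos(math.radians(lat)), 0.05)
    dlon = rng.normal(0.0, km) / (111.32 * coslat) if km > 0 else 0.0
    return wrap_longitude(lon + dlon), float(np.clip(lat + dlat, -90.0, 90.0))


def make_occurrences(
    tree: TimeTree,
    geo: dict[str, tuple[float, float]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[OccurrenceRecord]:
    """Occurrence localities for every tip.

    Fossil tips get 1..max_localities jittered localities, each with a
    uniform age range containing the tip's true age (range midpoint equals
    the true age by default; the asymmetry knob shifts it).  Extant tips
    get ``n_extant_samples`` range points (age range degenerate at 0),
    emulating evenly sampled points from a modern range polygon."""
    if rng is None:
        rng = config.rng()
    h = config.age_half_width
    records: list[OccurrenceRecord] = []
    for tip in tree.tips():
        if tip.label not in geo:
            raise ValueError(f"no simulated coordinate for tip {tip.label!r}")
        point = geo[tip.label]
        if tip.age == 0.0:
            for j in range(config.n_extant_samples):
                lon, lat = _jitter(point, config.extant_range_km, rng)
                records.append(OccurrenceRecord(
                    tip.label, f"{tip.label}_L{j + 1}", lon, lat, 0.0, 0.0
                ))
            continue
        multi = rng.random() < config.multi_locality_fraction \
            and config.max_localities >= 2
        m = int(rng.integers(2, config.max_localities + 1)) if multi else 1
        base_center = tip.age + config.age_midpoint_offset_frac * h
        for j in range(m):
            lon, lat = _jitter(point, config.jitter_km, rng)
            if j == 0 or h == 0.0 or rng.random() < 0.5:
                center = base_center
            else:
                # distinct but still true-age-containing range
                center = tip.age + rng.uniform(-0.5, 0.5) * h
            lo = max(center - h, 0.0)
            hi = center + h
            lo = min(lo, tip.age)  # guarantee the true age is inside
            hi = max(hi, tip.age)
            records.append(OccurrenceRecord(
                tip.label, f"{tip.label}_L{j + 1}", lon, lat, lo, hi
            ))
    return records


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig, out_dir=None) -> dict:
    """Simulate a full synthetic study: tree, character matrix, tip
    coordinates, occurrence table, and the true parameters.

    With ``out_dir`` the pieces are written as Newick, NEXUS, CSV and a
    true-parameters JSON sidecar.  Returns the in-memory objects."""
    rng = config.rng()
    tree = simulate_fbd_tree(config, rng)
    matrix = simulate_matrix(tree, config, rng)
    geo = simulate_geo_bm(tree, config.bm_sigma, config.root_lonlat, rng)
    occurrences = make_occurrences(tree, geo, config, rng)
    dataset = {
        "tree": tree,
        "matrix": matrix,
        "geo": geo,
        "occurrences": occurrences,
        "config": config,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(tree) + "\n")
        (out / "matrix.nex").write_text(matrix.to_nexus())
        write_occurrences_csv(occurrences, out / "occurrences.csv")
        params = asdict(config)
        params["true_root_lonlat"] = list(config.root_lonlat)
        (out / "true_params.json").write_text(
            json.dumps(params, indent=2, default=list) + "\n"
        )
    return dataset
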