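"""Continuous geocoordinates ancestral reconstruction on time trees.

Ancestral biogeography is modelled as a bivariate (longitude, latitude)
Brownian motion on the tree: increments along a branch of duration dt are
Gaussian with covariance ``Sigma * dt`` (deg^2/Ma).  Node estimates are
generalized-least-squares means under the tree covariance structure, the
rate matrix ``Sigma`` is estimated by REML, and per-node uncertainty is
expressed as a 2x2 covariance from which confidence ellipses are drawn.

The module also implements the two-pass strategy for trees whose tips
bundle several occurrence localities:

1. first pass — multi-locality tips are collapsed to spherical geocentroids
   and the tree is fitted as-is;
2. the tip-to-parent displacement yields a per-tip scaling factor
   ``s = dt / d`` (Ma per km) which converts geographic distance to time;
3. each multi-locality tip is split into one tip per locality.  Two
   localities bifurcate the terminal directly; three or more go through a
   geodesic distance matrix -> neighbor joining -> rooting on the
   closest-to-parent locality -> nonparametric rate smoothing
   (flush-tipped) -> scaling by ``s`` -> grafting;
4. second pass — the expanded tree, in which every tip is a single point,
   is refitted.

Coordinates are treated as planar after unwrapping longitudes about the
data's centroid meridian; latitudes are not re-projected (documented
limitation near the poles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .charmatrix import geocentroid
from .trees import BranchLengthTree, Node, TimeTree, TreeError

__all__ = [
    "EARTH_RADIUS_KM",
    "geodesic_km",
    "unwrap_longitudes",
    "wrap_longitude",
    "BrownianGeoModel",
    "GeoReconstruction",
    "fit_bm_asr",
    "first_pass",
    "ScalingFactor",
    "scaling_factor",
    "split_two_locality_tip",
    "nj_tree",
    "root_on_closest",
    "nprs_ultrametricize",
    "split_multi_locality_tip",
    "expand_multilocality_tips",
    "second_pass",
]

EARTH_RADIUS_KM = 6371.0

#: clamp margin for split-node ages, as a fraction of the original
#: terminal-branch duration
CLAMP_EPS_FRAC = 0.01


# ---------------------------------------------------------------------------
# Spherical geometry helpers
# ---------------------------------------------------------------------------


def geodesic_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle (haversine) distance in km between (lon, lat) points."""
    lon1, lat1 = map(math.radians, a)
    lon2, lat2 = map(math.radians, b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (
        math.sin(dlat / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def wrap_longitude(lon: float) -> float:
    """Map a longitude to (-180, 180]."""
    r = (lon - 0.0) % 360.0
    if r > 180.0:
        r -= 360.0
    return r


def unwrap_longitudes(lons: Sequence[float], center: float) -> np.ndarray:
    """Map longitudes into the continuous chart (center-180, center+180].

    Required because the Far East / Beringia zone spans the dateline; the
    inverse (:func:`wrap_longitude`) is applied to outputs."""
    out = np.empty(len(lons))
    for i, lon in enumerate(lons):
        r = (lon - center) % 360.0
        if r > 180.0:
            r -= 360.0
        out[i] = center + r
    return out


def _circular_mean_lon(lons: Sequence[float]) -> float:
    s = sum(math.sin(math.radians(l)) for l in lons)
    c = sum(math.cos(math.radians(l)) for l in lons)
    if abs(s) < 1e-12 and abs(c) < 1e-12:
        return 0.0
    return math.degrees(math.atan2(s, c))


# ---------------------------------------------------------------------------
# Brownian-motion GLS/REML reconstruction
# ---------------------------------------------------------------------------


def _tree_structure(tree: TimeTree):
    """Tip covariance matrix C (shared root-to-mrca path lengths) and, for
    every node, the vector c of shared path lengths with each tip."""
    tips = tree.tips()
    n = len(tips)
    tip_index = {id(t): i for i, t in enumerate(tips)}
    root_age = tree.root.age

    # tip sets per node (by preorder id)
    tipsets: dict[int, set[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            tipsets[node.id] = {tip_index[id(node)]}
        else:
            s: set[int] = set()
            for c in node.children:
                s |= tipsets[c.id]
            tipsets[node.id] = s

    C = np.zeros((n, n))
    for node in tree.preorder():
        depth = root_age - node.age
        if node.is_leaf:
            i = tip_index[id(node)]
            C[i, i] = depth
            continue
        kids = node.children
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                sa = tipsets[kids[a].id]
                sb = tipsets[kids[b].id]
                for i in sa:
                    for j in sb:
                        C[i, j] = C[j, i] = depth

    # shared-path vectors for every node
    cvecs: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        depth = root_age - node.age
        c = np.empty(n)
        inside = tipsets[node.id]
        for i in inside:
            c[i] = depth
        assigned = set(inside)
        anc = node.parent
        while anc is not None:
            adepth = root_age - anc.age
            for i in tipsets[anc.id] - assigned:
                c[i] = adepth
            assigned |= tipsets[anc.id]
            anc = anc.parent
        cvecs[node.id] = c
    return tips, C, cvecs


@dataclass
class _NodeEstimate:
    node_id: int
    label: Optional[str]
    age: float
    is_tip: bool
    mean: tuple[float, float]  # (lon, lat), wrapped
    cov: np.ndarray  # 2x2, deg^2


class GeoReconstruction:
    """Results of a Brownian-motion geocoordinates reconstruction.

    Carries per-node mean positions and 2x2 covariances, the fitted rate
    matrix ``sigma`` (deg^2/Ma), the restricted log-likelihood, and ellipse
    geometry at the configured confidence level.
    """

    def __init__(self, model, estimates, sigma, loglik, conf, center):
        self.model = model
        self.estimates: dict[int, _NodeEstimate] = estimates
        self.sigma = sigma
        self.llf = loglik
        self.conf = conf
        self.center_meridian = center

    @property
    def tree(self) -> TimeTree:
        return self.model.tree

    def node_mean(self, node_id: int) -> tuple[float, float]:
        return self.estimates[node_id].mean

    def node_cov(self, node_id: int) -> np.ndarray:
        return self.estimates[node_id].cov

    def root_mean(self) -> tuple[float, float]:
        return self.node_mean(self.tree.root.id)

    def ellipse(self, node_id: int, conf: Optional[float] = None):
        """(semi_major, semi_minor, orientation_deg) of the confidence
        ellipse; axes are sqrt(eigenvalue x chi^2_2 quantile)."""
        conf = self.conf if conf is None else conf
        cov = self.estimates[node_id].cov
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        q = chi2.ppf(conf, df=2)
        semi = np.sqrt(np.clip(w, 0.0, None) * q)
        angle = math.degrees(math.atan2(v[1, 0], v[0, 0]))
        return float(semi[0]), float(semi[1]), angle

    def ellipse_area(self, node_id: int, conf: Optional[float] = None) -> float:
        a, b, _ = self.ellipse(node_id, conf)
        return math.pi * a * b

    def contains(self, node_id: int, point: tuple[float, float],
                 conf: Optional[float] = None) -> bool:
        """Is a (lon, lat) point inside the node's confidence ellipse?"""
        conf = self.conf if conf is None else conf
        est = self.estimates[node_id]
        d = np.array([
            unwrap_longitudes([point[0]], est.mean[0])[0] - est.mean[0],
            point[1] - est.mean[1],
        ])
        cov = est.cov
        if np.linalg.det(cov) <= 0:
            return bool(np.allclose(d, 0.0))
        m2 = float(d @ np.linalg.solve(cov, d))
        return m2 <= chi2.ppf(conf, df=2)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates.values():
            smaj, smin, ang = self.ellipse(est.node_id)
            rows.append({
                "node_id": est.node_id,
                "label": est.label,
                "age": est.age,
                "is_tip": est.is_tip,
                "mean_lon": est.mean[0],
                "mean_lat": est.mean[1],
                "cov_lon_lon": est.cov[0, 0],
                "cov_lon_lat": est.cov[0, 1],
                "cov_lat_lat": est.cov[1, 1],
                "ellipse_semi_major": smaj,
                "ellipse_semi_minor": smin,
                "ellipse_angle_deg": ang,
            })
        return pd.DataFrame(rows).sort_values("node_id").reset_index(drop=True)

    def to_geojson(self) -> dict:
        """Points for node means plus geodesic branch segments, for
        external map rendering."""
        features = []
        for est in self.estimates.values():
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [est.mean[0], est.mean[1]]},
                "properties": {"node_id": est.node_id, "label": est.label,
                               "age": est.age, "is_tip": est.is_tip},
            })
        for parent, child in self.tree.branch_iter():
            pm = self.estimates[parent.id].mean
            cm = self.estimates[child.id].mean
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [list(pm), list(cm)]},
                "properties": {"parent": parent.id, "child": child.id},
            })
        return {"type": "FeatureCollection", "features": features}

    def summary(self) -> str:
        s = self.sigma
        lines = [
            "Brownian-motion geocoordinates reconstruction",
            "=" * 48,
            f"tips:                {len(self.tree.tips())}",
            f"nodes reconstructed: {len(self.estimates)}",
            f"confidence level:    {self.conf:.0%}",
            f"center meridian:     {self.center_meridian:.2f} deg",
            "rate matrix Sigma (deg^2/Ma):",
            f"  lon-lon {s[0, 0]: .5g}   lon-lat {s[0, 1]: .5g}",
            f"  lat-lon {s[1, 0]: .5g}   lat-lat {s[1, 1]: .5g}",
            f"log-likelihood:      {self.llf:.4f}",
            f"root mean (lon, lat): ({self.root_mean()[0]:.3f}, "
            f"{self.root_mean()[1]:.3f})",
        ]
        return "\n".join(lines)


class BrownianGeoModel:
    """Bivariate Brownian-motion model of tip geocoordinates on a time tree.

    Parameters
    ----------
    tree : TimeTree with >= 3 tips.
    tip_points : taxon -> (lon, lat) in WGS84 decimal degrees.
    center_meridian : chart center for longitude unwrapping; defaults to
        the circular mean of tip longitudes.
    """

    def __init__(self, tree: TimeTree, tip_points: dict,
                 center_meridian: Optional[float] = None):
        self.tree = tree
        missing = [t for t in tree.taxa if t not in tip_points]
        if missing:
            raise ValueError(f"tips without coordinates: {missing}")
        if len(tree.tips()) < 2:
            raise ValueError("need >= 2 tips for a Brownian reconstruction")
        self.tip_points = {t: tuple(map(float, tip_points[t]))
                           for t in tree.taxa}
        if center_meridian is None:
            center_meridian = _circular_mean_lon(
                [p[0] for p in self.tip_points.values()]
            )
        self.center_meridian = float(center_meridian)

    def fit(self, conf: float = 0.68) -> GeoReconstruction:
        tree = self.tree
        tips, C, cvecs = _tree_structure(tree)
        n = len(tips)
        lons = unwrap_longitudes(
            [self.tip_points[t.label][0] for t in tips], self.center_meridian
        )
        lats = np.array([self.tip_points[t.label][1] for t in tips])
        X = np.column_stack([lons, lats])

        # guard against (near-)singular C from zero-length pendant edges or
        # near-duplicate tips created by degenerate locality subtrees
        w = np.linalg.eigvalsh(C)
        if w[0] <= 1e-10 * w[-1]:
            ridge = 1e-9 * w[-1] + max(0.0, -w[0])
            C = C + ridge * np.eye(n)
        Cinv_X = np.linalg.solve(C, X)
        Cinv_1 = np.linalg.solve(C, np.ones(n))
        one_Cinv_one = float(np.ones(n) @ Cinv_1)
        root_mean = (np.ones(n) @ Cinv_X) / one_Cinv_one  # GLS estimate

        R = X - root_mean  # residuals about the GLS root
        Cinv_R = Cinv_X - np.outer(Cinv_1, root_mean)
        S = R.T @ Cinv_R
        sigma = S / (n - 1)  # REML estimate of the 2x2 rate matrix

        # log-likelihood at the fitted parameters (ML form, Sigma_ML = S/n)
        sign, logdet_C = np.linalg.slogdet(C)
        sigma_ml = S / n
        sign_s, logdet_S = np.linalg.slogdet(sigma_ml)
        if sign <= 0 or sign_s <= 0:
            loglik = float("nan")
        else:
            loglik = -0.5 * (
                2.0 * logdet_C + n * logdet_S + 2.0 * n
                + 2.0 * n * math.log(2.0 * math.pi)
            )

        root_age = tree.root.age
        internal = [nd for nd in tree.preorder() if not nd.is_leaf]
        if internal:
            # factor once: solve C X = [c_v] for all internal nodes jointly
            Cmat = np.column_stack([cvecs[nd.id] for nd in internal])
            Cinv_Cmat = np.linalg.solve(C, Cmat)
        estimates: dict[int, _NodeEstimate] = {}
        for j, node in enumerate(internal):
            c = cvecs[node.id]
            Cinv_c = Cinv_Cmat[:, j]
            mean_chart = root_mean + Cinv_c @ R
            depth = root_age - node.age
            # conditional BM variance plus uncertainty in the GLS root
            h = 1.0 - float(np.ones(n) @ Cinv_c)
            scalar = depth - float(c @ Cinv_c) + h * h / one_Cinv_one
            scalar = max(scalar, 0.0)
            cov = scalar * sigma
            mean = (wrap_longitude(mean_chart[0]), float(mean_chart[1]))
            estimates[node.id] = _NodeEstimate(
                node.id, node.label, node.age, False, mean, cov
            )
        for node in tree.tips():
            estimates[node.id] = _NodeEstimate(
                node.id, node.label, node.age, True,
                self.tip_points[node.label], np.zeros((2, 2)),
            )
        return GeoReconstruction(
            self, estimates, sigma, loglik, conf, self.center_meridian
        )


def fit_bm_asr(tree: TimeTree, tip_points: dict, conf: float = 0.68,
               center_meridian: Optional[float] = None) -> GeoReconstruction:
    """Functional wrapper: REML Brownian reconstruction of (lon, lat)."""
    return BrownianGeoModel(tree, tip_points, center_meridian).fit(conf)


# ---------------------------------------------------------------------------
# First pass: centroids for multi-locality tips
# ---------------------------------------------------------------------------


def first_pass(
    tree: TimeTree,
    occurrences: Sequence,
    extant_samples: Optional[dict] = None,
    conf: float = 0.68,
) -> GeoReconstruction:
    """Fit the Brownian model on the original tree with multi-locality tips
    collapsed to spherical geocentroids.  ``occurrences`` are
    OccurrenceRecord-like objects (taxon, lon, lat); ``extant_samples`` maps
    extant taxa to lists of range sample points."""
    pts: dict[str, list[tuple[float, float]]] = {}
    for rec in occurrences:
        pts.setdefault(rec.taxon, []).append((rec.lon, rec.lat))
    if extant_samples:
        for taxon, samples in extant_samples.items():
            pts.setdefault(taxon, []).extend(
                (p[0], p[1]) for p in samples
            )
    missing = [t for t in tree.taxa if t not in pts]
    if missing:
        raise ValueError(f"tips without occurrence coordinates: {missing}")
    tip_points = {t: geocentroid(pts[t]) for t in tree.taxa}
    return fit_bm_asr(tree, tip_points, conf=conf)


# ---------------------------------------------------------------------------
# Scaling factor (km -> Ma)
# ---------------------------------------------------------------------------


@dataclass
class ScalingFactor:
    """Per-tip conversion from geographic distance to time."""

    tip: str
    s: Optional[float]  # Ma per km; None when the distance is zero
    dt: float  # Ma between tip and its parent node
    d_km: float  # km between tip centroid and parent mean


def scaling_factor(tree: TimeTree, recon: GeoReconstruction,
                   tip: str) -> ScalingFactor:
    """s = (age(parent) - age(tip)) / geodesic(tip centroid, parent mean).

    A zero distance yields ``s=None``; callers fall back to the global
    median scaling factor across tips."""
    node = tree.node_for(tip)
    if node.parent is None:
        raise TreeError("tip has no parent")
    dt = node.parent.age - node.age
    tip_mean = recon.node_mean(node.id)
    parent_mean = recon.node_mean(node.parent.id)
    d = geodesic_km(tip_mean, parent_mean)
    s = (dt / d) if d > 0 else None
    return ScalingFactor(tip, s, dt, d)


# ---------------------------------------------------------------------------
# Rule (a): two-locality tips
# ---------------------------------------------------------------------------


def split_two_locality_tip(
    tree: TimeTree,
    tip: str,
    loc_a: tuple[str, tuple[float, float]],
    loc_b: tuple[str, tuple[float, float]],
    s: Optional[float],
    half_distance: bool = False,
    eps_frac: float = CLAMP_EPS_FRAC,
) -> tuple[TimeTree, dict[str, tuple[float, float]]]:
    """Bifurcate a terminal that bundles two localities.

    Both new tips keep the original tip age; the new node's age is the tip
    age plus the inter-locality distance scaled to time
    (``d*s``, or ``d*s/2`` with ``half_distance``), clamped just below the
    parent node.  Returns the new tree and labels -> points for the new
    tips."""
    node = tree.node_for(tip)
    if node.parent is None:
        raise TreeError("cannot split the root")
    t0, tp = node.age, node.parent.age
    eps = eps_frac * (tp - t0)
    (id_a, pt_a), (id_b, pt_b) = loc_a, loc_b
    d = geodesic_km(pt_a, pt_b)
    if d > 0 and s is not None:
        ds = d * s * (0.5 if half_distance else 1.0)
    else:
        ds = 1e-6 * (tp - t0)  # degenerate bifurcation just above the tip
    node_age = min(t0 + ds, tp - eps)
    node_age = max(node_age, t0 + 1e-6 * (tp - t0))

    sub_root = Node(None, node_age)
    lab_a, lab_b = f"{tip}__{id_a}", f"{tip}__{id_b}"
    sub_root.add_child(Node(lab_a, t0))
    sub_root.add_child(Node(lab_b, t0))
    subtree = TimeTree(sub_root)
    out = tree.graft_subtree(tip, subtree, node_age)
    return out, {lab_a: pt_a, lab_b: pt_b}


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> BranchLengthTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree represented with a trifurcating root (or a
    single edge for two labels).  Negative branch lengths are clamped to
    zero with the deficit transferred to the sibling branch (standard
    practice).  Exact on additive matrices.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need >= 2 labels")
    if n == 2:
        root = Node(None)
        root.add_child(Node(labels[0], length=0.0))
        root.add_child(Node(labels[1], length=float(D[0, 1])))
        return BranchLengthTree(root)

    active: list[Node] = [Node(lab) for lab in labels]
    dist = {  # symmetric dict keyed by node-id pairs
        (id(a), id(b)): float(D[i, j])
        for i, a in enumerate(active)
        for j, b in enumerate(active)
        if i < j
    }

    def d(a: Node, b: Node) -> float:
        if a is b:
            return 0.0
        return dist.get((id(a), id(b)), dist.get((id(b), id(a)), 0.0))

    def clamp(la: float, lb: float) -> tuple[float, float]:
        # move any negative length onto the sibling
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {id(a): sum(d(a, b) for b in active) for a in active}
        best, pair = None, None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[id(a)] - r[id(b)]
                if best is None or q < best - 1e-15:
                    best, pair = q, (a, b)
        a, b = pair
        dab = d(a, b)
        la = 0.5 * dab + (r[id(a)] - r[id(b)]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = clamp(la, lb)
        u = Node(None)
        a.length, b.length = la, lb
        u.add_child(a)
        u.add_child(b)
        for c in active:
            if c is a or c is b:
                continue
            dist[(id(u), id(c))] = 0.5 * (d(a, c) + d(b, c) - dab)
        active = [c for c in active if c is not a and c is not b] + [u]

    # final three-point join
    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    la, lb = clamp(la, lb)
    lc = max(lc, 0.0)
    root = Node(None)
    a.length, b.length, c.length = la, lb, lc
    for x in (a, b, c):
        root.add_child(x)
    return BranchLengthTree(root)


def _nj_path_lengths(tree: BranchLengthTree) -> dict[tuple[str, str], float]:
    labs = tree.taxa
    out = {}
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            out[(a, b)] = tree.path_length(a, b)
    return out


# ---------------------------------------------------------------------------
# Rooting on the closest-to-parent locality
# ---------------------------------------------------------------------------


def root_on_closest(
    nj: BranchLengthTree,
    parent_mean: tuple[float, float],
    localities: dict[str, tuple[float, float]],
) -> BranchLengthTree:
    """Root the unrooted NJ tree on the terminal branch of the locality
    geodesically closest to the parent node's mean position (ties broken by
    lowest locality id).  The root is placed at the branch midpoint."""
    labs = nj.taxa
    missing = [l for l in labs if l not in localities]
    if missing:
        raise ValueError(f"localities without coordinates: {missing}")
    best = min(
        sorted(labs),
        key=lambda l: (geodesic_km(localities[l], parent_mean), l),
    )
    work = nj.copy()
    tip = work.node_for(best)
    old_parent = tip.parent
    if old_parent is None:
        raise TreeError("cannot root on the current root")
    length = tip.length or 0.0

    # detach the tip, then re-hang the remainder from its old parent
    old_parent.children = [c for c in old_parent.children if c is not tip]

    def reorient(node: Node, new_parent_length: Optional[float]) -> Node:
        """Return `node` re-rooted: its old parent direction becomes a
        child carrying the old edge length."""
        new = Node(node.label, length=new_parent_length)
        for c in node.children:
            new.add_child(_copy_down(c))
        if node.parent is not None:
            node.parent.children = [
                c for c in node.parent.children if c is not node
            ]
            new.add_child(reorient(node.parent, node.length))
        return new

    def _copy_down(node: Node) -> Node:
        new = Node(node.label, length=node.length)
        for c in node.children:
            new.add_child(_copy_down(c))
        return new

    hang = reorient(old_parent, length / 2.0)
    root = Node(None)
    new_tip = Node(best, length=length / 2.0)
    root.add_child(new_tip)
    root.add_child(hang)
    out = BranchLengthTree(root)
    _suppress_unary(out)
    return out


def _suppress_unary(tree: BranchLengthTree) -> None:
    """Merge degree-2 internal nodes (summing edge lengths); keep the root."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.parent is not None and not node.is_leaf \
                    and len(node.children) == 1:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                idx = node.parent.children.index(node)
                child.parent = node.parent
                node.parent.children[idx] = child
                changed = True
        root = tree.root
        if len(root.children) == 1 and not root.children[0].is_leaf:
            new_root = root.children[0]
            new_root.parent = None
            new_root.length = None
            tree.root = new_root
            changed = True
    tree.index_nodes()


# ---------------------------------------------------------------------------
# Nonparametric rate smoothing
# ---------------------------------------------------------------------------


def nprs_ultrametricize(
    rooted: BranchLengthTree, tol: float = 1e-10
) -> tuple[TimeTree, float]:
    """Sanderson-style nonparametric rate smoothing.

    Node ages are chosen to minimize the sum over internal nodes of squared
    differences between each child edge's local rate (length / duration)
    and the parent edge's rate; at the root the term is the spread of the
    root children's rates about their mean.  All tips are flush at relative
    age 0 and the root is fixed at relative age 1 (the scale is not
    identifiable from rates alone).

    Returns the flush-tipped :class:`TimeTree` (relative ages) and the
    achieved objective value.  Pathological all-zero-length input falls
    back to uniform interpolation of ages by node depth.
    """
    nodes = list(rooted.preorder())
    tips = [n for n in nodes if n.is_leaf]
    if len(tips) < 2:
        raise TreeError("need >= 2 tips to ultrametricize")
    internal = [n for n in nodes if not n.is_leaf and n.parent is not None]

    total_len = sum((c.length or 0.0) for _, c in rooted.branch_iter())

    def subtree_height(node: Node) -> float:
        if node.is_leaf:
            return 0.0
        return max(
            (c.length or 0.0) + subtree_height(c) for c in node.children
        )

    def build_timetree(ages: dict[int, float]) -> TimeTree:
        def conv(node: Node) -> Node:
            new = Node(node.label, ages[node.id])
            for c in node.children:
                new.add_child(conv(c))
            return new

        return TimeTree(conv(rooted.root))

    # uniform-interpolation fallback for degenerate (all-zero-length) input
    if total_len <= 0:
        def levels(node: Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(levels(c) for c in node.children)

        root_levels = levels(rooted.root)
        ages = {n.id: levels(n) / root_levels for n in nodes}
        return build_timetree(ages), 0.0

    root_h = subtree_height(rooted.root)
    heights = {n.id: subtree_height(n) for n in nodes}

    # parametrize each internal non-root age as a fraction of its parent age
    lo, hi = 1e-6, 1.0 - 1e-6

    def ages_from_params(params: np.ndarray) -> dict[int, float]:
        ages = {rooted.root.id: 1.0}
        for n in nodes:
            if n.is_leaf:
                ages[n.id] = 0.0
        for val, node in zip(params, internal):
            f = 1.0 / (1.0 + math.exp(-val))  # logistic -> (0,1)
            ages[node.id] = f * ages[node.parent.id]
        return ages

    def objective_from_ages(ages: dict[int, float]) -> float:
        big = 1e12
        rates: dict[int, float] = {}
        for parent, child in rooted.branch_iter():
            dt = ages[parent.id] - ages[child.id]
            if dt <= 0:
                return big
            rates[child.id] = (child.length or 0.0) / dt
        obj = 0.0
        for node in nodes:
            if node.is_leaf:
                continue
            if node.parent is None:
                rs = [rates[c.id] for c in node.children]
                mean = sum(rs) / len(rs)
                obj += sum((r - mean) ** 2 for r in rs)
            else:
                rp = rates[node.id]
                obj += sum((rates[c.id] - rp) ** 2 for c in node.children)
        return obj

    if not internal:  # e.g. a two-tip tree: only the root age exists
        ages = ages_from_params(np.empty(0))
        return build_timetree(ages), objective_from_ages(ages)

    # initial guess: subtree-height-proportional ages (exact for clock input)
    x0 = []
    for node in internal:
        parent_h = heights[node.parent.id] if heights[node.parent.id] > 0 \
            else root_h
        f = heights[node.id] / parent_h if parent_h > 0 else 0.5
        f = min(max(f, lo), hi)
        x0.append(math.log(f / (1.0 - f)))
    x0 = np.array(x0)

    def fun(params: np.ndarray) -> float:
        return objective_from_ages(ages_from_params(params))

    res = minimize(
        fun, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000,
                 "maxfev": 40000},
    )
    best = res.x if res.fun <= fun(x0) else x0
    ages = ages_from_params(best)
    return build_timetree(ages), objective_from_ages(ages)


# ---------------------------------------------------------------------------
# Rule (b): three-or-more-locality tips
# ---------------------------------------------------------------------------


def split_multi_locality_tip(
    tree: TimeTree,
    tip: str,
    localities: Sequence[tuple[str, tuple[float, float]]],
    s: Optional[float],
    parent_mean: tuple[float, float],
    eps_frac: float = CLAMP_EPS_FRAC,
) -> tuple[TimeTree, dict[str, tuple[float, float]]]:
    """Split a tip bundling >= 3 localities.

    Pipeline: geodesic distance matrix -> neighbor joining -> rooting on
    the closest-to-parent locality -> nonparametric rate smoothing ->
    scaling km to Ma with ``s`` -> grafting so all new tips sit at the
    original tip age.  The subtree's time depth is the maximum pairwise
    path distance between localities (x ``s``), which degenerates exactly
    to rule (a)'s ``d*s`` for two localities; overshoot past the parent is
    clamped."""
    if len(localities) < 2:
        raise ValueError("need >= 2 localities to split a tip")
    node = tree.node_for(tip)
    if node.parent is None:
        raise TreeError("cannot split the root")
    t0, tp = node.age, node.parent.age
    eps = eps_frac * (tp - t0)

    ids = [lid for lid, _ in localities]
    pts = {lid: pt for lid, pt in localities}
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = geodesic_km(pts[ids[i]], pts[ids[j]])

    nj = nj_tree(D, ids)
    rooted = root_on_closest(nj, parent_mean, pts)
    smoothed, _ = nprs_ultrametricize(rooted)

    # depth of the grafted subtree in km: maximal pairwise spread
    pathlens = _nj_path_lengths(nj)
    max_pair_km = max(pathlens.values()) if pathlens else 0.0
    if s is not None and max_pair_km > 0:
        depth_ma = max_pair_km * s
    else:
        depth_ma = 1e-6 * (tp - t0)
    attach_age = min(t0 + depth_ma, tp - eps)
    attach_age = max(attach_age, t0 + 1e-6 * (tp - t0))

    # rescale relative ages (root 1, tips 0) into [t0, attach_age]; internal
    # ages are affinely lifted off the tips so every locality keeps a
    # strictly positive pendant branch (rate smoothing may otherwise
    # collapse nodes onto the tips, which would duplicate rows of the tip
    # covariance matrix in the second pass)
    span = attach_age - t0
    floor_frac = 1e-3

    def conv(sm_node: Node) -> Node:
        if sm_node.is_leaf:
            return Node(f"{tip}__{sm_node.label}", t0)
        rel = floor_frac + (1.0 - floor_frac) * sm_node.age
        new = Node(None, t0 + rel * span)
        for c in sm_node.children:
            new.add_child(conv(c))
        return new

    subtree = TimeTree(conv(smoothed.root))
    out = tree.graft_subtree(tip, subtree, attach_age)
    return out, {f"{tip}__{lid}": pts[lid] for lid in ids}


# ---------------------------------------------------------------------------
# Full expansion + second pass
# ---------------------------------------------------------------------------


def expand_multilocality_tips(
    tree: TimeTree,
    recon: GeoReconstruction,
    tip_localities: dict[str, Sequence[tuple[str, tuple[float, float]]]],
    half_distance: bool = False,
) -> tuple[TimeTree, dict[str, tuple[float, float]], pd.DataFrame]:
    """Split every tip bundling >= 2 localities using the first-pass
    reconstruction for scaling factors and rooting positions.

    Returns (expanded tree, tip -> point map covering all tips, log table
    of per-tip scaling factors and clamping)."""
    factors: dict[str, ScalingFactor] = {}
    for tip, locs in tip_localities.items():
        if len(locs) >= 2:
            factors[tip] = scaling_factor(tree, recon, tip)
    valid = [f.s for f in factors.values() if f.s is not None]
    median_s = float(np.median(valid)) if valid else None

    out = tree
    point_map: dict[str, tuple[float, float]] = {}
    log_rows = []
    for tip in tree.taxa:
        locs = list(tip_localities.get(tip, []))
        if len(locs) <= 1:
            if locs:
                point_map[tip] = locs[0][1]
            continue
        sf = factors[tip]
        s = sf.s if sf.s is not None else median_s
        fallback = sf.s is None
        node = tree.node_for(tip)
        parent_mean = recon.node_mean(node.parent.id)
        if len(locs) == 2:
            out, new_pts = split_two_locality_tip(
                out, tip, locs[0], locs[1], s, half_distance=half_distance
            )
        else:
            out, new_pts = split_multi_locality_tip(
                out, tip, locs, s, parent_mean
            )
        point_map.update(new_pts)
        log_rows.append({
            "tip": tip, "n_localities": len(locs), "s_ma_per_km": s,
            "s_fallback_median": fallback, "dt": sf.dt, "d_km": sf.d_km,
        })
    out.index_nodes()
    return out, point_map, pd.DataFrame(log_rows)


def second_pass(
    expanded_tree: TimeTree,
    tip_points: dict[str, tuple[float, float]],
    conf: float = 0.68,
) -> GeoReconstruction:
    """Refit the Brownian model on the expanded tree in which every tip
    corresponds to a single georeferenceable point."""
    return fit_bm_asr(expanded_tree, tip_points, conf=conf)
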