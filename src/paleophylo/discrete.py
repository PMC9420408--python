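"""Marginal ancestral state reconstruction for discrete characters.

Characters evolve on a time tree under a symmetric k-state Markov (Mk)
model; "ordered" characters restrict transitions to adjacent states
(|i - j| = 1), capturing designed transformation series such as the
longitudinal-zone character.  The rate ``r`` is the per-allowed-move rate:
``Q = r * A - diag(row sums)`` with ``A`` the 0/1 adjacency of allowed
moves.  This keeps ordered and unordered rates on a comparable scale.

The pruning (Felsenstein) algorithm gives the likelihood; marginal node
reconstructions come from the standard inside-outside (re-rooting) pass.
Missing states ('?') contribute all-ones partials.  The root prior is
uniform over k, which is also the stationary distribution of the
symmetric model.

The primary entry point is the model/results pair
:class:`MkAsrModel` / :class:`MkAsrResults`; the functional layer
(:func:`tree_log_likelihood`, :func:`fit_rate`, :func:`marginal_asr`) is
exposed for composition and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import Node, TimeTree

__all__ = [
    "MkModel",
    "MarginalReconstruction",
    "MkAsrModel",
    "MkAsrResults",
    "transition_probs",
    "tree_log_likelihood",
    "fit_rate",
    "marginal_asr",
    "unambiguous_synapomorphies",
    "reconstruct_matrix",
    "InvariantCharacterError",
]

DEFAULT_SYNAPOMORPHY_THRESHOLD = 0.9


class InvariantCharacterError(ValueError):
    """Character has no observed variation; its rate is not identifiable
    (mirrors ascertainment-bias 'variable' coding)."""


@dataclass(frozen=True)
class MkModel:
    """Symmetric k-state Markov model.

    rate : expected number of attempts per allowed move per Ma.
    ordered : only adjacent-state transitions allowed.
    """

    k: int
    ordered: bool = False
    rate: float = 1.0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    def adjacency(self) -> np.ndarray:
        if self.ordered:
            a = np.zeros((self.k, self.k))
            idx = np.arange(self.k - 1)
            a[idx, idx + 1] = 1.0
            a[idx + 1, idx] = 1.0
        else:
            a = np.ones((self.k, self.k)) - np.eye(self.k)
        return a

    def q_matrix(self) -> np.ndarray:
        q = self.rate * self.adjacency()
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        # Q is symmetric, so a real orthogonal eigendecomposition exists
        w, v = np.linalg.eigh(self.q_matrix())
        return w, v


def transition_probs(model: MkModel, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1."""
    if t < 0:
        raise ValueError("t must be >= 0")
    w, v = model.eig()
    p = (v * np.exp(w * t)) @ v.T
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _tip_partial(state: Optional[int], k: int) -> np.ndarray:
    if state is None:
        return np.ones(k)
    if not (0 <= state < k):
        raise ValueError(f"state {state} >= k={k}")
    vec = np.zeros(k)
    vec[state] = 1.0
    return vec


class _Pruning:
    """Shared machinery: per-branch transition matrices and partials."""

    def __init__(self, tree: TimeTree, char: dict, model: MkModel):
        self.tree = tree
        self.model = model
        self.k = model.k
        self.char = char
        missing = [t for t in tree.taxa if t not in char]
        if missing:
            raise ValueError(f"character does not cover tips: {missing}")
        self.w, self.v = model.eig()
        self.nodes = list(tree.preorder())
        self.post = list(reversed(self.nodes))
        # transition matrix on the branch above each non-root node
        self.P: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.parent is not None:
                t = node.parent.age - node.age
                p = (self.v * np.exp(self.w * t)) @ self.v.T
                np.clip(p, 0.0, None, out=p)
                p /= p.sum(axis=1, keepdims=True)
                self.P[node.id] = p

    def down_pass(self) -> tuple[dict[int, np.ndarray], float]:
        """Post-order conditional likelihoods; returns (partials, log-scale)."""
        down: dict[int, np.ndarray] = {}
        log_scale = 0.0
        for node in self.post:
            if node.is_leaf:
                vec = _tip_partial(self.char[node.label], self.k)
            else:
                vec = np.ones(self.k)
                for c in node.children:
                    vec = vec * (self.P[c.id] @ down[c.id])
                s = vec.max()
                if s <= 0:
                    raise FloatingPointError("zero likelihood at a node")
                vec = vec / s
                log_scale += math.log(s)
            down[node.id] = vec
        return down, log_scale

    def log_likelihood(self) -> float:
        down, log_scale = self.down_pass()
        root_like = float(np.mean(down[self.tree.root.id]))  # uniform prior
        return math.log(root_like) + log_scale

    def marginals(self) -> dict[int, np.ndarray]:
        """Marginal state probabilities at every node (inside-outside)."""
        down, _ = self.down_pass()
        prior = np.full(self.k, 1.0 / self.k)
        up: dict[int, np.ndarray] = {self.tree.root.id: prior.copy()}
        marg: dict[int, np.ndarray] = {}
        for node in self.nodes:  # preorder guarantees parent first
            if node.parent is not None:
                parent = node.parent
                # message from parent excluding this child's subtree
                msg = up[parent.id].copy()
                for sib in parent.children:
                    if sib is node:
                        continue
                    msg = msg * (self.P[sib.id] @ down[sib.id])
                vec = self.P[node.id].T @ msg
                s = vec.max()
                up[node.id] = vec / s if s > 0 else vec
            m = up[node.id] * down[node.id]
            total = m.sum()
            if total <= 0:
                raise FloatingPointError("zero marginal at a node")
            marg[node.id] = m / total
        return marg


def tree_log_likelihood(tree: TimeTree, char: dict, model: MkModel) -> float:
    """Log-likelihood of one character by Felsenstein pruning with a
    uniform root prior.  Missing tips contribute all-ones partials (a tree
    of entirely missing tips therefore has log-likelihood 0)."""
    return _Pruning(tree, char, model).log_likelihood()


def _check_variable(char: dict) -> None:
    observed = {s for s in char.values() if s is not None}
    if len(observed) <= 1:
        raise InvariantCharacterError(
            "character has <= 1 observed state; rate not identifiable"
        )


def fit_rate(
    tree: TimeTree,
    char: dict,
    model: MkModel,
    bracket: tuple[float, float] = (1e-6, 1e3),
    xatol: float = 1e-8,
) -> tuple[float, float]:
    """Maximum-likelihood rate by bounded 1-D optimization on log(rate).

    Returns (rate_mle, log_likelihood).  Raises
    :class:`InvariantCharacterError` for characters with no variation.
    """
    _check_variable(char)
    lo, hi = math.log(bracket[0]), math.log(bracket[1])

    def nll(log_r: float) -> float:
        m = replace(model, rate=math.exp(log_r))
        return -tree_log_likelihood(tree, char, m)

    res = minimize_scalar(
        nll, bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    rate = math.exp(res.x)
    return rate, -res.fun


@dataclass
class MarginalReconstruction:
    """Per-node state probability vectors for one character, plus the rate
    (point estimate or posterior mean) and log-likelihood at that rate."""

    node_probs: dict[int, np.ndarray]  # node id -> length-k vector
    rate: float
    log_likelihood: float
    k: int
    ordered: bool
    mode: str = "ML"
    rate_samples: Optional[np.ndarray] = None

    def to_frame(self, tree: TimeTree, character: str = "0") -> pd.DataFrame:
        """Node probability table (node id, character, state, probability)."""
        rows = []
        labels = {n.id: n.label for n in tree.preorder()}
        for nid, probs in self.node_probs.items():
            for state, p in enumerate(probs):
                rows.append({
                    "node_id": nid,
                    "label": labels.get(nid),
                    "character": character,
                    "state": state,
                    "probability": float(p),
                })
        return pd.DataFrame(rows)


def marginal_asr(
    tree: TimeTree,
    char: dict,
    model: MkModel,
    mode: str = "ML",
    n_samples: int = 3500,
    seed: Optional[int] = None,
    rate_max: float = 1e3,
) -> MarginalReconstruction:
    """Marginal ancestral reconstruction of one character.

    mode="ML": node marginals at the maximum-likelihood rate.
    mode="mcmc": the rate is sampled by a log-scale random-walk Metropolis
    under a uniform prior on (0, rate_max] with an adaptive step targeting
    ~0.3 acceptance, and node marginals are averaged over ``n_samples``
    post-burn-in samples.
    """
    _check_variable(char)
    if mode == "ML":
        rate, loglik = fit_rate(tree, char, model)
        m = replace(model, rate=rate)
        probs = _Pruning(tree, char, m).marginals()
        return MarginalReconstruction(
            probs, rate, loglik, model.k, model.ordered, "ML"
        )
    if mode != "mcmc":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    rate0, _ = fit_rate(tree, char, model)
    log_r = math.log(rate0)
    cur_ll = tree_log_likelihood(tree, char, replace(model, rate=rate0))
    step = 0.5
    n_burn = max(200, n_samples // 10)
    accepted = 0
    acc_probs: Optional[dict[int, np.ndarray]] = None
    samples = np.empty(n_samples)
    for it in range(n_burn + n_samples):
        prop = log_r + step * rng.standard_normal()
        r_new = math.exp(prop)
        if r_new <= rate_max:
            new_ll = tree_log_likelihood(tree, char, replace(model, rate=r_new))
            # uniform prior on the rate itself => Jacobian term r_new / r_old
            log_alpha = new_ll - cur_ll + (prop - log_r)
            if math.log(rng.random()) < log_alpha:
                log_r, cur_ll = prop, new_ll
                accepted += 1
        if it < n_burn:
            if (it + 1) % 50 == 0:  # adapt toward 0.3 acceptance
                acc = accepted / (it + 1)
                step *= math.exp(0.5 * (acc - 0.3))
            continue
        i = it - n_burn
        samples[i] = math.exp(log_r)
        probs = _Pruning(
            tree, char, replace(model, rate=samples[i])
        ).marginals()
        if acc_probs is None:
            acc_probs = {nid: v.copy() for nid, v in probs.items()}
        else:
            for nid, v in probs.items():
                acc_probs[nid] += v
    assert acc_probs is not None
    for nid in acc_probs:
        acc_probs[nid] /= n_samples
    mean_rate = float(samples.mean())
    loglik = tree_log_likelihood(tree, char, replace(model, rate=mean_rate))
    return MarginalReconstruction(
        acc_probs, mean_rate, loglik, model.k, model.ordered, "mcmc",
        rate_samples=samples,
    )


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------


class MkAsrModel:
    """Mk ancestral-state-reconstruction model for one character on a
    :class:`TimeTree`.

    Parameters
    ----------
    tree : time tree.
    char : taxon -> state (int) or None for '?'.
    k : number of states (default: 1 + max observed state).
    ordered : restrict transitions to adjacent states.
    """

    def __init__(self, tree: TimeTree, char: dict, k: Optional[int] = None,
                 ordered: bool = False):
        self.tree = tree
        self.char = dict(char)
        observed = [s for s in self.char.values() if s is not None]
        if k is None:
            if not observed:
                raise ValueError("cannot infer k from an all-missing character")
            k = max(observed) + 1
        self.skeleton = MkModel(k=max(k, 2), ordered=ordered)

    def loglike(self, rate: float) -> float:
        return tree_log_likelihood(
            self.tree, self.char, replace(self.skeleton, rate=rate)
        )

    def fit(self, mode: str = "ML", n_samples: int = 3500,
            seed: Optional[int] = None) -> "MkAsrResults":
        recon = marginal_asr(
            self.tree, self.char, self.skeleton,
            mode=mode, n_samples=n_samples, seed=seed,
        )
        return MkAsrResults(self, recon)


class MkAsrResults:
    """Fitted marginal reconstruction with rate estimate and node table."""

    def __init__(self, model: MkAsrModel, recon: MarginalReconstruction):
        self.model = model
        self.reconstruction = recon
        self.rate = recon.rate
        self.llf = recon.log_likelihood

    @property
    def node_probabilities(self) -> dict[int, np.ndarray]:
        return self.reconstruction.node_probs

    def to_frame(self, character: str = "0") -> pd.DataFrame:
        return self.reconstruction.to_frame(self.model.tree, character)

    def modal_state(self, node_id: int) -> tuple[int, float]:
        probs = self.reconstruction.node_probs[node_id]
        s = int(np.argmax(probs))
        return s, float(probs[s])

    def summary(self) -> str:
        r = self.reconstruction
        lines = [
            "Mk marginal ancestral state reconstruction",
            "=" * 46,
            f"states (k):        {r.k}",
            f"ordered:           {r.ordered}",
            f"mode:              {r.mode}",
            f"rate ({'posterior mean' if r.mode == 'mcmc' else 'MLE'}):"
            f"  {r.rate:.6g} per Ma",
            f"log-likelihood:    {r.log_likelihood:.4f}",
            f"tips:              {len(self.model.tree.tips())}",
            f"nodes:             {len(r.node_probs)}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Whole-matrix reconstruction & synapomorphies
# ---------------------------------------------------------------------------


def reconstruct_matrix(
    tree: TimeTree,
    matrix,
    characters: Optional[Sequence[int]] = None,
    mode: str = "ML",
    n_samples: int = 3500,
    seed: Optional[int] = None,
) -> dict[int, MarginalReconstruction]:
    """Reconstruct every (or selected) matrix character on the tree.
    Invariant characters are skipped.  Returns {column index: result}."""
    out: dict[int, MarginalReconstruction] = {}
    cols = range(matrix.n_char) if characters is None else characters
    for j in cols:
        char = matrix.character_dict(j)
        observed = [s for s in char.values() if s is not None]
        if len(set(observed)) <= 1:
            continue
        k = max(max(observed) + 1, 2)
        model = MkModel(k=k, ordered=bool(matrix.ordered[j]))
        sj = None if seed is None else seed + j
        out[j] = marginal_asr(
            tree, char, model, mode=mode, n_samples=n_samples, seed=sj
        )
    return out


def unambiguous_synapomorphies(
    recons: dict[int, MarginalReconstruction],
    tree: TimeTree,
    threshold: float = DEFAULT_SYNAPOMORPHY_THRESHOLD,
) -> pd.DataFrame:
    """Branches with a confident state change: parent and child top states
    both reach probability >= threshold and differ.  Reported in
    "character.state" notation (1-based character index)."""
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    rows = []
    for j, recon in recons.items():
        for parent, child in tree.branch_iter():
            pp = recon.node_probs[parent.id]
            cp = recon.node_probs[child.id]
            ps, cs = int(np.argmax(pp)), int(np.argmax(cp))
            if ps == cs:
                continue
            if pp[ps] >= threshold and cp[cs] >= threshold:
                rows.append({
                    "character": j,
                    "branch_child_id": child.id,
                    "branch_child_label": child.label,
                    "parent_state": ps,
                    "child_state": cs,
                    "parent_prob": float(pp[ps]),
                    "child_prob": float(cp[cs]),
                    "notation": f"{j + 1}.{cs}",
                })
    return pd.DataFrame(rows)
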