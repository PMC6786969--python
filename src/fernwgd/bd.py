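"""Linear birth-death model of gene-family evolution on a species tree.

Each gene duplicates at rate lambda and is lost at rate mu, independently,
along the branches of a species tree whose lengths share the rates' time
unit.  The module provides

* exact single- and multi-copy transition probabilities from the classical
  closed-form solution of the linear birth-death process,
* the gene-count likelihood by pruning over ancestral states 0..M, with
  optional conditioning on the family spanning the species-tree root
  (observed on both sides), which reduces bias in rate estimation,
* maximum-likelihood estimation of (lambda, mu) on the log-rate scale with a
  deterministic multi-start schedule,
* forward simulation of gene trees (one lineage entering at the root;
  optionally conditioned on every species retaining at least one gene), and
  the multi-rate null tree sets used to calibrate duplication-burst tests.

Transition matrices over states 0..M are assembled by iterated convolution of
the single-lineage offspring law; because every composition of an end state
m <= M uses parts <= M, the truncated convolution is exact for all entries,
and the row-sum deficit equals the probability of exceeding M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .trees import GeneTree, Node, SpeciesTree

__all__ = [
    "BDParams",
    "RootPrior",
    "GeneCountMatrix",
    "transition_prob",
    "transition_matrix",
    "root_spanning_probability",
    "family_loglik",
    "matrix_loglik",
    "estimate_rates",
    "RateEstimate",
    "simulate_gene_tree",
    "simulate_null",
    "sample_root_count",
]

DEFAULT_MULTIPLIERS = (0.5, 1.0, 3.0, 5.0)


@dataclass(frozen=True)
class BDParams:
    """Duplication (lambda) and loss (mu) rates per gene per time unit."""

    lam: float
    mu: float
    multiplier: float = 1.0

    def __post_init__(self):
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")

    @property
    def effective(self) -> tuple[float, float]:
        return self.lam * self.multiplier, self.mu * self.multiplier

    def scaled(self, multiplier: float) -> "BDParams":
        return BDParams(self.lam, self.mu, multiplier)


@dataclass(frozen=True)
class RootPrior:
    """Shifted geometric prior on the root gene count n >= 1.

    P(n) = p (1-p)^(n-1) with p = 1/mean, so the expectation is exactly
    ``mean``.
    """

    mean: float = 1.5

    def __post_init__(self):
        if self.mean <= 1.0:
            raise ValueError("prior mean must exceed 1")

    @property
    def p(self) -> float:
        return 1.0 / self.mean

    def pmf(self, n: int) -> float:
        if n < 1:
            return 0.0
        return self.p * (1.0 - self.p) ** (n - 1)

    def vector(self, m_max: int) -> np.ndarray:
        """pmf over states 0..m_max (state 0 has no prior mass)."""
        out = np.zeros(m_max + 1)
        n = np.arange(1, m_max + 1)
        out[1:] = self.p * (1.0 - self.p) ** (n - 1)
        return out

    def expectation(self) -> float:
        return 1.0 / self.p

    def pgf(self, x: float) -> float:
        """E[x^N] = p x / (1 - (1-p) x) for |x| <= 1."""
        return self.p * x / (1.0 - (1.0 - self.p) * x)


class GeneCountMatrix:
    """Gene-family counts: rows are families, columns are taxa."""

    def __init__(self, counts: pd.DataFrame, m_max: int = 100):
        if (counts.values < 0).any():
            raise ValueError("negative gene counts")
        if not np.issubdtype(counts.values.dtype, np.integer):
            counts = counts.astype(int)
        self.counts = counts
        self.m_max = m_max

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> list:
        return list(self.counts.index)

    def within_bound(self) -> "GeneCountMatrix":
        """Drop families with any count exceeding the truncation bound M."""
        keep = (self.counts <= self.m_max).all(axis=1)
        return GeneCountMatrix(self.counts.loc[keep], self.m_max)

    def n_excluded(self) -> int:
        return int((~(self.counts <= self.m_max).all(axis=1)).sum())

    def root_spanning(self, tree: SpeciesTree) -> pd.Series:
        """Per family: observed in >= 1 taxon on each side of the root."""
        left, right = (sorted(c.leaf_labels()) for c in tree.root.children)
        has_left = self.counts[left].sum(axis=1) > 0
        has_right = self.counts[right].sum(axis=1) > 0
        return has_left & has_right

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family")

    @classmethod
    def from_tsv(cls, path, m_max: int = 100) -> "GeneCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, m_max)


# ---------------------------------------------------------------------------
# Transition probabilities


def _alpha_beta(lam: float, mu: float, t: float) -> tuple[float, float]:
    """Extinction and birth parameters of the single-lineage offspring law.

    Starting from one gene, after time t the copy number is 0 with
    probability alpha and m >= 1 with probability (1-alpha)(1-beta)beta^(m-1).
    """
    if t == 0.0 or (lam == 0.0 and mu == 0.0):
        return 0.0, 0.0
    if math.isclose(lam, mu):
        a = lam * t / (1.0 + lam * t)
        return a, a
    e = math.exp((lam - mu) * t)
    denom = lam * e - mu
    return mu * (e - 1.0) / denom, lam * (e - 1.0) / denom


def _single_lineage_pmf(lam: float, mu: float, t: float, m_max: int) -> np.ndarray:
    alpha, beta = _alpha_beta(lam, mu, t)
    out = np.empty(m_max + 1)
    out[0] = alpha
    if m_max >= 1:
        out[1:] = (1.0 - alpha) * (1.0 - beta) * beta ** np.arange(m_max)
    return out


def transition_prob(n: int, m: int, t: float, params: BDParams) -> float:
    """P(count n -> count m after time t); exact, via n-fold convolution."""
    if n < 0 or m < 0 or t < 0:
        raise ValueError("n, m, t must be non-negative")
    if n == 0:
        return 1.0 if m == 0 else 0.0
    lam, mu = params.effective
    if t == 0.0 or (lam == 0.0 and mu == 0.0):
        return 1.0 if m == n else 0.0
    single = _single_lineage_pmf(lam, mu, t, m)
    row = single
    for _ in range(n - 1):
        row = np.convolve(row, single)[: m + 1]
    return float(row[m])


def transition_matrix(t: float, params: BDParams, m_max: int) -> np.ndarray:
    """(M+1) x (M+1) matrix T[n, m] = P(n -> m after time t)."""
    lam, mu = params.effective
    T = np.zeros((m_max + 1, m_max + 1))
    T[0, 0] = 1.0
    if m_max == 0:
        return T
    if t == 0.0 or (lam == 0.0 and mu == 0.0):
        np.fill_diagonal(T, 1.0)
        return T
    single = _single_lineage_pmf(lam, mu, t, m_max)
    T[1] = single
    for n in range(2, m_max + 1):
        T[n] = np.convolve(T[n - 1], single)[: m_max + 1]
    return T


# ---------------------------------------------------------------------------
# Likelihood


def _branch_pgf(lam: float, mu: float, t: float, z: float) -> float:
    """E[z^X] for the count X after time t starting from one gene."""
    alpha, beta = _alpha_beta(lam, mu, t)
    return alpha + (1.0 - alpha) * (1.0 - beta) * z / (1.0 - beta * z)


def root_spanning_probability(tree: SpeciesTree, params: BDParams,
                              prior: RootPrior) -> float:
    """P(a family is observed on both sides of the root) under the model.

    Computed in closed form: the probability that one root gene leaves no
    observed descendant within a clade follows the branch-wise probability
    generating function recursion; the prior is summed analytically through
    its own pgf (geometric series), so no truncation enters.
    """
    lam, mu = params.effective

    def none_observed(node: Node) -> float:
        if node.is_leaf:
            inner = 0.0
        else:
            inner = 1.0
            for child in node.children:
                inner *= none_observed(child)
        t = node.length or 0.0
        return _branch_pgf(lam, mu, t, inner)

    g_left, g_right = (none_observed(c) for c in tree.root.children)
    return 1.0 - prior.pgf(g_left) - prior.pgf(g_right) + prior.pgf(g_left * g_right)


def _branch_matrices(tree: SpeciesTree, params: BDParams, m_max: int) -> dict[Node, np.ndarray]:
    cache: dict[float, np.ndarray] = {}
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length or 0.0
        if t not in cache:
            cache[t] = transition_matrix(t, params, m_max)
        out[node] = cache[t]
    return out


def matrix_loglik(
    matrix: GeneCountMatrix,
    tree: SpeciesTree,
    params: BDParams,
    prior: RootPrior,
    condition: str = "root_spanning",
) -> float:
    """Summed log-likelihood of all families, vectorized over families.

    ``condition`` is ``"none"`` or ``"root_spanning"``; with the latter, every
    family must span the root (pre-filter with
    :meth:`GeneCountMatrix.root_spanning`) and each family's likelihood is
    divided by the spanning probability.
    """
    if condition not in ("none", "root_spanning"):
        raise ValueError(f"unknown condition {condition!r}")
    counts = matrix.counts
    m_max = matrix.m_max
    if (counts.values > m_max).any():
        raise ValueError("counts exceed the truncation bound M; filter first")
    if condition == "root_spanning" and not matrix.root_spanning(tree).all():
        raise ValueError("non-root-spanning families present under root_spanning conditioning")
    n_fam = len(counts)
    mats = _branch_matrices(tree, params, m_max)
    log_scale = np.zeros(n_fam)

    def up_message(child: Node) -> np.ndarray:
        """Message through the branch above ``child``: [f, s] is the
        probability of the observed counts below, given s genes at the
        branch top."""
        nonlocal log_scale
        if child.is_leaf:
            obs = counts[child.label].to_numpy()
            return mats[child][:, obs].T  # one-hot leaf: a column per family
        below = conditional(child)
        return below @ mats[child].T

    def conditional(node: Node) -> np.ndarray:
        nonlocal log_scale
        msg = up_message(node.children[0])
        for child in node.children[1:]:
            msg = msg * up_message(child)
        peak = msg.max(axis=1)
        peak = np.where(peak > 0, peak, 1.0)
        log_scale += np.log(peak)
        return msg / peak[:, None]

    root_msg = conditional(tree.root)
    per_family = root_msg @ prior.vector(m_max)
    with np.errstate(divide="ignore"):
        ll = np.log(per_family) + log_scale
    if np.any(np.isneginf(ll)):
        return -math.inf
    total = float(ll.sum())
    if condition == "root_spanning":
        total -= n_fam * math.log(root_spanning_probability(tree, params, prior))
    return total


def family_loglik(
    counts: Mapping[str, int],
    tree: SpeciesTree,
    params: BDParams,
    prior: RootPrior,
    condition: str = "none",
    m_max: int = 100,
) -> float:
    """Log-likelihood of a single family's taxon counts."""
    df = pd.DataFrame([dict(counts)])
    return matrix_loglik(GeneCountMatrix(df, m_max), tree, params, prior, condition)


# ---------------------------------------------------------------------------
# Rate estimation


@dataclass(frozen=True)
class RateEstimate:
    params: BDParams
    se_lam: float
    se_mu: float
    loglik: float
    converged: bool
    n_families: int
    message: str = ""


_MULTISTART = ((0.002, 0.002), (0.008, 0.008), (0.002, 0.012), (0.012, 0.002))


def estimate_rates(
    matrix: GeneCountMatrix,
    tree: SpeciesTree,
    prior: RootPrior = RootPrior(1.5),
    condition: str = "root_spanning",
    min_families_warn: int = 50,
) -> RateEstimate:
    """Maximum-likelihood (lambda, mu) from a gene-count matrix.

    Families exceeding the bound M are dropped; with root-spanning
    conditioning the non-spanning families are dropped too and the likelihood
    of each remaining family is divided by the spanning probability.
    Optimization runs on the log-rate scale from a fixed four-point start
    schedule (deterministic), first on a reduced state bound for speed, then
    polished at the full bound; standard errors come from the numerical
    curvature at the optimum.
    """
    work = matrix.within_bound()
    if condition == "root_spanning":
        work = GeneCountMatrix(work.counts.loc[work.root_spanning(tree)], work.m_max)
    n_fam = len(work.counts)
    if n_fam == 0:
        raise ValueError("no usable families")
    if n_fam < min_families_warn:
        import warnings

        warnings.warn(f"only {n_fam} families; rate estimates may be unstable")

    def neg_ll_at(theta: np.ndarray, m_max: int) -> float:
        lam, mu = np.exp(theta)
        m = GeneCountMatrix(work.counts, m_max)
        try:
            return -matrix_loglik(m, tree, BDParams(lam, mu), prior, condition)
        except (OverflowError, FloatingPointError):
            return math.inf

    # reduced bound: generous headroom above the largest observed count
    m_small = min(work.m_max, int(work.counts.values.max()) + 25)
    best = None
    for lam0, mu0 in _MULTISTART:
        res = optimize.minimize(
            neg_ll_at, np.log([lam0, mu0]), args=(m_small,),
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    # polish at the full bound
    res = optimize.minimize(
        neg_ll_at, best.x, args=(work.m_max,),
        method="Nelder-Mead",
        options={"fatol": 1e-8, "xatol": 1e-7, "maxiter": 200},
    )
    if res.fun > best.fun + 1.0:  # full-bound polish should never be far worse
        res = best
    theta = res.x
    lam, mu = np.exp(theta)
    converged = bool(res.success)
    # curvature-based standard errors via central differences on log-rates
    h = 1e-4
    H = np.zeros((2, 2))
    f0 = neg_ll_at(theta, work.m_max)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            fij = neg_ll_at(theta + ei + ej, work.m_max)
            fi = neg_ll_at(theta + ei, work.m_max)
            fj = neg_ll_at(theta + ej, work.m_max)
            H[i, j] = H[j, i] = (fij - fi - fj + f0) / (h * h)
    try:
        cov_log = np.linalg.inv(H)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        se_lam, se_mu = se_log * np.array([lam, mu])  # delta method
    except np.linalg.LinAlgError:
        se_lam = se_mu = math.nan
    estimate = RateEstimate(
        params=BDParams(float(lam), float(mu)),
        se_lam=float(se_lam),
        se_mu=float(se_mu),
        loglik=-float(f0),
        converged=converged,
        n_families=n_fam,
        message=str(res.message),
    )
    if not converged:
        raise RuntimeError(f"rate estimation did not converge: {estimate}")
    return estimate


# ---------------------------------------------------------------------------
# Simulation


def sample_root_count(prior: RootPrior, rng: np.random.Generator) -> int:
    """One draw from the shifted-geometric root prior (support n >= 1)."""
    return int(rng.geometric(prior.p))


class _GeneNamer:
    def __init__(self):
        self.counts: dict[str, int] = {}

    def next(self, taxon: str) -> str:
        self.counts[taxon] = self.counts.get(taxon, 0) + 1
        return f"{taxon}@{self.counts[taxon]}"


def _evolve_lineage(
    snode: Node,
    t_remaining: float,
    lam: float,
    mu: float,
    rng: np.random.Generator,
    wgd_node: Optional[Node],
    retention: float,
) -> Optional[Node]:
    """One gene lineage, currently ``t_remaining`` above species node
    ``snode``; returns the surviving gene subtree (lengths in time units) or
    None on extinction.  The returned node's ``length`` covers the span from
    this call's start point.
    """
    total = lam + mu
    elapsed = 0.0
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if wait >= t_remaining - elapsed:
            break
        elapsed += wait
        if rng.random() < (lam / total):
            # duplication: two daughter lineages over the remaining span
            left = _evolve_lineage(snode, t_remaining - elapsed, lam, mu, rng,
                                   wgd_node, retention)
            right = _evolve_lineage(snode, t_remaining - elapsed, lam, mu, rng,
                                    wgd_node, retention)
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left if right is None else right
                survivor.length = (survivor.length or 0.0) + elapsed
                return survivor
            dup = Node(length=elapsed)
            dup.add_child(left)
            dup.add_child(right)
            return dup
        return None  # loss
    # lineage reaches snode
    arrivals = [snode]
    if wgd_node is not None and snode is wgd_node:
        # whole-genome duplication at this node: the lineage doubles; the
        # extra copy is retained with the given probability (retention 0
        # consumes no randomness, so it reproduces the no-WGD stream)
        if retention > 0.0 and rng.random() < retention:
            arrivals = [snode, snode]
    subtrees = []
    for target in arrivals:
        if target.is_leaf:
            subtrees.append(Node(label=target.label, length=0.0))
        else:
            kids = []
            for child in target.children:
                sub = _evolve_lineage(child, child.length or 0.0, lam, mu, rng,
                                      wgd_node, retention)
                if sub is not None:
                    kids.append(sub)
            if not kids:
                subtrees.append(None)
            elif len(kids) == 1:
                subtrees.append(kids[0])
            else:
                spec = Node(length=0.0)
                for k in kids:
                    spec.add_child(k)
                subtrees.append(spec)
    subtrees = [s for s in subtrees if s is not None]
    if not subtrees:
        return None
    if len(subtrees) == 1:
        node = subtrees[0]
        node.length = (node.length or 0.0) + t_remaining
        return node
    wgd_vertex = Node(length=t_remaining)
    for s in subtrees:
        wgd_vertex.add_child(s)
    return wgd_vertex


def simulate_gene_tree(
    tree: SpeciesTree,
    params: BDParams,
    require_all_taxa: bool = True,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    wgd_node: Optional[Node] = None,
    retention: float = 0.0,
    max_rejections: int = 1_000_000,
) -> GeneTree:
    """Simulate one gene tree inside the species tree.

    A single gene lineage enters at the species-tree root; along each branch
    it duplicates at rate lambda and dies at rate mu; every lineage surviving
    to a speciation node enters both daughters.  With ``require_all_taxa``,
    trees missing a species are rejected and redrawn (rejection count in
    ``tree.n_rejections``).  An optional whole-genome duplication at
    ``wgd_node`` doubles each lineage reaching that node, the extra copy
    retained with probability ``retention``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lam, mu = params.effective
    taxa = tree.taxa
    rejections = 0
    while True:
        root = _evolve_lineage(tree.root, 0.0, lam, mu, rng, wgd_node, retention)
        if root is not None:
            namer = _GeneNamer()
            for leaf in root.leaves():
                leaf.label = namer.next(leaf.label)
            gt = GeneTree(root)
            if not require_all_taxa or gt.taxa == taxa:
                gt.n_rejections = rejections
                return gt
        rejections += 1
        if rejections >= max_rejections:
            raise RuntimeError(
                f"acceptance probability too low: {rejections} rejections "
                f"(rates {lam}, {mu})")


def simulate_null(
    tree: SpeciesTree,
    base: BDParams,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    n_per_condition: int = 1000,
    seed: Optional[int] = None,
) -> dict[str, list[GeneTree]]:
    """Null gene-tree sets at each rate multiplier (no WGD).

    Per-condition seeds are spawned deterministically from the master seed,
    so conditions are reproducible in isolation.
    """
    if any(m <= 0 for m in multipliers):
        raise ValueError("multipliers must be positive")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(multipliers))
    out: dict[str, list[GeneTree]] = {}
    for mult, child_seq in zip(multipliers, children):
        rng = np.random.default_rng(child_seq)
        params = base.scaled(mult)
        out[f"{mult:g}x"] = [
            simulate_gene_tree(tree, params, require_all_taxa=True, rng=rng)
            for _ in range(n_per_condition)
        ]
    return out


def write_null_sets(nulls: Mapping[str, list[GeneTree]], outdir,
                    base: BDParams, seed: Optional[int]) -> None:
    """Write one Newick file per null condition plus a JSON manifest
    (multipliers, seeds, per-condition rejection counts)."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"lambda": base.lam, "mu": base.mu, "seed": seed,
                "conditions": {}}
    for cond, trees in nulls.items():
        path = outdir / f"null_{cond}.nwk"
        with open(path, "w") as fh:
            for t in trees:
                fh.write(t.to_newick() + "\n")
        manifest["conditions"][cond] = {
            "file": path.name,
            "n_trees": len(trees),
            "total_rejections": sum(getattr(t, "n_rejections", 0)
                                    for t in trees),
        }
    (outdir / "null_manifest.json").write_text(json.dumps(manifest, indent=2))
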