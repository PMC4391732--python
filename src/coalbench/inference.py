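"""Tree estimation from alignments.

Three estimators live here:

* :func:`estimate_gene_tree_ml` -- clock-constrained maximum-likelihood
  gene trees (distance-based start, nearest-neighbor-interchange hill
  climbing with node-height optimization);
* :func:`run_concat_mcmc` -- a lightweight Metropolis-Hastings sampler for
  Bayesian inference on (concatenated) matrices under HKY+Gamma with a
  strict clock, stopping on the average standard deviation of split
  frequencies (ASDSF) across independent runs;
* :func:`consensus_allcompat` -- majority-rule consensus with all
  compatible splits added, the summary the benchmark scores.

The sampler is deliberately minimal: eight-taxon clock-tree space is small,
so Metropolis-coupled heating and the other conveniences of production
Bayesian phylogenetics packages are unnecessary.  The proposal mix is NNI
on the clock topology, node-height slides, a root-height multiplier, a
Dirichlet proposal on base frequencies, and multipliers on kappa and the
gamma shape.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform

from coalbench import _clocktree
from coalbench.likelihood import PruningEngine, discrete_gamma_rates
from coalbench.seqsim import Alignment, SubstitutionModel

__all__ = [
    "estimate_gene_tree_ml",
    "McmcConfig",
    "TreeSample",
    "Draw",
    "run_concat_mcmc",
    "consensus_allcompat",
    "average_stddev_split_freqs",
]


# ---------------------------------------------------------------------------
# clock-tree height machinery
# ---------------------------------------------------------------------------

def _preorder_internals(children, root):
    order = _clocktree.bottom_up_order(children, root)[::-1]  # preorder
    return [n for n in order if children[n, 0] >= 0 and n != root]


def _heights_from_params(x, children, root, pre_int, parent):
    heights = np.zeros(children.shape[0])
    heights[root] = math.exp(min(x[0], 50.0))  # clamp against line-search overshoot
    for i, node in enumerate(pre_int):
        f = 1.0 / (1.0 + math.exp(-min(max(x[i + 1], -50.0), 50.0)))
        heights[node] = f * heights[parent[node]]
    return heights

def _params_from_heights(heights, root, pre_int, parent):
    x = [math.log(max(heights[root], 1e-9))]
    for node in pre_int:
        f = heights[node] / heights[parent[node]] if heights[parent[node]] > 0 else 0.5
        f = min(max(f, 1e-6), 1 - 1e-6)
        x.append(math.log(f / (1 - f)))
    return np.array(x)


def _optimize_heights(engine, children, root, heights, pi, kappa, rates, maxfun):
    """Maximize the clock likelihood over node heights; returns (heights, lnL).

    Heights are parameterized as a log root height plus a logit fraction of
    the parent height per internal node, which enforces validity (every
    node strictly below its parent, tips at zero) by construction.
    """
    parent = _clocktree.parent_array(children)
    pre_int = _preorder_internals(children, root)
    x0 = _params_from_heights(heights, root, pre_int, parent)

    def negll(x):
        h = _heights_from_params(x, children, root, pre_int, parent)
        el = _clocktree.edge_lengths_from_heights(children, h, root)
        ll = engine.loglik(children, root, el, pi, kappa, rates)
        return -ll if math.isfinite(ll) else 1e300

    res = minimize(negll, x0, method="L-BFGS-B", options={"maxfun": maxfun})
    best = _heights_from_params(res.x, children, root, pre_int, parent)
    return best, -float(res.fun)


def _nni_candidates(children, root):
    """All rooted NNI rearrangements: (node c, index of child of c to swap
    with c's sibling)."""
    parent = _clocktree.parent_array(children)
    out = []
    for c in range(children.shape[0]):
        if children[c, 0] < 0 or c == root:
            continue
        for a_idx in (0, 1):
            out.append((c, a_idx, parent[c]))
    return out


def _apply_nni(children, c, a_idx, p):
    """Swap child ``a_idx`` of internal node ``c`` with ``c``'s sibling."""
    new = children.copy()
    s_idx = 0 if new[p, 1] == c else 1
    if new[p, s_idx] == c:  # c occupies both? impossible for binary trees
        raise AssertionError
    s = new[p, s_idx]
    a = new[c, a_idx]
    new[p, s_idx] = a
    new[c, a_idx] = s
    return new


def estimate_gene_tree_ml(
    alignment: Alignment,
    model: SubstitutionModel,
    clock: bool = True,
    n_rate_categories: int = 4,
    coarse_maxfun: int = 60,
    full_maxfun: int = 250,
) -> dendropy.Tree:
    """Clock-constrained ML gene tree for one alignment.

    Starts from the UPGMA tree on Jukes-Cantor-corrected distances and hill
    climbs over rooted NNI rearrangements, optimizing internal node heights
    (substitutions/site) at each step.  Deterministic: candidates are
    scanned in a fixed order and only strict improvements are accepted.
    Constant (signal-free) alignments return the tie-break resolution of
    the distance clustering, flagged via the ``low_signal`` attribute.
    """
    if not clock:
        raise NotImplementedError("only clock-constrained estimation is supported")
    n = len(alignment.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    engine = PruningEngine(alignment)
    labels = engine.labels
    rates = discrete_gamma_rates(model.gamma_shape, n_rate_categories)
    pi, kappa = model.freqs, model.kappa

    codes = alignment.codes[np.argsort(alignment.taxa)]
    diff = (codes[:, None, :] != codes[None, :, :]).mean(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(diff < 0.7499, -0.75 * np.log(np.clip(1 - 4 * diff / 3, 1e-12, None)), 3.0)
    np.fill_diagonal(d, 0.0)
    low_signal = not np.any(diff > 0)

    z = linkage(squareform(d, checks=False), method="average")
    children, heights = _clocktree.from_linkage(z, n)
    root = 2 * n - 2
    heights = np.maximum(heights, 1e-8)
    heights, lnl = _optimize_heights(engine, children, root, heights, pi, kappa, rates, full_maxfun)

    for _ in range(20):
        best = (lnl, None)
        for c, a_idx, p in _nni_candidates(children, root):
            cand = _apply_nni(children, c, a_idx, p)
            ch = heights.copy()
            floor = max(ch[int(cand[c, 0])], ch[int(cand[c, 1])])
            if ch[c] <= floor:
                ch[c] = 0.5 * (floor + ch[p])
            hh, ll = _optimize_heights(engine, cand, root, ch, pi, kappa, rates, coarse_maxfun)
            if ll > best[0] + 1e-6:
                best = (ll, (cand, hh))
        if best[1] is None:
            break
        children = best[1][0]
        heights, lnl = _optimize_heights(
            engine, children, root, best[1][1], pi, kappa, rates, full_maxfun
        )

    tree = _clocktree.to_dendropy(children, root, labels, heights=heights)
    tree.log_likelihood = lnl
    tree.low_signal = low_signal
    return tree


# ---------------------------------------------------------------------------
# Bayesian MCMC on concatenated matrices
# ---------------------------------------------------------------------------

_DEFAULT_WEIGHTS = {
    "nni": 3.0,
    "node_slide": 3.0,
    "root_scale": 1.0,
    "freqs": 1.0,
    "kappa": 1.0,
    "alpha": 1.0,
}


@dataclass
class McmcConfig:
    """Settings for the concatenated-matrix sampler.

    Defaults follow the benchmark protocol where one is stated (two runs,
    ASDSF stopping threshold 0.01, 25% burn-in, sampling stride 100) and
    common Bayesian-phylogenetics conventions where it is not.
    """

    n_runs: int = 2
    asdsf_threshold: float = 0.01
    burnin_fraction: float = 0.25
    thin: int = 100
    min_generations: int = 20_000
    max_generations: int = 1_000_000
    diagnostic_interval: int = 1_000
    n_rate_categories: int = 4
    proposal_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    height_prior_mean: float | None = None  # None: set from the starting tree
    kappa_log_sigma: float = 2.0
    alpha_log_sigma: float = 2.0
    dirichlet_alpha: float = 1.0
    freq_proposal_conc: float = 300.0
    scale_lambda: float = 0.6

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2 for split-frequency diagnostics")
        if not 0 < self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in (0, 1)")
        if not self.asdsf_threshold > 0:
            raise ValueError("asdsf_threshold must be > 0")
        if self.min_generations > self.max_generations:
            raise ValueError("min_generations must be <= max_generations")


@dataclass(frozen=True)
class Draw:
    """One thinned posterior draw (topology with heights plus parameters)."""

    newick: str
    clusters: frozenset
    splits: frozenset
    generation: int
    lnl: float
    kappa: float
    alpha: float
    pi: tuple
    height: float


@dataclass
class TreeSample:
    """Pooled post-burn-in posterior sample from all runs."""

    draws: list
    split_counts: Counter
    n_runs: int
    generation_stride: int
    labels: list
    converged: bool
    n_generations: int
    asdsf: float
    run_draws: list  # per-run post-burn-in draws (diagnostics, ASDSF recounts)

    def recount_split_counts(self) -> Counter:
        counts = Counter()
        for d in self.draws:
            counts.update(d.splits)
        return counts


def _split_freqs(draws) -> dict:
    counts = Counter()
    for d in draws:
        counts.update(d.splits)
    n = max(len(draws), 1)
    return {s: c / n for s, c in counts.items()}


def average_stddev_split_freqs(run_draws, min_freq: float = 0.1) -> float:
    """ASDSF across runs, over splits reaching ``min_freq`` in any run.

    Matches the usual convention: for each qualifying split, take the
    sample standard deviation of its frequency across runs, then average.
    Returns 0.0 when no split qualifies.
    """
    freqs = [_split_freqs(d) for d in run_draws]
    splits = {s for f in freqs for s, v in f.items() if v >= min_freq}
    if not splits:
        return 0.0
    sds = [np.std([f.get(s, 0.0) for f in freqs], ddof=1) for s in splits]
    return float(np.mean(sds))


class _Chain:
    def __init__(self, engine, cfg, rng, start_children, start_heights, pi0, run_index):
        self.engine = engine
        self.cfg = cfg
        self.rng = rng
        self.n = engine.n_tips
        self.root = 2 * self.n - 2
        self.children = start_children.copy()
        self.heights = start_heights.copy()
        self.parent = _clocktree.parent_array(self.children)
        self.kappa = 4.0
        self.alpha = 1.0
        self.pi = pi0.copy()
        self.rates = discrete_gamma_rates(self.alpha, cfg.n_rate_categories)
        self.height_prior_mean = cfg.height_prior_mean or max(start_heights[self.root], 1e-3)
        if run_index > 0:  # overdispersed start: random NNI shuffle
            for _ in range(4 * self.n):
                self._random_nni()
        self.lnl = self._loglik()
        self.generation = 0
        self.draws = []
        self.internals = [
            i for i in range(2 * self.n - 1) if self.children[i, 0] >= 0 and i != self.root
        ]
        moves, weights = zip(*cfg.proposal_weights.items())
        self.moves = moves
        self.cum_weights = np.cumsum(weights) / np.sum(weights)

    # -- model pieces ------------------------------------------------------
    def _loglik(self):
        el = _clocktree.edge_lengths_from_heights(self.children, self.heights, self.root)
        return self.engine.loglik(self.children, self.root, el, self.pi, self.kappa, self.rates)

    def _log_prior(self, heights=None, kappa=None, alpha=None):
        h = (heights if heights is not None else self.heights)[self.root]
        k = kappa if kappa is not None else self.kappa
        a = alpha if alpha is not None else self.alpha
        cfg = self.cfg
        lp = -h / self.height_prior_mean  # Exponential prior on tree height
        lp += -math.log(k) - (math.log(k) ** 2) / (2 * cfg.kappa_log_sigma**2)
        lp += -math.log(a) - (math.log(a) ** 2) / (2 * cfg.alpha_log_sigma**2)
        return lp  # flat Dirichlet(1,1,1,1) on pi, uniform on topologies

    # -- proposals ---------------------------------------------------------
    def _random_nni(self):
        internals = [
            i for i in range(2 * self.n - 1) if self.children[i, 0] >= 0 and i != self.root
        ]
        c = internals[int(self.rng.integers(len(internals)))]
        a_idx = int(self.rng.integers(2))
        p = self.parent[c]
        s_idx = 0 if self.children[p, 1] == c else 1
        s = self.children[p, s_idx]
        if self.heights[c] <= self.heights[s]:
            return
        self.children = _apply_nni(self.children, c, a_idx, p)
        self.parent = _clocktree.parent_array(self.children)

    def step(self):
        rng = self.rng
        move = self.moves[int(np.searchsorted(self.cum_weights, rng.random(), side="right"))]
        log_hastings = 0.0
        new_children, new_heights = None, None
        new_kappa, new_alpha, new_pi, new_rates = None, None, None, None

        if move == "nni":
            c = self.internals[int(rng.integers(len(self.internals)))]
            a_idx = int(rng.integers(2))
            p = self.parent[c]
            s_idx = 0 if self.children[p, 1] == c else 1
            s = self.children[p, s_idx]
            if self.heights[c] <= self.heights[s]:
                self.generation += 1
                return
            new_children = _apply_nni(self.children, c, a_idx, p)
        elif move == "node_slide":
            c = self.internals[int(rng.integers(len(self.internals)))]
            lo = max(self.heights[int(x)] for x in self.children[c])
            hi = self.heights[self.parent[c]]
            new_heights = self.heights.copy()
            new_heights[c] = lo + (hi - lo) * rng.random()
        elif move == "root_scale":
            m = math.exp(self.cfg.scale_lambda * (rng.random() - 0.5))
            new_heights = self.heights.copy()
            new_heights[self.root] *= m
            if new_heights[self.root] <= max(
                self.heights[int(x)] for x in self.children[self.root]
            ):
                self.generation += 1
                return
            log_hastings = math.log(m)
        elif move == "kappa":
            m = math.exp(self.cfg.scale_lambda * (rng.random() - 0.5))
            new_kappa = self.kappa * m
            log_hastings = math.log(m)
        elif move == "alpha":
            m = math.exp(self.cfg.scale_lambda * (rng.random() - 0.5))
            new_alpha = min(self.alpha * m, 300.0)
            new_rates = discrete_gamma_rates(new_alpha, self.cfg.n_rate_categories)
            log_hastings = math.log(m)
        elif move == "freqs":
            conc = self.cfg.freq_proposal_conc
            new_pi = rng.dirichlet(conc * self.pi)
            if np.any(new_pi < 1e-6):
                self.generation += 1
                return
            log_hastings = _dirichlet_logpdf(self.pi, conc * new_pi) - _dirichlet_logpdf(
                new_pi, conc * self.pi
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown move {move}")

        children = new_children if new_children is not None else self.children
        heights = new_heights if new_heights is not None else self.heights
        kappa = new_kappa if new_kappa is not None else self.kappa
        alpha = new_alpha if new_alpha is not None else self.alpha
        pi = new_pi if new_pi is not None else self.pi
        rates = new_rates if new_rates is not None else self.rates

        el = _clocktree.edge_lengths_from_heights(children, heights, self.root)
        lnl = self.engine.loglik(children, self.root, el, pi, kappa, rates)
        log_ratio = (
            lnl
            + self._log_prior(heights=heights, kappa=kappa, alpha=alpha)
            - self.lnl
            - self._log_prior()
            + log_hastings
        )
        if math.log(rng.random() + 1e-300) < log_ratio:
            self.children, self.heights = children, heights
            self.kappa, self.alpha, self.pi, self.rates = kappa, alpha, pi, rates
            self.lnl = lnl
            if new_children is not None:
                self.parent = _clocktree.parent_array(self.children)
        self.generation += 1

    def advance(self, n_gens, thin, labels):
        for _ in range(n_gens):
            self.step()
            if self.generation % thin == 0:
                self.draws.append(
                    Draw(
                        newick=_clocktree.newick(self.children, self.root, labels, self.heights),
                        clusters=_clocktree.clusters_bitmasks(self.children, self.root),
                        splits=_clocktree.splits_bitmasks(self.children, self.root, self.n),
                        generation=self.generation,
                        lnl=self.lnl,
                        kappa=self.kappa,
                        alpha=self.alpha,
                        pi=tuple(self.pi),
                        height=float(self.heights[self.root]),
                    )
                )

    def post_burnin(self, frac):
        cut = int(math.floor(frac * len(self.draws)))
        return self.draws[cut:]


def _dirichlet_logpdf(x, alpha):
    from scipy.special import gammaln

    return float(
        gammaln(np.sum(alpha)) - np.sum(gammaln(alpha)) + np.sum((alpha - 1) * np.log(x))
    )


def run_concat_mcmc(
    matrix: Alignment,
    cfg: McmcConfig,
    rng: np.random.Generator | int,
) -> TreeSample:
    """Bayesian MCMC under clock HKY+Gamma on a (concatenated) alignment.

    Runs ``cfg.n_runs`` independent chains, checks the ASDSF every
    ``cfg.diagnostic_interval`` generations, and stops once it falls below
    ``cfg.asdsf_threshold`` (after ``cfg.min_generations``).  If
    ``cfg.max_generations`` is reached first the sample is returned with
    ``converged=False`` -- never silently.  Draws are recorded every
    ``cfg.thin`` generations; the pooled sample discards the first
    ``cfg.burnin_fraction`` of each run.
    """
    if matrix.length == 0 or len(matrix.taxa) < 3:
        raise ValueError("concatenated matrix must be nonempty with >= 3 taxa")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    engine = PruningEngine(matrix)
    labels = engine.labels
    n = engine.n_tips

    # distance-based starting tree shared by all runs (later runs shuffle it)
    codes = matrix.codes[np.argsort(matrix.taxa)]
    diff = (codes[:, None, :] != codes[None, :, :]).mean(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(diff < 0.7499, -0.75 * np.log(np.clip(1 - 4 * diff / 3, 1e-12, None)), 3.0)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    children0, heights0 = _clocktree.from_linkage(z, n)
    heights0 = np.maximum(heights0, 1e-6)
    counts = np.bincount(matrix.codes.ravel(), minlength=4).astype(float)
    pi0 = np.clip(counts / counts.sum(), 1e-3, None)
    pi0 = pi0 / pi0.sum()

    chains = [
        _Chain(engine, cfg, np.random.default_rng(rng.integers(2**63)), children0, heights0, pi0, i)
        for i in range(cfg.n_runs)
    ]

    gen, asdsf, converged = 0, math.inf, False
    while True:
        for ch in chains:
            ch.advance(cfg.diagnostic_interval, cfg.thin, labels)
        gen += cfg.diagnostic_interval
        asdsf = average_stddev_split_freqs([ch.post_burnin(cfg.burnin_fraction) for ch in chains])
        if gen >= cfg.min_generations and asdsf < cfg.asdsf_threshold:
            converged = True
            break
        if gen >= cfg.max_generations:
            break

    run_draws = [ch.post_burnin(cfg.burnin_fraction) for ch in chains]
    pooled = [d for rd in run_draws for d in rd]
    split_counts = Counter()
    for d in pooled:
        split_counts.update(d.splits)
    return TreeSample(
        draws=pooled,
        split_counts=split_counts,
        n_runs=cfg.n_runs,
        generation_stride=cfg.thin,
        labels=labels,
        converged=converged,
        n_generations=gen,
        asdsf=asdsf,
        run_draws=run_draws,
    )


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _smaller_side(mask: int, labels) -> tuple:
    n = len(labels)
    full = (1 << n) - 1
    comp = full & ~mask
    a, b = (mask, comp) if bin(mask).count("1") <= bin(comp).count("1") else (comp, mask)
    side_a = tuple(sorted(labels[i] for i in range(n) if a >> i & 1))
    if bin(a).count("1") == bin(b).count("1"):
        side_b = tuple(sorted(labels[i] for i in range(n) if b >> i & 1))
        side_a = min(side_a, side_b)
    return side_a


def _compatible(a: int, b: int, full: int) -> bool:
    return (
        a & b == 0
        or a & b == a
        or a & b == b
        or (a | b) == full
    )


def consensus_allcompat(sample: TreeSample) -> dendropy.Tree:
    """Majority-rule consensus with all compatible splits added.

    Splits are accepted in decreasing frequency order (ties broken
    lexicographically on the sorted taxon set of the smaller side) whenever
    compatible with everything already accepted; every split with frequency
    above 0.5 is therefore always included.  Internal nodes of the returned
    tree carry their split frequency as ``support`` (and as the node label).
    """
    if not sample.draws:
        raise ValueError("empty tree sample")
    labels = sample.labels
    n = len(labels)
    full = (1 << n) - 1
    ndraws = len(sample.draws)
    items = sorted(
        sample.split_counts.items(),
        key=lambda kv: (-kv[1], len(_smaller_side(kv[0], labels)), _smaller_side(kv[0], labels)),
    )
    accepted = []
    for mask, count in items:
        if all(_compatible(mask, m, full) for m, _ in accepted):
            accepted.append((mask, count))

    # build a rooted representation: clusters are the split sides not
    # containing taxon 0 (masks are already canonicalized that way)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    node_for = {full: root}
    for mask, count in sorted(accepted, key=lambda kv: -bin(kv[0]).count("1")):
        host_mask = min(
            (m for m in node_for if m & mask == mask and m != mask),
            key=lambda m: bin(m).count("1"),
        )
        node = dendropy.Node()
        node.support = count / ndraws
        node.label = f"{node.support:.4f}"
        node_for[host_mask].add_child(node)
        node_for[mask] = node
    for i, lab in enumerate(labels):
        bit = 1 << i
        host_mask = min(
            (m for m in node_for if m & bit), key=lambda m: bin(m).count("1")
        )
        leaf = dendropy.Node()
        leaf.taxon = tns.require_taxon(label=lab)
        node_for[host_mask].add_child(leaf)
    return tree
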