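"""Seed-proximity gene scoring on the weighted interaction network.

Two complementary propagation schemes rank genes by closeness to a
disease-associated seed set:

* **direct-neighbor** (one-hop, "naive Bayes" in the network-propagation
  literature): a gene's score is the sum of edge weights connecting it to
  seed genes;
* **Gaussian smoothing** (diffusion): the unique minimizer of

  .. math::

     \\frac{1-\\alpha}{\\alpha} \\sum_i (f_i - y_i)^2
     + \\sum_{(i,j) \\in E} w'_{ij} (f_i - f_j)^2

  with seed labels :math:`y_i = 1` and symmetrically degree-normalized
  weights :math:`w'`, i.e. the solution of
  :math:`f = (1-\\alpha)(I - \\alpha S)^{-1} y` with
  :math:`S = D^{-1/2} W D^{-1/2}`.  Solved iteratively by the fixed-point
  update :math:`f \\leftarrow \\alpha S f + (1-\\alpha) y`, which converges
  because the spectral radius of :math:`\\alpha S` is below 1.

Direct scores capture only immediate interactions; diffusion lets seed
evidence flow through the whole component, so genes a few hops from many
seeds still score.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .models import GeneNetwork, GeneScore

logger = logging.getLogger(__name__)

__all__ = [
    "Normalization",
    "PropagationParams",
    "SelectionRule",
    "direct_neighbor_scores",
    "gaussian_smoothing_scores",
    "compute_gene_scores",
    "rank_candidate_genes",
    "NOT_IN_NETWORK",
]

NOT_IN_NETWORK = "NOT_IN_NETWORK"


class Normalization(str, enum.Enum):
    SYMMETRIC_DEGREE = "SYMMETRIC_DEGREE"
    NONE = "NONE"


@dataclass(frozen=True)
class PropagationParams:
    """Diffusion hyperparameters.

    ``alpha`` is the retention parameter: how much score keeps flowing
    through edges versus being pinned to the seed labels (higher = smoother,
    farther spread).  ``tol`` bounds the max-abs fixed-point residual.
    """

    alpha: float = 0.8
    tol: float = 1e-10
    max_iter: int = 10_000
    normalization: Normalization = Normalization.SYMMETRIC_DEGREE

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def _node_order(network: GeneNetwork) -> list[str]:
    return sorted(network.nodes)


def _weight_matrix(network: GeneNetwork, order: list[str]) -> sp.csr_matrix:
    index = {g: i for i, g in enumerate(order)}
    n = len(order)
    rows, cols, data = [], [], []
    for (a, b), w in network.edges.items():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def direct_neighbor_scores(network: GeneNetwork) -> dict[str, float]:
    """Sum of edge weights from each gene to the seed set.

    Seeds themselves are scored over the *other* seeds; a gene with no seed
    neighbor scores 0.
    """
    if not network.seeds:
        raise ValueError("seed set is empty")
    order = _node_order(network)
    W = _weight_matrix(network, order)
    y = np.array([1.0 if g in network.seeds else 0.0 for g in order])
    scores = W @ y
    # a seed's own label must not contribute to itself; W has no diagonal so
    # seed self-contribution is already zero
    return {g: float(s) for g, s in zip(order, scores)}


def gaussian_smoothing_scores(
    network: GeneNetwork, params: PropagationParams = PropagationParams()
) -> dict[str, float]:
    """Diffusion scores from the Gaussian-smoothing fixed point.

    Iterates ``f <- alpha * S f + (1 - alpha) * y`` to a max-abs residual of
    ``params.tol``.  Disconnected components are handled naturally by the
    linear system; an isolated node keeps ``(1 - alpha) * y_i``.
    Deterministic for fixed inputs.
    """
    if not network.seeds:
        raise ValueError("seed set is empty")
    order = _node_order(network)
    n = len(order)
    W = _weight_matrix(network, order)
    y = np.array([1.0 if g in network.seeds else 0.0 for g in order])

    if params.normalization is Normalization.SYMMETRIC_DEGREE:
        deg = np.asarray(W.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        D = sp.diags(inv_sqrt)
        S = D @ W @ D
    else:
        S = W

    alpha = params.alpha
    f = np.zeros(n)
    for _ in range(params.max_iter):
        f_next = alpha * (S @ f) + (1.0 - alpha) * y
        residual = float(np.max(np.abs(f_next - f))) if n else 0.0
        f = f_next
        if residual <= params.tol:
            break
    else:
        raise RuntimeError(
            f"diffusion did not converge within {params.max_iter} iterations "
            f"(last residual {residual:.3e})"
        )
    return {g: float(s) for g, s in zip(order, f)}


def _competition_ranks(items: list[tuple[str, float]]) -> dict[str, int]:
    """1-based competition ranks, descending score; ties share the best rank."""
    ranks: dict[str, int] = {}
    scores = [s for _, s in items]
    for gene, s in items:
        ranks[gene] = 1 + sum(1 for other in scores if other > s)
    return ranks


def compute_gene_scores(
    network: GeneNetwork, params: PropagationParams = PropagationParams()
) -> dict[str, GeneScore]:
    """Both propagation scores plus non-seed competition ranks per gene."""
    direct = direct_neighbor_scores(network)
    diffusion = gaussian_smoothing_scores(network, params)
    nonseed = sorted(g for g in network.nodes if g not in network.seeds)
    direct_ranks = _competition_ranks([(g, direct[g]) for g in nonseed])
    diff_ranks = _competition_ranks([(g, diffusion[g]) for g in nonseed])
    out: dict[str, GeneScore] = {}
    for g in sorted(network.nodes):
        seed = g in network.seeds
        out[g] = GeneScore(
            gene=g,
            direct=direct[g],
            diffusion=diffusion[g],
            direct_rank=None if seed else direct_ranks[g],
            diffusion_rank=None if seed else diff_ranks[g],
            is_seed=seed,
        )
    return out


@dataclass(frozen=True)
class SelectionRule:
    """Predicate deciding when a candidate gene counts as network-supported.

    Default: any direct seed contact (direct > 0) OR a diffusion rank within
    the top ``q`` fraction of non-seed genes.  ``q = 0`` disables the
    diffusion route entirely.
    """

    q: float = 0.10
    require_direct: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")


def rank_candidate_genes(
    scores: dict[str, GeneScore],
    candidate_genes: set[str],
    rule: SelectionRule = SelectionRule(),
) -> tuple[dict[str, GeneScore], dict[str, str]]:
    """Apply the network-support rule to candidate genes.

    Returns ``(selected, flags)``: the selected candidates' GeneScores, and
    a per-candidate flag map (SELECTED / NOT_SELECTED / NOT_IN_NETWORK).
    Candidates absent from the network are never selected.
    """
    n_nonseed = sum(1 for s in scores.values() if not s.is_seed)
    cutoff = rule.q * n_nonseed
    selected: dict[str, GeneScore] = {}
    flags: dict[str, str] = {}
    for gene in sorted(candidate_genes):
        score = scores.get(gene)
        if score is None:
            flags[gene] = NOT_IN_NETWORK
            continue
        by_direct = score.direct > 0
        by_diffusion = (
            score.diffusion_rank is not None and rule.q > 0 and score.diffusion_rank <= cutoff
        )
        if rule.require_direct:
            hit = by_direct
        else:
            hit = by_direct or by_diffusion
        if hit:
            selected[gene] = score
            flags[gene] = "SELECTED"
        else:
            flags[gene] = "NOT_SELECTED"
    return selected, flags
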