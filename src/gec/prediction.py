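"""Pathway-participation prediction and cancer-driver ranking.

Participation prediction asks, per pathway: can the genes known to
participate be told apart from nearby non-members using only their
(local or global) graphlet eigencentrality?  The protocol is repeated
k-fold cross-validation: in each fold ~20% of the pathway's in-network
genes are held out as positives, and the negatives are every network
gene that directly interacts with at least one retained (training)
pathway gene.

Local scoring asks "how central would this candidate be in the pathway
if it were to participate": for each test gene t the subgraph induced on
the m training genes plus t — an (m+1) x (m+1) adjacency — is built from
the full network, its graphlet eigencentrality computed, and t's own
entry recorded.  Interactions with nodes outside the pathway never enter
the matrix.  Global scoring simply reads the candidate's entry in the
full-network centrality vector.

Driver ranking is unsupervised: within each pathway, genes are ranked by
their local or global graphlet eigencentrality and the known driver
labels are used only for evaluation.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np

from .centrality import (
    DEFAULT_MAXITER,
    DEFAULT_TOL,
    CentralityVector,
    GraphletSupportError,
    PowerIterationError,
    graphlet_eigencentrality,
)
from .graphlets import graphlet_adjacency
from .network import Network
from .pathways import (
    PathwayCentralityResult,
    global_pathway_centrality,
    local_pathway_centrality,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSpec",
    "ScoredTestSet",
    "make_folds",
    "score_participation_local",
    "score_participation_global",
    "rank_cancer_candidates",
]


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold for one pathway.

    ``train_genes`` are the m retained pathway genes, ``held_out`` the
    positives of the test set, ``negatives`` the network genes adjacent
    to at least one training gene that are neither training nor
    held-out genes.
    """

    pathway: str
    iteration: int
    fold: int
    train_genes: frozenset[str]
    held_out: frozenset[str]
    negatives: frozenset[str]


@dataclass(frozen=True)
class ScoredTestSet:
    """Scores and labels over ``held_out | negatives`` for one fold."""

    fold: FoldSpec
    scores: Mapping[str, float]
    labels: Mapping[str, int]
    degenerate: bool = False

    @property
    def positive_fraction(self) -> float:
        labels = list(self.labels.values())
        return sum(labels) / len(labels) if labels else float("nan")


def make_folds(
    net: Network,
    genes: Iterable[str],
    iterations: int = 10,
    k: int = 5,
    seed: int = 0,
    pathway: str = "",
) -> list[FoldSpec]:
    """Seeded R x k-fold partitions of a pathway's in-network genes.

    Within each iteration the in-network genes are split into ``k``
    balanced folds (sizes differing by at most one); each fold in turn
    becomes the held-out positive set.  Fold membership is a pure
    function of (seed, iteration), so runs are reproducible.
    """
    present = sorted(x for x in set(genes) if x in net)
    if len(present) < k:
        raise ValueError(
            f"pathway {pathway or '<unnamed>'} has {len(present)} in-network "
            f"genes; at least {k} are required for {k}-fold CV"
        )
    folds: list[FoldSpec] = []
    arr = np.asarray(present, dtype=object)
    for it in range(1, iterations + 1):
        rng = np.random.default_rng([seed, it])
        perm = rng.permutation(len(arr))
        for f, chunk in enumerate(np.array_split(perm, k), start=1):
            held = frozenset(arr[chunk])
            train = frozenset(present) - held
            neigh: set[str] = set()
            for u in train:
                neigh |= net.neighbors(u)
            negatives = frozenset(neigh - train - held)
            folds.append(
                FoldSpec(
                    pathway=pathway, iteration=it, fold=f,
                    train_genes=train, held_out=held, negatives=negatives,
                )
            )
    return folds


def _test_genes(fold: FoldSpec) -> list[str]:
    return sorted(fold.held_out) + sorted(fold.negatives)


def _labels(fold: FoldSpec) -> dict[str, int]:
    out = {t: 1 for t in sorted(fold.held_out)}
    out.update({t: 0 for t in sorted(fold.negatives)})
    return out


def score_participation_local(
    net: Network,
    fold: FoldSpec,
    g: int,
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
    method: str = "auto",
) -> ScoredTestSet:
    """Score each test gene by its centrality in the candidate-augmented
    pathway subgraph.

    For every test gene t, the induced subgraph on train_genes | {t} is
    taken from the full network, its graphlet eigencentrality for ``g``
    computed, and t's own entry returned as its score.  Candidates with
    zero graphlet degree in their augmented subgraph score 0.  If the
    training subgraph itself contains no occurrence of ``g``, all scores
    are 0 and the result is flagged degenerate.

    ``method`` selects the execution path: ``"loop"`` scores candidates
    one by one, ``"batch"`` (G0 only) runs one vectorised power
    iteration over all candidates of the fold simultaneously — the same
    mathematics, evaluated column-wise.  ``"auto"`` picks ``"batch"``
    for G0 and ``"loop"`` otherwise.
    """
    if method == "auto":
        method = "batch" if g == 0 else "loop"
    if method == "batch":
        if g != 0:
            raise ValueError("batch scoring is implemented for G0 only")
        return _score_local_g0_batch(net, fold, tol, maxiter)
    return _score_local_loop(net, fold, g, tol, maxiter)


def _score_local_loop(
    net: Network, fold: FoldSpec, g: int, tol: float, maxiter: int
) -> ScoredTestSet:
    tests = _test_genes(fold)
    labels = _labels(fold)
    train = set(fold.train_genes)
    train_sub = net.subgraph(train)
    if graphlet_adjacency(train_sub, g).n_occurrences == 0:
        logger.warning(
            "pathway %s it%d fold%d: training subgraph has no G%d "
            "occurrence; all scores zero",
            fold.pathway, fold.iteration, fold.fold, g,
        )
        return ScoredTestSet(
            fold=fold, scores={t: 0.0 for t in tests}, labels=labels,
            degenerate=True,
        )
    scores: dict[str, float] = {}
    for t in tests:
        sub = net.subgraph(train | {t})
        try:
            vec = graphlet_eigencentrality(sub, g, tol=tol, maxiter=maxiter)
        except GraphletSupportError:  # pragma: no cover - train has occurrences
            scores[t] = 0.0
            continue
        scores[t] = vec[t]
    return ScoredTestSet(fold=fold, scores=scores, labels=labels)


def _score_local_g0_batch(
    net: Network, fold: FoldSpec, tol: float, maxiter: int
) -> ScoredTestSet:
    """Vectorised G0 local scoring: all candidates of a fold at once.

    Every candidate-augmented matrix shares the m x m training adjacency
    T and differs only in the candidate's incidence column, so the power
    iterations can run side by side as columns of an (m+1) x C state
    array.  Column c reproduces exactly the iteration the per-candidate
    route would run for candidate c.
    """
    train = sorted(fold.train_genes)
    tests = _test_genes(fold)
    labels = _labels(fold)
    m, c = len(train), len(tests)
    t_mat = np.zeros((m, m))
    for i, u in enumerate(train):
        nbrs = net.neighbors(u)
        for j in range(i + 1, m):
            if train[j] in nbrs:
                t_mat[i, j] = t_mat[j, i] = 1.0
    if c == 0:
        return ScoredTestSet(fold=fold, scores={}, labels=labels,
                             degenerate=t_mat.sum() == 0)
    if t_mat.sum() == 0:
        logger.warning(
            "pathway %s it%d fold%d: training subgraph has no edge; "
            "all scores zero", fold.pathway, fold.iteration, fold.fold,
        )
        return ScoredTestSet(
            fold=fold, scores={t: 0.0 for t in tests}, labels=labels,
            degenerate=True,
        )
    e_mat = np.zeros((m, c))
    for i, u in enumerate(train):
        nbrs = net.neighbors(u)
        for j, t in enumerate(tests):
            if t in nbrs:
                e_mat[i, j] = 1.0
    # per-candidate degrees in the augmented (m+1)-node subgraph
    d_train = t_mat.sum(axis=1)[:, None] + e_mat        # (m, c)
    d_cand = e_mat.sum(axis=0)                          # (c,)
    s_train = np.where(d_train > 0, 1.0 / np.sqrt(np.maximum(d_train, 1)), 0.0)
    s_cand = np.where(d_cand > 0, 1.0 / np.sqrt(np.maximum(d_cand, 1)), 0.0)
    support = np.vstack([d_train > 0, d_cand[None, :] > 0])  # (m+1, c)
    n_sup = support.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = support / np.sqrt(np.maximum(n_sup, 1))
    x_train, x_cand = x[:m], x[m]
    for it in range(1, maxiter + 1):
        z_train = x_train * s_train
        z_cand = x_cand * s_cand
        y_train = (t_mat @ z_train + e_mat * z_cand[None, :]) * s_train
        y_cand = (e_mat * z_train).sum(axis=0) * s_cand
        xn_train = 0.5 * (y_train + x_train)
        xn_cand = 0.5 * (y_cand + x_cand)
        res = np.sqrt(
            ((xn_train - x_train) ** 2).sum(axis=0)
            + (xn_cand - x_cand) ** 2
        )
        x_train, x_cand = xn_train, xn_cand
        if res.max() < tol:
            break
    else:
        raise PowerIterationError(maxiter, float(res.max()))
    norms = np.sqrt((x_train ** 2).sum(axis=0) + x_cand ** 2)
    vals = np.where(norms > 0, x_cand / np.maximum(norms, 1e-300), 0.0)
    scores = {t: max(float(v), 0.0) for t, v in zip(tests, vals)}
    return ScoredTestSet(fold=fold, scores=scores, labels=labels)


def score_participation_global(
    net: Network,
    fold: FoldSpec,
    g: int,
    cache: CentralityVector,
) -> ScoredTestSet:
    """Score each test gene by its entry in the full-network vector."""
    if cache.graphlet != g:
        raise ValueError(
            f"cache holds graphlet G{cache.graphlet}, requested G{g}"
        )
    tests = _test_genes(fold)
    return ScoredTestSet(
        fold=fold,
        scores={t: cache[t] for t in tests},
        labels=_labels(fold),
    )


def rank_cancer_candidates(
    net: Network,
    genes: Iterable[str],
    g: int,
    mode: str,
    cache: CentralityVector | None = None,
    pathway: str = "",
) -> PathwayCentralityResult:
    """Rank a pathway's genes by centrality (unsupervised).

    No cross-validation: the full pathway gene set is scored by local or
    global graphlet eigencentrality, and the caller pairs the ranking
    with a positive-label list (e.g. known cancer drivers in the
    pathway) for evaluation.
    """
    if mode == "local":
        return local_pathway_centrality(net, genes, g, pathway=pathway)
    if mode == "global":
        if cache is None:
            raise ValueError("global mode requires the cached full-network "
                             "centrality vector")
        return global_pathway_centrality(net, genes, g, cache, pathway=pathway)
    raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
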