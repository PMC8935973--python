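"""Full-sib family reconstruction from multilocus microsatellite genotypes.

Model: haplodiploidy with monogyny and monoandry — every worker in a colony
is the daughter of one diploid queen and one haploid father, so full sisters
share the father's single allele at every locus and draw one of the queen's
two alleles independently. Observed calls carry a mistyping rate e (an
observed allele is, with probability e, a frequency-weighted random allele
instead of the true one) and optionally allelic dropout.

The family likelihood marginalises the unknown parents: per locus,

    L(cluster) = sum_{a,b,c} p_a p_b p_c  prod_w  (M_w[a,c] + M_w[b,c]) / 2

where (a, b) is the queen's ordered genotype, c the father's allele, and
M_w[t1, t2] = P(worker w's observed genotype | true genotype {t1, t2}).
Independent loci are summed on the log scale. The null (all workers
unrelated) is the product of Hardy-Weinberg genotype probabilities under the
same error model.

Partitioning is a randomized-order agglomerative search: start from
singletons and repeatedly apply the merge with the largest positive gain in
total log-likelihood until no gain exceeds a threshold. Pairs of workers
that fail to share a single observed allele at more than ``max_incompatible``
loci are never considered for merging — full sisters always share the
paternal allele, so with e = 0.01 and 12 loci this prunes almost all
unrelated pairs at negligible risk to true families. Support for a cluster
is the fraction of independent restarts whose final partition contains
exactly that member set (a stated stand-in for a posterior inclusion
probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import ErrorModel

logger = logging.getLogger(__name__)

__all__ = [
    "SibshipPartition",
    "estimate_allele_freqs",
    "fullsib_loglik",
    "unrelated_loglik",
    "reconstruct_sibships",
    "filter_clusters",
]


@dataclass
class SibshipPartition:
    """Disjoint full-sib clusters with restart-consensus support."""

    clusters: list[tuple[str, ...]]
    support: list[float]
    total_loglik: float
    restart_logliks: list[float] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for cl in self.clusters:
            if seen & set(cl):
                raise ValueError("clusters are not disjoint")
            seen |= set(cl)
        if any(not 0.0 <= s <= 1.0 for s in self.support):
            raise ValueError("support must lie in [0, 1]")

    @property
    def workers(self) -> set[str]:
        return {w for cl in self.clusters for w in cl}

    def multi_clusters(self) -> list[tuple[str, ...]]:
        return [cl for cl in self.clusters if len(cl) >= 2]

    def singletons(self) -> list[str]:
        return [cl[0] for cl in self.clusters if len(cl) == 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (cl, s) in enumerate(zip(self.clusters, self.support)):
            for w in cl:
                rows.append((w, f"cl{i:04d}", s, len(cl)))
        return pd.DataFrame(rows, columns=["worker_id", "cluster_id", "cluster_support", "cluster_size"])


def estimate_allele_freqs(genotypes: pd.DataFrame) -> dict[str, pd.Series]:
    """Observed allele frequencies per locus from all non-missing calls."""
    freqs: dict[str, pd.Series] = {}
    for locus, sub in genotypes.groupby("locus", sort=True):
        alleles = pd.concat([sub["allele1_bp"], sub["allele2_bp"]]).dropna()
        if alleles.empty:
            continue
        counts = alleles.value_counts().sort_index()
        freqs[str(locus)] = counts / counts.sum()
    return freqs


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


class _Engine:
    """Precomputed per-worker observation matrices for fast cluster scoring."""

    def __init__(
        self,
        genotypes: pd.DataFrame,
        allele_freqs: dict[str, pd.Series],
        error: ErrorModel,
        freq_floor: float | None = None,
    ):
        if genotypes.empty:
            raise ValueError("empty genotype table")
        self.error = error
        self.workers: list[str] = list(pd.unique(genotypes["worker_id"]))
        self.windex = {w: i for i, w in enumerate(self.workers)}
        self.loci: list[str] = []
        self.freqs: list[np.ndarray] = []          # per locus, allele frequency vector
        self.obs: list[np.ndarray] = []            # per locus, (n_workers, 2) allele indices, -1 missing
        n_ind = genotypes["worker_id"].nunique()
        floor = freq_floor if freq_floor is not None else 1.0 / (2 * n_ind + 1)

        by_locus = dict(tuple(genotypes.groupby("locus", sort=True)))
        for locus in sorted(set(genotypes["locus"]) & set(allele_freqs)):
            f = allele_freqs[locus].astype(float)
            sub = by_locus[locus]
            observed = pd.concat([sub["allele1_bp"], sub["allele2_bp"]]).dropna().unique()
            unseen = [a for a in observed if a not in f.index]
            if unseen:
                logger.info(
                    "locus %s: %d observed allele(s) absent from frequency table; floor %.3g applied",
                    locus, len(unseen), floor,
                )
                f = pd.concat([f, pd.Series(floor, index=unseen)])
                f = f / f.sum()
            aindex = {a: i for i, a in enumerate(f.index)}
            k = len(f)
            obs = np.full((len(self.workers), 2), -1, dtype=int)
            for wid, a1, a2 in sub[["worker_id", "allele1_bp", "allele2_bp"]].itertuples(index=False):
                if pd.isna(a1) or pd.isna(a2):
                    continue  # half-missing treated as locus-missing
                obs[self.windex[wid]] = (aindex[a1], aindex[a2])
            self.loci.append(locus)
            self.freqs.append(f.to_numpy())
            self.obs.append(obs)

        # per worker per locus: M[t1, t2] = P(obs | true ordered (t1, t2))
        e = error.mistype_rate
        self._M: list[list[np.ndarray | None]] = []
        for li in range(len(self.loci)):
            p = self.freqs[li]
            k = len(p)
            eye = np.eye(k)
            per_locus: list[np.ndarray | None] = []
            for wi in range(len(self.workers)):
                i, j = self.obs[li][wi]
                if i < 0:
                    per_locus.append(None)  # missing: likelihood factor 1
                    continue
                qi = e * p[i] + (1 - e) * eye[i]     # P(observe allele i | true t)
                qj = e * p[j] + (1 - e) * eye[j]
                M = np.outer(qi, qj)
                if i != j:
                    M = M + np.outer(qj, qi)
                per_locus.append(M)
            self._M.append(per_locus)

    # -- cluster scoring ----------------------------------------------------

    def _sib_factor(self, wi: int, li: int) -> np.ndarray | None:
        """G_w[a, b, c] = (M[a, c] + M[b, c]) / 2, or None if locus missing."""
        M = self._M[li][wi]
        if M is None:
            return None
        return 0.5 * (M[:, None, :] + M[None, :, :])

    def fullsib_loglik(self, worker_ids) -> float:
        idx = [self.windex[w] for w in worker_ids]
        if not idx:
            return 0.0
        total = 0.0
        for li in range(len(self.loci)):
            p = self.freqs[li]
            prod = None
            offset = 0.0
            for wi in idx:
                G = self._sib_factor(wi, li)
                if G is None:
                    continue
                prod = G if prod is None else prod * G
                m = prod.max()
                if m > 0 and (m < 1e-250 or m > 1e250):
                    prod = prod / m
                    offset += np.log(m)
            if prod is None:
                continue  # locus missing for every member
            val = float(np.einsum("abc,a,b,c->", prod, p, p, p))
            total += (np.log(val) + offset) if val > 0 else -np.inf
        return total

    def unrelated_loglik(self, worker_ids) -> float:
        total = 0.0
        for w in worker_ids:
            wi = self.windex[w]
            for li in range(len(self.loci)):
                M = self._M[li][wi]
                if M is None:
                    continue
                p = self.freqs[li]
                val = float(p @ M @ p)
                total += np.log(val) if val > 0 else -np.inf
        return total

    # -- pair compatibility screen ------------------------------------------

    def incompatibility_counts(self) -> np.ndarray:
        """n x n matrix: loci where both workers are typed yet share no allele."""
        n = len(self.workers)
        out = np.zeros((n, n), dtype=int)
        for li in range(len(self.loci)):
            obs = self.obs[li]
            typed = obs[:, 0] >= 0
            a1 = obs[:, 0][:, None]
            a2 = obs[:, 1][:, None]
            share = (
                (a1 == a1.T) | (a1 == a2.T) | (a2 == a1.T) | (a2 == a2.T)
            )
            both = typed[:, None] & typed[None, :]
            out += (both & ~share).astype(int)
        return out


# ---------------------------------------------------------------------------
# public likelihoods
# ---------------------------------------------------------------------------


def fullsib_loglik(
    member_genotypes: pd.DataFrame,
    allele_freqs: dict[str, pd.Series],
    error: ErrorModel | None = None,
) -> float:
    """Log-likelihood that the given workers form one full-sib family.

    ``member_genotypes`` is a long genotype table restricted to the members;
    loci with no typed member contribute 0. For a single member this reduces
    to the Hardy-Weinberg log-probability of its genotype.
    """
    error = error or ErrorModel()
    eng = _Engine(member_genotypes, allele_freqs, error)
    return eng.fullsib_loglik(eng.workers)


def unrelated_loglik(
    member_genotypes: pd.DataFrame,
    allele_freqs: dict[str, pd.Series],
    error: ErrorModel | None = None,
) -> float:
    """Null log-likelihood: every worker an independent Hardy-Weinberg draw."""
    if member_genotypes.empty:
        return 0.0
    error = error or ErrorModel()
    eng = _Engine(member_genotypes, allele_freqs, error)
    return eng.unrelated_loglik(eng.workers)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def _greedy_partition(
    eng: _Engine,
    rng: np.random.Generator,
    tau: float,
    cluster_penalty: float,
    max_incompatible: int,
) -> tuple[list[frozenset[int]], float]:
    n = len(eng.workers)
    order = rng.permutation(n)
    incompat = eng.incompatibility_counts()
    candidate = incompat <= max_incompatible
    np.fill_diagonal(candidate, False)

    clusters: dict[int, frozenset[int]] = {i: frozenset([int(w)]) for i, w in enumerate(order)}
    ll: dict[int, float] = {}
    wid_of = {i: [eng.workers[w] for w in cl] for i, cl in clusters.items()}
    for i, cl in clusters.items():
        ll[i] = eng.fullsib_loglik(wid_of[i])

    def compatible(ci: int, cj: int) -> bool:
        a = np.fromiter(clusters[ci], dtype=int)
        b = np.fromiter(clusters[cj], dtype=int)
        return bool(candidate[np.ix_(a, b)].any())

    # gain cache over live cluster-id pairs
    gains: dict[tuple[int, int], tuple[float, float]] = {}  # (gain, merged_ll)

    def eval_pair(ci: int, cj: int):
        members = wid_of[ci] + wid_of[cj]
        mll = eng.fullsib_loglik(members)
        gains[(ci, cj)] = (mll - ll[ci] - ll[cj] + cluster_penalty, mll)

    # initial clusters are singletons: read pair candidacy off the matrix
    member_of = {i: next(iter(cl)) for i, cl in clusters.items()}
    live = sorted(clusters)
    for ii, ci in enumerate(live):
        for cj in live[ii + 1 :]:
            if candidate[member_of[ci], member_of[cj]]:
                eval_pair(ci, cj)

    next_id = n
    while gains:
        # argmax with random tie-break
        best_key = max(gains, key=lambda k: (gains[k][0], rng.random()))
        best_gain, best_ll = gains[best_key]
        if best_gain <= tau:
            break
        ci, cj = best_key
        merged = clusters[ci] | clusters[cj]
        del clusters[ci], clusters[cj], ll[ci], ll[cj], wid_of[ci], wid_of[cj]
        gains = {k: v for k, v in gains.items() if ci not in k and cj not in k}
        cid = next_id
        next_id += 1
        clusters[cid] = merged
        wid_of[cid] = [eng.workers[w] for w in sorted(merged)]
        ll[cid] = best_ll
        for other in list(clusters):
            if other != cid and compatible(cid, other):
                eval_pair(min(cid, other), max(cid, other))

    total = float(sum(ll.values()))
    return list(clusters.values()), total


def reconstruct_sibships(
    genotypes: pd.DataFrame,
    allele_freqs: dict[str, pd.Series] | None = None,
    error: ErrorModel | None = None,
    restarts: int = 3,
    seed: int = 0,
    tau: float = 0.0,
    cluster_penalty: float = 0.0,
    max_incompatible: int = 2,
) -> SibshipPartition:
    """Partition workers into full-sib families by maximum likelihood.

    Runs ``restarts`` independent randomized-order agglomerative searches;
    the reported partition is the highest-likelihood restart, and each
    cluster's support is the fraction of restarts whose final partition
    contains exactly that member set. Allele frequencies default to the
    observed frequencies across all workers.

    ``tau`` is the minimum log-likelihood gain a merge must exceed;
    ``cluster_penalty`` adds an optional BIC-style reward per merge.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if genotypes["worker_id"].nunique() < 2:
        raise ValueError("need at least 2 workers to reconstruct sibships")
    error = error or ErrorModel()
    if allele_freqs is None:
        allele_freqs = estimate_allele_freqs(genotypes)
    eng = _Engine(genotypes, allele_freqs, error)

    ss = np.random.SeedSequence(seed)
    results = []
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        clusters, total = _greedy_partition(eng, rng, tau, cluster_penalty, max_incompatible)
        results.append((total, [frozenset(eng.workers[w] for w in cl) for cl in clusters]))

    best_total, best_clusters = max(results, key=lambda r: r[0])
    counts: dict[frozenset, int] = {}
    for _, clusters in results:
        for cl in clusters:
            counts[cl] = counts.get(cl, 0) + 1
    support = [counts.get(cl, 0) / restarts for cl in best_clusters]

    ordered = sorted(zip(best_clusters, support), key=lambda cs: (-len(cs[0]), sorted(cs[0])))
    return SibshipPartition(
        clusters=[tuple(sorted(cl)) for cl, _ in ordered],
        support=[s for _, s in ordered],
        total_loglik=best_total,
        restart_logliks=[r[0] for r in results],
    )


def filter_clusters(
    partition: SibshipPartition,
    min_support: float = 0.80,
    min_size: int = 2,
) -> SibshipPartition:
    """Keep clusters with support >= ``min_support`` (inclusive) and size >=
    ``min_size``; members of rejected clusters are re-reported as singletons
    with support 1.0."""
    kept, supp = [], []
    for cl, s in zip(partition.clusters, partition.support):
        if len(cl) >= min_size and s >= min_support:
            kept.append(cl)
            supp.append(s)
        else:
            for w in cl:
                kept.append((w,))
                supp.append(1.0)
    return SibshipPartition(kept, supp, partition.total_loglik, partition.restart_logliks)
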