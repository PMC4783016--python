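"""Two-pass seed-based network clustering of dereplicated sequences.

Pass one (initial clustering) builds a sparse network whose edges are unique
sequence pairs within the k-mer distance threshold, then repeatedly peels
off the most-connected node (the *seed*) together with its direct
neighbors. Connectivity is abundance-weighted: a node's duplicates act as
implicit distance-zero neighbors, so its weighted degree is the abundance
of its active neighbors plus its own abundance minus one. Peeling stops
when every remaining node is isolated; those leftovers are singletons.

Pass two (refinement) takes the initial seeds and the singletons as
candidates, computes exact NW dissimilarities among them, and peels the
resulting refined network the same way. Each refined seed's final cluster
is the seed, its refined-network neighbors, and every not-yet-assigned node
of the *initial* network directly connected to any of those -- so reads
absorbed into an initial star follow their seed when seeds merge. Assignment
is greedy: once a node is claimed it leaves both networks, giving a
deterministic partition of all unique sequences.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from . import seqio
from .alignment import nw_distance
from .calibration import CalibrationResult, determine_kmer_threshold
from .config import RunConfig
from .kmer import build_codebook, build_profiles, profile_pair_fn
from .scheduler import DistanceEdge, run_pair_tasks

logger = logging.getLogger(__name__)


class SequenceNetwork:
    """Undirected graph over unique sequences with an active-node set."""

    def __init__(self, n: int):
        self.n = n
        self.adj: list[set[int]] = [set() for _ in range(n)]
        self.active: set[int] = set(range(n))

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError(f"self-loop edge on node {i}")
        if not (0 <= i < self.n and 0 <= j < self.n):
            raise ValueError(f"edge ({i}, {j}) outside node range [0, {self.n})")
        self.adj[i].add(j)
        self.adj[j].add(i)

    def active_neighbors(self, node: int) -> set[int]:
        return self.adj[node] & self.active

    def degree(self, node: int) -> int:
        return len(self.adj[node])


@dataclass
class Cluster:
    seed: int
    members: set[int]
    stage: str = "initial"


@dataclass
class ClusteringResult:
    clusters: list[Cluster] = field(default_factory=list)

    def assignment(self) -> dict[int, int]:
        """node index -> position of its cluster in formation order."""
        out: dict[int, int] = {}
        for ci, c in enumerate(self.clusters):
            for u in c.members:
                out[u] = ci
        return out


def build_network(edges: list[DistanceEdge], n: int) -> SequenceNetwork:
    """Symmetric adjacency from threshold-passing pairs; duplicates collapse."""
    net = SequenceNetwork(n)
    for e in edges:
        net.add_edge(e.i, e.j)
    return net


def weighted_degree(network: SequenceNetwork, node: int, abundance) -> int:
    """Abundance of active neighbors plus the node's own duplicates.

    A read duplicated a times contributes a-1 implicit zero-distance
    neighbors, so a ten-fold-duplicated isolated read is as attractive a
    seed as a ten-neighbor hub of unit-abundance reads.
    """
    if node not in network.active:
        raise ValueError(f"node {node} is not active")
    total = sum(abundance[v] for v in network.adj[node] if v in network.active)
    return total + abundance[node] - 1


def select_seed(network: SequenceNetwork, abundance) -> int:
    """Active node with maximal weighted degree; ties go to the smallest index."""
    if not network.active:
        raise ValueError("no active nodes to select a seed from")
    best_node = -1
    best_deg = -1
    for node in sorted(network.active):
        deg = weighted_degree(network, node, abundance)
        if deg > best_deg:
            best_node, best_deg = node, deg
    return best_node


def peel_clusters(
    network: SequenceNetwork, abundance
) -> tuple[ClusteringResult, set[int]]:
    """Iteratively remove the best seed and its neighbors until all isolated.

    Leftover isolated nodes are the singletons; they are also recorded as
    size-1 clusters so the result is a full partition.
    """
    result = ClusteringResult()
    while any(network.active_neighbors(u) for u in network.active):
        seed = select_seed(network, abundance)
        members = {seed} | network.active_neighbors(seed)
        result.clusters.append(Cluster(seed=seed, members=set(members)))
        network.active -= members
    singletons = set(network.active)
    for s in sorted(singletons):
        result.clusters.append(Cluster(seed=s, members={s}))
    network.active = set()
    return result, singletons


def refine(
    initial: ClusteringResult,
    singletons: set[int],
    uniques,
    abundance,
    nw_threshold: float,
    params,
    initial_network: SequenceNetwork,
    granularity: int = 2000,
    n_workers: int = 1,
) -> ClusteringResult:
    """Merge initial clusters whose representatives align within threshold.

    Candidates are the initial seeds plus the singletons. NW dissimilarity is
    computed for all candidate pairs through the chunked scheduler, edges at
    or below ``nw_threshold`` form the refined network, and peeling proceeds
    by abundance-weighted degree recomputed after every removal.
    """
    cands = sorted({c.seed for c in initial.clusters} | set(singletons))
    pos = {g: li for li, g in enumerate(cands)}

    def dfn(a: int, b: int) -> float:
        return nw_distance(uniques[cands[a]].seq, uniques[cands[b]].seq, params)

    edges = run_pair_tasks(len(cands), granularity, dfn, nw_threshold, n_workers)
    refined = SequenceNetwork(len(cands))
    for e in edges:
        refined.add_edge(e.i, e.j)

    n = initial_network.n
    assigned: set[int] = set()
    final = ClusteringResult()
    while refined.active:
        best_local = -1
        best_key = None
        for u in refined.active:
            deg = sum(
                abundance[cands[v]] for v in refined.adj[u] if v in refined.active
            ) + abundance[cands[u]] - 1
            key = (-deg, cands[u])  # max degree, ties to smallest global index
            if best_key is None or key < best_key:
                best_key, best_local = key, u
        nbrs = refined.active_neighbors(best_local)
        core = {cands[u] for u in ({best_local} | nbrs)}
        attach: set[int] = set()
        for g in core:
            attach |= {
                w
                for w in initial_network.adj[g]
                if w not in assigned and w not in core
            }
        members = core | attach
        final.clusters.append(
            Cluster(seed=cands[best_local], members=members, stage="final")
        )
        assigned |= members
        refined.active -= {best_local} | nbrs
        # defensive: an attached node that happens to be a candidate leaves
        # the refined network too (assignment is exclusive and greedy)
        refined.active -= {pos[w] for w in attach if w in pos}

    leftover = set(range(n)) - assigned
    if leftover:  # pragma: no cover - partition postcondition
        raise RuntimeError(
            f"refinement left {len(leftover)} unique sequences unassigned"
        )
    return final


@dataclass
class ClusterRun:
    """Everything produced by one end-to-end clustering run."""

    otus: list[seqio.OTU]
    derep: seqio.DereplicatedSet
    calibration: CalibrationResult | None
    kmer_threshold: float
    initial: ClusteringResult
    singletons: set[int]
    final: ClusteringResult
    initial_network: SequenceNetwork
    n_initial_edges: int
    timings: dict[str, float]
    config: RunConfig

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def assignment(self) -> dict[str, str]:
        """read id -> OTU name, for evaluation against a truth table."""
        return {rid: otu.name for otu in self.otus for rid in otu.member_ids}


def cluster_dataset(records, config: RunConfig | None = None) -> ClusterRun:
    """Run the whole pipeline: dereplicate, calibrate, cluster, refine, name.

    Deterministic for a fixed config (including its RNG seed), regardless of
    worker count and granularity.
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    derep = seqio.dereplicate(records)
    timings["dereplicate"] = time.perf_counter() - t0
    n = len(derep.uniques)
    logger.info("dereplicated %d reads into %d uniques", derep.n_reads, n)

    t0 = time.perf_counter()
    codebook = build_codebook(derep.uniques, config.k)
    profiles = build_profiles(derep.uniques, codebook)
    timings["kmer_encoding"] = time.perf_counter() - t0

    calibration = None
    if config.kmer_threshold is not None:
        kmer_threshold = config.kmer_threshold
    elif n < 2:
        kmer_threshold = 0.0  # single unique sequence: nothing to compare
    else:
        t0 = time.perf_counter()
        calibration = determine_kmer_threshold(
            derep.uniques,
            config.nw_threshold,
            sample_size=config.sample_size,
            quantile=config.quantile,
            params=config.nw_params,
            k=config.k,
            rng_seed=config.rng_seed,
            min_qualifying=config.min_qualifying,
        )
        kmer_threshold = calibration.kmer_threshold
        timings["calibration"] = time.perf_counter() - t0
        logger.info(
            "k-mer threshold %.4f from %d sampled pairs (%d qualifying)",
            kmer_threshold,
            calibration.n_pairs,
            calibration.n_qualifying_pairs,
        )

    t0 = time.perf_counter()
    edges = run_pair_tasks(
        n,
        config.granularity,
        profile_pair_fn(profiles),
        kmer_threshold,
        config.effective_workers,
    )
    timings["kmer_distances"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    network = build_network(edges, n)
    initial, singletons = peel_clusters(network, derep.abundance)
    timings["initial_clustering"] = time.perf_counter() - t0
    logger.info(
        "initial pass: %d clusters, %d singletons from %d edges",
        len(initial.clusters),
        len(singletons),
        len(edges),
    )

    t0 = time.perf_counter()
    final = refine(
        initial,
        singletons,
        derep.uniques,
        derep.abundance,
        config.nw_threshold,
        config.nw_params,
        network,
        granularity=config.granularity,
        n_workers=config.effective_workers,
    )
    timings["refinement"] = time.perf_counter() - t0

    otus = seqio.rehydrate(final, derep)
    logger.info("final: %d OTUs over %d reads", len(otus), derep.n_reads)
    return ClusterRun(
        otus=otus,
        derep=derep,
        calibration=calibration,
        kmer_threshold=kmer_threshold,
        initial=initial,
        singletons=singletons,
        final=final,
        initial_network=network,
        n_initial_edges=len(edges),
        timings=timings,
        config=config,
    )


def verify_membership_structure(run: ClusterRun) -> bool:
    """Post-hoc check of the structural guarantee on every final OTU.

    Each member must be (a) the refined seed, (b) within the NW threshold of
    the refined seed, or (c) connected in the initial k-mer network to a node
    of type (a) or (b). Raises ``AssertionError`` naming the first violation.
    """
    uniques = run.derep.uniques
    params = run.config.nw_params
    t = run.config.nw_threshold
    for c in run.final.clusters:
        near = {
            m
            for m in c.members
            if m == c.seed or nw_distance(uniques[m].seq, uniques[c.seed].seq, params) <= t
        }
        for m in c.members - near:
            if not (run.initial_network.adj[m] & near):
                raise AssertionError(
                    f"node {m} in cluster seeded by {c.seed} is neither within "
                    "the NW threshold of the seed nor connected to a node that is"
                )
    return True
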