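"""Target-network synergy score between two drugs' target sets.

For drugs with mapped target sets Tk (size m) and Th (size n) on a scoring
network with centrality scores CS, the score is a pair of centrality-
weighted means of distance kernels:

    S = sum_i CS(t_ki) exp(-D(t_ki, Th)/n^2) / sum_i CS(t_ki)
      + sum_j CS(t_hj) exp(-D(t_hj, Tk)/m^2) / sum_j CS(t_hj)

where D(t, T) is the minimum unweighted shortest-path length from t to any
member of T. The score favours combinations whose targets sit on network
hubs and lie close to each other; it is symmetric, lies in [0, 2], and
reaches 2 exactly when the mapped target sets coincide. Unreachable
targets contribute a kernel factor of 0 (the limit of the decay kernel at
infinite distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import DomainError, UndefinedScoreError, warn
from .network import InteractionNetwork

#: Sentinel distance for targets with no path to the destination set.
UNREACHABLE = float("inf")


@dataclass(frozen=True)
class TargetSet:
    """A drug's protein targets, deduplicated, order preserved."""

    drug_id: str
    targets: tuple[str, ...]

    def __post_init__(self):
        seen: dict[str, None] = dict.fromkeys(self.targets)
        object.__setattr__(self, "targets", tuple(seen))

    @property
    def size(self) -> int:
        return len(self.targets)

    def mapped(self, net: InteractionNetwork) -> tuple[str, ...]:
        """Targets present in the scoring network, order preserved."""
        return tuple(t for t in self.targets if t in net)


@dataclass(frozen=True)
class DistanceRecord:
    source: str
    destination: str  # drug_id of the destination set
    distance: float   # hops, or UNREACHABLE


def min_distance(t: str, T: TargetSet, net: InteractionNetwork) -> DistanceRecord:
    """Minimum shortest-path length (hops) from node ``t`` to the set ``T``.

    Restricted to nodes present in the network: members of ``T`` outside
    the network are ignored, and if ``t`` is absent or no member is
    reachable the distance is :data:`UNREACHABLE`. ``t in T`` gives 0.
    """
    if T.size == 0:
        raise DomainError(f"min_distance to empty target set {T.drug_id!r}")
    members = set(T.mapped(net))
    if t in T.targets and t in net:
        return DistanceRecord(t, T.drug_id, 0.0)
    if t not in net or not members:
        return DistanceRecord(t, T.drug_id, UNREACHABLE)
    # one BFS from t, stop at the first (= closest) member of T
    dist = 0.0
    if t in members:
        return DistanceRecord(t, T.drug_id, 0.0)
    lengths = nx.single_source_shortest_path_length(net.graph, t)
    best = min((d for v, d in lengths.items() if v in members), default=None)
    dist = UNREACHABLE if best is None else float(best)
    return DistanceRecord(t, T.drug_id, dist)


def s_tnetwork(Tk: TargetSet, Th: TargetSet, net: InteractionNetwork,
               cs: pd.DataFrame, exponent_sign: str = "decay") -> float:
    """Target-network synergy score of two drugs on a scoring network.

    Parameters
    ----------
    Tk, Th
        The two drugs' target sets.
    net
        The scoring network (centralities and distances live here).
    cs
        Centrality table from :func:`synscreen.network.compute_centralities`.
    exponent_sign
        ``decay`` (default) applies exp(-D/n^2); ``literal`` applies
        exp(+D/n^2), which rewards distant targets.

    Raises
    ------
    UndefinedScoreError
        If either drug has no target mapped to the network, or the mapped
        targets carry zero total centrality.
    """
    if exponent_sign not in ("decay", "literal"):
        raise DomainError(f"exponent_sign {exponent_sign!r} not in "
                          "('decay', 'literal')")
    mk = Tk.mapped(net)
    mh = Th.mapped(net)
    for ts, m in ((Tk, mk), (Th, mh)):
        if not m:
            raise UndefinedScoreError(
                f"drug {ts.drug_id!r} has no target mapped to the scoring "
                "network", code="score.no_mapped_targets")
    dropped_k = Tk.size - len(mk)
    dropped_h = Th.size - len(mh)
    if dropped_k or dropped_h:
        warn(f"targets outside scoring network excluded: "
             f"{Tk.drug_id}={dropped_k}, {Th.drug_id}={dropped_h}",
             code="score.targets_dropped")
    m, n = len(mk), len(mh)

    def half(sources: tuple[str, ...], dest: TargetSet, denom_sq: int) -> float:
        num = 0.0
        den = 0.0
        for t in sources:
            w = float(cs.at[t, "cs"])
            d = min_distance(t, dest, net).distance
            if d == UNREACHABLE:
                kern = 0.0
            else:
                expo = d / denom_sq
                kern = math.exp(-expo if exponent_sign == "decay" else expo)
            num += w * kern
            den += w
        if den == 0.0:
            raise UndefinedScoreError(
                "mapped targets carry zero total centrality",
                code="score.zero_centrality")
        return num / den

    # the Tk-weighted mean uses the other set's size n, and vice versa
    return half(mk, Th, n * n) + half(mh, Tk, m * m)
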