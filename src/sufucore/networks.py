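"""Spearman association screening and co-occurrence networks.

Two screens share the same correlation machinery:

* genus-flavor screening — a dominant genus is *strongly flavor
  associated* when, within a stage, it correlates with more than a
  stage-specific number of characteristic compounds at |rho| > 0.7 and
  p < 0.05 (more than 12 compounds in the early stage, more than 7 in
  the late stage, reading the "more than" thresholds strictly);
* genus-genus co-occurrence — dominant genera are nodes, and an edge is
  retained when |rho| > 0.7 and p < 0.05; a node's degree counts its
  retained edges, positive and negative alike.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks
on ties). p-values default to the t approximation
t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom; an exact
permutation p-value is available for n <= 8. Raw p-values are used by
default, faithful to the screening rule; Benjamini-Hochberg adjustment
is available as an option.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, ValidationError

__all__ = [
    "ScreeningCriteria",
    "Edge",
    "Network",
    "spearman_rho",
    "spearman_p",
    "spearman_matrix",
    "FlavorScreenResult",
    "genus_flavor_screen",
    "cooccurrence_network",
    "degree",
]


@dataclass(frozen=True)
class ScreeningCriteria:
    """All thresholds of the three-criterion core screen in one object.

    count_rule "strict_greater" reads "more than 12" literally (a genus
    with exactly 12 qualifying compounds fails); "at_least" makes the
    boundary inclusive. degree_rule works the same way for "degree > 4".
    flavor_sign "positive_only" counts only positive correlations in the
    qualifying-compound tally (the promoter-only convention under which the core reduces to the
    flavor formers); the default "both" counts |rho|.
    """

    rho_min: float = 0.7
    p_max: float = 0.05
    flavor_count_min_early: int = 12
    flavor_count_min_late: int = 7
    degree_min: int = 4
    abundance_min: float = 0.01
    count_rule: str = "strict_greater"
    degree_rule: str = "strict_greater"
    flavor_sign: str = "both"
    p_adjust: str | None = None  # None (raw) or "bh"

    def __post_init__(self) -> None:
        if not 0 < self.rho_min <= 1:
            raise ValidationError("rho_min must be in (0, 1]")
        if not 0 < self.p_max < 1:
            raise ValidationError("p_max must be in (0, 1)")
        for name in ("flavor_count_min_early", "flavor_count_min_late", "degree_min"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.count_rule not in ("strict_greater", "at_least"):
            raise ValidationError(f"unknown count_rule {self.count_rule!r}")
        if self.degree_rule not in ("strict_greater", "at_least"):
            raise ValidationError(f"unknown degree_rule {self.degree_rule!r}")
        if self.flavor_sign not in ("both", "positive_only"):
            raise ValidationError(f"unknown flavor_sign {self.flavor_sign!r}")
        if self.p_adjust not in (None, "bh"):
            raise ValidationError(f"unknown p_adjust {self.p_adjust!r}")

    def count_threshold(self, stage: str) -> int:
        if stage == "early":
            return self.flavor_count_min_early
        if stage == "late":
            return self.flavor_count_min_late
        raise ValidationError(f"screening stage must be 'early' or 'late', got {stage!r}")

    def count_passes(self, count: int, stage: str) -> bool:
        thr = self.count_threshold(stage)
        return count > thr if self.count_rule == "strict_greater" else count >= thr

    def degree_passes(self, deg: int) -> bool:
        if self.degree_rule == "strict_greater":
            return deg > self.degree_min
        return deg >= self.degree_min


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    rho: float
    p: float
    sign: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"rho out of [-1, 1]: {self.rho}")
        expected = "positive" if self.rho > 0 else "negative"
        if self.sign == "":
            object.__setattr__(self, "sign", expected)
        elif self.sign != expected:
            raise ValidationError(
                f"edge {self.source}-{self.target}: sign {self.sign!r} "
                f"inconsistent with rho={self.rho}"
            )
        if self.source == self.target:
            raise ValidationError(f"self-loop on {self.source!r}")


@dataclass
class Network:
    """Undirected association network with per-node degree.

    Invariants: no self-loops, at most one edge per unordered pair, and
    degree(v) = number of retained edges incident to v (so the degree
    sum equals twice the edge count).
    """

    nodes: list[str]
    edges: list[Edge]
    degrees: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, nodes: list[str], edges: list[Edge]) -> "Network":
        known = set(nodes)
        seen = set()
        for e in edges:
            if e.source not in known or e.target not in known:
                raise ValidationError(f"edge {e.source}-{e.target} uses unknown node")
            key = frozenset((e.source, e.target))
            if key in seen:
                raise ValidationError(f"duplicate edge {e.source}-{e.target}")
            seen.add(key)
        deg = {v: 0 for v in nodes}
        for e in edges:
            deg[e.source] += 1
            deg[e.target] += 1
        return cls(nodes=list(nodes), edges=list(edges), degrees=deg)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, rho=e.rho, p=e.p, sign=e.sign)
        return g


def degree(net: Network, v: str) -> int:
    """Number of retained edges incident to ``v``."""
    if v not in net.degrees:
        raise ValidationError(f"unknown node {v!r}")
    return net.degrees[v]


# ---------------------------------------------------------------------------
# Spearman machinery


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-D")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    xa = _as_vector(x, "x")
    ya = _as_vector(y, "y")
    if len(xa) != len(ya):
        raise ValidationError("x and y must have equal length")
    if len(xa) < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_p(rho: float, n: int, method: str = "t_approx", x=None, y=None) -> float:
    """Two-sided p-value for an observed Spearman rho.

    ``t_approx`` uses t = rho sqrt((n-2)/(1-rho^2)) on n-2 df, with
    |rho| = 1 mapped to p = 0 by convention. ``exact_perm`` enumerates
    all n! permutations of the observed y values (ties permuted as
    observed) and requires the data vectors; limited to n <= 8.
    """
    if abs(rho) > 1 + 1e-12:
        raise ValidationError(f"|rho| must be <= 1, got {rho}")
    if n < 3:
        raise ValidationError("need n >= 3")
    if method == "t_approx":
        r = min(1.0, abs(rho))
        if r >= 1.0:
            return 0.0
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        return float(2.0 * stats.t.sf(t, n - 2))
    if method == "exact_perm":
        if x is None or y is None:
            raise ValidationError("exact_perm requires the data vectors x and y")
        xa = _as_vector(x, "x")
        ya = _as_vector(y, "y")
        if len(xa) != n or len(ya) != n:
            raise ValidationError("vector lengths must equal n")
        if n > 8:
            raise ValidationError("exact_perm is limited to n <= 8")
        if np.ptp(xa) == 0 or np.ptp(ya) == 0:
            raise ValidationError("correlation undefined for a constant vector")
        rx = stats.rankdata(xa)
        ry = stats.rankdata(ya)
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        rx /= math.sqrt(rx @ rx)
        ry /= math.sqrt(ry @ ry)  # permutation-invariant normalization
        observed = abs(rx @ ry)
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = ry[perms] @ rx
        return float(np.mean(np.abs(rhos) >= observed - 1e-12))
    raise ValidationError(f"unknown method {method!r}")


def spearman_matrix(X: pd.DataFrame, Y: pd.DataFrame | None = None):
    """All-pairs Spearman rho and t-approximation p-values.

    ``X`` (and optionally ``Y``) hold variables in columns and matched
    samples in rows. Returns ``(rho, p)`` DataFrames of shape
    (X columns x Y columns); with ``Y=None`` the X-vs-X matrix is
    returned. Constant columns yield NaN rho and p = 1.
    """
    Xa = X.to_numpy(dtype=float)
    n = Xa.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples")
    Ya = Xa if Y is None else Y.to_numpy(dtype=float)
    if Ya.shape[0] != n:
        raise ValidationError("sample mismatch between the two matrices")

    def ranks(A):
        R = np.apply_along_axis(stats.rankdata, 0, A)
        R = R - R.mean(axis=0)
        norm = np.sqrt((R**2).sum(axis=0))
        keep = norm > 0
        R[:, keep] = R[:, keep] / norm[keep]
        R[:, ~keep] = np.nan
        return R

    RX = ranks(Xa)
    RY = RX if Y is None else ranks(Ya)
    rho = RX.T @ RY
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(rho)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(t, n - 2)
        p = np.where(r >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), 1.0, p)
    cols = X.columns if Y is None else Y.columns
    return (
        pd.DataFrame(rho, index=X.columns, columns=cols),
        pd.DataFrame(p, index=X.columns, columns=cols),
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        val = flat[order[rank]] * m / (rank + 1)
        running = min(running, val)
        adj[order[rank]] = running
    return adj.reshape(p.shape)


# ---------------------------------------------------------------------------
# screens


@dataclass
class FlavorScreenResult:
    """Outcome of the genus-flavor screen for one stage."""

    stage: str
    associations: dict[str, list[tuple[str, float, float]]]  # genus -> (compound, rho, p)
    qualifying_counts: dict[str, int]
    passing: list[str]  # screened genus set, input order


def genus_flavor_screen(
    at: AbundanceTable | pd.DataFrame,
    flavor: pd.DataFrame,
    crit: ScreeningCriteria,
    stage: str,
) -> FlavorScreenResult:
    """Screen dominant genera for strong flavor association within a stage.

    ``at`` must be stage-restricted and already reduced to the dominant
    genera (an :class:`AbundanceTable` or a samples x genera matrix);
    ``flavor`` is a compounds x samples matrix of characteristic
    compounds whose columns match ``at``'s sample ids. A genus passes
    when its number of qualifying compounds (|rho| > rho_min and
    p < p_max, restricted to positive rho under flavor_sign
    "positive_only") satisfies the stage's count rule.
    """
    abund = at.values if isinstance(at, AbundanceTable) else at
    genera = list(abund.columns)
    sample_ids = list(abund.index)
    if not genera:
        raise ValidationError("empty dominant genus set")
    if list(flavor.columns) != sample_ids:
        raise ValidationError(
            "flavor matrix columns must match the abundance sample ids"
        )
    rho, p = spearman_matrix(abund, flavor.T)  # genera x compounds
    if crit.p_adjust == "bh":
        p = pd.DataFrame(_bh_adjust(p.to_numpy()), index=p.index, columns=p.columns)
    strong = (rho.abs() > crit.rho_min) & (p < crit.p_max)
    if crit.flavor_sign == "positive_only":
        strong &= rho > 0

    compounds = list(flavor.index)
    strong_np = strong.to_numpy()
    rho_np = rho.to_numpy()
    p_np = p.to_numpy()
    associations: dict[str, list[tuple[str, float, float]]] = {}
    counts: dict[str, int] = {}
    passing: list[str] = []
    for i, g in enumerate(genera):
        idx = np.flatnonzero(strong_np[i])
        hits = [(compounds[j], float(rho_np[i, j]), float(p_np[i, j])) for j in idx]
        associations[g] = hits
        counts[g] = len(hits)
        if crit.count_passes(len(hits), stage):
            passing.append(g)
    return FlavorScreenResult(
        stage=stage, associations=associations, qualifying_counts=counts, passing=passing
    )


def cooccurrence_network(
    at: AbundanceTable,
    dominant: list[str],
    crit: ScreeningCriteria = ScreeningCriteria(),
) -> Network:
    """Genus-genus co-occurrence network over a stage's samples.

    Nodes are the dominant genera; an (undirected) edge is retained when
    |rho| > rho_min and p < p_max. Degree and correlation sign are
    recorded on the result.
    """
    if len(dominant) < 2:
        raise ValidationError("need at least 2 dominant genera")
    missing = [g for g in dominant if g not in at.genera]
    if missing:
        raise ValidationError(f"genera not in the abundance table: {missing}")
    sub = at.values[dominant]
    if sub.shape[0] < 3:
        raise ValidationError("need at least 3 samples in the stage")
    rho, p = spearman_matrix(sub)
    if crit.p_adjust == "bh":
        iu = np.triu_indices(len(dominant), k=1)
        padj = p.to_numpy().copy()
        padj[iu] = _bh_adjust(p.to_numpy()[iu])
        p = pd.DataFrame(padj, index=p.index, columns=p.columns)
    edges = []
    for i, gi in enumerate(dominant):
        for gj in dominant[i + 1 :]:
            r = rho.loc[gi, gj]
            if np.isnan(r):
                continue
            if abs(r) > crit.rho_min and p.loc[gi, gj] < crit.p_max:
                edges.append(Edge(gi, gj, float(r), float(p.loc[gi, gj])))
    return Network.from_edges(list(dominant), edges)
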