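"""Constraint-based Bayesian-network structure learning on Gaussian data.

Markov-blanket / parents-children discovery (Grow-Shrink, IAMB,
Fast-IAMB, Inter-IAMB, MMPC) with a choice of conditional-independence
tests on the partial correlation (exact t, Fisher-Z, Monte-Carlo
permutation, Gaussian mutual information), AND-rule symmetry correction,
v-structure orientation and Meek-rule propagation to a PDAG.

All variables are treated as jointly Gaussian; conditioning is performed
by least-squares residualization.  Candidate sets are always iterated in
sorted label order so that results do not depend on column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain, combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CITestResult",
    "PDAG",
    "ci_test",
    "learn_structure",
    "consensus_structure",
    "ALGORITHMS",
    "CI_TESTS",
]

log = logging.getLogger(__name__)

CI_TESTS = ("pearson_t", "fisher_z", "mc_permutation", "mutual_information")
ALGORITHMS = ("gs", "iamb", "fast_iamb", "inter_iamb", "mmpc")


@dataclass
class CITestResult:
    x: str
    y: str
    Z: tuple[str, ...]
    statistic: float
    p_value: float
    r: float
    test: str
    n_eff: int
    df_ok: bool = True


@dataclass
class PDAG:
    """Partially directed acyclic graph over named nodes."""

    nodes: list[str]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        for a, b in self.directed:
            if a == b:
                raise ValueError(f"self-loop {a}->{b}")
            if frozenset((a, b)) in self.undirected:
                raise ValueError(f"edge {a}-{b} both directed and undirected")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed subgraph contains a cycle")

    def adjacent(self, a: str, b: str) -> bool:
        return ((a, b) in self.directed or (b, a) in self.directed
                or frozenset((a, b)) in self.undirected)

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [{"from": a, "to": b, "type": "directed"}
                for a, b in sorted(self.directed)]
        rows += [{"from": min(e), "to": max(e), "type": "undirected"}
                 for e in sorted(self.undirected, key=sorted)]
        return pd.DataFrame(rows, columns=["from", "to", "type"])

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "directed": sorted(list(e) for e in self.directed),
            "undirected": sorted(sorted(e) for e in self.undirected),
        }


# ---------------------------------------------------------------------------
# conditional-independence tests


def _partial_corr(X: np.ndarray, xi: int, yi: int, zi: tuple[int, ...]) -> float:
    if zi:
        design = np.column_stack([X[:, list(zi)], np.ones(len(X))])
        coef, *_ = np.linalg.lstsq(design, X[:, [xi, yi]], rcond=None)
        res = X[:, [xi, yi]] - design @ coef
        rx, ry = res[:, 0], res[:, 1]
    else:
        rx = X[:, xi] - X[:, xi].mean()
        ry = X[:, yi] - X[:, yi].mean()
    sx, sy = np.sqrt((rx ** 2).sum()), np.sqrt((ry ** 2).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))


def _residual_pair(X: np.ndarray, xi: int, yi: int, zi: tuple[int, ...]
                   ) -> tuple[np.ndarray, np.ndarray]:
    if zi:
        design = np.column_stack([X[:, list(zi)], np.ones(len(X))])
        coef, *_ = np.linalg.lstsq(design, X[:, [xi, yi]], rcond=None)
        res = X[:, [xi, yi]] - design @ coef
        return res[:, 0], res[:, 1]
    return X[:, xi] - X[:, xi].mean(), X[:, yi] - X[:, yi].mean()


def ci_test(data: pd.DataFrame, x: str, y: str, Z=(),
            method: str = "fisher_z", B: int = 199, seed: int = 0
            ) -> CITestResult:
    """Conditional-independence test of x and y given Z.

    All four methods are built on the partial correlation ``r`` of x and y
    after least-squares residualization on Z:

    - ``pearson_t``: t = r sqrt((n-|Z|-2)/(1-r^2)), two-sided p, df=n-|Z|-2
    - ``fisher_z``: z = atanh(r) sqrt(n-|Z|-3), two-sided normal p
    - ``mc_permutation``: permute the x-residuals B times,
      p = (1 + #{|r*| >= |r|}) / (1 + B)
    - ``mutual_information`` (Gaussian): MI = -0.5 ln(1-r^2),
      G = 2 n MI, p from chi-square(1)

    Insufficient degrees of freedom yield a non-rejecting result (p = 1)
    with a logged warning, the skip behaviour constraint learners need.
    """
    if method not in CI_TESTS:
        raise ValueError(f"unknown test {method!r}; choose from {CI_TESTS}")
    Z = tuple(Z)
    df = data[[x, y, *Z]].dropna()
    X = df.to_numpy(float)
    n = len(df)
    k = len(Z)
    xi, yi, zi = 0, 1, tuple(range(2, 2 + k))

    min_n = {"pearson_t": k + 3, "fisher_z": k + 4,
             "mc_permutation": k + 3, "mutual_information": k + 3}[method]
    if n < min_n:
        log.warning("insufficient n for %s(%s,%s|%s): n=%d; reporting p=1",
                    method, x, y, Z, n)
        return CITestResult(x, y, Z, np.nan, 1.0, np.nan, method, n, df_ok=False)

    r = _partial_corr(X, xi, yi, zi)
    if not np.isfinite(r):
        log.warning("constant residuals in %s(%s,%s|%s); reporting p=1",
                    method, x, y, Z)
        return CITestResult(x, y, Z, np.nan, 1.0, np.nan, method, n, df_ok=False)

    r_safe = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    if method == "pearson_t":
        dof = n - k - 2
        t = r_safe * np.sqrt(dof / (1.0 - r_safe ** 2))
        p = 2.0 * stats.t.sf(abs(t), df=dof)
        stat = t
    elif method == "fisher_z":
        z = np.arctanh(r_safe) * np.sqrt(n - k - 3)
        p = 2.0 * stats.norm.sf(abs(z))
        stat = z
    elif method == "mutual_information":
        mi = -0.5 * np.log(1.0 - r_safe ** 2)
        stat = 2.0 * n * mi
        p = stats.chi2.sf(stat, df=1)
    else:  # mc_permutation
        rx, ry = _residual_pair(X, xi, yi, zi)
        sx = np.sqrt((rx ** 2).sum())
        sy = np.sqrt((ry ** 2).sum())
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(len(rx)) for _ in range(B)])
        null_r = (rx[perms] - rx.mean()) @ (ry - ry.mean()) / (sx * sy)
        p = (1.0 + np.sum(np.abs(null_r) >= abs(r))) / (1.0 + B)
        stat = r
    return CITestResult(x, y, Z, float(stat), float(p), r, method, n)


class _Tester:
    """Cached CI tester bound to one dataset / test / alpha."""

    def __init__(self, data: pd.DataFrame, method: str, alpha: float,
                 B: int = 199, seed: int = 0):
        self.data = data
        self.method = method
        self.alpha = alpha
        self.B = B
        self.seed = seed
        self._cache: dict = {}

    def p(self, x: str, y: str, Z) -> float:
        key = (min(x, y), max(x, y), frozenset(Z))
        if key not in self._cache:
            # one deterministic seed per distinct test, independent of call order
            sub_seed = self.seed + (hash(key) % 100003)
            self._cache[key] = ci_test(self.data, x, y, tuple(sorted(Z)),
                                       method=self.method, B=self.B,
                                       seed=sub_seed).p_value
        return self._cache[key]

    def dependent(self, x: str, y: str, Z) -> bool:
        return self.p(x, y, Z) < self.alpha


# ---------------------------------------------------------------------------
# Markov blanket / parents-children discovery


def _shrink(t: str, mb: list[str], tester: _Tester,
            keep: str | None = None) -> list[str]:
    changed = True
    while changed:
        changed = False
        for x in sorted(mb):
            if x == keep:
                continue
            rest = [m for m in mb if m != x]
            if not tester.dependent(x, t, rest):
                mb.remove(x)
                changed = True
                break
    return mb


def _mb_gs(t: str, variables: list[str], tester: _Tester) -> list[str]:
    mb: list[str] = []
    changed = True
    while changed:
        changed = False
        for x in sorted(v for v in variables if v != t and v not in mb):
            if tester.dependent(x, t, mb):
                mb.append(x)
                changed = True
    return _shrink(t, mb, tester)


def _mb_iamb(t: str, variables: list[str], tester: _Tester) -> list[str]:
    mb: list[str] = []
    while True:
        cands = sorted(v for v in variables if v != t and v not in mb)
        if not cands:
            break
        scored = sorted((tester.p(x, t, mb), x) for x in cands)
        p_best, x_best = scored[0]
        if p_best < tester.alpha:
            mb.append(x_best)
        else:
            break
    return _shrink(t, mb, tester)


def _mb_inter_iamb(t: str, variables: list[str], tester: _Tester) -> list[str]:
    mb: list[str] = []
    while True:
        cands = sorted(v for v in variables if v != t and v not in mb)
        if not cands:
            break
        scored = sorted((tester.p(x, t, mb), x) for x in cands)
        p_best, x_best = scored[0]
        if p_best < tester.alpha:
            mb.append(x_best)
            _shrink(t, mb, tester, keep=x_best)  # interleaved shrinking
        else:
            break
    return _shrink(t, mb, tester)


def _mb_fast_iamb(t: str, variables: list[str], tester: _Tester,
                  max_rounds: int = 100) -> list[str]:
    mb: list[str] = []
    seen_states: set[tuple] = set()
    for _ in range(max_rounds):
        cands = sorted(v for v in variables if v != t and v not in mb)
        scored = sorted((tester.p(x, t, mb), x) for x in cands)
        batch = [x for p, x in scored if p < tester.alpha]
        if not batch:
            break
        # speculative batch insertion: admit in association order until a
        # candidate fails against the growing blanket
        added = False
        for x in batch:
            if tester.dependent(x, t, mb):
                mb.append(x)
                added = True
            else:
                break
        _shrink(t, mb, tester)
        state = tuple(sorted(mb))
        if not added or state in seen_states:
            break
        seen_states.add(state)
    return mb


def _subsets(items, max_size=None):
    items = sorted(items)
    upper = len(items) if max_size is None else min(max_size, len(items))
    return chain.from_iterable(combinations(items, k) for k in range(upper + 1))


def _pc_mmpc(t: str, variables: list[str], tester: _Tester) -> list[str]:
    pc: list[str] = []
    excluded: set[str] = set()
    while True:
        best_x, best_worst = None, None
        for x in sorted(v for v in variables
                        if v != t and v not in pc and v not in excluded):
            worst = max(tester.p(x, t, S) for S in _subsets(pc))
            if worst >= tester.alpha:
                excluded.add(x)
                continue
            if best_worst is None or worst < best_worst:
                best_x, best_worst = x, worst
        if best_x is None:
            break
        pc.append(best_x)
    # backward: drop members separated by some subset of the rest
    changed = True
    while changed:
        changed = False
        for x in sorted(pc):
            rest = [v for v in pc if v != x]
            if any(tester.p(x, t, S) >= tester.alpha for S in _subsets(rest)):
                pc.remove(x)
                changed = True
                break
    return pc


_MB_FUNCS = {"gs": _mb_gs, "iamb": _mb_iamb, "fast_iamb": _mb_fast_iamb,
             "inter_iamb": _mb_inter_iamb}


# ---------------------------------------------------------------------------
# skeleton, orientation, Meek rules


def _skeleton_from_blankets(nodes: list[str], mbs: dict[str, list[str]],
                            tester: _Tester) -> set[frozenset]:
    """AND-rule symmetry plus subset-separation refinement."""
    edges: set[frozenset] = set()
    for x, y in combinations(sorted(nodes), 2):
        if y not in mbs[x] or x not in mbs[y]:
            continue
        pools = sorted([sorted(set(mbs[x]) - {y}), sorted(set(mbs[y]) - {x})],
                       key=len)
        separated = False
        tried = set()
        for pool in pools:
            for S in _subsets(pool):
                if S in tried:
                    continue
                tried.add(S)
                if tester.p(x, y, S) >= tester.alpha:
                    separated = True
                    break
            if separated:
                break
        if not separated:
            edges.add(frozenset((x, y)))
    return edges


def _find_sepsets(nodes: list[str], edges: set[frozenset], tester: _Tester,
                  mbs: dict[str, list[str]] | None = None
                  ) -> dict[frozenset, tuple[tuple[str, ...], float]]:
    """Best separating set (max p over tested subsets) for nonadjacent pairs."""
    adj = {v: sorted({next(iter(e - {v})) for e in edges if v in e})
           for v in nodes}
    sepsets: dict[frozenset, tuple[tuple[str, ...], float]] = {}
    for x, y in combinations(sorted(nodes), 2):
        if frozenset((x, y)) in edges:
            continue
        common = set(adj[x]) & set(adj[y])
        if not common:
            continue
        pools = [set(adj[x]) - {y}, set(adj[y]) - {x}]
        if mbs is not None:
            pools += [set(mbs[x]) - {y}, set(mbs[y]) - {x}]
        best_S, best_p = (), -1.0
        for S in {S for pool in pools for S in _subsets(pool)}:
            p = tester.p(x, y, S)
            if p > best_p:
                best_S, best_p = tuple(sorted(S)), p
        sepsets[frozenset((x, y))] = (best_S, best_p)
    return sepsets


def _orient_v_structures(nodes: list[str], edges: set[frozenset],
                         sepsets: dict) -> tuple[set[tuple], set[frozenset]]:
    adj = {v: sorted({next(iter(e - {v})) for e in edges if v in e})
           for v in nodes}
    candidates = []
    for x, y in combinations(sorted(nodes), 2):
        key = frozenset((x, y))
        if key in edges or key not in sepsets:
            continue
        S, p = sepsets[key]
        for z in sorted(set(adj[x]) & set(adj[y])):
            if z not in S:
                candidates.append((p, x, z, y))
    # conflicts resolved in favour of the candidate with the lower p-value
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    directed: set[tuple] = set()
    undirected = set(edges)
    for p, x, z, y in candidates:
        if (z, x) in directed or (z, y) in directed:
            log.warning("conflicting v-structure %s->%s<-%s (p=%.3g) skipped",
                        x, z, y, p)
            continue
        for a in (x, y):
            undirected.discard(frozenset((a, z)))
            directed.add((a, z))
    return directed, undirected


def _meek(nodes: list[str], directed: set[tuple], undirected: set[frozenset]
          ) -> tuple[set[tuple], set[frozenset]]:
    """Meek orientation-propagation rules 1-4 applied to a fixed point."""

    def adjacent(a, b):
        return ((a, b) in directed or (b, a) in directed
                or frozenset((a, b)) in undirected)

    def orient(a, b):
        undirected.discard(frozenset((a, b)))
        directed.add((a, b))

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for u, v in ((a, b), (b, a)):
                # R1: w -> u, u - v, w and v nonadjacent  =>  u -> v
                if any((w, u) in directed and not adjacent(w, v)
                       for w in nodes if w not in (u, v)):
                    orient(u, v)
                    changed = True
                    break
                # R2: u -> w -> v and u - v  =>  u -> v
                if any((u, w) in directed and (w, v) in directed
                       for w in nodes if w not in (u, v)):
                    orient(u, v)
                    changed = True
                    break
                # R3: u - c, u - d, c -> v, d -> v, c and d nonadjacent
                nbrs = [c for c in nodes
                        if frozenset((u, c)) in undirected and c not in (u, v)]
                r3 = False
                for c, d in combinations(sorted(nbrs), 2):
                    if ((c, v) in directed and (d, v) in directed
                            and not adjacent(c, d)):
                        orient(u, v)
                        changed = True
                        r3 = True
                        break
                if r3:
                    break
                # R4: u - c, c -> d, d -> v, v and c nonadjacent  =>  u -> v
                r4 = False
                for c in nbrs:
                    if adjacent(v, c):
                        continue
                    if any((c, d) in directed and (d, v) in directed
                           for d in nodes if d not in (u, v, c)):
                        orient(u, v)
                        changed = True
                        r4 = True
                        break
                if r4:
                    break
            if changed:
                break
    return directed, undirected


def learn_structure(data: pd.DataFrame, algorithm: str = "iamb",
                    test: str = "fisher_z", alpha: float = 0.05,
                    B: int = 199, seed: int = 0) -> PDAG:
    """Learn a PDAG over the columns of ``data``.

    Markov-blanket algorithms (gs, iamb, fast_iamb, inter_iamb) recover
    blankets per node, apply the AND symmetry rule with subset-separation
    refinement, orient v-structures and propagate Meek rules.  ``mmpc``
    recovers parents-children sets and returns skeleton + v-structures
    only, matching its narrower scope.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    df = data.dropna()
    nodes = sorted(df.columns)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    if len(df) <= len(nodes) + 3:
        raise ValueError(f"need n > nodes + 3 ({len(df)} rows, {len(nodes)} nodes)")
    tester = _Tester(df, test, alpha, B=B, seed=seed)

    if algorithm == "mmpc":
        pcs = {t: _pc_mmpc(t, nodes, tester) for t in nodes}
        edges = {frozenset((x, y)) for x, y in combinations(sorted(nodes), 2)
                 if y in pcs[x] and x in pcs[y]}
        sepsets = _find_sepsets(nodes, edges, tester, mbs=pcs)
        directed, undirected = _orient_v_structures(nodes, edges, sepsets)
        return PDAG(nodes=nodes, directed=directed, undirected=undirected)

    mb_fn = _MB_FUNCS[algorithm]
    mbs = {t: mb_fn(t, nodes, tester) for t in nodes}
    edges = _skeleton_from_blankets(nodes, mbs, tester)
    sepsets = _find_sepsets(nodes, edges, tester, mbs=mbs)
    directed, undirected = _orient_v_structures(nodes, edges, sepsets)
    directed, undirected = _meek(nodes, directed, undirected)
    return PDAG(nodes=nodes, directed=directed, undirected=undirected)


# ---------------------------------------------------------------------------
# cross-algorithm consensus


def consensus_structure(pdags: list[PDAG]) -> tuple[PDAG, list[dict]]:
    """Edges present with identical type and orientation in every input.

    Returns the consensus PDAG and a disagreement report listing each pair
    that is not classified identically across inputs.
    """
    if not pdags:
        raise ValueError("need at least one PDAG")
    nodes = pdags[0].nodes
    for p in pdags[1:]:
        if sorted(p.nodes) != sorted(nodes):
            raise ValueError("PDAGs do not share node labels")

    def classify(p: PDAG, a: str, b: str) -> str:
        if (a, b) in p.directed:
            return f"{a}->{b}"
        if (b, a) in p.directed:
            return f"{b}->{a}"
        if frozenset((a, b)) in p.undirected:
            return f"{a}-{b}"
        return "absent"

    directed, undirected = set(), set()
    report = []
    for a, b in combinations(sorted(nodes), 2):
        kinds = [classify(p, a, b) for p in pdags]
        if len(set(kinds)) == 1:
            kind = kinds[0]
            if kind == f"{a}->{b}":
                directed.add((a, b))
            elif kind == f"{b}->{a}":
                directed.add((b, a))
            elif kind == f"{a}-{b}":
                undirected.add(frozenset((a, b)))
        elif any(k != "absent" for k in kinds):
            orient_conflict = len({k for k in kinds if k != "absent"}) > 1
            report.append({
                "edge": f"{a}-{b}",
                "per_input": kinds,
                "kind": ("orientation_disagreement" if orient_conflict
                         else "presence_disagreement"),
            })
    return PDAG(nodes=sorted(nodes), directed=directed,
                undirected=undirected), report
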