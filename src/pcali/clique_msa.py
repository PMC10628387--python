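"""Clique-based multiple alignment seeding.

The pairwise alignments of n proteins form a graph whose nodes are residues
(protein index, residue index) and whose edges join residues aligned in
some PA. If all PAs were mutually consistent, every MSA column would be a
maximal clique of this graph. The seeder ranks nodes by a local clustering
count, grows cliques per node incrementally (keeping only the largest
``cap`` at each step), assembles mutually order-consistent cliques greedily
by decreasing size, attaches leftover residues to the column most connected
to them, and emits the resulting column order as an MSA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structio import GAP, Msa


@dataclass
class PAGraph:
    """Residue-level graph of pairwise alignments.

    A residue has at most one link into each other protein, so node degree
    is bounded by n-1 for n proteins.
    """

    n: int
    lengths: list
    adj: dict = field(default_factory=dict)

    def nodes(self):
        return [(p, r) for p in range(self.n) for r in range(self.lengths[p])]

    def neighbors(self, v):
        return self.adj.get(v, set())


def build_graph(pas, ids: list, lengths: list) -> PAGraph:
    """Edges for every aligned column of every PA (one PA per protein pair;
    a conflicting duplicate raises)."""
    index = {name: k for k, name in enumerate(ids)}
    g = PAGraph(n=len(ids), lengths=list(lengths))
    g.adj = {v: set() for v in g.nodes()}
    seen = {}
    for pa in pas:
        p, q = index[pa.id1], index[pa.id2]
        key = (min(p, q), max(p, q))
        pairs = frozenset(pa.aligned_pairs if p < q
                          else [(j, i) for i, j in pa.aligned_pairs])
        if key in seen:
            if seen[key] != pairs:
                raise ValueError(f"conflicting duplicate PA for pair {key}")
            continue
        seen[key] = pairs
        a, b = key
        for i, j in pairs:
            g.adj[(a, i)].add((b, j))
            g.adj[(b, j)].add((a, i))
    return g


def clustering_coefficients(g: PAGraph) -> dict:
    """Per node, the number of unordered neighbor pairs that are themselves
    adjacent."""
    out = {}
    for v in g.nodes():
        nb = sorted(g.neighbors(v))
        c = 0
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                if nb[b] in g.neighbors(nb[a]):
                    c += 1
        out[v] = c
    return out


def cliques_for_node(g: PAGraph, v, cap: int = 100) -> list:
    """Incremental clique growth over v's neighbor list.

    Each successive neighbor joins every clique it is fully linked to,
    otherwise it seeds a new clique with v and the previously processed
    neighbors compatible with it; after each step only the ``cap`` largest
    cliques survive (size ties keep the earlier-created). Returns the final
    clique list, deduplicated, as frozensets.
    """
    nb = sorted(g.neighbors(v))
    if not nb:
        return []
    cliques: list[set] = [{v, nb[0]}]
    processed = [nb[0]]
    for u in nb[1:]:
        joined = False
        for cl in cliques:
            if all(u in g.neighbors(w) for w in cl):
                cl.add(u)
                joined = True
        if not joined:
            # seed from {v, u} plus earlier neighbors still fully linked
            new = {v, u}
            for w in processed:
                if all(w in g.neighbors(x) for x in new):
                    new.add(w)
            cliques.append(new)
        processed.append(u)
        if len(cliques) > cap:
            cliques = sorted(cliques, key=lambda c: -len(c))[:cap]
    uniq = []
    seen = set()
    for cl in cliques:
        f = frozenset(cl)
        if f not in seen:
            seen.add(f)
            uniq.append(f)
    return uniq


def enumerate_all(g: PAGraph, cap: int = 100) -> list:
    """Cliques over all nodes in clustering-coefficient order with the n/2
    exclusion: a node already stored in a clique larger than n/2, or whose
    stored clique sizes sum beyond n/2, is skipped as a seed."""
    coeff = clustering_coefficients(g)
    ranking = sorted(g.nodes(), key=lambda v: (-coeff[v], v))
    half = g.n / 2.0
    max_size = {v: 0 for v in g.nodes()}
    sum_size = {v: 0 for v in g.nodes()}
    out, seen = [], set()
    for v in ranking:
        if max_size[v] > half or sum_size[v] > half:
            continue
        for cl in cliques_for_node(g, v, cap=cap):
            if cl not in seen:
                seen.add(cl)
                out.append(cl)
            for m in cl:
                max_size[m] = max(max_size[m], len(cl))
                sum_size[m] += len(cl)
    return out


# ---------------------------------------------------------------------------
# Assembly

def _bounds(columns: list, p: int, r: int) -> tuple:
    """(lb, ub): indices bracketing where a column holding residue r of
    protein p may sit in the current column order."""
    lb, ub = -1, len(columns)
    for idx, col in enumerate(columns):
        if p in col:
            if col[p] < r:
                lb = max(lb, idx)
            elif col[p] > r:
                ub = min(ub, idx)
    return lb, ub


def assemble_msa(cliques: list, g: PAGraph, sequences: list, names: list,
                 coeff: dict | None = None) -> Msa:
    """Greedy assembly of order-consistent cliques into MSA columns.

    Cliques are accepted in decreasing size (ties: larger summed clustering
    coefficient, then lexicographic member order) if their residues are
    still unused and a consistent slot exists in the maintained column
    order. Orphan residues then attach to the accepted column with most
    links to them when order-consistent (ties leftmost), else seed a
    singleton column.
    """
    if coeff is None:
        coeff = clustering_coefficients(g)
    ranked = sorted(cliques, key=lambda c: (-len(c),
                                            -sum(coeff.get(m, 0) for m in c),
                                            sorted(c)))
    columns: list[dict] = []
    used = set()
    for cl in ranked:
        members = sorted(cl)
        if any(m in used for m in members):
            continue
        if len({p for p, _ in members}) != len(members):
            continue  # two residues of one protein can never share a column
        lb, ub = -1, len(columns)
        ok = True
        for p, r in members:
            l, u = _bounds(columns, p, r)
            lb, ub = max(lb, l), min(ub, u)
        if lb >= ub:
            continue
        columns.insert(lb + 1, {p: r for p, r in members})
        used.update(members)

    # orphans: most-connected consistent column, else a fresh singleton
    for p in range(g.n):
        for r in range(g.lengths[p]):
            v = (p, r)
            if v in used:
                continue
            lb, ub = _bounds(columns, p, r)
            best, best_links, best_idx = None, 0, None
            for idx in range(lb + 1, ub):
                col = columns[idx]
                if p in col:
                    continue
                links = sum(1 for m in col.items() if m in g.neighbors(v))
                if links > best_links:
                    best, best_links, best_idx = col, links, idx
            if best is not None:
                best[p] = r
            else:
                columns.insert(lb + 1, {p: r})
            used.add(v)

    order = _topo_order(columns, g.n, g.lengths)
    rows = []
    for p in range(g.n):
        row = []
        for idx in order:
            col = columns[idx]
            row.append(sequences[p][col[p]] if p in col else GAP)
        rows.append("".join(row))
    msa = Msa(list(names), rows)
    for p in range(g.n):
        assert msa.ungapped(p) == sequences[p], "residue conservation violated"
    return msa


def _topo_order(columns: list, n: int, lengths: list) -> list:
    """Topological order of columns under per-protein residue precedence;
    mutually unordered columns sort by average normalized residue position."""
    import heapq

    k = len(columns)
    succ = [set() for _ in range(k)]
    indeg = [0] * k
    for p in range(n):
        holders = sorted(((columns[idx][p], idx) for idx in range(k)
                          if p in columns[idx]))
        for (_, a), (_, b) in zip(holders, holders[1:]):
            if b not in succ[a]:
                succ[a].add(b)
                indeg[b] += 1

    def avg_pos(idx):
        col = columns[idx]
        return sum(r / max(lengths[p], 1) for p, r in col.items()) / len(col)

    heap = [(avg_pos(i), i) for i in range(k) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        _, i = heapq.heappop(heap)
        order.append(i)
        for j in succ[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(heap, (avg_pos(j), j))
    assert len(order) == k, "cyclic column order after assembly"
    return order


def clique_msa(structures, pas, cap: int = 100) -> Msa:
    """Seed MSA from the maximal cliques of the PA graph of ``pas``."""
    ids = [s.id for s in structures]
    lengths = [len(s) for s in structures]
    g = build_graph(pas, ids, lengths)
    coeff = clustering_coefficients(g)
    cliques = enumerate_all(g, cap=cap)
    return assemble_msa(cliques, g, [s.sequence for s in structures], ids,
                        coeff=coeff)
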