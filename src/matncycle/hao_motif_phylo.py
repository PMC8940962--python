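"""HAO-family protein classification by active-site motif and phylogeny.

Hydroxylamine dehydrogenase (HAO, EC 1.7.2.6) proteins of aerobic
ammonia-oxidizing bacteria carry a tyrosine that cross-links the active site
to the catalytic heme of the adjacent subunit; its presence is associated
with oxidative catalysis, its absence with reductive catalysis. The εHao
subfamily of Campylobacterota instead carries a tryptophan at the equivalent
position plus a conserved methionine eight residues upstream.

The pipeline here: (1) map the annotated key-tyrosine position of the
reference alignment's anchor row to an alignment column; (2) align each
query protein to the reference alignment treated as a frozen profile
(position-specific BLOSUM62 scores, affine gaps, reference columns
immutable); (3) read the anchor-column residue of the aligned query and call
the class; (4) place queries on a neighbor-joining p-distance tree with the
labeled references and assign the nearest single-class clade.

The packaged reference alignment is a synthetic stand-in that reproduces the
motif structure of the real reference set (AOB and anammox HAO, εHao,
nitrate-reductase-like rows); load your own alignment + sidecar for real use.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.Align import substitution_matrices

from .io import read_fasta

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_BLOSUM = substitution_matrices.load("BLOSUM62")


@dataclass
class ReferenceAlignment:
    rows: list                 # [(id, aligned sequence), ...], equal lengths
    anchor_ref: str            # id of the row carrying the annotated anchor
    anchor_pos: int            # 1-based ungapped position of the key tyrosine
    class_labels: dict         # id -> reference class label

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("reference alignment rows have unequal lengths")
        ids = [i for i, _ in self.rows]
        if self.anchor_ref not in ids:
            raise ValueError(f"anchor reference {self.anchor_ref!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])


@dataclass
class AlignedQuery:
    query_id: str
    query: str                 # original ungapped sequence
    row: str                   # gapped row over the reference columns
    insertions: dict           # columns-consumed -> inserted residues
    score: float
    col_to_query_idx: dict     # 1-based column -> 0-based query index


@dataclass
class MotifCall:
    query_id: str
    anchor_column_residue: str
    met_minus8: bool
    call: str                  # oxidative-HAO-like | epsilonHao-like | ambiguous


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # [(TreeNode, branch length)]

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        def rec(node):
            if not node.children:
                return node.name
            inner = ",".join(f"{rec(c)}:{bl:.8g}" for c, bl in node.children)
            return f"({inner})"

        return rec(self) + ";"


@dataclass
class TreeResult:
    newick: str
    root: TreeNode
    leaves: list


def load_reference(fasta_path, sidecar_path) -> ReferenceAlignment:
    """Load a reference alignment FASTA plus its YAML anchor/label sidecar."""
    rows = read_fasta(fasta_path)
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    return ReferenceAlignment(
        rows=rows,
        anchor_ref=meta["anchor_ref"],
        anchor_pos=int(meta["anchor_pos"]),
        class_labels=dict(meta["class_labels"]),
    )


def load_packaged_reference() -> ReferenceAlignment:
    """Load the packaged synthetic HAO reference alignment."""
    data = importlib.resources.files("matncycle") / "data"
    return load_reference(
        str(data / "synthetic_hao_refs.afa"), str(data / "synthetic_hao_refs.yaml")
    )


def map_anchor_column(refaln: ReferenceAlignment) -> int:
    """Alignment column (1-based) of the anchor row's Nth non-gap residue."""
    aligned = dict(refaln.rows)[refaln.anchor_ref]
    count = 0
    for col, res in enumerate(aligned, start=1):
        if res != GAP:
            count += 1
            if count == refaln.anchor_pos:
                return col
    raise ValueError(
        f"anchor position {refaln.anchor_pos} beyond the {count} residues of "
        f"{refaln.anchor_ref!r}"
    )


def _profile_scores(refaln: ReferenceAlignment) -> np.ndarray:
    """(L, |AA20|) position-specific scores: BLOSUM62 averaged over column
    residue frequencies (gaps excluded)."""
    L = refaln.length
    freqs = np.zeros((L, len(AA20)))
    aa_idx = {a: i for i, a in enumerate(AA20)}
    for _, seq in refaln.rows:
        for col, res in enumerate(seq):
            if res in aa_idx:
                freqs[col, aa_idx[res]] += 1
    totals = freqs.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs /= totals
    blo = np.array([[float(_BLOSUM[a][b]) for b in AA20] for a in AA20])
    return freqs @ blo.T  # scores[col, query-aa-index]


def align_query_to_reference(
    query_id: str, query: str, refaln: ReferenceAlignment
) -> AlignedQuery:
    """Global alignment of a query against the frozen reference profile.

    Three-state affine-gap Needleman-Wunsch over the reference columns:
    deletions put gaps in the query row; insertions (query residues falling
    between reference columns) are recorded separately and never disturb
    column indexing. A gap of length k costs GAP_OPEN + k * GAP_EXTEND.
    """
    if not query:
        raise ValueError("empty query sequence")
    query = query.upper()
    aa_idx = {a: i for i, a in enumerate(AA20)}
    scores = _profile_scores(refaln)
    L, q = refaln.length, len(query)
    NEG = -1e18

    def s(i, j):  # column i (1-based), residue j (1-based)
        res = query[j - 1]
        if res in aa_idx:
            return scores[i - 1, aa_idx[res]]
        return 0.0  # X / nonstandard residue: neutral

    M = np.full((L + 1, q + 1), NEG)
    D = np.full((L + 1, q + 1), NEG)
    I = np.full((L + 1, q + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, L + 1):
        D[i, 0] = -(GAP_OPEN + GAP_EXTEND * i)
    for j in range(1, q + 1):
        I[0, j] = -(GAP_OPEN + GAP_EXTEND * j)
    for i in range(1, L + 1):
        for j in range(1, q + 1):
            M[i, j] = s(i, j) + max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            D[i, j] = max(
                M[i - 1, j] - (GAP_OPEN + GAP_EXTEND),
                D[i - 1, j] - GAP_EXTEND,
                I[i - 1, j] - (GAP_OPEN + GAP_EXTEND),
            )
            I[i, j] = max(
                M[i, j - 1] - (GAP_OPEN + GAP_EXTEND),
                I[i, j - 1] - GAP_EXTEND,
                D[i, j - 1] - (GAP_OPEN + GAP_EXTEND),
            )
    # traceback from the best terminal state
    state = max(("M", "D", "I"), key=lambda st: {"M": M, "D": D, "I": I}[st][L, q])
    i, j = L, q
    row = []
    insertions: dict[int, str] = {}
    col_to_query = {}
    while i > 0 or j > 0:
        if state == "M":
            row.append(query[j - 1])
            col_to_query[i] = j - 1
            prev = max(
                ("M", "D", "I"), key=lambda st: {"M": M, "D": D, "I": I}[st][i - 1, j - 1]
            )
            i, j = i - 1, j - 1
        elif state == "D":
            row.append(GAP)
            cand = {
                "M": M[i - 1, j] - (GAP_OPEN + GAP_EXTEND),
                "D": D[i - 1, j] - GAP_EXTEND,
                "I": I[i - 1, j] - (GAP_OPEN + GAP_EXTEND),
            }
            prev = max(cand, key=cand.get)
            i = i - 1
        else:  # insertion between columns i and i+1
            insertions[i] = query[j - 1] + insertions.get(i, "")
            cand = {
                "M": M[i, j - 1] - (GAP_OPEN + GAP_EXTEND),
                "I": I[i, j - 1] - GAP_EXTEND,
                "D": D[i, j - 1] - (GAP_OPEN + GAP_EXTEND),
            }
            prev = max(cand, key=cand.get)
            j = j - 1
        if i == 0 and j == 0:
            break
        state = prev
    return AlignedQuery(
        query_id=query_id,
        query=query,
        row="".join(reversed(row)),
        insertions=insertions,
        score=float(max(M[L, q], D[L, q], I[L, q])),
        col_to_query_idx=col_to_query,
    )


def classify_hao(aligned: AlignedQuery, anchor_col: int) -> MotifCall:
    """Call the HAO class from the residue at the anchor column.

    Tyrosine -> oxidative-HAO-like. Tryptophan -> epsilonHao-like, with the
    methionine checked eight residues before the tryptophan in the query's
    own (ungapped) coordinates and reported as ``met_minus8``. A gap, X, or
    any other residue -> ambiguous.
    """
    if anchor_col < 1 or anchor_col > len(aligned.row):
        raise ValueError(f"anchor column {anchor_col} beyond alignment")
    res = aligned.row[anchor_col - 1]
    if res == "Y":
        return MotifCall(aligned.query_id, res, False, "oxidative-HAO-like")
    if res == "W":
        qi = aligned.col_to_query_idx[anchor_col]
        met = qi >= 8 and aligned.query[qi - 8] == "M"
        return MotifCall(aligned.query_id, res, met, "epsilonHao-like")
    return MotifCall(aligned.query_id, res, False, "ambiguous")


def pdistance_matrix(rows: list) -> pd.DataFrame:
    """Pairwise p-distance: mismatches over columns without a gap in either."""
    if len(rows) < 3:
        raise ValueError("need at least 3 aligned sequences")
    ids = [i for i, _ in rows]
    seqs = [np.frombuffer(s.encode(), dtype="S1") for _, s in rows]
    n = len(ids)
    d = np.zeros((n, n))
    gap = GAP.encode()
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(f"no comparable columns for pair ({ids[i]}, {ids[j]})")
            d[i, j] = d[j, i] = float((seqs[i][ok] != seqs[j][ok]).mean())
    return pd.DataFrame(d, index=ids, columns=ids)


def nj_tree(dist: pd.DataFrame) -> TreeResult:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The minimum-Q pair is chosen; ties break lexicographically on the sorted
    member-name tuples of the candidate pair. Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch (their sum
    stays equal to the pair distance). The root is the final trifurcation.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # active clusters keyed by sorted leaf-name tuple
    active = {(name,): TreeNode(name=name) for name in labels}
    d = {
        (a,): {(b,): float(dist.loc[a, b]) for b in labels if b != a} for a in labels
    }

    def clamp(la, lb):
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 3:
        n = len(active)
        keys = sorted(active)
        r = {k: sum(d[k][m] for m in keys if m != k) for k in keys}
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                qv = (n - 2) * d[a][b] - r[a] - r[b]
                cand = (qv, (a, b))
                if best is None or cand < best:
                    best = cand
        _, (a, b) = best
        la = d[a][b] / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        la, lb = clamp(la, lb)
        u = tuple(sorted(a + b))
        node = TreeNode(children=[(active[a], la), (active[b], lb)])
        new_d = {}
        for k in keys:
            if k in (a, b):
                continue
            new_d[k] = (d[a][k] + d[b][k] - d[a][b]) / 2
        del active[a], active[b]
        for k in list(d):
            d[k].pop(a, None)
            d[k].pop(b, None)
        d.pop(a), d.pop(b)
        for k, v in new_d.items():
            d[k][u] = v
        d[u] = dict(new_d)
        active[u] = node
    # final three-point join
    (ka, kb, kc) = sorted(active)
    dab, dac, dbc = d[ka][kb], d[ka][kc], d[kb][kc]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = TreeNode(
        children=[
            (active[ka], max(la, 0.0)),
            (active[kb], max(lb, 0.0)),
            (active[kc], max(lc, 0.0)),
        ]
    )
    leaves = [leaf.name for leaf in root.leaves()]
    return TreeResult(newick=root.to_newick(), root=root, leaves=leaves)


def _adjacency(root: TreeNode):
    """Undirected (node-id keyed) adjacency with branch lengths."""
    adj: dict[int, list] = {}
    nodes: dict[int, TreeNode] = {}

    def walk(node):
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for child, bl in node.children:
            adj[id(node)].append((id(child), bl))
            adj.setdefault(id(child), []).append((id(node), bl))
            walk(child)

    walk(root)
    return adj, nodes


def midpoint_root(tree: TreeResult) -> dict:
    """Parent map of the midpoint-rooted tree.

    Finds the longest leaf-to-leaf path (ties broken lexicographically by
    leaf-name pair) and roots the topology at its midpoint, returning
    ``{node id: parent node id}`` with a synthetic root id of -1 plus the
    ``{id: TreeNode}`` map. Rooting on the deepest split is what makes
    nested-clade reading of an (unrooted) NJ tree well defined.
    """
    adj, nodes = _adjacency(tree.root)
    leaf_ids = [nid for nid, n in nodes.items() if not n.children]

    def paths_from(src):
        dist, prev = {src: 0.0}, {src: None}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, bl in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + bl
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = None
    for a in leaf_ids:
        dist, prev = paths_from(a)
        for b in leaf_ids:
            if b == a:
                continue
            key = (-dist[b], tuple(sorted((nodes[a].name, nodes[b].name))), a, b)
            if best is None or key < best[0]:
                best = (key, a, b, prev)
    (_, a, b, prev) = best
    # path b -> a; find the edge containing the midpoint
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    lengths = []
    for u, v in zip(path, path[1:]):
        bl = next(l for w, l in adj[u] if w == v)
        lengths.append(bl)
    half = sum(lengths) / 2
    acc = 0.0
    for (u, v), bl in zip(zip(path, path[1:]), lengths):
        if acc + bl >= half or (u, v) == (path[-2], path[-1]):
            mid_edge = (u, v)
            break
        acc += bl
    # root on mid_edge: parents point toward a synthetic root (-1)
    u, v = mid_edge
    parent = {u: -1, v: -1}

    def orient(src, came_from):
        for w, _ in adj[src]:
            if w != came_from and w not in parent:
                parent[w] = src
                orient(w, src)

    orient(u, v)
    orient(v, u)
    return parent, nodes


def assign_clade(tree: TreeResult, ref_labels: dict) -> dict:
    """Assign each query leaf the class of its nearest single-class clade.

    The tree is midpoint-rooted; walking rootward from the query leaf, the
    first ancestor whose clade contains at least one labeled reference
    decides: one reference class -> that class; mixed classes ->
    'unresolved'. Reference leaves keep their own label.
    """
    if not any(name in ref_labels for name in tree.leaves):
        raise ValueError("tree contains no labeled reference leaves")
    parent, nodes = midpoint_root(tree)
    children: dict[int, list] = {}
    for nid, pid in parent.items():
        children.setdefault(pid, []).append(nid)
    ref_sets: dict[int, set] = {}

    def collect(nid):
        node = nodes.get(nid)
        s = set()
        if node is not None and not node.children and node.name in ref_labels:
            s.add(ref_labels[node.name])
        for cid in children.get(nid, []):
            s |= collect(cid)
        ref_sets[nid] = s
        return s

    collect(-1)
    out = {}
    for nid, node in nodes.items():
        if node.children:
            continue
        if node.name in ref_labels:
            out[node.name] = ref_labels[node.name]
            continue
        cur = nid
        assigned = "unresolved"
        while cur in parent:
            cur = parent[cur]
            classes = ref_sets.get(cur, set())
            if classes:
                assigned = next(iter(classes)) if len(classes) == 1 else "unresolved"
                break
        out[node.name] = assigned
    return out


def classify_hao_sequences(
    queries: list, refaln: ReferenceAlignment | None = None
) -> tuple[pd.DataFrame, TreeResult, dict]:
    """Full pipeline: align, motif-call, and place queries on the NJ tree.

    Returns ``(calls table, tree, clade assignment per leaf)``.
    """
    refaln = load_packaged_reference() if refaln is None else refaln
    col = map_anchor_column(refaln)
    aligned_rows = list(refaln.rows)
    calls = []
    for qid, seq in queries:
        aq = align_query_to_reference(qid, seq, refaln)
        call = classify_hao(aq, col)
        calls.append(
            (qid, call.anchor_column_residue, call.met_minus8, call.call, aq.score)
        )
        aligned_rows.append((qid, aq.row))
    dist = pdistance_matrix(aligned_rows)
    tree = nj_tree(dist)
    clades = assign_clade(tree, refaln.class_labels)
    calls_df = pd.DataFrame(
        calls,
        columns=["query_id", "anchor_residue", "met_minus8", "call", "align_score"],
    )
    calls_df["clade"] = calls_df["query_id"].map(clades)
    return calls_df, tree, clades
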