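"""Gene trees for pucA/pucB: alignment, distances, neighbor-joining, bootstrap.

Coding sequences are aligned codon-wise (gaps only in whole-codon units)
by progressive alignment over a k-mer-distance UPGMA guide tree.  Pairwise
evolutionary distances, in substitutions per site, drop gapped/ambiguous
columns per sequence pair (pairwise deletion) and support three models:

- JC69: d = -(3/4) ln(1 - (4/3) p)
- TN93: the two-transition-rate closed form with empirical pair frequencies
- MCL:  maximum composite likelihood — the TN93 rate parameters are
  estimated once by maximizing the summed pairwise multinomial
  log-likelihood over all pairs, then each pair's distance is estimated
  under the shared parameters.

Trees come from standard neighbor-joining (Q-matrix selection,
Studier-Keppler distance update); negative branch lengths are clamped to
zero with the deficit transferred to the adjacent branch.  Bootstrap
resamples alignment columns (codon triplets for codon alignments) with
replacement and reports, per internal edge, the percentage of replicates
containing the same leaf bipartition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.distance import squareform

from .io import SeqRecord

SATURATION_NOTE = "saturated"
_ACGT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_ACGT)}


class SaturationError(ValueError):
    """A pairwise distance is at or beyond model saturation."""


# ---------------------------------------------------------------------------
# Multiple alignment


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows keyed by ordered sequence ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def take_columns(self, index: np.ndarray) -> "MultipleAlignment":
        rows = ["".join(row[j] for j in index) for row in self.rows]
        return MultipleAlignment(list(self.ids), rows)


def _kmer_set(seq: str, k: int = 4) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _codon_score(a: str, b: str) -> float:
    return sum(1.0 if x == y else -1.0 for x, y in zip(a, b))


_GAP_CODON = "---"
_GAP_COL_PENALTY = -2.0


def _profile_score(col_a: list[str], col_b: list[str]) -> float:
    total = 0.0
    n = 0
    for a in col_a:
        if a == _GAP_CODON:
            continue
        for b in col_b:
            if b == _GAP_CODON:
                continue
            total += _codon_score(a, b)
            n += 1
    return total / n if n else 0.0


def _align_profiles(prof_a: list[list[str]], prof_b: list[list[str]]):
    """Needleman-Wunsch over codon columns with a linear gap penalty."""
    la, lb = len(prof_a[0]), len(prof_b[0])
    cols_a = [[row[i] for row in prof_a] for i in range(la)]
    cols_b = [[row[j] for row in prof_b] for j in range(lb)]
    score = np.zeros((la + 1, lb + 1))
    trace = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = np.arange(la + 1) * _GAP_COL_PENALTY
    score[0, :] = np.arange(lb + 1) * _GAP_COL_PENALTY
    trace[1:, 0] = 1
    trace[0, 1:] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1, j - 1] + _profile_score(cols_a[i - 1], cols_b[j - 1])
            up = score[i - 1, j] + _GAP_COL_PENALTY
            left = score[i, j - 1] + _GAP_COL_PENALTY
            best = max(diag, up, left)
            score[i, j] = best
            trace[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback
    out_a: list[list[str]] = [[] for _ in prof_a]
    out_b: list[list[str]] = [[] for _ in prof_b]
    i, j = la, lb
    while i > 0 or j > 0:
        t = trace[i, j]
        if t == 0:
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            i, j = i - 1, j - 1
        elif t == 1:
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r in range(len(prof_b)):
                out_b[r].append(_GAP_CODON)
            i -= 1
        else:
            for r in range(len(prof_a)):
                out_a[r].append(_GAP_CODON)
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            j -= 1
    for rows in (out_a, out_b):
        for r in rows:
            r.reverse()
    return out_a, out_b


def align_codons(records: list[SeqRecord]) -> MultipleAlignment:
    """Codon-aware progressive multiple alignment of coding sequences.

    Sequences whose length is not a multiple of three are trimmed (with a
    warning); the guide tree is UPGMA over 4-mer distances; gaps are
    inserted only in whole-codon units.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences to align")
    seqs = []
    for rec in records:
        s = rec.sequence.upper()
        if len(s) % 3:
            warnings.warn(f"{rec.id}: trailing partial codon trimmed")
            s = s[: len(s) - len(s) % 3]
        seqs.append(s)
    ids = [r.id for r in records]
    n = len(seqs)
    if n == 2:
        profiles = {0: [_codons(seqs[0])], 1: [_codons(seqs[1])]}
        members = {0: [0], 1: [1]}
        pa, pb = _align_profiles(profiles[0], profiles[1])
        merged, order = pa + pb, [0, 1]
        return _finish_alignment(ids, merged, order)
    # k-mer distances -> UPGMA guide tree via scipy linkage
    kmers = [_kmer_set(s) for s in seqs]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(kmers[i] & kmers[j])
            denom = 0.5 * (len(kmers[i]) + len(kmers[j]))
            d = 1.0 - inter / denom if denom else 1.0
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, list[list[str]]] = {i: [_codons(s)] for i, s in enumerate(seqs)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        pa, pb = _align_profiles(profiles.pop(a), profiles.pop(b))
        profiles[n + step] = pa + pb
        members[n + step] = members.pop(a) + members.pop(b)
    final_key = n + len(Z) - 1
    return _finish_alignment(ids, profiles[final_key], members[final_key])


def _codons(seq: str) -> list[str]:
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def _finish_alignment(ids, profile_rows, member_order) -> MultipleAlignment:
    ordered = [None] * len(ids)
    for row, orig in zip(profile_rows, member_order):
        ordered[orig] = "".join(row)
    return MultipleAlignment(list(ids), ordered)


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Symmetric distances with per-pair usable-site counts after pairwise deletion."""

    ids: list[str]
    matrix: np.ndarray
    usable_sites: np.ndarray
    saturated: np.ndarray  # boolean mask

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    def any_saturated(self) -> bool:
        return bool(self.saturated.any())

    def saturated_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.saturated[i, j]:
                    pairs.append((self.ids[i], self.ids[j]))
        return pairs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def _pair_counts(row_a: str, row_b: str):
    """Difference-category counts over pairwise-deleted columns.

    Returns (n_usable, purine transitions, pyrimidine transitions,
    transversions, base-count vector pooled over both rows).
    """
    base_counts = np.zeros(4)
    p1 = p2 = q = usable = 0
    for a, b in zip(row_a, row_b):
        if a not in _NT_INDEX or b not in _NT_INDEX:
            continue  # pairwise deletion of gaps/ambiguity codes
        usable += 1
        base_counts[_NT_INDEX[a]] += 1
        base_counts[_NT_INDEX[b]] += 1
        if a == b:
            continue
        pair = {a, b}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    return usable, p1, p2, q, base_counts


def _jc69(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return np.nan
    return -0.75 * np.log(arg)


def _tn93_closed_form(P1: float, P2: float, Q: float, g: np.ndarray) -> float:
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    if gA * gG == 0 or gC * gT == 0 or gR * gY == 0:
        return _jc69(P1 + P2 + Q)  # degenerate composition: fall back
    c1 = 2 * gA * gG / gR
    c2 = 2 * gC * gT / gY
    c3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - P1 / c1 - Q / (2 * gR)
    w2 = 1 - P2 / c2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return np.nan
    return -c1 * np.log(w1) - c2 * np.log(w2) - c3 * np.log(w3)


def tn93_expected_proportions(d: float, k1: float, k2: float, g: np.ndarray):
    """Expected (P1, P2, Q) difference fractions at distance d under TN93.

    k1 and k2 are the purine and pyrimidine transition/transversion rate
    ratios (alpha1/beta, alpha2/beta); g the equilibrium base frequencies
    (A, C, G, T).
    """
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    # mean rate at beta = 1: mu = 2 gA gG k1 + 2 gC gT k2 + 2 gR gY
    mu = 2 * gA * gG * k1 + 2 * gC * gT * k2 + 2 * gR * gY
    t = d / mu
    e2 = np.exp(-t)  # transversion eigenvalue is -beta with Q[i,j] = rate * pi_j
    e3 = np.exp(-(gR * k1 + gY) * t)
    e4 = np.exp(-(gY * k2 + gR) * t)
    Q = 2 * gR * gY * (1 - e2)
    P1 = (2 * gA * gG / gR) * (gR + gY * e2 - e3) if gR > 0 else 0.0
    P2 = (2 * gC * gT / gY) * (gY + gR * e2 - e4) if gY > 0 else 0.0
    return P1, P2, Q


def _mcl_pair_loglik(d, counts, k1, k2, g):
    usable, n1, n2, nq = counts
    if usable == 0:
        return 0.0
    P1, P2, Q = tn93_expected_proportions(d, k1, k2, g)
    eps = 1e-12
    P1, P2, Q = max(P1, eps), max(P2, eps), max(Q, eps)
    same = max(1.0 - P1 - P2 - Q, eps)
    n_same = usable - n1 - n2 - nq
    return (n1 * np.log(P1) + n2 * np.log(P2) + nq * np.log(Q)
            + n_same * np.log(same))


def _mcl_fit_pair(counts, k1, k2, g, d_max=10.0) -> float:
    res = minimize_scalar(
        lambda d: -_mcl_pair_loglik(d, counts, k1, k2, g),
        bounds=(1e-9, d_max),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def pairwise_distance(msa: MultipleAlignment, model: str = "MCL") -> DistanceMatrix:
    """Pairwise evolutionary distances under JC69, TN93 or MCL.

    Columns with a gap or ambiguity in either member of a pair are removed
    for that pair only.  Saturated pairs (observed divergence at or beyond
    the model's invertible range) are flagged, not raised.
    """
    model = model.upper()
    if model not in ("JC69", "TN93", "MCL"):
        raise ValueError(f"unknown model {model!r}")
    n = len(msa.ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    rows = [r.upper() for r in msa.rows]
    counts = {}
    pooled = np.zeros(4)
    for i in range(n):
        for j in range(i + 1, n):
            usable, p1, p2, q, bases = _pair_counts(rows[i], rows[j])
            counts[(i, j)] = (usable, p1, p2, q, bases)
            pooled += bases
    D = np.zeros((n, n))
    usable_mat = np.zeros((n, n), dtype=np.int64)
    saturated = np.zeros((n, n), dtype=bool)

    if model == "MCL":
        g = pooled / pooled.sum() if pooled.sum() else np.full(4, 0.25)
        k1, k2 = _mcl_estimate_parameters(counts, g)
    for (i, j), (usable, p1, p2, q, bases) in counts.items():
        usable_mat[i, j] = usable_mat[j, i] = usable
        if usable == 0:
            d = np.nan
        elif model == "JC69":
            d = _jc69((p1 + p2 + q) / usable)
        elif model == "TN93":
            g_pair = bases / bases.sum()
            d = _tn93_closed_form(p1 / usable, p2 / usable, q / usable, g_pair)
        elif p1 + p2 + q == 0:
            d = 0.0
        else:
            d = _mcl_fit_pair((usable, p1, p2, q), k1, k2, g)
            # at the optimizer's ceiling the pair is effectively saturated
            if d > 9.0:
                d = np.nan
        if np.isnan(d):
            saturated[i, j] = saturated[j, i] = True
        else:
            D[i, j] = D[j, i] = d
    D[saturated] = np.nan
    return DistanceMatrix(list(msa.ids), D, usable_mat, saturated)


def _mcl_estimate_parameters(counts, g) -> tuple[float, float]:
    """Shared TN93 rate ratios maximizing the summed pairwise log-likelihood."""

    def neg_total(log_k):
        k1, k2 = np.exp(log_k)
        total = 0.0
        for (usable, p1, p2, q, _bases) in counts.values():
            if usable == 0:
                continue
            d = _mcl_fit_pair((usable, p1, p2, q), k1, k2, g)
            total += _mcl_pair_loglik(d, (usable, p1, p2, q), k1, k2, g)
        return -total

    res = minimize(
        neg_total,
        x0=np.log([2.0, 2.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 80},
    )
    k1, k2 = np.exp(res.x)
    return float(k1), float(k2)


# ---------------------------------------------------------------------------
# Trees and neighbor-joining


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        names = []
        for child in self.children:
            names.extend(child.leaf_names())
        return names


@dataclass
class Tree:
    """An unrooted tree stored with a (tri- or multifurcating) root node."""

    root: Node

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self) -> str:
        return _newick(self.root, top=True) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each is normalized as the side not containing the lexicographically
        smallest leaf, so topologically identical trees yield equal sets.
        """
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        parts = set()

        def walk(node: Node):
            names = set()
            for child in node.children:
                names |= walk(child)
            if node.is_leaf:
                names = {node.name}
            if 1 < len(names) < len(all_leaves) - 1:
                side = names if anchor not in names else all_leaves - names
                parts.add(frozenset(side))
            return names

        for child in self.root.children:
            walk(child)
        return parts

    def total_branch_length(self) -> float:
        total = 0.0

        def walk(node: Node):
            nonlocal total
            for child in node.children:
                total += child.length
                walk(child)

        walk(self.root)
        return total

    def annotate_supports(self, supports: dict[frozenset, float]) -> None:
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)

        def walk(node: Node):
            names = set()
            for child in node.children:
                names |= walk(child)
            if node.is_leaf:
                names = {node.name}
            elif 1 < len(names) < len(all_leaves) - 1:
                side = names if anchor not in names else all_leaves - names
                node.support = supports.get(frozenset(side))
            return names

        for child in self.root.children:
            walk(child)


def _fmt_branch(x: float) -> str:
    return f"{x:.10g}"


def _newick(node: Node, top: bool = False) -> str:
    if node.is_leaf:
        label = node.name.replace(" ", "_")
        return label if top else f"{label}:{_fmt_branch(node.length)}"
    inner = ",".join(_newick(c) for c in node.children)
    support = "" if node.support is None else f"{node.support:g}"
    if top:
        return f"({inner}){support}"
    return f"({inner}){support}:{_fmt_branch(node.length)}"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard neighbor-joining on a distance matrix.

    Deterministic given the matrix: ties in the Q criterion break on the
    first (row-major) minimum.  Negative branch lengths are clamped to zero
    and the deficit moved to the sister branch so path lengths are
    preserved.
    """
    if dm.any_saturated():
        pairs = ", ".join("-".join(p) for p in dm.saturated_pairs())
        raise SaturationError(f"saturated distance(s): {pairs}")
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes = [Node(name=i) for i in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # Studier-Keppler update
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # final three-way join (three-point formulas)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    la, lc = _clamp_pair(la, lc)
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root)


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    if x < 0:
        y += x
        x = 0.0
    if y < 0:
        x = max(x + y, 0.0)
        y = 0.0
    return x, y


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap(
    msa: MultipleAlignment,
    replicates: int,
    seed: int,
    model: str = "MCL",
    codon_aware: bool = True,
) -> dict[frozenset, float]:
    """Per-bipartition bootstrap support percentages for the NJ tree.

    Columns (codon triplets when *codon_aware* and the alignment length is
    a multiple of three) are resampled with replacement; the tree is rebuilt
    per replicate; support is the percentage of replicates whose NJ tree
    contains each bipartition of the original tree.  Fully reproducible for
    a fixed seed.  Saturated distances arising in a replicate are replaced
    by the replicate's largest finite distance so the replicate still
    contributes a topology.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    original = neighbor_joining(pairwise_distance(msa, model))
    target_parts = original.bipartitions()
    hits = {part: 0 for part in target_parts}
    ncol = msa.ncol
    codon_mode = codon_aware and ncol % 3 == 0
    units = ncol // 3 if codon_mode else ncol
    for _ in range(replicates):
        pick = rng.integers(0, units, size=units)
        if codon_mode:
            index = np.concatenate([np.arange(3 * u, 3 * u + 3) for u in pick])
        else:
            index = pick
        sample = msa.take_columns(index)
        dm = pairwise_distance(sample, model)
        if dm.any_saturated():
            finite = dm.matrix[~np.isnan(dm.matrix)]
            fill = finite.max() if finite.size else 1.0
            mat = np.where(np.isnan(dm.matrix), fill, dm.matrix)
            np.fill_diagonal(mat, 0.0)
            dm = DistanceMatrix(dm.ids, mat, dm.usable_sites,
                                np.zeros_like(dm.saturated))
        rep_parts = neighbor_joining(dm).bipartitions()
        for part in target_parts:
            if part in rep_parts:
                hits[part] += 1
    return {part: 100.0 * k / replicates for part, k in hits.items()}


def build_tree(
    records: list[SeqRecord],
    model: str = "MCL",
    replicates: int = 1000,
    seed: int | None = None,
    codon_aware: bool = True,
    prealigned: bool = False,
) -> tuple[Tree, DistanceMatrix, MultipleAlignment]:
    """Align, compute distances, NJ, and (optionally) bootstrap in one call."""
    if prealigned:
        msa = MultipleAlignment([r.id for r in records],
                                [r.sequence.upper() for r in records])
    else:
        msa = align_codons(records)
    dm = pairwise_distance(msa, model)
    tree = neighbor_joining(dm)
    if replicates and replicates > 0:
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        supports = bootstrap(msa, replicates, seed, model, codon_aware)
        tree.annotate_supports(supports)
    return tree, dm, msa
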