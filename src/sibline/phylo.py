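"""SNP-matrix phylogeny: IUPAC coding, p-distances, neighbor joining.

Genotypes are coded as single characters (hom-ref -> reference base,
hom-alt -> alternate base, het -> the two-base IUPAC ambiguity code,
missing -> N), invariant columns are removed as in SNP-ascertainment
workflows, and an allele-sharing p-distance feeds a Saitou-Nei
neighbor-joining tree.  Distance + NJ stands in for maximum-likelihood
inference: the biological signal of interest — strain samples
clustering together, inbred strains on shorter branches — is fully
recoverable by distance methods at this scale.

Per-site distance cost between two genotype characters:
0 if identical, 1 if their implied base sets are disjoint, 0.5 if
they share exactly one base (het vs hom of a shared allele, or two
hets sharing one allele) — the expected allele-sharing mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "GenotypeAlignment",
    "TreeNode",
    "Tree",
    "alignment_from_genotypes",
    "remove_invariant_sites",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "write_phylip",
    "read_phylip",
]

IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_CHAR_SETS = {v: k for k, v in IUPAC_CODES.items()}
_CHAR_SETS["N"] = frozenset("ACGT")

_ALPHABET = "ACGTRYSWKMN"
_CHAR_TO_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_N_CODE = _CHAR_TO_CODE["N"]

# cost lookup: identical -> 0, disjoint base sets -> 1, one shared -> 0.5
_COST = np.zeros((len(_ALPHABET), len(_ALPHABET)))
for _a, _i in _CHAR_TO_CODE.items():
    for _b, _j in _CHAR_TO_CODE.items():
        if _a == _b:
            _COST[_i, _j] = 0.0
        elif _CHAR_SETS[_a].isdisjoint(_CHAR_SETS[_b]):
            _COST[_i, _j] = 1.0
        else:
            _COST[_i, _j] = 0.5


@dataclass
class GenotypeAlignment:
    """Samples x sites character matrix (int-coded over ACGTRYSWKMN)."""

    samples: list[str]
    codes: np.ndarray  # (n_samples, n_sites) uint8 into _ALPHABET

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def chars(self) -> list[str]:
        """Rows as character strings (for PHYLIP output)."""
        return ["".join(_ALPHABET[c] for c in row) for row in self.codes]


class NonSnpRecordError(ValueError):
    pass


def alignment_from_genotypes(table) -> tuple[GenotypeAlignment, int]:
    """IUPAC-code a :class:`~sibline.hetmetrics.VariantTable`.

    Returns the alignment and the number of rejected (non single-base)
    records.
    """
    from .hetmetrics import GT_HET, GT_HOM_ALT, GT_HOM_REF

    n_samples = len(table.samples)
    cols = []
    rejected = 0
    for k in range(table.n_sites):
        ref, alt = str(table.ref[k]), str(table.alt[k])
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            rejected += 1
            continue
        het_char = IUPAC_CODES[frozenset((ref, alt))]
        lut = {
            GT_HOM_REF: _CHAR_TO_CODE[ref],
            GT_HOM_ALT: _CHAR_TO_CODE[alt],
            GT_HET: _CHAR_TO_CODE[het_char],
        }
        col = np.full(n_samples, _N_CODE, dtype=np.uint8)
        for gt_val, code in lut.items():
            col[table.gt[k] == gt_val] = code
        cols.append(col)
    codes = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((n_samples, 0), dtype=np.uint8)
    )
    return GenotypeAlignment(samples=list(table.samples), codes=codes), rejected


def remove_invariant_sites(aln: GenotypeAlignment) -> tuple[GenotypeAlignment, int]:
    """Drop columns whose non-N characters imply < 2 distinct bases.

    Ambiguity codes count for both of their bases, so a column of
    {A, A, R} is variable (R implies A and G) while {A, N, N} is not.
    """
    if aln.n_sites == 0:
        raise ValueError("empty alignment")
    # base incidence per column via a code -> base-set membership table
    member = np.zeros((len(_ALPHABET), 4), dtype=bool)
    for ch, i in _CHAR_TO_CODE.items():
        if ch == "N":
            continue
        for b in _CHAR_SETS[ch]:
            member[i, "ACGT".index(b)] = True
    incidence = member[aln.codes].any(axis=0)  # (n_sites, 4)
    variable = incidence.sum(axis=1) >= 2
    removed = int((~variable).sum())
    if not variable.any():
        raise ValueError("all columns invariant; nothing left to analyse")
    return (
        GenotypeAlignment(samples=aln.samples, codes=aln.codes[:, variable]),
        removed,
    )


def pairwise_distance(aln: GenotypeAlignment) -> np.ndarray:
    """Allele-sharing p-distance matrix over comparable (non-N) sites."""
    n = len(aln.samples)
    if n < 2:
        raise ValueError("need >= 2 samples")
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = aln.codes[i], aln.codes[j]
        usable = (a != _N_CODE) & (b != _N_CODE)
        m = int(usable.sum())
        if m == 0:
            raise ValueError(
                f"no comparable sites between {aln.samples[i]} and {aln.samples[j]}"
            )
        d = float(_COST[a[usable], b[usable]].mean())
        D[i, j] = D[j, i] = d
    return D


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # edge to parent
    support: float | None = None
    children: list["TreeNode"] = None

    def __post_init__(self):
        if self.children is None:
            self.children = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.name])
        out = frozenset()
        for c in self.children:
            out |= c.leaf_names()
        return out


@dataclass
class Tree:
    """Unrooted tree (root is an arbitrary internal vertex of degree 3)."""

    root: TreeNode
    clamped_deficit: float = 0.0  # total negative branch length set to 0

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(n):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the leaf set of the child side."""
        all_leaves = self.root.leaf_names()
        out = set()

        def walk(n):
            for c in n.children:
                side = c.leaf_names()
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(_canonical_split(side, all_leaves))
                walk(c)

        walk(self.root)
        return out

    def newick(self, include_support: bool = False) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if include_support and n.support is not None:
                label = f"{n.support:g}"
            return f"({inner}){label}:{n.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic distances between leaves (for round-trip checks)."""
        names: list[str] = []
        paths: dict[str, list[TreeNode]] = {}

        def walk(n, path):
            if n.is_leaf:
                names.append(n.name)
                paths[n.name] = path + [n]
            for c in n.children:
                walk(c, path + [n])

        walk(self.root, [])
        n = len(names)
        D = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            pi, pj = paths[names[i]], paths[names[j]]
            k = 0
            while k < min(len(pi), len(pj)) and pi[k] is pj[k]:
                k += 1
            d = sum(x.length for x in pi[k:]) + sum(x.length for x in pj[k:])
            D[i, j] = D[j, i] = d
        return names, D


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Orient a split away from the lexicographically first leaf."""
    anchor = min(all_leaves)
    return frozenset(all_leaves - side) if anchor in side else frozenset(side)


def neighbor_joining(D: np.ndarray, labels: list[str]) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the smallest (i, j) index pair;
    negative intermediate branch lengths are clamped to zero with the
    total deficit recorded on the returned tree.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix/label size mismatch")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    nodes = [TreeNode(name=lab) for lab in labels]
    if n == 1:
        return Tree(root=nodes[0])
    if n == 2:
        # a single edge of length d, displayed as two half-edges
        root = TreeNode(children=nodes)
        nodes[0].length = D[0, 1] / 2
        nodes[1].length = D[0, 1] / 2
        return Tree(root=root)

    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li_raw = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        nodes[i].length = clamp(li_raw)
        nodes[j].length = clamp(dij - li_raw)
        new = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new vertex to the remaining taxa
        new_row = np.zeros(len(D) + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # three-leaf star: solve the three edge lengths exactly
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return Tree(root=root, clamped_deficit=deficit)


def bootstrap_support(
    aln: GenotypeAlignment,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[Tree, dict[frozenset, float]]:
    """Site-resampling bootstrap over the distance + NJ pipeline.

    Columns are resampled with replacement, the tree rebuilt per
    replicate, and each original bipartition scored by the percentage
    of replicate trees containing it.  Supports are also attached to
    the internal nodes of the returned (original-data) tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(pairwise_distance(aln), aln.samples)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.n_sites, aln.n_sites)
        rep = GenotypeAlignment(samples=aln.samples, codes=aln.codes[:, cols])
        rep_tree = neighbor_joining(pairwise_distance(rep), rep.samples)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}

    all_leaves = tree.root.leaf_names()

    def annotate(n):
        for c in n.children:
            if not c.is_leaf:
                side = c.leaf_names()
                if 1 < len(side) < len(all_leaves) - 1:
                    c.support = supports[_canonical_split(side, all_leaves)]
            annotate(c)

    annotate(tree.root)
    return tree, supports


def write_phylip(path: str, aln: GenotypeAlignment) -> None:
    """Relaxed PHYLIP (name, space, sequence)."""
    with open(path, "w") as fh:
        fh.write(f"{len(aln.samples)} {aln.n_sites}\n")
        for name, row in zip(aln.samples, aln.chars()):
            fh.write(f"{name} {row}\n")


def read_phylip(path: str) -> GenotypeAlignment:
    with open(path) as fh:
        header = fh.readline().split()
        n, m = int(header[0]), int(header[1])
        samples, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split()
            if len(seq) != m:
                raise ValueError(f"sequence length != {m} for {name}")
            samples.append(name)
            rows.append([_CHAR_TO_CODE[c] for c in seq])
    if len(samples) != n:
        raise ValueError("sample count does not match header")
    return GenotypeAlignment(
        samples=samples, codes=np.asarray(rows, dtype=np.uint8)
    )
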