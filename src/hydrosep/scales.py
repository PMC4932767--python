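"""Hydrophobicity scales: parsing, transformation, comparison and clustering.

A hydrophobicity scale assigns each of the 20 standard amino acids a real
number.  Scales are compared through the Pearson correlation r of their 20
paired values; the dissimilarity sqrt(1 - r^2) treats a scale and its sign
inversion as identical (r = -1 gives dissimilarity 0), which is the desired
behaviour because an inverted scale ranks residues identically up to
orientation.  Scales are clustered with UPGMA (average linkage) on that
dissimilarity and the ultrametric tree is cut at a join-height threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The 20 standard amino acids in alphabetical one-letter order.  All vector
#: representations of a scale use this order.
AA_ALPHABETICAL = "ACDEFGHIKLMNPQRSTVWY"

#: Residue order of the `I` line of an AAindex flat-file entry
#: (A R N D C Q E G H I / L K M F P S T W Y V).
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

CATEGORIES = ("experimental", "calculated", "improved", "inverted", "random", "evolved")

DEFAULT_CLUSTER_THRESHOLD = 0.05
#: Alternative threshold mentioned in some summaries of the clustering; kept
#: as a named constant so configs can select it explicitly.
ALT_CLUSTER_THRESHOLD = 0.07


class ScaleError(ValueError):
    """Base class for scale construction/parsing problems."""


class ScaleParseError(ScaleError):
    pass


class DegenerateScaleError(ScaleError):
    """Raised when an operation is undefined for a constant scale."""


@dataclass(frozen=True)
class HydrophobicityScale:
    """A 20-entry amino-acid -> hydrophobicity map with provenance.

    Parameters
    ----------
    id : str
        Short unique identifier (e.g. an AAindex accession).
    name : str
        Free-text description.
    category : str
        One of ``experimental, calculated, improved, inverted, random,
        evolved``.
    values : mapping
        One finite real per standard one-letter amino-acid code.
    """

    id: str
    name: str
    category: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ScaleError(f"scale {self.id!r}: unknown category {self.category!r}")
        keys = set(self.values)
        expected = set(AA_ALPHABETICAL)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            n_ok = len(expected & keys)
            msg = f"scale {self.id!r}: {n_ok} of 20 amino acids present"
            if missing:
                msg += f"; missing {','.join(missing)}"
            if extra:
                msg += f"; unexpected {','.join(extra)}"
            raise ScaleError(msg)
        vals = [float(self.values[a]) for a in AA_ALPHABETICAL]
        if not all(math.isfinite(v) for v in vals):
            raise ScaleError(f"scale {self.id!r}: non-finite value")
        if len(set(vals)) < 2:
            raise DegenerateScaleError(f"scale {self.id!r}: constant (degenerate) scale")
        # freeze a plain dict so the dataclass is safely hashable by id
        object.__setattr__(self, "values", {a: float(self.values[a]) for a in AA_ALPHABETICAL})

    def as_vector(self) -> np.ndarray:
        """Values as a length-20 array in alphabetical amino-acid order."""
        return np.array([self.values[a] for a in AA_ALPHABETICAL], dtype=float)

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


# ---------------------------------------------------------------------------
# parsing

def parse_scale_table(source: str, dialect: str) -> list[HydrophobicityScale]:
    """Parse one or more scales from flat text.

    Two dialects are supported: ``aaindex_flat`` (H/D/I lines, 20 numbers in
    AAindex residue order, entries terminated by ``//``) and ``two_column``
    (records introduced by a ``#id:`` header, one ``AA<TAB>value`` line per
    residue, optional ``#name:`` / ``#category:`` metadata lines).
    """
    if dialect == "aaindex_flat":
        scales = _parse_aaindex(source)
    elif dialect == "two_column":
        scales = _parse_two_column(source)
    else:
        raise ScaleParseError(f"unknown dialect {dialect!r}")
    seen: set[str] = set()
    for s in scales:
        if s.id in seen:
            raise ScaleParseError(f"duplicate scale id {s.id!r}")
        seen.add(s.id)
    return scales


def _parse_two_column(source: str) -> list[HydrophobicityScale]:
    scales: list[HydrophobicityScale] = []
    cur_id: str | None = None
    cur_name = ""
    cur_cat = "experimental"
    cur_vals: dict[str, float] = {}

    def flush() -> None:
        nonlocal cur_id, cur_name, cur_cat, cur_vals
        if cur_id is None:
            return
        try:
            scales.append(HydrophobicityScale(cur_id, cur_name or cur_id, cur_cat, cur_vals))
        except ScaleError as e:
            raise ScaleParseError(str(e)) from e
        cur_id, cur_name, cur_cat, cur_vals = None, "", "experimental", {}

    for lineno, raw in enumerate(source.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#id:"):
            flush()
            cur_id = line[4:].strip()
            cur_vals = {}
        elif line.startswith("#name:"):
            cur_name = line[6:].strip()
        elif line.startswith("#category:"):
            cur_cat = line[10:].strip()
        elif line.startswith("#"):
            continue
        else:
            if cur_id is None:
                raise ScaleParseError(f"line {lineno}: value line before any '#id:' header")
            parts = line.split()
            if len(parts) != 2:
                raise ScaleParseError(f"line {lineno}: expected 'AA value', got {line!r}")
            aa, sval = parts
            if aa in cur_vals:
                raise ScaleParseError(f"scale {cur_id!r}: duplicate amino acid {aa!r}")
            try:
                cur_vals[aa] = float(sval)
            except ValueError as e:
                raise ScaleParseError(
                    f"scale {cur_id!r}: non-numeric value {sval!r} for {aa!r}"
                ) from e
    flush()
    return scales


def _parse_aaindex(source: str) -> list[HydrophobicityScale]:
    scales: list[HydrophobicityScale] = []
    cur: dict[str, str] = {}
    numbers: list[float] = []
    reading_values = False
    for lineno, raw in enumerate(source.splitlines(), 1):
        if raw.startswith("//"):
            if cur.get("H"):
                if len(numbers) != 20:
                    raise ScaleParseError(
                        f"scale {cur['H']!r}: {len(numbers)} of 20 amino acids"
                    )
                vals = dict(zip(AAINDEX_ORDER, numbers))
                try:
                    scales.append(
                        HydrophobicityScale(
                            cur["H"], cur.get("D", cur["H"]),
                            cur.get("category", "experimental"), vals,
                        )
                    )
                except ScaleError as e:
                    raise ScaleParseError(str(e)) from e
            cur, numbers, reading_values = {}, [], False
        elif raw.startswith("H "):
            cur["H"] = raw[2:].strip()
            reading_values = False
        elif raw.startswith("D "):
            cur["D"] = raw[2:].strip()
            reading_values = False
        elif raw.startswith("I "):
            reading_values = True
        elif raw[:1] == " " and reading_values:
            for tok in raw.split():
                if tok in ("NA", "-"):
                    raise ScaleParseError(
                        f"scale {cur.get('H', '?')!r}: missing value ({tok}) on line {lineno}"
                    )
                try:
                    numbers.append(float(tok))
                except ValueError as e:
                    raise ScaleParseError(
                        f"scale {cur.get('H', '?')!r}: non-numeric value {tok!r}"
                    ) from e
        else:
            reading_values = False
    if cur.get("H"):
        raise ScaleParseError(f"scale {cur['H']!r}: unterminated entry (missing '//')")
    return scales


def builtin_scales() -> list[HydrophobicityScale]:
    """Well-known published scales bundled with the package (two-column file)."""
    text = resources.files("hydrosep.data").joinpath("scales_builtin.txt").read_text()
    return parse_scale_table(text, "two_column")


# ---------------------------------------------------------------------------
# transforms & comparison

def reverse_scale(s: HydrophobicityScale) -> HydrophobicityScale:
    """Sign-invert every value (an algebraically reversed scale)."""
    return HydrophobicityScale(
        id=s.id[:-4] if s.id.endswith("_rev") else s.id + "_rev",
        name=s.name + " (reversed)" if not s.id.endswith("_rev") else s.name.replace(" (reversed)", ""),
        category="inverted",
        values={a: -v for a, v in s.values.items()},
    )


def minmax_normalize(s: HydrophobicityScale) -> HydrophobicityScale:
    """Affinely map the values onto [0, 1] via (x - min) / (max - min)."""
    v = s.as_vector()
    lo, hi = v.min(), v.max()
    if hi == lo:  # unreachable through the constructor, kept for safety
        raise DegenerateScaleError(f"scale {s.id!r}: constant scale cannot be normalized")
    return HydrophobicityScale(
        id=s.id, name=s.name, category=s.category,
        values={a: (x - lo) / (hi - lo) for a, x in s.values.items()},
    )


def scale_dissimilarity(a: HydrophobicityScale, b: HydrophobicityScale) -> float:
    """sqrt(1 - r^2) with r the Pearson correlation of the 20 paired values."""
    va, vb = a.as_vector(), b.as_vector()
    if va.std() == 0 or vb.std() == 0:
        raise DegenerateScaleError("correlation undefined for a constant scale")
    r = float(np.corrcoef(va, vb)[0, 1])
    r = min(1.0, max(-1.0, r))
    return math.sqrt(max(0.0, 1.0 - r * r))


def dissimilarity_matrix(scales: Sequence[HydrophobicityScale]) -> np.ndarray:
    n = len(scales)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = scale_dissimilarity(scales[i], scales[j])
    return d


# ---------------------------------------------------------------------------
# UPGMA clustering

@dataclass
class TreeNode:
    """Node of the rooted ultrametric UPGMA tree (leaf iff no children)."""

    name: str
    height: float
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.name
        else:
            body = "(" + ",".join(c._newick(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.10g}"


def _cluster_labels() -> Iterable[str]:
    """a, b, ..., z, aa, ab, ..."""
    for size in itertools.count(1):
        for combo in itertools.product("abcdefghijklmnopqrstuvwxyz", repeat=size):
            yield "".join(combo)


@dataclass
class ScaleClustering:
    """UPGMA clustering of a set of scales at a join-height threshold."""

    scale_ids: list[str]
    dissimilarity: np.ndarray
    tree: TreeNode
    clusters: dict[str, str]
    threshold: float

    def to_newick(self) -> str:
        return self.tree.newick()

    def to_tsv(self) -> str:
        lines = ["scale_id\tcluster_label"]
        lines += [f"{sid}\t{self.clusters[sid]}" for sid in self.scale_ids]
        return "\n".join(lines) + "\n"


def upgma_cluster(
    scales: Sequence[HydrophobicityScale],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    dissimilarity: np.ndarray | None = None,
) -> ScaleClustering:
    """UPGMA tree over the pairwise dissimilarities, cut at *threshold*.

    The join height of a merge equals half the average-linkage distance, so
    leaves sit at height 0 and the tree is ultrametric.  When two candidate
    merges are equidistant the pair whose smallest member ids sort first is
    merged, which makes the tree deterministic.  Clusters are the maximal
    subtrees whose root height is at or below *threshold*; labels a, b, c ...
    follow the tree's left-to-right leaf order.
    """
    if len(scales) < 2:
        raise ScaleError("clustering needs at least 2 scales")
    if not (0.0 < threshold < 1.0):
        raise ScaleError(f"threshold must be in (0,1), got {threshold}")
    ids = [s.id for s in scales]
    if len(set(ids)) != len(ids):
        raise ScaleError("duplicate scale ids")
    d = dissimilarity_matrix(scales) if dissimilarity is None else np.asarray(dissimilarity, float)

    # active clusters: id -> (member indices, node)
    active: dict[int, tuple[list[int], TreeNode]] = {
        i: ([i], TreeNode(name=ids[i], height=0.0)) for i in range(len(scales))
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(len(scales)) for j in range(i + 1, len(scales))
    }
    next_id = len(scales)
    while len(active) > 1:
        best_key = None
        best_d = math.inf
        for (i, j), dij in dist.items():
            if dij < best_d - 1e-12:
                best_d, best_key = dij, (i, j)
            elif abs(dij - best_d) <= 1e-12:
                # deterministic tie-break on lexicographically smallest member ids
                cand = tuple(sorted((min(ids[m] for m in active[i][0]),
                                     min(ids[m] for m in active[j][0]))))
                cur = tuple(sorted((min(ids[m] for m in active[best_key[0]][0]),
                                    min(ids[m] for m in active[best_key[1]][0]))))
                if cand < cur:
                    best_key = (i, j)
        i, j = best_key  # type: ignore[misc]
        mem_i, node_i = active[i]
        mem_j, node_j = active[j]
        # canonical child order: subtree with lexicographically smallest member first
        if min(ids[m] for m in mem_i) > min(ids[m] for m in mem_j):
            node_i, node_j = node_j, node_i
            mem_i, mem_j = mem_j, mem_i
        height = best_d / 2.0
        height = max(height, node_i.height, node_j.height)  # guard ultrametricity
        new_node = TreeNode(name=f"n{next_id}", height=height, children=(node_i, node_j))
        new_members = mem_i + mem_j
        ni, nj = len(active[i][0]), len(active[j][0])
        # average-linkage update
        new_dist: dict[tuple[int, int], float] = {}
        for k in active:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dist[(k, next_id)] = (ni * dik + nj * djk) / (ni + nj)
        del active[i], active[j]
        dist = {key: v for key, v in dist.items() if i not in key and j not in key}
        dist.update(new_dist)
        active[next_id] = (new_members, new_node)
        next_id += 1

    (_, root), = active.values()

    clusters: dict[str, str] = {}
    label_gen = _cluster_labels()

    def cut(node: TreeNode) -> None:
        if node.height <= threshold:
            label = next(label_gen)
            for leaf in node.leaves():
                clusters[leaf.name] = label
        else:
            for c in node.children:
                cut(c)

    cut(root)
    return ScaleClustering(
        scale_ids=ids, dissimilarity=d, tree=root, clusters=clusters, threshold=threshold
    )


# ---------------------------------------------------------------------------
# amino-acid distance analysis

def aa_difference_matrix(
    s: HydrophobicityScale, low: float = 0.1, high: float = 0.9
) -> tuple[np.ndarray, set[tuple[str, str]], set[tuple[str, str]]]:
    """Pairwise |v(x) - v(y)| on the min-max-normalized scale.

    Returns the symmetric 20x20 matrix (alphabetical residue order) plus the
    set of "similar" unordered pairs (difference < *low*) and "distant" pairs
    (difference > *high*).
    """
    v = minmax_normalize(s).as_vector()
    m = np.abs(v[:, None] - v[None, :])
    similar: set[tuple[str, str]] = set()
    distant: set[tuple[str, str]] = set()
    for i in range(20):
        for j in range(i + 1, 20):
            pair = (AA_ALPHABETICAL[i], AA_ALPHABETICAL[j])
            if m[i, j] < low:
                similar.add(pair)
            elif m[i, j] > high:
                distant.add(pair)
    return m, similar, distant
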