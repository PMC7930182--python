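"""TCR-repertoire analytics.

Clonotypes are keyed by nucleotide sequence for diversity and overlap
statistics (clonality, Morisita-Horn, Gini/Lorenz), matching how rearrangement
tables are deduplicated, and by CDR3 amino-acid sequence for the
similarity-clustering workflow (top-N selection, pairwise alignment distances,
UPGMA dendrograms, exact-match sharing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .errors import ValidationError

CLONOTYPE_COLUMNS = ["nucleotide", "amino_acid", "count", "frequency",
                     "v_gene", "j_gene", "status"]
PRODUCTIVE_STATUS = "In"


@dataclass
class Repertoire:
    """Clonotype table: nt/aa sequence, template count, frequency, V/J, status."""

    clonotypes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.clonotypes
        missing = [c for c in CLONOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"repertoire missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("empty repertoire")
        counts = df["count"]
        if (counts <= 0).any() or not np.allclose(counts, counts.round()):
            raise ValidationError("clonotype counts must be positive integers")
        if df["nucleotide"].duplicated().any():
            dup = df.loc[df["nucleotide"].duplicated(), "nucleotide"].iloc[0]
            raise ValidationError(f"duplicate nucleotide clonotype: {dup[:30]}...")

    @classmethod
    def from_counts(cls, df: pd.DataFrame) -> "Repertoire":
        """Build a repertoire, (re)computing frequencies as count / total count."""
        df = df.copy()
        df["count"] = df["count"].astype(int)
        df["frequency"] = df["count"] / df["count"].sum()
        return cls(df[CLONOTYPE_COLUMNS] if set(CLONOTYPE_COLUMNS) <= set(df.columns)
                   else df.assign(**{c: "" for c in CLONOTYPE_COLUMNS if c not in df.columns})[
                       CLONOTYPE_COLUMNS])

    @property
    def frequencies(self) -> np.ndarray:
        return self.clonotypes["frequency"].to_numpy(dtype=float)

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    @property
    def total_templates(self) -> int:
        return int(self.clonotypes["count"].sum())


def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep productive (in-frame, status 'In') clonotypes; renormalize frequencies."""
    kept = rep.clonotypes[rep.clonotypes["status"] == PRODUCTIVE_STATUS]
    if len(kept) == 0:
        raise ValidationError("no productive clonotypes after filtering")
    return Repertoire.from_counts(kept.reset_index(drop=True))


def clonality(rep: Repertoire) -> float:
    """1 - Pielou evenness: 1 - H / ln(R) over clonotype frequencies.

    0 for a perfectly even repertoire, approaching 1 for a near-monoclonal
    one. Undefined (NaN) when the repertoire has a single clonotype.
    """
    p = rep.frequencies
    r = len(p)
    if r < 2:
        return float("nan")
    return 1.0 - float(entropy(p)) / math.log(r)


def _union_frequency_vectors(rep_a: Repertoire, rep_b: Repertoire, key="nucleotide"):
    a = rep_a.clonotypes.set_index(key)
    b = rep_b.clonotypes.set_index(key)
    union = a.index.union(b.index)
    return (a.reindex(union), b.reindex(union))


def morisita_overlap(rep_a: Repertoire, rep_b: Repertoire, variant: str = "horn") -> float:
    """Repertoire overlap on the union of nucleotide clonotypes, in [0, 1].

    variant='horn' (default) is the Morisita-Horn index on frequencies,
    2*sum(p*q) / (sum(p^2) + sum(q^2)): 1 iff the frequency vectors are
    identical, 0 iff the clonotype sets are disjoint. variant='classic' is the
    original count-based Morisita index with the Simpson small-sample
    correction.
    """
    a, b = _union_frequency_vectors(rep_a, rep_b)
    if variant == "horn":
        p = a["frequency"].fillna(0.0).to_numpy()
        q = b["frequency"].fillna(0.0).to_numpy()
        denom = float(p @ p + q @ q)
        return float(2.0 * (p @ q) / denom)
    if variant == "classic":
        x = a["count"].fillna(0.0).to_numpy()
        y = b["count"].fillna(0.0).to_numpy()
        tx, ty = x.sum(), y.sum()
        if tx < 2 or ty < 2:
            raise ValidationError("classic Morisita needs >= 2 templates per repertoire")
        lam_x = float((x * (x - 1)).sum() / (tx * (tx - 1)))
        lam_y = float((y * (y - 1)).sum() / (ty * (ty - 1)))
        return float(2.0 * (x @ y) / ((lam_x + lam_y) * tx * ty))
    raise ValidationError(f"unknown Morisita variant {variant!r}")


def gini_index(values) -> float:
    """Gini inequality of clone frequencies: mean |f_i - f_j| / (2 * mean)."""
    f = np.sort(np.asarray(values, dtype=float))
    r = len(f)
    if r == 0:
        raise ValidationError("gini_index of an empty vector")
    total = f.sum()
    if total == 0:
        raise ValidationError("gini_index of an all-zero vector")
    i = np.arange(1, r + 1)
    return float(((2 * i - r - 1) @ f) / (r * total))


def lorenz_curve(values) -> np.ndarray:
    """Lorenz points (cumulative clone share, cumulative frequency share).

    Clones sorted ascending by frequency; (R+1) x 2 array from (0,0) to (1,1).
    """
    f = np.sort(np.asarray(values, dtype=float))
    r = len(f)
    if r == 0:
        raise ValidationError("lorenz_curve of an empty vector")
    x = np.arange(r + 1) / r
    y = np.concatenate([[0.0], np.cumsum(f) / f.sum()])
    return np.column_stack([x, y])


def gini_from_lorenz(points: np.ndarray) -> float:
    """1 - 2 * trapezoid area under the Lorenz curve (internal cross-check)."""
    x, y = points[:, 0], points[:, 1]
    return float(1.0 - 2.0 * np.trapezoid(y, x))


def top_n_aa(rep: Repertoire, n: int = 100):
    """Top-n productive CDR3 amino-acid sequences by aggregated frequency.

    Frequencies of nucleotide clonotypes translating to the same amino-acid
    sequence are summed. Ties are broken lexicographically by sequence.
    Returns (list of (aa, frequency), truncated flag); the flag is True when
    the repertoire has fewer than n unique amino-acid sequences.
    """
    df = rep.clonotypes
    df = df[df["amino_acid"].astype(str).str.len() > 0]
    if len(df) == 0:
        raise ValidationError("no amino-acid sequences present")
    agg = df.groupby("amino_acid")["frequency"].sum().reset_index()
    agg = agg.sort_values(["frequency", "amino_acid"], ascending=[False, True])
    short = len(agg) < n
    out = list(agg.head(n).itertuples(index=False, name=None))
    return [(aa, float(fr)) for aa, fr in out], short


def shared_exact_clonotypes(top_a, top_b):
    """Exact-string CDR3 amino-acid sequences present in both top lists."""
    if not top_a or not top_b:
        raise ValidationError("shared_exact_clonotypes needs two non-empty lists")
    set_a = {aa for aa, _ in top_a}
    set_b = {aa for aa, _ in top_b}
    shared = sorted(set_a & set_b)
    return len(shared), shared


# ---------------------------------------------------------------------------
# Distance matrices and UPGMA dendrograms
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = self.matrix
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0) or (d < 0).any():
            raise ValidationError("distance matrix must be symmetric, non-negative, zero-diagonal")


@dataclass
class DendroNode:
    height: float
    label: str | None = None
    children: tuple = ()
    weight: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


@dataclass
class Dendrogram:
    root: DendroNode
    labels: list = field(default_factory=list)

    def merge_heights(self) -> list:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node.height)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return sorted(out)

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise tree distances (2 x merge height under the midpoint convention)."""
        n = len(self.labels)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        d = np.zeros((n, n))

        def walk(node):
            if node.is_leaf:
                return [node.label]
            sides = [walk(c) for c in node.children]
            for a in sides[0]:
                for b in sides[1]:
                    d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return sides[0] + sides[1]

        walk(self.root)
        return DistanceMatrix(labels=list(self.labels), matrix=d)

    def to_newick(self) -> str:
        def fmt(node, parent_height):
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        root = self.root
        inner = ",".join(fmt(c, root.height) for c in root.children)
        return f"({inner});"


def upgma_dendrogram(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram with deterministic tie-breaking.

    Merge height is half the average linkage distance (midpoint convention),
    so cophenetic distances reproduce an ultrametric input exactly. When two
    candidate pairs are equidistant the pair whose smallest leaf label sorts
    first wins, making the topology invariant to input order.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValidationError("UPGMA needs at least two leaves")
    weights = dm.weights if dm.weights is not None else np.zeros(n)
    clusters = {
        i: {"node": DendroNode(0.0, label=dm.labels[i], weight=float(weights[i])),
            "size": 1, "min_label": str(dm.labels[i])}
        for i in range(n)
    }
    dist = {(i, j): float(dm.matrix[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                *sorted((clusters[kv[0][0]]["min_label"], clusters[kv[0][1]]["min_label"])),
            ),
        )
        (a, b), d_ab = best
        ca, cb = clusters.pop(a), clusters.pop(b)
        first, second = sorted((ca, cb), key=lambda c: c["min_label"])
        merged = {
            "node": DendroNode(d_ab / 2.0, children=(first["node"], second["node"])),
            "size": ca["size"] + cb["size"],
            "min_label": first["min_label"],
        }
        new_dist = {}
        for k in clusters:
            d_ak = dist.pop((min(a, k), max(a, k)))
            d_bk = dist.pop((min(b, k), max(b, k)))
            new_dist[(k, next_id)] = (ca["size"] * d_ak + cb["size"] * d_bk) / merged["size"]
        dist = {kv: v for kv, v in dist.items() if a not in kv and b not in kv}
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1
    root = next(iter(clusters.values()))["node"]
    return Dendrogram(root=root, labels=list(dm.labels))
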