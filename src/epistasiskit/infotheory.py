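"""Entropy, information gain, interaction information and the attribute dendrogram.

All entropies are Shannon entropies in bits.  The information gain of an
attribute A about the class C is the mutual information

    IG(C; A) = H(C) - H(C | A) = H(A) + H(C) - H(A, C),

reported both in bits and in the percent display convention (bits x 100).
Its likelihood-ratio significance statistic is G^2 = 2 N ln(2) IG with
df = (|C|-1)(|A|-1).  Pairwise epistasis is measured by the interaction
information

    I(A; B; C) = IG(A x B; C) - IG(A; C) - IG(B; C),

positive for synergy, negative for redundancy.  Attributes are compared by
the Rajski distance d(A, B) = 1 - I(A; B)/H(A, B), a metric on discrete
attributes (0 for informationally identical, 1 for independent), and the
attribute dendrogram is agglomerated from that distance matrix with the
Lance-Williams recurrence using Ward coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))


@dataclass
class Attribute:
    """A per-subject categorical attribute (a SNP, a recoded SNP, a product)."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("attribute values must be a non-empty 1-D array")
        if (self.values < 0).any():
            raise ValueError("negative category index (drop missing before analysis)")

    def __len__(self) -> int:
        return self.values.size

    @property
    def cardinality(self) -> int:
        return int(np.unique(self.values).size)


@dataclass
class IgResult:
    ig_bits: float
    g2: float
    df: int
    p_value: float

    @property
    def ig_percent(self) -> float:
        return self.ig_bits * 100.0


@dataclass
class InteractionResult:
    pair: tuple[str, str]
    interaction_bits: float

    @property
    def interaction_percent(self) -> float:
        return self.interaction_bits * 100.0

    @property
    def synergy(self) -> bool:
        return self.interaction_bits > 0


def _as_values(attr) -> np.ndarray:
    return attr.values if isinstance(attr, Attribute) else np.asarray(attr, dtype=int)


def entropy(attr) -> float:
    """Shannon entropy H = -sum p log2 p over observed categories, in bits."""
    values = _as_values(attr)
    _, counts = np.unique(values, return_counts=True)
    p = counts / values.size
    return float(-(p * np.log2(p)).sum())


def joint_entropy(a, b) -> float:
    av, bv = _as_values(a), _as_values(b)
    pairs = av.astype(np.int64) * (bv.max() + 1) + bv
    return entropy(pairs)


def mutual_information(a, b) -> float:
    """I(A; B) = H(A) + H(B) - H(A, B) in bits."""
    return entropy(a) + entropy(b) - joint_entropy(a, b)


def product_attribute(a: Attribute, b: Attribute) -> Attribute:
    """Cartesian-product attribute over observed cells only."""
    av, bv = _as_values(a), _as_values(b)
    pairs = av.astype(np.int64) * (bv.max() + 1) + bv
    _, codes = np.unique(pairs, return_inverse=True)
    name_a = a.name if isinstance(a, Attribute) else "A"
    name_b = b.name if isinstance(b, Attribute) else "B"
    return Attribute(values=codes, name=f"{name_a}x{name_b}")


def information_gain(class_attr, attr) -> IgResult:
    """IG(C; A) with its G^2 statistic and chi-square p-value.

    A single observed category in either attribute yields ig = 0, df = 0,
    p = 1 (no information, no test).
    """
    cv, av = _as_values(class_attr), _as_values(attr)
    if cv.size != av.size:
        raise ValueError("class and attribute lengths differ")
    n = cv.size
    kc = np.unique(cv).size
    ka = np.unique(av).size
    if kc < 2 or ka < 2:
        return IgResult(ig_bits=0.0, g2=0.0, df=0, p_value=1.0)
    ig = max(0.0, mutual_information(cv, av))
    g2 = 2.0 * n * LN2 * ig
    df = (kc - 1) * (ka - 1)
    p = float(stats.chi2.sf(g2, df))
    return IgResult(ig_bits=ig, g2=g2, df=df, p_value=p)


def interaction_information(class_attr, a: Attribute, b: Attribute) -> InteractionResult:
    """I(A; B; C) = IG(AxB; C) - IG(A; C) - IG(B; C), in bits."""
    cv = _as_values(class_attr)
    ab = product_attribute(a, b)
    ig_ab = mutual_information(cv, ab.values)
    ig_a = mutual_information(cv, _as_values(a))
    ig_b = mutual_information(cv, _as_values(b))
    name_a = a.name if isinstance(a, Attribute) else "A"
    name_b = b.name if isinstance(b, Attribute) else "B"
    return InteractionResult(pair=(name_a, name_b), interaction_bits=float(ig_ab - ig_a - ig_b))


def rajski_distance(a, b) -> float:
    """Rajski distance d = 1 - I(A;B)/H(A,B); constant pair defined as d = 0."""
    h_joint = joint_entropy(a, b)
    if h_joint == 0.0:
        return 0.0
    d = 1.0 - mutual_information(a, b) / h_joint
    return float(min(1.0, max(0.0, d)))


# ---------------------------------------------------------------------------
# Lance-Williams agglomeration
# ---------------------------------------------------------------------------

def _ward_coeff(n_i: int, n_j: int, n_k: int) -> tuple[float, float, float, float]:
    tot = n_i + n_j + n_k
    return ((n_i + n_k) / tot, (n_j + n_k) / tot, -n_k / tot, 0.0)


def _average_coeff(n_i: int, n_j: int, n_k: int) -> tuple[float, float, float, float]:
    return (n_i / (n_i + n_j), n_j / (n_i + n_j), 0.0, 0.0)


_COEFFS = {"ward": _ward_coeff, "average": _average_coeff}


def lance_williams_linkage(dist: np.ndarray, method: str = "ward") -> np.ndarray:
    """Agglomerative linkage by the Lance-Williams recurrence on a distance matrix.

    d(i+j, k) = a_i d(i,k) + a_j d(j,k) + b d(i,j) + g |d(i,k) - d(j,k)|,
    with coefficients per ``method`` applied to the distances as given
    (for Ward this is the plain-distance convention).  Returns a scipy-style
    (m-1) x 4 linkage matrix [left, right, height, size].
    """
    coeff = _COEFFS[method]
    d = np.asarray(dist, dtype=float).copy()
    m = d.shape[0]
    if d.shape != (m, m) or m < 2:
        raise ValueError("need a square distance matrix over >= 2 attributes")
    active = list(range(m))          # current cluster ids
    sizes = {i: 1 for i in range(m)}
    dmat = {frozenset((i, j)): d[i, j] for i in range(m) for j in range(i + 1, m)}
    linkage = np.zeros((m - 1, 4))
    next_id = m
    for step in range(m - 1):
        i, j = min(
            ((a, b) for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda ij: (dmat[frozenset(ij)], ij),
        )
        height = dmat[frozenset((i, j))]
        linkage[step] = [min(i, j), max(i, j), height, sizes[i] + sizes[j]]
        active = [a for a in active if a not in (i, j)]
        for k in active:
            a_i, a_j, b, g = coeff(sizes[i], sizes[j], sizes[k])
            dik = dmat.pop(frozenset((i, k)))
            djk = dmat.pop(frozenset((j, k)))
            dmat[frozenset((next_id, k))] = (
                a_i * dik + a_j * djk + b * height + g * abs(dik - djk)
            )
        sizes[next_id] = sizes[i] + sizes[j]
        active.append(next_id)
        next_id += 1
    return linkage


@dataclass
class Dendrogram:
    """Attribute dendrogram with per-leaf-pair interaction annotations."""

    labels: list[str]
    linkage: np.ndarray                       # scipy-style (m-1) x 4
    distance_matrix: np.ndarray
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick text; child branch lengths = parent height - child height."""
        m = len(self.labels)
        heights = {i: 0.0 for i in range(m)}
        nodes = {i: self.labels[i] for i in range(m)}
        for step, (left, right, height, _) in enumerate(self.linkage):
            left, right = int(left), int(right)
            bl = height - heights[left]
            br = height - heights[right]
            new = m + step
            nodes[new] = f"({nodes[left]}:{bl:.6g},{nodes[right]}:{br:.6g})"
            heights[new] = height
        return nodes[m + len(self.linkage) - 1] + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage, columns=["left", "right", "height", "size"])


def build_dendrogram(attrs: list[Attribute], class_attr) -> Dendrogram:
    """Ward/Lance-Williams dendrogram of attributes on Rajski distances.

    Leaf-pair edges are annotated with I(A; B; C) (bits), positive = synergy.
    """
    if len(attrs) < 2:
        raise ValueError("need at least 2 attributes")
    m = len(attrs)
    d = np.zeros((m, m))
    interactions: dict[tuple[str, str], float] = {}
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = rajski_distance(attrs[i], attrs[j])
            info = interaction_information(class_attr, attrs[i], attrs[j])
            interactions[(attrs[i].name, attrs[j].name)] = info.interaction_bits
    linkage = lance_williams_linkage(d, method="ward")
    return Dendrogram(
        labels=[a.name for a in attrs], linkage=linkage,
        distance_matrix=d, interactions=interactions,
    )


def interaction_matrix(attrs: list[Attribute], class_attr) -> pd.DataFrame:
    """All pairwise I(A;B;C) values as a tidy table (bits and percent)."""
    rows = []
    for i in range(len(attrs)):
        for j in range(i + 1, len(attrs)):
            r = interaction_information(class_attr, attrs[i], attrs[j])
            rows.append({
                "snp_a": r.pair[0], "snp_b": r.pair[1],
                "interaction_bits": r.interaction_bits,
                "interaction_percent": r.interaction_percent,
                "synergy": r.synergy,
            })
    return pd.DataFrame(rows)
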