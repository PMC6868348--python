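"""Relationship classification and diagnostics from IBD estimates.

Each pair's (Z0, Z1, Z2) lies on the 2-simplex; relationship classes sit at
theoretical centroids - duplicates/MZ twins at (0,0,1), parent-offspring at
(0,1,0), full siblings at (1/4,1/2,1/4), second degree at (1/2,1/2,0),
third degree at (3/4,1/4,0) and unrelated pairs at (1,0,0).  Pairs whose
coefficient of relatedness PI_HAT = Z2 + Z1/2 falls below the cutoff
(default 0.2) are called unrelated outright; the rest are assigned the
nearest centroid by Euclidean distance in (Z0, Z1, Z2) space, ties broken
toward the lower degree.  Class separability is assessed by convex-hull
intersection in barycentric (ternary-diagram) coordinates, and calls are
cross-tabulated against pedigree-expected classes for consistency checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from sklearn.base import BaseEstimator, ClassifierMixin

from .pedigree import Pedigree

__all__ = [
    "CENTROIDS", "CLASS_DEGREES", "ClassifierConfig", "RelationshipCall",
    "ternary_coordinates", "invert_ternary", "NearestCentroidKinshipClassifier",
    "classify_relationship", "class_separation", "pedigree_consistency",
]

#: Theoretical (Z0, Z1, Z2) per relationship class, ordered by degree so
#: that argmin tie-breaking prefers the lower degree.
CENTROIDS: dict[str, tuple[float, float, float]] = {
    "duplicate": (0.0, 0.0, 1.0),
    "parent-offspring": (0.0, 1.0, 0.0),
    "full-sibling": (0.25, 0.5, 0.25),
    "second-degree": (0.5, 0.5, 0.0),
    "third-degree": (0.75, 0.25, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}

CLASS_DEGREES: dict[str, float] = {
    "duplicate": 0, "parent-offspring": 1, "full-sibling": 1,
    "second-degree": 2, "third-degree": 3, "unrelated": math.inf,
}

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass
class ClassifierConfig:
    """Relatedness cutoff plus (optionally overridden) class centroids."""

    relatedness_cutoff: float = 0.2
    centroids: Mapping[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.relatedness_cutoff <= 1.0):
            raise ValueError("relatedness cutoff must lie in [0, 1]")
        for name, z in (self.centroids or CENTROIDS).items():
            if abs(sum(z) - 1.0) > 1e-9 or min(z) < -1e-12:
                raise ValueError(f"centroid {name} must lie on the simplex")


@dataclass(frozen=True)
class RelationshipCall:
    """One pair's relationship call."""

    id1: str
    id2: str
    relationship: str
    degree: float
    distance: float      # Euclidean distance to the chosen centroid (nan if cutoff)


def ternary_coordinates(z0, z1, z2):
    """Barycentric embedding of simplex points into the plane.

    Corners: Z0 -> (0, 0), Z1 -> (1, 0), Z2 -> (1/2, sqrt(3)/2); a point is
    Z1*(1,0) + Z2*(1/2, sqrt(3)/2).  Accepts scalars or arrays.
    """
    z0 = np.asarray(z0, float)
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    total = z0 + z1 + z2
    if np.any(np.abs(total - 1.0) > 1e-6) or np.any(np.minimum(np.minimum(z0, z1), z2) < -1e-9):
        raise ValueError("input must lie on the probability simplex")
    x = z1 + 0.5 * z2
    y = _SQRT3_2 * z2
    if x.ndim == 0:
        return float(x), float(y)
    return x, y

def invert_ternary(x, y):
    """Inverse of :func:`ternary_coordinates` (plane -> simplex)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z2 = y / _SQRT3_2
    z1 = x - 0.5 * z2
    z0 = 1.0 - z1 - z2
    if z0.ndim == 0:
        return float(z0), float(z1), float(z2)
    return z0, z1, z2


class NearestCentroidKinshipClassifier(BaseEstimator, ClassifierMixin):
    """Cutoff-plus-nearest-centroid relationship classifier.

    Parameters
    ----------
    relatedness_cutoff : float
        PI_HAT below this calls the pair unrelated (the ``-t`` cutoff of
        relationship-inference tools; 0.2 default, 0.375 the strict variant).
    centroids : mapping, optional
        Overrides the theoretical class centroids.
    """

    def __init__(self, relatedness_cutoff: float = 0.2,
                 centroids: Mapping[str, tuple[float, float, float]] | None = None):
        self.relatedness_cutoff = relatedness_cutoff
        self.centroids = centroids

    def fit(self, X=None, y=None) -> "NearestCentroidKinshipClassifier":
        cfg = ClassifierConfig(self.relatedness_cutoff, self.centroids)
        cents = dict(cfg.centroids or CENTROIDS)
        names = sorted(cents, key=lambda n: CLASS_DEGREES.get(n, math.inf))
        self.class_names_ = names
        self.centroid_matrix_ = np.array([cents[n] for n in names], float)
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """Class labels for an (n, 3) array of bounded (Z0, Z1, Z2) rows."""
        self.fit()
        Z = np.atleast_2d(np.asarray(Z, float))
        pi_hat = Z[:, 2] + Z[:, 1] / 2.0
        d = np.linalg.norm(Z[:, None, :] - self.centroid_matrix_[None, :, :], axis=2)
        best = np.argmin(d, axis=1)     # stable: first (lowest-degree) minimum
        labels = np.array([self.class_names_[b] for b in best], dtype=object)
        labels[pi_hat < self.relatedness_cutoff] = "unrelated"
        return labels

    def call(self, id1: str, id2: str, z: Sequence[float]) -> RelationshipCall:
        self.fit()
        z = np.asarray(z, float)
        label = str(self.predict(z[None, :])[0])
        if label in self.class_names_:
            dist = float(np.linalg.norm(
                z - self.centroid_matrix_[self.class_names_.index(label)]))
        else:
            dist = math.nan
        return RelationshipCall(id1, id2, label, CLASS_DEGREES[label], dist)

    def classify_table(self, ibd_table: pd.DataFrame) -> pd.DataFrame:
        """Classify every valid row of an IBD table (ID1/ID2/Z0/Z1/Z2...)."""
        self.fit()
        out = ibd_table.copy()
        ok = out[["Z0", "Z1", "Z2"]].notna().all(axis=1)
        labels = pd.Series("flagged", index=out.index, dtype=object)
        if ok.any():
            labels[ok] = self.predict(out.loc[ok, ["Z0", "Z1", "Z2"]].to_numpy())
        out["relationship"] = labels
        out["degree"] = labels.map(lambda c: CLASS_DEGREES.get(c, math.nan))
        return out


def classify_relationship(est, config: ClassifierConfig | None = None
                          ) -> RelationshipCall:
    """Classify one :class:`~kinseq.ibd.IBDEstimate`."""
    config = config or ClassifierConfig()
    clf = NearestCentroidKinshipClassifier(config.relatedness_cutoff,
                                           config.centroids)
    return clf.call(est.id1, est.id2, est.z)


def _class_geometry(points: np.ndarray):
    """Convex hull of a point cloud; degenerate clouds give Point/LineString."""
    return MultiPoint([tuple(p) for p in points]).convex_hull


def class_separation(z_values: np.ndarray, labels: Sequence[str]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise class-overlap report in ternary coordinates.

    Two classes overlap iff the convex hulls of their points intersect
    (single points and collinear clouds are handled as degenerate hulls).
    Returns a boolean overlap matrix and the matrix of minimum inter-hull
    distances.  Classes with no points are skipped.
    """
    z = np.atleast_2d(np.asarray(z_values, float))
    labels = np.asarray(labels, dtype=object)
    x, y = ternary_coordinates(z[:, 0], z[:, 1], z[:, 2])
    pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
    classes = [c for c in pd.unique(labels) if (labels == c).any()]
    geoms = {c: _class_geometry(pts[labels == c]) for c in classes}
    overlap = pd.DataFrame(False, index=classes, columns=classes)
    dist = pd.DataFrame(0.0, index=classes, columns=classes)
    for i, a in enumerate(classes):
        for b in classes[i:]:
            hit = bool(geoms[a].intersects(geoms[b]))
            overlap.loc[a, b] = overlap.loc[b, a] = hit
            d = float(geoms[a].distance(geoms[b]))
            dist.loc[a, b] = dist.loc[b, a] = d
    return overlap, dist


def pedigree_consistency(pedigree: Pedigree, calls: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.Series, list[tuple[str, str]]]:
    """Cross-tabulate called vs pedigree-expected relationship classes.

    ``calls`` needs columns ID1, ID2, relationship.  Returns the confusion
    table (rows = expected, columns = called), per-expected-class
    sensitivity (fraction of pairs called exactly right), and the list of
    pedigree pairs absent from the calls.
    """
    called = {}
    for _, r in calls.iterrows():
        called[frozenset((r["ID1"], r["ID2"]))] = r["relationship"]
    expected_rows = []
    missing_pairs: list[tuple[str, str]] = []
    for a, b in pedigree.pairs():
        exp = pedigree.expected_relationship(a, b).relationship
        got = called.get(frozenset((a, b)))
        if got is None:
            missing_pairs.append((a, b))
        else:
            expected_rows.append((exp, got))
    if not expected_rows:
        raise ValueError("no pedigree pairs present in the calls")
    df = pd.DataFrame(expected_rows, columns=["expected", "called"])
    confusion = pd.crosstab(df["expected"], df["called"])
    correct = (df["expected"] == df["called"]).astype(float)
    sensitivity = correct.groupby(df["expected"]).mean()
    return confusion, sensitivity, missing_pairs
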