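"""Feature vectors of nerves: face-vector alphabets, proportions, spread, PCA.

A single nerve is too rich an object for standard statistics, so each sample
is summarized by the distribution of its per-cell face-vectors: enumerate all
face-vectors occurring in any nerve under comparison (the *alphabet*), then
represent each nerve by the vector of proportions of its cells having each
face-vector.  These proportion vectors live in a common Euclidean space and
can be compared with a multivariate two-sample test or projected with PCA.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .nerve import Nerve

__all__ = [
    "FaceVectorAlphabet",
    "FeatureMatrix",
    "enumerate_face_vectors",
    "feature_vector",
    "feature_matrix",
    "spread",
    "pca_project",
]


def _canonical(fv: Sequence[int]) -> tuple[int, ...]:
    t = tuple(int(x) for x in fv)
    while len(t) > 1 and t[-1] == 0:
        t = t[:-1]
    return t


class FaceVectorAlphabet:
    """Deterministically ordered enumeration of distinct face-vectors.

    Vectors are padded with zeros to a common length and sorted
    lexicographically, so the column order of any feature matrix built from
    the same comparison set is reproducible.
    """

    def __init__(self, vectors: Iterable[Sequence[int]]):
        distinct = {_canonical(v) for v in vectors}
        if not distinct:
            raise ValueError("empty alphabet")
        width = max(len(v) for v in distinct)
        padded = sorted(v + (0,) * (width - len(v)) for v in distinct)
        self._vectors: tuple[tuple[int, ...], ...] = tuple(_canonical(v) for v in padded)
        self._index: dict[tuple[int, ...], int] = {v: i for i, v in enumerate(self._vectors)}

    @classmethod
    def from_nerves(cls, nerves: Iterable[Nerve]) -> "FaceVectorAlphabet":
        nerves = list(nerves)
        if not nerves:
            raise ValueError("need at least one nerve to enumerate face-vectors")
        return cls(n.face_vector(v) for n in nerves for v in n.vertices)

    @property
    def vectors(self) -> tuple[tuple[int, ...], ...]:
        return self._vectors

    def index(self, fv: Sequence[int]) -> int:
        key = _canonical(fv)
        if key not in self._index:
            raise ValueError(
                f"face-vector {key} is not in the alphabet; the alphabet must be "
                "enumerated from every nerve under comparison"
            )
        return self._index[key]

    def __len__(self) -> int:
        return len(self._vectors)

    def __iter__(self):
        return iter(self._vectors)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FaceVectorAlphabet) and self._vectors == other._vectors

    def column_names(self) -> list[str]:
        return ["fv_" + "_".join(map(str, v)) for v in self._vectors]


def enumerate_face_vectors(nerves: Iterable[Nerve]) -> FaceVectorAlphabet:
    """Enumerate the distinct face-vectors occurring in any of the nerves."""
    return FaceVectorAlphabet.from_nerves(nerves)


def feature_vector(nerve: Nerve, alphabet: FaceVectorAlphabet) -> np.ndarray:
    """Proportion of cells of ``nerve`` having each alphabet face-vector.

    Components sum to one.  Raises if the nerve contains a face-vector
    missing from the alphabet (the alphabet was not built from the full
    comparison set).
    """
    counts = np.zeros(len(alphabet), dtype=float)
    vertices = nerve.vertices
    for v in vertices:
        counts[alphabet.index(nerve.face_vector(v))] += 1
    return counts / len(vertices)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-sample proportion vectors over a shared face-vector alphabet."""

    values: np.ndarray  # (n_samples, len(alphabet))
    alphabet: FaceVectorAlphabet
    meta: pd.DataFrame  # one row per sample: sample_id, cohort, [stage, tissue]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.meta):
            raise ValueError("values and meta row counts differ")
        if self.values.shape[1] != len(self.alphabet):
            raise ValueError("column count does not match alphabet size")
        sums = self.values.sum(axis=1)
        if self.values.size and not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("feature-matrix rows must sum to 1")

    @property
    def cohorts(self) -> list[str]:
        return list(pd.unique(self.meta["cohort"]))

    def cohort_values(self, cohort: str) -> np.ndarray:
        mask = (self.meta["cohort"] == cohort).to_numpy()
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        fv = pd.DataFrame(self.values, columns=self.alphabet.column_names())
        return pd.concat([self.meta.reset_index(drop=True), fv], axis=1)


def feature_matrix(
    cohorts: Mapping[str, Sequence[Nerve]],
    stage: str | None = None,
    tissue: str | None = None,
) -> FeatureMatrix:
    """Build the shared-alphabet feature matrix for labeled cohorts of nerves.

    The alphabet is enumerated from the union of all cohorts so that every
    row lives in the same space; rows keep cohort membership as metadata.
    """
    for label, nerves in cohorts.items():
        if len(nerves) == 0:
            raise ValueError(f"cohort {label!r} is empty")
    all_nerves = [n for nerves in cohorts.values() for n in nerves]
    alphabet = enumerate_face_vectors(all_nerves)
    rows, meta = [], []
    for label, nerves in cohorts.items():
        for i, n in enumerate(nerves):
            rows.append(feature_vector(n, alphabet))
            meta.append({"sample_id": f"{label}:{i}", "cohort": label,
                         "stage": stage, "tissue": tissue})
    return FeatureMatrix(np.asarray(rows), alphabet, pd.DataFrame(meta))


def spread(vectors: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Average pairwise Euclidean distance of a set of vectors.

    The mean runs over the n(n−1)/2 unordered pairs.  Zero iff all vectors
    coincide.
    """
    arr = np.atleast_2d(np.asarray(vectors, dtype=float))
    if arr.shape[0] < 2:
        raise ValueError("spread needs at least two vectors")
    return float(pdist(arr).mean())


def pca_project(
    matrix: FeatureMatrix | np.ndarray, k: int = 2, return_loadings: bool = False
):
    """Project samples onto the first ``k`` principal axes.

    Column-centered SVD with no variance scaling (feature proportions share
    a scale).  Sign convention: within each component, the loading of
    largest magnitude is made positive, so scores are deterministic.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range for a {n}x{p} matrix")
    centered = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    if return_loadings:
        return scores, vt[:k]
    return scores
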