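"""Distance matrices from pairwise UCO alignments and Mantel correlation.

For each UCO gene, an inter-species distance matrix is built with entry
d(i, j) = 1 - pident(i, j)/100 from the pairwise local alignment of the two
species' representative proteins.  Consistency between two UCO matrices is
quantified by the Mantel statistic: the matrices are restricted to their
shared species, the off-diagonal upper-triangle entries are standardized
(sample standard deviation, divisor m - 1 over the m = n(n-1)/2 entries),
and r is the mean cross-product — i.e. the Pearson correlation of the two
flattened triangles, so r(x, x) = 1 exactly.  Significance comes from a
one-tailed permutation test that simultaneously permutes rows and columns
of one matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import align
from .align import SequenceRecord
from .errors import InsufficientOverlapError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

MIN_SHARED_SPECIES = 3


@dataclass
class DistanceMatrix:
    """Symmetric species-by-species dissimilarity matrix for one UCO gene."""

    species_ids: list[str]
    values: np.ndarray
    uco_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.species_ids)

    def restrict(self, species: list[str]) -> "DistanceMatrix":
        idx = [self.species_ids.index(s) for s in species]
        return DistanceMatrix(species_ids=list(species),
                              values=self.values[np.ix_(idx, idx)],
                              uco_id=self.uco_id)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.species_ids,
                     columns=self.species_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, uco_id: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(species_ids=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float), uco_id=uco_id)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_permutation: float
    n_shared_species: int
    permutations: int
    seed: int


def pairwise_distance_matrix(
    uco_id: str,
    sequences: dict[str, SequenceRecord],
    matrix_name: str = align.DEFAULT_MATRIX,
) -> DistanceMatrix:
    """Identity-based distance matrix for one UCO across species.

    Each unordered species pair is aligned once; the entry is
    1 - percent_identity/100, so identical proteins are at distance 0 and a
    pair with no alignable region at distance 1.
    """
    species = sorted(sequences)
    if len(species) < 2:
        raise ValueError(f"UCO {uco_id!r}: need at least 2 species")
    n = len(species)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        hit = align.smith_waterman(sequences[species[i]], sequences[species[j]],
                                   matrix_name=matrix_name)
        values[i, j] = values[j, i] = 1.0 - hit.percent_identity / 100.0
    return DistanceMatrix(species_ids=species, values=values, uco_id=uco_id)


def _shared_species(x: DistanceMatrix, y: DistanceMatrix) -> list[str]:
    return sorted(set(x.species_ids) & set(y.species_ids))


def _standardized_triangle(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise UndefinedCorrelationError("zero variance in distance matrix")
    return (v - v.mean()) / sd


def _r_from_triangles(vx: np.ndarray, vy: np.ndarray) -> float:
    m = len(vx)
    return float(_standardized_triangle(vx) @ _standardized_triangle(vy) / (m - 1))


def mantel_r(x: DistanceMatrix, y: DistanceMatrix) -> float:
    """Mantel correlation of two distance matrices over their shared species."""
    shared = _shared_species(x, y)
    if len(shared) < MIN_SHARED_SPECIES:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared species (need >= {MIN_SHARED_SPECIES})")
    xs, ys = x.restrict(shared), y.restrict(shared)
    return _r_from_triangles(xs.upper_triangle(), ys.upper_triangle())


def mantel_permutation_p(
    x: DistanceMatrix,
    y: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-tailed (greater) permutation test for the Mantel correlation.

    Rows and columns of y are permuted simultaneously; the p-value counts
    permuted r >= observed r and includes the observed statistic, so
    p >= 1/(permutations + 1).
    """
    shared = _shared_species(x, y)
    if len(shared) < MIN_SHARED_SPECIES:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared species (need >= {MIN_SHARED_SPECIES})")
    xs, ys = x.restrict(shared), y.restrict(shared)
    vx = _standardized_triangle(xs.upper_triangle())
    iu = np.triu_indices(len(shared), k=1)
    vy_raw = ys.values
    r_obs = _r_from_triangles(xs.upper_triangle(), ys.upper_triangle())
    rng = np.random.default_rng(seed)
    m = len(vx)
    count = 1  # the observed statistic itself
    for _ in range(permutations):
        perm = rng.permutation(len(shared))
        vp = vy_raw[np.ix_(perm, perm)][iu]
        r_perm = float(vx @ _standardized_triangle(vp) / (m - 1))
        if r_perm >= r_obs:
            count += 1
    return MantelResult(r=r_obs, p_permutation=count / (permutations + 1),
                        n_shared_species=len(shared),
                        permutations=permutations, seed=seed)


def all_pairs_correlation(matrices: list[DistanceMatrix]) -> pd.DataFrame:
    """Mantel r for every unordered pair of matrices.

    Emits exactly C(m, 2) rows (columns: uco_i, uco_j, r, n_shared); pairs
    with fewer than three shared species, or with a constant triangle, get
    r = NaN rather than an error.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    # Fast path: matrices on a common species panel share standardized
    # triangles, so all pairwise r values reduce to one matrix product.
    panels = {tuple(m.species_ids) for m in matrices}
    if len(panels) == 1 and matrices[0].n >= MIN_SHARED_SPECIES:
        return _all_pairs_common_panel(matrices)
    rows = []
    for i, j in itertools.combinations(range(len(matrices)), 2):
        x, y = matrices[i], matrices[j]
        shared = _shared_species(x, y)
        try:
            r = mantel_r(x, y)
        except (InsufficientOverlapError, UndefinedCorrelationError):
            r = np.nan
        rows.append((x.uco_id, y.uco_id, r, len(shared)))
    return pd.DataFrame(rows, columns=["uco_i", "uco_j", "r", "n_shared"])


def _all_pairs_common_panel(matrices: list[DistanceMatrix]) -> pd.DataFrame:
    n = matrices[0].n
    m = n * (n - 1) // 2
    z = np.empty((len(matrices), m))
    for k, mat in enumerate(matrices):
        v = mat.upper_triangle()
        sd = v.std(ddof=1)
        z[k] = (v - v.mean()) / sd if sd > 0 else np.nan
    rmat = z @ z.T / (m - 1)
    idx_i, idx_j = np.triu_indices(len(matrices), k=1)
    return pd.DataFrame({
        "uco_i": [matrices[i].uco_id for i in idx_i],
        "uco_j": [matrices[j].uco_id for j in idx_j],
        "r": rmat[idx_i, idx_j],
        "n_shared": n,
    })
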