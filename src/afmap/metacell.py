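"""Meta-cell construction: KNN aggregation within donor x cell type.

Correlation estimates across sparse single nuclei are noisy; meta-cells
sum the counts of k mutually neighboring nuclei (in a PCA embedding of
the RNA modality) from the same donor and cell type, with a cap on how
many nuclei any two meta-cells may share.  The same nucleus-to-meta-cell
assignment is applied verbatim to the gene and peak matrices so both
modalities stay aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from afmap.datamodel import SparseCountMatrix


@dataclass
class PCAEmbedding:
    coords: np.ndarray  # observations x components
    components: np.ndarray  # components x features (orthonormal rows)
    explained_variance: np.ndarray


@dataclass
class MetacellAssignment:
    metacell_id: str
    members: list[str]
    donor_id: str
    cell_type: str


def pca_embed(norm_expr: SparseCountMatrix | np.ndarray, n_components: int = 10) -> PCAEmbedding:
    """PCA of per-feature standardized expression.

    Features are centered and scaled to unit variance (constant
    features pass through unscaled); component variances are
    non-increasing and loadings orthonormal.
    """
    dense = (
        norm_expr.to_dense() if isinstance(norm_expr, SparseCountMatrix) else np.asarray(norm_expr)
    )
    n, g = dense.shape
    if n < n_components + 1:
        raise ValueError(f"need more than {n_components} observations, got {n}")
    centered = dense - dense.mean(axis=0)
    sd = centered.std(axis=0)
    scaled = centered / np.where(sd > 0, sd, 1.0)
    rank = min(n - 1, g)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(scaled)
    return PCAEmbedding(
        coords=coords,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
    )


def make_metacells(
    embedding: np.ndarray,
    nucleus_table: pd.DataFrame,
    k: int = 30,
    max_shared: int = 10,
    seed: int = 0,
) -> list[MetacellAssignment]:
    """Greedy randomized meta-cell selection under an overlap cap.

    Within each donor x cell-type group, a k-NN graph (Euclidean, self
    included among the k members) is built in the embedding; seed
    nuclei are visited in randomized order and a seed's neighborhood is
    emitted as a meta-cell iff it shares at most ``max_shared`` nuclei
    with every meta-cell already emitted in that group.  Groups smaller
    than k are skipped with a warning.  Deterministic given ``seed``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    embedding = np.asarray(embedding)
    rng = np.random.default_rng(seed)
    out: list[MetacellAssignment] = []
    nt = nucleus_table.reset_index(drop=True)
    groups = nt.groupby(["donor_id", "cell_type"], sort=True).indices
    counter = 0
    for (donor, ct) in sorted(groups):
        idx = np.sort(groups[(donor, ct)])
        if len(idx) < k:
            warnings.warn(
                f"group ({donor}, {ct}) has {len(idx)} < k={k} nuclei; skipped"
            )
            continue
        coords = embedding[idx]
        nn = NearestNeighbors(n_neighbors=k).fit(coords)
        _, nbrs = nn.kneighbors(coords)  # includes self (distance 0)
        emitted: list[set[int]] = []
        for s in rng.permutation(len(idx)):
            hood = set(nbrs[s])
            if all(len(hood & prev) <= max_shared for prev in emitted):
                emitted.append(hood)
                members = sorted(nt.loc[idx[list(hood)], "nucleus_id"])
                out.append(
                    MetacellAssignment(
                        metacell_id=f"mc{counter:05d}",
                        members=members,
                        donor_id=donor,
                        cell_type=ct,
                    )
                )
                counter += 1
    return out


def aggregate_matrix(
    counts: SparseCountMatrix, assignment: list[MetacellAssignment]
) -> SparseCountMatrix:
    """Sum member-nucleus counts per meta-cell (either modality)."""
    pos = {o: i for i, o in enumerate(counts.obs_ids)}
    rows, cols, vals = [], [], []
    for r, mc in enumerate(assignment):
        for m in mc.members:
            if m not in pos:
                raise KeyError(f"meta-cell member {m!r} missing from matrix")
            rows.append(r)
            cols.append(pos[m])
            vals.append(1)
    ind = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(assignment), counts.shape[0])
    )
    agg = ind @ counts.matrix
    return SparseCountMatrix(
        agg, [mc.metacell_id for mc in assignment], list(counts.feature_ids)
    )


def assignment_table(assignment: list[MetacellAssignment]) -> pd.DataFrame:
    """Long-format (metacell_id, nucleus_id, donor_id, cell_type) table."""
    rows = [
        {"metacell_id": mc.metacell_id, "nucleus_id": m,
         "donor_id": mc.donor_id, "cell_type": mc.cell_type}
        for mc in assignment
        for m in mc.members
    ]
    return pd.DataFrame(rows, columns=["metacell_id", "nucleus_id", "donor_id", "cell_type"])


def metacell_metadata(assignment: list[MetacellAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metacell_id": mc.metacell_id,
                "donor_id": mc.donor_id,
                "cell_type": mc.cell_type,
                "n_members": len(mc.members),
            }
            for mc in assignment
        ]
    )
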