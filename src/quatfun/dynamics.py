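"""Cα elastic-network normal modes, cross-correlated motions, and the
coupling–dynamics R² statistic.

An anisotropic network model (uniform springs, distance cutoff) replaces
the all-atom NMA of the original protocol; all non-rigid modes enter the
covariance, and the dynamic cross-correlation matrix (DCCM) is the
trace-normalized 3x3-block covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .coevolution import CouplingMatrix
from .structure_annotation import ContactMap, ResidueKey, StructureModel

DEFAULT_CUTOFF = 15.0
ZERO_MODE_RTOL = 1e-8


@dataclass
class ElasticNetworkModel:
    nodes: list[ResidueKey]
    coords: np.ndarray            # N x 3
    cutoff: float
    spring_constant: float
    hessian: np.ndarray           # 3N x 3N

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class CrossCorrelationMatrix:
    nodes: list[ResidueKey]
    matrix: np.ndarray            # N x N, symmetric, unit diagonal

    def index(self, key: ResidueKey) -> int:
        return self.nodes.index(key)


@dataclass
class CouplingDynamicsResult:
    r2: float
    correlation: float
    p_value: float
    n: int
    x: np.ndarray                 # per-residue mean coupling to LBRs
    y: np.ndarray                 # per-residue mean DCCM to LBRs
    residues: list[ResidueKey]


def _ca_nodes(s: StructureModel) -> tuple[list[ResidueKey], np.ndarray]:
    nodes, coords = [], []
    for key, atoms in s.residues().items():
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is not None:
            nodes.append(key)
            coords.append(ca.coord)
    return nodes, np.array(coords, dtype=float)


def build_enm(
    s: StructureModel | tuple,
    cutoff: float = DEFAULT_CUTOFF,
    spring_constant: float = 1.0,
) -> ElasticNetworkModel:
    """Anisotropic network model over Cα nodes.

    Off-diagonal 3x3 super-element for a connected pair is
    -k * (d d^T) / |d|²; diagonal blocks are negative row sums.
    """
    if isinstance(s, StructureModel):
        nodes, coords = _ca_nodes(s)
    else:
        nodes, coords = s
        coords = np.asarray(coords, dtype=float)
    n = len(nodes)
    if n < 2:
        # the two-node spring is a valid (and tested) limit case
        raise ValueError("need >= 2 residues with a CA atom")

    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(cutoff))

    adj_rows = [i for i, j in pairs] + [j for i, j in pairs]
    adj_cols = [j for i, j in pairs] + [i for i, j in pairs]
    adj = csr_matrix(
        (np.ones(len(adj_rows)), (adj_rows, adj_cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} Å: "
            f"{n_comp} components with sizes {sizes.tolist()}"
        )

    hessian = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = coords[j] - coords[i]
        d2 = float(d @ d)
        block = -spring_constant * np.outer(d, d) / d2
        hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return ElasticNetworkModel(
        nodes=nodes, coords=coords, cutoff=cutoff,
        spring_constant=spring_constant, hessian=hessian,
    )


def mode_spectrum(enm: ElasticNetworkModel) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors of the Hessian."""
    vals, vecs = np.linalg.eigh(enm.hessian)
    return vals, vecs


def n_zero_modes(eigvals: np.ndarray, rtol: float = ZERO_MODE_RTOL) -> int:
    return int(np.sum(eigvals < rtol * eigvals.max()))


def compute_dccm(
    enm: ElasticNetworkModel, rtol: float = ZERO_MODE_RTOL
) -> CrossCorrelationMatrix:
    """DCCM from the pseudoinverse of the Hessian over all non-rigid modes."""
    vals, vecs = mode_spectrum(enm)
    keep = vals >= rtol * vals.max()
    if not keep.any():
        raise ValueError("no internal modes")
    inv = vecs[:, keep] / vals[keep]
    cov = inv @ vecs[:, keep].T

    n = enm.n_nodes
    # trace of each 3x3 block
    traces = np.zeros((n, n))
    for k in range(3):
        traces += cov[k::3, k::3]
    diag = np.diag(traces)
    if np.any(diag <= 0):
        raise ValueError("singular normalization: node with zero variance")
    norm = np.sqrt(np.outer(diag, diag))
    matrix = traces / norm
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 1.0)
    return CrossCorrelationMatrix(nodes=list(enm.nodes), matrix=matrix)


def coupling_dynamics_r2(
    cm: CouplingMatrix,
    dccm: CrossCorrelationMatrix,
    interface: set | frozenset,
    lbr_set: set | frozenset,
    exclude_direct: bool = False,
    contacts: ContactMap | None = None,
    chains: set | None = None,
) -> CouplingDynamicsResult:
    """Squared Pearson correlation, over interface residues, between mean
    coupling to the LBRs and mean motional correlation with the LBRs.

    ``exclude_direct`` removes interface residues in direct contact with any
    LBR (requires ``contacts``); ``chains`` optionally restricts the
    interface residues used to specific chains.
    """
    node_index = {key: i for i, key in enumerate(dccm.nodes)}
    lbrs = [k for k in sorted(lbr_set) if k in node_index]
    if not lbrs:
        raise ValueError("no LBRs present in the DCCM")
    used = [k for k in sorted(interface) if k in node_index]
    if chains is not None:
        used = [k for k in used if k.chain in chains]
    if exclude_direct:
        if contacts is None:
            raise ValueError("exclude_direct requires a contact map")
        lbr_all = set(lbr_set)
        used = [
            k for k in used
            if not any(
                frozenset((k, l)) in contacts.residue_pairs for l in lbr_all
            )
        ]
    used = [k for k in used if k not in set(lbrs)]
    # one point per sequence position: homodimer chains map to the same
    # coupling columns, so keeping both would duplicate observations
    seen_cols: set[int] = set()
    deduped = []
    for k in used:
        col = cm.column(k)
        if col is None or col in seen_cols:
            continue
        seen_cols.add(col)
        deduped.append(k)
    used = deduped
    if len(used) < 5:
        raise ValueError(
            f"need >= 5 interface residues after exclusions (got {len(used)})"
        )

    lbr_nodes = [node_index[k] for k in lbrs]
    x, y = [], []
    for k in used:
        cols = cm.pair_scores([(k, l) for l in lbrs])
        if cols.size == 0:
            continue
        x.append(float(np.nanmean(cols)))
        y.append(float(np.mean(dccm.matrix[node_index[k], lbr_nodes])))
    x = np.array(x)
    y = np.array(y)
    if x.size < 5:
        raise ValueError("fewer than 5 mapped interface residues")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant coupling or correlation values")
    r, p = pearsonr(x, y)
    return CouplingDynamicsResult(
        r2=float(r * r), correlation=float(r), p_value=float(p),
        n=int(x.size), x=x, y=y, residues=used[: x.size],
    )
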