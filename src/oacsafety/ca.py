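"""Correspondence analysis of the drug × SOC table, with contribution biplots.

The correspondence matrix P = O/n is centred by the outer product of its row
masses r and column masses c and standardized cell-wise:

    S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)

The SVD S = U diag(sigma) V' yields principal inertias lambda_k = sigma_k^2
(summing to Pearson's chi-square / n), principal coordinates
F = diag(r)^{-1/2} U diag(sigma) for the SOC rows and
G = diag(c)^{-1/2} V diag(sigma) for the drug columns, and contributions
ctr_row[i,k] = r_i F[i,k]^2 / lambda_k (columns analogous).

Biplots use the *contribution* scaling: drugs are plotted as points in
principal coordinates, SOCs as vectors whose coordinates are the left
singular vectors U (standard coordinates scaled by sqrt of mass), so the
squared vector coordinate equals the SOC's contribution to that dimension —
the longer the vector, the more that SOC drives the displayed separation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contingency import ContingencyTable

_EPS = 1e-14


@dataclass
class CAResult:
    socs: tuple[str, ...]
    drugs: tuple[str, ...]
    row_masses: np.ndarray          # r_i
    col_masses: np.ndarray          # c_j
    singular_values: np.ndarray     # sigma_k, K = min(I, J) - 1 entries
    inertia: np.ndarray             # lambda_k = sigma_k^2
    inertia_share: np.ndarray       # lambda_k / total (zeros if total == 0)
    row_principal: np.ndarray       # F, I × K
    col_principal: np.ndarray       # G, J × K
    row_contrib: np.ndarray         # ctr per SOC × dim
    col_contrib: np.ndarray         # ctr per drug × dim
    biplot_vectors: np.ndarray      # U: SOC arrows, squared = contribution
    retained_dims: int = 2

    @property
    def total_inertia(self) -> float:
        return float(self.inertia.sum())


def fit_ca(table: ContingencyTable) -> CAResult:
    """Correspondence analysis of a contingency table via SVD.

    Requires at least a 2×2 table with no zero margins. An exactly
    independent table is valid and yields zero inertia and all-zero
    coordinates.
    """
    counts = table.counts.astype(float)
    n_rows, n_cols = counts.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("correspondence analysis needs at least a 2x2 table")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    r = counts.sum(axis=1) / n
    c = counts.sum(axis=0) / n
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("zero margin; drop empty rows/columns first")

    P = counts / n
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    K = min(n_rows, n_cols) - 1
    U, sigma, V = U[:, :K], sigma[:K], Vt[:K].T
    sigma = np.where(sigma < _EPS, 0.0, sigma)

    # SVD sign indeterminacy: force the largest-magnitude row loading positive
    for k in range(K):
        pivot = np.argmax(np.abs(U[:, k]))
        if U[pivot, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1

    F = U * sigma / np.sqrt(r)[:, None]
    G = V * sigma / np.sqrt(c)[:, None]
    lam = sigma**2
    with np.errstate(invalid="ignore", divide="ignore"):
        ctr_row = np.where(lam > _EPS, r[:, None] * F**2 / lam, 0.0)
        ctr_col = np.where(lam > _EPS, c[:, None] * G**2 / lam, 0.0)
    total = lam.sum()
    share = lam / total if total > _EPS else np.zeros_like(lam)
    result = CAResult(
        socs=table.socs, drugs=table.drugs,
        row_masses=r, col_masses=c,
        singular_values=sigma, inertia=lam, inertia_share=share,
        row_principal=F, col_principal=G,
        row_contrib=ctr_row, col_contrib=ctr_col,
        biplot_vectors=U,
    )
    result.retained_dims = retain_dimensions(result)
    return result


def retain_dimensions(result: CAResult) -> int:
    """Number of dimensions to interpret, by the average-inertia rule.

    Dimensions whose inertia share exceeds the uniform expectation
    1/(min(I,J)-1) are kept; a floor of two dimensions applies so a biplot
    is always drawable.
    """
    n_dims = len(result.inertia)
    if n_dims == 0:
        return 0
    threshold = 1.0 / n_dims
    leading = 0
    for share in result.inertia_share:
        if share > threshold:
            leading += 1
        else:
            break
    return min(max(2, leading), n_dims)


@dataclass(frozen=True)
class VariableSelection:
    """SOCs most responsible for the separation in the retained dimensions."""

    threshold: float                 # 1 / number of SOCs analysed
    contributions: pd.Series         # inertia-weighted mean ctr over retained dims
    selected: tuple[str, ...]        # above-threshold SOCs, by contribution
    top: tuple[str, ...]             # top-n SOCs, by contribution


def select_variables(
    result: CAResult, dims: int | None = None, top_n: int = 5
) -> VariableSelection:
    """Rank SOCs by inertia-weighted mean contribution over retained dims.

    The importance threshold is the uniform-contribution expectation, i.e.
    the reciprocal of the number of SOCs analysed. ``top_n`` larger than the
    number of SOCs is clamped. Ties break lexicographically on SOC code.
    """
    dims = dims if dims is not None else result.retained_dims
    if dims > len(result.inertia):
        raise ValueError("dims exceeds available dimensions")
    lam = result.inertia[:dims]
    weight = lam.sum()
    if weight > _EPS:
        agg = (result.row_contrib[:, :dims] * lam).sum(axis=1) / weight
    else:
        agg = np.zeros(len(result.socs))
    contributions = pd.Series(agg, index=list(result.socs), name="contribution")
    order = sorted(contributions.index, key=lambda s: (-contributions[s], s))
    threshold = 1.0 / len(result.socs)
    selected = tuple(s for s in order if contributions[s] > threshold)
    top_n = min(top_n, len(order))
    return VariableSelection(
        threshold=threshold,
        contributions=contributions,
        selected=selected,
        top=tuple(order[:top_n]),
    )


def profile_distance_ranking(result: CAResult, dims: int | None = None) -> pd.DataFrame:
    """Pairwise drug distances in the retained principal coordinates, ascending.

    Nearby drugs have similar reaction profiles (in retained dimensions the
    Euclidean distance approximates the chi-square distance between the
    drugs' SOC profiles).
    """
    dims = dims if dims is not None else result.retained_dims
    G = result.col_principal[:, :dims]
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(result.drugs), 2):
        rows.append(dict(drug_a=a, drug_b=b,
                         distance=float(np.linalg.norm(G[i] - G[j]))))
    return pd.DataFrame(rows).sort_values(
        ["distance", "drug_a", "drug_b"], ignore_index=True
    )


def coordinates_frame(result: CAResult, dims: int = 2) -> pd.DataFrame:
    """Biplot export: drugs as points, SOCs as contribution vectors."""
    dims = min(dims, result.row_principal.shape[1])
    rows = []
    for j, drug in enumerate(result.drugs):
        rows.append(
            dict(entity=drug, type="point", mass=float(result.col_masses[j]),
                 **{f"dim{k + 1}": float(result.col_principal[j, k]) for k in range(dims)},
                 **{f"contribution_dim{k + 1}": float(result.col_contrib[j, k])
                    for k in range(dims)})
        )
    for i, soc in enumerate(result.socs):
        rows.append(
            dict(entity=soc, type="vector", mass=float(result.row_masses[i]),
                 **{f"dim{k + 1}": float(result.biplot_vectors[i, k]) for k in range(dims)},
                 **{f"contribution_dim{k + 1}": float(result.row_contrib[i, k])
                    for k in range(dims)})
        )
    return pd.DataFrame(rows)


def inertia_frame(result: CAResult) -> pd.DataFrame:
    """Inertia spectrum export: one row per dimension, with cumulative share."""
    return pd.DataFrame(
        dict(
            dim=np.arange(1, len(result.inertia) + 1),
            singular_value=result.singular_values,
            inertia=result.inertia,
            share=result.inertia_share,
            cumulative=np.cumsum(result.inertia_share),
        )
    )
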