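"""Structural connectome handling and the symmetric normalized graph Laplacian.

The diffusion engine operates on the symmetric normalized Laplacian

    L = I - D^(-1/2) C D^(-1/2)

of an undirected, weighted, nonnegative structural connectivity matrix C
(streamline-count-derived weights between grey-matter regions), with D the
diagonal degree matrix (row sums of C).  The region ordering of the
connectome is the canonical ordering for every downstream regional vector;
tau tables are re-indexed to it by label, never by column position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative max asymmetry tolerated before warning-symmetrization
SYMMETRY_RTOL = 1e-8


class ConnectomeError(ValueError):
    """Raised for structurally invalid connectivity input."""


@dataclass
class Connectome:
    """Validated undirected weighted brain graph.

    Attributes
    ----------
    weights : (n, n) ndarray
        Symmetric nonnegative connection weights, zero diagonal.
    region_labels : list of str
        Canonical region ordering for all downstream vectors.
    """

    weights: np.ndarray
    region_labels: list[str]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def degree(self) -> np.ndarray:
        """Per-region degree (row sums of the weight matrix)."""
        return self.weights.sum(axis=1)

    @classmethod
    def from_array(
        cls, weights: np.ndarray, region_labels: Sequence[str] | None = None
    ) -> "Connectome":
        """Validate a raw weight matrix and return a :class:`Connectome`.

        Asymmetry above ``SYMMETRY_RTOL`` is resolved by averaging the two
        directions, (W + W.T) / 2, with a logged warning; the diagonal is
        zeroed.  Negative weights, non-square input, and isolated regions
        (zero degree) are rejected.
        """
        W = np.asarray(weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ConnectomeError(f"connectome matrix must be square, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ConnectomeError("connectome contains non-finite entries")
        if np.any(W < 0):
            raise ConnectomeError("connectome contains negative weights")

        scale = np.abs(W).max()
        if scale > 0 and np.abs(W - W.T).max() > SYMMETRY_RTOL * scale:
            logger.warning(
                "CONN_ASYMMETRY: input asymmetric (max dev %.3g); "
                "averaging both directions",
                np.abs(W - W.T).max(),
            )
            W = 0.5 * (W + W.T)
        else:
            W = 0.5 * (W + W.T)  # remove sub-tolerance noise too
        np.fill_diagonal(W, 0.0)

        if region_labels is None:
            region_labels = [f"region_{i}" for i in range(W.shape[0])]
        labels = [str(x) for x in region_labels]
        if len(labels) != W.shape[0]:
            raise ConnectomeError(
                f"{len(labels)} labels for {W.shape[0]} regions"
            )
        if len(set(labels)) != len(labels):
            raise ConnectomeError("duplicate region labels")

        deg = W.sum(axis=1)
        if np.any(deg <= 0):
            bad = [labels[i] for i in np.nonzero(deg <= 0)[0]]
            raise ConnectomeError(f"isolated regions with zero degree: {bad}")
        return cls(weights=W, region_labels=labels)


@dataclass
class Laplacian:
    """Symmetric normalized graph Laplacian with cached eigendecomposition.

    ``matrix`` is I - D^(-1/2) C D^(-1/2).  It is symmetric positive
    semi-definite, its eigenvalues lie in [0, 2], and sqrt(degree) spans its
    null space.  The eigendecomposition is computed lazily once and reused
    by the diffusion engine for every (alpha, beta, s) evaluation.
    """

    matrix: np.ndarray
    region_labels: list[str]
    degree: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and orthonormal eigenvectors (ascending), cached."""
        if self._eig is None:
            w, V = np.linalg.eigh(self.matrix)
            self._eig = (w, V)
        return self._eig


def build_laplacian(c: Connectome) -> Laplacian:
    """Build L = I - D^(-1/2) C D^(-1/2) from a validated connectome."""
    deg = c.degree
    if np.any(deg <= 0):
        raise ConnectomeError("zero-degree region: normalized Laplacian undefined")
    dinv = 1.0 / np.sqrt(deg)
    L = np.eye(c.n_regions) - (dinv[:, None] * c.weights) * dinv[None, :]
    L = 0.5 * (L + L.T)  # enforce exact symmetry against rounding
    return Laplacian(matrix=L, region_labels=list(c.region_labels), degree=deg.copy())


def _looks_numeric(values: Sequence) -> bool:
    try:
        np.asarray(values, dtype=float)
        return True
    except (TypeError, ValueError):
        return False


def load_connectome(
    path: str | Path, labels: Sequence[str] | None = None
) -> Connectome:
    """Load a dense connectivity matrix from CSV/TSV.

    The file may carry region labels as a header row and/or a first column;
    both are detected by attempting numeric conversion.  Explicit ``labels``
    override anything found in the file.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, header=None, comment="#", float_precision="round_trip")

    file_labels: list[str] | None = None
    if not _looks_numeric(raw.iloc[0].tolist()):
        file_labels = [str(x) for x in raw.iloc[0].tolist()]
        raw = raw.iloc[1:].reset_index(drop=True)
    if raw.shape[1] and not _looks_numeric(raw.iloc[:, 0].tolist()):
        col_labels = [str(x) for x in raw.iloc[:, 0].tolist()]
        raw = raw.iloc[:, 1:]
        if file_labels is not None and len(file_labels) == len(col_labels) + 1:
            file_labels = file_labels[1:]  # header had a corner cell
        if file_labels is None:
            file_labels = col_labels

    W = raw.to_numpy(dtype=float)
    return Connectome.from_array(W, labels if labels is not None else file_labels)


def read_region_mask(path: str | Path) -> list[str]:
    """Read an exclusion mask file: one region label per line, '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
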