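"""Genomic relationship matrices: additive (G), dominance (D) and epistatic.

G follows the centered-dosage construction G = MM' / sum_j 2 p_j q_j with
row entries (2-2p, 1-2p, -2p) for dosages (2, 1, 0), frequencies taken
from the genotyped individuals themselves.  D uses the dominance coding
(-2p^2, 2pq, -2q^2) scaled by sum_j 4 p_j^2 q_j^2; under Hardy-Weinberg
proportions this coding is orthogonal to the additive one.  The
additive-by-additive epistatic kernel is the Hadamard (elementwise)
product G * G.

Sites monomorphic in the frequency reference carry no information and the
scalings assume 2pq > 0, so such columns are excluded (with a logged
count) before building any kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .traits import QTNSet

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSet",
    "additive_grm",
    "dominance_grm",
    "hadamard_kernel",
    "marker_subset",
    "build_kernels",
]


def _check_freqs(dosages: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dosages = np.asarray(dosages)
    freqs = np.asarray(freqs, dtype=float)
    if dosages.shape[1] != len(freqs):
        raise ValueError("dosage columns do not align with frequency vector")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError(
            "monomorphic site in frequency reference; exclude such sites upstream"
        )
    return dosages, freqs


def additive_grm(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Additive GRM: center dosages by 2p, G = MM' / sum 2pq."""
    dosages, p = _check_freqs(dosages, freqs)
    M = dosages.astype(np.float64) - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    G = (M @ M.T) / denom
    return 0.5 * (G + G.T)


def dominance_grm(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Dominance GRM: D = Md Md' / sum 4 p^2 q^2 with the centered dominance
    coding (-2q^2, 2pq, -2p^2) for dosages (2, 1, 0) of the allele with
    frequency p — zero mean and orthogonal to the additive code under
    Hardy-Weinberg proportions."""
    dosages, p = _check_freqs(dosages, freqs)
    q = 1.0 - p
    d = dosages
    Md = np.empty(d.shape, dtype=np.float64)
    Md[:] = np.where(d == 2, -2.0 * q * q, np.where(d == 1, 2.0 * p * q, -2.0 * p * p))
    denom = float(np.sum(4.0 * p * p * q * q))
    D = (Md @ Md.T) / denom
    return 0.5 * (D + D.T)


def hadamard_kernel(G: np.ndarray) -> np.ndarray:
    """Additive-by-additive epistatic kernel: elementwise square of G."""
    G = np.asarray(G)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    return G * G


@dataclass
class KernelSet:
    """Relationship matrices for one evaluation cycle."""

    G: np.ndarray
    D: np.ndarray | None
    GxG: np.ndarray | None
    freqs_used: np.ndarray
    marker_set: str  # {"all_sites", "qtn_only"}
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.G.shape[0]
        for K, name in ((self.G, "G"), (self.D, "D"), (self.GxG, "GxG")):
            if K is not None and K.shape != (n, n):
                raise ValueError(f"{name} has inconsistent shape")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def matrices(self) -> dict[str, np.ndarray]:
        out = {"G": self.G}
        if self.D is not None:
            out["D"] = self.D
        if self.GxG is not None:
            out["GxG"] = self.GxG
        return out

    def to_tsv(self, path, which: str = "G") -> None:
        """Write one kernel as a square TSV with an id header row/column."""
        import pandas as pd

        K = self.matrices()[which]
        ids = (self.individual_ids if self.individual_ids is not None
               else np.arange(self.n))
        pd.DataFrame(K, index=ids, columns=ids).to_csv(path, sep="\t")


def marker_subset(
    dosages: np.ndarray,
    qtn: QTNSet | None,
    mode: str = "all_sites",
) -> tuple[np.ndarray, np.ndarray]:
    """Select marker columns: every site, or the causal QTN only.

    Returns ``(dosage_submatrix, column_indices)``.  Columns monomorphic in
    the submatrix are retained here; frequency-based exclusion happens in
    :func:`build_kernels` against the frequency reference.
    """
    dosages = np.asarray(dosages)
    if mode == "all_sites":
        cols = np.arange(dosages.shape[1])
    elif mode == "qtn_only":
        if qtn is None:
            raise ValueError("qtn_only mode requires a QTNSet")
        cols = np.asarray(qtn.site_index)
    else:
        raise ValueError(f"unknown marker mode {mode!r}")
    if len(cols) == 0:
        raise ValueError("empty marker selection")
    return dosages[:, cols], cols


def build_kernels(
    dosages: np.ndarray,
    qtn: QTNSet | None = None,
    marker_set: str = "all_sites",
    with_nonadditive: bool = False,
    freqs: np.ndarray | None = None,
    individual_ids: np.ndarray | None = None,
) -> KernelSet:
    """Build G (and optionally D, G*G) from a dosage matrix.

    Frequencies default to those of the genotyped individuals themselves
    (dosage mean / 2).  Monomorphic columns in that reference are dropped
    with a logged count.
    """
    sub, cols = marker_subset(dosages, qtn, marker_set)
    if freqs is None:
        p = sub.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=float)[cols]
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("excluding %d monomorphic sites from kernels", n_mono)
        sub, p = sub[:, poly], p[poly]
    if sub.shape[1] == 0:
        raise ValueError("no polymorphic markers left for kernel construction")
    G = additive_grm(sub, p)
    D = dominance_grm(sub, p) if with_nonadditive else None
    GxG = hadamard_kernel(G) if with_nonadditive else None
    return KernelSet(G=G, D=D, GxG=GxG, freqs_used=p, marker_set=marker_set,
                     individual_ids=individual_ids)
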