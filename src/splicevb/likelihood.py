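"""Multinomial read-group likelihood and effective lengths for skipped-exon events.

For one event in one cell the three group counts are multinomial with
proportions obtained by mixing the two isoforms' effective lengths with the
splicing ratio psi:

    rho_k  proportional to  psi * L[0, k] + (1 - psi) * L[1, k].

Effective length ``L[h, k]`` is the number of read start positions on
isoform ``h`` producing a read of group ``k``.  The authoritative
construction enumerates every start position; closed forms are a checked
fast path.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit

__all__ = [
    "SEExonStructure",
    "GroupProbabilities",
    "VELOCITY_LENGTHS",
    "effective_lengths_se",
    "effective_lengths_se_closed",
    "compute_rho",
    "log_likelihood",
]

#: Length matrix for velocity mode (spliced / unspliced pseudo-isoforms):
#: unit lengths, no ambiguous group, so rho = (psi, 1 - psi, 0).
VELOCITY_LENGTHS = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

# z beyond this magnitude gives psi indistinguishable from 0/1 but still
# strictly inside (0, 1) in float64, keeping log(rho) finite during fitting.
_Z_CLIP = 30.0


@dataclasses.dataclass(frozen=True)
class SEExonStructure:
    """Exon and read geometry of a skipped-exon event (lengths in nt).

    Isoform 1 is exon1-exon2-exon3 (inclusion); isoform 2 is exon1-exon3
    (exclusion).  ``min_overhang`` is the number of bases a read must extend
    past a junction boundary on each side to count as isoform-unique.
    """

    e1_len: int
    e2_len: int
    e3_len: int
    read_len: int
    min_overhang: int = 1

    def __post_init__(self) -> None:
        if min(self.e1_len, self.e2_len, self.e3_len, self.read_len) < 1:
            raise ValueError("exon lengths and read length must be >= 1")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")


@dataclasses.dataclass(frozen=True)
class GroupProbabilities:
    """Read-group proportion vector for one (cell, event)."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", rho)
        if rho.shape != (3,) or np.any(rho < 0):
            raise ValueError("rho must be a non-negative 3-vector")
        if abs(rho.sum() - 1.0) > 1e-12:
            raise ValueError("rho must sum to 1")


def effective_lengths_se(structure: SEExonStructure) -> np.ndarray:
    """Effective-length matrix of a skipped-exon event by position enumeration.

    Every read start position on each isoform is classified:

    * isoform 1: a read is isoform-1-unique when it reaches at least
      ``min_overhang`` nt past the exon1|exon2 boundary and at least
      ``min_overhang`` nt before the exon2|exon3 boundary (unambiguous
      evidence of the included exon); otherwise ambiguous.
    * isoform 2: a read is isoform-2-unique when it spans the exon1|exon3
      junction with >= ``min_overhang`` nt on each side; otherwise ambiguous.

    Positions with sub-overhang junction evidence are counted as ambiguous
    symmetrically on both isoforms: the shared ambiguous length is taken
    from the isoform-1 enumeration, so ``l13 == l23`` holds exactly in all
    geometries.

    Returns
    -------
    ndarray, shape (2, 3)
        ``[[l11, 0, l13], [0, l22, l13]]``.
    """
    e1, e2, e3 = structure.e1_len, structure.e2_len, structure.e3_len
    r, h = structure.read_len, structure.min_overhang
    if r < 2 * h:
        warnings.warn(
            f"read_len={r} < 2*min_overhang={2 * h}: no junction read can be "
            "isoform-2-unique (l22 = 0)",
            stacklevel=2,
        )

    # isoform 1: exon1-exon2-exon3, coordinates 0 .. e1+e2+e3-1
    n1 = e1 + e2 + e3 - r + 1
    group1 = 0
    amb1 = 0
    for p in range(max(n1, 0)):
        end = p + r - 1
        if end >= e1 + h - 1 and p <= e1 + e2 - h:
            group1 += 1
        else:
            amb1 += 1

    # isoform 2: exon1-exon3, junction after coordinate e1-1
    n2 = e1 + e3 - r + 1
    group2 = 0
    for p in range(max(n2, 0)):
        end = p + r - 1
        if p <= e1 - h and end >= e1 + h - 1:
            group2 += 1

    return np.array(
        [[float(group1), 0.0, float(amb1)], [0.0, float(group2), float(amb1)]]
    )


def effective_lengths_se_closed(structure: SEExonStructure) -> np.ndarray:
    """Closed-form effective lengths; valid when ``min(e1, e3) >= read_len``.

    ``l11 = e2 + r - 2h + 1`` and ``l22 = r - 2h + 1`` (clamped at zero);
    the ambiguous length is the remaining isoform-1 start positions,
    ``e1 + e2 + e3 - r + 1 - l11``, which reduces to the generic
    ``e1 + e3 - 2r + 2h`` whenever the l11 clamp does not bind.
    """
    e1, e2, e3 = structure.e1_len, structure.e2_len, structure.e3_len
    r, h = structure.read_len, structure.min_overhang
    if min(e1, e3) < r:
        raise ValueError("closed form requires min(e1, e3) >= read_len")
    l11 = max(0, e2 + r - 2 * h + 1)
    l22 = max(0, r - 2 * h + 1)
    l13 = max(0, e1 + e2 + e3 - r + 1) - l11
    return np.array([[float(l11), 0.0, float(l13)], [0.0, float(l22), float(l13)]])


def compute_rho(psi: float, L: np.ndarray) -> GroupProbabilities:
    """Read-group proportions for splicing ratio ``psi`` and length matrix ``L``."""
    L = np.asarray(L, dtype=float)
    if L.shape != (2, 3) or np.any(L < 0) or not np.any(L > 0):
        raise ValueError("L must be a non-negative 2x3 matrix with a positive entry")
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi={psi} outside [0, 1]")
    num = psi * L[0] + (1.0 - psi) * L[1]
    total = num.sum()
    if total <= 0:
        raise ValueError(
            "degenerate mixture: selected isoform has all-zero effective lengths"
        )
    return GroupProbabilities(rho=num / total)


def log_likelihood(s, psi: float, L: np.ndarray) -> float:
    """Multinomial log-likelihood of group counts ``s`` (constant omitted).

    Returns ``sum_k s_k * log(rho_k)``; the multinomial coefficient is
    dropped since it is constant in psi and cancels in ELBO differences.
    Zero counts contribute zero even where ``rho_k == 0``; a positive count
    in a zero-probability group gives ``-inf``.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (3,) or np.any(s < 0) or np.any(s != np.floor(s)):
        raise ValueError("s must be a non-negative integer 3-vector")
    rho = compute_rho(psi, L).rho
    out = 0.0
    for k in range(3):
        if s[k] > 0:
            if rho[k] == 0:
                return -np.inf
            out += s[k] * np.log(rho[k])
    return float(out)


# ---------------------------------------------------------------------------
# Vectorised internals shared with the inference engine
# ---------------------------------------------------------------------------

def _split_lengths(lengths: np.ndarray):
    """Per-event isoform length rows and their totals: (l1, l2, T1, T2)."""
    l1 = lengths[:, 0, :]
    l2 = lengths[:, 1, :]
    return l1, l2, l1.sum(axis=1), l2.sum(axis=1)


def loglik_from_z(z, counts, lengths):
    """Log-likelihood per (..., cell, event) at logit-scale z (constant omitted).

    Parameters
    ----------
    z : ndarray broadcastable to (..., M, N)
    counts : ndarray (M, N, 3)
    lengths : ndarray (N, 2, 3)
    """
    l1, l2, T1, T2 = _split_lengths(lengths)
    psi = expit(np.clip(z, -_Z_CLIP, _Z_CLIP))
    S = counts
    num = psi[..., None] * l1 + (1.0 - psi[..., None]) * l2
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(S > 0, S * np.log(num), 0.0)
    total = psi * T1 + (1.0 - psi) * T2
    n = S.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(n > 0, n * np.log(total), 0.0)
    return term.sum(axis=-1) - norm


def loglik_and_grad_z(z, counts, lengths):
    """Log-likelihood and its gradient with respect to z, vectorised.

    Returns ``(ll, dll_dz)`` each of the broadcast shape of ``z`` against
    (M, N).
    """
    l1, l2, T1, T2 = _split_lengths(lengths)
    zc = np.clip(z, -_Z_CLIP, _Z_CLIP)
    psi = expit(zc)
    S = counts
    num = psi[..., None] * l1 + (1.0 - psi[..., None]) * l2
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(S > 0, S * np.log(num), 0.0)
        gradterm = np.where(S > 0, S * (l1 - l2) / num, 0.0)
    total = psi * T1 + (1.0 - psi) * T2
    n = S.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = logterm.sum(axis=-1) - np.where(n > 0, n * np.log(total), 0.0)
        dll_dpsi = gradterm.sum(axis=-1) - np.where(n > 0, n * (T1 - T2) / total, 0.0)
    dll_dz = dll_dpsi * psi * (1.0 - psi)
    return ll, dll_dz
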