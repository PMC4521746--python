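"""Tandemer algebra.

A tandem mass spectrometer isolates a parent ion, fragments it, and measures
the mass of a product ion.  For an isotope tracing experiment this yields, for
a chosen *metabolite fragment pair* (MFP) ``A^N_K`` — parent fragment ``N``
(atoms retained in the MS1 ion) and product fragment ``K ⊆ N`` (atoms retained
in the MS2 ion) — the relative abundance of every transition
``[M+i] > [m+j]`` from a parent ion carrying ``i`` labeled atoms to a product
ion carrying ``j``.  These abundances form the *tandemer distribution matrix*,
a ``(|N|+1) x (|K|+1)`` probability matrix.

This module holds the pure in-memory algebra over such matrices: feasibility
of individual transitions, marginalization of a full positional isotopomer
distribution onto an MFP, the Cauchy product that combines the matrices of two
condensation substrates, and the parent/product mass-isotopomer marginals.
Atom indices are 1-based everywhere on the interface, matching the fragment
notation ``A^{2,3,4}_{2,3}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .errors import ValidationError

#: entries more negative than this raise; less negative are clamped to zero
NEGATIVE_CLAMP_TOL = 1e-12
#: tolerance on probability normalization of produced matrices
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class Metabolite:
    """A network species with ``n_atoms`` tracked atoms (e.g. carbons).

    ``is_media`` marks species whose positional labeling is supplied
    externally (tracer specification) rather than balanced.
    """

    id: str
    n_atoms: int
    is_media: bool = False

    def __post_init__(self):
        if self.n_atoms < 0:
            raise ValidationError(f"metabolite {self.id!r}: n_atoms must be >= 0")


@dataclass(frozen=True, order=True)
class MFP:
    """A metabolite fragment pair ``A^N_K`` with ``K ⊆ N ⊆ {1..n}``.

    ``parent`` and ``product`` are stored sorted, so equality and ordering are
    canonical.  The product fragment may be empty (the matrix degenerates to a
    column vector holding the parent mass-isotopomer distribution).
    """

    metabolite: str
    parent: tuple[int, ...]
    product: tuple[int, ...]

    def __init__(self, metabolite: str, parent, product):
        object.__setattr__(self, "metabolite", metabolite)
        object.__setattr__(self, "parent", tuple(sorted(parent)))
        object.__setattr__(self, "product", tuple(sorted(product)))
        if len(set(self.parent)) != len(self.parent):
            raise ValidationError(f"{self}: duplicate parent atoms")
        if not set(self.product) <= set(self.parent):
            raise ValidationError(f"{self}: product fragment not within parent")
        if any(a < 1 for a in self.parent):
            raise ValidationError(f"{self}: atom indices are 1-based")

    @property
    def n_parent(self) -> int:
        return len(self.parent)

    @property
    def n_product(self) -> int:
        return len(self.product)

    @property
    def shape(self) -> tuple[int, int]:
        """Shape of the tandemer distribution matrix for this MFP."""
        return (self.n_parent + 1, self.n_product + 1)

    def __repr__(self) -> str:  # e.g. E[1,2,3,4|2,3]
        p = ",".join(map(str, self.parent))
        q = ",".join(map(str, self.product))
        return f"{self.metabolite}[{p}|{q}]"


def is_feasible(i: int, j: int, n_parent: int, n_product: int) -> bool:
    """Whether the tandemer ``[M+i] > [m+j]`` is a non-empty isotopomer set.

    The product fragment is enclosed in the parent fragment, so ``j`` cannot
    exceed ``i``; and at most ``|N| - |K|`` labels can sit outside the product
    fragment, so ``j >= i - (|N| - |K|)``.
    """
    if not (0 <= n_product <= n_parent):
        raise ValidationError(f"need 0 <= n_product <= n_parent, got {n_product}, {n_parent}")
    if not (0 <= i <= n_parent and 0 <= j <= n_product):
        raise ValidationError(f"(i={i}, j={j}) out of range for sizes ({n_parent}, {n_product})")
    return i - (n_parent - n_product) <= j <= i


def n_feasible(n_parent: int, n_product: int) -> int:
    """Number of feasible tandemers, ``(|N| - |K| + 1)(|K| + 1)``."""
    if not (0 <= n_product <= n_parent):
        raise ValidationError(f"need 0 <= n_product <= n_parent, got {n_product}, {n_parent}")
    return (n_parent - n_product + 1) * (n_product + 1)


def feasible_mask(n_parent: int, n_product: int) -> np.ndarray:
    """Boolean mask of shape ``(|N|+1, |K|+1)``, True on feasible entries."""
    i = np.arange(n_parent + 1)[:, None]
    j = np.arange(n_product + 1)[None, :]
    return (j <= i) & (j >= i - (n_parent - n_product))


def clamp_small_negatives(values: np.ndarray, tol: float = NEGATIVE_CLAMP_TOL) -> np.ndarray:
    """Zero out tiny floating-point negatives; larger ones signal a bad model."""
    if values.min(initial=0.0) < -tol:
        raise ValidationError(
            f"negative abundance {values.min():.3e} beyond clamp tolerance {tol:g}"
        )
    return np.where(values < 0, 0.0, values) + 0.0  # also drops negative zeros


@dataclass
class TandemerMatrix:
    """A ``(|N|+1) x (|K|+1)`` probability matrix over ``[M+i] > [m+j]``.

    Entry ``(i, j)`` is the relative abundance of the tandemer with ``i``
    labels in the parent fragment and ``j`` in the product fragment.
    Infeasible entries are identically zero; feasible entries sum to one.
    ``mfp`` may be None for anonymous matrices (e.g. raw Cauchy products).
    """

    values: np.ndarray
    mfp: MFP | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("tandemer matrix must be 2-D")
        if self.mfp is not None and self.values.shape != self.mfp.shape:
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match MFP {self.mfp} "
                f"shape {self.mfp.shape}"
            )

    @property
    def n_parent(self) -> int:
        return self.values.shape[0] - 1

    @property
    def n_product(self) -> int:
        return self.values.shape[1] - 1

    def validate(self, tol: float = NORMALIZATION_TOL) -> "TandemerMatrix":
        """Check normalization, non-negativity, and feasibility zeroing."""
        self.values = clamp_small_negatives(self.values)
        total = self.values.sum()
        if abs(total - 1.0) > tol:
            raise ValidationError(f"tandemer matrix sums to {total!r}, not 1")
        mask = feasible_mask(self.n_parent, self.n_product)
        if np.any(self.values[~mask] != 0.0):
            raise ValidationError("nonzero abundance on an infeasible tandemer")
        return self

    def is_normalized(self, tol: float = NORMALIZATION_TOL) -> bool:
        return abs(self.values.sum() - 1.0) <= tol


@dataclass
class IsotopomerDistribution:
    """Probability vector over all ``2^n`` positional labeling patterns.

    Index ``p`` corresponds to the binary string of ``p`` over ``n`` digits
    with atom 1 in the most significant position, e.g. for n=4 the pattern
    ``1001`` (atoms 1 and 4 labeled) is index 9.
    """

    metabolite: str
    values: np.ndarray
    n_atoms: int = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = int(self.values.size).bit_length() - 1
        if self.values.size != 1 << n:
            raise ValidationError(
                f"isotopomer vector for {self.metabolite!r} has length "
                f"{self.values.size}, not a power of two"
            )
        self.n_atoms = n

    @classmethod
    def from_patterns(
        cls, metabolite: str, n_atoms: int, patterns: dict[str, float]
    ) -> "IsotopomerDistribution":
        """Build from a sparse ``{'1001': 0.6, ...}`` mapping."""
        values = np.zeros(1 << n_atoms)
        for pat, frac in patterns.items():
            if len(pat) != n_atoms or set(pat) - {"0", "1"}:
                raise ValidationError(f"bad isotopomer pattern {pat!r} for {metabolite!r}")
            values[int(pat, 2)] += frac
        return cls(metabolite, values)

    def validate(self, tol: float = NORMALIZATION_TOL) -> "IsotopomerDistribution":
        self.values = clamp_small_negatives(self.values)
        total = self.values.sum()
        if abs(total - 1.0) > tol:
            raise ValidationError(
                f"isotopomer distribution of {self.metabolite!r} sums to {total!r}"
            )
        return self


def _atom_mask(atoms: tuple[int, ...], n_atoms: int) -> int:
    """Bit mask for 1-based atom indices (atom 1 = most significant bit)."""
    mask = 0
    for a in atoms:
        if not 1 <= a <= n_atoms:
            raise ValidationError(f"atom index {a} out of range 1..{n_atoms}")
        mask |= 1 << (n_atoms - a)
    return mask


def label_counts(n_atoms: int, atoms: tuple[int, ...]) -> np.ndarray:
    """For every pattern index, the number of labeled atoms within ``atoms``."""
    idx = np.arange(1 << n_atoms, dtype=np.uint32)
    return np.bitwise_count(idx & np.uint32(_atom_mask(atoms, n_atoms))).astype(np.intp)


def tandemer_from_isotopomers(dist: IsotopomerDistribution, mfp: MFP) -> TandemerMatrix:
    """Marginalize a full isotopomer distribution onto an MFP.

    Entry ``(i, j)`` collects the abundance of every isotopomer with ``i``
    labeled atoms inside the parent fragment and ``j`` inside the product
    fragment — the defining aggregation of the tandemer distribution.
    """
    if mfp.metabolite != dist.metabolite:
        raise ValidationError(f"MFP {mfp} does not belong to metabolite {dist.metabolite!r}")
    i_of = label_counts(dist.n_atoms, mfp.parent)
    j_of = label_counts(dist.n_atoms, mfp.product)
    values = np.zeros(mfp.shape)
    np.add.at(values, (i_of, j_of), dist.values)
    return TandemerMatrix(values, mfp).validate()


def cauchy_product(
    a: TandemerMatrix, b: TandemerMatrix, mfp: MFP | None = None
) -> TandemerMatrix:
    """2-D Cauchy product (full discrete convolution) of two tandemer matrices.

    ``C(i,j) = sum_{i1+i2=i, j1+j2=j} A(i1,j1) B(i2,j2)``: the labeling of a
    condensation product is the independent union of the labelings of its two
    substrate fragments, so label counts add and distributions convolve.
    The result has shape ``(pA+pB+1, kA+kB+1)``; infeasible entries come out
    zero automatically since the inputs have none.
    """
    for name, m in (("A", a), ("B", b)):
        if not m.is_normalized():
            warnings.warn(
                f"cauchy_product: operand {name} sums to {m.values.sum()!r}, not 1",
                stacklevel=2,
            )
    values = convolve2d(a.values, b.values, mode="full")
    return TandemerMatrix(clamp_small_negatives(values), mfp)


def parent_mid(t: TandemerMatrix) -> np.ndarray:
    """Mass-isotopomer distribution of the parent fragment (row sums)."""
    return t.values.sum(axis=1)


def product_mid(t: TandemerMatrix) -> np.ndarray:
    """Mass-isotopomer distribution of the product fragment (column sums)."""
    return t.values.sum(axis=0)
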