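"""Joint site frequency spectrum construction and summary-statistic binning.

The JSFS ``J`` is a ``(y1+1) x (y2+1)`` matrix: ``J[a, b]`` counts the sites
at which exactly ``a`` sequences of P1 and ``b`` of P2 carry the derived
allele, where "derived" means *different from the aligned outgroup base*.
Sites at which several non-outgroup nucleotides segregate (multiple hits)
enter through the same rule: every sequence differing from the outgroup
counts as a derived carrier.

Summary statistics are the sums of ``J`` over the ``n_SS`` classes of a
partition of ``A = {0..y1} x {0..y2}`` minus the invisible ``(0,0)`` cell and
the fixed-derived ``(y1,y2)`` cell.  The default partition crosses five
frequency classes per axis — absent, low (up to 10% of the sample),
intermediate, high (the mirror-image top band), and fixed — giving 25 cells
of which the two excluded corners are singletons: 23 statistics.  High- and
low-frequency polymorphisms are binned in a mirrored fashion because sites
with mutations on the outgroup branch swap those classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .finite_sites import Alignment

__all__ = [
    "Partition",
    "default_partition",
    "polarize_alignment",
    "build_jsfs",
    "summarize_jsfs",
    "jsfs_total",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Partition:
    """A partition of the JSFS index set into summary-statistic classes.

    ``cell_class[a, b]`` gives the class index of cell ``(a, b)``, or -1 for
    the two excluded corners ``(0, 0)`` and ``(y1, y2)``.
    """

    cell_class: np.ndarray
    n_classes: int

    def __post_init__(self):
        cc = self.cell_class
        excluded = np.argwhere(cc < 0)
        if not (len(excluded) == 2
                and (excluded == [0, 0]).all(1).any()
                and (excluded == [cc.shape[0] - 1, cc.shape[1] - 1]).all(1).any()):
            raise ValueError("exactly the (0,0) and (y1,y2) cells must be excluded")
        present = np.unique(cc[cc >= 0])
        if not np.array_equal(present, np.arange(self.n_classes)):
            raise ValueError("class indices must be 0..n_classes-1 and all non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_class.shape

    def classes(self) -> list[np.ndarray]:
        """Cells of each class as arrays of (a, b) pairs."""
        return [np.argwhere(self.cell_class == k) for k in range(self.n_classes)]


def _axis_bins(y: int) -> list[tuple[int, int]]:
    """Five frequency bands on one axis: {0}, low, intermediate, high, {y}."""
    if y < 4:
        raise ValueError(
            f"sample size {y} too small for the 5-band partition; "
            "supply a coarser custom partition")
    c = math.ceil(0.1 * y)
    bins = [(0, 0), (1, c), (c + 1, y - 1 - c), (y - c, y - 1), (y, y)]
    if any(lo > hi for lo, hi in bins):
        raise ValueError(
            f"sample size {y} too small for the 5-band partition; "
            "supply a coarser custom partition")
    return bins


def default_partition(y1: int, y2: int) -> Partition:
    """The default 23-class partition for sample sizes ``(y1, y2)``.

    Five mirrored frequency bands per axis are crossed into 25 cells; the
    ``(0,0)`` and ``(y1,y2)`` corner cells (both singletons) are excluded,
    leaving exactly 23 classes.  Class boundaries can be replaced by
    constructing a :class:`Partition` directly.
    """
    bins1, bins2 = _axis_bins(y1), _axis_bins(y2)
    cell_class = np.full((y1 + 1, y2 + 1), -1, dtype=np.int64)
    k = 0
    for i, (lo1, hi1) in enumerate(bins1):
        for j, (lo2, hi2) in enumerate(bins2):
            if (i, j) in ((0, 0), (4, 4)):
                continue
            cell_class[lo1:hi1 + 1, lo2:hi2 + 1] = k
            k += 1
    cell_class[0, 0] = -1
    cell_class[y1, y2] = -1
    return Partition(cell_class=cell_class, n_classes=k)


def polarize_alignment(aln: Alignment) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-site derived-allele counts ``(a, b)`` against the outgroup base.

    Sites containing gaps or ambiguity codes in any counted row are dropped.
    Returns ``(a, b, n_dropped)`` with the invisible ``(0,0)`` sites removed.
    """
    if not aln.has_outgroup:
        raise ValueError("polarization requires an outgroup row")
    seqs = np.char.upper(aln.seqs.astype("S1"))
    valid = np.isin(seqs, _VALID).all(axis=0)
    out = aln.outgroup_row.astype("S1")
    out = np.char.upper(out)
    a = (seqs[aln.p1_rows] != out).sum(axis=0)
    b = (seqs[aln.p2_rows] != out).sum(axis=0)
    keep = valid & ((a > 0) | (b > 0))
    return a[keep], b[keep], int((~valid).sum())


def build_jsfs(a: np.ndarray, b: np.ndarray, y1: int, y2: int) -> np.ndarray:
    """Tabulate per-site derived counts into the ``(y1+1) x (y2+1)`` JSFS."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    bad = np.nonzero((a < 0) | (a > y1) | (b < 0) | (b > y2))[0]
    if bad.size:
        raise ValueError(
            f"site {bad[0]} has derived counts ({a[bad[0]]}, {b[bad[0]]}) "
            f"outside the sample sizes ({y1}, {y2})")
    J = np.zeros((y1 + 1, y2 + 1), dtype=np.int64)
    np.add.at(J, (a, b), 1)
    J[0, 0] = 0
    return J


def summarize_jsfs(jsfs: np.ndarray, partition: Partition) -> np.ndarray:
    """Summary vector ``S_i = sum of J over the cells of class A_i``."""
    jsfs = np.asarray(jsfs)
    if jsfs.shape != partition.shape:
        raise ValueError(
            f"JSFS shape {jsfs.shape} does not match partition {partition.shape}")
    mask = partition.cell_class >= 0
    return np.bincount(partition.cell_class[mask],
                       weights=jsfs[mask].astype(float),
                       minlength=partition.n_classes).astype(np.int64)


def jsfs_total(jsfs: np.ndarray) -> int:
    """Total SNPs over A (excluding the (0,0) and (y1,y2) corners)."""
    total = int(np.asarray(jsfs).sum()) - int(jsfs[0, 0]) - int(jsfs[-1, -1])
    return total
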