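"""Base composition around 5' cfDNA fragment ends.

Both physical ends of a double-stranded fragment are 5' termini (one per
strand).  For the left end the window is read forward off the reference; for
the right end it is the reverse complement, so both windows run 5'->3' with
position +0 the first base of the fragment and negative positions upstream
(outside) of it.  Frequencies are compared against the composition of
uniformly sampled genomic windows to obtain a signed bias matrix, mirroring
the way nuclease cutting preferences are visualized as heatmaps / logo plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import Fragment, Genome

__all__ = [
    "EndContextMatrix",
    "BiasMatrix",
    "end_context_frequencies",
    "bias_vs_background",
    "group_difference",
    "total_bias_per_position",
    "BASES",
]

BASES = "ACGT"
_COMP = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


@dataclass
class EndContextMatrix:
    """Per-position base frequencies at 5' fragment ends.

    ``values[i, b]`` is the frequency of base ``BASES[b]`` at position
    ``positions[i]`` (-k..k-1 relative to the 5'-most fragment base).
    """

    values: np.ndarray  # shape (2k, 4); rows sum to 1
    k: int
    n_ends: int
    n_skipped: int = 0

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.k, self.k)

    def __post_init__(self):
        assert self.values.shape == (2 * self.k, 4)
        if self.n_ends > 0:
            np.testing.assert_allclose(self.values.sum(axis=1), 1.0, atol=1e-9)


@dataclass
class BiasMatrix:
    """Observed minus background frequency per position/base (rows sum to 0)."""

    values: np.ndarray
    k: int
    n_ends: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.k, self.k)

    def __post_init__(self):
        assert self.values.shape == (2 * self.k, 4)
        np.testing.assert_allclose(self.values.sum(axis=1), 0.0, atol=1e-9)


def _windows_for_contig(
    enc: np.ndarray, starts: np.ndarray, ends: np.ndarray, k: int
) -> tuple[np.ndarray, int]:
    """Stack of encoded 2k windows (both ends, 5'->3'); returns (windows, skipped)."""
    n = len(enc)
    skipped = 0
    out = []
    # left 5' ends: reference [start-k, start+k)
    ok = (starts >= k) & (starts + k <= n)
    skipped += int((~ok).sum())
    if ok.any():
        idx = starts[ok, None] + np.arange(-k, k)[None, :]
        win = enc[idx]
        good = (win < 4).all(axis=1)
        skipped += int((~good).sum())
        out.append(win[good])
    # right 5' ends: reverse complement of [end-k, end+k)
    ok = (ends >= k) & (ends + k <= n)
    skipped += int((~ok).sum())
    if ok.any():
        idx = ends[ok, None] + np.arange(-k, k)[None, :]
        win = enc[idx]
        good = (win < 4).all(axis=1)
        skipped += int((~good).sum())
        win = win[good][:, ::-1]
        win = _COMP[win]
        out.append(win)
    if out:
        return np.concatenate(out), skipped
    return np.empty((0, 2 * k), dtype=np.int64), skipped


def end_context_frequencies(
    fragments: Iterable[Fragment],
    genome: Genome,
    k: int = 5,
    length_range: tuple[int, int] | None = None,
) -> EndContextMatrix:
    """Base frequencies at positions -k..k-1 around both 5' fragment ends.

    Ends whose window runs off the contig or contains N are skipped (and
    counted in ``n_skipped``).  ``length_range`` restricts to fragments whose
    length lies in the inclusive range — used for the length-stratified view
    (e.g. the 50-125 bp stratum).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        if length_range is not None and not (length_range[0] <= f.length <= length_range[1]):
            continue
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    counts = np.zeros((2 * k, 4), dtype=np.int64)
    skipped = 0
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        win, sk = _windows_for_contig(genome.encoded(chrom), arr[:, 0], arr[:, 1], k)
        skipped += sk
        for pos in range(2 * k):
            counts[pos] += np.bincount(win[:, pos], minlength=4)
    n_ends = int(counts[0].sum())
    if n_ends == 0:
        raise ValueError("no usable fragment ends (all skipped or no fragments)")
    return EndContextMatrix(counts / n_ends, k, n_ends, skipped)


def background_frequencies(
    genome: Genome, k: int = 5, n_background: int = 100_000, seed: int = 0
) -> EndContextMatrix:
    """Composition of random genomic windows with the same 5'-end geometry.

    Positions are sampled uniformly over the genome and each window is
    counted in both orientations (forward and reverse complement), matching
    the exact 50/50 two-strand treatment of real fragment ends without adding
    strand-sampling noise.
    """
    rng = np.random.default_rng(seed)
    names = list(genome.lengths)
    lens = np.array([genome.lengths[c] for c in names], dtype=float)
    probs = lens / lens.sum()
    counts = np.zeros((2 * k, 4), dtype=np.int64)
    total = 0
    picks = rng.choice(len(names), size=n_background, p=probs)
    for ci in np.unique(picks):
        enc = genome.encoded(names[ci])
        m = int((picks == ci).sum())
        pos = rng.integers(k, len(enc) - k, size=m)
        idx = pos[:, None] + np.arange(-k, k)[None, :]
        win = enc[idx]
        good = (win < 4).all(axis=1)
        win = win[good]
        win = np.concatenate([win, _COMP[win[:, ::-1]]])
        total += win.shape[0]
        for p in range(2 * k):
            counts[p] += np.bincount(win[:, p], minlength=4)
    if total == 0:
        raise ValueError("no valid background windows sampled")
    return EndContextMatrix(counts / total, k, total)


def bias_vs_background(
    matrix: EndContextMatrix,
    genome: Genome,
    n_background: int = 100_000,
    seed: int = 0,
) -> BiasMatrix:
    """Observed end frequencies minus random-genomic-window background."""
    bg = background_frequencies(genome, matrix.k, n_background, seed)
    return BiasMatrix(matrix.values - bg.values, matrix.k, matrix.n_ends)


def group_difference(
    matrices_a: Sequence[EndContextMatrix | BiasMatrix],
    matrices_b: Sequence[EndContextMatrix | BiasMatrix],
) -> np.ndarray:
    """Per-cell median across samples within each group, then A minus B.

    Antisymmetric under swapping the groups.  Works on frequency or bias
    matrices of matching shape.
    """
    if not matrices_a or not matrices_b:
        raise ValueError("need at least one matrix per group")
    stack_a = np.stack([m.values for m in matrices_a])
    stack_b = np.stack([m.values for m in matrices_b])
    if stack_a.shape[1:] != stack_b.shape[1:]:
        raise ValueError("group matrices have mismatched shapes")
    return np.median(stack_a, axis=0) - np.median(stack_b, axis=0)


def total_bias_per_position(bias: BiasMatrix) -> np.ndarray:
    """Sum of |bias| over bases at each position (logo-plot total height)."""
    return np.abs(bias.values).sum(axis=1)
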