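"""SNP- and family-level quality filters for pool-frequency matrices.

Filtering order is depth -> frequency -> family -> binning.  The frequency
bounds apply to the per-SNP mean frequency across families (the same mean
that centers the genomic relationship matrix), with boundary values 0.02 and
0.98 retained.  Mean depth is computed over all families including zero-depth
(missing) cells, since depth 0 is a real sequencing outcome of the SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DegenerateDataError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PoolFrequencyMatrix:
    """SNP x family allele-frequency estimates with missing mask.

    ``values`` holds frequencies in [0, 1] wherever ``missing`` is False
    (missing cells may hold any placeholder, conventionally 0).  ``depths``
    optionally holds the per-cell read count; for GBS data a depth of 0
    coincides with a missing call.
    """

    values: np.ndarray
    missing: Optional[np.ndarray] = None
    snp_ids: list = field(default_factory=list)
    family_ids: list = field(default_factory=list)
    depths: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D SNP x family matrix")
        n_snps, n_fam = self.values.shape
        if self.missing is None:
            self.missing = np.zeros_like(self.values, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValidationError("missing mask shape does not match values")
        if not self.snp_ids:
            self.snp_ids = [f"snp{i + 1}" for i in range(n_snps)]
        if not self.family_ids:
            self.family_ids = [f"fam{j + 1}" for j in range(n_fam)]
        if len(self.snp_ids) != n_snps or len(self.family_ids) != n_fam:
            raise ValidationError("id label lengths do not match matrix shape")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=float)
            if self.depths.shape != self.values.shape:
                raise ValidationError("depths shape does not match values")
            if (self.depths < 0).any():
                raise ValidationError("depths must be non-negative")
        obs = self.values[~self.missing]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValidationError("non-missing frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_families(self) -> int:
        return self.values.shape[1]

    def mean_depths(self) -> np.ndarray:
        """Per-SNP mean read depth over all families (zeros included)."""
        if self.depths is None:
            raise ValidationError("matrix has no depth information")
        return self.depths.mean(axis=1)

    def mean_frequencies(self) -> np.ndarray:
        """Per-SNP mean frequency over non-missing families."""
        n_obs = (~self.missing).sum(axis=1)
        if (n_obs == 0).any():
            bad = [self.snp_ids[i] for i in np.flatnonzero(n_obs == 0)[:5]]
            raise DegenerateDataError(f"SNP(s) with all cells missing: {bad}")
        vals = np.where(self.missing, 0.0, self.values)
        return vals.sum(axis=1) / n_obs

    def take_snps(self, idx: np.ndarray) -> "PoolFrequencyMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            missing=self.missing[idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            depths=None if self.depths is None else self.depths[idx],
        )

    def take_families(self, idx: np.ndarray) -> "PoolFrequencyMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            missing=self.missing[:, idx],
            family_ids=[self.family_ids[j] for j in idx],
            depths=None if self.depths is None else self.depths[:, idx],
        )


@dataclass(frozen=True)
class DepthBinSpec:
    """Ordered depth-bin edges; bins are (lo, hi] except the first, [e0, e1]."""

    edges: tuple = (0.0, 10.0, 20.0, 30.0, 40.0, 60.0)
    labels: Optional[tuple] = None

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)
        if self.labels is None:
            labels = tuple(
                f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])
            )
            object.__setattr__(self, "labels", labels)
        elif len(self.labels) != len(edges) - 1:
            raise ValidationError("need one label per bin")


@dataclass
class FilterReport:
    """Accounting of one filtering step; always reconciles n_in = n_out + removed."""

    n_in: int
    n_out: int
    removed: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_in == self.n_out + sum(self.removed.values())


def filter_snps(
    matrix: PoolFrequencyMatrix,
    max_mean_depth: Optional[float] = 60.0,
    min_freq: float = 0.02,
    max_freq: float = 0.98,
):
    """Drop SNPs by mean depth and mean-frequency bounds.

    SNPs with mean depth strictly above ``max_mean_depth`` are removed first,
    then SNPs whose mean non-missing frequency falls strictly outside
    ``[min_freq, max_freq]``.  Returns ``(filtered_matrix, FilterReport)``.
    """
    n_in = matrix.n_snps
    keep = np.ones(n_in, dtype=bool)
    removed_depth = 0
    if max_mean_depth is not None:
        if matrix.depths is None:
            raise ValidationError("depth filtering requested but matrix has no depths")
        keep &= matrix.mean_depths() <= max_mean_depth
        removed_depth = n_in - int(keep.sum())
    sub = matrix.take_snps(np.flatnonzero(keep)) if removed_depth else matrix
    mf = sub.mean_frequencies()
    keep_f = (mf >= min_freq) & (mf <= max_freq)
    removed_freq = int((~keep_f).sum())
    out = sub.take_snps(np.flatnonzero(keep_f)) if removed_freq else sub
    if out.n_snps == 0:
        raise DegenerateDataError("all SNPs removed by filtering")
    report = FilterReport(
        n_in=n_in,
        n_out=out.n_snps,
        removed={"mean_depth": removed_depth, "mean_frequency": removed_freq},
    )
    return out, report


def assign_depth_bins(matrix: PoolFrequencyMatrix, spec: DepthBinSpec = DepthBinSpec()):
    """Assign each SNP to a depth bin by its mean depth.

    Returns a dict mapping bin label to an array of SNP indices.  SNPs with
    mean depth above the last edge are excluded (with a logged warning count),
    mirroring the high-depth discard rule; SNPs below the first edge are
    likewise excluded.
    """
    if matrix.n_snps == 0:
        return {}
    md = matrix.mean_depths()
    edges = np.asarray(spec.edges)
    bins: dict = {}
    assigned = np.zeros(matrix.n_snps, dtype=bool)
    for k, label in enumerate(spec.labels):
        lo, hi = edges[k], edges[k + 1]
        if k == 0:
            in_bin = (md >= lo) & (md <= hi)
        else:
            in_bin = (md > lo) & (md <= hi)
        in_bin &= ~assigned  # shared edges resolve to the lower bin
        bins[label] = np.flatnonzero(in_bin)
        assigned |= in_bin
    n_excluded = int((~assigned).sum())
    if n_excluded:
        log.warning("%d SNPs outside the depth-bin range were not assigned", n_excluded)
    return bins


def filter_families(matrix: PoolFrequencyMatrix, max_missing_rate: float = 0.5):
    """Drop families whose fraction of missing SNP calls exceeds the cap."""
    rates = matrix.missing.mean(axis=0)
    keep = rates <= max_missing_rate
    removed = int((~keep).sum())
    out = matrix.take_families(np.flatnonzero(keep)) if removed else matrix
    if out.n_families == 0:
        raise DegenerateDataError("all families removed by missing-rate filter")
    return out, FilterReport(
        n_in=matrix.n_families, n_out=out.n_families, removed={"missing_rate": removed}
    )


def subsample_snps(matrix: PoolFrequencyMatrix, n: int, seed) -> PoolFrequencyMatrix:
    """Uniform random subsample of ``n`` SNPs without replacement."""
    if n <= 0:
        raise ValidationError("subsample size must be positive")
    if n > matrix.n_snps:
        raise ValidationError(
            f"requested {n} SNPs but only {matrix.n_snps} available"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = np.sort(rng.choice(matrix.n_snps, size=n, replace=False))
    return matrix.take_snps(idx)
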