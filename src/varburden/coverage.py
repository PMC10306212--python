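"""Coverage harmonization between case and control cohorts.

Cases and public control cohorts are captured and sequenced differently, so
burden counts are only comparable on bases that are well covered in *both*
groups.  Per base (stored as intervals) we track the fraction of individuals
covered at depth strictly greater than a threshold, and the joint gate keeps
a base only when that fraction reaches the required minimum in cases and in
controls simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicIntervals


@dataclass
class CoverageProfile:
    """Fraction of samples covered above the depth cutoff, per interval.

    Intervals are 0-based half-open and non-overlapping within a chromosome.
    """

    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CoverageProfile":
        """Build from a table with columns chrom, start, end, fraction."""
        required = {"chrom", "start", "end", "fraction"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"coverage table missing columns: {sorted(missing)}")
        if ((frame["fraction"] < 0) | (frame["fraction"] > 1)).any():
            raise ValueError("coverage fractions must lie in [0, 1]")
        by_chrom = {}
        for chrom, grp in frame.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping coverage intervals on {chrom}")
            by_chrom[str(chrom)] = (starts, ends, grp["fraction"].to_numpy(float))
        return cls(by_chrom)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, int(s), int(e), float(f))
            for chrom in sorted(self._by_chrom)
            for s, e, f in zip(*self._by_chrom[chrom])
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "fraction"])

    def intervals_at_least(self, min_fraction: float) -> GenomicIntervals:
        """Intervals whose covered-sample fraction is >= ``min_fraction``."""
        keep = []
        for chrom, (starts, ends, fracs) in self._by_chrom.items():
            sel = fracs >= min_fraction
            keep.extend(
                (chrom, int(s), int(e)) for s, e in zip(starts[sel], ends[sel])
            )
        return GenomicIntervals.from_tuples(keep)


def case_coverage_fraction(
    depths: pd.DataFrame, depth_min: int = 10
) -> CoverageProfile:
    """Per-base fraction of case samples with depth strictly above ``depth_min``.

    ``depths`` has columns chrom, start, end plus one column per sample
    holding the read depth over that interval.  The strict inequality matches
    a ">10x" depth rule: a sample at exactly ``depth_min`` does not count.
    """
    meta = ["chrom", "start", "end"]
    sample_cols = [c for c in depths.columns if c not in meta]
    if not sample_cols:
        raise ValueError("depth table has no sample columns")
    mat = depths[sample_cols].to_numpy()
    if (mat < 0).any():
        raise ValueError("read depths must be non-negative")
    frame = depths[meta].copy()
    frame["fraction"] = (mat > depth_min).mean(axis=1)
    return CoverageProfile.from_frame(frame)


def joint_coverage_gate(
    case_cov: CoverageProfile,
    control_cov: CoverageProfile,
    coverage_frac_min: float = 0.90,
) -> GenomicIntervals:
    """Bases adequately covered in both cohorts, as a minimal interval set.

    A base is retained iff the covered fraction is at least
    ``coverage_frac_min`` (inclusive) in cases AND in controls.
    """
    return case_cov.intervals_at_least(coverage_frac_min).intersect(
        control_cov.intervals_at_least(coverage_frac_min)
    )
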