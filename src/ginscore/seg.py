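"""Segmented copy-number profiles and the fraction of genome altered (FGA).

FGA is the summary of genomic instability used throughout the package: the
summed length of copy-number segments whose log2 ratio magnitude exceeds a
threshold (0.2 by default), divided by the total measured segment length.

Coordinates are 0-based half-open internally.  The on-disk SEG dialect is
1-based inclusive (columns ``sample_id, chrom, loc_start, loc_end,
seg_mean``) and is converted on read, so a file row contributes
``loc_end - loc_start + 1`` bases.  File rows must satisfy
``loc_start < loc_end``; a consequence is that single-base segments cannot
be represented in this dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SEG_COLUMNS = ("sample_id", "chrom", "loc_start", "loc_end", "seg_mean")

DEFAULT_ALTERATION_THRESHOLD = 0.2


class SegParseError(ValueError):
    """A SEG file row could not be parsed or violates the format contract."""


class SegValidationError(ValueError):
    """A segment profile violates a structural invariant (e.g. overlap)."""


@dataclass(frozen=True)
class Segment:
    """One copy-number segment, 0-based half-open.

    ``log2_ratio`` holds the log2 copy-number ratio, or the linear ratio when
    the profile is scored in linear mode (see :func:`compute_fga`).
    """

    chromosome: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SegValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end}: start must be < end"
            )
        if not math.isfinite(self.log2_ratio):
            raise SegValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end}: non-finite value"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """All copy-number segments of one sample, sorted by (chromosome, start)."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chromosome, s.start))
        self._check_overlap()

    def _check_overlap(self) -> None:
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chromosome == prev.chromosome and seg.start < prev.end:
                raise SegValidationError(
                    f"sample {self.sample_id!r}: overlapping segments on "
                    f"{seg.chromosome}: {prev.start}-{prev.end} and {seg.start}-{seg.end}"
                )
            prev = seg

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class FgaValue:
    """Fraction of genome altered for one sample."""

    sample_id: str
    fga: float
    altered_length: int
    total_length: int

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise SegValidationError(f"sample {self.sample_id!r}: total length must be > 0")
        if not (0.0 <= self.fga <= 1.0):
            raise SegValidationError(f"sample {self.sample_id!r}: fga {self.fga} outside [0, 1]")


def read_seg(path: str | Path) -> list[SegmentProfile]:
    """Read a SEG-like tab-separated file into one profile per sample.

    The header must contain the columns ``sample_id, chrom, loc_start,
    loc_end, seg_mean`` (case-insensitive).  Coordinates are 1-based
    inclusive on disk and converted to 0-based half-open.  Rows with a
    non-finite ``seg_mean`` are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in SEG_COLUMNS if c not in cols]
    if missing:
        raise SegParseError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns={cols[c]: c for c in SEG_COLUMNS})

    profiles: dict[str, list[Segment]] = {}
    order: list[str] = []
    n_dropped = 0
    # header is line 1; data row i (0-based) is file line i + 2
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        try:
            start = int(row.loc_start)
            end = int(row.loc_end)
        except (TypeError, ValueError) as exc:
            raise SegParseError(f"{path}, line {line_no}: non-integer coordinates") from exc
        try:
            value = float(row.seg_mean)
        except (TypeError, ValueError) as exc:
            raise SegParseError(f"{path}, line {line_no}: non-numeric seg_mean") from exc
        if not math.isfinite(value):
            n_dropped += 1
            continue
        if start >= end:
            raise SegParseError(f"{path}, line {line_no}: start >= end ({start} >= {end})")
        sid = str(row.sample_id)
        if sid not in profiles:
            profiles[sid] = []
            order.append(sid)
        # 1-based inclusive -> 0-based half-open: length = end - start + 1
        profiles[sid].append(Segment(str(row.chrom), start - 1, end, value))
    if n_dropped:
        logger.info("read_seg(%s): dropped %d row(s) with non-finite seg_mean", path, n_dropped)
    return [SegmentProfile(sid, profiles[sid]) for sid in order]


def write_seg(profiles: Iterable[SegmentProfile], path: str | Path) -> None:
    """Write profiles as a SEG-like file readable by :func:`read_seg`."""
    path = Path(path)
    rows = []
    for prof in profiles:
        for seg in prof.segments:
            rows.append(
                (prof.sample_id, seg.chromosome, seg.start + 1, seg.end, seg.log2_ratio)
            )
    pd.DataFrame(rows, columns=list(SEG_COLUMNS)).to_csv(path, sep="\t", index=False)


def compute_fga(
    profile: SegmentProfile,
    alteration_threshold: float = DEFAULT_ALTERATION_THRESHOLD,
    linear: bool = False,
) -> FgaValue:
    """Fraction of genome altered of one profile.

    A segment counts as altered when ``|log2_ratio| > alteration_threshold``
    (strict), so deletions count through the absolute value.  With
    ``linear=True`` values are treated as linear copy-number ratios and the
    threshold is applied to ``|value - 1|``.
    """
    if alteration_threshold <= 0:
        raise ValueError("alteration_threshold must be > 0")
    if not profile.segments:
        raise SegValidationError(
            f"sample {profile.sample_id!r}: empty profile, FGA undefined (total length zero)"
        )
    altered = 0
    total = 0
    for seg in profile.segments:
        deviation = abs(seg.log2_ratio - 1.0) if linear else abs(seg.log2_ratio)
        total += seg.length
        if deviation > alteration_threshold:
            altered += seg.length
    return FgaValue(profile.sample_id, altered / total, altered, total)


def compute_fga_table(
    profiles: Sequence[SegmentProfile],
    alteration_threshold: float = DEFAULT_ALTERATION_THRESHOLD,
    linear: bool = False,
) -> pd.DataFrame:
    """FGA for every profile, as a DataFrame indexed by sample id."""
    values = [compute_fga(p, alteration_threshold, linear) for p in profiles]
    return pd.DataFrame(
        {
            "fga": [v.fga for v in values],
            "altered_length": [v.altered_length for v in values],
            "total_length": [v.total_length for v in values],
        },
        index=pd.Index([v.sample_id for v in values], name="sample_id"),
    )
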