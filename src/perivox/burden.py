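"""PVS burden counting on anatomically selected slices and rater agreement.

The clinical protocol counts perivascular spaces on two standard axial
slices: the basal ganglia (BG) slice showing the anterior commissure,
and the centrum semiovale (CSO) slice 1 cm above the uppermost slice of
the lateral ventricles.  A "count" is the number of distinct PVS
cross-sections on the slice, realised here as 2D connected components
(8-connectivity by default, so a diagonal-touching thin PVS stays one
structure).  Agreement between automated and rater counts is quantified
with tie-corrected Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "CountRecord",
    "CorrelationResult",
    "select_slice",
    "count_on_slice",
    "spearman",
    "agreement_report",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)
FOUR_CONN = ndimage.generate_binary_structure(2, 1)


@dataclass
class CountRecord:
    subject_id: str
    region: str  # "BG" | "CSO"
    slice_index: int
    count: int
    source: str  # rater or model identifier

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.region not in ("BG", "CSO"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class CorrelationResult:
    rs: float
    p_value: float
    n: int
    defined: bool = True


def select_slice(
    region: str,
    n_slices: int,
    slice_thickness_mm: float,
    bg_slice_index: int | None = None,
    ventricle_top_index: int | None = None,
    explicit_index: int | None = None,
) -> int:
    """Resolve the counting slice for a region.

    BG uses the anterior-commissure(-analogue) slice; CSO is
    ``ventricle_top_index + ceil(10 mm / slice_thickness)``.  An
    ``explicit_index`` (real-data mode, landmarks supplied by the user)
    is echoed unchanged.  Out-of-range results are clamped with a
    warning.
    """
    if explicit_index is not None:
        idx = explicit_index
    elif region == "BG":
        if bg_slice_index is None:
            raise ValueError("BG slice requires an anterior-commissure index")
        idx = bg_slice_index
    elif region == "CSO":
        if ventricle_top_index is None:
            raise ValueError("CSO slice requires the uppermost-ventricle index")
        idx = ventricle_top_index + math.ceil(10.0 / slice_thickness_mm)
    else:
        raise ValueError(f"unknown region {region!r}")
    if not 0 <= idx < n_slices:
        import warnings

        clamped = min(max(idx, 0), n_slices - 1)
        warnings.warn(
            f"{region} slice {idx} outside volume (0..{n_slices - 1}); "
            f"clamped to {clamped}"
        )
        idx = clamped
    return idx


def count_on_slice(
    mask: np.ndarray,
    slice_index: int,
    connectivity: int = 8,
    min_area: int = 1,
) -> int:
    """Connected-component count of one axial slice of a 3D binary mask.

    ``min_area`` (pixels) drops components below the given size; the
    default of 1 disables the filter.
    """
    if not 0 <= slice_index < mask.shape[2]:
        raise IndexError(
            f"slice {slice_index} out of range (0..{mask.shape[2] - 1})"
        )
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = EIGHT_CONN if connectivity == 8 else FOUR_CONN
    sl = np.asarray(mask[:, :, slice_index]).astype(bool)
    labels, n = ndimage.label(sl, structure=structure)
    if min_area <= 1:
        return int(n)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(sizes >= min_area))


def _tie_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y) -> CorrelationResult:
    """Tie-corrected Spearman correlation (average ranks, then Pearson).

    Two-sided p-value: exact over all permutations of one vector for
    n <= 8, the t-distribution approximation otherwise.  A constant
    vector leaves the coefficient undefined (``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rs=float("nan"), p_value=float("nan"), n=n, defined=False)
    rx, ry = _tie_ranks(x), _tie_ranks(y)

    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rs = pearson(rx, ry)
    if n <= 8:
        ref = abs(rs) - 1e-12
        hits = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(pearson(rx, np.asarray(perm))) >= ref:
                hits += 1
        p = hits / total
    else:
        r = min(max(rs, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rs=rs, p_value=float(p), n=n)


def _counts_by_subject(records: list[CountRecord], region: str, source: str) -> dict[str, int]:
    return {
        r.subject_id: r.count
        for r in records
        if r.region == region and r.source == source
    }


def agreement_report(records: list[CountRecord]) -> pd.DataFrame:
    """All pairwise source-vs-source Spearman correlations per region.

    Subjects missing from either source of a pair are excluded with a
    warning.  Returns a frame (region, source_a, source_b, rs, p, n).
    """
    rows = []
    regions = sorted({r.region for r in records})
    for region in regions:
        sources = sorted({r.source for r in records if r.region == region})
        for i, sa in enumerate(sources):
            for sb in sources[i + 1 :]:
                ca = _counts_by_subject(records, region, sa)
                cb = _counts_by_subject(records, region, sb)
                common = sorted(ca.keys() & cb.keys())
                missing = sorted(ca.keys() ^ cb.keys())
                if missing:
                    import warnings

                    warnings.warn(
                        f"{region} {sa} vs {sb}: excluding subjects {missing}"
                    )
                if len(common) < 3:
                    continue
                x = [ca[s] for s in common]
                y = [cb[s] for s in common]
                res = spearman(x, y)
                rows.append(
                    (region, sa, sb, res.rs, res.p_value, res.n, res.defined)
                )
    return pd.DataFrame(
        rows, columns=["region", "source_a", "source_b", "rs", "p", "n", "defined"]
    )


def scatter_data(records: list[CountRecord], region: str, source_a: str, source_b: str) -> pd.DataFrame:
    """Paired counts for a scatter plot of one source against another."""
    ca = _counts_by_subject(records, region, source_a)
    cb = _counts_by_subject(records, region, source_b)
    common = sorted(ca.keys() & cb.keys())
    return pd.DataFrame(
        {
            "subject_id": common,
            source_a: [ca[s] for s in common],
            source_b: [cb[s] for s in common],
        }
    )
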