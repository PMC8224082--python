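"""Differentiation morphometry: fusion index and myotube width.

The fusion index is the fraction of nuclei residing in myotubes (cells with
at least ``min_nuclei_per_mt`` nuclei, 2 by default).  Myotube width is
normally a manual measurement (a line across the widest part of the fiber);
``width_from_mask`` reproduces it on a binary mask as twice the largest
inscribed-circle radius along the medial axis.  Group comparisons follow
the square-root-transform Welch convention; fold-type quantities (e.g.
Western-blot ratios) use a one-sample t-test on logs against 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .stats import TTestReport, one_sample_test, welch_test

__all__ = [
    "fusion_index",
    "fusion_index_from_table",
    "width_from_mask",
    "compare_groups_sqrt",
    "one_sample_log_test",
]

#: A cell counts as a myotube when it contains at least this many nuclei.
DEFAULT_MIN_NUCLEI_PER_MT = 2


def fusion_index(nuclei_in_myotubes: int, total_nuclei: int) -> float:
    """Fraction of nuclei inside myotubes; in [0, 1]."""
    if total_nuclei <= 0:
        raise ValueError("total_nuclei must be positive")
    if nuclei_in_myotubes < 0 or nuclei_in_myotubes > total_nuclei:
        raise ValueError("nuclei_in_myotubes must lie in [0, total_nuclei]")
    return nuclei_in_myotubes / total_nuclei


def fusion_index_from_table(counts, min_nuclei_per_mt: int = DEFAULT_MIN_NUCLEI_PER_MT) -> float:
    """Pooled fusion index from per-cell nuclei counts.

    ``counts`` holds the number of nuclei of each counted cell; cells with
    ≥ ``min_nuclei_per_mt`` nuclei are myotubes.  Pooling images before the
    ratio gives the count-weighted result.
    """
    c = np.asarray(counts, dtype=int)
    if (c < 1).any():
        raise ValueError("every cell has at least one nucleus")
    total = int(c.sum())
    fused = int(c[c >= min_nuclei_per_mt].sum())
    return fusion_index(fused, total)


def width_from_mask(mask: np.ndarray, pixel_size_um: float) -> float:
    """Width of an elongated object at its widest point, in µm.

    Computed as twice the maximum of the Euclidean distance transform (the
    largest inscribed circle, centred on the medial axis), which matches a
    perpendicular line across the widest part of the fiber to within one
    pixel.  Requires a single connected component.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = int(measure.label(mask, connectivity=2).max())
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected object (found {n_comp})")
    dist = ndimage.distance_transform_edt(np.pad(mask, 1))
    return float(2.0 * dist.max() * pixel_size_um)


def compare_groups_sqrt(values_a, values_b, names: tuple[str, str] = ("a", "b")) -> TTestReport:
    """Welch's t-test on square-root-transformed values.

    Group means and s.e.m. in the report are on the original scale; the
    test statistic and p-value come from the transformed values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("square-root transform requires nonnegative values")
    rep = welch_test(np.sqrt(a), np.sqrt(b), names=names)
    means = {names[0]: float(np.mean(a)), names[1]: float(np.mean(b))}
    sems = {
        names[0]: float(np.std(a, ddof=1) / np.sqrt(a.size)),
        names[1]: float(np.std(b, ddof=1) / np.sqrt(b.size)),
    }
    return TTestReport(
        test=rep.test,
        statistic=rep.statistic,
        p_value=rep.p_value,
        df=rep.df,
        group_means=means,
        group_sems=sems,
        degenerate=rep.degenerate,
    )


def one_sample_log_test(values, null_value: float = 1.0) -> TTestReport:
    """One-sample t-test of log(values / null_value) against 0."""
    x = np.asarray(values, dtype=float)
    if (x <= 0).any():
        raise ValueError("log transform requires positive values")
    if null_value <= 0:
        raise ValueError("null_value must be positive")
    return one_sample_test(np.log(x / null_value), popmean=0.0, name="values")
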