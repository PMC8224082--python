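"""Nuclear-periphery shell profiling ("nuclear circle analysis").

Fluorescence intensity of a nuclear protein (e.g. the basket nucleoporin
TPR) is profiled in one-pixel-wide shells that run parallel to the nuclear
periphery, from the contour of the segmented nucleus inward.  The shells
are realized as iso-distance layers of the Euclidean distance transform of
each nucleus mask: shell 0 is the layer of pixels contouring the nucleus,
shell k the pixels roughly k pixels further in.  The shells are then
partitioned into a nuclear-periphery (NP) band — every shell whose distance
from the contour is below a configurable cut-off (1.5 µm by default) — and
the nucleoplasm (all remaining, deeper shells).  Per-nucleus compartment
means are background-subtracted and summarized as the nucleoplasm : NP
intensity ratio, the quantity that distinguishes myoblast from myotube
nuclei.

Coordinate convention
---------------------
``boundary_distance_map`` returns, for every nucleus pixel, the Euclidean
distance (µm) to the nearest pixel outside that nucleus, so the contour
layer carries one pixel unit and a single-pixel nucleus is its own
boundary.  Shell indices subtract that one-pixel offset:
``k = floor(d_px) - 1``, giving the contour layer k = 0 and a nominal
depth of ``k × pixel_size_um`` µm.  The NP band collects shells with depth
strictly below ``band_um``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import TTestReport, paired_test, welch_test

__all__ = [
    "boundary_distance_map",
    "shell_index_map",
    "shell_means",
    "compartment_summary",
    "aggregate_and_test",
    "GroupReport",
]

#: Columns of the tidy shell-profile frame (one row per nucleus per shell).
SHELL_PROFILE_COLUMNS = ["nucleus_id", "shell_index", "distance_um", "pixel_count", "mean_fi"]

#: Columns of the per-nucleus compartment summary frame.
COMPARTMENT_COLUMNS = [
    "nucleus_id",
    "np_mean_fi",
    "nucleoplasm_mean_fi",
    "background_fi",
    "np_mean_bgsub",
    "nucleoplasm_bgsub",
    "ratio",
    "band_um",
    "valid",
]


def boundary_distance_map(labels: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Per-label Euclidean distance (µm) to the nearest exterior pixel.

    Each labeled nucleus is transformed independently, so pixels of one
    nucleus never count a touching neighbour's pixels as interior.
    Background pixels carry 0.  An empty label grid yields an all-zero map.

    Parameters
    ----------
    labels
        2-D integer label grid, 0 = background.
    pixel_size_um
        Physical pixel size in µm (> 0).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2-D grid")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    out = np.zeros(labels.shape, dtype=float)
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # pad the crop so the EDT sees exterior on all sides of the object
        rows = slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, labels.shape[0]))
        cols = slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, labels.shape[1]))
        crop = labels[rows, cols] == lab
        padded = np.pad(crop, 1)
        dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        out[rows, cols][crop] = dist[crop] * pixel_size_um
    return out


def shell_index_map(labels: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Integer shell index per nucleus pixel; -1 outside any nucleus.

    Shell 0 is the contour layer (distance one pixel unit); deeper shells
    increase toward the nuclear center.
    """
    dist_um = boundary_distance_map(labels, pixel_size_um)
    dist_px = dist_um / pixel_size_um
    k = np.floor(dist_px).astype(int) - 1
    k[labels == 0] = -1
    return k


def shell_means(channel: np.ndarray, labels: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Per-nucleus, per-shell pixel counts and mean fluorescence intensity.

    Returns a tidy frame with one row per (nucleus, shell):
    ``nucleus_id, shell_index, distance_um, pixel_count, mean_fi``.
    Within each nucleus the shell pixel counts sum to the nucleus area.
    """
    channel = np.asarray(channel, dtype=float)
    labels = np.asarray(labels)
    if channel.shape != labels.shape:
        raise ValueError("channel and labels must share shape")
    k = shell_index_map(labels, pixel_size_um)
    inside = labels > 0
    if not inside.any():
        return pd.DataFrame(columns=SHELL_PROFILE_COLUMNS)
    lab = labels[inside].astype(np.int64)
    shell = k[inside].astype(np.int64)
    fi = channel[inside]
    n_shell = int(shell.max()) + 1
    flat = lab * n_shell + shell  # unique (label, shell) code
    counts = np.bincount(flat)
    sums = np.bincount(flat, weights=fi)
    nz = np.nonzero(counts)[0]
    df = pd.DataFrame(
        {
            "nucleus_id": nz // n_shell,
            "shell_index": nz % n_shell,
            "pixel_count": counts[nz].astype(int),
            "mean_fi": sums[nz] / counts[nz],
        }
    )
    df["distance_um"] = df["shell_index"] * pixel_size_um
    df = df.sort_values(["nucleus_id", "shell_index"], ignore_index=True)
    return df[SHELL_PROFILE_COLUMNS]


def compartment_summary(
    profiles: pd.DataFrame,
    band_um: float = 1.5,
    background_fi: float = 0.0,
) -> pd.DataFrame:
    """Partition shell profiles into NP band and nucleoplasm per nucleus.

    The NP mean is the pixel-count-weighted mean over shells with
    ``distance_um < band_um``; the nucleoplasm mean is taken over all
    remaining shells.  The background is subtracted from the two compartment
    means (not per pixel) and the ratio nucleoplasm : NP is formed from the
    subtracted values.  Nuclei that lie entirely within the band have no
    nucleoplasm; they are returned with ``valid = False`` and an undefined
    (NaN) ratio, as is any nucleus whose background-subtracted NP mean is
    not positive.
    """
    if background_fi < 0:
        raise ValueError("background_fi must be nonnegative")
    rows = []
    for nid, prof in profiles.groupby("nucleus_id"):
        in_band = prof["distance_um"].to_numpy() < band_um
        w = prof["pixel_count"].to_numpy(dtype=float)
        fi = prof["mean_fi"].to_numpy(dtype=float)
        np_mean = float(np.average(fi[in_band], weights=w[in_band]))
        has_interior = bool((~in_band).any())
        nucleoplasm_mean = (
            float(np.average(fi[~in_band], weights=w[~in_band])) if has_interior else np.nan
        )
        np_bgsub = np_mean - background_fi
        nucleoplasm_bgsub = nucleoplasm_mean - background_fi if has_interior else np.nan
        valid = has_interior and np_bgsub > 0
        ratio = nucleoplasm_bgsub / np_bgsub if valid else np.nan
        rows.append(
            {
                "nucleus_id": nid,
                "np_mean_fi": np_mean,
                "nucleoplasm_mean_fi": nucleoplasm_mean,
                "background_fi": background_fi,
                "np_mean_bgsub": np_bgsub,
                "nucleoplasm_bgsub": nucleoplasm_bgsub,
                "ratio": ratio,
                "band_um": band_um,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows, columns=COMPARTMENT_COLUMNS)


@dataclass(frozen=True)
class GroupReport:
    """Aggregate of compartment summaries over experimental groups.

    ``group_stats`` holds one row per group: nucleus count, mean
    background-subtracted NP and nucleoplasm intensity, mean and s.e.m. of
    the per-nucleus ratio, and the within-group paired t-test of NP vs
    nucleoplasm.  ``between_groups`` holds one row per group pair and
    metric with the two-sided Welch test.
    """

    group_stats: pd.DataFrame
    between_groups: pd.DataFrame


def aggregate_and_test(
    summaries: pd.DataFrame,
    group_col: str = "group",
    metrics: tuple[str, ...] = ("np_mean_bgsub", "nucleoplasm_bgsub", "ratio"),
) -> GroupReport:
    """Group-level report: per-group means/s.e.m., paired NP-vs-nucleoplasm
    t-test within each group, and pairwise Welch tests between groups.

    Only summaries flagged ``valid`` enter the statistics (one value per
    nucleus).  Requires at least 2 valid nuclei per group.
    """
    if group_col not in summaries.columns:
        raise ValueError(f"missing group column {group_col!r}")
    valid = summaries[summaries["valid"]]
    stats_rows = []
    for grp, sub in valid.groupby(group_col, sort=False):
        if len(sub) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 valid nuclei")
        rep = paired_test(
            sub["np_mean_bgsub"].to_numpy(),
            sub["nucleoplasm_bgsub"].to_numpy(),
            names=("np", "nucleoplasm"),
        )
        ratio = sub["ratio"].to_numpy()
        stats_rows.append(
            {
                group_col: grp,
                "n_nuclei": len(sub),
                "np_mean": rep.group_means["np"],
                "np_sem": rep.group_sems["np"],
                "nucleoplasm_mean": rep.group_means["nucleoplasm"],
                "nucleoplasm_sem": rep.group_sems["nucleoplasm"],
                "ratio_mean": float(np.mean(ratio)),
                "ratio_sem": float(np.std(ratio, ddof=1) / np.sqrt(len(ratio))),
                "paired_t": rep.statistic,
                "paired_p": rep.p_value,
                "paired_degenerate": rep.degenerate,
            }
        )
    group_stats = pd.DataFrame(stats_rows)
    groups = list(group_stats[group_col])
    pair_rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            sub_a = valid[valid[group_col] == ga]
            sub_b = valid[valid[group_col] == gb]
            for metric in metrics:
                rep = welch_test(sub_a[metric].to_numpy(), sub_b[metric].to_numpy(), names=(str(ga), str(gb)))
                pair_rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "metric": metric,
                        "welch_t": rep.statistic,
                        "welch_p": rep.p_value,
                        "df": rep.df,
                    }
                )
    between = pd.DataFrame(
        pair_rows, columns=["group_a", "group_b", "metric", "welch_t", "welch_p", "df"]
    )
    return GroupReport(group_stats=group_stats, between_groups=between)
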