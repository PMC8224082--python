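"""Synthetic ground-truth inputs for every pipeline stage.

The source experiments deposit no raw data, so each quantification stage is
validated against simulated inputs with known truth: fluorescence fields of
nuclei with a bright peripheral rim and a dimmer nucleoplasm at a
configurable intensity ratio (the myoblast regime has a nucleoplasm at
roughly 40 % of the periphery, the myotube regime roughly 15 %), NPC-like
spot fields of known density, negative-binomial gene-count tables with
known bound and condition-differential genes, and qPCR Ct tables encoding
known fold changes.

All generators are pure functions of their spec (including its seed):
identical inputs give bit-identical outputs.  The rim band of a simulated
nucleus is defined by the same boundary-distance shell rule the downstream
analysis uses, so the generated "true ratio" and the recovered ratio share
one coordinate convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import GeneCountTable
from .qpcr import CtTable
from .segmentation import NucleusField
from .shells import shell_index_map

__all__ = [
    "ImageSimSpec",
    "CountSimSpec",
    "QpcrSimSpec",
    "SimulatedImageField",
    "SimulatedSpotField",
    "simulate_image_field",
    "simulate_npc_field",
    "simulate_chip_counts",
    "simulate_ct_table",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails within the retry budget."""


# ---------------------------------------------------------------------------
# specs


@dataclass
class ImageSimSpec:
    """Parameters of a simulated multi-channel nucleus field.

    Defaults emulate the source imaging conditions: 90 nm pixels, nuclei of
    ~5 µm mean radius, a 1.5 µm bright rim, and Gaussian noise at 5 % of
    the rim intensity (a realistic confocal regime).  ``noise`` is
    ``("gaussian", sd)`` or ``("poisson", gain)``; ``None`` selects the
    Gaussian default.
    """

    field_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.09
    n_nuclei: int = 5
    nucleus_radius_um: tuple[float, float] = (5.0, 0.5)
    rim_width_um: float = 1.5
    rim_intensity_au: float = 10000.0
    interior_to_rim_ratio: float = 0.4
    background_au: float = 1000.0
    noise: tuple[str, float] | None = None
    npc_density_per_um2: float = 10.0
    allow_overlap: bool = False
    include_nucleoli: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interior_to_rim_ratio < 0:
            raise ValueError("interior_to_rim_ratio must be >= 0")
        if self.background_au < 0 or self.rim_intensity_au < 0:
            raise ValueError("intensities must be >= 0")
        if self.rim_width_um >= self.nucleus_radius_um[0]:
            raise ValueError("rim_width_um must be below the mean nucleus radius")
        if self.npc_density_per_um2 < 0:
            raise ValueError("npc_density_per_um2 must be >= 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.noise is None:
            self.noise = ("gaussian", 0.05 * self.rim_intensity_au)
        kind = self.noise[0]
        if kind not in {"gaussian", "poisson"}:
            raise ValueError(f"unknown noise model {kind!r}")


@dataclass
class CountSimSpec:
    """Parameters of a simulated ChIP gene-count table.

    ``gene_length_bp`` gives (log-mean, log-sd) of a log-normal length
    distribution (default centred near 20 kb, as for mouse genes).  Bound
    genes have their baseline mean multiplied by ``bound_enrichment_fold``;
    differential genes carry ``differential_log2fc`` in MT relative to MB.
    """

    n_genes: int = 2000
    gene_length_bp: tuple[float, float] = (np.log(20000.0), 0.8)
    samples_per_condition: int = 3
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    bound_fraction: float = 0.3
    bound_enrichment_fold: float = 8.0
    differential_fraction: float = 0.1
    differential_log2fc: float = 2.0
    library_size_factors: tuple[float, ...] | None = None
    conditions: tuple[str, str] = ("MB", "MT")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound_fraction must lie in [0, 1]")
        if not 0 <= self.differential_fraction <= 1:
            raise ValueError("differential_fraction must lie in [0, 1]")
        if self.bound_enrichment_fold < 1:
            raise ValueError("bound_enrichment_fold must be >= 1")
        n_samples = 2 * self.samples_per_condition
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != n_samples:
                raise ValueError("library_size_factors must have one entry per sample")
            if any(s <= 0 for s in self.library_size_factors):
                raise ValueError("library_size_factors must be positive")


@dataclass
class QpcrSimSpec:
    """Parameters of a simulated qPCR Ct table.

    ``true_log2_fold_change`` maps gene -> group -> log2 fold change vs the
    calibrator group; the calibrator itself is fixed at fold 1 (log2 fold
    0) for every gene.  Reactions are simulated in triplicate by default.
    """

    genes: tuple[str, ...] = ("Tpr", "Myog", "Myh4")
    groups: tuple[str, ...] = ("WT_MB", "WT_MT")
    calibrator_group: str = "WT_MB"
    replicates: int = 3
    reference_gene: str = "Gapdh"
    true_log2_fold_change: dict = field(default_factory=dict)
    reference_ct: float = 15.0
    gene_offset_ct: dict | None = None
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.calibrator_group not in self.groups:
            raise ValueError("calibrator_group must be one of groups")
        if self.reference_gene in self.genes:
            raise ValueError("reference_gene must not appear among target genes")
        for gene, per_group in self.true_log2_fold_change.items():
            if per_group.get(self.calibrator_group, 0.0) != 0.0:
                raise ValueError(f"calibrator fold change must be 1 (gene {gene})")

    def lfc(self, gene: str, group: str) -> float:
        return float(self.true_log2_fold_change.get(gene, {}).get(group, 0.0))


# ---------------------------------------------------------------------------
# image field


@dataclass
class SimulatedImageField:
    """Simulated channels plus ground truth."""

    field: NucleusField
    labels: np.ndarray
    truth: pd.DataFrame
    spec: ImageSimSpec


def _nucleus_mask(rng: np.random.Generator, radius_px: float) -> np.ndarray:
    """Rasterize one star-convex nucleus: an ellipse with a low-order radial
    Fourier perturbation of total amplitude <= 10 % of the radius."""
    ecc = rng.uniform(0.9, 1.1)
    a, b = radius_px * ecc, radius_px / ecc
    phi0 = rng.uniform(0.0, np.pi)
    modes = np.array([2, 3, 4])
    amps = rng.uniform(0.0, 0.1 / len(modes), size=len(modes))
    phases = rng.uniform(0.0, 2 * np.pi, size=len(modes))
    r_max = max(a, b) * 1.1
    n = int(np.ceil(r_max)) + 2
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1].astype(float)
    x = xx * np.cos(phi0) + yy * np.sin(phi0)
    y = -xx * np.sin(phi0) + yy * np.cos(phi0)
    theta = np.arctan2(y, x)
    rho = np.hypot(x, y)
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    pert = 1.0 + sum(
        amp * np.cos(k * theta + ph) for amp, k, ph in zip(amps, modes, phases)
    )
    return rho <= r_ell * pert


def _paste_or(dest: np.ndarray, patch: np.ndarray, r0: int, c0: int) -> None:
    """OR a boolean patch into dest at (r0, c0), clipping at the borders."""
    h, w = dest.shape
    ph, pw = patch.shape
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + ph, h), min(c0 + pw, w)
    if rr1 <= rr0 or cc1 <= cc0:
        return
    dest[rr0:rr1, cc0:cc1] |= patch[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]


def _place_nuclei(spec: ImageSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Label grid of placed nuclei (labels 1..n, in placement order)."""
    from scipy import ndimage

    h, w = spec.field_shape_px
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)  # prior foreground dilated by 1 px
    mean_r, sd_r = spec.nucleus_radius_um
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_nuclei)
    for i in range(spec.n_nuclei):
        sub = np.random.default_rng(seeds[i])
        placed = False
        for _ in range(300):
            radius_um = max(sub.normal(mean_r, sd_r), spec.rim_width_um * 1.5)
            mask = _nucleus_mask(sub, radius_um / spec.pixel_size_um)
            mh, mw = mask.shape
            if mh >= h or mw >= w:
                continue
            r0 = int(sub.integers(0, h - mh))
            c0 = int(sub.integers(0, w - mw))
            region = occupied[r0 : r0 + mh, c0 : c0 + mw]
            if spec.allow_overlap or not (region & mask).any():
                labels[r0 : r0 + mh, c0 : c0 + mw][mask] = i + 1
                # store a dilated copy so neighbouring nuclei keep a gap wide
                # enough to survive the segmentation's morphological closing
                gap = 4
                grown = ndimage.binary_dilation(
                    np.pad(mask, gap), structure=np.ones((3, 3), dtype=bool), iterations=gap
                )
                _paste_or(occupied, grown, r0 - gap, c0 - gap)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} without overlap; "
                "enlarge the field or reduce n_nuclei"
            )
    return labels


def _apply_noise(img: np.ndarray, noise: tuple[str, float], rng: np.random.Generator) -> np.ndarray:
    kind, param = noise
    if kind == "gaussian":
        out = img + rng.normal(0.0, param, size=img.shape) if param > 0 else img.copy()
    else:  # poisson with camera gain: counts = gain * Poisson(signal / gain)
        gain = param
        out = gain * rng.poisson(np.maximum(img, 0.0) / gain).astype(float)
    return np.maximum(out, 0.0)


def simulate_image_field(spec: ImageSimSpec) -> SimulatedImageField:
    """Simulate DNA / NUP / target channels plus a per-nucleus truth table.

    The target channel carries ``rim_intensity_au`` in the rim band (the
    shells within ``rim_width_um`` of the boundary, by the downstream shell
    rule) and ``interior_to_rim_ratio x rim_intensity_au`` in the interior,
    on top of a uniform background; the NUP channel is rim-only with
    NPC-like bright pixels at ``npc_density_per_um2`` over the rim area;
    the DNA channel fills the whole nucleus.  Truth rows give each
    nucleus's noiseless rim and interior means and the background-free
    interior : rim intensity ratio.
    """
    labels = _place_nuclei(spec, np.random.default_rng(spec.seed))
    px = spec.pixel_size_um
    k = shell_index_map(labels, px)
    inside = labels > 0
    rim = inside & (k * px < spec.rim_width_um)
    interior = inside & ~rim

    rim_i = spec.rim_intensity_au
    target = np.full(labels.shape, spec.background_au, dtype=float)
    target[rim] += rim_i
    target[interior] += spec.interior_to_rim_ratio * rim_i
    dna = np.full(labels.shape, spec.background_au, dtype=float)
    dna[inside] += rim_i
    nup = np.full(labels.shape, spec.background_au, dtype=float)
    nup[rim] += rim_i

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if spec.include_nucleoli:
        target = _carve_nucleoli(target, labels, interior, spec, rng)

    # NPC-like puncta on the rim of the NUP channel
    rim_area_um2 = rim.sum() * px**2
    n_spots = rng.poisson(spec.npc_density_per_um2 * rim_area_um2)
    rim_idx = np.flatnonzero(rim)
    if n_spots > 0 and rim_idx.size > 0:
        chosen = rng.choice(rim_idx, size=min(n_spots, rim_idx.size), replace=False)
        nup.ravel()[chosen] += rim_i

    truth_rows = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if not m.any():
            continue
        rows, cols = np.nonzero(m)
        rim_m, int_m = m & rim, m & interior
        rim_mean = float(target[rim_m].mean()) if rim_m.any() else np.nan
        int_mean = float(target[int_m].mean()) if int_m.any() else np.nan
        sig = rim_mean - spec.background_au
        ratio = (int_mean - spec.background_au) / sig if int_m.any() and sig > 0 else np.nan
        truth_rows.append(
            {
                "nucleus_id": lab,
                "centroid_row": float(rows.mean()),
                "centroid_col": float(cols.mean()),
                "area_px": int(m.sum()),
                "true_rim_mean": rim_mean,
                "true_interior_mean": int_mean,
                "true_ratio": ratio,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "nucleus_id",
            "centroid_row",
            "centroid_col",
            "area_px",
            "true_rim_mean",
            "true_interior_mean",
            "true_ratio",
        ],
    )

    channels = {
        "dna": _apply_noise(dna, spec.noise, rng),
        "nup": _apply_noise(nup, spec.noise, rng),
        "target": _apply_noise(target, spec.noise, rng),
    }
    field = NucleusField(channels=channels, pixel_size_um=px, meta={"seed": spec.seed})
    return SimulatedImageField(field=field, labels=labels, truth=truth, spec=spec)


def _carve_nucleoli(
    target: np.ndarray,
    labels: np.ndarray,
    interior: np.ndarray,
    spec: ImageSimSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Optionally darken 1-3 round nucleolus-like regions per nucleus."""
    out = target.copy()
    yy, xx = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    for lab in range(1, labels.max() + 1):
        m = (labels == lab) & interior
        if not m.any():
            continue
        idx = np.flatnonzero(m)
        for _ in range(rng.integers(1, 4)):
            c = idx[rng.integers(idx.size)]
            cr, cc = divmod(c, labels.shape[1])
            r_nucleolus = rng.uniform(2, 5)
            disk = (yy - cr) ** 2 + (xx - cc) ** 2 <= r_nucleolus**2
            region = disk & m
            out[region] = spec.background_au + 0.3 * (out[region] - spec.background_au)
    return out


# ---------------------------------------------------------------------------
# NPC spot field


@dataclass
class SimulatedSpotField:
    """Simulated spot channel with its analysis mask and true count."""

    channel: np.ndarray
    mask: np.ndarray
    n_spots_true: int
    mask_area_um2: float
    pixel_size_um: float
    spec: ImageSimSpec


def simulate_npc_field(spec: ImageSimSpec, mask: np.ndarray | None = None) -> SimulatedSpotField:
    """Simulate an NPC-like spot field at known density.

    The number of spots is Poisson with mean ``density x mask area``.
    Spots are single-pixel point emitters placed uniformly at random in the
    mask under a minimum-separation constraint (no two spots 8-adjacent):
    NPCs are physical objects of finite size, and the constraint keeps each
    emitter resolvable as its own connected component.
    """
    h, w = spec.field_shape_px
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (h, w):
            raise ValueError("mask shape must match field_shape_px")
    area_um2 = float(mask.sum()) * spec.pixel_size_um**2
    if area_um2 <= 0:
        raise ValueError("mask area must be positive")
    rng = np.random.default_rng(spec.seed)
    n_spots = int(rng.poisson(spec.npc_density_per_um2 * area_um2))
    channel = np.full((h, w), spec.background_au, dtype=float)
    if n_spots > 0:
        candidates = np.flatnonzero(mask)
        rng.shuffle(candidates)
        blocked = np.zeros((h, w), dtype=bool)
        accepted = []
        for flat in candidates:
            r, c = divmod(int(flat), w)
            if blocked[r, c]:
                continue
            accepted.append((r, c))
            if len(accepted) == n_spots:
                break
            blocked[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2] = True
        if len(accepted) < n_spots:
            raise PlacementError(
                f"could only place {len(accepted)} of {n_spots} spots at "
                f"density {spec.npc_density_per_um2}/um^2"
            )
        rows, cols = zip(*accepted)
        channel[np.asarray(rows), np.asarray(cols)] += spec.rim_intensity_au
    channel = _apply_noise(channel, spec.noise, rng)
    return SimulatedSpotField(
        channel=channel,
        mask=mask,
        n_spots_true=n_spots,
        mask_area_um2=area_um2,
        pixel_size_um=spec.pixel_size_um,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# ChIP counts


def simulate_chip_counts(spec: CountSimSpec) -> tuple[GeneCountTable, pd.DataFrame]:
    """Simulate a genes × samples NB count table with known truth.

    Gene means follow ``baseline x enrichment x size_factor x
    2^(log2fc x [condition == MT])`` with bound genes enriched
    ``bound_enrichment_fold``-fold and differential genes carrying
    ``differential_log2fc``.  Counts are gamma-Poisson draws at the given
    dispersion (Poisson when the dispersion is 0).  The truth table lists
    each gene's length, bound flag and true log2 fold change.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    mu_log, sd_log = spec.gene_length_bp
    lengths = np.maximum(rng.lognormal(mu_log, sd_log, size=n).astype(np.int64), 200)
    bound = rng.random(n) < spec.bound_fraction
    differential = rng.random(n) < spec.differential_fraction
    lfc = np.where(differential, spec.differential_log2fc, 0.0)

    ref, alt = spec.conditions
    nps = spec.samples_per_condition
    samples = [f"{ref}_{i + 1}" for i in range(nps)] + [f"{alt}_{i + 1}" for i in range(nps)]
    condition = np.array([ref] * nps + [alt] * nps)
    antibodies = [("TPR-N", "TPR-C")[i % 2] for i in range(nps)] * 2
    sf = (
        np.asarray(spec.library_size_factors, dtype=float)
        if spec.library_size_factors is not None
        else np.ones(2 * nps)
    )

    base = spec.baseline_mean * np.where(bound, spec.bound_enrichment_fold, 1.0)
    mu = base[:, None] * sf[None, :] * 2.0 ** (lfc[:, None] * (condition == alt)[None, :])
    if spec.dispersion > 0:
        lam = rng.gamma(shape=1.0 / spec.dispersion, scale=spec.dispersion * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    table = GeneCountTable(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        sample_info=pd.DataFrame(
            {"condition": condition, "antibody": antibodies}, index=samples
        ),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": lengths,
            "bound": bound,
            "true_log2fc": lfc,
            "baseline_mean": base,
        }
    ).set_index("gene_id")
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct_table(spec: QpcrSimSpec) -> tuple[CtTable, pd.DataFrame]:
    """Simulate a Ct table whose 2^-ΔΔCT analysis recovers known folds.

    Target Ct = reference_ct + gene offset - true log2 fold change + noise;
    the reference gene sits at ``reference_ct`` (+ noise) in every sample,
    and the calibrator group encodes fold 1.  With ``ct_noise_sd = 0`` the
    ΔΔCT round trip is exact.
    """
    rng = np.random.default_rng(spec.seed)
    offsets = (
        spec.gene_offset_ct
        if spec.gene_offset_ct is not None
        else {g: 2.0 + i for i, g in enumerate(spec.genes)}
    )
    rows = []
    for group in spec.groups:
        sample = group  # one biological sample per group; replicates are technical
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": spec.reference_gene,
                    "replicate": rep,
                    "ct": spec.reference_ct + noise,
                }
            )
        for gene in spec.genes:
            for rep in range(1, spec.replicates + 1):
                noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct": spec.reference_ct + offsets[gene] - spec.lfc(gene, group) + noise,
                    }
                )
    table = CtTable(
        data=pd.DataFrame(rows),
        reference_gene=spec.reference_gene,
        calibrator_group=spec.calibrator_group,
    )
    truth = pd.DataFrame(
        [
            {"gene": g, "group": grp, "true_fold_change": 2.0 ** spec.lfc(g, grp)}
            for g in spec.genes
            for grp in spec.groups
        ]
    )
    return table, truth
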