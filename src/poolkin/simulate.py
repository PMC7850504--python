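"""Seeded generators of synthetic bulk-frequency panels.

The generators emulate the statistical structure the analysis pipeline
assumes — hierarchically structured reference groups, a two-pool
longitudinal admixture gradient with climate covariates, and admixed focal
groups — so every stage can be exercised without the (undeposited) real
frequency matrix.  Drift is modelled with the Balding-Nichols
distribution: a daughter frequency given ancestral frequency p0 and drift
parameter F is Beta(p0 (1-F)/F, (1-p0)(1-F)/F), which has mean p0 and
variance F p0 (1-p0).  Bulk genotyping of b plants is emulated as
binomial sampling of 2b gene copies, adding variance p(1-p)/(2b).

Two equally drifted sister groups at drift F show an expected pairwise
Nei Gst of (F/2)/(1 - F/2) between their mean frequency vectors (the
pooled total heterozygosity itself shrinks with F), inverted by
:func:`drift_from_pairwise_gst`.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CLIMATE_COLUMNS, FrequencyMatrix, MarkerPanel, PassportTable

__all__ = [
    "GroupSpec",
    "GradientSpec",
    "AdmixtureSpec",
    "SimConfig",
    "balding_nichols",
    "drift_from_pairwise_gst",
    "generate_reference_panel",
    "generate_swf_gradient",
    "generate_admixed_focal",
    "generate_marker_panel",
    "swf_panel_config",
]

#: total genetic map length in cM emulated by default (maize-like).
DEFAULT_MAP_LENGTH_CM = 1600.0


@dataclass
class GroupSpec:
    """One reference group: label, size, group- and landrace-level drift."""

    label: str
    n_landraces: int
    fst: float                 # group drift from the shared ancestral pool
    landrace_fst: float = 0.05  # further drift of each landrace within its group

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0 or not 0.0 <= self.landrace_fst < 1.0:
            raise ValueError("drift F must lie in [0, 1)")


@dataclass
class GradientSpec:
    """A longitudinal admixture cline between two ancestral pools.

    Landrace i at longitude x has ancestry in pool 'East' interpolated
    linearly between ``ancestry_endpoints`` across ``longitude_range``;
    ``neighbor_mixing`` smooths base frequencies with the adjacent
    landraces along the cline, adding spatial autocorrelation, and
    ``landrace_fst`` adds local drift on top.
    """

    n_landraces: int = 194
    longitude_range: tuple[float, float] = (-1.8, 3.2)
    latitude_range: tuple[float, float] = (42.6, 45.2)
    ancestry_endpoints: tuple[float, float] = (0.0, 1.0)
    pool_fst: float = 0.10          # divergence of the two ancestral pools
    landrace_fst: float = 0.02
    neighbor_mixing: float = 0.3
    n_no_coordinates: int = 0       # landraces emitted without lat/lon


@dataclass
class AdmixtureSpec:
    """Focal group built as an alpha:(1-alpha) blend of two references."""

    focal_label: str
    ref_y: str
    ref_w: str
    alpha: float = 0.5
    drift_fst: float = 0.01
    n_landraces: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class SimConfig:
    n_loci: int = 23412
    n_chromosomes: int = 10
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    groups: list[GroupSpec] = field(default_factory=list)
    gradient: GradientSpec | None = None
    admixture: AdmixtureSpec | None = None
    bulk_size: int | None = 15     # plants per bulk; None disables sampling noise
    n_missing_loci: int = 0        # loci given >=1 missing call (filter fixture)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


def balding_nichols(rng: np.random.Generator, p0: np.ndarray, F: float,
                    size=None) -> np.ndarray:
    """Draw drifted frequencies; F = 0 returns the ancestral values."""
    p0 = np.asarray(p0, dtype=float)
    if F == 0.0:
        return np.broadcast_to(p0, size).copy() if size is not None else p0.copy()
    scale = (1.0 - F) / F
    # loci already fixed stay fixed under pure drift
    safe = np.clip(p0, 1e-12, 1.0 - 1e-12)
    out = rng.beta(safe * scale, (1.0 - safe) * scale, size=size)
    return np.where(p0 <= 0.0, 0.0, np.where(p0 >= 1.0, 1.0, out))


def drift_from_pairwise_gst(gst: float) -> float:
    """Invert the two-sister-group moment Gst = (F/2)/(1 - F/2)."""
    return 2.0 * gst / (1.0 + gst)


def _bulk_noise(rng: np.random.Generator, p: np.ndarray,
                bulk_size: int | None) -> np.ndarray:
    if bulk_size is None:
        return p
    copies = 2 * bulk_size
    return rng.binomial(copies, np.clip(p, 0.0, 1.0)) / copies


def generate_marker_panel(n_loci: int, n_chromosomes: int,
                          rng: np.random.Generator,
                          total_length_cM: float = DEFAULT_MAP_LENGTH_CM
                          ) -> MarkerPanel:
    """Uniform marker positions over equal-length chromosomes."""
    per = np.full(n_chromosomes, n_loci // n_chromosomes)
    per[: n_loci % n_chromosomes] += 1
    chrom_len = total_length_cM / n_chromosomes
    rows = []
    locus = 0
    for c in range(n_chromosomes):
        pos = np.sort(rng.uniform(0.0, chrom_len, size=per[c]))
        for p in pos:
            rows.append((f"snp{locus:06d}", f"chr{c + 1:02d}", p))
            locus += 1
    return MarkerPanel(pd.DataFrame(rows, columns=["locus_id", "chromosome",
                                                   "position_cM"]))


def _ancestral(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    lo, hi = cfg.ancestral_freq_range
    return rng.uniform(lo, hi, size=cfg.n_loci)


def generate_reference_panel(cfg: SimConfig
                             ) -> tuple[FrequencyMatrix, PassportTable, MarkerPanel]:
    """Hierarchical reference panel: ancestral pool -> groups -> landraces.

    Group frequencies drift from a shared ancestral pool at each group's
    F, landraces drift further at the landrace-level F, and bulk binomial
    noise is added last.  Passport rows carry the true group labels.
    """
    if not cfg.groups:
        raise ValueError("config defines no groups")
    rng = np.random.default_rng(cfg.seed)
    panel = generate_marker_panel(cfg.n_loci, cfg.n_chromosomes, rng)
    p0 = _ancestral(rng, cfg)
    ids, rows, labels = [], [], []
    for spec in cfg.groups:
        pg = balding_nichols(rng, p0, spec.fst)
        for i in range(spec.n_landraces):
            p = balding_nichols(rng, pg, spec.landrace_fst)
            p = _bulk_noise(rng, p, cfg.bulk_size)
            ids.append(f"{spec.label}_{i:03d}")
            labels.append(spec.label)
            rows.append(p)
    values = np.vstack(rows)
    values = _inject_missing(rng, values, cfg.n_missing_loci)
    fm = FrequencyMatrix(ids, panel.locus_ids, values)
    pp = PassportTable(pd.DataFrame({"landrace_id": ids, "group": labels}))
    return fm, pp, panel


def _inject_missing(rng: np.random.Generator, values: np.ndarray,
                    n_missing_loci: int) -> np.ndarray:
    if n_missing_loci == 0:
        return values
    n, L = values.shape
    if n_missing_loci > L:
        raise ValueError("more missing loci requested than loci present")
    cols = rng.choice(L, size=n_missing_loci, replace=False)
    out = values.copy()
    for c in cols:
        k = 1 + rng.binomial(n - 1, 0.1)   # at least one landrace missing
        out[rng.choice(n, size=k, replace=False), c] = np.nan
    return out


def generate_swf_gradient(cfg: SimConfig
                          ) -> tuple[FrequencyMatrix, PassportTable, MarkerPanel]:
    """Longitudinal admixture gradient with climate covariates.

    Two ancestral pools diverge from a common pool at ``pool_fst``;
    landrace base frequencies interpolate between them according to a
    linear-in-longitude ancestry, are smoothed with cline neighbours, and
    receive local drift plus bulk noise.  Climate covariates follow the
    Atlantic-west / Mediterranean-east contrast: monthly temperature rises and
    precipitation falls with longitude, plus noise.
    """
    spec = cfg.gradient
    if spec is None:
        raise ValueError("config defines no gradient")
    rng = np.random.default_rng(cfg.seed)
    panel = generate_marker_panel(cfg.n_loci, cfg.n_chromosomes, rng)
    p0 = _ancestral(rng, cfg)
    pool_w = balding_nichols(rng, p0, spec.pool_fst)
    pool_e = balding_nichols(rng, p0, spec.pool_fst)

    n = spec.n_landraces
    lon = np.sort(rng.uniform(*spec.longitude_range, size=n))
    lat = rng.uniform(*spec.latitude_range, size=n)
    a0, a1 = spec.ancestry_endpoints
    t = (lon - spec.longitude_range[0]) / max(
        spec.longitude_range[1] - spec.longitude_range[0], 1e-12)
    alpha = a0 + (a1 - a0) * t

    base = alpha[:, None] * pool_e + (1.0 - alpha[:, None]) * pool_w
    m = spec.neighbor_mixing
    if m > 0 and n >= 3:
        smoothed = base.copy()
        smoothed[1:-1] = (1 - m) * base[1:-1] + (m / 2) * (base[:-2] + base[2:])
        smoothed[0] = (1 - m) * base[0] + m * base[1]
        smoothed[-1] = (1 - m) * base[-1] + m * base[-2]
        base = smoothed

    rows = []
    for i in range(n):
        p = balding_nichols(rng, base[i], spec.landrace_fst)
        rows.append(_bulk_noise(rng, p, cfg.bulk_size))
    values = _inject_missing(rng, np.vstack(rows), cfg.n_missing_loci)
    ids = [f"SWF_{i:03d}" for i in range(n)]
    fm = FrequencyMatrix(ids, panel.locus_ids, values)

    climate = {}
    for j, col in enumerate(CLIMATE_COLUMNS):
        if col.startswith("tmean"):
            climate[col] = 14.0 + 2.0 * j / 6.0 + 0.8 * lon + rng.normal(0, 0.3, n)
        else:
            climate[col] = 90.0 - 8.0 * lon + rng.normal(0, 3.0, n)
    passport = pd.DataFrame({"landrace_id": ids, "group": "SWF",
                             "latitude": lat, "longitude": lon, **climate})
    if spec.n_no_coordinates:
        drop = rng.choice(n, size=spec.n_no_coordinates, replace=False)
        passport.loc[drop, ["latitude", "longitude"]] = np.nan
    return fm, PassportTable(passport), panel


def generate_admixed_focal(
    refY_freqs,
    refW_freqs,
    alpha: float,
    drift_F: float,
    n_landraces: int,
    seed: int | None = None,
    bulk_size: int | None = None,
    label: str = "FOCAL",
) -> FrequencyMatrix:
    """Focal landraces built as alpha*Y + (1-alpha)*W plus drift and noise."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    y = np.asarray(refY_freqs, dtype=float)
    w = np.asarray(refW_freqs, dtype=float)
    if y.shape != w.shape or y.ndim != 1:
        raise ValueError("parental vectors must be 1-D and equal length")
    rng = np.random.default_rng(seed)
    base = alpha * y + (1.0 - alpha) * w
    rows = []
    for _ in range(n_landraces):
        p = balding_nichols(rng, base, drift_F)
        rows.append(_bulk_noise(rng, p, bulk_size))
    ids = [f"{label}_{i:03d}" for i in range(n_landraces)]
    return FrequencyMatrix(ids, [f"snp{j:06d}" for j in range(y.size)],
                           np.vstack(rows))


def swf_panel_config(seed: int = 0, n_loci: int = 23412,
                      scale: float = 1.0) -> SimConfig:
    """Config emulating a full-size SWF-style landrace panel.

    Seven reference groups of realistic sizes, a 194-landrace
    longitudinal gradient, 23412 loci of which 378 carry missing calls and
    15-plant bulks.  ``scale`` in (0, 1] shrinks group sizes and locus
    count proportionally for faster runs.
    """
    def s(x: int) -> int:
        return max(int(round(x * scale)), 2)

    groups = [
        GroupSpec("AND", s(12), 0.15),
        GroupSpec("CAR", s(25), 0.12),
        GroupSpec("MEX", s(22), 0.12),
        GroupSpec("NFA", s(28), 0.20),
        GroupSpec("NFE", s(9), 0.20),
        GroupSpec("CBD", s(15), 0.10),
        GroupSpec("ITA", s(17), 0.12),
    ]
    return SimConfig(
        n_loci=max(int(round(n_loci * scale)), 100),
        groups=groups,
        gradient=GradientSpec(n_landraces=s(194),
                              n_no_coordinates=s(36) if scale == 1.0 else 0),
        bulk_size=15,
        n_missing_loci=max(int(round(378 * scale)), 0),
        seed=seed,
    )
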