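"""Synthetic data generators with known ground truth.

Every downstream stage of the toolkit can be exercised without any external
data: image stacks of bright sub-resolution puncta over dim host-nucleus
blobs, qPCR plates generated from true copy numbers through a log-linear
amplification model, and titer datasets with prescribed medians and
dispersions.  Generators are pure functions of their arguments including the
seed.

The named reference conditions in :data:`REFERENCE_CONDITIONS` encode the
study conditions the toolkit was validated against: per-stage germline titer
medians under control, un-enriched and yeast-enriched diets, with dispersions
calibrated once from the published summary statistics (see
``docs/methods.md``).  These are synthetic stand-ins for the undeposited
per-ovariole tables, not the original measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError
from .image_titer import ImageStack

# log10 threshold-cycle slope for amplification efficiency E:
# each cycle multiplies template by (1 + E), so Ct is linear in log10(copies)
# with slope -1 / log10(1 + E).  Perfect doubling (E = 1) gives -3.3219.


def slope_from_efficiency(efficiency: float) -> float:
    if not 0 < efficiency <= 1.5:
        raise ValueError("amplification efficiency must be in (0, 1.5]")
    return -1.0 / math.log10(1.0 + efficiency)


@dataclass
class StackGroundTruth:
    """Every object rendered into a synthetic stack.

    ``punctum_centers`` are (z, y, x) voxel coordinates; each punctum's
    intensity lives in its single center plane, except for the
    ``straddler_indices`` whose footprint is echoed into the adjacent plane
    listed in ``echo_planes`` (emulating a nucleoid caught between two focal
    planes).
    """

    punctum_centers: list[tuple[int, float, float]]
    punctum_radius_px: float
    nuclei_centers: list[tuple[float, float, float]]
    seed: int
    straddler_indices: list[int] = field(default_factory=list)
    echo_planes: dict[int, int] = field(default_factory=dict)
    amplitude: float = 1000.0
    background: float = 100.0

    @property
    def n_puncta(self) -> int:
        return len(self.punctum_centers)

    def per_plane_counts(self, n_planes: int) -> np.ndarray:
        """Primary punctum count per plane (echoes not included)."""
        counts = np.zeros(n_planes, dtype=int)
        for z, _, _ in self.punctum_centers:
            counts[z] += 1
        return counts

    def straddle_fraction(self) -> float:
        return len(self.straddler_indices) / max(1, self.n_puncta)


def _place_points(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    n: int,
    min_sep: float,
    margin: float,
    z_quotas: Mapping[int, int] | None,
) -> np.ndarray:
    """Dart-throwing placement of (z, y, x) points at 3D minimum separation."""
    nz, ny, nx = shape
    if ny - 2 * margin <= 0 or nx - 2 * margin <= 0:
        raise CapacityError("stack too small for the requested punctum margin")
    if z_quotas is None:
        targets = [(None, n)]
    else:
        targets = sorted(z_quotas.items())
        if any(not 0 <= z < nz for z, _ in targets):
            raise ValueError("z quota plane out of range")
    placed = np.empty((0, 3), dtype=float)
    max_tries = max(2000, 400 * n)
    tries = 0
    for zplane, quota in targets:
        got = 0
        while got < quota:
            if tries >= max_tries:
                raise CapacityError(
                    f"could not place {n} puncta at separation {min_sep}"
                )
            tries += 1
            z = rng.integers(0, nz) if zplane is None else zplane
            y = rng.uniform(margin, ny - 1 - margin)
            x = rng.uniform(margin, nx - 1 - margin)
            cand = np.array([z, y, x], dtype=float)
            if placed.size:
                d2 = np.sum((placed - cand) ** 2, axis=1)
                if d2.min() < min_sep**2:
                    continue
            placed = np.vstack([placed, cand])
            got += 1
    return placed


def _stamp_gaussian_2d(plane: np.ndarray, yc: float, xc: float, sigma: float,
                       amplitude: float) -> None:
    r = int(math.ceil(3 * sigma))
    ny, nx = plane.shape
    y0, y1 = max(0, int(yc) - r), min(ny, int(yc) + r + 1)
    x0, x1 = max(0, int(xc) - r), min(nx, int(xc) + r + 1)
    yy = np.arange(y0, y1)[:, None] - yc
    xx = np.arange(x0, x1)[None, :] - xc
    plane[y0:y1, x0:x1] += amplitude * np.exp(
        -(yy**2 + xx**2) / (2 * sigma**2)
    )


def _stamp_gaussian_3d(vol: np.ndarray, zc: float, yc: float, xc: float,
                       sigma_xy: float, sigma_z: float, amplitude: float) -> None:
    rz = int(math.ceil(3 * sigma_z))
    nz = vol.shape[0]
    z0, z1 = max(0, int(zc) - rz), min(nz, int(zc) + rz + 1)
    for z in range(z0, z1):
        a = amplitude * math.exp(-((z - zc) ** 2) / (2 * sigma_z**2))
        _stamp_gaussian_2d(vol[z], yc, xc, sigma_xy, a)


def make_stack(
    shape: tuple[int, int, int] = (16, 128, 128),
    n_puncta: int = 100,
    punctum_radius_px: float = 3.0,
    min_separation_px: float = 7.0,
    nuclei_spec: tuple[int, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    straddle_fraction: float = 0.0,
    echo_amplitude_frac: float = 0.6,
    amplitude: float = 1000.0,
    background: float = 100.0,
    nucleus_amplitude: float = 300.0,
    noise_model: str = "gaussian",
    z_quotas: Mapping[int, int] | None = None,
    strict: bool = True,
    z_step_um: float = 1.5,
) -> tuple[ImageStack, StackGroundTruth]:
    """Render a synthetic confocal stack of puncta over optional nuclei.

    Puncta are isotropic 2D Gaussian profiles (sigma = radius / 2) confined
    to a single focal plane; a ``straddle_fraction`` of them echo a dimmer
    copy into the adjacent plane, emulating nucleoids caught between planes.
    Host nuclei (``nuclei_spec = (count, radius_px)``) are large 3D blobs
    rendered at lower peak intensity than puncta so a single threshold can
    separate them.  Noise is additive Gaussian by default (``noise_model``
    may be ``"poisson"``).  Same seed, same arguments: bit-identical output.

    Raises :class:`CapacityError` when ``n_puncta`` cannot be placed at the
    requested minimum separation within a bounded number of retries.
    """
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    if n_puncta < 0:
        raise ValueError("n_puncta must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= straddle_fraction <= 1:
        raise ValueError("straddle_fraction must be in [0, 1]")
    if strict and n_puncta > 0 and min_separation_px <= 2 * punctum_radius_px:
        raise ValueError(
            "strict separation requires min_separation_px > 2 * punctum_radius_px"
        )
    rng = np.random.default_rng(seed)
    vol = np.full(shape, float(background))
    sigma = punctum_radius_px / 2.0
    margin = 3 * sigma + 1

    nuclei_centers: list[tuple[float, float, float]] = []
    if nuclei_spec is not None:
        n_nuc, nuc_radius = nuclei_spec
        for _ in range(int(n_nuc)):
            zc = rng.uniform(0, shape[0] - 1)
            yc = rng.uniform(nuc_radius, shape[1] - 1 - nuc_radius)
            xc = rng.uniform(nuc_radius, shape[2] - 1 - nuc_radius)
            _stamp_gaussian_3d(
                vol, zc, yc, xc,
                sigma_xy=nuc_radius / 2.0,
                sigma_z=max(1.0, nuc_radius / 6.0),
                amplitude=nucleus_amplitude,
            )
            nuclei_centers.append((zc, yc, xc))

    if z_quotas is not None and sum(z_quotas.values()) != n_puncta:
        raise ValueError("z_quotas must sum to n_puncta")
    pts = _place_points(rng, shape, n_puncta, min_separation_px, margin, z_quotas)

    n_straddle = int(round(straddle_fraction * n_puncta))
    straddlers = sorted(rng.choice(n_puncta, size=n_straddle, replace=False).tolist()) \
        if n_straddle else []
    echo_planes: dict[int, int] = {}

    centers: list[tuple[int, float, float]] = []
    for i, (z, y, x) in enumerate(pts):
        z = int(z)
        centers.append((z, float(y), float(x)))
        _stamp_gaussian_2d(vol[z], y, x, sigma, amplitude)
        if i in straddlers:
            ze = z + 1 if z + 1 < shape[0] else z - 1
            _stamp_gaussian_2d(vol[ze], y, x, sigma, amplitude * echo_amplitude_frac)
            echo_planes[i] = ze

    if noise_model == "gaussian":
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, size=shape)
    elif noise_model == "poisson":
        vol = rng.poisson(np.clip(vol, 0, None)).astype(float)
    else:
        raise ValueError("noise_model must be 'gaussian' or 'poisson'")
    vol = np.clip(vol, 0, None)

    stack = ImageStack(voxels=vol, z_step_um=z_step_um)
    truth = StackGroundTruth(
        punctum_centers=centers,
        punctum_radius_px=punctum_radius_px,
        nuclei_centers=nuclei_centers,
        seed=seed,
        straddler_indices=straddlers,
        echo_planes=echo_planes,
        amplitude=amplitude,
        background=background,
    )
    return stack, truth


def stage10_plane_quotas(n_puncta: int, n_planes: int,
                         z_center: int | None = None) -> dict[int, int]:
    """Per-plane punctum quotas for an exactly-doubling stage-10 stack.

    The half-depth doubling rule counts planes from the Z-center (the unique
    widest plane) down to the bottom of the sample and doubles the sum.  The
    quotas place exactly half the puncta in that counted range, with the
    Z-center plane the strict per-plane maximum, so the doubled total equals
    the true count by construction.
    """
    if n_puncta < 4 or n_puncta % 2:
        raise ValueError("stage-10 quotas require an even n_puncta >= 4")
    m = n_puncta // 2
    f = m // 5
    lower = [m - 2 * f] + ([f, f] if f else [])
    base, rem = divmod(m, 3)
    upper = [base + (1 if i < rem else 0) for i in range(3)]
    upper = [u for u in upper if u > 0]
    if max(upper) >= lower[0]:  # pragma: no cover - guarded by construction
        raise ValueError("quota construction failed")
    zc = n_planes // 2 if z_center is None else z_center
    if zc - len(upper) < 0 or zc + len(lower) - 1 > n_planes - 1:
        raise ValueError("stack too shallow for stage-10 quotas")
    quotas = {zc - len(upper) + i: u for i, u in enumerate(upper)}
    for i, q in enumerate(lower):
        quotas[zc + i] = q
    return quotas


def make_stage10_stack(
    n_puncta: int = 200,
    shape: tuple[int, int, int] = (16, 160, 160),
    seed: int = 0,
    **kwargs,
) -> tuple[ImageStack, StackGroundTruth]:
    """Stack emulating a stage-10 cyst for the half-depth doubling procedure.

    Puncta are distributed over planes so the doubled half-depth count equals
    the true count exactly (see :func:`stage10_plane_quotas`).
    """
    quotas = stage10_plane_quotas(n_puncta, shape[0])
    return make_stack(
        shape=shape, n_puncta=n_puncta, seed=seed, z_quotas=quotas, **kwargs
    )


# ---------------------------------------------------------------------------
# qPCR plates


@dataclass
class PlateGroundTruth:
    """True state behind a synthetic qPCR plate.

    ``true_copies_by_sample`` maps sample id -> {gene -> copies per
    reaction}; uninfected samples carry 0 for the endosymbiont gene, and
    zero-copy wells emit the no-amplification sentinel (an empty Ct).
    ``true_intercept`` is the Ct of a single template copy.
    """

    true_copies_by_sample: Mapping[str, Mapping[str, float]]
    true_efficiency: float
    ct_noise_sd: float
    seed: int
    true_intercept: float = 38.0

    def __post_init__(self) -> None:
        if not 0 < self.true_efficiency <= 1.5:
            raise ValueError("efficiency must be in (0, 1.5]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        for sample, genes in self.true_copies_by_sample.items():
            for gene, copies in genes.items():
                if copies < 0:
                    raise ValueError(f"negative copies for {sample}/{gene}")

    @property
    def true_slope(self) -> float:
        return slope_from_efficiency(self.true_efficiency)


def make_qpcr_plate(
    ground: PlateGroundTruth,
    dilution_series: Sequence[float],
    replicates: int = 3,
    plate: str = "P1",
    treatment_by_sample: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a plate of wells plus its plasmid dilution series.

    Ct values follow the log-linear amplification model
    ``Ct = intercept + slope * log10(copies) + N(0, ct_noise_sd)`` with
    ``slope = -1 / log10(1 + efficiency)``.  Zero-copy wells carry NaN Ct
    (the no-amplification sentinel, written as an empty field in CSV).

    Returns ``(wells, dilution)`` DataFrames with columns
    ``plate, well, sample, gene, treatment, replicate, ct`` and
    ``gene, known_copies, ct``.
    """
    series = np.asarray(dilution_series, dtype=float)
    if np.any(series <= 0):
        raise ValueError("dilution series copies must be positive")
    if series.size < 3:
        raise ValueError("dilution series needs at least 3 points")
    if series.max() / series.min() < 100:
        raise ValueError("dilution series must span at least 2 decades")
    rng = np.random.default_rng(ground.seed)
    m, b = ground.true_slope, ground.true_intercept

    def ct_of(copies: float) -> float:
        if copies <= 0:
            return np.nan
        ct = b + m * math.log10(copies)
        if ground.ct_noise_sd > 0:
            ct += rng.normal(0.0, ground.ct_noise_sd)
        return ct

    rows = []
    widx = 0
    for sample in sorted(ground.true_copies_by_sample):
        genes = ground.true_copies_by_sample[sample]
        treatment = (treatment_by_sample or {}).get(sample, "")
        for gene in sorted(genes):
            for rep in range(1, replicates + 1):
                well = f"{chr(ord('A') + widx // 12)}{widx % 12 + 1}"
                widx += 1
                rows.append(
                    {
                        "plate": plate,
                        "well": well,
                        "sample": sample,
                        "gene": gene,
                        "treatment": treatment,
                        "replicate": rep,
                        "ct": ct_of(genes[gene]),
                    }
                )
    wells = pd.DataFrame(rows)

    genes_present = sorted({g for gm in ground.true_copies_by_sample.values() for g in gm}) \
        or ["wsp"]
    dil_rows = [
        {"gene": gene, "known_copies": c, "ct": ct_of(c)}
        for gene in genes_present
        for c in series
    ]
    dilution = pd.DataFrame(dil_rows)
    return wells, dilution


# ---------------------------------------------------------------------------
# Titer datasets


def make_titer_dataset(
    median: float,
    dispersion: float,
    n: int,
    distribution: str = "lognormal",
    seed: int = 0,
) -> np.ndarray:
    """Draw n titer values with the requested theoretical median.

    ``lognormal``: ``dispersion`` is the standard deviation of log values and
    the distribution is parameterized so exp(mu) equals ``median``.
    ``normal``: ``dispersion`` is the standard deviation (values are clipped
    at zero, titers being counts).  ``dispersion = 0`` returns n copies of
    the median.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if dispersion == 0:
        return np.full(n, float(median))
    if distribution == "lognormal":
        return np.exp(rng.normal(math.log(median), dispersion, size=n))
    if distribution == "normal":
        return np.clip(rng.normal(median, dispersion, size=n), 0.0, None)
    raise ValueError("distribution must be 'lognormal' or 'normal'")


class TiterSpec(NamedTuple):
    """Parameters of one synthetic study condition."""

    median: float
    dispersion: float
    distribution: str


#: Synthetic stand-ins for the study's per-stage titer distributions.
#: Medians are the published condition medians; dispersions were fixed once
#: from the published test statistics (see docs/methods.md) and are not
#: per-dataset estimates.
REFERENCE_CONDITIONS: dict[tuple[str, str], TiterSpec] = {
    ("control", "gsc_single"): TiterSpec(61.5, 22.0, "normal"),
    ("control", "gsc_cluster_cell"): TiterSpec(58.9, 22.0, "normal"),
    ("control", "stage4"): TiterSpec(1140.0, 0.30, "lognormal"),
    ("control", "stage10"): TiterSpec(22500.0, 0.35, "lognormal"),
    ("un-enriched", "gsc_single"): TiterSpec(79.0, 25.5, "normal"),
    ("yeast-enriched", "gsc_single"): TiterSpec(55.0, 25.5, "normal"),
    ("un-enriched", "stage4"): TiterSpec(1180.0, 0.30, "lognormal"),
    ("yeast-enriched", "stage4"): TiterSpec(1260.0, 0.30, "lognormal"),
    ("un-enriched", "stage10"): TiterSpec(22900.0, 0.35, "lognormal"),
    ("yeast-enriched", "stage10"): TiterSpec(8240.0, 0.35, "lognormal"),
}


def reference_dataset(condition: str, stage: str, n: int, seed: int = 0) -> np.ndarray:
    """Draw a synthetic dataset for a named study condition and stage."""
    spec = REFERENCE_CONDITIONS[(condition, stage)]
    return make_titer_dataset(spec.median, spec.dispersion, n, spec.distribution, seed)


def make_ovariole_table(
    seed: int = 0,
    n_per_condition: int = 15,
    conditions: Sequence[str] = ("un-enriched", "yeast-enriched"),
    drift: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic per-ovariole titer table in the analysis CSV schema.

    Columns: ``ovariole, acquisition_order, condition, gsc_single,
    gsc_cluster_total, gsc_cluster_cells, stage4, stage10``.  ``drift`` maps
    a condition to a total multiplicative change applied linearly across
    acquisition order (e.g. 0.5 halves titers from first to last ovariole),
    emulating time-correlated intrusions into an imaging session.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    oid = 0
    for cond, child in zip(conditions, ss.spawn(len(conditions))):
        sub = child.spawn(5)
        rng = np.random.default_rng(sub[0])
        cond_key = cond if (cond, "gsc_single") in REFERENCE_CONDITIONS else "control"
        gsc = reference_dataset(cond_key, "gsc_single", n_per_condition,
                                int(sub[1].generate_state(1)[0] % 2**31))
        s4 = reference_dataset(cond_key, "stage4", n_per_condition,
                               int(sub[2].generate_state(1)[0] % 2**31))
        s10 = reference_dataset(cond_key, "stage10", n_per_condition,
                                int(sub[3].generate_state(1)[0] % 2**31))
        cell_spec = REFERENCE_CONDITIONS[("control", "gsc_cluster_cell")]
        n_cells = rng.integers(2, 5, size=n_per_condition)
        per_cell = make_titer_dataset(
            cell_spec.median, cell_spec.dispersion, n_per_condition,
            cell_spec.distribution, int(sub[4].generate_state(1)[0] % 2**31),
        )
        factor = np.ones(n_per_condition)
        if drift and cond in drift:
            total = drift[cond]
            factor = np.linspace(1.0, total, n_per_condition)
        for i in range(n_per_condition):
            oid += 1
            rows.append(
                {
                    "ovariole": f"ov{oid:03d}",
                    "acquisition_order": i + 1,
                    "condition": cond,
                    "gsc_single": gsc[i] * factor[i],
                    "gsc_cluster_total": per_cell[i] * n_cells[i] * factor[i],
                    "gsc_cluster_cells": int(n_cells[i]),
                    "stage4": s4[i] * factor[i],
                    "stage10": s10[i] * factor[i],
                }
            )
    return pd.DataFrame(rows)


def make_method_comparison(
    n: int = 60,
    r_squared: float = 0.854,
    mean_count: float = 400.0,
    sd_count: float = 120.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired manual/semi-automated recounts with a designed R-squared.

    The semi-automated count equals the manual count plus independent
    Gaussian scoring noise sized so the population R-squared of the
    auto-on-manual regression is ``r_squared``.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must be in (0, 1)")
    rng = np.random.default_rng(seed)
    manual = np.clip(rng.normal(mean_count, sd_count, size=n), 1.0, None)
    noise_sd = sd_count * math.sqrt(1.0 / r_squared - 1.0)
    auto = np.clip(manual + rng.normal(0.0, noise_sd, size=n), 0.0, None)
    return pd.DataFrame({"manual": manual, "auto": auto})
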