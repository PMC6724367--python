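"""Absolute qPCR quantification from plasmid standard curves.

Copy numbers are inferred by comparing threshold-cycle (Ct) values against a
standard curve fitted to a plasmid dilution series of known copy number:
``Ct = b + m * log10(copies)``, so ``copies = 10**((Ct - b) / m)``.  The
per-cycle amplification efficiency follows from the slope as
``E = 10**(-1/m) - 1`` (perfect doubling: m = -3.3219, E = 100%).

Relative titer (endosymbiont gene over a host reference gene, wsp/rpl32) is
provided for comparison but is only meaningful when host gene copy number is
stable across conditions — nurse-cell endoreplication violates that
assumption, which is exactly why absolute quantification is the primary
route here.

No-amplification wells carry an empty Ct (NaN in memory), never a fabricated
cycle number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import InsufficientDataError, InvalidCurveError, SchemaError, UndefinedRatioError

WELL_COLUMNS = ["plate", "well", "sample", "gene", "treatment", "replicate", "ct"]


@dataclass(frozen=True)
class DilutionPoint:
    """One point of the plasmid standard dilution series."""

    known_copies: float
    ct: float

    def __post_init__(self) -> None:
        if self.known_copies <= 0:
            raise ValueError("known_copies must be positive")
        if not math.isfinite(self.ct):
            raise ValueError("ct must be finite")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Ct-vs-log10(copies) line with derived efficiency."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise InvalidCurveError("standard curve slope must be negative")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


@dataclass
class QpcrWell:
    """One reaction well.  ``ct=None``/NaN is the no-amplification sentinel."""

    plate: str
    well: str
    sample: str
    gene: str
    ct: float | None
    treatment: str = ""
    replicate: int = 1
    flies_per_sample: int = 5

    @property
    def amplified(self) -> bool:
        return self.ct is not None and math.isfinite(self.ct)


@dataclass
class CopyEstimate:
    """Aggregated copies-per-reaction for one sample and gene."""

    sample: str
    gene: str
    copies_per_reaction: float
    replicate_copies: list[float] = field(default_factory=list)
    aggregation: str = "median"
    infected: bool = True
    n_sentinel: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_reaction < 0:
            raise ValueError("copies must be >= 0")
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")


def efficiency_from_slope(slope: float) -> float:
    """Per-cycle amplification efficiency implied by the Ct slope."""
    if slope >= 0:
        raise InvalidCurveError("efficiency undefined for non-negative slope")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(points: Iterable[DilutionPoint | tuple[float, float]],
                       qc_warn: bool = True) -> StandardCurve:
    """Least-squares fit of Ct on log10(known copies).

    Requires at least 3 points spanning at least 2 decades of copy number.
    A positive slope raises :class:`InvalidCurveError`.  Efficiency outside
    [0.9, 1.1] or R-squared below 0.98 triggers a QC warning.
    """
    pts = [p if isinstance(p, DilutionPoint) else DilutionPoint(*p) for p in points]
    if len(pts) < 3:
        raise InsufficientDataError("standard curve needs >= 3 dilution points")
    copies = np.array([p.known_copies for p in pts])
    cts = np.array([p.ct for p in pts])
    if copies.max() / copies.min() < 100:
        raise InsufficientDataError("dilution series must span >= 2 decades")
    fit = linregress(np.log10(copies), cts)
    if fit.slope >= 0:
        raise InvalidCurveError(
            f"fitted slope {fit.slope:.3f} is non-negative; Ct must fall "
            "with template abundance"
        )
    curve = StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=efficiency_from_slope(float(fit.slope)),
        n_points=len(pts),
    )
    if qc_warn:
        if not 0.9 <= curve.efficiency <= 1.1:
            warnings.warn(
                f"amplification efficiency {curve.efficiency:.2f} outside "
                "[0.90, 1.10]", stacklevel=2,
            )
        if curve.r_squared < 0.98:
            warnings.warn(
                f"standard curve R^2 = {curve.r_squared:.3f} < 0.98",
                stacklevel=2,
            )
    return curve


def ct_to_copies(curve: StandardCurve, ct: float | None) -> float:
    """Invert the standard curve; the sentinel (None/NaN) maps to 0 copies."""
    if ct is None or not math.isfinite(ct):
        return 0.0
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def fit_standard_curves(dilution: pd.DataFrame, qc_warn: bool = True) -> dict[str, StandardCurve]:
    """One curve per gene from a ``gene, known_copies, ct`` table."""
    required = {"gene", "known_copies", "ct"}
    if not required.issubset(dilution.columns):
        raise SchemaError(f"dilution table needs columns {sorted(required)}")
    return {
        gene: fit_standard_curve(
            list(zip(sub["known_copies"], sub["ct"])), qc_warn=qc_warn
        )
        for gene, sub in dilution.groupby("gene")
    }


def _well_cts(wells) -> tuple[str, str, list[float | None]]:
    """Validate a homogeneous group of wells; return sample, gene, cts."""
    if isinstance(wells, pd.DataFrame):
        missing = [c for c in ("sample", "gene", "ct") if c not in wells.columns]
        if missing:
            raise SchemaError(f"well table missing columns {missing}")
        recs = [
            QpcrWell(
                plate=str(r.get("plate", "")), well=str(r.get("well", "")),
                sample=str(r["sample"]), gene=str(r["gene"]),
                ct=None if pd.isna(r["ct"]) else float(r["ct"]),
                treatment=str(r.get("treatment", "")),
                replicate=int(r.get("replicate", 1)),
            )
            for _, r in wells.iterrows()
        ]
    else:
        recs = list(wells)
    if not recs:
        raise InsufficientDataError("no wells supplied")
    samples = {w.sample for w in recs}
    genes = {w.gene for w in recs}
    if len(samples) != 1 or len(genes) != 1:
        raise SchemaError(
            f"wells mix samples {sorted(samples)} / genes {sorted(genes)}"
        )
    return samples.pop(), genes.pop(), [w.ct for w in recs]


def summarize_sample(wells, curve: StandardCurve,
                     aggregation: str = "median") -> CopyEstimate:
    """Aggregate per-replicate copy estimates for one sample and gene.

    Sentinel (no-amplification) replicates are excluded from the aggregate
    and counted in ``n_sentinel``; an all-sentinel sample reports 0 copies
    with ``infected=False``.  Aggregation is the median of per-replicate
    copies by default (robust to a single outlier well) or the mean.
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    sample, gene, cts = _well_cts(wells)
    numeric = [ct for ct in cts if ct is not None and math.isfinite(ct)]
    n_sentinel = len(cts) - len(numeric)
    if not numeric:
        return CopyEstimate(sample, gene, 0.0, [], aggregation,
                            infected=False, n_sentinel=n_sentinel)
    reps = [ct_to_copies(curve, ct) for ct in numeric]
    agg = float(np.median(reps) if aggregation == "median" else np.mean(reps))
    return CopyEstimate(sample, gene, agg, reps, aggregation,
                        infected=True, n_sentinel=n_sentinel)


def quantify_plate(wells: pd.DataFrame, curves: dict[str, StandardCurve],
                   aggregation: str = "median") -> pd.DataFrame:
    """Copy estimates for every (sample, gene) on a plate.

    Each gene is quantified against its own standard curve (one curve per
    plate per gene).  Returns a table with columns ``sample, gene,
    treatment, copies_per_reaction, n_replicates, n_sentinel, infected``.
    """
    rows = []
    for (sample, gene), sub in wells.groupby(["sample", "gene"]):
        if gene not in curves:
            raise SchemaError(f"no standard curve supplied for gene {gene!r}")
        est = summarize_sample(sub, curves[gene], aggregation)
        treatment = sub["treatment"].iloc[0] if "treatment" in sub.columns else ""
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "treatment": treatment,
                "copies_per_reaction": est.copies_per_reaction,
                "n_replicates": len(est.replicate_copies),
                "n_sentinel": est.n_sentinel,
                "infected": est.infected,
            }
        )
    return pd.DataFrame(rows)


def relative_ratio(wsp: CopyEstimate, rpl32: CopyEstimate) -> float:
    """Endosymbiont/host copy ratio (e.g. wsp/rpl32) for one sample.

    A zero-copy denominator raises :class:`UndefinedRatioError` rather than
    returning a silent infinity.
    """
    if wsp.sample != rpl32.sample:
        raise SchemaError(
            f"ratio across different samples: {wsp.sample!r} vs {rpl32.sample!r}"
        )
    if rpl32.copies_per_reaction == 0:
        raise UndefinedRatioError(
            f"sample {wsp.sample!r}: reference gene has 0 copies"
        )
    return wsp.copies_per_reaction / rpl32.copies_per_reaction


def classify_infection(wells, max_cycle: float = 40.0) -> bool:
    """True iff any replicate amplifies below the max-cycle cutoff."""
    _, _, cts = _well_cts(wells)
    return any(
        ct is not None and math.isfinite(ct) and ct < max_cycle for ct in cts
    )


def extrapolate_source_copies(
    copies_per_reaction: float,
    template_volume_ul: float,
    extract_volume_ul: float,
    dilution_factor: float = 1.0,
    flies_per_sample: int = 5,
) -> float:
    """Back-extrapolate reaction copies to copies per source fly.

    ``copies/reaction x (extract volume / template volume) x dilution factor
    / flies per sample``.
    """
    for name, v in (
        ("template_volume_ul", template_volume_ul),
        ("extract_volume_ul", extract_volume_ul),
        ("dilution_factor", dilution_factor),
        ("flies_per_sample", flies_per_sample),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if copies_per_reaction < 0:
        raise ValueError("copies_per_reaction must be >= 0")
    return (
        copies_per_reaction
        * (extract_volume_ul / template_volume_ul)
        * dilution_factor
        / flies_per_sample
    )
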