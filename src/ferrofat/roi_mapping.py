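"""Aggregate per-ROI fits into organ-level measurements.

Pancreas: head/body/tail ROI fits are averaged (plain arithmetic mean of
T2* and of FF) into global values.  Heart: sixteen segmental T2* values
(AHA numbering — six basal, six mid, four apical) are averaged into a
global T2* and screened against the 20 ms conservative normal limit.
Liver: T2* is converted to liver iron concentration (LIC, mg Fe / g dry
weight) through a linear R2* calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relaxometry import FitResult

__all__ = [
    "RegionFit",
    "PancreasMeasurement",
    "CardiacT2StarMap",
    "LiverMeasurement",
    "aggregate_pancreas",
    "summarize_cardiac",
    "lic_from_t2star",
    "liver_measurement",
    "correct_susceptibility",
    "LIC_SLOPE_MG_G_PER_HZ",
    "LIC_INTERCEPT_MG_G",
    "HEART_SEGMENT_NORMAL_MS",
]

#: Default linear R2*->LIC calibration (mg/g dw per Hz, and intercept);
#: config-exposed because published calibrations vary slightly.
LIC_SLOPE_MG_G_PER_HZ = 0.0254
LIC_INTERCEPT_MG_G = 0.202

#: Conservative normal limit for segmental and global heart T2* (ms);
#: a segment is pathological when T2* <= this value.
HEART_SEGMENT_NORMAL_MS = 20.0

N_CARDIAC_SEGMENTS = 16


class MissingRegionError(ValueError):
    """A required ROI fit is absent or unusable; nothing is imputed."""


@dataclass(frozen=True)
class RegionFit:
    """Minimal per-region record: T2* (ms) and fat fraction (fraction)."""

    t2star_ms: float
    ff: float


@dataclass(frozen=True)
class PancreasMeasurement:
    """Regional and global pancreatic T2*/FF.  FF is reported in percent."""

    head: RegionFit
    body: RegionFit
    tail: RegionFit
    global_t2star_ms: float
    global_ff_pct: float


@dataclass(frozen=True)
class CardiacT2StarMap:
    """Sixteen segmental T2* values plus global mean and pathological count."""

    segments_ms: tuple[float, ...]
    global_t2star_ms: float
    n_pathological_segments: int


@dataclass(frozen=True)
class LiverMeasurement:
    t2star_ms: float
    lic_mg_g_dw: float


def _require_region(fit: FitResult | None, name: str) -> RegionFit:
    if fit is None:
        raise MissingRegionError(f"pancreatic {name} ROI fit is missing")
    if not fit.converged:
        raise MissingRegionError(f"pancreatic {name} ROI fit did not converge")
    if fit.at_bound:
        raise MissingRegionError(
            f"pancreatic {name} ROI fit is pinned at a T2* bound (degenerate data)"
        )
    if fit.ff is None:
        raise MissingRegionError(f"pancreatic {name} ROI fit carries no fat fraction")
    return RegionFit(t2star_ms=fit.t2star_ms, ff=fit.ff)


def aggregate_pancreas(
    head: FitResult | None, body: FitResult | None, tail: FitResult | None
) -> PancreasMeasurement:
    """Global pancreatic values as arithmetic means of the three regions.

    Every region must be a converged fat-water fit; a missing or
    non-converged region raises :class:`MissingRegionError` rather than
    being silently averaged over.
    """
    regions = {
        "head": _require_region(head, "head"),
        "body": _require_region(body, "body"),
        "tail": _require_region(tail, "tail"),
    }
    t2s = [r.t2star_ms for r in regions.values()]
    ff = [r.ff for r in regions.values()]
    return PancreasMeasurement(
        head=regions["head"],
        body=regions["body"],
        tail=regions["tail"],
        global_t2star_ms=float(np.mean(t2s)),
        global_ff_pct=float(np.mean(ff)) * 100.0,
    )


def summarize_cardiac(
    segment_values, pathological_threshold_ms: float = HEART_SEGMENT_NORMAL_MS
) -> CardiacT2StarMap:
    """Global heart T2* and pathological-segment count from 16 segments.

    Accepts 16 segmental T2* values (floats) or :class:`FitResult` objects
    in AHA order.  A segment is pathological when its T2* is at or below
    the conservative normal limit (default 20 ms).
    """
    values = [
        float(v.t2star_ms) if isinstance(v, FitResult) else float(v)
        for v in segment_values
    ]
    if len(values) != N_CARDIAC_SEGMENTS:
        raise ValueError(
            f"cardiac summary requires exactly {N_CARDIAC_SEGMENTS} segments, got {len(values)}"
        )
    arr = np.asarray(values, dtype=float)
    return CardiacT2StarMap(
        segments_ms=tuple(values),
        global_t2star_ms=float(arr.mean()),
        n_pathological_segments=int(np.sum(arr <= pathological_threshold_ms)),
    )


def lic_from_t2star(
    t2star_ms: float,
    slope_mg_g_per_hz: float = LIC_SLOPE_MG_G_PER_HZ,
    intercept_mg_g: float = LIC_INTERCEPT_MG_G,
) -> float:
    """Liver iron concentration (mg/g dw) from liver T2* (ms).

    Linear calibration on the relaxation rate: ``LIC = a * R2* + b`` with
    ``R2* = 1000 / T2*`` in Hz.  Strictly decreasing in T2*; the
    large-T2* asymptote is the intercept ``b``.
    """
    if t2star_ms <= 0:
        raise ValueError("T2* must be positive")
    r2s_hz = 1000.0 / t2star_ms
    return slope_mg_g_per_hz * r2s_hz + intercept_mg_g


def liver_measurement(t2star_ms: float, **calibration) -> LiverMeasurement:
    return LiverMeasurement(
        t2star_ms=float(t2star_ms), lic_mg_g_dw=lic_from_t2star(t2star_ms, **calibration)
    )


def correct_susceptibility(segments_ms, coefficients=None):
    """Hook for geometric susceptibility-artifact correction of segmental T2*.

    The published correction requires scanner- and slice-specific
    coefficients that are not redistributable; with ``coefficients=None``
    (the only supported value) this is a documented no-op returning the
    input unchanged.
    """
    if coefficients is not None:
        raise NotImplementedError(
            "susceptibility correction coefficients are not available; "
            "only the identity hook is provided"
        )
    return list(segments_ms)
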