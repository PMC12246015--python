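"""Mechanoregulation scoring of conformal surface fields.

The biophysical stimulus combines the solid and fluid cues at each surface
node,

    S = OSS / a + WSS / b,      a = 0.0375,  b = 10 mPa,

and is mapped to a predicted tissue phenotype by fixed intervals (upper
bounds inclusive):

    S <= 0.01        resorption / very low stimulus
    0.01 < S <= 1    bone differentiation
    1 < S <= 3       cartilage differentiation
    3 < S <= 6       fibrous tissue differentiation
    S > 6            very high stimulus (cell death)

The surface-average curve ``S_avg(t)`` uses the stimulus of the averages:
the arithmetic mean of OSS over all surface nodes and the area-weighted
mean of WSS.  Its two maxima, ``S_Max1`` on the compression half-cycle
[0, T/2) and ``S_Max2`` on the release half-cycle [T/2, T), locate the
reference time points; phenotype maps are evaluated at the ``S_Max2`` time
with per-node OSS and WSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .synthetic_fields import FieldSeries

__all__ = [
    "StimulusConstants",
    "Phenotype",
    "StimulusTimeSeries",
    "PhenotypeSummary",
    "ConformalityError",
    "stimulus",
    "classify",
    "classify_array",
    "match_nodes",
    "averaged_series",
    "find_smax",
    "phenotype_map",
    "phenotype_percentages",
    "compare_designs",
    "contribution_shares",
]


class ConformalityError(ValueError):
    """Solid and fluid node sets do not match."""


@dataclass(frozen=True)
class StimulusConstants:
    a: float = 0.0375  # strain scale, dimensionless
    b: float = 10.0  # stress scale, mPa

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("stimulus constants must be positive")


class Phenotype(str, Enum):
    VERY_LOW = "very_low"
    BONE = "bone"
    CARTILAGE = "cartilage"
    FIBROUS = "fibrous"
    VERY_HIGH = "very_high"


#: interval upper bounds, inclusive, in class order
_THRESHOLDS = (0.01, 1.0, 3.0, 6.0)
_CLASSES = tuple(Phenotype)


def stimulus(oss, wss, consts: StimulusConstants = StimulusConstants()):
    """Stimulus ``S = OSS/a + WSS/b``; accepts scalars or arrays."""
    oss = np.asarray(oss, dtype=float)
    wss = np.asarray(wss, dtype=float)
    if np.any(oss < 0) or np.any(wss < 0):
        raise ValueError("OSS and WSS must be non-negative")
    s = oss / consts.a + wss / consts.b
    return float(s) if s.ndim == 0 else s


def classify(s: float) -> Phenotype:
    """Phenotype class of one stimulus value (upper bounds inclusive)."""
    if not np.isfinite(s):
        raise ValueError(f"cannot classify non-finite stimulus {s!r}")
    for theta, cls in zip(_THRESHOLDS, _CLASSES):
        if s <= theta:
            return cls
    return Phenotype.VERY_HIGH


def classify_array(s: np.ndarray) -> np.ndarray:
    """Vectorized classification; returns an object array of Phenotype."""
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("cannot classify non-finite stimulus values")
    idx = np.searchsorted(np.asarray(_THRESHOLDS), s, side="left")
    out = np.empty(s.shape, dtype=object)
    classes = list(_CLASSES)
    for i in range(len(classes)):
        out[idx == i] = classes[i]
    return out


def match_nodes(
    fe_positions: np.ndarray,
    cfd_positions: np.ndarray,
    tolerance: float = 1e-6,
) -> np.ndarray:
    """Bijective index mapping pairing FE to CFD nodes within ``tolerance``.

    Returns ``mapping`` such that ``cfd_positions[mapping[i]]`` is the
    partner of ``fe_positions[i]``; the identity when the clouds coincide in
    order.  Unmatched or doubly-matched nodes raise
    :class:`ConformalityError` naming the offenders.
    """
    fe = np.asarray(fe_positions, dtype=float).reshape(-1, 3)
    cfd = np.asarray(cfd_positions, dtype=float).reshape(-1, 3)
    if len(fe) == 0 or len(cfd) == 0:
        raise ConformalityError("empty node set")
    if len(fe) != len(cfd):
        raise ConformalityError(
            f"node counts differ: {len(fe)} FE vs {len(cfd)} CFD"
        )
    dist, idx = cKDTree(cfd).query(fe)
    bad = np.nonzero(dist > tolerance)[0]
    if len(bad):
        raise ConformalityError(
            f"{len(bad)} FE node(s) without a CFD partner within "
            f"{tolerance} mm; first offenders: {bad[:5].tolist()}"
        )
    if len(np.unique(idx)) != len(idx):
        dup = np.nonzero(np.bincount(idx, minlength=len(cfd)) > 1)[0]
        raise ConformalityError(
            f"mapping is not bijective; CFD nodes matched twice: {dup[:5].tolist()}"
        )
    return idx


@dataclass(frozen=True)
class StimulusTimeSeries:
    times: np.ndarray  # s
    oss_avg: np.ndarray  # arithmetic mean over surface nodes
    wss_avg: np.ndarray  # area-weighted mean, mPa
    s_avg: np.ndarray  # stimulus of the averages
    consts: StimulusConstants = StimulusConstants()

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class PhenotypeSummary:
    """Surface-area percentage per phenotype class at one evaluation time."""

    design: str
    t_eval: float
    percentages: dict[Phenotype, float]

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"percentages sum to {total}, not 100")

    def __getitem__(self, cls: Phenotype) -> float:
        return self.percentages[cls]


def _require_conformal(strain: FieldSeries, wss: FieldSeries) -> None:
    if not np.array_equal(strain.mesh.node_ids, wss.mesh.node_ids):
        raise ConformalityError("strain and WSS series use different node sets")
    if not np.allclose(strain.mesh.areas, wss.mesh.areas):
        raise ConformalityError("strain and WSS series use different area weights")
    if strain.times.shape != wss.times.shape or not np.allclose(
        strain.times, wss.times
    ):
        raise ValueError("strain and WSS series use different time grids")


def averaged_series(
    strain: FieldSeries,
    wss: FieldSeries,
    consts: StimulusConstants = StimulusConstants(),
) -> StimulusTimeSeries:
    """Surface-average curves: arithmetic-mean OSS, area-weighted WSS, and
    the stimulus of the two averages at every time."""
    _require_conformal(strain, wss)
    oss_avg = strain.mean_series(area_weighted=False)
    wss_avg = wss.mean_series(area_weighted=True)
    return StimulusTimeSeries(
        times=strain.times.copy(),
        oss_avg=oss_avg,
        wss_avg=wss_avg,
        s_avg=oss_avg / consts.a + wss_avg / consts.b,
        consts=consts,
    )


def find_smax(series: StimulusTimeSeries) -> tuple[tuple[float, float], tuple[float, float]]:
    """``((S_Max1, t1), (S_Max2, t2))``: maxima of ``S_avg`` on the
    compression half-cycle [0, T/2) and the release half-cycle [T/2, T).

    Ties are broken toward the later time so a time-symmetric cycle still
    yields its second maximum in the release phase.
    """
    t = series.times - series.times[0]
    period = series.period
    if period <= 0 or len(t) < 3:
        raise ValueError("series does not span a full loading cycle")
    half = 0.5 * period
    out = []
    for lo, hi in ((0.0, half), (half, period)):
        sel = np.nonzero((t >= lo - 1e-12) & (t < hi - 1e-12))[0]
        if len(sel) == 0:
            raise ValueError("half-cycle window contains no samples")
        vals = series.s_avg[sel]
        best = sel[len(vals) - 1 - int(np.argmax(vals[::-1]))]  # last argmax
        out.append((float(series.s_avg[best]), float(series.times[best])))
    return out[0], out[1]


def _time_index(times: np.ndarray, t_eval: float) -> int:
    i = int(np.argmin(np.abs(times - t_eval)))
    if abs(times[i] - t_eval) > 1e-9:
        raise ValueError(f"t_eval={t_eval} s is not a sample time of the series")
    return i


def phenotype_map(
    strain: FieldSeries,
    wss: FieldSeries,
    t_eval: float,
    consts: StimulusConstants = StimulusConstants(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node stimulus and phenotype at ``t_eval``.

    Returns ``(S, classes)`` with ``classes`` an object array of
    :class:`Phenotype`.
    """
    _require_conformal(strain, wss)
    i = _time_index(strain.times, t_eval)
    s = stimulus(strain.values[i], wss.values[i], consts)
    return s, classify_array(s)


def phenotype_percentages(
    classes: np.ndarray,
    areas: np.ndarray,
    design: str = "",
    t_eval: float = float("nan"),
) -> PhenotypeSummary:
    """Surface-area percentage per phenotype class."""
    classes = np.asarray(classes, dtype=object)
    areas = np.asarray(areas, dtype=float)
    if classes.shape != areas.shape:
        raise ValueError("class map and area weights differ in length")
    total = areas.sum()
    values = np.array([c.value for c in classes.ravel()]).reshape(classes.shape)
    pct = {
        cls: float(100.0 * areas[values == cls.value].sum() / total)
        for cls in Phenotype
    }
    return PhenotypeSummary(design=design, t_eval=t_eval, percentages=pct)


def compare_designs(
    summary: PhenotypeSummary, reference: PhenotypeSummary
) -> dict[Phenotype, float]:
    """Per-class percentage-point change of ``summary`` vs ``reference``."""
    return {
        cls: summary.percentages[cls] - reference.percentages[cls]
        for cls in Phenotype
    }


def contribution_shares(
    oss_avg: float, wss_avg: float, consts: StimulusConstants = StimulusConstants()
) -> tuple[float, float]:
    """Percentage shares of the solid and fluid terms in the stimulus."""
    s = stimulus(oss_avg, wss_avg, consts)
    if s == 0:
        raise ZeroDivisionError("stimulus is zero; shares are undefined")
    return (
        100.0 * (oss_avg / consts.a) / s,
        100.0 * (wss_avg / consts.b) / s,
    )
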