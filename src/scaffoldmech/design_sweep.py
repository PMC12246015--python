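"""Two-step scaffold modification strategy and pipeline orchestration.

Step 1 varies the number of strands per horizontal layer (``N_H``) at fixed
strand diameter, layer count and spans, which sweeps the horizontal span
``Y`` and with it the porosity.  Step 2 takes the step-1 selection and
rescales the whole lattice at fixed envelope and (near-)fixed porosity:
the span-to-diameter ratios ``x1 = h / D_strand`` and ``x2 = Y / D_strand``
are frozen, the layer count ``N_V`` is varied with ``N_H = N_V`` (the
constant ``x3`` role), and the strand diameter follows from the vertical
fit ``H = N_V * x1 * D_strand``.  Applying step 2 with the base layer count
reproduces the base design exactly.

``run_sweep`` executes the full pipeline per design (layout, porosity,
synthetic field cycle, surface-average stimulus, ``S_Max2`` phenotype map)
and ``select_best`` applies the improvement criterion with the
one-percentage-point stopping rule.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    PoreMetrics,
    ScaffoldSpec,
    build_layout,
    pore_equivalent_diameter,
    porosity as compute_porosity,
)
from .mechanics import LoadingProtocol
from .mechanoreg import (
    Phenotype,
    PhenotypeSummary,
    StimulusConstants,
    averaged_series,
    compare_designs,
    contribution_shares,
    find_smax,
    phenotype_map,
    phenotype_percentages,
)
from .synthetic_fields import FluidProperties, SurrogateParams, generate_cycle

__all__ = [
    "ScalingRatios",
    "DesignResult",
    "SweepReport",
    "step1_designs",
    "step2_designs",
    "enumerate_full_factorial",
    "run_sweep",
    "select_best",
]

log = logging.getLogger(__name__)

#: feasible strand diameters for direct ink writing, mm
DIW_BOUNDS_MM = (0.5, 0.8)


@dataclass(frozen=True)
class ScalingRatios:
    """Span-to-diameter ratios frozen from a base design for step 2."""

    h_to_Dstrand: float
    Y_to_Dstrand: float
    NH_equals_NV: bool = True

    def __post_init__(self) -> None:
        if self.h_to_Dstrand <= 0 or self.Y_to_Dstrand <= 0:
            raise ValueError("scaling ratios must be positive")

    @classmethod
    def from_spec(cls, spec: ScaffoldSpec) -> "ScalingRatios":
        return cls(
            h_to_Dstrand=spec.h / spec.D_strand,
            Y_to_Dstrand=spec.Y / spec.D_strand,
        )


def step1_designs(
    base: ScaffoldSpec, nh_range: range | list[int] = range(6, 11)
) -> list[ScaffoldSpec]:
    """Step-1 family: vary ``N_H`` at fixed ``N_V``, ``D_strand`` and ``h``.

    ``Y`` is recomputed per the span convention for each ``N_H``; names
    follow ``S1-H{N_H}-V{N_V}``.
    """
    designs = []
    for nh in nh_range:
        if nh < 2:
            raise ValueError("N_H must be at least 2")
        designs.append(
            replace(base, name=f"S1-H{nh}-V{base.N_V}", N_H=nh, Y=None, h=base.h)
        )
    return designs


def step2_designs(
    base: ScaffoldSpec,
    nv_set: tuple[int, ...] | None = None,
    diw_bounds: tuple[float, float] = DIW_BOUNDS_MM,
    exclude_unmanufacturable: bool = True,
) -> list[ScaffoldSpec]:
    """Step-2 family: porosity-preserving rescaling of ``base``.

    For each ``N_V`` the strand diameter solves the vertical fit
    ``H_scaffold = N_V * x1 * D_strand`` with ``x1`` frozen from the base;
    ``h`` and ``Y`` follow from the frozen ratios and ``N_H = N_V``.
    Variants whose strand diameter falls outside the printable bounds are
    excluded with a log message (or kept when
    ``exclude_unmanufacturable=False``).
    """
    if nv_set is None:
        nv_set = (base.N_V - 1, base.N_V + 1, base.N_V + 2)
    ratios = ScalingRatios.from_spec(base)
    designs = []
    for nv in nv_set:
        d_strand = base.H_scaffold / (nv * ratios.h_to_Dstrand)
        spec = ScaffoldSpec(
            name=f"S2-H{nv}-V{nv}",
            D_scaffold=base.D_scaffold,
            H_scaffold=base.H_scaffold,
            D_strand=d_strand,
            N_H=nv,
            N_V=nv,
            Y=ratios.Y_to_Dstrand * d_strand,
            h=ratios.h_to_Dstrand * d_strand,
        )
        lo, hi = diw_bounds
        if not lo <= d_strand <= hi:
            log.warning(
                "design %s excluded: D_strand=%.0f um outside printable %0.f-%0.f um",
                spec.name, d_strand * 1000, lo * 1000, hi * 1000,
            )
            if exclude_unmanufacturable:
                continue
        designs.append(spec)
    return designs


def enumerate_full_factorial(
    step1: list[ScaffoldSpec], nv_offsets: tuple[int, ...] = (-1, 1, 2)
) -> list[ScaffoldSpec]:
    """Apply the step-2 variant rule to every step-1 design.

    Returns the full design list (manufacturability not enforced, matching
    the combinatorial count of the two-step strategy had it been run as a
    full factorial).
    """
    out = []
    for base in step1:
        nv_set = tuple(base.N_V + o for o in nv_offsets)
        variants = step2_designs(base, nv_set, exclude_unmanufacturable=False)
        out.extend(
            replace(v, name=f"{v.name}-of-{base.name}") for v in variants
        )
    return out


@dataclass(frozen=True)
class DesignResult:
    spec: ScaffoldSpec
    pore: PoreMetrics
    peak_oss_avg: float
    peak_wss_avg: float  # mPa
    s_max1: tuple[float, float]  # (value, time s)
    s_max2: tuple[float, float]
    oss_share_pct: float  # at the S_Max2 time
    wss_share_pct: float
    summary: PhenotypeSummary
    deltas: dict[Phenotype, float] = field(default_factory=dict)
    failed: str | None = None


@dataclass(frozen=True)
class SweepReport:
    results: list[DesignResult]
    reference: str
    selected: str
    stopping_trace: list[str]

    def result(self, name: str) -> DesignResult:
        for r in self.results:
            if r.spec.name == name:
                return r
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "selected": self.selected,
            "stopping_trace": self.stopping_trace,
            "designs": [
                {
                    "name": r.spec.name,
                    "N_H": r.spec.N_H,
                    "N_V": r.spec.N_V,
                    "D_strand_um": r.spec.D_strand * 1000,
                    "Y_mm": r.spec.Y,
                    "h_mm": r.spec.h,
                    "porosity_pct": r.pore.porosity * 100,
                    "D_pore_um": r.pore.D_pore,
                    "peak_oss_avg": r.peak_oss_avg,
                    "peak_wss_avg_mpa": r.peak_wss_avg,
                    "s_max1": list(r.s_max1),
                    "s_max2": list(r.s_max2),
                    "oss_share_pct": r.oss_share_pct,
                    "wss_share_pct": r.wss_share_pct,
                    "phenotype_pct": {
                        c.value: p for c, p in r.summary.percentages.items()
                    },
                    "deltas_pct": {c.value: d for c, d in r.deltas.items()},
                    "failed": r.failed,
                }
                for r in self.results
            ],
        }

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return str(path)


def _evaluate_design(
    spec: ScaffoldSpec,
    protocol: LoadingProtocol,
    fluid: FluidProperties,
    params: SurrogateParams,
    consts: StimulusConstants,
    n_nodes: int,
    resolution: float,
    seed: int,
) -> DesignResult:
    layout = build_layout(spec)
    pore = compute_porosity(layout, resolution=resolution, seed=seed)
    design_params = replace(params, seed=seed)
    proto = replace(protocol, scaffold_height=spec.H_scaffold)
    oss_s, wss_s = generate_cycle(
        spec, proto, fluid, design_params,
        n_nodes=n_nodes, layout=layout, design_porosity=pore.porosity,
    )
    series = averaged_series(oss_s, wss_s, consts)
    smax1, smax2 = find_smax(series)
    i2 = int(np.argmin(np.abs(series.times - smax2[1])))
    oss_share, wss_share = contribution_shares(
        series.oss_avg[i2], series.wss_avg[i2], consts
    )
    _, classes = phenotype_map(oss_s, wss_s, smax2[1], consts)
    summary = phenotype_percentages(
        classes, oss_s.mesh.areas, design=spec.name, t_eval=smax2[1]
    )
    return DesignResult(
        spec=spec,
        pore=pore,
        peak_oss_avg=float(series.oss_avg.max()),
        peak_wss_avg=float(series.wss_avg.max()),
        s_max1=smax1,
        s_max2=smax2,
        oss_share_pct=oss_share,
        wss_share_pct=wss_share,
        summary=summary,
    )


def run_sweep(
    designs: list[ScaffoldSpec],
    protocol: LoadingProtocol | None = None,
    fluid: FluidProperties | None = None,
    params: SurrogateParams | None = None,
    consts: StimulusConstants | None = None,
    reference: str | None = None,
    seed: int = 0,
    n_nodes: int = 10_000,
    resolution: float = 0.025,
    criterion: Phenotype = Phenotype.CARTILAGE,
    stop_threshold: float = 1.0,
) -> SweepReport:
    """Run the full pipeline over ``designs`` and select the best one.

    Each design gets a deterministic seed derived from ``seed`` and its
    name, so reports are reproducible and independent of design order.  A
    design that fails in any stage is marked failed and the sweep continues.
    """
    if not designs:
        raise ValueError("no designs to sweep")
    protocol = protocol or LoadingProtocol()
    fluid = fluid or FluidProperties()
    params = params or SurrogateParams()
    consts = consts or StimulusConstants()
    reference = reference or designs[0].name
    results: list[DesignResult] = []
    for spec in designs:
        name_digest = int.from_bytes(spec.name.encode()[-4:], "little")
        design_seed = int(
            np.random.SeedSequence([seed, name_digest]).generate_state(1)[0]
            % (2**31)
        )
        try:
            results.append(
                _evaluate_design(
                    spec, protocol, fluid, params, consts,
                    n_nodes, resolution, design_seed,
                )
            )
        except Exception as exc:  # noqa: BLE001 - failed designs are reported
            log.error("design %s failed: %s", spec.name, exc)
            empty = PhenotypeSummary(
                spec.name, float("nan"), {c: (100.0 if i == 0 else 0.0)
                                          for i, c in enumerate(Phenotype)},
            )
            results.append(
                DesignResult(
                    spec=spec,
                    pore=PoreMetrics(1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
                    peak_oss_avg=float("nan"), peak_wss_avg=float("nan"),
                    s_max1=(math.nan, math.nan), s_max2=(math.nan, math.nan),
                    oss_share_pct=math.nan, wss_share_pct=math.nan,
                    summary=empty, failed=str(exc),
                )
            )
    ref_result = next((r for r in results if r.spec.name == reference), None)
    if ref_result is None:
        raise ValueError(f"reference design {reference!r} not in sweep")
    results = [
        replace(r, deltas=compare_designs(r.summary, ref_result.summary))
        if r.failed is None else r
        for r in results
    ]
    selected, trace = select_best(
        [r for r in results if r.failed is None],
        criterion=criterion,
        stop_threshold=stop_threshold,
    )
    return SweepReport(
        results=results,
        reference=reference,
        selected=selected.spec.name,
        stopping_trace=trace,
    )


def select_best(
    results: list[DesignResult],
    criterion: Phenotype = Phenotype.CARTILAGE,
    stop_threshold: float = 1.0,
) -> tuple[DesignResult, list[str]]:
    """Sequential selection with the < 1 percentage-point stopping rule.

    Walking the results in order, a candidate replaces the incumbent only
    when it improves the criterion by at least ``stop_threshold`` points;
    an improvement below the threshold keeps the earlier (simpler) design
    and records the stopping decision.  For a strictly improving sequence
    this returns the last design; exact ties keep the design with fewer
    layers.
    """
    if not results:
        raise ValueError("empty report")
    best = results[0]
    trace = [f"start with {best.spec.name} ({best.summary[criterion]:.2f}%)"]
    for cand in results[1:]:
        gain = cand.summary[criterion] - best.summary[criterion]
        if gain >= stop_threshold:
            trace.append(
                f"{cand.spec.name} improves {criterion.value} by "
                f"{gain:.2f} points: selected"
            )
            best = cand
        elif gain > 0:
            trace.append(
                f"{cand.spec.name} improves by only {gain:.2f} points "
                f"(< {stop_threshold:g}): stopped, keeping {best.spec.name}"
            )
        else:
            trace.append(
                f"{cand.spec.name} does not improve ({gain:.2f} points): "
                f"keeping {best.spec.name}"
            )
    return best, trace
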