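"""Synthetic pullback cohorts with known functional-pattern ground truth.

The study's per-vessel traces are not publicly deposited, so this module
generates pullback traces whose statistical structure matches the published
cohort: vessels ~65 mm long with distal pre-PCI QFR around 0.74, a pattern
mix of 43/17/12/28 % (focal / serial / diffuse / combination), focal lesions
as logistic step-downs with a ~2 mm transition and diffuse disease as linear
ramps gentle enough that no 10-mm window loses 0.05 (otherwise the archetype
would not be diffuse by the qualitative rules).

PCI is simulated mechanistically: a stent removes the drop of every focal
component whose core it covers; a partially covered diffuse component keeps
a residual drop proportional to its uncovered length; a small in-stent
gradient is added per stent.  Stenting a portion of a diffuse area therefore
raises the residual QFR but often not enough — the mechanism behind the
published association between diffuse disease and suboptimal PCI
(post-PCI QFR ≤ 0.89).  No pressure-flow physics is modelled and the
outcome model is not fitted to the clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import GenerationError, InvalidParameterError
from .patterns import COMBINATION, DIFFUSE, FOCAL, PATTERNS, SERIAL
from .trace import POST_PCI, PRE_PCI, PullbackTrace

#: Default pattern mix (focal, serial, diffuse, combination), the published
#: cohort proportions 51/20/15/34 of 120.
DEFAULT_PATTERN_MIX: dict[str, float] = {
    FOCAL: 0.43,
    SERIAL: 0.17,
    DIFFUSE: 0.12,
    COMBINATION: 0.28,
}

STENT_FOCAL = "stent-focal-components"
STENT_MAX_DROP = "stent-max-drop-segment"

# Diffuse ramps steeper than this would lose ≥0.05 over some 10-mm window
# and stop being diffuse by the qualitative rules; kept well below 0.005 so
# trace noise cannot push a 10-mm window over the focal threshold either.
_DIFFUSE_SLOPE_RANGE = (0.0028, 0.0038)
_DIFFUSE_SLOPE_CAP = 0.0040


@dataclass(frozen=True)
class LesionComponent:
    """One generating lesion: a logistic focal step or a linear diffuse ramp.

    ``total_drop`` is the QFR lost across the component; for focal
    components ``center_mm``/``width_mm`` parameterise the logistic
    transition, with ``[start_mm, end_mm)`` a nominal ±5 mm extent.
    """

    kind: str  # "focal" | "diffuse"
    start_mm: float
    end_mm: float
    total_drop: float
    center_mm: float | None = None
    width_mm: float = 2.0

    def __post_init__(self):
        if self.total_drop <= 0:
            raise GenerationError("component total_drop must be positive")
        if self.end_mm <= self.start_mm:
            raise GenerationError("component extent must be non-empty")

    @property
    def length_mm(self) -> float:
        return self.end_mm - self.start_mm

    def cumulative_drop(self, x: np.ndarray) -> np.ndarray:
        """QFR lost proximal-to-``x`` attributable to this component."""
        if self.kind == "focal":
            s = self.width_mm / 5.0
            return self.total_drop * expit((x - self.center_mm) / s)
        frac = np.clip((x - self.start_mm) / self.length_mm, 0.0, 1.0)
        return self.total_drop * frac


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for a synthetic cohort.

    Defaults emulate the published cohort: 120 vessels in ~111 patients
    (about 8 % of patients contribute two vessels), total vessel length
    55–80 mm (median ≈65), distal pre-PCI QFR targeted at 0.70–0.77,
    additive Gaussian trace noise with σ = 0.005 QFR units.
    """

    seed: int
    n_vessels: int = 120
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MIX)
    )
    tvl_range_mm: tuple[float, float] = (55.0, 80.0)
    distal_qfr_range: tuple[float, float] = (0.70, 0.77)
    noise_sd: float = 0.005
    step_mm: float = 0.5
    multi_vessel_fraction: float = 0.08
    stent_strategy: str = STENT_FOCAL
    max_stent_mm: float = 40.0
    instent_loss_max: float = 0.012

    def __post_init__(self):
        if self.n_vessels < 1:
            raise InvalidParameterError("n_vessels must be ≥ 1")
        if set(self.pattern_mix) != set(PATTERNS):
            raise InvalidParameterError(f"pattern_mix must cover {PATTERNS}")
        if any(v < 0 for v in self.pattern_mix.values()):
            raise InvalidParameterError("pattern_mix probabilities must be ≥ 0")
        if abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise InvalidParameterError("pattern_mix must sum to 1")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be ≥ 0")
        if self.max_stent_mm <= 0:
            raise InvalidParameterError("max_stent_mm must be positive")
        if self.stent_strategy not in (STENT_FOCAL, STENT_MAX_DROP):
            raise InvalidParameterError(f"unknown stent strategy {self.stent_strategy!r}")


@dataclass
class SyntheticVessel:
    """A generated vessel: pre-PCI trace, ground truth, and (after
    :func:`simulate_pci`) the post-PCI trace and outcome."""

    vessel_id: str
    patient_id: str
    true_pattern: str
    ostial_qfr: float
    tvl_mm: float
    components: list[LesionComponent]
    trace_pre: PullbackTrace
    trace_post: PullbackTrace | None = None
    post_qfr: float | None = None
    stented_intervals: list[tuple[float, float]] = field(default_factory=list)


def _build_trace(
    vessel_id: str,
    phase: str,
    q0: float,
    tvl: float,
    components: list[LesionComponent],
    step_mm: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> PullbackTrace:
    n = int(round(tvl / step_mm))
    pos = np.arange(n + 1) * step_mm
    pos[-1] = tvl
    q = np.full(pos.shape, q0, dtype=float)
    for comp in components:
        q -= comp.cumulative_drop(pos)
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd, size=pos.shape)
    q = np.clip(q, 0.01, 1.05)
    return PullbackTrace(vessel_id=vessel_id, positions_mm=pos, qfr=q, phase=phase)


def _make_components(
    pattern: str, tvl: float, q0: float, spec: CohortSpec, rng: np.random.Generator
) -> list[LesionComponent]:
    lo, hi = spec.distal_qfr_range

    def focal_comp(center: float, drop: float) -> LesionComponent:
        width = rng.uniform(1.5, 3.0)
        return LesionComponent(
            kind="focal",
            start_mm=max(0.0, center - 5.0),
            end_mm=min(tvl, center + 5.0),
            total_drop=drop,
            center_mm=center,
            width_mm=width,
        )

    if pattern == FOCAL:
        target = rng.uniform(max(lo, 0.72), hi + 0.01)
        drop = q0 - target
        center = rng.uniform(12.0, tvl - 10.0)
        return [focal_comp(center, drop)]

    if pattern == SERIAL:
        target = rng.uniform(lo - 0.02, hi - 0.02)
        total = q0 - target
        n = 3 if (tvl >= 64.0 and total >= 0.24 and rng.uniform() < 0.4) else 2
        c1 = rng.uniform(9.0, 13.0)
        max_spacing = (tvl - 8.0 - c1) / (n - 1)
        if max_spacing < 20.0:
            n = 2
            max_spacing = tvl - 8.0 - c1
        spacings = rng.uniform(20.0, max(20.0, min(max_spacing, 28.0)), size=n - 1)
        centers = c1 + np.concatenate([[0.0], np.cumsum(spacings)])
        w = rng.dirichlet(np.full(n, 3.0))
        drops = 0.07 + w * (total - 0.07 * n)
        if np.any(drops < 0.05):
            raise GenerationError("serial lesion drops below the focal threshold")
        return [focal_comp(c, d) for c, d in zip(centers, drops)]

    if pattern == DIFFUSE:
        a = rng.uniform(5.0, 9.0)
        length = tvl - a - rng.uniform(5.0, 9.0)
        slope = rng.uniform(*_DIFFUSE_SLOPE_RANGE)
        drop = slope * length
        return [
            LesionComponent(kind="diffuse", start_mm=a, end_mm=a + length, total_drop=drop)
        ]

    if pattern == COMBINATION:
        target = rng.uniform(lo, hi - 0.02)
        total = q0 - target
        slope = rng.uniform(*_DIFFUSE_SLOPE_RANGE)
        d_diffuse = rng.uniform(0.072, min(0.18, total - 0.07))
        l_diffuse = d_diffuse / slope
        l_cap = tvl - 35.0  # leaves room for the focal lesion and both margins
        if l_diffuse > l_cap:
            slope_needed = d_diffuse / l_cap
            if slope_needed > _DIFFUSE_SLOPE_CAP:
                d_diffuse = _DIFFUSE_SLOPE_CAP * l_cap
                slope_needed = _DIFFUSE_SLOPE_CAP
            slope = slope_needed
            l_diffuse = d_diffuse / slope
        d_focal = max(total - d_diffuse, 0.07)
        gap = rng.uniform(8.0, 12.0)
        if rng.uniform() < 0.5:  # focal proximal, ramp distal
            center = rng.uniform(10.0, 14.0)
            ramp_start = center + 5.0 + gap
        else:  # ramp proximal, focal distal
            ramp_start = rng.uniform(5.0, 8.0)
            center = ramp_start + l_diffuse + gap + 5.0
        ramp = LesionComponent(
            kind="diffuse",
            start_mm=ramp_start,
            end_mm=ramp_start + l_diffuse,
            total_drop=d_diffuse,
        )
        if center + 8.0 > tvl or ramp.end_mm > tvl - 4.0:
            raise GenerationError("combination layout does not fit the vessel")
        return sorted([ramp, focal_comp(center, d_focal)], key=lambda c: c.start_mm)

    raise InvalidParameterError(f"unknown pattern {pattern!r}")


def _sample_tvl(pattern: str, spec: CohortSpec, rng: np.random.Generator) -> float:
    lo, hi = spec.tvl_range_mm
    if pattern == DIFFUSE:
        # a gentle ramp deep enough to matter needs room; diffuse vessels in
        # the published cohort are also slightly longer (67 [62-70] mm)
        lo = max(lo, 65.0)
    return rng.uniform(lo, hi)


def generate_vessel(
    pattern: str,
    spec: CohortSpec,
    seed: int,
    vessel_id: str = "V0001",
    patient_id: str = "P0001",
) -> SyntheticVessel:
    """Generate one vessel of the requested pattern.

    The zero-noise trace satisfies the generating pattern's qualitative
    rules by construction; the distal pre-PCI QFR lands in (or, for pure
    diffuse disease, just above) the cohort spec's target range.
    """
    if pattern not in PATTERNS:
        raise InvalidParameterError(f"pattern must be one of {PATTERNS}")
    rng = np.random.default_rng(seed)
    q0 = rng.uniform(0.97, 1.0)
    tvl = _sample_tvl(pattern, spec, rng)
    components = _make_components(pattern, tvl, q0, spec, rng)
    total_drop = sum(c.total_drop for c in components)
    if q0 - total_drop < 0.55:
        raise GenerationError("requested drops exceed the minimum distal QFR")
    trace_pre = _build_trace(
        vessel_id, PRE_PCI, q0, tvl, components, spec.step_mm, spec.noise_sd, rng
    )
    return SyntheticVessel(
        vessel_id=vessel_id,
        patient_id=patient_id,
        true_pattern=pattern,
        ostial_qfr=q0,
        tvl_mm=tvl,
        components=components,
        trace_pre=trace_pre,
    )


# ---------------------------------------------------------------------------
# PCI simulation
# ---------------------------------------------------------------------------

def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def _core(comp: LesionComponent) -> tuple[float, float]:
    """The steep core of a focal component (must be covered to abolish it)."""
    return comp.center_mm - comp.width_mm, comp.center_mm + comp.width_mm


def residual_components(
    components: list[LesionComponent],
    stents: list[tuple[float, float]],
) -> list[LesionComponent]:
    """Deterministic stent bookkeeping.

    A focal component is abolished iff its core lies inside a stented
    interval, otherwise it persists unchanged (an untreated lesion).  A
    diffuse component keeps a drop proportional to its uncovered length,
    redistributed over the uncovered sub-intervals.
    """
    out: list[LesionComponent] = []
    for comp in components:
        if comp.kind == "focal":
            cs, ce = _core(comp)
            covered = any(s <= cs and ce <= e for s, e in stents)
            if not covered:
                out.append(comp)
            continue
        pieces = [(comp.start_mm, comp.end_mm)]
        for s, e in stents:
            nxt = []
            for ps, pe in pieces:
                if e <= ps or s >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < s:
                    nxt.append((ps, s))
                if e < pe:
                    nxt.append((e, pe))
            pieces = nxt
        uncovered = sum(pe - ps for ps, pe in pieces)
        if uncovered <= 1e-9:
            continue
        per_mm = comp.total_drop / comp.length_mm
        for ps, pe in pieces:
            out.append(
                LesionComponent(
                    kind="diffuse", start_mm=ps, end_mm=pe,
                    total_drop=per_mm * (pe - ps),
                )
            )
    return out


def _plan_stents(
    vessel: SyntheticVessel,
    strategy: str,
    max_stent_mm: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    tvl = vessel.tvl_mm
    stents: list[tuple[float, float]] = []

    if strategy == STENT_MAX_DROP:
        from .metrics import max_drop_over_window
        from .trace import preprocess_trace

        t = preprocess_trace(vessel.trace_pre)
        _, start = max_drop_over_window(t)
        length = min(rng.uniform(0.65, 1.0) * max_stent_mm, tvl)
        center = min(max(start + 10.0, length / 2), tvl - length / 2)
        return [(center - length / 2, center + length / 2)]

    # every focal lesion gets its own stent while the total stays under the
    # cap (largest drops first); a lesion beyond the cap is left untreated
    used = 0.0
    focal = sorted(
        (c for c in vessel.components if c.kind == "focal"),
        key=lambda c: -c.total_drop,
    )
    for comp in focal:
        length = min(2 * comp.width_mm + rng.uniform(10.0, 14.0), max_stent_mm)
        if used + length > max_stent_mm + 1e-9:
            continue  # total stent cap reached: lesion left untreated
        lo = max(0.0, comp.center_mm - length / 2)
        stents.append((lo, min(tvl, lo + length)))
        used += length
    # the remaining cap covers the most diseased diffuse area from its
    # proximal end; coverage is partial when the area outruns the cap
    diffuse = sorted(
        (c for c in vessel.components if c.kind == "diffuse"),
        key=lambda c: -c.total_drop,
    )
    for comp in diffuse:
        remaining = max_stent_mm - used
        if remaining < 8.0:
            break
        cover = min(rng.uniform(0.65, 1.0) * remaining, comp.length_mm)
        if cover < 8.0:
            continue
        stents.append((comp.start_mm, comp.start_mm + cover))
        used += cover
    if not stents:  # PCI always implants at least one stent
        length = min(max_stent_mm, 18.0, tvl)
        stents.append((0.0, length))
    return stents


def simulate_pci(
    vessel: SyntheticVessel,
    spec: CohortSpec,
    seed: int,
    strategy: str | None = None,
    max_stent_mm: float | None = None,
) -> SyntheticVessel:
    """Simulate stenting and rebuild the post-PCI trace.

    Returns a new :class:`SyntheticVessel` with ``trace_post``, ``post_qfr``
    and ``stented_intervals`` filled in.  Fully covered focal drops vanish;
    partially covered diffuse gradients persist proportionally; each stent
    adds a small in-stent gradient (uniform on ``[0, instent_loss_max]``).
    """
    strategy = strategy or spec.stent_strategy
    max_stent = max_stent_mm if max_stent_mm is not None else spec.max_stent_mm
    if max_stent <= 0:
        raise InvalidParameterError("max_stent_mm must be positive")
    if not vessel.components:
        raise InvalidParameterError("vessel has no lesion components")
    rng = np.random.default_rng(seed)
    stents = _plan_stents(vessel, strategy, max_stent, rng)
    residual = residual_components(vessel.components, stents)
    for s, e in stents:
        loss = rng.uniform(0.0, spec.instent_loss_max)
        if loss > 1e-6:
            residual.append(
                LesionComponent(kind="diffuse", start_mm=s, end_mm=e, total_drop=loss)
            )
    trace_post = _build_trace(
        vessel.vessel_id, POST_PCI, vessel.ostial_qfr, vessel.tvl_mm,
        residual, spec.step_mm, spec.noise_sd, rng,
    )
    return replace_vessel(
        vessel,
        trace_post=trace_post,
        post_qfr=trace_post.distal_qfr,
        stented_intervals=[(float(s), float(e)) for s, e in stents],
    )


def replace_vessel(vessel: SyntheticVessel, **changes) -> SyntheticVessel:
    return replace(vessel, **changes)


def generate_cohort(spec: CohortSpec) -> list[SyntheticVessel]:
    """Generate a full cohort: draw patterns from the mix, generate each
    vessel, and pass every vessel through :func:`simulate_pci`.

    About ``multi_vessel_fraction`` of patients contribute two vessels
    (emulating 120 vessels in 111 patients); everything is reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vessels
    patterns = list(spec.pattern_mix)
    probs = np.asarray([spec.pattern_mix[p] for p in patterns])
    drawn = rng.choice(patterns, size=n, p=probs)

    n_extra = int(round(spec.multi_vessel_fraction * n))
    n_patients = max(1, n - n_extra)
    hosts = rng.choice(n_patients, size=min(n_extra, n_patients), replace=False)
    patient_of = list(range(n_patients)) + [int(h) for h in hosts]
    patient_of = patient_of[:n]

    vessel_seeds = rng.integers(0, 2**31 - 1, size=n)
    pci_seeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    for i in range(n):
        v = generate_vessel(
            str(drawn[i]),
            spec,
            int(vessel_seeds[i]),
            vessel_id=f"V{i + 1:04d}",
            patient_id=f"P{patient_of[i] + 1:04d}",
        )
        cohort.append(simulate_pci(v, spec, int(pci_seeds[i])))
    return cohort


def realized_mix(cohort: list[SyntheticVessel]) -> dict[str, int]:
    counts = {p: 0 for p in PATTERNS}
    for v in cohort:
        counts[v.true_pattern] += 1
    return counts
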