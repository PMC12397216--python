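"""Routing transforms across the anchor-age chain.

The chain stores one *backward* field per adjacent anchor pair (older →
younger). Everything else is derived: forward fields by numerical inversion,
multi-step routes by composition, and fractional steps to non-anchor ages by
linear scaling of displacements. An intermediate-age model is the weighted
average of the two bracketing templates, each warped partway toward the
intermediate age, with weights proportional to temporal proximity — e.g. a
P8 model mixes the P7 template (weight 6/7) and the P14 template (weight
1/7).

Segmentation volumes are only ever transformed *down* from the adult
(oldest) template, using backward fields alone, so label boundaries never
depend on the numerically inverted forward transforms.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field as _dcfield

import numpy as np

from .core import (
    AgeRangeError,
    ChainError,
    IntensityVolume,
    LabelVolume,
    PointSet,
    TemplateChain,
)
from .fields import compose_fields, map_points, scale_field, warp_volume, zero_field

__all__ = [
    "InterpolationPlan",
    "RouteStep",
    "TranslationRoute",
    "neighbors",
    "plan_interpolation",
    "make_intermediate_template",
    "build_route",
    "route_field",
    "translate_volume",
    "transform_segmentation",
    "translate_points",
    "compile_4d",
    "Compiled4D",
]


@dataclass(frozen=True)
class InterpolationPlan:
    """Temporal weights for synthesizing an intermediate-age model.

    ``fraction`` is ``(t - younger) / (older - younger)``; the younger
    template gets weight ``1 - fraction``, the older one ``fraction``, so
    the template closer in age always weighs more.
    """

    target_age: float
    younger: float
    older: float
    fraction: float
    weight_younger: float
    weight_older: float


@dataclass(frozen=True)
class RouteStep:
    """One pairwise hop of a route: a stored field, possibly inverted
    (direction 'forward') and/or linearly scaled (fraction < 1)."""

    pair: tuple[float, float]  # (older, younger) anchor pair holding the field
    direction: str  # 'backward' (down in age) or 'forward' (up)
    fraction: float  # portion of the pair's deformation applied
    from_age: float
    to_age: float


@dataclass(frozen=True)
class TranslationRoute:
    source_age: float
    target_age: float
    steps: tuple[RouteStep, ...]
    description: str = ""

    def __len__(self) -> int:
        return len(self.steps)


def _check_span(age: float, chain: TemplateChain) -> None:
    lo, hi = chain.span
    if not (lo <= age <= hi):
        raise AgeRangeError(
            f"age P{age} outside the chain span P{lo}–P{hi}"
        )


def neighbors(age: float, chain: TemplateChain) -> tuple[float, float]:
    """Tightest bracketing anchors ``(younger, older)``; an anchor age
    brackets itself."""
    _check_span(age, chain)
    ages = chain.anchor_ages
    if age in ages:
        return (age, age)
    i = bisect.bisect_left(ages, age)
    return (ages[i - 1], ages[i])


def plan_interpolation(age: float, chain: TemplateChain) -> InterpolationPlan:
    """Linear temporal weights for ``age`` between its bracketing anchors."""
    y, o = neighbors(age, chain)
    if y == o:  # anchor: degenerate plan, single weight 1
        return InterpolationPlan(target_age=age, younger=y, older=o,
                                 fraction=0.0, weight_younger=1.0,
                                 weight_older=0.0)
    f = (age - y) / (o - y)
    return InterpolationPlan(target_age=age, younger=y, older=o, fraction=f,
                             weight_younger=1.0 - f, weight_older=f)


def _bracket_of_pair(lo_age: float, hi_age: float,
                     chain: TemplateChain) -> tuple[float, float]:
    """The (younger, older) anchor bracket containing [lo_age, hi_age]."""
    ages = chain.anchor_ages
    y = ages[bisect.bisect_right(ages, lo_age) - 1]
    o = ages[bisect.bisect_left(ages, hi_age)]
    if y == o:  # both endpoints are the same anchor — no step needed
        raise ChainError(f"degenerate bracket at P{y}")
    return y, o


def build_route(source_age: float, target_age: float,
                chain: TemplateChain) -> TranslationRoute:
    """Sequence of pairwise steps carrying data from one age to another.

    The route passes through every anchor between the two ages; non-anchor
    endpoints contribute a single fractional step within their bracket.
    Equal ages yield an empty route.
    """
    _check_span(source_age, chain)
    _check_span(target_age, chain)
    if source_age == target_age:
        return TranslationRoute(source_age, target_age, (),
                                description="identity")

    down = target_age < source_age
    lo, hi = sorted((source_age, target_age))
    between = [a for a in chain.anchor_ages if lo < a < hi]
    knots = [source_age] + (between[::-1] if down else between) + [target_age]
    # dedupe endpoints that are themselves anchors already in `between`
    knots = [k for i, k in enumerate(knots) if i == 0 or k != knots[i - 1]]

    steps = []
    for p, q in zip(knots, knots[1:]):
        y, o = _bracket_of_pair(min(p, q), max(p, q), chain)
        frac = abs(p - q) / (o - y)
        steps.append(RouteStep(
            pair=(o, y),
            direction="backward" if q < p else "forward",
            fraction=frac,
            from_age=p,
            to_age=q,
        ))
    direction = "backward (down in age)" if down else "forward (up in age)"
    return TranslationRoute(source_age, target_age, tuple(steps),
                            description=f"{direction}, {len(steps)} step(s)")


def _step_field(step: RouteStep, chain: TemplateChain, tol: float = 0.05):
    """Materialize a RouteStep as a pull field from_age → to_age."""
    if step.direction == "backward":
        base = chain.backward_fields[step.pair]
    else:
        base = chain.forward_field(step.pair, tol=tol)
    return scale_field(base, step.fraction,
                       source=chain.space(step.from_age),
                       target=chain.space(step.to_age))


def route_field(route: TranslationRoute, chain: TemplateChain,
                tol: float = 0.05):
    """Compose a route into a single pull field (source → target space).

    Results are cached on the chain keyed by (source, target, tol) — route
    composition dominates the cost of interactive use.
    """
    if not route.steps:
        sp = chain.space(route.source_age)
        return zero_field(sp, sp.with_age(route.target_age))
    key = (route.source_age, route.target_age, tol)
    cached = chain._route_cache.get(key)
    if cached is not None:
        return cached
    composed = _step_field(route.steps[0], chain, tol)
    for step in route.steps[1:]:
        composed = compose_fields(outer=composed,
                                  inner=_step_field(step, chain, tol))
    chain._route_cache[key] = composed
    return composed


def translate_volume(
    vol: IntensityVolume | LabelVolume,
    source_age: float,
    target_age: float,
    chain: TemplateChain,
    mode: str | None = None,
) -> IntensityVolume | LabelVolume:
    """Warp a volume from ``source_age`` space into ``target_age`` space.

    Same-age translation returns the input unchanged (bit-identical).
    """
    if vol.space.age != source_age:
        raise ChainError(
            f"volume is in P{vol.space.age} space, not P{source_age}"
        )
    if source_age == target_age:
        return vol
    field = route_field(build_route(source_age, target_age, chain), chain)
    return warp_volume(vol, field, mode=mode)


def transform_segmentation(
    labels: LabelVolume, target_age: float, chain: TemplateChain
) -> LabelVolume:
    """Transform a segmentation down from the adult (oldest) anchor space.

    Segmentations travel only backwards in age, so the route uses stored
    backward fields exclusively (with a fractional terminal step for
    non-anchor target ages) and the output label set is a subset of the
    input's.
    """
    adult = chain.anchor_ages[-1]
    if labels.space.age != adult:
        raise ChainError(
            "segmentations are transformed only down from the adult "
            f"(P{adult}) template, not upward in age; got a volume in "
            f"P{labels.space.age} space"
        )
    _check_span(target_age, chain)
    if target_age == adult:
        return labels
    route = build_route(adult, target_age, chain)
    assert all(s.direction == "backward" for s in route.steps)
    field = route_field(route, chain)
    return warp_volume(labels, field, mode="nearest")


def translate_points(
    points: PointSet, source_age: float, target_age: float,
    chain: TemplateChain
) -> PointSet:
    """Map point coordinates from one age to another.

    Uses the pull-field duality: the field that resamples volumes from
    ``target_age`` into ``source_age`` maps points the opposite way,
    ``source_age`` → ``target_age``. Same-age translation is the identity.
    """
    if points.space.age != source_age:
        raise ChainError(
            f"points are in P{points.space.age} space, not P{source_age}"
        )
    if source_age == target_age:
        return points
    # volume route target→source == point route source→target
    field = route_field(build_route(target_age, source_age, chain), chain)
    return map_points(points, field)


def make_intermediate_template(age: float,
                               chain: TemplateChain) -> IntensityVolume:
    """Synthesize the model volume for an intermediate age.

    Both bracketing templates are transformed partway into the intermediate
    space — the younger via the linearly scaled forward field, the older via
    the scaled backward field — and averaged with temporal-proximity
    weights. Anchor ages return the stored template itself.
    """
    _check_span(age, chain)
    plan = plan_interpolation(age, chain)
    if plan.younger == plan.older:
        try:
            return chain.templates[age]
        except KeyError:
            raise ChainError(f"no template stored for anchor age P{age}")
    y, o, f = plan.younger, plan.older, plan.fraction
    if (o, y) not in chain.backward_fields:
        raise ChainError(f"missing backward field for bracket (P{o}, P{y})")
    try:
        t_young, t_old = chain.templates[y], chain.templates[o]
    except KeyError as e:
        raise ChainError(f"missing template for anchor age P{e.args[0]}")

    mid = chain.space(age)
    fwd = scale_field(chain.forward_field((o, y)), f,
                      source=chain.space(y), target=mid)
    bwd = scale_field(chain.backward_fields[(o, y)], 1.0 - f,
                      source=chain.space(o), target=mid)
    warped_young = warp_volume(t_young, fwd, mode="linear")
    warped_old = warp_volume(t_old, bwd, mode="linear")
    values = (plan.weight_younger * warped_young.values
              + plan.weight_older * warped_old.values)
    return IntensityVolume(space=mid, values=values)


@dataclass
class Compiled4D:
    """An ordered per-day series of volumes with provenance manifest."""

    volumes: dict[int, IntensityVolume]
    manifest: list[dict] = _dcfield(default_factory=list)

    @property
    def ages(self) -> list[int]:
        return sorted(self.volumes)

    def n_interpolated(self) -> int:
        return sum(1 for m in self.manifest if m["kind"] == "interpolated")

    def split(self, ranges: list[tuple[int, int]]) -> list["Compiled4D"]:
        """Split into contiguous subset series by inclusive age ranges."""
        out = []
        for lo, hi in ranges:
            vols = {a: v for a, v in self.volumes.items() if lo <= a <= hi}
            man = [m for m in self.manifest if lo <= m["age"] <= hi]
            out.append(Compiled4D(volumes=vols, manifest=man))
        return out


def compile_4d(
    chain: TemplateChain,
    age_range: tuple[int, int] | None = None,
    splits: list[tuple[int, int]] | None = None,
) -> Compiled4D | list[Compiled4D]:
    """One model volume per integer age: anchors verbatim, the rest
    synthesized. With ``splits``, returns contiguous subset series instead
    (the full-span atlas ships as three such subsets, P4–20 / P21–37 /
    P38–56, to keep file sizes manageable)."""
    lo, hi = age_range if age_range is not None else chain.span
    lo, hi = int(lo), int(hi)
    _check_span(lo, chain)
    _check_span(hi, chain)
    volumes: dict[int, IntensityVolume] = {}
    manifest: list[dict] = []
    for age in range(lo, hi + 1):
        is_anchor = float(age) in chain.anchor_ages
        volumes[age] = (chain.templates[float(age)] if is_anchor
                        else make_intermediate_template(float(age), chain))
        manifest.append({
            "age": age,
            "kind": "template" if is_anchor else "interpolated",
        })
    series = Compiled4D(volumes=volumes, manifest=manifest)
    if splits is not None:
        return series.split(splits)
    return series
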