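"""The multi-attribute sleep-scenario space and its narrative rendering.

A *scenario* is one imagined night of sleep, described by 17 categorical
parameters spanning five time periods (the day before, the pre-sleep period,
during sleep, upon waking, and the day after). Sixteen parameters offer three
options; wake after sleep onset (WASO) offers five, giving
``3**16 * 5 = 215,233,605`` distinct scenarios.

Level indices are **1-based** everywhere in this package: level 1 is the first
option of a parameter and acts as the reference level in the choice model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "PERIODS",
    "ParameterDef",
    "ScenarioSpace",
    "Scenario",
    "load_space",
    "canonical_space",
    "space_size",
    "render_narrative",
    "random_scenario",
]

#: Chronological order of the five time periods of a scenario.
PERIODS: tuple[str, ...] = (
    "day_before",
    "pre_sleep",
    "during_sleep",
    "upon_waking",
    "day_after",
)


@dataclass(frozen=True)
class ParameterDef:
    """One adjustable parameter of a sleep scenario.

    Parameters
    ----------
    name:
        Unique identifier, e.g. ``"total_sleep_time"``.
    period:
        One of :data:`PERIODS`.
    levels:
        Ordered option phrases; level ``i`` (1-based) is ``levels[i - 1]``.
    """

    name: str
    period: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(
                f"unknown period {self.period!r} for parameter {self.name!r}; "
                f"expected one of {PERIODS}"
            )
        if len(self.levels) < 2:
            raise ValueError(f"parameter {self.name!r} needs >= 2 levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class ScenarioSpace:
    """An ordered collection of scenario parameters."""

    parameters: tuple[ParameterDef, ...]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dupes}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(p.n_levels for p in self.parameters)

    def index_of(self, name: str) -> int:
        """0-based position of parameter ``name``."""
        return self._index[name]

    def __getitem__(self, name: str) -> ParameterDef:
        return self.parameters[self._index[name]]

    def names_in_period(self, period: str) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters if p.period == period)


@dataclass(frozen=True)
class Scenario:
    """A point of a :class:`ScenarioSpace`: one 1-based level per parameter."""

    levels: tuple[int, ...]

    def validate(self, space: ScenarioSpace) -> None:
        if len(self.levels) != space.n_parameters:
            raise ValueError(
                f"scenario has {len(self.levels)} levels; space has "
                f"{space.n_parameters} parameters"
            )
        for lv, p in zip(self.levels, space.parameters):
            if not 1 <= lv <= p.n_levels:
                raise ValueError(
                    f"level {lv} out of range 1..{p.n_levels} for {p.name!r}"
                )

    def level_of(self, name: str, space: ScenarioSpace) -> int:
        return self.levels[space.index_of(name)]


def _space_from_mapping(doc: Mapping) -> ScenarioSpace:
    try:
        raw = doc["parameters"]
    except (KeyError, TypeError):
        raise ValueError("space definition must contain a 'parameters' list")
    params = []
    for entry in raw:
        levels = entry.get("levels") or []
        if not levels:
            raise ValueError(f"parameter {entry.get('name')!r} has an empty level list")
        params.append(
            ParameterDef(
                name=str(entry["name"]),
                period=str(entry["period"]),
                levels=tuple(str(s) for s in levels),
            )
        )
    return ScenarioSpace(parameters=tuple(params))


def load_space(source: str | None = None) -> ScenarioSpace:
    """Load a scenario space from a YAML definition.

    With ``source=None`` the packaged canonical 17-parameter space is
    returned. Otherwise ``source`` is a path to (or YAML text of) a document
    with a top-level ``parameters`` list whose entries carry ``name``,
    ``period`` and ``levels``.
    """
    if source is None:
        text = (
            resources.files("sleepconjoint.data")
            .joinpath("canonical_space.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        try:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
    return _space_from_mapping(yaml.safe_load(text))


_CANONICAL: ScenarioSpace | None = None


def canonical_space() -> ScenarioSpace:
    """The packaged 17-parameter space (cached)."""
    global _CANONICAL
    if _CANONICAL is None:
        _CANONICAL = load_space(None)
    return _CANONICAL


def space_size(space: ScenarioSpace) -> int:
    """Exact number of distinct scenarios (product of level counts)."""
    return math.prod(p.n_levels for p in space.parameters)


# Per-parameter sentence templates; ``{p}`` receives the option phrase
# verbatim. The connective text is a fixed package constant patterned on the
# instrument's exemplar narrative; it is presentation, not a scientific claim.
_TEMPLATES: dict[str, str] = {
    "amount_of_activity": "During the day yesterday, {p}.",
    "day_went_well": "How did the day go? {p}.",
    "mood_day_before": "{p} yesterday.",
    "readiness_to_sleep": "When it was time for bed, {p}.",
    "cognitive_arousal": "{p} as I lay in bed.",
    "physiological_arousal": "{p} lying in bed.",
    "sleep_onset_latency": "{p} to fall asleep.",
    "wake_after_sleep_onset": "{p}.",
    "total_sleep_time": "{p}.",
    "dream": "{p}.",
    "feeling_refreshed": "This morning, {p} on waking.",
    "motivated_to_get_up": "{p} to get out of bed.",
    "alertness": "During the day, {p}.",
    "thinking": "{p}.",
    "mood_day_after": "{p}.",
    "sociability": "{p}.",
    "physical_activity": "Physically, {p} today.",
}
_DEFAULT_TEMPLATE = "{p}."


def render_narrative(
    scenario: Scenario,
    space: ScenarioSpace,
    highlight: Iterable[str] | None = None,
) -> str:
    """Render a scenario as a deterministic first-person narrative.

    Sentences follow period order (day before -> pre-sleep -> during sleep ->
    upon waking -> day after); within a period, parameter order. Every
    selected option phrase appears verbatim in the output. Parameters named in
    ``highlight`` have their phrase wrapped in ``**...**``.
    """
    scenario.validate(space)
    marked = set(highlight or ())
    sentences: list[str] = []
    for period in PERIODS:
        for p in space.parameters:
            if p.period != period:
                continue
            phrase = p.levels[scenario.level_of(p.name, space) - 1]
            if p.name in marked:
                phrase = f"**{phrase}**"
            template = _TEMPLATES.get(p.name, _DEFAULT_TEMPLATE)
            sentences.append(template.format(p=phrase))
    return " ".join(sentences)


def random_scenario(space: ScenarioSpace, rng: np.random.Generator | int) -> Scenario:
    """Draw a scenario uniformly (each parameter level independently uniform)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    levels = tuple(int(rng.integers(1, p.n_levels + 1)) for p in space.parameters)
    return Scenario(levels=levels)
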